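"""Nucleotide-resolved reaction network for GTPase membrane cycling.

The full network tracks the GTPase by compartment (membrane ``_m`` /
cytosol ``_c``), nucleotide state (GDP/GTP) and binding partner (free,
GDI-bound, effector-bound).  Reaction numbering follows the lumped loop:

* R1/R2 (optional, off by default): GDI binding at the membrane and
  membrane cycling of the GTPase·GDI complex.  In fibroblasts the apparent
  dissociation rate of Rac is GDI-independent, so these reactions are
  negligible (the ``rho_Eq = 0`` regime) and the default topology omits
  them.
* R3: cytosolic GTPase + GDI binding, nucleotide-resolved.
* R4: membrane association/dissociation of free GTPase; association is a
  single geometry-scaled first-order rate on the cytosol-volume basis,
  dissociation is nucleotide-resolved (GDP-bound Rac leaves an order of
  magnitude faster than GTP-bound).
* R5: effector binding, restricted to membrane-bound, GDI-free, GTP-loaded
  GTPase; the effector complex does not dissociate from the membrane.
* GEF (GDP -> GTP, membrane only), GAP (GTP -> GDP, membrane) and a
  cytosolic GAP activity.  GDI-bound GTPase exchanges no nucleotide.

All concentrations are µM on the cytosol-volume basis; time in seconds.
The observable of photobleaching experiments is

    k_offAp = (R4_off_D*[RhoGDP_m] + R4_off_T*[RhoGTP_m])
              / ([RhoGDP_m] + [RhoGTP_m] + [RhoGTP.Eff_m]).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "DetailedRateSet",
    "SpeciesState",
    "ConditionSpec",
    "ObservableSet",
    "ReactionNetwork",
    "Trajectory",
    "build_network",
    "simulate",
    "steady_state",
    "observables",
    "effective_membrane_gdi_kd",
    "apply_condition",
]


@dataclass(frozen=True)
class DetailedRateSet:
    """Kinetic constants of the detailed network.

    Bimolecular on-rates (R3, R5, R1) in 1/(µM·s); everything else 1/s.
    ``R4_on`` is the membrane association rate already scaled to the cell's
    surface-to-volume ratio (cytosol-volume basis).  The R1/R2 membrane-GDI
    rates default to zero (simplified fibroblast topology).
    """

    R3_on_D: float
    R3_off_D: float
    R3_on_T: float
    R3_off_T: float
    R4_on: float
    R4_off_D: float
    R4_off_T: float
    R5_on: float
    R5_off: float
    k_GEF: float
    k_GAP: float
    k_GAPc: float
    R1_on: float = 0.0
    R1_off: float = 0.0
    R2_on: float = 0.0
    R2_off: float = 0.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def K_D3_D(self) -> float:
        return self.R3_off_D / self.R3_on_D

    @property
    def K_D3_T(self) -> float:
        return self.R3_off_T / self.R3_on_T


_CORE_SPECIES = (
    "RhoGDP_m",
    "RhoGTP_m",
    "RhoGTPEff_m",
    "RhoGDP_c",
    "RhoGTP_c",
    "RhoGDPGDI_c",
    "RhoGTPGDI_c",
    "GDI",
    "Eff",
)
_MEMBRANE_GDI_SPECIES = ("RhoGDPGDI_m", "RhoGTPGDI_m")


@dataclass
class SpeciesState:
    """Concentrations (µM, cytosol-volume basis) keyed by species name."""

    conc: dict[str, float]

    def __getitem__(self, name: str) -> float:
        return self.conc.get(name, 0.0)

    @property
    def rho_total(self) -> float:
        return sum(v for k, v in self.conc.items() if k.startswith("Rho"))

    @property
    def gdi_total(self) -> float:
        return self["GDI"] + sum(
            v for k, v in self.conc.items() if "GDI" in k and k != "GDI"
        )

    @property
    def eff_total(self) -> float:
        return self["Eff"] + self["RhoGTPEff_m"]

    @property
    def membrane_rho(self) -> float:
        return sum(
            v for k, v in self.conc.items() if k.startswith("Rho") and k.endswith("_m")
        )

    @property
    def active_rho(self) -> float:
        """All GTP-loaded GTPase, membrane and cytosol, any partner."""
        return sum(v for k, v in self.conc.items() if k.startswith("RhoGTP"))


@dataclass(frozen=True)
class ConditionSpec:
    """A perturbation applied to a base model (one experimental condition)."""

    label: str
    Rho_total: float | None = None
    GDI_total: float | None = None
    Eff_total: float | None = None
    GEF_fold: float = 1.0
    mutant: str = "wild-type"  # or "constitutively-active"

    def __post_init__(self) -> None:
        if self.mutant not in ("wild-type", "constitutively-active"):
            raise ValueError(f"unknown mutant label {self.mutant!r}")


@dataclass(frozen=True)
class ObservableSet:
    """Per-condition observables of the eight-condition experiment."""

    r0: float
    active_total: float
    koffap: float | None = None
    r0_f: float | None = None


@dataclass(frozen=True)
class Reaction:
    name: str
    rate_constant: float
    reactants: tuple[int, ...]
    products: tuple[int, ...]


@dataclass
class ReactionNetwork:
    """Mass-action reaction system with conserved Rho/GDI/effector totals."""

    species: tuple[str, ...]
    reactions: list[Reaction]
    rates: DetailedRateSet
    include_membrane_gdi: bool

    def index(self, name: str) -> int:
        return self.species.index(name)

    def stoichiometry(self) -> np.ndarray:
        N = np.zeros((len(self.species), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for i in rxn.reactants:
                N[i, j] -= 1
            for i in rxn.products:
                N[i, j] += 1
        return N

    def reaction_rates(self, y: np.ndarray) -> np.ndarray:
        v = np.empty(len(self.reactions))
        for j, rxn in enumerate(self.reactions):
            r = rxn.rate_constant
            for i in rxn.reactants:
                r *= y[i]
            v[j] = r
        return v

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        return self._N @ self.reaction_rates(y)

    def __post_init__(self) -> None:
        self._N = self.stoichiometry()
        self._rho_idx = np.array(
            [i for i, s in enumerate(self.species) if s.startswith("Rho")]
        )
        self._gdi_idx = np.array(
            [i for i, s in enumerate(self.species) if "GDI" in s]
        )
        self._eff_idx = np.array(
            [i for i, s in enumerate(self.species) if "Eff" in s]
        )

    def conserved_totals(self, y: np.ndarray) -> dict[str, float]:
        return {
            "Rho": float(y[self._rho_idx].sum()),
            "GDI": float(y[self._gdi_idx].sum()),
            "Eff": float(y[self._eff_idx].sum()),
        }

    def reaction_table(self) -> pd.DataFrame:
        """Plain-text export of the mass-action reaction list."""
        rows = []
        for rxn in self.reactions:
            rows.append(
                {
                    "name": rxn.name,
                    "rate_constant": rxn.rate_constant,
                    "reactants": " + ".join(self.species[i] for i in rxn.reactants),
                    "products": " + ".join(self.species[i] for i in rxn.products),
                }
            )
        return pd.DataFrame(rows)


def build_network(
    rates: DetailedRateSet, include_membrane_gdi: bool = False
) -> ReactionNetwork:
    """Assemble the mass-action reaction list for the chosen topology.

    With ``include_membrane_gdi`` off (default) the membrane GDI reactions
    R1/R2 are absent: 7 GTPase species with GDI binding only in the cytosol
    (the topology validated for Rac in fibroblasts).  Turning the flag on
    adds the two membrane GTPase·GDI complexes and their four reactions.
    """
    species = _CORE_SPECIES + (
        _MEMBRANE_GDI_SPECIES if include_membrane_gdi else ()
    )
    if include_membrane_gdi and max(
        rates.R1_on, rates.R1_off, rates.R2_on, rates.R2_off
    ) == 0.0:
        warnings.warn(
            "membrane-GDI topology requested but all R1/R2 rates are zero",
            stacklevel=2,
        )
    ix = {s: i for i, s in enumerate(species)}
    r = rates
    rxns = [
        Reaction("GEF", r.k_GEF, (ix["RhoGDP_m"],), (ix["RhoGTP_m"],)),
        Reaction("GAP", r.k_GAP, (ix["RhoGTP_m"],), (ix["RhoGDP_m"],)),
        Reaction("GAPc", r.k_GAPc, (ix["RhoGTP_c"],), (ix["RhoGDP_c"],)),
        Reaction("R4_on_D", r.R4_on, (ix["RhoGDP_c"],), (ix["RhoGDP_m"],)),
        Reaction("R4_off_D", r.R4_off_D, (ix["RhoGDP_m"],), (ix["RhoGDP_c"],)),
        Reaction("R4_on_T", r.R4_on, (ix["RhoGTP_c"],), (ix["RhoGTP_m"],)),
        Reaction("R4_off_T", r.R4_off_T, (ix["RhoGTP_m"],), (ix["RhoGTP_c"],)),
        Reaction(
            "R3_on_D", r.R3_on_D, (ix["RhoGDP_c"], ix["GDI"]), (ix["RhoGDPGDI_c"],)
        ),
        Reaction(
            "R3_off_D", r.R3_off_D, (ix["RhoGDPGDI_c"],), (ix["RhoGDP_c"], ix["GDI"])
        ),
        Reaction(
            "R3_on_T", r.R3_on_T, (ix["RhoGTP_c"], ix["GDI"]), (ix["RhoGTPGDI_c"],)
        ),
        Reaction(
            "R3_off_T", r.R3_off_T, (ix["RhoGTPGDI_c"],), (ix["RhoGTP_c"], ix["GDI"])
        ),
        Reaction(
            "R5_on", r.R5_on, (ix["RhoGTP_m"], ix["Eff"]), (ix["RhoGTPEff_m"],)
        ),
        Reaction(
            "R5_off", r.R5_off, (ix["RhoGTPEff_m"],), (ix["RhoGTP_m"], ix["Eff"])
        ),
    ]
    if include_membrane_gdi:
        rxns += [
            Reaction(
                "R1_on_D", r.R1_on, (ix["RhoGDP_m"], ix["GDI"]), (ix["RhoGDPGDI_m"],)
            ),
            Reaction(
                "R1_off_D", r.R1_off, (ix["RhoGDPGDI_m"],), (ix["RhoGDP_m"], ix["GDI"])
            ),
            Reaction(
                "R1_on_T", r.R1_on, (ix["RhoGTP_m"], ix["GDI"]), (ix["RhoGTPGDI_m"],)
            ),
            Reaction(
                "R1_off_T", r.R1_off, (ix["RhoGTPGDI_m"],), (ix["RhoGTP_m"], ix["GDI"])
            ),
            Reaction("R2_on_D", r.R2_on, (ix["RhoGDPGDI_c"],), (ix["RhoGDPGDI_m"],)),
            Reaction("R2_off_D", r.R2_off, (ix["RhoGDPGDI_m"],), (ix["RhoGDPGDI_c"],)),
            Reaction("R2_on_T", r.R2_on, (ix["RhoGTPGDI_c"],), (ix["RhoGTPGDI_m"],)),
            Reaction("R2_off_T", r.R2_off, (ix["RhoGTPGDI_m"],), (ix["RhoGTPGDI_c"],)),
        ]
    return ReactionNetwork(
        species=species,
        reactions=rxns,
        rates=rates,
        include_membrane_gdi=include_membrane_gdi,
    )


@dataclass
class Trajectory:
    t: np.ndarray
    y: np.ndarray          # (n_species, n_times)
    species: tuple[str, ...]

    def final_state(self) -> SpeciesState:
        return SpeciesState(dict(zip(self.species, self.y[:, -1])))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y.T, columns=list(self.species))
        df.insert(0, "t", self.t)
        return df


def _initial_vector(
    network: ReactionNetwork, initial: SpeciesState | dict[str, float]
) -> np.ndarray:
    conc = initial.conc if isinstance(initial, SpeciesState) else initial
    unknown = set(conc) - set(network.species)
    if unknown:
        raise ValueError(f"unknown species: {sorted(unknown)}")
    y0 = np.array([conc.get(s, 0.0) for s in network.species], dtype=float)
    if y0.min() < 0:
        raise ValueError("initial concentrations must be non-negative")
    return y0


def simulate(
    network: ReactionNetwork,
    initial: SpeciesState | dict[str, float],
    t_end: float,
    n_out: int = 200,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate the network ODEs from an initial state.

    Conserved totals drift by less than 1e-6 relative along the trajectory
    (checked; failure raises with integrator diagnostics).
    """
    y0 = _initial_vector(network, initial)
    sol = solve_ivp(
        network.rhs,
        (0.0, t_end),
        y0,
        method="LSODA",
        t_eval=np.linspace(0.0, t_end, n_out),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    start = network.conserved_totals(y0)
    end = network.conserved_totals(sol.y[:, -1])
    for k in start:
        if start[k] > 0 and abs(end[k] - start[k]) > 1e-6 * start[k]:
            raise RuntimeError(
                f"conservation violated for {k}: {start[k]} -> {end[k]}"
            )
    return Trajectory(t=sol.t, y=sol.y, species=network.species)


def _default_guess(
    network: ReactionNetwork, totals: dict[str, float]
) -> np.ndarray:
    n_rho = len(network._rho_idx)
    y0 = np.zeros(len(network.species))
    for i in network._rho_idx:
        y0[i] = totals["Rho"] / n_rho
    bound_gdi = sum(
        y0[i] for i in network._gdi_idx if network.species[i] != "GDI"
    )
    bound_eff = y0[network.index("RhoGTPEff_m")]
    y0[network.index("GDI")] = max(totals["GDI"] - bound_gdi, 0.0)
    y0[network.index("Eff")] = max(totals["Eff"] - bound_eff, 0.0)
    if totals["GDI"] < bound_gdi or totals["Eff"] < bound_eff:
        # not enough partner to bind the uniform guess: start all-free
        y0[:] = 0.0
        y0[network.index("RhoGDP_c")] = totals["Rho"]
        y0[network.index("GDI")] = totals["GDI"]
        y0[network.index("Eff")] = totals["Eff"]
    return y0


def steady_state(
    network: ReactionNetwork,
    totals: dict[str, float],
    x0: np.ndarray | SpeciesState | None = None,
    tol: float = 1e-10,
) -> SpeciesState:
    """Steady state with conserved Rho/GDI/effector totals.

    Newton (via MINPACK hybr) on the conservation-reduced residual, seeded
    from a short integration (or from ``x0``, e.g. a previous solution when
    scanning parameters).  Falls back to long-time integration on failure.

    ``totals`` maps ``{"Rho": µM, "GDI": µM, "Eff": µM}``.
    """
    for key in ("Rho", "GDI", "Eff"):
        if key not in totals:
            raise ValueError(f"totals must include {key!r}")
    if totals["Rho"] <= 0:
        raise ValueError("total GTPase must be positive")

    if x0 is None:
        y0 = _default_guess(network, totals)
        sol = solve_ivp(
            network.rhs, (0.0, 500.0), y0, method="LSODA", rtol=1e-8, atol=1e-12
        )
        seed = sol.y[:, -1] if sol.success else y0
    else:
        seed = _initial_vector(network, x0) if not isinstance(x0, np.ndarray) else x0
        seed = np.asarray(seed, dtype=float).copy()

    omit = [network.index(s) for s in ("RhoGDP_c", "GDI", "Eff")]
    keep = [i for i in range(len(network.species)) if i not in omit]

    def residual(y: np.ndarray) -> np.ndarray:
        dy = network.rhs(0.0, y)
        cons = network.conserved_totals(y)
        return np.concatenate(
            [
                dy[keep],
                [
                    cons["Rho"] - totals["Rho"],
                    cons["GDI"] - totals["GDI"],
                    cons["Eff"] - totals["Eff"],
                ],
            ]
        )

    sol = root(residual, seed, method="hybr", tol=tol)
    y = sol.x
    ok = (
        sol.success
        and float(np.max(np.abs(residual(y)))) < 1e-8 * max(totals["Rho"], 1.0)
        and y.min() > -1e-9 * totals["Rho"]
    )
    if not ok:
        # fall back to long-time integration, then re-polish
        y0 = _default_guess(network, totals)
        traj = solve_ivp(
            network.rhs, (0.0, 2e5), y0, method="LSODA", rtol=1e-10, atol=1e-14
        )
        if not traj.success:
            raise RuntimeError(f"steady-state fallback failed: {traj.message}")
        sol = root(residual, traj.y[:, -1], method="hybr", tol=tol)
        y = sol.x
        if (
            float(np.max(np.abs(residual(y)))) > 1e-7 * max(totals["Rho"], 1.0)
            or y.min() < -1e-8 * totals["Rho"]
        ):
            raise RuntimeError(
                "steady state did not converge; max residual "
                f"{float(np.max(np.abs(residual(y)))):.3e}"
            )
    y = np.clip(y, 0.0, None)
    return SpeciesState(dict(zip(network.species, y)))


def observables(state: SpeciesState, rates: DetailedRateSet) -> ObservableSet:
    """Experimental observables of a steady state.

    ``koffap`` is the species-weighted membrane dissociation rate of the
    photobleaching experiment; ``r0`` the membrane fraction of total
    GTPase; ``active_total`` all GTP-loaded GTPase (µM).
    """
    mem_free = state["RhoGDP_m"] + state["RhoGTP_m"] + state["RhoGTPEff_m"]
    if mem_free <= 0:
        raise ValueError("no membrane-bound GTPase: k_offAp undefined")
    koffap = (
        rates.R4_off_D * state["RhoGDP_m"] + rates.R4_off_T * state["RhoGTP_m"]
    ) / mem_free
    total = state.rho_total
    return ObservableSet(
        r0=state.membrane_rho / total,
        active_total=state.active_rho,
        koffap=koffap,
        r0_f=mem_free / total,
    )


def effective_membrane_gdi_kd(K_D3: float, R4_on: float, R4_off: float) -> float:
    """Composite dissociation constant, cytosolic GDI vs. membrane GTPase.

    Thermodynamic cycle: extracting a membrane-bound GTPase with cytosolic
    GDI is equivalent to membrane dissociation followed by cytosolic GDI
    binding, so the effective constant is ``K_D3 * R4_on / R4_off`` (µM).
    With the fitted Rac constants this gives about 34 nM for GTP-loaded and
    2.5 nM for GDP-loaded Rac — one order of magnitude apart purely because
    the off-rates differ, with near-identical cytosolic affinities.
    """
    if R4_off <= 0:
        raise ValueError("R4_off must be positive")
    return K_D3 * R4_on / R4_off


def apply_condition(
    rates: DetailedRateSet,
    totals: dict[str, float],
    cond: ConditionSpec,
) -> tuple[DetailedRateSet, dict[str, float]]:
    """Apply an experimental perturbation to base rates and totals.

    GEF co-expression multiplies ``k_GEF``; GDI over/under-expression
    replaces the GDI total; the constitutively active mutant is modeled as
    hydrolysis-insensitive (``k_GAP = k_GAPc = 0``).
    """
    new_rates = rates
    if cond.GEF_fold != 1.0:
        new_rates = replace(new_rates, k_GEF=rates.k_GEF * cond.GEF_fold)
    if cond.mutant == "constitutively-active":
        new_rates = replace(new_rates, k_GAP=0.0, k_GAPc=0.0)
    new_totals = dict(totals)
    if cond.Rho_total is not None:
        new_totals["Rho"] = cond.Rho_total
    if cond.GDI_total is not None:
        new_totals["GDI"] = cond.GDI_total
    if cond.Eff_total is not None:
        new_totals["Eff"] = cond.Eff_total
    return new_rates, new_totals
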