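"""Lumped four-state model of GTPase membrane cycling with GDI.

Nucleotide and effector states are collapsed into a single lumped GTPase
species ``Rho_L`` that occupies four states arranged in a loop:

    Rho_m  <--R1L-->  Rho.GDI_m
      ^                   ^
     R4L                 R2L
      v                   v
    Rho_c  <--R3L-->  Rho.GDI_c

R1L/R3L are GDI binding at the membrane/cytosol, R2L/R4L membrane cycling of
the complex/free GTPase.  Membrane species are carried on a cytosol-volume
concentration basis (µM), so the surface-to-volume ratio of the cell scales
the membrane association rates (``scale_membrane_on_rate``).

With free GDI folded into pseudo-first-order on-rates, four non-dimensional
dissociation parameters remain; two ratios

    rho_GDI = K*_D3L / K*_D1L      (membrane localization's effect on GDI affinity)
    rho_m   = K_D4L / K_D2L        (GDI's effect on membrane affinity)

control the thermodynamics of the loop.  Detailed balance (zero net cycle
flux) requires ``rho_GDI == rho_m == rho_Eq``; then the membrane fractions
have closed forms depending only on dissociation parameters:

    r0   = (K_DGDI + rho_Eq) / (K_Dm*K_DGDI + K_Dm + K_DGDI + rho_Eq)
    r0_f =  K_DGDI           / (K_Dm*K_DGDI + K_Dm + K_DGDI + rho_Eq)

Away from detailed balance a steady state still exists but carries a net
cycle flux whose sign is fixed by the second law: clockwise (GDI-mediated
removal of GTPase from the membrane) when rho_GDI > rho_m, counterclockwise
(GDI-mediated delivery) when rho_GDI < rho_m.

Any three of {K_DGDI, K_Dm, rho_Eq, r0, r0_f} determine the remaining two
(``invert_observables``); all ten combinations reduce to linear solves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "LumpedRateSet",
    "LumpedNonDimParams",
    "CellGeometry",
    "LumpedState",
    "FluxDirection",
    "InconsistentObservablesError",
    "NonIdentifiableError",
    "scale_membrane_on_rate",
    "nondim",
    "rates_from_nondim",
    "r0_equilibrium",
    "r0f_equilibrium",
    "steady_state_general",
    "flux_direction",
    "contour_chart",
    "invert_observables",
]

_RHO_EQ_RTOL = 1e-6


class InconsistentObservablesError(ValueError):
    """The supplied observables admit no positive physical solution."""


class NonIdentifiableError(ValueError):
    """The supplied combination of observables does not pin down the rest."""


class FluxDirection(Enum):
    CLOCKWISE_REMOVAL = "clockwise-removal"
    COUNTERCLOCKWISE_DELIVERY = "counterclockwise-delivery"
    EQUILIBRIUM = "equilibrium"


@dataclass(frozen=True)
class LumpedRateSet:
    """Kinetic constants of the four-state loop.

    GDI on-rates (``k1_on``, ``k3_on``) are bimolecular, 1/(µM·s); all other
    rates are first order, 1/s.  ``k4_on`` is the geometry-scaled membrane
    association rate on the cytosol-volume basis.
    """

    k1_on: float   # membrane GTPase + GDI ->
    k1_off: float
    k2_on: float   # Rho.GDI_c -> Rho.GDI_m
    k2_off: float
    k3_on: float   # cytosolic GTPase + GDI ->
    k3_off: float
    k4_on: float   # Rho_c -> Rho_m
    k4_off: float

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class LumpedNonDimParams:
    """Non-dimensional dissociation parameters of the lumped loop.

    ``rho_Eq`` is only defined (non-None) when rho_GDI and rho_m agree to
    relative tolerance 1e-6 (detailed balance).
    """

    K_DGDI: float
    K_Dm: float
    rho_GDI: float
    rho_m: float
    rho_Eq: float | None

    def require_rho_eq(self) -> float:
        if self.rho_Eq is None:
            raise ValueError(
                "rho_Eq undefined: rho_GDI != rho_m (no detailed balance)"
            )
        return self.rho_Eq


@dataclass(frozen=True)
class CellGeometry:
    """Cell geometry for membrane-flux scaling.

    ``reference_ratio`` is the surface-to-volume ratio (1/µm) of the system
    in which the membrane association rate was measured.
    """

    surface: float
    volume: float
    reference_ratio: float

    def __post_init__(self) -> None:
        if self.surface < 0 or self.volume <= 0 or self.reference_ratio <= 0:
            raise ValueError("invalid geometry")

    @property
    def ratio(self) -> float:
        return self.surface / self.volume


@dataclass(frozen=True)
class LumpedState:
    """Steady state of the four-state loop on the cytosol-volume basis (µM)."""

    Rho_c: float
    RhoGDI_c: float
    Rho_m: float
    RhoGDI_m: float
    net_cycle_flux: float  # µM/s, positive = clockwise (removal)

    @property
    def total(self) -> float:
        return self.Rho_c + self.RhoGDI_c + self.Rho_m + self.RhoGDI_m

    @property
    def r0(self) -> float:
        return (self.Rho_m + self.RhoGDI_m) / self.total

    @property
    def r0_f(self) -> float:
        return self.Rho_m / self.total


def scale_membrane_on_rate(k4_on_ref: float, geometry: CellGeometry) -> float:
    """Rescale a membrane association rate to a new surface-to-volume ratio.

    On the cytosol-volume basis all membrane fluxes scale with Sfc/Vol, so a
    rate measured at ``reference_ratio`` becomes
    ``k4_on_ref * (Sfc/Vol) / reference_ratio``.
    """
    return k4_on_ref * geometry.ratio / geometry.reference_ratio


def nondim(rates: LumpedRateSet, GDI_free: float) -> LumpedNonDimParams:
    """Non-dimensionalize a rate set at a clamped free-GDI concentration.

    K_DGDI = k3_off / (k3_on * GDI_free); K_Dm = k4_off / k4_on;
    rho_GDI = K*_D3L/K*_D1L; rho_m = K_D4L/K_D2L.
    """
    if GDI_free <= 0:
        raise ValueError("free GDI concentration must be positive")
    for name in ("k1_on", "k2_on", "k3_on", "k4_on"):
        if getattr(rates, name) == 0:
            raise ValueError(f"zero on-rate {name}: dissociation parameter undefined")
    K_DGDI = rates.k3_off / (rates.k3_on * GDI_free)
    K_Dm = rates.k4_off / rates.k4_on
    K_D1s = rates.k1_off / (rates.k1_on * GDI_free)
    K_D2 = rates.k2_off / rates.k2_on
    rho_GDI = K_DGDI / K_D1s
    rho_m = K_Dm / K_D2
    rho_Eq = None
    if abs(rho_GDI - rho_m) <= _RHO_EQ_RTOL * abs(rho_m):
        rho_Eq = 0.5 * (rho_GDI + rho_m)
    return LumpedNonDimParams(
        K_DGDI=K_DGDI, K_Dm=K_Dm, rho_GDI=rho_GDI, rho_m=rho_m, rho_Eq=rho_Eq
    )


def rates_from_nondim(
    K_DGDI: float,
    K_Dm: float,
    rho_GDI: float,
    rho_m: float,
    GDI_free: float = 1.0,
    k_scale: float = 1.0,
) -> LumpedRateSet:
    """Construct a rate set realizing given non-dimensional parameters.

    On-rates are set to ``k_scale`` (1/s pseudo-first-order; the GDI
    bimolecular rates are k_scale/GDI_free) and off-rates follow from the
    dissociation parameters.  Used to build detailed-balance or driven rate
    sets for simulation and testing.
    """
    if min(K_DGDI, K_Dm, rho_GDI, rho_m) <= 0:
        raise ValueError("non-dimensional parameters must be positive")
    K_D1s = K_DGDI / rho_GDI
    K_D2 = K_Dm / rho_m
    return LumpedRateSet(
        k1_on=k_scale / GDI_free,
        k1_off=K_D1s * k_scale,
        k2_on=k_scale,
        k2_off=K_D2 * k_scale,
        k3_on=k_scale / GDI_free,
        k3_off=K_DGDI * k_scale,
        k4_on=k_scale,
        k4_off=K_Dm * k_scale,
    )


def _denominator(K_DGDI: float, K_Dm: float, rho_Eq: float) -> float:
    return K_Dm * K_DGDI + K_Dm + K_DGDI + rho_Eq


def r0_equilibrium(p: LumpedNonDimParams) -> float:
    """Equilibrium fraction of GTPase at the membrane (GDI-bound included)."""
    rho = p.require_rho_eq()
    return (p.K_DGDI + rho) / _denominator(p.K_DGDI, p.K_Dm, rho)


def r0f_equilibrium(p: LumpedNonDimParams) -> float:
    """Equilibrium fraction of GTPase at the membrane and free of GDI."""
    rho = p.require_rho_eq()
    return p.K_DGDI / _denominator(p.K_DGDI, p.K_Dm, rho)


def _loop_rhs(t, y, r: LumpedRateSet, gdi_free, gdi_total):
    """ODE right-hand side; species order (Rho_c, RhoGDI_c, Rho_m, RhoGDI_m)."""
    rho_c, rhogdi_c, rho_m, rhogdi_m = y
    if gdi_total is not None:
        gdi = max(gdi_total - rhogdi_c - rhogdi_m, 0.0)
    else:
        gdi = gdi_free
    j1 = r.k1_on * gdi * rho_m - r.k1_off * rhogdi_m      # Rho_m -> RhoGDI_m
    j2 = r.k2_off * rhogdi_m - r.k2_on * rhogdi_c          # RhoGDI_m -> RhoGDI_c
    j3 = r.k3_off * rhogdi_c - r.k3_on * gdi * rho_c       # RhoGDI_c -> Rho_c
    j4 = r.k4_on * rho_c - r.k4_off * rho_m                # Rho_c -> Rho_m
    return np.array([j3 - j4, j2 - j3, j4 - j1, j1 - j2])


def steady_state_general(
    rates: LumpedRateSet,
    rho_total: float,
    GDI_free: float | None = None,
    GDI_total: float | None = None,
    t_max: float = 1e7,
    rtol: float = 1e-12,
) -> LumpedState:
    """Steady state of the four-state loop without assuming detailed balance.

    GDI is either clamped at a free concentration (``GDI_free``, the
    convention of the non-dimensional charts) or explicitly conserved
    (``GDI_total``); exactly one must be given.

    The loop is linear in the GTPase species for clamped GDI, so the steady
    state is a null-space solve; for conserved GDI a time integration seeds a
    Newton polish.  The reported ``net_cycle_flux`` is the common net flux of
    the four reactions, positive clockwise (membrane removal direction
    Rho_m -> RhoGDI_m -> RhoGDI_c -> Rho_c -> Rho_m).
    """
    if rho_total <= 0:
        raise ValueError("rho_total must be positive")
    if (GDI_free is None) == (GDI_total is None):
        raise ValueError("give exactly one of GDI_free or GDI_total")

    if GDI_free is not None:
        r = rates
        g = GDI_free
        # Rate matrix of the linear system dy/dt = M y.
        M = np.array(
            [
                [-(r.k3_on * g + r.k4_on), r.k3_off, r.k4_off, 0.0],
                [r.k3_on * g, -(r.k3_off + r.k2_on), 0.0, r.k2_off],
                [r.k4_on, 0.0, -(r.k4_off + r.k1_on * g), r.k1_off],
                [0.0, r.k2_on, r.k1_on * g, -(r.k1_off + r.k2_off)],
            ]
        )
        A = np.vstack([M[:-1], np.ones(4)])
        b = np.zeros(4)
        b[-1] = rho_total
        y, *_ = np.linalg.lstsq(A, b, rcond=None)
        resid = float(np.max(np.abs(M @ y)))
        scale = max(abs(M).max() * rho_total, 1e-300)
        if resid > 1e-9 * scale or y.min() < -1e-12 * rho_total:
            raise RuntimeError(f"steady-state solve failed, residual {resid:.3e}")
        y = np.clip(y, 0.0, None)
    else:
        y0 = np.array([rho_total, 0.0, 0.0, 0.0])
        sol = solve_ivp(
            _loop_rhs,
            (0.0, t_max),
            y0,
            args=(rates, None, GDI_total),
            method="LSODA",
            rtol=rtol,
            atol=1e-14 * rho_total,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message}")
        y = sol.y[:, -1]
        deriv = _loop_rhs(0.0, y, rates, None, GDI_total)
        if np.max(np.abs(deriv)) > 1e-8 * max(rates.k4_on, 1.0) * rho_total:
            raise RuntimeError("steady state not reached within t_max")
        g = max(GDI_total - y[1] - y[3], 0.0)

    rho_c, rhogdi_c, rho_m, rhogdi_m = y
    j1 = rates.k1_on * g * rho_m - rates.k1_off * rhogdi_m
    return LumpedState(
        Rho_c=rho_c,
        RhoGDI_c=rhogdi_c,
        Rho_m=rho_m,
        RhoGDI_m=rhogdi_m,
        net_cycle_flux=j1,
    )


def flux_direction(
    rho_GDI: float, rho_m: float, rtol: float = 1e-6
) -> FluxDirection:
    """Sign of the net cycle flux from the thermodynamic driving ratio.

    The loop affinity for the clockwise direction is rho_GDI/rho_m: > 1
    drives clockwise flux (GDI-mediated removal), < 1 counterclockwise
    (GDI-mediated delivery), = 1 is detailed balance.
    """
    if rho_GDI <= 0 or rho_m <= 0:
        raise ValueError("rho_GDI and rho_m must be positive")
    if abs(rho_GDI - rho_m) <= rtol * abs(rho_m):
        return FluxDirection.EQUILIBRIUM
    return (
        FluxDirection.CLOCKWISE_REMOVAL
        if rho_GDI > rho_m
        else FluxDirection.COUNTERCLOCKWISE_DELIVERY
    )


def contour_chart(
    rho_Eq: float,
    K_DGDI_grid: np.ndarray | None = None,
    K_Dm_grid: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Equilibrium membrane-fraction surfaces over a (K_DGDI, K_Dm) grid.

    Returns a long-format table (columns K_DGDI, K_Dm, rho_Eq, r0, r0_f) and
    the iso-fraction contour levels 0.09, 0.19, ..., 0.89 used in the
    reference charts (10% steps; upper contour 9%, lowest 89%).
    """
    if K_DGDI_grid is None:
        K_DGDI_grid = np.logspace(-4, 2, 61)
    if K_Dm_grid is None:
        K_Dm_grid = np.logspace(-4, 2, 61)
    K_DGDI_grid = np.asarray(K_DGDI_grid, float)
    K_Dm_grid = np.asarray(K_Dm_grid, float)
    for grid in (K_DGDI_grid, K_Dm_grid):
        if np.log10(grid.max() / grid.min()) < 3:
            raise ValueError("grids must span at least 3 decades")
    kg, km = np.meshgrid(K_DGDI_grid, K_Dm_grid, indexing="ij")
    denom = km * kg + km + kg + rho_Eq
    table = pd.DataFrame(
        {
            "K_DGDI": kg.ravel(),
            "K_Dm": km.ravel(),
            "rho_Eq": rho_Eq,
            "r0": ((kg + rho_Eq) / denom).ravel(),
            "r0_f": (kg / denom).ravel(),
        }
    )
    levels = np.arange(0.09, 0.90, 0.10)
    return table, levels


def invert_observables(
    *,
    K_DGDI: float | None = None,
    K_Dm: float | None = None,
    rho_Eq: float | None = None,
    r0: float | None = None,
    r0_f: float | None = None,
) -> dict[str, float]:
    """Solve the equilibrium closed forms for the two unspecified quantities.

    Exactly three of the five keyword arguments must be given; returns the
    full consistent set of five.  Raises
    :class:`InconsistentObservablesError` when no positive solution exists
    (e.g. ``r0 < r0_f``) and :class:`NonIdentifiableError` when the
    combination leaves a one-parameter family (``r0 == r0_f`` with
    ``rho_Eq = 0`` given).
    """
    given = {
        k: v
        for k, v in dict(
            K_DGDI=K_DGDI, K_Dm=K_Dm, rho_Eq=rho_Eq, r0=r0, r0_f=r0_f
        ).items()
        if v is not None
    }
    if len(given) != 3:
        raise ValueError("exactly three observables must be supplied")
    for k, v in given.items():
        if k in ("r0", "r0_f"):
            if not 0.0 < v < 1.0:
                raise InconsistentObservablesError(f"{k} must lie in (0, 1)")
        elif k == "rho_Eq":
            if v < 0:
                raise InconsistentObservablesError("rho_Eq must be >= 0")
        elif v <= 0:
            raise InconsistentObservablesError(f"{k} must be positive")
    if r0 is not None and r0_f is not None and r0 < r0_f:
        raise InconsistentObservablesError("r0 < r0_f is impossible")

    K, Km, rho = K_DGDI, K_Dm, rho_Eq

    if K is not None and Km is not None and rho is not None:
        pass  # forward evaluation below
    elif r0 is not None and r0_f is not None and K is not None:
        D = K / r0_f
        rho = r0 * D - K
        Km = (D - K - rho) / (K + 1.0)
    elif r0 is not None and r0_f is not None and Km is not None:
        den = 1.0 - r0 - Km * r0_f
        if den <= 0:
            raise InconsistentObservablesError(
                "no positive solution for (r0, r0_f, K_Dm)"
            )
        D = Km / den
        rho = (r0 - r0_f) * D
        K = r0_f * D
    elif r0 is not None and r0_f is not None and rho is not None:
        if r0 == r0_f:
            if rho == 0.0:
                raise NonIdentifiableError(
                    "r0 = r0_f with rho_Eq = 0 leaves (K_DGDI, K_Dm) "
                    "underdetermined"
                )
            raise InconsistentObservablesError(
                "r0 = r0_f requires rho_Eq = 0"
            )
        D = rho / (r0 - r0_f)
        K = r0_f * D
        Km = (D - K - rho) / (K + 1.0)
    elif r0 is not None and K is not None and Km is not None:
        A = Km * K + Km + K
        rho = (r0 * A - K) / (1.0 - r0)
    elif r0 is not None and K is not None and rho is not None:
        Km = (K + rho) * (1.0 - r0) / (r0 * (K + 1.0))
    elif r0 is not None and Km is not None and rho is not None:
        den = r0 * (Km + 1.0) - 1.0
        num = rho * (1.0 - r0) - r0 * Km
        if den == 0 or num / den <= 0:
            raise InconsistentObservablesError(
                "no positive solution for (r0, K_Dm, rho_Eq)"
            )
        K = num / den
    elif r0_f is not None and K is not None and Km is not None:
        rho = K / r0_f - Km * K - Km - K
    elif r0_f is not None and K is not None and rho is not None:
        Km = (K / r0_f - K - rho) / (K + 1.0)
    elif r0_f is not None and Km is not None and rho is not None:
        den = 1.0 / r0_f - Km - 1.0
        if den <= 0:
            raise InconsistentObservablesError(
                "no positive solution for (r0_f, K_Dm, rho_Eq)"
            )
        K = (Km + rho) / den
    else:  # pragma: no cover - all combinations enumerated above
        raise AssertionError("unreachable")

    if K is None or Km is None or rho is None:
        raise AssertionError("solver failed to assign all parameters")
    if K <= 0 or Km <= 0 or rho < -1e-12:
        raise InconsistentObservablesError(
            "observables imply a non-physical (negative) parameter"
        )
    rho = max(rho, 0.0)
    D = _denominator(K, Km, rho)
    out = {
        "K_DGDI": K,
        "K_Dm": Km,
        "rho_Eq": rho,
        "r0": (K + rho) / D,
        "r0_f": K / D,
    }
    # consistency: supplied fractions must be reproduced
    for name in ("r0", "r0_f"):
        v = given.get(name)
        if v is not None and not math.isclose(out[name], v, rel_tol=1e-8):
            raise InconsistentObservablesError(
                f"supplied {name}={v} inconsistent with remaining observables"
            )
    return out
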