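"""Constrained multi-start parameter estimation for the detailed network.

The observable dataset mirrors the published eight-condition experiment:
per condition, the membrane fraction ``r0``, the apparent dissociation rate
``koffap`` (1/s) and the total active GTPase normalized to a control
condition (``active_norm``).  The misfit is a weighted sum of squared
relative residuals; active values are normalized to the anchor condition
before comparison, and missing observables are simply absent rows.

Rates span decades, so optimization runs in log10-parameter space with
bounded trust-region least squares from Latin-hypercube multistarts.  The
per-start table is retained for identifiability diagnostics: equal-misfit
starts with scattered parameters flag a non-identifiable parameterization.

Free parameters are a named subset of:

``R4_on``, ``R4_off_D``, ``R4_off_T``
    membrane association (geometry-scaled, 1/s) and nucleotide-resolved
    dissociation rates (1/s);
``K_D3_T``
    cytosolic GTPase–GDI dissociation parameter, GTP-loaded (µM); the
    GDP-loaded value is tied to it by the ``kd3_ratio`` constraint
    (K_D3_D / K_D3_T, fitted value 0.99);
``gef_gap``
    basal membrane GEF/GAP activity ratio (k_GAP held fixed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .network import (
    ConditionSpec,
    DetailedRateSet,
    apply_condition,
    build_network,
    observables,
    steady_state,
)

__all__ = [
    "ExperimentalDataset",
    "FitSpec",
    "FitResult",
    "NetworkFitter",
    "predict_dataset",
    "objective",
    "fit",
    "sensitivity_sweep",
]

_PARAM_NAMES = ("R4_on", "R4_off_D", "R4_off_T", "K_D3_T", "gef_gap")
_PENALTY = 1e3  # residual magnitude assigned when a steady state fails

OBSERVABLE_CLASSES = ("r0", "koffap", "active_norm")


@dataclass
class ExperimentalDataset:
    """Multi-condition observable table with a normalization anchor.

    ``data`` has columns ``condition``, ``observable`` (one of
    ``r0``/``koffap``/``active_norm``), ``value`` and ``weight``;
    ``conditions`` maps labels to :class:`ConditionSpec`.
    """

    data: pd.DataFrame
    conditions: dict[str, ConditionSpec]
    anchor: str = "wt"

    def __post_init__(self) -> None:
        required = {"condition", "observable", "value", "weight"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"dataset must have columns {sorted(required)}")
        if self.anchor not in self.conditions:
            raise ValueError(f"anchor condition {self.anchor!r} missing")
        bad = set(self.data["observable"]) - set(OBSERVABLE_CLASSES)
        if bad:
            raise ValueError(f"unknown observable classes: {sorted(bad)}")

    def n_points(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class FitSpec:
    """What to fit, within which bounds, from how many starts.

    ``free`` maps parameter names (see module docstring) to (lo, hi)
    bounds; everything else is taken from ``base_rates``.  ``kd3_ratio``
    is the equality constraint K_D3_D/K_D3_T.
    """

    free: dict[str, tuple[float, float]]
    base_rates: DetailedRateSet
    base_totals: dict[str, float]
    kd3_ratio: float = 0.99
    n_starts: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.free.items():
            if name not in _PARAM_NAMES:
                raise ValueError(f"unknown free parameter {name!r}")
            if not (0 < lo < hi) or not np.isfinite(hi):
                raise ValueError(f"bounds for {name} must be finite and positive")


@dataclass
class FitResult:
    """Best parameters, misfit, and the per-start diagnostic table."""

    params: dict[str, float]
    misfit: float
    starts: pd.DataFrame
    seed: int

    def is_identifiable(self, misfit_rtol: float = 0.01, param_rtol: float = 0.05) -> bool:
        """Heuristic: starts that tie on misfit must agree on parameters."""
        best = self.starts["misfit"].min()
        tied = self.starts[self.starts["misfit"] <= best * (1 + misfit_rtol) + 1e-30]
        if len(tied) < 2:
            return True
        for name in self.params:
            vals = tied[name].to_numpy()
            if np.ptp(vals) > param_rtol * np.abs(vals).mean():
                return False
        return True


def _rates_with_params(
    base: DetailedRateSet, params: dict[str, float], kd3_ratio: float
) -> DetailedRateSet:
    """Realize a parameter dict as a full rate set (constraints applied)."""
    updates: dict[str, float] = {}
    for name in ("R4_on", "R4_off_D", "R4_off_T"):
        if name in params:
            updates[name] = params[name]
    if "K_D3_T" in params:
        updates["R3_off_T"] = params["K_D3_T"] * base.R3_on_T
        updates["R3_off_D"] = kd3_ratio * params["K_D3_T"] * base.R3_on_D
    if "gef_gap" in params:
        updates["k_GEF"] = params["gef_gap"] * base.k_GAP
    return replace(base, **updates)


class _ModelEvaluator:
    """Steady-state observable predictions with per-condition warm starts."""

    def __init__(
        self,
        base_rates: DetailedRateSet,
        base_totals: dict[str, float],
        conditions: dict[str, ConditionSpec],
        anchor: str,
        include_membrane_gdi: bool = False,
    ):
        self.base_rates = base_rates
        self.base_totals = base_totals
        self.conditions = conditions
        self.anchor = anchor
        self.include_membrane_gdi = include_membrane_gdi
        self._warm: dict[str, np.ndarray] = {}

    def predict(self, params: dict[str, float], kd3_ratio: float) -> pd.DataFrame:
        rates = _rates_with_params(self.base_rates, params, kd3_ratio)
        rows = []
        order = [self.anchor] + [
            lbl for lbl in self.conditions if lbl != self.anchor
        ]
        anchor_active = None
        for label in order:
            cond = self.conditions[label]
            cond_rates, cond_totals = apply_condition(
                rates, self.base_totals, cond
            )
            net = build_network(
                cond_rates, include_membrane_gdi=self.include_membrane_gdi
            )
            state = steady_state(net, cond_totals, x0=self._warm.get(label))
            self._warm[label] = np.array(
                [state[s] for s in net.species], dtype=float
            )
            obs = observables(state, cond_rates)
            if label == self.anchor:
                anchor_active = obs.active_total
            rows.append(
                {
                    "condition": label,
                    "r0": obs.r0,
                    "koffap": obs.koffap,
                    "active_total": obs.active_total,
                }
            )
        df = pd.DataFrame(rows)
        df["active_norm"] = df["active_total"] / anchor_active
        return df


def predict_dataset(
    rates: DetailedRateSet,
    totals: dict[str, float],
    conditions: dict[str, ConditionSpec],
    anchor: str = "wt",
    include_membrane_gdi: bool = False,
) -> pd.DataFrame:
    """Model observables for every condition (wide table, one row each)."""
    ev = _ModelEvaluator(rates, totals, conditions, anchor, include_membrane_gdi)
    return ev.predict({}, kd3_ratio=1.0)


def _residuals(
    params: dict[str, float],
    dataset: ExperimentalDataset,
    evaluator: _ModelEvaluator,
    kd3_ratio: float,
) -> np.ndarray:
    try:
        pred = evaluator.predict(params, kd3_ratio).set_index("condition")
    except RuntimeError:
        return np.full(dataset.n_points(), _PENALTY)
    res = np.empty(dataset.n_points())
    for i, row in enumerate(dataset.data.itertuples(index=False)):
        model = pred.loc[row.condition, row.observable]
        res[i] = np.sqrt(row.weight) * (model - row.value) / row.value
    return res


def objective(
    params: dict[str, float],
    dataset: ExperimentalDataset,
    base_rates: DetailedRateSet,
    base_totals: dict[str, float],
    kd3_ratio: float = 0.99,
) -> float:
    """Weighted sum of squared relative residuals over all observables."""
    ev = _ModelEvaluator(
        base_rates, base_totals, dataset.conditions, dataset.anchor
    )
    return float(np.sum(_residuals(params, dataset, ev, kd3_ratio) ** 2))


def fit(dataset: ExperimentalDataset, spec: FitSpec) -> FitResult:
    """Best-of-N-starts bounded local optimization in log-parameter space.

    Deterministic given ``spec.seed``; all starts are recorded.  Raises if
    every start fails outright.
    """
    names = list(spec.free)
    lo = np.log10([spec.free[n][0] for n in names])
    hi = np.log10([spec.free[n][1] for n in names])
    if dataset.n_points() < len(names):
        raise ValueError("fewer data points than free parameters")

    sampler = qmc.LatinHypercube(d=len(names), seed=spec.seed)
    starts_u = lo + sampler.random(spec.n_starts) * (hi - lo)

    evaluator = _ModelEvaluator(
        spec.base_rates, spec.base_totals, dataset.conditions, dataset.anchor
    )

    def vec_residuals(u: np.ndarray) -> np.ndarray:
        params = {n: 10.0 ** ui for n, ui in zip(names, u)}
        return _residuals(params, dataset, evaluator, spec.kd3_ratio)

    rows = []
    best = None
    for k, u0 in enumerate(starts_u):
        try:
            sol = least_squares(
                vec_residuals,
                u0,
                bounds=(lo, hi),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
        except Exception as exc:  # noqa: BLE001 - per-start diagnostics
            rows.append({"start": k, "misfit": np.inf, "error": str(exc)})
            continue
        misfit = float(np.sum(sol.fun**2))
        row = {"start": k, "misfit": misfit, "error": ""}
        row.update({n: 10.0 ** ui for n, ui in zip(names, sol.x)})
        rows.append(row)
        if best is None or misfit < best[0]:
            best = (misfit, {n: 10.0 ** ui for n, ui in zip(names, sol.x)})
    starts = pd.DataFrame(rows)
    if best is None:
        raise RuntimeError(
            "all optimization starts failed:\n" + starts.to_string()
        )
    return FitResult(params=best[1], misfit=best[0], starts=starts, seed=spec.seed)


class NetworkFitter:
    """Estimator-style wrapper around :func:`fit`.

    ``NetworkFitter(spec).fit(dataset)`` stores the result in fitted
    attributes ``params_``, ``misfit_``, ``starts_`` and returns ``self``.
    """

    def __init__(self, spec: FitSpec):
        self.spec = spec

    def get_params(self, deep: bool = True) -> dict:
        return {"spec": self.spec}

    def set_params(self, **kwargs) -> "NetworkFitter":
        for k, v in kwargs.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, dataset: ExperimentalDataset) -> "NetworkFitter":
        result = fit(dataset, self.spec)
        self.params_ = result.params
        self.misfit_ = result.misfit
        self.starts_ = result.starts
        self.result_ = result
        return self

    def fitted_rates_(self) -> DetailedRateSet:
        if not hasattr(self, "params_"):
            raise AttributeError("fitter is not fitted")
        return _rates_with_params(
            self.spec.base_rates, self.params_, self.spec.kd3_ratio
        )


def sensitivity_sweep(
    rates: DetailedRateSet,
    totals: dict[str, float],
    axis: str,
    values: np.ndarray,
    include_membrane_gdi: bool = False,
) -> pd.DataFrame:
    """Steady-state observables along one swept input, everything else fixed.

    ``axis`` is one of ``GDI_total``, ``GEF_fold`` or ``Rho_total``;
    ``values`` the swept grid.  Returns columns ``value``, ``r0``,
    ``active_fraction``, ``koffap``.  Consecutive solves are warm-started.
    """
    if axis not in ("GDI_total", "GEF_fold", "Rho_total"):
        raise ValueError(f"unknown sweep axis {axis!r}")
    rows = []
    warm = None
    for v in np.asarray(values, dtype=float):
        cond_rates, cond_totals = rates, dict(totals)
        if axis == "GDI_total":
            cond_totals["GDI"] = v
        elif axis == "Rho_total":
            cond_totals["Rho"] = v
        else:
            cond_rates = replace(rates, k_GEF=rates.k_GEF * v)
        net = build_network(cond_rates, include_membrane_gdi=include_membrane_gdi)
        state = steady_state(net, cond_totals, x0=warm)
        warm = np.array([state[s] for s in net.species])
        obs = observables(state, cond_rates)
        rows.append(
            {
                "value": v,
                "r0": obs.r0,
                "active_fraction": obs.active_total / state.rho_total,
                "koffap": obs.koffap,
            }
        )
    return pd.DataFrame(rows)
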