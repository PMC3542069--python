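"""Synthetic observable datasets with known ground truth.

The generator emulates the structure of the published eight-condition Rac
dataset (NIH3T3 fibroblasts): wild-type or constitutively active (G12V)
GFP-Rac, each alone, with GEF (Tiam1) co-expression, with GDI
over-expression, or with GDI knockdown.  Observables per condition are the
membrane fraction ``r0``, the apparent dissociation rate ``koffap`` and
total active Rac normalized to the 'wt' control, perturbed by mean-one
lognormal multiplicative noise (all observables are positive).

The fixture parameter set is the published fitted Rac set: cytosolic Rac–GDI
dissociation parameter 1.3e-4 µM with GDP/GTP ratio 0.99, membrane
association 2.84/s (at surface-to-volume 0.524/µm), dissociation 0.15/s
(GDP) and 0.011/s (GTP), GEF/GAP 1.9 with 3.25-fold Tiam increase,
endogenous GDI 0.14 µM, GFP-Rac 0.05 µM, effector 0.5 µM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .betacell import BetaCellGeometry, BetaCellBaseline
from .fitting import ExperimentalDataset
from .network import (
    ConditionSpec,
    DetailedRateSet,
    apply_condition,
    build_network,
    observables,
    steady_state,
)

__all__ = [
    "NoiseModel",
    "GroundTruth",
    "generate_dataset",
    "nih3t3_fixture",
    "betacell_fixture",
    "NIH3T3_SURFACE_TO_VOLUME",
]

# Published fitted Rac parameters (NIH3T3)
NIH3T3_SURFACE_TO_VOLUME = 0.524  # 1/µm
_K_D3_T = 1.3e-4     # µM, cytosolic Rac(GTP)-GDI dissociation parameter
_KD3_RATIO = 0.99    # K_D3_D / K_D3_T
_R4_ON = 2.84        # 1/s at the NIH3T3 surface-to-volume ratio
_R4_OFF_D = 0.15     # 1/s
_R4_OFF_T = 0.011    # 1/s
_GEF_GAP = 1.9
_TIAM_FOLD = 3.25
_GDI_TOTAL = 0.14    # µM
_GFP_RAC = 0.05      # µM
_ENDOGENOUS_RAC = 0.05  # µM; not reported, taken equal to GFP-Rac
_EFF_TOTAL = 0.5     # µM

# Unreported auxiliary rates (do not affect steady-state observables beyond
# their ratios; see methods note): bimolecular on-rates and absolute GAP
# activity set the timescales only.
_R3_ON = 100.0       # 1/(µM·s)
_R5_ON = 10.0        # 1/(µM·s)
_K_D5 = 1.0          # µM, membrane RacGTP-effector
_K_GAP = 1.0         # 1/s
_K_GAPC = 0.05       # 1/s

# GDI over-expression and knockdown levels, relative to the endogenous
# 0.14 µM (no reported values; realistic transfection/knockdown range).
GDI_OVEREXPRESSION_FOLD = 5.0
GDI_KNOCKDOWN_FOLD = 0.25

# Observables absent from the reference dataset (two koffap, one active
# measurement were not performed; the affected conditions are a choice).
DEFAULT_MISSING = (
    ("wt+GDI", "koffap"),
    ("G12V+GDI", "koffap"),
    ("G12V-GDI", "active_norm"),
)


@dataclass(frozen=True)
class NoiseModel:
    """Mean-one lognormal multiplicative noise per observable class."""

    cv_r0: float = 0.05
    cv_koffap: float = 0.05
    cv_active: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.cv_r0, self.cv_koffap, self.cv_active) < 0:
            raise ValueError("CVs must be non-negative")

    def cv_for(self, observable: str) -> float:
        return {
            "r0": self.cv_r0,
            "koffap": self.cv_koffap,
            "active_norm": self.cv_active,
        }[observable]


@dataclass
class GroundTruth:
    """A full rate set plus base totals and the condition list."""

    rates: DetailedRateSet
    totals: dict[str, float]
    conditions: dict[str, ConditionSpec]
    anchor: str = "wt"


def _sample_factor(rng: np.random.Generator, cv: float) -> float:
    """Mean-one lognormal factor with coefficient of variation ``cv``."""
    if cv == 0.0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))


def generate_dataset(
    truth: GroundTruth,
    noise: NoiseModel,
    conditions: dict[str, ConditionSpec] | None = None,
    missing: tuple[tuple[str, str], ...] = DEFAULT_MISSING,
) -> ExperimentalDataset:
    """Noisy per-condition observables from detailed-network steady states.

    Active totals are normalized to the anchor condition *after* noise is
    applied, as in the experiment (each bar has its own measurement error).
    Reproducible given ``noise.seed``: one root seed spawns independent
    per-condition streams.
    """
    conditions = conditions if conditions is not None else truth.conditions
    if truth.anchor not in conditions:
        raise ValueError(f"anchor {truth.anchor!r} not among conditions")
    root = np.random.SeedSequence(noise.seed)
    streams = {
        label: np.random.default_rng(child)
        for label, child in zip(conditions, root.spawn(len(conditions)))
    }
    rows = []
    raw_active: dict[str, float] = {}
    for label, cond in conditions.items():
        rates, totals = apply_condition(truth.rates, truth.totals, cond)
        net = build_network(rates)
        try:
            state = steady_state(net, totals)
        except RuntimeError as exc:
            raise RuntimeError(
                f"steady-state failure for condition {label!r}: {exc}"
            ) from exc
        obs = observables(state, rates)
        rng = streams[label]
        noisy_r0 = obs.r0 * _sample_factor(rng, noise.cv_r0)
        noisy_koffap = obs.koffap * _sample_factor(rng, noise.cv_koffap)
        raw_active[label] = obs.active_total * _sample_factor(
            rng, noise.cv_active
        )
        rows.append({"condition": label, "r0": noisy_r0, "koffap": noisy_koffap})

    anchor_active = raw_active[truth.anchor]
    records = []
    for row in rows:
        label = row["condition"]
        entries = {
            "r0": row["r0"],
            "koffap": row["koffap"],
            "active_norm": raw_active[label] / anchor_active,
        }
        for obs_name, value in entries.items():
            if (label, obs_name) in missing:
                continue
            records.append(
                {
                    "condition": label,
                    "observable": obs_name,
                    "value": value,
                    "weight": 1.0,
                }
            )
    return ExperimentalDataset(
        data=pd.DataFrame(records),
        conditions=dict(conditions),
        anchor=truth.anchor,
    )


def nih3t3_rates() -> DetailedRateSet:
    """The published fitted Rac rate set (fibroblast topology)."""
    return DetailedRateSet(
        R3_on_D=_R3_ON,
        R3_off_D=_KD3_RATIO * _K_D3_T * _R3_ON,
        R3_on_T=_R3_ON,
        R3_off_T=_K_D3_T * _R3_ON,
        R4_on=_R4_ON,
        R4_off_D=_R4_OFF_D,
        R4_off_T=_R4_OFF_T,
        R5_on=_R5_ON,
        R5_off=_K_D5 * _R5_ON,
        k_GEF=_GEF_GAP * _K_GAP,
        k_GAP=_K_GAP,
        k_GAPc=_K_GAPC,
    )


def nih3t3_fixture(
    endogenous_rac: float = _ENDOGENOUS_RAC,
    gdi_over_fold: float = GDI_OVEREXPRESSION_FOLD,
    gdi_knock_fold: float = GDI_KNOCKDOWN_FOLD,
) -> GroundTruth:
    """Ground truth for the eight-condition fibroblast experiment.

    Endogenous (unlabeled) Rac is carried inside the total Rac pool, held
    constant across transfections and halved under GDI knockdown.
    """
    rho_base = _GFP_RAC + endogenous_rac
    rho_knock = _GFP_RAC + 0.5 * endogenous_rac
    gdi_over = gdi_over_fold * _GDI_TOTAL
    gdi_knock = gdi_knock_fold * _GDI_TOTAL
    conditions = {
        "wt": ConditionSpec("wt"),
        "wt+tiam": ConditionSpec("wt+tiam", GEF_fold=_TIAM_FOLD),
        "wt+GDI": ConditionSpec("wt+GDI", GDI_total=gdi_over),
        "wt-GDI": ConditionSpec(
            "wt-GDI", GDI_total=gdi_knock, Rho_total=rho_knock
        ),
        "G12V": ConditionSpec("G12V", mutant="constitutively-active"),
        "G12V+tiam": ConditionSpec(
            "G12V+tiam", GEF_fold=_TIAM_FOLD, mutant="constitutively-active"
        ),
        "G12V+GDI": ConditionSpec(
            "G12V+GDI", GDI_total=gdi_over, mutant="constitutively-active"
        ),
        "G12V-GDI": ConditionSpec(
            "G12V-GDI",
            GDI_total=gdi_knock,
            Rho_total=rho_knock,
            mutant="constitutively-active",
        ),
    }
    return GroundTruth(
        rates=nih3t3_rates(),
        totals={"Rho": rho_base, "GDI": _GDI_TOTAL, "Eff": _EFF_TOTAL},
        conditions=conditions,
    )


def betacell_fixture() -> tuple[BetaCellGeometry, BetaCellBaseline]:
    """Pancreatic β-cell geometry and pre-stimulus baseline state.

    Plasma membrane 500 µm², granule membrane 3600 µm² (10000 granules),
    cytosolic volume 850 µm³; pre-stimulus cytosolic Rac 0.11 µM, Cdc42
    0.15 µM, total GDI 0.39 µM, membrane fraction of Rac 28%.
    """
    geometry = BetaCellGeometry()
    baseline = BetaCellBaseline()
    return geometry, baseline
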