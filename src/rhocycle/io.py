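"""Configuration loading, result writing and run manifests.

Configs are JSON objects with a documented schema per stage; unknown keys
are rejected so typos fail loudly.  Every run writes a ``manifest.json``
echoing the resolved configuration, the seed and the package version, and
CSV tables carry a header comment naming the units (µM, s, µm).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__

__all__ = ["RunConfig", "load_config", "write_results", "UNITS_NOTE"]

UNITS_NOTE = "# units: concentrations uM, times s, lengths um\n"

_STAGES = {
    "polarize": {"h", "h_w", "L", "L_w", "m", "D_iff", "n_grid"},
    "koffap-chart": {"g_min", "g_max", "n_grid", "e_levels", "ratio"},
    "lumped-chart": {"rho_Eq", "kd_min", "kd_max", "n_grid"},
    "simulate": {
        "rates",
        "totals",
        "condition",
        "t_end",
        "include_membrane_gdi",
    },
    "fit": {"dataset", "free", "n_starts", "kd3_ratio"},
    "betacell": {"fold_kd_sgdi", "a", "b", "c", "cdc42_mode", "t_end"},
}


@dataclass
class RunConfig:
    """A validated stage configuration."""

    stage: str
    params: dict
    seed: int = 0
    outdir: str = "."

    def manifest(self) -> dict:
        return {
            "stage": self.stage,
            "params": self.params,
            "seed": self.seed,
            "package_version": __version__,
        }


def load_config(path: str | Path, stage: str | None = None) -> RunConfig:
    """Load and validate a JSON stage configuration.

    The file must contain ``stage`` (unless supplied here) and may contain
    ``params``, ``seed`` and ``outdir``.  Unknown top-level keys or unknown
    ``params`` keys for the stage are rejected by name.
    """
    path = Path(path)
    raw = json.loads(path.read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a JSON object")
    allowed_top = {"stage", "params", "seed", "outdir"}
    extra = set(raw) - allowed_top
    if extra:
        raise ValueError(f"unknown config keys: {sorted(extra)}")
    stage = raw.get("stage", stage)
    if stage not in _STAGES:
        raise ValueError(
            f"unknown stage {stage!r}; expected one of {sorted(_STAGES)}"
        )
    params = raw.get("params", {})
    bad = set(params) - _STAGES[stage]
    if bad:
        raise ValueError(f"unknown parameter keys for {stage!r}: {sorted(bad)}")
    return RunConfig(
        stage=stage,
        params=params,
        seed=int(raw.get("seed", 0)),
        outdir=str(raw.get("outdir", ".")),
    )


def dump_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "stage": config.stage,
                "params": config.params,
                "seed": config.seed,
                "outdir": config.outdir,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )


def write_results(
    tables: dict[str, pd.DataFrame],
    manifest: dict,
    outdir: str | Path,
) -> list[Path]:
    """Write CSV tables plus a manifest.json; returns the written paths.

    Tables are written deterministically (fixed column order, repr float
    formatting), so identical inputs produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        path = outdir / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(UNITS_NOTE)
            table.to_csv(fh, index=False, lineterminator="\n")
        written.append(path)
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(mpath)
    return written


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_results`."""
    return pd.read_csv(path, comment="#")
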