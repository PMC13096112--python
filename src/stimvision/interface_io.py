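"""File formats, run configuration, and per-patient report assembly.

CSV dialect throughout: UTF-8, comma separator, '.' decimal, header required.
Nested outputs are JSON.  Reports are plot-ready data tables (heatmap and
waterfall orderings), not rendered figures.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dwis_core import (
    DEFAULT_LAMBDA,
    DEFAULT_LAMBDA_GRID,
    ImprovementMatrix,
    LambdaSensitivityReport,
    ProgramRanking,
    WeightVector,
    clinical_view_reorder,
)
from .signal_features import ApertureTrace

logger = logging.getLogger("stimvision")

__all__ = [
    "RunConfig",
    "PatientReport",
    "read_trace_csv",
    "read_trace_json",
    "read_feature_table",
    "write_feature_table",
    "build_patient_report",
    "write_json_atomic",
]

KEY_COLUMNS = ["patient_id", "hand", "condition"]


@dataclass
class RunConfig:
    """Analysis configuration shared by the CLI subcommands."""

    baseline_label: str = "OFF"
    lam: float = DEFAULT_LAMBDA
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    bootstrap_B: int = 10_000
    permutation_iters: int = 10_000
    seed: int = 0
    catalog_path: str | None = None
    fdr_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lambda must lie in [0, 1]")
        if self.bootstrap_B < 1 or self.permutation_iters < 1:
            raise ValueError("bootstrap_B and permutation_iters must be >= 1")
        if not (0.0 < self.fdr_alpha < 1.0):
            raise ValueError("fdr_alpha must lie in (0, 1)")

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        bad = set(payload) - known
        if bad:
            raise ValueError(f"unknown config field(s): {sorted(bad)}")
        if "lambda_grid" in payload:
            payload["lambda_grid"] = tuple(payload["lambda_grid"])
        return cls(**payload)


def read_trace_csv(
    path: str, patient_id: str = "", hand: str = "right", condition: str = ""
) -> ApertureTrace:
    """Read one trial from a CSV with columns ``time_s``, ``aperture``.

    The sampling rate is inferred from the median time step.
    """
    df = pd.read_csv(path)
    for col in ("time_s", "aperture"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    dt = float(np.median(np.diff(df["time_s"].to_numpy(dtype=float))))
    if dt <= 0:
        raise ValueError(f"{path}: time_s must be strictly increasing")
    return ApertureTrace(
        samples=df["aperture"].to_numpy(dtype=float),
        sampling_rate=1.0 / dt,
        patient_id=patient_id,
        hand=hand,
        condition=condition or os.path.splitext(os.path.basename(path))[0],
    )


def read_trace_json(path: str) -> ApertureTrace:
    """Read one trial from a JSON bundle {patient_id, hand, condition, fs, samples}."""
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    for key in ("fs", "samples"):
        if key not in payload:
            raise ValueError(f"{path}: missing required field {key!r}")
    return ApertureTrace(
        samples=np.asarray(payload["samples"], dtype=float),
        sampling_rate=float(payload["fs"]),
        patient_id=str(payload.get("patient_id", "")),
        hand=str(payload.get("hand", "right")),
        condition=str(payload.get("condition", "")),
    )


def read_feature_table(path: str) -> pd.DataFrame:
    """Read a feature table CSV keyed by (patient_id, hand, condition).

    Unknown extra columns are preserved with a warning; missing cells stay
    missing.  Non-numeric feature cells raise with the offending row/column.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: no header") from exc
    for col in KEY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing key column {col!r}")
    feature_cols = [c for c in df.columns if c not in KEY_COLUMNS]
    for col in feature_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ValueError(f"{path}: non-numeric value in row {row}, column {col!r}")
        df[col] = coerced
    return df


def write_feature_table(table: pd.DataFrame, path: str) -> None:
    for col in KEY_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"feature table missing key column {col!r}")
    table.to_csv(path, index=False)


def write_json_atomic(payload: dict, path: str) -> None:
    """Write JSON via a temp file + rename so readers never see partial output."""
    directory = os.path.dirname(os.path.abspath(path))
    os.makedirs(directory, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.remove(tmp)
        raise


@dataclass
class PatientReport:
    """Plot-ready per-patient decision display.

    ``engineering_view`` keeps chronological program order; ``clinical_view``
    sorts columns by responsiveness and rows by DWIS; ``waterfall`` lists
    (program, delta-DWIS, rank) sorted best to worst with the off-baseline
    anchored at zero.
    """

    engineering_view: pd.DataFrame
    clinical_view: pd.DataFrame
    waterfall: pd.DataFrame
    best_program: str
    stable_across_lambda: bool | None
    order_meta: dict = field(default_factory=dict)
    therapy_comparison: pd.DataFrame | None = None

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        self.engineering_view.to_csv(os.path.join(out_dir, "engineering_view.csv"))
        self.clinical_view.to_csv(os.path.join(out_dir, "clinical_view.csv"))
        self.waterfall.to_csv(os.path.join(out_dir, "waterfall.csv"), index=False)
        if self.therapy_comparison is not None:
            self.therapy_comparison.to_csv(
                os.path.join(out_dir, "therapy_comparison.csv"), index=False
            )
        write_json_atomic(
            {
                "best_program": self.best_program,
                "stable_across_lambda": self.stable_across_lambda,
                **self.order_meta,
            },
            os.path.join(out_dir, "report.json"),
        )


def build_patient_report(
    matrix: ImprovementMatrix,
    ranking: ProgramRanking,
    weights: WeightVector,
    stability: LambdaSensitivityReport | None = None,
    therapy_scores: dict[str, float] | None = None,
) -> PatientReport:
    """Assemble the per-patient decision display from scoring outputs.

    Values are never mutated: both heatmap views contain the same multiset of
    cells, only the orderings differ.
    """
    engineering = matrix.to_frame()
    clinical, meta = clinical_view_reorder(matrix, ranking, weights)
    order = ranking.order
    waterfall = pd.DataFrame(
        {
            "program": [ranking.program_labels[i] for i in order],
            "delta_dwis": ranking.dwis[order],
            "rank": np.arange(1, len(order) + 1),
        }
    )
    therapy = None
    if therapy_scores is not None:
        therapy = pd.DataFrame(
            sorted(therapy_scores.items(), key=lambda kv: -kv[1]),
            columns=["condition", "dwis"],
        )
    return PatientReport(
        engineering_view=engineering,
        clinical_view=clinical,
        waterfall=waterfall,
        best_program=ranking.best_program,
        stable_across_lambda=None if stability is None else stability.stable,
        order_meta=meta,
        therapy_comparison=therapy,
    )
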