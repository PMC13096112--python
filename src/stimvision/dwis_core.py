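"""Dynamically Weighted Improvement Score (DWIS) for ranking stimulation programs.

Given per-condition kinematic feature vectors for one patient-hand session,
this module

1. forms the *improvement matrix*: oriented percent change of each feature in
   each DBS-on program relative to the patient-specific stimulation-off
   baseline (positive always = improvement),
2. quantifies per-feature *responsiveness* as the standard deviation of
   oriented improvement across programs,
3. normalizes responsiveness into patient-specific weights, optionally shrunk
   toward uniform weights over the responsive feature set by a mixing
   coefficient lambda,
4. scores each program with the weighted sum of its oriented improvements
   (the DWIS) and ranks programs; the off-baseline is anchored at zero.

The scoring machinery is feature-agnostic: it needs only the catalog's
orientation metadata, so the catalog can be swapped without touching code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .signal_features import FeatureCatalog, default_catalog

__all__ = [
    "ImprovementMatrix",
    "WeightVector",
    "ProgramRanking",
    "LambdaSensitivityReport",
    "build_improvement_matrix",
    "responsiveness",
    "dynamic_weights",
    "compute_dwis",
    "lambda_sensitivity",
    "clinical_view_reorder",
    "DEFAULT_LAMBDA",
    "DEFAULT_LAMBDA_GRID",
]

DEFAULT_LAMBDA = 0.1
DEFAULT_LAMBDA_GRID = tuple(np.round(np.arange(0.0, 0.451, 0.05), 2))

#: relative tolerance below which a baseline value is treated as zero and the
#: percent change is masked rather than reported as a huge/infinite value
BASELINE_TOL = 1e-9


@dataclass
class ImprovementMatrix:
    """Programs x features matrix of oriented percent change vs baseline.

    ``values[p, j]`` is ``orientation_sign(j) * 100 * (x_j(p) - x_j(off)) /
    |x_j(off)|``.  ``mask[p, j]`` is True for cells excluded from scoring
    (near-zero baseline denominator or missing feature value).
    """

    values: np.ndarray
    mask: np.ndarray
    program_labels: list[str]
    feature_names: list[str]
    baseline_condition: str
    excluded_features: list[str] = field(default_factory=list)

    @property
    def n_programs(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.program_labels, columns=self.feature_names)
        return df.mask(pd.DataFrame(self.mask, index=df.index, columns=df.columns))


@dataclass
class WeightVector:
    """Responsiveness-derived feature weights with shrinkage lambda."""

    responsiveness: np.ndarray
    weights: np.ndarray
    lam: float
    feature_names: list[str]
    responsive_set: np.ndarray  # boolean mask over features
    uniform_fallback: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lambda must lie in [0, 1]")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if abs(float(np.sum(self.weights)) - 1.0) > 1e-12:
            raise ValueError("weights must sum to one")


@dataclass
class ProgramRanking:
    """DWIS scores and rank order for one session.

    DWIS units are weighted percent improvement.  The off-baseline has DWIS 0
    by construction, so delta-DWIS vs OFF equals the DWIS itself.
    """

    program_labels: list[str]
    dwis: np.ndarray
    baseline_condition: str
    ties: list[tuple[str, str]] = field(default_factory=list)

    @property
    def order(self) -> np.ndarray:
        """Program indices sorted by descending DWIS (ties: earlier program)."""
        # stable sort on negated scores keeps chronological order among ties
        return np.argsort(-self.dwis, kind="stable")

    @property
    def ranks(self) -> np.ndarray:
        ranks = np.empty(len(self.dwis), dtype=int)
        ranks[self.order] = np.arange(1, len(self.dwis) + 1)
        return ranks

    @property
    def best_program(self) -> str:
        return self.program_labels[int(self.order[0])]

    @property
    def delta_top2(self) -> float:
        if len(self.dwis) < 2:
            return np.nan
        srt = self.dwis[self.order]
        return float(srt[0] - srt[1])

    @property
    def delta_top_median(self) -> float:
        srt = self.dwis[self.order]
        return float(srt[0] - np.median(srt))

    def as_dict(self) -> dict:
        return {
            "baseline": self.baseline_condition,
            "best_program": self.best_program,
            "delta_top2": self.delta_top2,
            "delta_top_median": self.delta_top_median,
            "programs": [
                {
                    "program": lbl,
                    "dwis": float(self.dwis[i]),
                    "rank": int(self.ranks[i]),
                }
                for i, lbl in enumerate(self.program_labels)
            ],
        }


def build_improvement_matrix(
    feature_table: pd.DataFrame,
    baseline_condition: str,
    catalog: FeatureCatalog | None = None,
    condition_column: str = "condition",
) -> ImprovementMatrix:
    """Oriented percent-change matrix vs the stimulation-off baseline.

    ``feature_table`` holds one row per condition for a single patient-hand
    session with a condition label column and one column per catalog feature.
    Lower-is-better features are sign-flipped so that positive cells always
    mean improvement.  Cells whose baseline magnitude is below a relative
    tolerance are masked (with a warning) rather than reported as infinite.
    """
    catalog = catalog or default_catalog()
    table = feature_table.set_index(condition_column) if condition_column in feature_table.columns else feature_table
    if baseline_condition not in table.index:
        raise ValueError(f"baseline condition {baseline_condition!r} not found")
    programs = [c for c in table.index if c != baseline_condition]
    if len(programs) == 0:
        raise ValueError("no program rows besides the baseline")
    names = catalog.names
    x = table.loc[programs, names].to_numpy(dtype=float)
    base = table.loc[baseline_condition, names].to_numpy(dtype=float)

    signs = np.array([catalog.orientation_sign(n) for n in names], dtype=float)
    scale = np.nanmax(np.abs(np.vstack([x, base[None, :]])), axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    base_ok = np.abs(base) > BASELINE_TOL * scale
    mask = ~np.isfinite(x) | ~base_ok[None, :] | ~np.isfinite(base)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        values = signs[None, :] * 100.0 * (x - base[None, :]) / np.abs(base)[None, :]
    values = np.where(mask, np.nan, values)

    excluded = [names[j] for j in range(len(names)) if mask[:, j].all()]
    if np.any(~base_ok):
        bad = [names[j] for j in np.nonzero(~base_ok)[0]]
        warnings.warn(
            f"baseline near zero for feature(s) {bad}; cells masked", stacklevel=2
        )
    return ImprovementMatrix(
        values=values,
        mask=mask,
        program_labels=[str(p) for p in programs],
        feature_names=list(names),
        baseline_condition=baseline_condition,
        excluded_features=excluded,
    )


def responsiveness(matrix: ImprovementMatrix) -> np.ndarray:
    """Per-feature sample SD of oriented improvement across programs.

    Masked cells are excluded; a feature with fewer than two usable cells
    gets responsiveness 0 (it cannot discriminate between programs).
    """
    if matrix.n_programs < 2:
        raise ValueError("responsiveness undefined for fewer than 2 programs")
    r = np.zeros(matrix.values.shape[1])
    for j in range(matrix.values.shape[1]):
        col = matrix.values[~matrix.mask[:, j], j]
        if len(col) >= 2:
            r[j] = float(np.std(col, ddof=1))
    return r


def dynamic_weights(
    r: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
    feature_names: list[str] | None = None,
) -> WeightVector:
    """Normalize responsiveness into weights, shrunk toward uniform.

    Base weights are r_j / sum(r).  With shrinkage lambda in [0, 1], weights
    blend toward the uniform distribution over the *responsive* set
    {j : r_j > 0}; non-responsive features keep weight zero.  If every r_j is
    zero the weights fall back to uniform over all features (with a warning).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("responsiveness must be non-negative")
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must lie in [0, 1]")
    names = feature_names or [f"f{j}" for j in range(len(r))]
    responsive = r > 0
    if not responsive.any():
        warnings.warn("all responsiveness values are zero; using uniform weights", stacklevel=2)
        w = np.full(len(r), 1.0 / len(r))
        return WeightVector(r, w, lam, names, np.ones(len(r), dtype=bool), uniform_fallback=True)
    base = r / r.sum()
    uniform = responsive / responsive.sum()
    w = (1.0 - lam) * base + lam * uniform
    w = w / w.sum()  # guard rounding
    return WeightVector(r, w, lam, names, responsive)


def compute_dwis(
    matrix: ImprovementMatrix,
    weights: WeightVector,
    include_baseline: bool = True,
) -> ProgramRanking:
    """Weighted sum of oriented improvements per program, ranked descending.

    For programs with masked cells the weights are renormalized over the
    unmasked features, so missing cells do not silently deflate a score.  The
    baseline condition is appended with DWIS exactly 0.
    """
    if matrix.values.size == 0:
        raise ValueError("empty improvement matrix")
    if len(weights.weights) != len(matrix.feature_names):
        raise ValueError("weight vector does not match matrix features")
    w = weights.weights
    scores = np.empty(matrix.n_programs)
    for p in range(matrix.n_programs):
        ok = ~matrix.mask[p]
        wp = w[ok]
        tot = wp.sum()
        if tot == 0:
            scores[p] = 0.0
            continue
        scores[p] = float(np.dot(wp / tot, matrix.values[p, ok]))
    labels = list(matrix.program_labels)
    if include_baseline:
        labels.append(matrix.baseline_condition)
        scores = np.append(scores, 0.0)
    ties = [
        (labels[i], labels[j])
        for i in range(len(scores))
        for j in range(i + 1, len(scores))
        if scores[i] == scores[j]
    ]
    return ProgramRanking(
        program_labels=labels,
        dwis=scores,
        baseline_condition=matrix.baseline_condition,
        ties=ties,
    )


@dataclass
class LambdaSensitivityReport:
    """Best program and full ranking per shrinkage value."""

    lambdas: list[float]
    best_programs: list[str]
    rankings: list[ProgramRanking]
    kendall_tau: list[float]

    @property
    def stable(self) -> bool:
        return len(set(self.best_programs)) == 1

    @property
    def swap_points(self) -> list[float]:
        """Lambda values where the top program differs from the previous grid point."""
        return [
            self.lambdas[i]
            for i in range(1, len(self.lambdas))
            if self.best_programs[i] != self.best_programs[i - 1]
        ]


def lambda_sensitivity(
    matrix: ImprovementMatrix,
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
) -> LambdaSensitivityReport:
    """Ranking stability across a grid of shrinkage values.

    DWIS(p; lambda) is affine in lambda, so rank changes on the grid happen
    only at crossings of two programs' score lines; the report flags whether
    the top choice is identical across the whole grid and gives Kendall's tau
    between the ranking at lambda=0 and each grid point.
    """
    r = responsiveness(matrix)
    rankings = []
    for lam in lambda_grid:
        w = dynamic_weights(r, lam, matrix.feature_names)
        rankings.append(compute_dwis(matrix, w))
    ref = rankings[0].ranks
    taus = [float(kendalltau(ref, rk.ranks).statistic) for rk in rankings]
    return LambdaSensitivityReport(
        lambdas=[float(l) for l in lambda_grid],
        best_programs=[rk.best_program for rk in rankings],
        rankings=rankings,
        kendall_tau=taus,
    )


def clinical_view_reorder(
    matrix: ImprovementMatrix,
    ranking: ProgramRanking,
    weights: WeightVector,
) -> tuple[pd.DataFrame, dict]:
    """Bedside re-ordering: columns by descending responsiveness, rows by DWIS.

    Values are unchanged; only row/column order differs from the chronological
    'engineering view'.  Returns the reordered frame and the permutations.
    """
    df = matrix.to_frame()
    col_order = np.argsort(-weights.responsiveness, kind="stable")
    prog_scores = {
        lbl: float(ranking.dwis[i]) for i, lbl in enumerate(ranking.program_labels)
    }
    row_order = np.argsort(
        [-prog_scores[lbl] for lbl in matrix.program_labels], kind="stable"
    )
    reordered = df.iloc[row_order, col_order]
    meta = {
        "row_order": [matrix.program_labels[i] for i in row_order],
        "column_order": [matrix.feature_names[j] for j in col_order],
    }
    return reordered, meta
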