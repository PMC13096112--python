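"""Cohort-level inference on optimal-program improvements.

Aggregates within-patient optimal-vs-baseline percent changes across the
cohort and runs the inferential battery: one-sample Wilcoxon signed-rank
tests of median improvement > 0 with Benjamini-Hochberg FDR correction,
nonparametric bootstrap confidence intervals for medians, DWIS polarity and
program-separation summaries, and the clinician-concordance mixed-effects
models (MDS-UPDRS item 3.5 vs delta-DWIS with a random intercept per
patient-hand, fitted by REML).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .dwis_core import ProgramRanking

__all__ = [
    "LmmEstimate",
    "wilcoxon_median_gt0",
    "bh_fdr",
    "bootstrap_median_ci",
    "cohort_summary",
    "dwis_polarity_stats",
    "separation_tests",
    "concordance_lmm",
    "per_patient_rank_correlation",
    "raw_feature_lmm",
]

FDR_ALPHA = 0.05


def _exact_signed_rank_p(x: np.ndarray) -> float:
    """Exact one-sided P(W+ >= observed) under random sign flips.

    Midranks handle tied magnitudes; doubling makes them integers, so the
    null distribution is the coefficient sequence of prod_i (1 + z^(2 r_i)),
    the standard signed-rank generating polynomial.  Equivalent to summing
    over all 2^n sign assignments.
    """
    ranks = stats.rankdata(np.abs(x))
    doubled = np.round(2 * ranks).astype(int)
    w_obs = int(np.round(doubled[x > 0].sum()))
    total = int(doubled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return float(counts[w_obs:].sum() / 2 ** len(x))


def wilcoxon_median_gt0(values) -> float:
    """One-sided p-value that the median exceeds zero.

    Zeros are discarded (Wilcoxon convention).  The exact null distribution of
    W+ (sign-flip enumeration, midranks for ties) is used up to n = 25; beyond
    that the normal approximation with continuity correction applies.

    Raises
    ------
    ValueError
        If all values are zero (degenerate sample).
    """
    x = np.asarray(values, dtype=float)
    x = x[x != 0]
    if len(x) == 0:
        raise ValueError("degenerate sample: all values are zero")
    if len(x) <= 25:
        return _exact_signed_rank_p(x)
    res = stats.wilcoxon(x, alternative="greater", method="approx", correction=True)
    return float(res.pvalue)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bootstrap_median_ci(
    values, n_boot: int = 10_000, seed: int = 0, level: float = 0.95
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the median."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("bootstrap CI needs at least 3 observations")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    medians = np.median(x[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(medians, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def cohort_summary(
    optimal_improvements: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = FDR_ALPHA,
) -> pd.DataFrame:
    """Per-feature median/IQR/CI/p/q table, sorted by median improvement.

    ``optimal_improvements`` is patients x features (oriented percent change
    at each patient's optimal program).  Features with more than 50% missing
    values are excluded with a warning; within a feature, missing values are
    dropped pairwise.
    """
    if len(optimal_improvements) < 5:
        raise ValueError("cohort summary needs at least 5 patients")
    rows = []
    dropped = []
    pvals = []
    kept = []
    for j, name in enumerate(optimal_improvements.columns):
        col = optimal_improvements[name].to_numpy(dtype=float)
        col = col[np.isfinite(col)]
        if len(col) < 0.5 * len(optimal_improvements):
            dropped.append(name)
            continue
        q1, q3 = np.percentile(col, [25, 75])
        lo, hi = bootstrap_median_ci(col, n_boot=n_boot, seed=seed + j)
        try:
            p = wilcoxon_median_gt0(col)
        except ValueError:
            p = 1.0
        pvals.append(p)
        kept.append(name)
        rows.append(
            {
                "feature": name,
                "median": float(np.median(col)),
                "iqr_lo": float(q1),
                "iqr_hi": float(q3),
                "ci_lo": lo,
                "ci_hi": hi,
                "p": p,
                "n": len(col),
            }
        )
    if dropped:
        warnings.warn(f"features excluded (>50% missing): {dropped}", stacklevel=2)
    table = pd.DataFrame(rows)
    table["q"] = bh_fdr(table["p"].to_numpy())
    table["significant"] = table["q"] < alpha
    return table.sort_values("median", ascending=False).reset_index(drop=True)


def dwis_polarity_stats(rankings: list[ProgramRanking]) -> dict:
    """Fraction of patient-program combinations with positive DWIS.

    The baseline condition (DWIS 0) is excluded.  Also reports the per-patient
    distribution of the positive fraction (median and IQR), mirroring the
    per-session therapeutic-window readout.
    """
    if not rankings:
        raise ValueError("no rankings supplied")
    n_pos = 0
    n_tot = 0
    per_patient = []
    for rk in rankings:
        scores = np.array(
            [
                rk.dwis[i]
                for i, lbl in enumerate(rk.program_labels)
                if lbl != rk.baseline_condition
            ]
        )
        n_pos += int(np.sum(scores > 0))
        n_tot += len(scores)
        per_patient.append(100.0 * np.mean(scores > 0))
    per_patient = np.array(per_patient)
    q1, q3 = np.percentile(per_patient, [25, 75])
    return {
        "n_positive": n_pos,
        "n_total": n_tot,
        "percent_positive": 100.0 * n_pos / n_tot,
        "per_patient_percent_median": float(np.median(per_patient)),
        "per_patient_percent_iqr": (float(q1), float(q3)),
    }


def separation_tests(rankings: list[ProgramRanking]) -> dict:
    """Aggregate top-vs-second and top-vs-median DWIS separations.

    Sessions with a single program are excluded with a warning.  Separations
    are tested against zero with the one-sample Wilcoxon signed-rank test.
    """
    top2, top_med = [], []
    for rk in rankings:
        n_prog = sum(1 for lbl in rk.program_labels if lbl != rk.baseline_condition)
        if n_prog < 2:
            warnings.warn("session with <2 programs excluded from separation tests", stacklevel=2)
            continue
        prog_scores = np.array(
            [
                rk.dwis[i]
                for i, lbl in enumerate(rk.program_labels)
                if lbl != rk.baseline_condition
            ]
        )
        srt = np.sort(prog_scores)[::-1]
        top2.append(float(srt[0] - srt[1]))
        top_med.append(float(srt[0] - np.median(srt)))
    if len(top2) < 5:
        raise ValueError("separation tests need at least 5 sessions with >=2 programs")
    return {
        "median_delta_top2": float(np.median(top2)),
        "p_top2": wilcoxon_median_gt0(top2),
        "median_delta_top_median": float(np.median(top_med)),
        "p_top_median": wilcoxon_median_gt0(top_med),
        "n_sessions": len(top2),
    }


@dataclass
class LmmEstimate:
    """Fixed-effect estimate from a random-intercept mixed model."""

    beta: float
    se: float
    z: float
    p: float
    ci95: tuple[float, float]
    random_intercept_var: float
    model: str
    singular: bool = False
    covariates: dict | None = None


def _fit_mixedlm(endog, exog, groups, model_tag: str, param: str) -> LmmEstimate:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = MixedLM(endog, exog, groups=groups).fit(reml=True)
    beta = float(fit.params[param])
    se = float(fit.bse[param])
    if not np.isfinite(se) or se <= 0:
        raise ValueError("mixed model fixed-effect SE is not positive")
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    var_re = float(fit.cov_re.iloc[0, 0]) if fit.cov_re.size else 0.0
    covariates = {
        name: {"beta": float(fit.params[name]), "p": float(fit.pvalues[name])}
        for name in fit.params.index
        if name not in (param, "Intercept") and not name.startswith("Group")
    }
    return LmmEstimate(
        beta=beta,
        se=se,
        z=float(z),
        p=float(p),
        ci95=(beta - 1.96 * se, beta + 1.96 * se),
        random_intercept_var=var_re,
        model=model_tag,
        singular=var_re < 1e-10,
        covariates=covariates or None,
    )


def concordance_lmm(records: pd.DataFrame, model: str = "improvement") -> LmmEstimate:
    """Clinician-concordance mixed model.

    ``records`` needs columns ``patient_hand``, ``delta_dwis``, and the
    MDS-UPDRS item 3.5 scores ``baseline_score`` and ``program_score`` (the
    improvement is baseline minus program score).  Two specifications:

    - ``improvement``: UPDRS improvement ~ delta_dwis, random intercept per
      patient-hand.
    - ``raw-score``: program score ~ delta_dwis + baseline score, random
      intercept per patient-hand (robustness to baseline scaling).
    """
    required = {"patient_hand", "delta_dwis", "baseline_score", "program_score"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"concordance records missing columns: {sorted(missing)}")
    groups = records["patient_hand"]
    if groups.nunique() < 5:
        raise ValueError("concordance model needs at least 5 patient-hand clusters")
    if records["delta_dwis"].nunique() == 1:
        raise ValueError("no fixed-effect variance: delta_dwis is constant")
    exog = pd.DataFrame({"Intercept": 1.0, "delta_dwis": records["delta_dwis"]})
    if model == "improvement":
        endog = records["baseline_score"] - records["program_score"]
        return _fit_mixedlm(endog, exog, groups, "improvement-model", "delta_dwis")
    if model == "raw-score":
        exog["baseline_score"] = records["baseline_score"]
        endog = records["program_score"]
        return _fit_mixedlm(endog, exog, groups, "raw-score-model", "delta_dwis")
    raise ValueError(f"unknown model {model!r}")


def per_patient_rank_correlation(
    rankings: list[ProgramRanking], clinical_scores: dict[int, dict[str, float]]
) -> pd.DataFrame:
    """Spearman rho between DWIS- and UPDRS-based program rankings per patient.

    ``clinical_scores[i]`` maps program label -> UPDRS improvement for the
    i-th session.  Higher DWIS and higher UPDRS improvement both mean better,
    so rho = 1 is perfect agreement.  Sessions with constant clinical scores
    get rho = NaN and are flagged.
    """
    rows = []
    for i, rk in enumerate(rankings):
        scores = clinical_scores[i]
        labels = [lbl for lbl in rk.program_labels if lbl != rk.baseline_condition]
        if len(labels) < 3:
            raise ValueError("rank correlation needs >=3 programs per session")
        dwis = [float(rk.dwis[rk.program_labels.index(lbl)]) for lbl in labels]
        clin = [scores[lbl] for lbl in labels]
        if len(set(clin)) == 1:
            rho, undefined = np.nan, True
        else:
            rho = float(stats.spearmanr(dwis, clin).statistic)
            undefined = False
        best_clin = {lbl for lbl in labels if scores[lbl] == max(clin)}
        rows.append(
            {
                "session": i,
                "spearman_rho": rho,
                "rho_undefined": undefined,
                "dwis_best": rk.best_program,
                "agreement": rk.best_program in best_clin,
            }
        )
    return pd.DataFrame(rows)


def raw_feature_lmm(long_table: pd.DataFrame, alpha: float = FDR_ALPHA) -> pd.DataFrame:
    """Per-feature condition effect on raw values, random intercept per subject.

    ``long_table`` has columns ``subject``, ``condition`` (baseline/optimal),
    ``feature``, ``value``.  For each feature a mixed model value ~ condition
    is fitted by REML; p-values are BH-FDR corrected across features.
    """
    required = {"subject", "condition", "feature", "value"}
    missing = required - set(long_table.columns)
    if missing:
        raise ValueError(f"long table missing columns: {sorted(missing)}")
    if long_table["subject"].nunique() < 2:
        raise ValueError("raw-value mixed model needs at least 2 subjects")
    conditions = sorted(long_table["condition"].unique())
    if len(conditions) != 2:
        raise ValueError("expected exactly 2 conditions (baseline, optimal)")
    treated = conditions[1] if conditions[0].lower().startswith("base") else conditions[0]
    rows = []
    for feat, sub in long_table.groupby("feature", sort=False):
        sub = sub.dropna(subset=["value"])
        exog = pd.DataFrame(
            {"Intercept": 1.0, "condition": (sub["condition"] == treated).astype(float)}
        )
        est = _fit_mixedlm(sub["value"], exog, sub["subject"], "raw-feature", "condition")
        rows.append({"feature": feat, "beta": est.beta, "se": est.se, "p": est.p})
    table = pd.DataFrame(rows)
    table["q"] = bh_fdr(table["p"].to_numpy())
    table["significant"] = table["q"] < alpha
    return table
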