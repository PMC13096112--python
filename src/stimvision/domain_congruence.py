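"""Sparse-PCA kinematic domains and cross-therapy congruence.

The per-patient optimal-vs-baseline improvement matrix (patients x features)
is distilled into a small number of sparse principal components — kinematic
"domains" such as movement speed, movement consistency, and rhythm/timing.
Two cohorts' domain structures (e.g. electrical stimulation vs levodopa) are
compared with Tucker's congruence coefficient on matched components and a
permutation test of global structural similarity.

Sparse components come from the l1-penalized dictionary-learning formulation
(scikit-learn's SparsePCA): minimize reconstruction error plus
penalty * ||loadings||_1, giving exact-zero loadings.  Because sparse
components are not orthogonal, explained variance is computed on sequentially
orthogonalized projection scores (QR), the standard adjusted-variance
convention, so variance is never double counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import SparsePCA

__all__ = [
    "LoadingMatrix",
    "CongruenceResult",
    "standardize_columns",
    "sparse_pca",
    "bootstrap_loading_ci",
    "tucker_phi",
    "congruence_matrix",
    "permutation_similarity_test",
]


@dataclass
class LoadingMatrix:
    """Sparse component loadings (features x components) with variance shares."""

    loadings: np.ndarray
    feature_names: list[str]
    explained_variance: np.ndarray  # percent of total variance per component
    cohort: str = ""
    component_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.component_labels:
            self.component_labels = [f"PC{i+1}" for i in range(self.loadings.shape[1])]

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    @property
    def cumulative_variance(self) -> np.ndarray:
        return np.cumsum(self.explained_variance)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.loadings, index=self.feature_names, columns=self.component_labels)


@dataclass
class CongruenceResult:
    """Pairwise Tucker coefficients between two cohorts' components."""

    phi_matrix: np.ndarray
    matched_pairs: list[tuple[int, int]]
    matched_phi: np.ndarray
    global_statistic: float  # mean |phi| over matched pairs
    permutation_p: float | None = None
    n_permutations: int = 0


def standardize_columns(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each column to mean 0, sample SD 1; drop constant columns."""
    if len(matrix) < 2:
        raise ValueError("standardization needs at least 2 rows")
    sd = matrix.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"constant column(s) dropped: {constant}", stacklevel=2)
        matrix = matrix.drop(columns=constant)
        sd = sd.drop(index=constant)
    return (matrix - matrix.mean()) / sd


def _orthogonalized_variance(x: np.ndarray, loadings: np.ndarray) -> np.ndarray:
    """Adjusted explained variance (percent) via QR of the projected scores."""
    scores = x @ loadings
    # zero columns would break QR-based attribution; give them zero variance
    norms = np.linalg.norm(scores, axis=0)
    keep = norms > 1e-12
    out = np.zeros(loadings.shape[1])
    if keep.any():
        _, r = np.linalg.qr(scores[:, keep])
        out[keep] = np.diag(r) ** 2 / (x.shape[0] - 1)
    total = np.sum(np.var(x, axis=0, ddof=1))
    return 100.0 * out / total


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Sign convention: the largest-magnitude loading of each component is positive."""
    out = loadings.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            out[:, j] = -col
    return out


def sparse_pca(
    matrix: pd.DataFrame | np.ndarray,
    k: int = 3,
    penalty: float = 1.0,
    seed: int = 0,
    feature_names: list[str] | None = None,
    cohort: str = "",
    standardize: bool = True,
) -> LoadingMatrix:
    """Fit k sparse components to a patients x features matrix.

    Components are ordered by (orthogonalized) explained variance, descending,
    and sign-fixed so each component's largest-magnitude loading is positive.
    ``penalty`` is the l1 coefficient; at 0 the loadings span the ordinary
    PCA subspace.

    Raises
    ------
    ValueError
        If the penalty drives every loading to exactly zero.
    """
    if isinstance(matrix, pd.DataFrame):
        feature_names = feature_names or list(matrix.columns)
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        feature_names = feature_names or [f"f{j}" for j in range(x.shape[1])]
    if x.shape[0] < k + 2:
        raise ValueError(f"need at least {k + 2} rows to fit {k} components")
    if standardize:
        frame = standardize_columns(pd.DataFrame(x, columns=feature_names))
        feature_names = list(frame.columns)
        x = frame.to_numpy()
    else:
        x = x - x.mean(axis=0)

    if penalty <= 0:
        # l1-free limit: ordinary PCA loadings
        _, _, vt = np.linalg.svd(x, full_matrices=False)
        loadings = vt[:k].T
    else:
        model = SparsePCA(n_components=k, alpha=penalty, random_state=seed, max_iter=2000)
        model.fit(x)
        loadings = model.components_.T
    if not np.any(loadings):
        raise ValueError("empty components: penalty drove all loadings to zero")
    var = _orthogonalized_variance(x, loadings)
    order = np.argsort(-var, kind="stable")
    loadings = _fix_signs(loadings[:, order])
    return LoadingMatrix(
        loadings=loadings,
        feature_names=feature_names,
        explained_variance=var[order],
        cohort=cohort,
    )


def tucker_phi(a, b) -> float:
    """Tucker's congruence coefficient between two loading vectors.

    phi = sum(a_i b_i) / sqrt(sum(a_i^2) * sum(b_i^2)); in [-1, 1], invariant
    to positive rescaling of either vector, sign-flipping one vector flips phi.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("loading vectors must have equal length")
    na, nb = np.dot(a, a), np.dot(b, b)
    if na == 0 or nb == 0:
        raise ValueError("tucker_phi undefined for a zero vector")
    return float(np.dot(a, b) / np.sqrt(na * nb))


def congruence_matrix(
    l1: LoadingMatrix, l2: LoadingMatrix, optimal_assignment: bool = False
) -> CongruenceResult:
    """Pairwise Tucker phi between two cohorts' components.

    Both matrices must share the feature set in the same order.  The matched
    diagonal pairs components by index after each cohort's own variance
    ordering; with ``optimal_assignment`` the pairing instead maximizes the
    summed |phi| (used for bootstrap alignment).  Signed phi is reported in
    the matrix; the global statistic is the mean |phi| over matched pairs.
    """
    if l1.feature_names != l2.feature_names:
        diff = set(l1.feature_names) ^ set(l2.feature_names)
        raise ValueError(f"feature sets differ (symmetric difference: {sorted(diff)})")
    k1, k2 = l1.k, l2.k
    phi = np.empty((k1, k2))
    for i in range(k1):
        for j in range(k2):
            phi[i, j] = tucker_phi(l1.loadings[:, i], l2.loadings[:, j])
    if optimal_assignment:
        rows, cols = linear_sum_assignment(-np.abs(phi))
        pairs = list(zip(rows.tolist(), cols.tolist()))
    else:
        pairs = [(i, i) for i in range(min(k1, k2))]
    matched = np.array([phi[i, j] for i, j in pairs])
    return CongruenceResult(
        phi_matrix=phi,
        matched_pairs=pairs,
        matched_phi=matched,
        global_statistic=float(np.mean(np.abs(matched))),
    )


def permutation_similarity_test(
    l1: LoadingMatrix,
    l2: LoadingMatrix,
    iters: int = 10_000,
    seed: int = 0,
    data2: pd.DataFrame | None = None,
    k: int = 3,
    penalty: float = 1.0,
) -> CongruenceResult:
    """Permutation test of global structural similarity between two cohorts.

    The observed statistic is the mean |phi| over the matched diagonal pairs.
    The null permutes the feature labels of the second cohort: when ``data2``
    (that cohort's raw patients x features matrix) is supplied, its feature
    columns are permuted and the sparse components refitted per iteration;
    otherwise the rows of the second loading matrix are permuted directly
    (refit-free, exploiting the permutation equivariance of the fit).  The
    p-value uses the add-one convention (1 + #{null >= observed}) / (1 + iters).
    """
    if iters < 100:
        warnings.warn(f"{iters} permutations gives an unstable p-value", stacklevel=2)
    rng = np.random.default_rng(seed)
    observed = congruence_matrix(l1, l2)
    n_features = len(l2.feature_names)
    count = 0
    for _ in range(iters):
        perm = rng.permutation(n_features)
        if data2 is not None:
            cols = [data2.columns[i] for i in perm]
            shuffled = data2[cols]
            shuffled.columns = list(data2.columns)
            l2_null = sparse_pca(
                shuffled, k=k, penalty=penalty, seed=seed, cohort=l2.cohort
            )
            null_loadings = l2_null.loadings
        else:
            null_loadings = l2.loadings[perm, :]
        null_matched = [
            tucker_phi(l1.loadings[:, i], null_loadings[:, j])
            for i, j in observed.matched_pairs
        ]
        if np.mean(np.abs(null_matched)) >= observed.global_statistic:
            count += 1
    p = (1 + count) / (1 + iters)
    return CongruenceResult(
        phi_matrix=observed.phi_matrix,
        matched_pairs=observed.matched_pairs,
        matched_phi=observed.matched_phi,
        global_statistic=observed.global_statistic,
        permutation_p=float(p),
        n_permutations=iters,
    )


def bootstrap_loading_ci(
    matrix: pd.DataFrame,
    k: int = 3,
    penalty: float = 1.0,
    n_boot: int = 10_000,
    seed: int = 0,
    level: float = 0.95,
    standardize: bool = True,
) -> tuple[LoadingMatrix, pd.DataFrame]:
    """Patient-level bootstrap CIs for every component loading.

    Patients (rows) are resampled with replacement; each refit is aligned to
    the point estimate by the |phi|-maximizing assignment with sign
    correction before the percentile interval is formed.  Resamples with too
    few distinct patients to fit are skipped and counted.
    """
    point = sparse_pca(matrix, k=k, penalty=penalty, seed=seed, standardize=standardize)
    rng = np.random.default_rng(seed)
    n = len(matrix)
    reps = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(idx)) < k + 2:
            skipped += 1
            continue
        sample = matrix.iloc[idx]
        try:
            fit = sparse_pca(sample, k=k, penalty=penalty, seed=seed, standardize=standardize)
        except ValueError:
            skipped += 1
            continue
        if fit.feature_names != point.feature_names:
            skipped += 1  # constant column dropped in this resample
            continue
        aligned = np.zeros_like(point.loadings)
        cong = congruence_matrix(point, fit, optimal_assignment=True)
        for (i, j), phi in zip(cong.matched_pairs, cong.matched_phi):
            aligned[:, i] = np.sign(phi if phi != 0 else 1.0) * fit.loadings[:, j]
        reps.append(aligned)
    if not reps:
        raise ValueError("all bootstrap resamples were skipped")
    stack = np.stack(reps)
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(stack, alpha, axis=0)
    hi = np.quantile(stack, 1.0 - alpha, axis=0)
    rows = []
    for jf, feat in enumerate(point.feature_names):
        for jc, comp in enumerate(point.component_labels):
            rows.append(
                {
                    "feature": feat,
                    "component": comp,
                    "loading": point.loadings[jf, jc],
                    "ci_lo": lo[jf, jc],
                    "ci_hi": hi[jf, jc],
                }
            )
    ci = pd.DataFrame(rows)
    ci.attrs["n_boot_used"] = len(reps)
    ci.attrs["n_boot_skipped"] = skipped
    return point, ci
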