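"""DWIS scoring core against a hand-expanded brute-force oracle."""

import math

import numpy as np
import pandas as pd
import pytest

from stimvision import (
    build_improvement_matrix,
    compute_dwis,
    clinical_view_reorder,
    default_catalog,
    dynamic_weights,
    lambda_sensitivity,
    responsiveness,
)
from stimvision.dwis_core import ImprovementMatrix
from stimvision.signal_features import CatalogEntry, FeatureCatalog


def two_feature_catalog():
    return FeatureCatalog(
        [
            CatalogEntry("up", "speed", "higher_better", "up"),
            CatalogEntry("down", "variability", "lower_better", "down"),
        ]
    )


def session_table(rows: dict[str, tuple[float, float]]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"condition": c, "up": v[0], "down": v[1]} for c, v in rows.items()]
    )


# --------------------------------------------------------------------------
# brute force oracle: every sum expanded with explicit loops
# --------------------------------------------------------------------------


def brute_force_dwis(values, mask, lam):
    """Independent re-derivation of responsiveness, weights, and DWIS."""
    n_prog, n_feat = len(values), len(values[0])
    r = []
    for j in range(n_feat):
        col = [values[p][j] for p in range(n_prog) if not mask[p][j]]
        if len(col) < 2:
            r.append(0.0)
            continue
        m = sum(col) / len(col)
        r.append(math.sqrt(sum((x - m) ** 2 for x in col) / (len(col) - 1)))
    total_r = sum(r)
    responsive = [j for j in range(n_feat) if r[j] > 0]
    w = []
    for j in range(n_feat):
        base = r[j] / total_r
        uni = 1.0 / len(responsive) if j in responsive else 0.0
        w.append((1 - lam) * base + lam * uni)
    scores = []
    for p in range(n_prog):
        num = den = 0.0
        for j in range(n_feat):
            if not mask[p][j]:
                num += w[j] * values[p][j]
                den += w[j]
        scores.append(num / den if den > 0 else 0.0)
    return w, scores


def random_instance(rng, n_prog=5, n_feat=5):
    values = rng.normal(0, 30, size=(n_prog, n_feat))
    mask = rng.random((n_prog, n_feat)) < 0.1
    # keep at least 2 unmasked per feature so responsiveness is defined
    for j in range(n_feat):
        if mask[:, j].sum() > n_prog - 2:
            mask[:2, j] = False
    return ImprovementMatrix(
        values=np.where(mask, np.nan, values),
        mask=mask,
        program_labels=[f"Pr{p}" for p in range(n_prog)],
        feature_names=[f"f{j}" for j in range(n_feat)],
        baseline_condition="OFF",
    )


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for i in range(200):
            m = random_instance(rng)
            lam = float(rng.uniform(0, 1))
            r = responsiveness(m)
            w = dynamic_weights(r, lam, m.feature_names)
            rk = compute_dwis(m, w, include_baseline=False)
            w_bf, scores_bf = brute_force_dwis(m.values.tolist(), m.mask.tolist(), lam)
            assert np.allclose(w.weights, w_bf, atol=1e-10)
            assert np.allclose(rk.dwis, scores_bf, atol=1e-8)
            assert list(rk.order) == list(np.argsort(-np.asarray(scores_bf), kind="stable"))


class TestImprovementMatrix:
    def test_higher_better_percent_change(self):
        table = session_table({"OFF": (10.0, 2.0), "Pr1": (13.0, 1.5)})
        m = build_improvement_matrix(table, "OFF", two_feature_catalog())
        assert m.values[0, 0] == pytest.approx(30.0)

    def test_lower_better_orientation_flip(self):
        table = session_table({"OFF": (10.0, 2.0), "Pr1": (13.0, 1.5)})
        m = build_improvement_matrix(table, "OFF", two_feature_catalog())
        # raw change -25% on a lower-is-better feature -> +25% improvement
        assert m.values[0, 1] == pytest.approx(25.0)

    def test_zero_baseline_masked_with_warning(self):
        table = session_table({"OFF": (0.0, 2.0), "Pr1": (13.0, 1.5)})
        with pytest.warns(UserWarning, match="baseline near zero"):
            m = build_improvement_matrix(table, "OFF", two_feature_catalog())
        assert m.mask[0, 0]
        assert "up" in m.excluded_features

    def test_missing_baseline_raises(self):
        table = session_table({"Pr1": (13.0, 1.5)})
        with pytest.raises(ValueError, match="baseline"):
            build_improvement_matrix(table, "OFF", two_feature_catalog())

    def test_scale_invariance_of_raw_features(self):
        """Multiplying a raw feature column by c > 0 changes nothing downstream."""
        t1 = session_table({"OFF": (10.0, 2.0), "Pr1": (13.0, 1.5), "Pr2": (8.0, 2.4)})
        t2 = t1.copy()
        t2["up"] = 7.3 * t2["up"]
        m1 = build_improvement_matrix(t1, "OFF", two_feature_catalog())
        m2 = build_improvement_matrix(t2, "OFF", two_feature_catalog())
        assert np.allclose(m1.values, m2.values)


class TestResponsivenessAndWeights:
    def test_textbook_sample_sd(self):
        m = ImprovementMatrix(
            values=np.array([[10.0], [20.0], [30.0]]),
            mask=np.zeros((3, 1), bool),
            program_labels=["a", "b", "c"],
            feature_names=["f"],
            baseline_condition="OFF",
        )
        assert responsiveness(m)[0] == pytest.approx(10.0)

    def test_masked_entry_excluded_from_sd(self):
        mask = np.array([[False], [True], [False]])
        m = ImprovementMatrix(
            values=np.where(mask, np.nan, np.array([[10.0], [20.0], [30.0]])),
            mask=mask,
            program_labels=["a", "b", "c"],
            feature_names=["f"],
            baseline_condition="OFF",
        )
        assert responsiveness(m)[0] == pytest.approx(np.sqrt(200.0))  # SD of [10, 30]

    def test_single_program_raises(self):
        m = ImprovementMatrix(
            values=np.array([[10.0]]),
            mask=np.zeros((1, 1), bool),
            program_labels=["a"],
            feature_names=["f"],
            baseline_condition="OFF",
        )
        with pytest.raises(ValueError, match="responsiveness undefined"):
            responsiveness(m)

    @pytest.mark.parametrize(
        "lam,expected",
        [(0.0, [0.25, 0.75]), (0.1, [0.275, 0.725]), (1.0, [0.5, 0.5])],
    )
    def test_shrinkage_formula(self, lam, expected):
        w = dynamic_weights(np.array([10.0, 30.0]), lam)
        assert np.allclose(w.weights, expected)

    def test_weights_sum_to_one_across_lambda(self):
        rng = np.random.default_rng(7)
        r = rng.uniform(0, 50, size=23)
        r[rng.random(23) < 0.3] = 0.0
        for lam in np.linspace(0, 1, 21):
            w = dynamic_weights(r, lam)
            assert abs(w.weights.sum() - 1.0) < 1e-12
            assert np.all(w.weights >= 0)
            assert np.all(w.weights[~w.responsive_set] == 0)

    def test_all_zero_responsiveness_uniform_fallback(self):
        with pytest.warns(UserWarning, match="uniform"):
            w = dynamic_weights(np.zeros(4), 0.2)
        assert w.uniform_fallback
        assert np.allclose(w.weights, 0.25)


class TestDwisRanking:
    def test_weighted_sum_example(self):
        m = ImprovementMatrix(
            values=np.array([[40.0, -20.0], [10.0, 10.0]]),
            mask=np.zeros((2, 2), bool),
            program_labels=["Pr1", "Pr2"],
            feature_names=["a", "b"],
            baseline_condition="OFF",
        )
        w = dynamic_weights(np.array([1.0, 3.0]), 0.0, ["a", "b"])  # weights .25/.75
        rk = compute_dwis(m, w)
        assert rk.dwis[0] == pytest.approx(-5.0)

    def test_baseline_anchored_at_zero(self):
        table = session_table({"OFF": (10.0, 2.0), "Pr1": (13.0, 1.5), "Pr2": (9.0, 2.5)})
        m = build_improvement_matrix(table, "OFF", two_feature_catalog())
        w = dynamic_weights(responsiveness(m), 0.1, m.feature_names)
        rk = compute_dwis(m, w)
        off = rk.program_labels.index("OFF")
        assert rk.dwis[off] == 0.0

    def test_rank_and_separation_metrics(self):
        m = ImprovementMatrix(
            values=np.array([[2.0], [1.5], [0.3]]),
            mask=np.zeros((3, 1), bool),
            program_labels=["Pr1", "Pr2", "Pr3"],
            feature_names=["f"],
            baseline_condition="OFF",
        )
        w = dynamic_weights(np.array([1.0]), 0.0, ["f"])
        rk = compute_dwis(m, w, include_baseline=False)
        assert list(rk.ranks) == [1, 2, 3]
        assert rk.delta_top2 == pytest.approx(0.5)
        assert rk.best_program == "Pr1"
        assert rk.delta_top2 >= 0
        assert sorted(rk.ranks) == [1, 2, 3]

    def test_empty_matrix_raises(self):
        m = ImprovementMatrix(
            values=np.empty((0, 0)),
            mask=np.empty((0, 0), bool),
            program_labels=[],
            feature_names=[],
            baseline_condition="OFF",
        )
        with pytest.raises(ValueError, match="empty"):
            compute_dwis(m, dynamic_weights(np.array([1.0]), 0.0))


class TestLambdaSensitivity:
    def test_dominant_program_stable_across_grid(self):
        values = np.vstack([np.full(4, 50.0), np.full(4, 10.0), np.full(4, -5.0)])
        values += np.random.default_rng(0).normal(0, 1, values.shape)
        m = ImprovementMatrix(
            values=values,
            mask=np.zeros_like(values, bool),
            program_labels=["Pr1", "Pr2", "Pr3"],
            feature_names=list("abcd"),
            baseline_condition="OFF",
        )
        rep = lambda_sensitivity(m)
        assert rep.stable
        assert all(t == 1.0 for t in rep.kendall_tau)

    def test_single_point_grid_degenerates(self):
        values = np.array([[30.0, 5.0], [10.0, 20.0]])
        m = ImprovementMatrix(
            values=values,
            mask=np.zeros_like(values, bool),
            program_labels=["Pr1", "Pr2"],
            feature_names=["a", "b"],
            baseline_condition="OFF",
        )
        rep = lambda_sensitivity(m, lambda_grid=(0.0,))
        assert rep.stable and len(rep.rankings) == 1

    def test_constructed_crossing_flagged(self):
        """Two programs whose DWIS(lambda) lines cross inside the grid.

        With features a, b, responsiveness r = (r_a, r_b) fixed by a third
        program, DWIS_p(lambda) is affine in lambda; choosing improvements so
        the lines cross near lambda = 0.3 must flip the top rank there.
        """
        # r derived from columns: a has much larger spread than b
        values = np.array(
            [
                [60.0, 0.0],   # Pr1: wins at low lambda (weight on a)
                [30.0, 28.0],  # Pr2: wins when weights even out
                [0.0, 8.0],    # Pr3: pins responsiveness
            ]
        )
        m = ImprovementMatrix(
            values=values,
            mask=np.zeros_like(values, bool),
            program_labels=["Pr1", "Pr2", "Pr3"],
            feature_names=["a", "b"],
            baseline_condition="OFF",
        )
        # brute-force dense-lambda scan as the oracle for the crossing
        r = responsiveness(m)
        crossings = []
        dense = np.linspace(0, 0.45, 1000)
        tops = []
        for lam in dense:
            w = dynamic_weights(r, float(lam), m.feature_names)
            tops.append(compute_dwis(m, w, include_baseline=False).best_program)
        for i in range(1, len(tops)):
            if tops[i] != tops[i - 1]:
                crossings.append(dense[i])
        rep = lambda_sensitivity(m)
        if crossings:
            assert not rep.stable
            assert rep.swap_points
            assert min(abs(s - crossings[0]) for s in rep.swap_points) <= 0.05
        else:
            assert rep.stable


class TestClinicalViewReorder:
    def _setup(self, values):
        m = ImprovementMatrix(
            values=np.asarray(values, float),
            mask=np.zeros_like(np.asarray(values), dtype=bool),
            program_labels=[f"Pr{i}" for i in range(len(values))],
            feature_names=[f"f{j}" for j in range(len(values[0]))],
            baseline_condition="OFF",
        )
        w = dynamic_weights(responsiveness(m), 0.0, m.feature_names)
        rk = compute_dwis(m, w, include_baseline=False)
        return m, rk, w

    def test_value_multiset_preserved(self):
        rng = np.random.default_rng(5)
        m, rk, w = self._setup(rng.normal(0, 20, (4, 5)))
        reordered, _ = clinical_view_reorder(m, rk, w)
        assert sorted(reordered.to_numpy().ravel()) == pytest.approx(
            sorted(m.values.ravel())
        )

    def test_rows_sorted_by_dwis_columns_by_responsiveness(self):
        rng = np.random.default_rng(6)
        m, rk, w = self._setup(rng.normal(0, 20, (5, 4)))
        reordered, meta = clinical_view_reorder(m, rk, w)
        row_scores = [
            rk.dwis[m.program_labels.index(lbl)] for lbl in meta["row_order"]
        ]
        assert row_scores == sorted(row_scores, reverse=True)
        col_r = [
            w.responsiveness[m.feature_names.index(f)] for f in meta["column_order"]
        ]
        assert col_r == sorted(col_r, reverse=True)
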