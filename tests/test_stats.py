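"""Group statistics: ANOVA/t-test oracles, Bonferroni rules, compact letters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mycophen import stats


class TestSummarize:
    def test_hand_computed(self):
        s = stats.summarize({"g": [1, 2, 3]})
        assert s.loc["g", "mean"] == 2.0
        assert s.loc["g", "sd"] == 1.0
        assert s.loc["g", "n"] == 3

    def test_single_value_warns(self):
        with pytest.warns(UserWarning, match="single"):
            s = stats.summarize({"g": [5.0]})
        assert s.loc["g", "sd"] == 0.0

    def test_constant_group(self):
        assert stats.summarize({"g": [4, 4, 4]}).loc["g", "sd"] == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            stats.summarize({"g": []})


class TestAnova:
    def test_fixture_hand_decomposition(self):
        res = stats.one_way_anova({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert res.F == pytest.approx(13.5, abs=1e-12)
        assert res.p == pytest.approx(float(sps.f.sf(13.5, 1, 4)), abs=1e-12)
        assert res.p == pytest.approx(0.0213, abs=5e-4)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(7)
        groups = {f"g{i}": rng.normal(i * 0.3, 1.0, 25) for i in range(4)}
        res = stats.one_way_anova(groups)
        ref = sps.f_oneway(*groups.values())
        assert res.F == pytest.approx(float(ref.statistic), abs=1e-8)
        assert res.p == pytest.approx(float(ref.pvalue), abs=1e-8)

    def test_identical_groups(self):
        res = stats.one_way_anova({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.F == 0.0 and res.p == 1.0

    def test_all_values_identical_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            stats.one_way_anova({"a": [2, 2], "b": [2, 2]})

    def test_zero_within_variance_unequal_means(self):
        with pytest.warns(UserWarning, match="zero within-group"):
            res = stats.one_way_anova({"a": [1, 1], "b": [2, 2]})
        assert res.p == 0.0 and np.isinf(res.F)

    def test_affine_invariance_of_F(self):
        """F is unchanged by y -> a*y + b, the reason radius and growth-speed
        rows share one F value when timepoints are fixed."""
        rng = np.random.default_rng(11)
        groups = {f"g{i}": rng.normal(i, 1.0, 20) for i in range(3)}
        transformed = {k: 3.7 * v - 12.0 for k, v in groups.items()}
        assert stats.one_way_anova(transformed).F == pytest.approx(
            stats.one_way_anova(groups).F, rel=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            stats.one_way_anova({"a": [1, 2, 3]})


class TestBonferroni:
    def test_pair_count_and_symmetry(self):
        rng = np.random.default_rng(2)
        groups = {f"g{i}": rng.normal(0, 1, 10) for i in range(4)}
        mat = stats.bonferroni_pairwise(groups)
        off_diag = mat.values[~np.eye(4, dtype=bool)]
        assert np.isfinite(off_diag).all()
        assert np.isnan(np.diag(mat.values)).all()
        assert np.allclose(mat.values, mat.values.T, equal_nan=True)

    def test_multiplication_rule_against_reference(self):
        rng = np.random.default_rng(3)
        groups = {f"g{i}": rng.normal(i * 0.5, 1, 12) for i in range(4)}
        mat = stats.bonferroni_pairwise(groups)
        raw = float(sps.ttest_ind(groups["g0"], groups["g1"]).pvalue)
        assert mat.loc["g0", "g1"] == pytest.approx(min(1.0, raw * 6), abs=1e-12)

    def test_capped_at_one(self):
        rng = np.random.default_rng(4)
        groups = {f"g{i}": rng.normal(0, 1, 8) for i in range(4)}
        assert (stats.bonferroni_pairwise(groups).values[~np.eye(4, dtype=bool)] <= 1).all()

    def test_welch_differs_under_unequal_variance(self):
        rng = np.random.default_rng(5)
        groups = {"a": rng.normal(0, 0.5, 10), "b": rng.normal(1, 5.0, 30)}
        pooled = stats.bonferroni_pairwise(groups, method="pooled").loc["a", "b"]
        welch = stats.bonferroni_pairwise(groups, method="welch").loc["a", "b"]
        assert pooled != welch


def _pmat(names, sig_pairs):
    """Adjusted-p matrix: 0.001 for significant pairs, 0.9 otherwise."""
    k = len(names)
    mat = pd.DataFrame(np.full((k, k), 0.9), index=names, columns=names)
    np.fill_diagonal(mat.values, np.nan)
    for a, b in sig_pairs:
        mat.loc[a, b] = mat.loc[b, a] = 0.001
    return mat


class TestCompactLetters:
    def test_full_separation(self):
        names = ["w", "x", "y", "z"]
        means = {"w": 4, "x": 3, "y": 2, "z": 1}
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
        letters = stats.compact_letters(_pmat(names, pairs), means=means)
        assert letters == {"w": "a", "x": "b", "y": "c", "z": "d"}

    def test_no_separation(self):
        letters = stats.compact_letters(_pmat(["a", "b", "c"], []))
        assert set(letters.values()) == {"a"}

    def test_single_significant_pair_pattern(self):
        """Largest vs smallest differ; middle groups bridge both letters."""
        names = ["X2-N", "X2-5", "X2-14", "X2-T"]
        means = {"X2-N": 0.80, "X2-5": 0.81, "X2-14": 0.93, "X2-T": 0.65}
        letters = stats.compact_letters(_pmat(names, [("X2-14", "X2-T")]), means=means)
        assert letters["X2-14"] == "a"
        assert letters["X2-T"] == "b"
        assert letters["X2-N"] == "ab" and letters["X2-5"] == "ab"

    def test_round_trip_reproduces_significance_relation(self):
        """Groups share a letter iff their adjusted p is above alpha."""
        rng = np.random.default_rng(13)
        names = [f"g{i}" for i in range(6)]
        for _ in range(25):
            k = len(names)
            p = rng.random((k, k))
            p = (p + p.T) / 2
            np.fill_diagonal(p, np.nan)
            mat = pd.DataFrame(p, index=names, columns=names)
            means = {g: float(rng.normal()) for g in names}
            letters = stats.compact_letters(mat, alpha=0.5, means=means)
            for i in range(k):
                for j in range(i + 1, k):
                    share = bool(set(letters[names[i]]) & set(letters[names[j]]))
                    assert share == (mat.iloc[i, j] >= 0.5)

    def test_malformed_matrix_rejected(self):
        bad = pd.DataFrame(np.zeros((2, 3)))
        with pytest.raises(ValueError, match="square"):
            stats.compact_letters(bad)


class TestMakeTable:
    @staticmethod
    def _df(rng, n=12):
        rows = []
        for gi, g in enumerate(["g1", "g2", "g3", "g4"]):
            for _ in range(n):
                rows.append({"group": g,
                             **{f"f{j}": rng.normal(gi * (j + 1), 1.0)
                                for j in range(10)}})
        return pd.DataFrame(rows)

    def test_shape_and_determinism(self):
        df = self._df(np.random.default_rng(17))
        t1 = stats.make_table(df, "group")
        t2 = stats.make_table(df, "group")
        assert t1.shape == (10, 6)  # 4 group columns + F + p
        pd.testing.assert_frame_equal(t1, t2)

    def test_small_p_floored(self):
        rng = np.random.default_rng(19)
        df = pd.DataFrame({"group": ["a"] * 10 + ["b"] * 10,
                           "f": np.r_[rng.normal(0, 1, 10), rng.normal(30, 1, 10)]})
        table = stats.make_table(df, "group")
        assert table.loc["f", "p"] == "<0.001"

    def test_missing_group_labels_rejected(self):
        df = pd.DataFrame({"group": ["a", None], "f": [1.0, 2.0]})
        with pytest.raises(ValueError, match="missing group"):
            stats.make_table(df, "group")
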