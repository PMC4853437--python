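import numpy as np
import pandas as pd
import pytest

from socspat import (
    attribute_matrices,
    homoscedasticity_report,
    mantel,
    mrqap_dsp,
    perm_pearson,
    perm_ttest,
    variance_partition,
)


def _sym(rng, n):
    m = rng.normal(size=(n, n))
    m = np.triu(m, 1)
    m = m + m.T
    return m


class TestPermPearson:
    def test_perfect_line_minimal_p(self):
        x = np.arange(10.0)
        r, p = perm_pearson(x, 2 * x + 1, "greater", n_perm=199, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200)

    def test_wrong_tail_near_one(self):
        x = np.arange(10.0)
        _, p = perm_pearson(x, -x, "greater", n_perm=199, seed=0)
        assert p == pytest.approx(1.0)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            perm_pearson([1, 1, 1], [1, 2, 3])

    def test_two_sided_symmetric(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r1, p1 = perm_pearson(x, y, "two-sided", n_perm=499, seed=5)
        r2, p2 = perm_pearson(x, -y, "two-sided", n_perm=499, seed=5)
        assert r1 == pytest.approx(-r2)
        assert p1 == p2


class TestPermTtest:
    def test_identical_groups(self):
        vals = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        labels = ["a"] * 3 + ["b"] * 3
        t, p = perm_ttest(vals, labels, "greater", n_perm=199, seed=0)
        assert t == pytest.approx(0.0)
        assert p > 0.4

    def test_complete_separation_minimal_p(self):
        vals = [5.0, 6.0, 7.0, 1.0, 2.0, 3.0]
        labels = ["a"] * 3 + ["b"] * 3
        _, p = perm_ttest(vals, labels, "greater", n_perm=199, seed=0)
        # only label arrangements reproducing the separation beat it
        assert p < 0.06

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            perm_ttest([1.0, 2.0], ["a", "a"])


class TestAttributeMatrices:
    def _individuals(self):
        return pd.DataFrame(
            {
                "id": ["a", "b", "c"],
                "sex": ["F", "M", "F"],
                "age": [5.0, 8.0, 8.0],
                "matriline": ["m1", "m1", None],
            }
        )

    def test_distances_and_binaries(self):
        mds = pd.Series([1.0, 0.0, -1.0], index=["a", "b", "c"])
        out = attribute_matrices(self._individuals(), mds)
        assert out["age_dist"].loc["a", "b"] == 3.0
        assert out["mds_dist"].loc["a", "c"] == 2.0
        assert out["sex_same"].loc["a", "c"] == 1.0
        assert out["sex_same"].loc["a", "b"] == 0.0
        assert out["kinship"].loc["a", "b"] == 1.0

    def test_missing_matriline_is_singleton(self):
        mds = pd.Series([0.0, 0.0, 0.0], index=["a", "b", "c"])
        out = attribute_matrices(self._individuals(), mds)
        assert out["singleton_matrilines"] == ["c"]
        assert out["kinship"].loc["c", "a"] == 0.0
        assert out["kinship"].loc["c", "b"] == 0.0


class TestMantel:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(2)
        a = _sym(rng, 8)
        r, p = mantel(a, a, "greater", n_perm=199, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200)

    def test_negated_matrix(self):
        rng = np.random.default_rng(3)
        a = _sym(rng, 8)
        r, _ = mantel(a, -a, n_perm=99, seed=0)
        assert r == pytest.approx(-1.0)

    def test_constant_matrix_errors(self):
        with pytest.raises(ValueError):
            mantel(np.ones((4, 4)), np.ones((4, 4)))

    def test_matches_skbio(self):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(4)
        a, b = np.abs(_sym(rng, 10)), np.abs(_sym(rng, 10))
        np.fill_diagonal(a, 0)
        np.fill_diagonal(b, 0)
        r_ours, p_ours = mantel(a, b, "two-sided", n_perm=9999, seed=1)
        r_ref, p_ref, _ = skbio_dist.mantel(
            skbio_dist.DistanceMatrix(a), skbio_dist.DistanceMatrix(b),
            permutations=9999, alternative="two-sided",
        )
        assert r_ours == pytest.approx(r_ref)
        assert p_ours == pytest.approx(p_ref, abs=0.02)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        a, b = _sym(rng, 7), _sym(rng, 7)
        perm = rng.permutation(7)
        r1, _ = mantel(a, b, n_perm=9, seed=0)
        r2, _ = mantel(a[np.ix_(perm, perm)], b[np.ix_(perm, perm)], n_perm=9, seed=0)
        assert r1 == pytest.approx(r2)


class TestMrqapDsp:
    def test_single_predictor_reduces_to_qap(self):
        rng = np.random.default_rng(6)
        y, x = _sym(rng, 8), _sym(rng, 8)
        res = mrqap_dsp(y, {"x": x}, n_perm=499, seed=3)
        r_m, p_m = mantel(y, x, "two-sided", n_perm=499, seed=3)
        assert res.terms.loc["x", "partial_r"] == pytest.approx(r_m)
        assert res.terms.loc["x", "p"] == pytest.approx(p_m)

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(7)
        x1, x2 = _sym(rng, 12), _sym(rng, 12)
        noise = _sym(rng, 12) * 0.3
        y = 2.0 * x1 + noise
        res = mrqap_dsp(y, {"x1": x1, "x2": x2}, n_perm=499, seed=4)
        assert res.terms.loc["x1", "p"] < 0.01
        assert res.terms.loc["x2", "p"] > 0.05
        assert res.terms.loc["x1", "beta"] == pytest.approx(2.0, abs=0.1)

    def test_collinear_predictor_named(self):
        rng = np.random.default_rng(8)
        x = _sym(rng, 6)
        with pytest.raises(ValueError, match="collinear predictor set"):
            mrqap_dsp(_sym(rng, 6), {"x": x, "x_copy": 2 * x}, n_perm=9, seed=0)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(9)
        y, x1, x2 = _sym(rng, 7), _sym(rng, 7), _sym(rng, 7)
        perm = rng.permutation(7)
        r1 = mrqap_dsp(y, {"a": x1, "b": x2}, n_perm=9, seed=0)
        r2 = mrqap_dsp(
            y[np.ix_(perm, perm)],
            {"a": x1[np.ix_(perm, perm)], "b": x2[np.ix_(perm, perm)]},
            n_perm=9,
            seed=0,
        )
        for term in ("a", "b"):
            assert r1.terms.loc[term, "beta"] == pytest.approx(r2.terms.loc[term, "beta"])


class TestVariancePartition:
    def test_saturated_continuous_signal(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=40)
        labels = rng.choice(list("abc"), size=40)
        y = 3.0 * x
        res = variance_partition(y, x, labels, n_perm=199, seed=0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.terms.loc["continuous", "semipartial_r2"] > 0.9
        assert res.terms.loc["categorical", "semipartial_r2"] == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_blocks_decompose(self):
        # balanced design: group indicator orthogonal to the within-group x
        labels = np.array(["a", "b"] * 20)
        x = np.tile([1.0, -1.0, -1.0, 1.0], 10)
        rng = np.random.default_rng(11)
        y = 1.5 * x + 2.0 * (labels == "a") + rng.normal(0, 0.1, 40)
        res = variance_partition(y, x, labels, n_perm=99, seed=0)
        total = (
            res.terms["semipartial_r2"].sum()
        )
        assert total == pytest.approx(res.r_squared, abs=0.01)

    def test_seven_levels_df_six(self):
        rng = np.random.default_rng(12)
        labels = np.repeat([f"g{k}" for k in range(7)], 5)
        y = rng.normal(size=35)
        x = rng.normal(size=35)
        res = variance_partition(y, x, labels, n_perm=49, seed=0)
        assert res.terms.loc["categorical", "df"] == 6
        assert res.terms.loc["continuous", "df"] == 1

    def test_overparameterised_errors(self):
        with pytest.raises(ValueError):
            variance_partition([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], ["a", "b", "c"])

    def test_singleton_level_flagged(self):
        rng = np.random.default_rng(13)
        labels = ["a"] * 10 + ["b"] * 10 + ["c"]
        y, x = rng.normal(size=21), rng.normal(size=21)
        res = variance_partition(y, x, labels, n_perm=49, seed=0)
        assert res.terms.attrs["singleton_levels"] == ["c"]

    def test_residual_mode_available(self):
        rng = np.random.default_rng(14)
        y, x = rng.normal(size=30), rng.normal(size=30)
        labels = rng.choice(["a", "b", "c"], size=30)
        res = variance_partition(y, x, labels, n_perm=99, seed=1, permute="residuals")
        assert 0 <= res.terms.loc["continuous", "p"] <= 1


class TestPermutationPvalueContract:
    """p in [1/(n_perm+1), 1], reproducible under a fixed seed."""

    def test_bounds_and_reproducibility(self):
        rng = np.random.default_rng(15)
        x, y = rng.normal(size=12), rng.normal(size=12)
        for _ in range(2):
            results = [
                perm_pearson(x, y, n_perm=99, seed=7)[1],
                perm_ttest(y, ["a"] * 6 + ["b"] * 6, n_perm=99, seed=7)[1],
                mantel(_sym(rng, 6), _sym(rng, 6), n_perm=99, seed=7)[1],
            ]
            for p in results:
                assert 1 / 100 <= p <= 1.0
        again = perm_pearson(x, y, n_perm=99, seed=7)[1]
        assert again == results[0]


def test_homoscedasticity_report_keys():
    rng = np.random.default_rng(16)
    y = rng.normal(size=30)
    x = rng.normal(size=30)
    labels = rng.choice(["a", "b", "c"], size=30)
    out = homoscedasticity_report(y, x, labels)
    assert set(out) == {
        "breusch_pagan_stat", "breusch_pagan_p", "bartlett_stat", "bartlett_p"
    }
    assert all(np.isfinite(v) for v in out.values())
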