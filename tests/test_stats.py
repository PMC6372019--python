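"""Statistical battery against closed-form and permutation oracles."""

import numpy as np
import pytest
from oracles import pearson_formula
from scipy import stats as sps

from cytoconn.stats import (
    anova1,
    bh_fdr,
    bin_distances,
    edge_distance,
    hemisphere_split,
    ols,
    partial_corr,
    pearson_test,
    posthoc_ttests,
    residualize,
    ttest2,
)


class TestTtest2:
    def test_identical_samples_give_zero_t(self):
        r = ttest2([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)
        assert r.df == 4

    def test_matches_direct_formula_oracle(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([4.0, 5.0, 6.0])
        r = ttest2(x, y)
        sp2 = ((2) * x.var(ddof=1) + (2) * y.var(ddof=1)) / 4
        t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        p = 2 * sps.t.sf(abs(t), 4)
        assert r.statistic == pytest.approx(t, abs=1e-10)
        assert r.p == pytest.approx(p, abs=1e-10)

    def test_swapping_samples_negates_t(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 10), rng.normal(1, 1, 12)
        a, b = ttest2(x, y), ttest2(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p == pytest.approx(b.p)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ttest2([1.0, 1.0], [2.0, 2.0])


class TestPearsonTest:
    def test_perfect_linear_association(self):
        x = np.arange(10.0)
        r = pearson_test(x, 2 * x + 1)
        assert r.statistic == pytest.approx(1.0)

    def test_orthogonal_vectors_give_zero_r(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, -1.0, 0.0, 1.0])
        r = pearson_test(x, y)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        y = 0.45 * x + rng.normal(size=20)
        res = pearson_test(x, y)
        n_perm = 100_000
        perms = np.stack([rng.permutation(y) for _ in range(n_perm)])
        xc = x - x.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        r_perm = (pc @ xc) / np.sqrt((xc**2).sum() * (pc**2).sum(axis=1))
        p_mc = (np.sum(np.abs(r_perm) >= abs(res.statistic)) + 1) / (n_perm + 1)
        assert res.p == pytest.approx(p_mc, abs=0.01)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_test(np.ones(5), np.arange(5.0))


class TestPartialCorr:
    def test_no_covariates_reduces_to_pearson(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=15), rng.normal(size=15)
        assert partial_corr(x, y).statistic == pytest.approx(
            pearson_test(x, y).statistic
        )

    def test_degenerate_outcome_equal_to_covariate_rejected(self):
        rng = np.random.default_rng(3)
        c = rng.normal(size=20)
        x = rng.normal(size=20)
        with pytest.raises(ValueError, match="residuals constant"):
            partial_corr(x, c.copy(), covariates=c)

    def test_matches_recursive_formula_oracle(self):
        rng = np.random.default_rng(4)
        x, y, c = rng.normal(size=(3, 30))
        rho = partial_corr(x, y, covariates=c).statistic
        rxy = pearson_formula(x, y)
        rxc = pearson_formula(x, c)
        ryc = pearson_formula(y, c)
        expected = (rxy - rxc * ryc) / np.sqrt((1 - rxc**2) * (1 - ryc**2))
        assert rho == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        x, y = rng.normal(size=(2, 30))
        C = rng.normal(size=(30, 2))
        df = pd.DataFrame({"x": x, "y": y, "c1": C[:, 0], "c2": C[:, 1]})
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        res = partial_corr(x, y, covariates=C)
        assert res.statistic == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=(2, 20))
        c = rng.normal(size=20)
        with pytest.raises(ValueError, match="collinear"):
            partial_corr(x, y, covariates=np.column_stack([c, 2 * c]))


class TestOls:
    def test_exact_linear_fit(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 3))
        y = 1.5 + X @ np.array([2.0, -1.0, 0.5])
        fit = ols(y, X)
        assert np.allclose(fit.residuals, 0, atol=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_intercept_only_gives_mean(self):
        y = np.array([1.0, 2.0, 6.0])
        fit = ols(y, np.empty((3, 0)))
        assert fit.params[0] == pytest.approx(3.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(25, 4))
        y = rng.normal(size=25)
        fit = ols(y, X)
        D = np.column_stack([np.ones(25), X])
        beta = np.linalg.solve(D.T @ D, D.T @ y)
        assert np.allclose(fit.params, beta, atol=1e-8)
        assert np.allclose(fit.fitted + fit.residuals, y, atol=1e-10)
        assert np.allclose(D.T @ fit.residuals, 0, atol=1e-8)

    def test_rank_deficiency_rejected(self):
        rng = np.random.default_rng(9)
        c = rng.normal(size=20)
        with pytest.raises(ValueError, match="rank"):
            ols(rng.normal(size=20), np.column_stack([c, c]))


class TestResidualize:
    def test_exact_linear_values_residualize_to_zero(self):
        rng = np.random.default_rng(10)
        N = rng.normal(size=(30, 3))
        values = 2.0 + N @ np.array([1.0, -2.0, 0.3])
        assert np.allclose(residualize(values, N), 0, atol=1e-10)

    def test_uncorrelated_values_are_roughly_centered(self):
        rng = np.random.default_rng(11)
        values = rng.normal(size=200)
        nuisance = rng.normal(size=(200, 2))
        res = residualize(values, nuisance)
        assert res.mean() == pytest.approx(0.0, abs=1e-10)
        assert np.corrcoef(res, values - values.mean())[0, 1] > 0.95

    def test_residuals_orthogonal_to_nuisance(self):
        rng = np.random.default_rng(12)
        dist = rng.uniform(1, 10, 100)
        values = 2.0 * dist + rng.normal(size=100)
        res = residualize(values, dist)
        assert abs(pearson_formula(res, dist)) < 1e-8


class TestAnova1:
    def test_identical_groups_give_zero_f(self):
        r = anova1([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert r.statistic == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)
        assert r.df == (1, 4)

    def test_all_constant_groups_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            anova1([[1.0, 1.0], [1.0, 1.0]])

    def test_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(13)
        groups = [rng.normal(loc, 1, 15) for loc in (0.0, 0.4, 1.0)]
        r = anova1(groups)
        grand = np.concatenate(groups).mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        F = (ss_between / 2) / (ss_within / (45 - 3))
        assert r.statistic == pytest.approx(F, abs=1e-10)

    def test_posthoc_covers_all_pairs(self):
        rng = np.random.default_rng(14)
        groups = [rng.normal(loc, 1, 10) for loc in (0, 1, 2)]
        res = posthoc_ttests(groups, ["a", "b", "c"])
        assert [r.name for r in res] == [
            "posthoc_a_vs_b", "posthoc_a_vs_c", "posthoc_b_vs_c",
        ]


class TestBhFdr:
    def test_single_p_unchanged(self):
        q, flags = bh_fdr([0.03])
        assert q[0] == pytest.approx(0.03)
        assert flags[0]

    def test_step_up_hand_computation(self):
        q, _ = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_uniform_ties(self):
        q, flags = bh_fdr(np.full(7, 0.5))
        assert np.allclose(q, 0.5)
        assert not flags.any()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_fdr([0.5, 1.2])

    def test_q_monotone_and_bounded_below_by_p(self):
        rng = np.random.default_rng(15)
        p = rng.random(50)
        q, _ = bh_fdr(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class _Geo:
    def __init__(self, region, centroid, hemisphere="left"):
        self.region = region
        self.centroid = np.asarray(centroid, dtype=float)
        self.volume = 1.0
        self.surface_area = 1.0
        self.hemisphere = hemisphere


class TestEdgeDistance:
    def test_three_four_five(self):
        d = edge_distance([_Geo(1, (0, 0, 0)), _Geo(2, (3, 4, 0))])
        assert d[0, 1] == pytest.approx(5.0)
        assert np.all(np.diag(d) == 0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(16)
        geo = [_Geo(i + 1, rng.normal(size=3)) for i in range(10)]
        d = edge_distance(geo)
        for i in range(10):
            for j in range(10):
                assert d[i, j] == pytest.approx(
                    np.linalg.norm(geo[i].centroid - geo[j].centroid)
                )

    def test_duplicate_centroids_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            edge_distance([_Geo(1, (0, 0, 0)), _Geo(2, (0, 0, 0))])


class TestBinDistances:
    def test_exact_quartiles(self):
        cats = bin_distances(np.arange(8.0))
        assert (cats == "short").sum() == 2
        assert (cats == "mid").sum() == 4
        assert (cats == "long").sum() == 2

    def test_ties_resolved_by_stable_order(self):
        cats = bin_distances(np.full(4, 2.0))
        assert list(cats) == ["short", "mid", "mid", "long"]

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(17)
        d = rng.uniform(0, 100, 100)
        cats = bin_distances(d)
        order = np.argsort(d, kind="stable")
        assert set(order[:25]) == set(np.nonzero(cats == "short")[0])
        assert set(order[-25:]) == set(np.nonzero(cats == "long")[0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="four"):
            bin_distances([1.0, 2.0, 3.0])


class TestHemisphereSplit:
    def test_two_plus_two(self):
        hemi = {1: "left", 2: "left", 3: "right", 4: "right"}
        iu, ju = np.triu_indices(4, 1)
        masks = hemisphere_split(iu + 1, ju + 1, hemi)
        assert masks["LH"].sum() == 1
        assert masks["RH"].sum() == 1
        assert masks["LH-RH"].sum() == 4

    def test_all_left(self):
        hemi = {1: "left", 2: "left", 3: "left"}
        masks = hemisphere_split([1, 1, 2], [2, 3, 3], hemi)
        assert masks["LH"].all()
        assert not masks["RH"].any() and not masks["LH-RH"].any()

    def test_sixty_region_counts_match_binomial_oracle(self):
        hemi = {r: ("left" if r <= 30 else "right") for r in range(1, 61)}
        iu, ju = np.triu_indices(60, 1)
        masks = hemisphere_split(iu + 1, ju + 1, hemi)
        assert masks["LH"].sum() == 435
        assert masks["RH"].sum() == 435
        assert masks["LH-RH"].sum() == 900
        assert masks["LH"].sum() + masks["RH"].sum() + masks["LH-RH"].sum() == 1770

    def test_missing_label_rejected(self):
        with pytest.raises(ValueError, match="missing hemisphere"):
            hemisphere_split([1], [2], {1: "left"})
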