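"""Expression statistics: detection, DE, clustering, co-expression."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from scqpcr import (
    AssayPanel,
    ExpressionMatrix,
    SingleMoleculeCutoff,
    coexpression,
    detection_call,
    differential_expression,
    hierarchical_cluster,
    pooled_vs_grouped,
    simulate_cell_population,
)
from scqpcr.expression import _ranksum_pvalue, _spearman_perm_p

from conftest import two_population_matrix


class TestDetectionCall:
    def test_all_replicates_below_cutoff_detected(self):
        assert detection_call(np.array([[20.0, 21.0, 22.0]]), cutoff=23.2)[0]

    def test_one_failed_replicate_blocks_detection(self):
        # the "all replicates" rule: 2 of 3 below is not enough
        assert not detection_call(np.array([[20.0, 21.0, np.nan]]), cutoff=23.2)[0]
        assert not detection_call(np.array([[20.0, 21.0, 25.0]]), cutoff=23.2)[0]

    def test_null_run_detection_rate_is_fp_rate_to_the_replicates(self, rng):
        # independent chamber false positives at rate q -> cell rate q^r
        q, reps, n = 0.2, 3, 20_000
        fp = rng.random((n, reps)) < q
        cts = np.where(fp, 20.0, np.nan)
        rate = detection_call(cts, cutoff=23.2).mean()
        assert rate == pytest.approx(q**reps, abs=3 * np.sqrt(q**reps / n))

    def test_cutoff_object_uses_offset(self):
        c = SingleMoleculeCutoff(mean_ct=21.5, sd_ct=0.67, preamp_cycle_offset=5)
        assert detection_call(np.array([[27.0]]), c)[0]  # below 28.2
        assert not detection_call(np.array([[29.0]]), c)[0]


class TestDifferentialExpression:
    def test_shifted_gene_flagged(self):
        em = two_population_matrix(n_per_pop=80, n_genes=6, n_shifted=1,
                                   fold=10.0, seed=3)
        res = differential_expression(em)
        assert res.set_index("gene").loc["g0", "significant"]

    def test_null_labels_control_type_one_error(self):
        # permuted labels: identical distributions in both groups
        rng = np.random.default_rng(8)
        flags, total = 0, 0
        for rep in range(300):
            x = rng.lognormal(3.0, 1.0, (60, 8))
            df = pd.DataFrame(x, columns=[f"g{i}" for i in range(8)])
            em = ExpressionMatrix(df, pd.Series(["A"] * 30 + ["B"] * 30))
            res = differential_expression(em)
            flags += int(res["significant"].sum())
            total += len(res)
        assert flags / total <= 0.01

    def test_constant_gene_all_ties_p_one(self):
        df = pd.DataFrame({"g": np.ones(12)})
        em = ExpressionMatrix(df, pd.Series(["A"] * 6 + ["B"] * 6))
        res = differential_expression(em)
        assert res.loc[0, "pvalue"] == 1.0
        assert not res.loc[0, "significant"]

    def test_single_population_rejected(self):
        df = pd.DataFrame({"g": np.arange(6.0)})
        em = ExpressionMatrix(df, pd.Series(["A"] * 6))
        with pytest.raises(ValueError):
            differential_expression(em)

    def test_adjusted_p_monotone_and_not_below_raw(self):
        em = two_population_matrix(n_per_pop=40, n_genes=10, n_shifted=4,
                                   fold=3.0, seed=5)
        res = differential_expression(em).sort_values("pvalue")
        assert np.all(res["qvalue"].to_numpy() >= res["pvalue"].to_numpy() - 1e-12)
        assert np.all(np.diff(res["qvalue"].to_numpy()) >= -1e-12)


def bh_stepup_oracle(pvals, alpha):
    """Brute-force Benjamini–Hochberg: largest k with p_(k) <= k*alpha/m."""
    p = np.asarray(pvals)
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * alpha / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


class TestOracles:
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=50),
           st.sampled_from([0.01, 0.05, 0.1]))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bh_matches_stepup_enumeration(self, pvals, alpha):
        ours = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
        assert np.array_equal(ours, bh_stepup_oracle(pvals, alpha))

    @pytest.mark.parametrize("nx,ny,seed", [(3, 3, 0), (4, 5, 1), (6, 6, 2),
                                            (5, 3, 3)])
    def test_ranksum_matches_exact_enumeration(self, nx, ny, seed):
        # enumerate every assignment of the pooled sample to the two groups
        from itertools import combinations as comb
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, nx)
        y = rng.normal(0.5, 1, ny)
        pooled = np.concatenate([x, y])
        assert len(np.unique(pooled)) == nx + ny  # continuous: no ties
        u_obs = sps.mannwhitneyu(x, y, alternative="two-sided").statistic
        ranks = sps.rankdata(pooled)
        us = []
        for idx in comb(range(nx + ny), nx):
            rx = ranks[list(idx)]
            us.append(rx.sum() - nx * (nx + 1) / 2)
        us = np.asarray(us)
        mid = nx * ny / 2
        p_exact = np.mean(np.abs(us - mid) >= abs(u_obs - mid) - 1e-9)
        _, p_ours = _ranksum_pvalue(x, y)
        assert p_ours == pytest.approx(p_exact, abs=1e-9)


class TestClustering:
    def test_duplicate_cells_merge_first_at_zero_distance(self):
        x = np.array([[1.0, 5.0, 2.0], [1.0, 5.0, 2.0], [9.0, 1.0, 4.0]])
        em = ExpressionMatrix(pd.DataFrame(x), pd.Series(["p"] * 3))
        res = hierarchical_cluster(em)
        assert res.linkage[0, 2] == pytest.approx(0.0)
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}

    def test_anticorrelated_profiles_at_maximum_distance(self):
        x = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        logx = np.log10(x + 1)
        em = ExpressionMatrix(pd.DataFrame(x), pd.Series(["p"] * 2))
        res = hierarchical_cluster(em)
        r = np.corrcoef(logx)[0, 1]
        assert res.distance[0, 1] == pytest.approx((1 - r) / 2)
        assert res.distance[0, 1] > 0.9

    def test_merge_heights_non_decreasing(self):
        em = two_population_matrix(n_per_pop=25, seed=9)
        res = hierarchical_cluster(em)
        heights = res.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-9)

    def test_two_populations_recovered(self):
        em = two_population_matrix(n_per_pop=60, n_genes=10, n_shifted=5,
                                   fold=4.0, seed=1)
        res = hierarchical_cluster(em)
        truth = (em.population == "B").to_numpy().astype(int)
        pred = res.labels_k2 - 1
        agreement = max(np.mean(pred == truth), np.mean(pred == 1 - truth))
        assert agreement >= 0.95

    def test_zero_variance_cell_warns_and_gets_max_distance(self):
        x = np.array([[2.0, 2.0, 2.0], [1.0, 5.0, 9.0], [9.0, 5.0, 1.0]])
        em = ExpressionMatrix(pd.DataFrame(x), pd.Series(["p"] * 3))
        with pytest.warns(RuntimeWarning, match="zero variance"):
            res = hierarchical_cluster(em)
        assert res.distance[0, 1] == 1.0 and res.distance[0, 2] == 1.0

    def test_single_cell_rejected(self):
        em = ExpressionMatrix(pd.DataFrame({"g": [1.0]}), pd.Series(["p"]))
        with pytest.raises(ValueError):
            hierarchical_cluster(em)


class TestCoexpression:
    def test_gene_with_itself_has_rho_one(self, rng):
        x = rng.lognormal(3, 1, 50)
        rho, _ = _spearman_perm_p(x, x.copy(), 200, rng)
        assert rho == pytest.approx(1.0)

    def test_correlated_pair_detected(self):
        corr = np.eye(3)
        corr[0, 1] = corr[1, 0] = 0.85
        panel = AssayPanel(["a", "b", "c"], mean_copies=300.0, lognormal_cv=0.8,
                           correlation=corr)
        t = simulate_cell_population(panel, 90, seed=4)
        em = ExpressionMatrix(
            pd.DataFrame(t.counts.astype(float), columns=panel.gene_names),
            pd.Series(["K"] * 90))
        res = coexpression(em, n_perm=2000, seed=0)
        row = res[(res.gene_a == "a") & (res.gene_b == "b")].iloc[0]
        assert row["rho"] > 0.5
        assert row["significant"]

    def test_undetected_gene_pair_not_assessable(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": np.zeros(5),
                           "c": [2.0, 1, 4, 3, 5]})
        em = ExpressionMatrix(df, pd.Series(["p"] * 5))
        res = coexpression(em, n_perm=200, seed=0)
        ab = res[(res.gene_a == "a") & (res.gene_b == "b")].iloc[0]
        ac = res[(res.gene_a == "a") & (res.gene_b == "c")].iloc[0]
        assert not ab["assessable"] and np.isnan(ab["rho"])
        assert ac["assessable"]

    def test_too_few_permutations_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [3.0, 2, 1]})
        em = ExpressionMatrix(df, pd.Series(["p"] * 3))
        with pytest.raises(ValueError):
            coexpression(em, n_perm=50)

    def test_permutation_p_super_uniform_under_null(self):
        # p-values from independent gene pairs stochastically dominate U(0,1)
        rng = np.random.default_rng(17)
        pvals = []
        for _ in range(400):
            x = rng.lognormal(3, 1, 40)
            y = rng.lognormal(3, 1, 40)
            _, p = _spearman_perm_p(x, y, 200, rng)
            pvals.append(p)
        ks = sps.kstest(pvals, "uniform", alternative="greater")
        assert ks.pvalue > 0.01


class TestPooledVsGrouped:
    def _simpson_matrix(self, seed=0, n=80):
        corr = np.array([[1.0, 0.6], [0.6, 1.0]])
        pa = AssayPanel(["x", "y"], mean_copies=[2000.0, 50.0], lognormal_cv=0.5,
                        correlation=corr)
        pb = AssayPanel(["x", "y"], mean_copies=[50.0, 2000.0], lognormal_cv=0.5,
                        correlation=corr)
        ta = simulate_cell_population(pa, n, population="A", seed=seed)
        tb = simulate_cell_population(pb, n, population="B", seed=seed + 1000)
        df = pd.DataFrame(np.vstack([ta.counts, tb.counts]).astype(float),
                          columns=["x", "y"])
        return ExpressionMatrix(df, pd.Series(["A"] * n + ["B"] * n))

    def test_constructed_simpsons_paradox_reverses_sign(self):
        em = self._simpson_matrix(seed=2)
        res = pooled_vs_grouped(em, "x", "y", n_perm=500, seed=0)
        assert res.pooled_rho < 0
        assert all(r > 0 for r in res.group_rho.values())
        assert res.sign_reversal

    def test_single_population_split_in_two_shows_no_reversal(self, rng):
        corr = np.array([[1.0, 0.5], [0.5, 1.0]])
        panel = AssayPanel(["x", "y"], mean_copies=300.0, lognormal_cv=0.6,
                           correlation=corr)
        t = simulate_cell_population(panel, 120, seed=6)
        df = pd.DataFrame(t.counts.astype(float), columns=["x", "y"])
        em = ExpressionMatrix(df, pd.Series(["A"] * 60 + ["B"] * 60))
        res = pooled_vs_grouped(em, "x", "y", n_perm=300, seed=0)
        assert not res.sign_reversal
        within = np.mean(list(res.group_rho.values()))
        assert res.pooled_rho == pytest.approx(within, abs=0.15)

    def test_within_population_permutation_scheme(self):
        em = self._simpson_matrix(seed=3)
        res = pooled_vs_grouped(em, "x", "y", n_perm=500, scheme="within", seed=0)
        assert np.isfinite(res.pooled_p)
        assert res.sign_reversal

    def test_summary_reports_both_levels(self):
        em = self._simpson_matrix(seed=4)
        res = pooled_vs_grouped(em, "x", "y", n_perm=200, seed=0)
        s = res.summary()
        assert "pooled" in s and "sign reversal" in s
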