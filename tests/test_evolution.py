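"""Cross-species correlation, conservation and divergence-trend analyses."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cpgevo import (
    ConservationTable,
    class_conservation,
    conservation_table,
    dcpg_sliding_trend,
    diff_expression_dcpg,
    fisher_z_pvalue,
    ortholog_comparisons,
    pairwise_ncpg_conservation,
    spearman_correlation,
    trend_slope,
    tss_tts_conservation_ratio,
)
from cpgevo.expression import build_expression_matrix


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman_correlation(x, x**3).r == pytest.approx(1.0)
        assert spearman_correlation(x, -x).r == pytest.approx(-1.0)

    def test_constant_vector_is_missing(self):
        assert math.isnan(spearman_correlation(np.ones(10), np.arange(10.0)).r)

    def test_population_value_recovered(self, rng):
        # Pearson rho = 2 sin(pi * rho_s / 6) gives population Spearman 0.5
        rho = 2 * math.sin(math.pi * 0.5 / 6)
        cov = [[1, rho], [rho, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=10_000)
        assert spearman_correlation(xy[:, 0], xy[:, 1]).r == pytest.approx(0.5, abs=0.03)

    def test_missing_values_excluded_pairwise(self):
        x = np.array([1.0, 2, 3, 4, np.nan, 6])
        y = np.array([1.0, 2, 3, 4, 5, np.nan])
        assert spearman_correlation(x, y).n == 4


class TestFisherZ:
    def test_zero_correlation(self):
        z, p = fisher_z_pvalue(0.0, 500)
        assert z == 0.0 and p == 1.0

    def test_known_value(self):
        """r=0.5, n=100: z = arctanh(0.5) * sqrt(97) ~ 5.410, p ~ 6.3e-8."""
        z, p = fisher_z_pvalue(0.5, 100)
        assert z == pytest.approx(math.atanh(0.5) * math.sqrt(97))
        assert z == pytest.approx(5.410, abs=0.005)
        assert p == pytest.approx(6.3e-8, rel=0.05)

    def test_p_decreases_with_n(self):
        assert fisher_z_pvalue(0.3, 1000)[1] < fisher_z_pvalue(0.3, 100)[1]

    def test_degenerate_correlation_flagged(self):
        z, p, flagged = fisher_z_pvalue(1.0, 50, _return_flag=True)
        assert math.isinf(z) and p > 0 and flagged

    def test_matches_permutation_p(self, rng):
        """Fisher-z p within a factor of 2 of a 10,000-permutation p for
        moderate correlations at n=50."""
        n = 50
        for target in (0.25, 0.35):
            x = rng.normal(size=n)
            y = target * x + math.sqrt(1 - target**2) * rng.normal(size=n)
            res = spearman_correlation(x, y)
            if not 0.1 < abs(res.r) <= 0.45:
                continue
            _, p_fisher = fisher_z_pvalue(res.r, n)
            rx = stats.rankdata(x)
            ry = stats.rankdata(y)
            perm_rs = np.empty(10_000)
            for i in range(10_000):
                perm_rs[i] = np.corrcoef(rx, rng.permutation(ry))[0, 1]
            p_perm = (np.sum(np.abs(perm_rs) >= abs(res.r)) + 1) / (10_000 + 1)
            assert p_fisher / p_perm < 2 and p_perm / p_fisher < 2


class TestClassConservation:
    def test_printed_human_mouse_table(self):
        """277 HH + 132 LL of 481 single-TSS ortholog pairs: 85% conserved,
        overwhelmingly non-independent."""
        res = class_conservation(ConservationTable(hh=277, hl=54, lh=18, ll=132))
        assert res.conserved_fraction == pytest.approx(409 / 481)
        assert res.conserved_fraction == pytest.approx(0.8503, abs=1e-4)
        assert res.p_value < 1e-49
        assert res.p_reliable

    def test_independence_table(self):
        res = class_conservation(ConservationTable(50, 50, 50, 50))
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_chi2_matches_brute_force_oracle(self, rng):
        """Sum (O-E)^2 / E with margins-derived expectations, on 100 random
        2x2 tables."""
        for _ in range(100):
            t = ConservationTable(*(int(v) for v in rng.integers(1, 200, 4)))
            res = class_conservation(t)
            obs = np.array([[t.hh, t.hl], [t.lh, t.ll]], dtype=float)
            rows, cols = obs.sum(1), obs.sum(0)
            exp = np.outer(rows, cols) / obs.sum()
            chi2 = ((obs - exp) ** 2 / exp).sum()
            assert res.chi2 == pytest.approx(chi2, rel=1e-10)
            assert res.p_value == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-9)

    def test_conserved_fraction_invariant_under_organism_swap(self, rng):
        a = rng.choice(["HCP", "LCP"], 500)
        b = rng.choice(["HCP", "LCP"], 500)
        assert (
            class_conservation(a, b).conserved_fraction
            == class_conservation(b, a).conserved_fraction
        )

    def test_labels_interface_counts(self):
        a = ["HCP", "HCP", "LCP", "LCP", "unclassified"]
        b = ["HCP", "LCP", "HCP", "LCP", "HCP"]
        t = conservation_table(a, b)
        assert (t.hh, t.hl, t.lh, t.ll) == (1, 1, 1, 1)


class TestPairwiseConservation:
    def pairs(self, n):
        return pd.DataFrame({"gene_a": [f"g{i}" for i in range(n)],
                             "gene_b": [f"h{i}" for i in range(n)]})

    def test_identical_values_give_unit_correlation(self, rng):
        n = 200
        vals = rng.gamma(2.0, 0.2, n)
        a = pd.Series(vals, index=[f"g{i}" for i in range(n)])
        b = pd.Series(vals, index=[f"h{i}" for i in range(n)])
        res = pairwise_ncpg_conservation(a, b, self.pairs(n))
        assert res.r == pytest.approx(1.0)
        assert tss_tts_conservation_ratio(res.r, res.r) == pytest.approx(0.0)

    def test_shuffled_ortholog_map_destroys_correlation(self, rng):
        n = 2000
        vals = rng.gamma(2.0, 0.2, n)
        a = pd.Series(vals, index=[f"g{i}" for i in range(n)])
        b = pd.Series(rng.permutation(vals), index=[f"h{i}" for i in range(n)])
        res = pairwise_ncpg_conservation(a, b, self.pairs(n))
        assert abs(res.r) < 3 / math.sqrt(n)

    def test_nonpositive_tts_correlation_flags_ratio(self):
        assert math.isnan(tss_tts_conservation_ratio(0.5, -0.1))

    def test_tss_more_conserved_than_tts_under_smaller_drift(self, values_bundle):
        b = values_bundle
        ga = b.organism_a.gene_truth.set_index("gene_id")
        gb = b.organism_b.gene_truth.set_index("gene_id")
        r_tss = pairwise_ncpg_conservation(ga["ncpg_tss"], gb["ncpg_tss"], b.orthologs).r
        r_tts = pairwise_ncpg_conservation(ga["ncpg_tts"], gb["ncpg_tts"], b.orthologs).r
        assert r_tss > r_tts > 0
        assert tss_tts_conservation_ratio(r_tss, r_tts) > 0


def bundle_comparisons(bundle, tissue="tissue0"):
    ga = bundle.organism_a.gene_truth.set_index("gene_id")
    gb = bundle.organism_b.gene_truth.set_index("gene_id")
    em_a = build_expression_matrix(bundle.expression_a.raw, bundle.expression_a.sample_tissues)
    em_b = build_expression_matrix(bundle.expression_b.raw, bundle.expression_b.sample_tissues)
    return ortholog_comparisons(
        ga["ncpg_tss"], gb["ncpg_tss"], ga["ncpg_tts"], gb["ncpg_tts"],
        em_a.log2_rpkm, em_b.log2_rpkm, bundle.orthologs,
    )


class TestSlidingTrend:
    def test_zero_ratios_give_zero_windows(self, rng):
        d = rng.normal(0, 0.1, 1000)
        out = dcpg_sliding_trend(d, np.zeros(1000), window_size=400)
        assert np.allclose(out["mean_log2_ratio"], 0.0)
        assert out["mean_dcpg"].is_monotonic_increasing

    def test_exactly_one_window_equals_global_means(self, rng):
        d = rng.normal(0, 0.1, 400)
        e = rng.normal(0, 1.0, 400)
        out = dcpg_sliding_trend(d, e, window_size=400)
        assert len(out) == 1
        assert out.loc[0, "mean_dcpg"] == pytest.approx(d.mean())
        assert out.loc[0, "mean_log2_ratio"] == pytest.approx(e.mean())

    def test_too_few_pairs_suggests_smaller_window(self, rng):
        with pytest.raises(ValueError, match="smaller window"):
            dcpg_sliding_trend(rng.normal(size=100), rng.normal(size=100), window_size=400)

    def test_coupled_generator_recovers_slope(self, values_bundle):
        """Windows track the built-in coupling: rank correlation of window
        means > 0.9 and the median OLS slope over seeds within 30% of the
        generator beta (a single seed carries substantial window noise)."""
        from cpgevo.simulate import SimulationConfig, simulate_bundle

        comp = bundle_comparisons(values_bundle)
        tr = dcpg_sliding_trend(comp["dcpg_tss"], comp["log2_ratio_tissue0"])
        beta = values_bundle.config.divergence_beta
        slopes = [trend_slope(tr)]
        window_rs = [spearman_correlation(tr["mean_dcpg"], tr["mean_log2_ratio"]).r]
        for seed in (101, 102, 103, 104):
            b = simulate_bundle(SimulationConfig(seed=seed, n_genes=5000), sequences=False)
            c = bundle_comparisons(b)
            t = dcpg_sliding_trend(c["dcpg_tss"], c["log2_ratio_tissue0"])
            slopes.append(trend_slope(t))
            window_rs.append(spearman_correlation(t["mean_dcpg"], t["mean_log2_ratio"]).r)
        assert np.median(window_rs) > 0.9 and min(window_rs) > 0.8
        rel_err = np.abs(np.array(slopes) - beta) / beta
        assert np.median(rel_err) < 0.3
        assert (np.array(slopes) > 0).all()


class TestDiffExpression:
    def test_groups_partition_when_threshold_below_all_ratios(self):
        comp = pd.DataFrame(
            {"dcpg_tss": [0.1, -0.1, 0.2, -0.2], "dcpg_tts": [0.0] * 4,
             "log2_ratio_t": [2.0, -2.0, 3.0, -1.5]}
        )
        out = diff_expression_dcpg(comp, "t", fold_threshold=2 ** 1.4)
        assert out.n_up + out.n_down == 4

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            diff_expression_dcpg(pd.DataFrame({"log2_ratio_t": [], "dcpg_tss": [], "dcpg_tts": []}),
                                 "t", fold_threshold=1.0)

    def test_coupled_generator_up_group_has_larger_dcpg(self, values_bundle):
        comp = bundle_comparisons(values_bundle)
        out = diff_expression_dcpg(comp, "tissue0")
        assert out.mean_dcpg_tss_up > out.mean_dcpg_tss_down
        assert out.p_tss < 0.01
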