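"""DE engine: filtering, size factors, dispersions, Wald test, BH.

Independent oracles used here: brute-force step-up enumeration of the BH
definition, a dense NB likelihood grid search for the GLM fold change, and
statsmodels' NB GLM as a cross-check for the IRLS fitter.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from shufflepower.de import (
    adjust_bh,
    estimate_dispersions,
    estimate_size_factors,
    filter_low_counts,
    run_de,
    wald_test,
)
from shufflepower.simulate import SimConfig, generate_counts, generate_null_counts

from conftest import make_count_matrix


# ----------------------------------------------------------------------
class TestFilterLowCounts:
    def test_zero_row_removed_unit_row_kept(self):
        cm = make_count_matrix([[0] * 8, [1] * 8, [5] * 8])
        out = filter_low_counts(cm, 1.0)
        assert list(out.annotation_ids) == ["ann_1", "ann_2"]

    def test_toy_matrix_counts(self, toy_cm):
        out = filter_low_counts(toy_cm, 1.0)
        assert out.n_annotations == 7
        assert out.n_samples == 8

    def test_all_removed_warns(self):
        cm = make_count_matrix([[0] * 8, [1, 0, 0, 0, 0, 0, 0, 0]])
        with pytest.warns(UserWarning):
            out = filter_low_counts(cm, 5.0)
        assert out.n_annotations == 0

    def test_negative_threshold_rejected(self, toy_cm):
        with pytest.raises(ValueError):
            filter_low_counts(toy_cm, -1.0)


# ----------------------------------------------------------------------
class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([5, 10, 20, 80])
        cm = make_count_matrix(np.tile(col[:, None], (1, 8)))
        sf = estimate_size_factors(cm)
        np.testing.assert_allclose(sf.to_numpy(), 1.0)

    def test_two_by_two_worked_example(self):
        """counts [[4,16],[1,4]]: geomeans 8, 2; ratios (0.5, 2) in both
        rows; medians 0.5 and 2 already have geometric mean 1."""
        counts = pd.DataFrame([[4, 16], [1, 4]], index=["a", "b"], columns=["s1", "s2"])
        groups = pd.Series(["CD", "CD", "HFD", "HFD"], index=["s1", "s2", "s3", "s4"])
        # need >= 2 samples per group for the container: embed in 4 samples
        counts = pd.DataFrame(
            [[4, 16, 4, 16], [1, 4, 1, 4]],
            index=["a", "b"],
            columns=["s1", "s2", "s3", "s4"],
        )
        from shufflepower.countmatrix import CountMatrix

        cm = CountMatrix(counts, groups, pd.Series(["g", "g"], index=["a", "b"]))
        sf = estimate_size_factors(cm)
        np.testing.assert_allclose(sf.to_numpy(), [0.5, 2.0, 0.5, 2.0])

    def test_column_scaling_equivariance(self, rng):
        """Multiplying one column by c multiplies its factor by c relative
        to the rest (after renormalisation the ratio is preserved)."""
        counts = rng.poisson(100, size=(50, 6))
        cm = make_count_matrix(counts, n_per_group=3)
        sf1 = estimate_size_factors(cm)
        scaled = counts.copy()
        scaled[:, 0] *= 4
        cm2 = make_count_matrix(scaled, n_per_group=3)
        sf2 = estimate_size_factors(cm2)
        ratio = (sf2 / sf1).to_numpy()
        assert ratio[0] / ratio[1] == pytest.approx(4.0, rel=1e-6)

    def test_geometric_mean_is_one(self, rng):
        cm = make_count_matrix(rng.poisson(30, size=(40, 8)))
        sf = estimate_size_factors(cm)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)

    def test_sparse_fallback(self, rng):
        """No annotation positive in every sample: the positive-count
        fallback still produces positive factors."""
        counts = rng.poisson(20, size=(30, 8))
        mask = rng.random((30, 8)) < 0.2
        counts[mask] = 0
        counts[:, 0] = 0  # guarantee no all-positive row
        counts[0, 0] = 5
        cm = make_count_matrix(counts)
        sf = estimate_size_factors(cm)
        assert (sf > 0).all()


# ----------------------------------------------------------------------
class TestDispersions:
    def test_poisson_data_recovers_near_zero(self):
        cfg = SimConfig(
            n_annotations_per_class={"g": 500},
            dispersion_intercept=1e-6,
            dispersion_slope=0.0,
            mean_log_mu=2.5,
            sd_log_mu=0.4,
            seed=10,
        )
        cm, _ = generate_null_counts(cfg)
        sf = estimate_size_factors(cm)
        disp = estimate_dispersions(cm, sf)
        assert disp.alpha_final.median() <= 0.05

    def test_constant_alpha_recovery(self):
        cfg = SimConfig(
            n_annotations_per_class={"g": 500},
            dispersion_intercept=0.2,
            dispersion_slope=0.0,
            mean_log_mu=2.5,
            sd_log_mu=0.4,
            seed=11,
        )
        cm, _ = generate_null_counts(cfg)
        sf = estimate_size_factors(cm)
        disp = estimate_dispersions(cm, sf)
        assert 0.1 <= disp.alpha_final.median() <= 0.4

    def test_zero_variance_row_floored_not_crashed(self):
        counts = np.vstack([np.full(8, 10), np.random.default_rng(0).poisson(50, (30, 8))])
        cm = make_count_matrix(counts)
        sf = estimate_size_factors(cm)
        disp = estimate_dispersions(cm, sf)
        assert np.isfinite(disp.alpha_final).all()
        assert (disp.alpha_final > 0).all()
        assert disp.alpha_gene.iloc[0] == pytest.approx(1e-8)


# ----------------------------------------------------------------------
def nb_loglik_grid(y, indicator, alpha, log2fc_grid, intercept_grid):
    """Dense grid maximisation of the NB log-likelihood; returns the
    log2fc at the joint maximum.  Independent of the IRLS path."""
    best = (-np.inf, np.nan)
    r = 1.0 / alpha
    for b0 in intercept_grid:
        for b1 in log2fc_grid:
            mu = 2.0 ** (b0 + b1 * indicator)
            p = r / (r + mu)
            ll = stats.nbinom.logpmf(y, r, p).sum()
            if ll > best[0]:
                best = (ll, b1)
    return best[1]


class TestWaldTest:
    @staticmethod
    def _fit(cm, alpha_value=0.1):
        sf = pd.Series(1.0, index=cm.sample_ids)
        n = cm.n_annotations
        disp_final = pd.Series(alpha_value, index=cm.annotation_ids)
        from shufflepower.de import DispersionEstimates

        disp = DispersionEstimates(
            alpha_gene=disp_final,
            alpha_trend=disp_final,
            alpha_final=disp_final,
            trend_coefficients=(alpha_value, 0.0),
            base_mean=pd.Series(np.nan, index=cm.annotation_ids),
        )
        return wald_test(cm, sf, disp)

    def test_fourfold_toy_log2fc(self):
        """All CD counts 10, all HFD counts 40: group-mean ratio 4 = 2^2."""
        cm = make_count_matrix([[10, 10, 10, 10, 40, 40, 40, 40]])
        tab = self._fit(cm)
        assert tab.log2fc.iloc[0] == pytest.approx(2.0, abs=1e-4)

    def test_symmetric_groups_give_zero_fc(self):
        cm = make_count_matrix([[7, 7, 7, 7, 7, 7, 7, 7]])
        tab = self._fit(cm)
        assert abs(tab.log2fc.iloc[0]) < 1e-8

    def test_matches_grid_search_oracle(self, rng):
        """IRLS MLE equals dense likelihood grid maximisation on toy data."""
        for _ in range(3):
            y = rng.poisson([20, 25, 18, 22, 60, 55, 70, 40])
            cm = make_count_matrix(y[None, :])
            tab = self._fit(cm, alpha_value=0.05)
            grid = np.arange(-1.0, 3.0, 0.01)
            igrid = np.arange(2.0, 7.0, 0.01)
            b1 = nb_loglik_grid(y, cm.design_indicator(), 0.05, grid, igrid)
            assert tab.log2fc.iloc[0] == pytest.approx(b1, abs=0.02)

    def test_matches_statsmodels_glm(self, rng):
        """Coefficient and SE agree with statsmodels NB GLM (independent
        IRLS implementation) including non-unit offsets."""
        import statsmodels.api as sm

        y = rng.poisson([30, 40, 25, 35, 80, 90, 60, 100]).astype(float)
        cm = make_count_matrix(y[None, :].astype(int))
        sf = pd.Series([0.8, 1.0, 1.2, 1.0, 0.9, 1.1, 1.0, 1.0], index=cm.sample_ids)
        alpha = 0.08
        from shufflepower.de import LN2, DispersionEstimates

        a = pd.Series(alpha, index=cm.annotation_ids)
        disp = DispersionEstimates(a, a, a, (alpha, 0.0), a * np.nan)
        tab = wald_test(cm, sf, disp)
        X = np.column_stack([np.ones(8), cm.design_indicator()])
        res = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=np.log(sf)
        ).fit()
        assert tab.log2fc.iloc[0] == pytest.approx(res.params[1] / LN2, abs=1e-5)
        assert tab.se.iloc[0] == pytest.approx(res.bse[1] / LN2, rel=1e-3)

    def test_fit_failure_flagged_not_raised(self):
        """An all-zero annotation cannot separate the groups; it must come
        back flagged with p = 1, not crash."""
        cm = make_count_matrix([[0] * 8, [10, 12, 9, 11, 30, 28, 33, 29]])
        tab = self._fit(cm)
        assert set(tab.flag) <= {"ok", "fit_failed"}
        assert ((tab.pvalue >= 0) & (tab.pvalue <= 1)).all()


# ----------------------------------------------------------------------
def bh_bruteforce(p):
    """Literal BH definition: padj_(i) = min_{k >= i} m * p_(k) / k."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    adj = np.empty(m)
    for i in range(m):
        adj[i] = min(min(m * sorted_p[k] / (k + 1) for k in range(i, m)), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


class TestAdjustBH:
    def test_all_ones_fixed_point(self):
        np.testing.assert_allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)

    def test_hand_computed_examples(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(adjust_bh([0.001, 0.9]), [0.002, 0.9])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])
        with pytest.raises(ValueError):
            adjust_bh([np.nan, 0.5])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=40)
    )
    def test_matches_bruteforce_and_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests

        ours = adjust_bh(pvals)
        np.testing.assert_allclose(ours, bh_bruteforce(pvals), atol=1e-12)
        _, sm_adj, _, _ = multipletests(pvals, method="fdr_bh")
        np.testing.assert_allclose(ours, sm_adj, atol=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=40)
    )
    def test_bh_invariants(self, pvals):
        """padj >= p elementwise, capped at 1, order-preserving."""
        p = np.asarray(pvals)
        adj = adjust_bh(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-12).all()


# ----------------------------------------------------------------------
class TestRunDE:
    def test_per_class_multiplicity(self):
        """BH within the miRNA class uses only the miRNA family size: a
        moderately small p among 5 miRNAs adjusts far less than the same p
        among 2,000 genes."""
        rng = np.random.default_rng(3)
        counts = rng.poisson(50, size=(105, 8))
        classes = ["gene"] * 100 + ["miRNA"] * 5
        cm = make_count_matrix(counts, classes=classes)
        tab = run_de(cm)
        mirna = tab[tab["class"] == "miRNA"]
        gene = tab[tab["class"] == "gene"]
        assert len(mirna) == 5
        # padj computed within class: for each class max padj ratio bounded by class size
        assert (mirna.padj <= np.minimum(mirna.pvalue * 5, 1.0) + 1e-12).all()
        assert len(gene) <= 100

    def test_null_simulation_rarely_significant(self):
        cfg = SimConfig(
            n_annotations_per_class={"g": 2000}, mean_log_mu=2.5, sd_log_mu=0.5, seed=21
        )
        cm, _ = generate_null_counts(cfg)
        tab = run_de(cm, alpha_sig=0.05)
        assert tab.significant.sum() <= 10  # BH under the global null

    def test_strong_spikes_detected(self):
        cfg = SimConfig(
            n_annotations_per_class={"g": 2000},
            de_fraction=0.025,
            de_log2fc_range=(2.0, 2.0),
            mean_log_mu=2.5,
            sd_log_mu=0.4,
            seed=22,
        )
        cm, truth = generate_counts(cfg)
        tab = run_de(cm)
        de_ids = truth.index[truth.true_log2fc != 0]
        found = tab.reindex(de_ids).significant.fillna(False)
        assert found.sum() >= 45  # of 50

    def test_padj_ge_pvalue(self, toy_cm):
        tab = run_de(toy_cm)
        assert (tab.padj >= tab.pvalue - 1e-12).all()

    def test_log2fc_matches_reference_nb_de_implementation(self):
        """Unshrunk MLE log2 fold changes agree with an independent NB-GLM
        DE implementation (pydeseq2) on a mixed null/DE fixture."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from pydeseq2.dds import DeseqDataSet
            from pydeseq2.ds import DeseqStats

            cfg = SimConfig(
                n_annotations_per_class={"g": 400},
                mean_log_mu=2.0,
                sd_log_mu=0.6,
                de_fraction=0.2,
                seed=77,
            )
            cm, _ = generate_counts(cfg)
            meta = pd.DataFrame({"condition": cm.groups.values}, index=cm.sample_ids)
            dds = DeseqDataSet(
                counts=cm.counts.T, metadata=meta, design="~condition", quiet=True
            )
            dds.deseq2()
            ds = DeseqStats(dds, contrast=["condition", "HFD", "CD"], quiet=True)
            ds.summary()
            ref = ds.results_df
        ours = run_de(cm)
        merged = ours.join(ref[["log2FoldChange"]]).dropna()
        merged = merged[merged.base_mean >= 20]
        assert len(merged) > 300
        slope, intercept = np.polyfit(merged.log2FoldChange, merged.log2fc, 1)
        assert slope == pytest.approx(1.0, abs=0.02)
        assert intercept == pytest.approx(0.0, abs=0.01)

    def test_count_scaling_leaves_inference_unchanged(self, rng):
        """Multiplying all counts by c rescales size factors but leaves
        normalised factors, log2FC and p-values essentially unchanged."""
        counts = rng.poisson(80, size=(300, 8))
        cm1 = make_count_matrix(counts)
        cm2 = make_count_matrix(counts * 3)
        sf1 = estimate_size_factors(cm1)
        sf2 = estimate_size_factors(cm2)
        np.testing.assert_allclose(sf1, sf2, rtol=1e-9)  # both geo-mean 1
        t1, t2 = run_de(cm1), run_de(cm2)
        np.testing.assert_allclose(t1.log2fc, t2.log2fc, atol=0.02)
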