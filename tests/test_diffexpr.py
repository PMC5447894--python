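import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.stats import spearmanr

from genact.diffexpr import (
    DEFilterSpec,
    VoomData,
    bh_adjust,
    build_design,
    de_summary,
    filter_expressed,
    fit_models,
    moderate,
    voom_transform,
)
from genact.normalization import NormFactors, logcpm, tmm_factors
from genact.simdata import SimConfig, simulate_counts


def _norm_for(counts: pd.DataFrame) -> NormFactors:
    lib = counts.sum(axis=0).astype(float)
    return NormFactors(library_size=lib, tmm_factor=pd.Series(1.0, index=counts.columns))


def _meta(n_per_group=4):
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(2 * n_per_group)],
            "sample_type": ["A"] * n_per_group + ["B"] * n_per_group,
            "replicate": list(range(1, n_per_group + 1)) * 2,
        }
    )


class TestFilterExpressed:
    def _inputs(self, medians, active):
        genes = [f"g{i}" for i in range(len(medians))]
        lc = pd.DataFrame(
            np.tile(np.asarray(medians, dtype=float)[:, None], (1, 4)), index=genes
        )
        calls = pd.DataFrame({"A": active, "B": [False] * len(active)}, index=genes)
        return lc, calls

    def test_median_exactly_at_threshold_excluded(self):
        lc, calls = self._inputs([3.71], [True])
        assert len(filter_expressed(lc, calls)) == 0

    def test_median_above_threshold_included(self):
        lc, calls = self._inputs([3.72], [True])
        assert list(filter_expressed(lc, calls)) == ["g0"]

    def test_all_inactive_empty(self):
        lc, calls = self._inputs([10.0, 12.0], [False, False])
        assert len(filter_expressed(lc, calls)) == 0

    def test_active_in_either_type_counts(self):
        genes = ["g0"]
        lc = pd.DataFrame(np.full((1, 4), 9.0), index=genes)
        calls = pd.DataFrame({"A": [False], "B": [True]}, index=genes)
        assert list(filter_expressed(lc, calls)) == ["g0"]


class TestVoom:
    def test_weights_positive_finite(self, small_sim):
        nf = tmm_factors(small_sim.counts)
        X, _, _ = build_design(small_sim.meta)
        voom = voom_transform(small_sim.counts, nf, X)
        w = voom.weights.to_numpy()
        assert np.all(w > 0) and np.all(np.isfinite(w))

    def test_homoskedastic_flat_weights(self):
        # log-normal counts with constant log-scale variance: trend flat,
        # weight spread small
        rng = np.random.default_rng(0)
        n_genes = 800
        base = rng.uniform(4, 12, size=n_genes)
        logc = base[:, None] + rng.normal(0, 0.3, size=(n_genes, 8))
        counts = pd.DataFrame(np.round(2.0 ** logc).astype(np.int64),
                              index=[f"g{i}" for i in range(n_genes)],
                              columns=[f"s{i}" for i in range(8)])
        nf = _norm_for(counts)
        X, _, _ = build_design(_meta())
        voom = voom_transform(counts, nf, X)
        w = voom.weights.to_numpy()
        assert w.std() / w.mean() < 0.2

    def test_trend_direction_on_nb_counts(self):
        # strong NB dispersion: low-mean genes noisier, so mean weight
        # increases with expression
        cfg = SimConfig(n_genes=2000, dispersion_mean=0.4, baseline_mean=4.0,
                        baseline_sd=2.0, seed=13)
        res = simulate_counts(cfg)
        nf = tmm_factors(res.counts)
        X, _, _ = build_design(res.meta)
        voom = voom_transform(res.counts, nf, X)
        mean_lc = voom.log2cpm.mean(axis=1)
        mean_w = voom.weights.mean(axis=1)
        rho, _ = spearmanr(mean_lc, mean_w)
        assert rho > 0

    def test_too_few_samples_error(self):
        counts = pd.DataFrame(np.ones((10, 3), dtype=int))
        nf = _norm_for(counts)
        X = np.column_stack([np.ones(3), [0, 1, 1]])
        with pytest.raises(ValueError):
            voom_transform(counts, nf, X)


class TestFitModels:
    def test_unit_weights_group_mean_difference(self):
        rng = np.random.default_rng(5)
        y = rng.normal(5, 1, size=(20, 8))
        genes = [f"g{i}" for i in range(20)]
        voom = VoomData(
            log2cpm=pd.DataFrame(y, index=genes),
            weights=pd.DataFrame(np.ones_like(y), index=genes),
            trend_x=np.array([0.0, 1.0]),
            trend_y=np.array([1.0, 1.0]),
        )
        X = np.column_stack([np.ones(8), np.repeat([1.0, 0.0], 4)])
        fits = fit_models(voom, X)
        expected = y[:, :4].mean(axis=1) - y[:, 4:].mean(axis=1)
        assert np.allclose(fits["coef"].to_numpy(), expected, atol=1e-10)

    def test_duplicated_rows_identical_fits(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=(1, 8))
        w = rng.uniform(0.5, 2.0, size=(1, 8))
        y2 = np.vstack([y, y])
        w2 = np.vstack([w, w])
        voom = VoomData(pd.DataFrame(y2), pd.DataFrame(w2),
                        np.array([0.0, 1.0]), np.array([1.0, 1.0]))
        X, _, _ = build_design(_meta())
        fits = fit_models(voom, X)
        assert fits.iloc[0].equals(fits.iloc[1])

    def test_brute_force_normal_equations(self):
        rng = np.random.default_rng(7)
        X, _, _ = build_design(_meta())
        for _ in range(10):
            y = rng.normal(size=(5, 8))
            w = rng.uniform(0.2, 3.0, size=(5, 8))
            voom = VoomData(pd.DataFrame(y), pd.DataFrame(w),
                            np.array([0.0, 1.0]), np.array([1.0, 1.0]))
            fits = fit_models(voom, X)
            for g in range(5):
                Wm = np.diag(w[g])
                beta = np.linalg.solve(X.T @ Wm @ X, X.T @ Wm @ y[g])
                assert abs(fits["coef"].iloc[g] - beta[1]) < 1e-9

    def test_rank_deficient_design_error(self):
        meta = _meta()
        meta["replicate"] = meta["sample_type"]  # block aliases treatment
        with pytest.raises(ValueError, match="rank"):
            build_design(meta)


class TestModerate:
    def _fits(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "coef": rng.normal(size=n),
                "stdev_unscaled": np.full(n, 0.5),
                "s2": rng.chisquare(4, size=n) / 4.0,
                "df": 4.0,
            },
            index=[f"g{i}" for i in range(n)],
        )

    def test_no_moderation_limit(self):
        fits = self._fits()
        res = moderate(fits, d0=0.0, s0_sq=1.0)
        ordinary_t = fits["coef"] / (fits["stdev_unscaled"] * np.sqrt(fits["s2"]))
        assert np.allclose(res.table["mod_t"], ordinary_t, atol=1e-9)

    def test_full_shrinkage_limit(self):
        fits = self._fits()
        res = moderate(fits, d0=np.inf, s0_sq=0.7)
        assert np.allclose(res.table["s2_post"], 0.7, atol=1e-12)

    def test_posterior_variance_between_extremes(self):
        fits = self._fits()
        res = moderate(fits)
        s2 = fits["s2"].to_numpy()
        lo = np.minimum(s2, res.s0_sq)
        hi = np.maximum(s2, res.s0_sq)
        assert np.all(res.table["s2_post"] >= lo - 1e-12)
        assert np.all(res.table["s2_post"] <= hi + 1e-12)

    def test_type_i_error_on_null(self):
        cfg = SimConfig(n_genes=2000, frac_de=0.0, dispersion_mean=0.1,
                        baseline_mean=np.log(1e6 / 2000 / 1.65), baseline_sd=1.0, seed=31)
        res_sim = simulate_counts(cfg)
        nf = tmm_factors(res_sim.counts)
        X, ccol, _ = build_design(res_sim.meta)
        voom = voom_transform(res_sim.counts, nf, X)
        fits = fit_models(voom, X, ccol)
        res = moderate(fits)
        frac = (res.table["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_needs_enough_genes(self):
        with pytest.raises(ValueError):
            moderate(self._fits(n=5))

    def test_degenerate_variances_infinite_d0(self):
        fits = self._fits()
        fits["s2"] = 1.3
        res = moderate(fits)
        assert np.isinf(res.d0)
        assert np.allclose(res.table["s2_post"], res.s0_sq)


class TestBhAdjust:
    def test_hand_case(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_p(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, np.nan])

    def test_against_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_sm, atol=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_permutation_and_monotonicity(self, p_list):
        p = np.array(p_list)
        q = bh_adjust(p)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(p))
        q_perm = bh_adjust(p[perm])
        assert np.allclose(q_perm, q[perm], atol=1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all((q >= p - 1e-12) & (q <= 1.0))


class TestDeSummary:
    def _result(self, log2fc, q):
        from genact.diffexpr import ModeratedResult

        n = len(log2fc)
        table = pd.DataFrame(
            {
                "log2fc": log2fc,
                "mod_t": np.zeros(n),
                "p": q,
                "q": q,
                "df": 4.0,
                "s2": 1.0,
                "s2_post": 1.0,
            },
            index=[f"g{i}" for i in range(n)],
        )
        return ModeratedResult(table=table, d0=4.0, s0_sq=1.0)

    def test_q_exactly_at_fdr_counted(self):
        s = de_summary(self._result([2.0], [0.01]))
        assert s["n_sig"] == 1 and s["n_up"] == 1

    def test_lfc_exactly_one_excluded_from_filtered_tally(self):
        s = de_summary(self._result([1.0, -1.0, 1.01], [0.001, 0.001, 0.001]))
        assert s["n_sig"] == 3
        assert s["n_up_lfc"] == 1 and s["n_down_lfc"] == 0

    def test_empty_results(self):
        s = de_summary(self._result([], []))
        assert s["n_sig"] == 0 and s["n_up"] == 0 and s["n_down"] == 0

    def test_average_fc_linear_scale(self):
        s = de_summary(self._result([1.0, 2.0, -3.0], [0.001] * 3))
        assert s["avg_fc_up"] == pytest.approx((2.0 + 4.0) / 2.0)
        assert s["avg_fc_down"] == pytest.approx(8.0)


class TestPipelineProperties:
    def test_determinism(self):
        cfg = SimConfig(n_genes=400, frac_de=0.1, dispersion_mean=0.1,
                        baseline_mean=6.0, seed=77)
        outs = []
        for _ in range(2):
            res = simulate_counts(cfg)
            nf = tmm_factors(res.counts)
            X, ccol, _ = build_design(res.meta)
            voom = voom_transform(res.counts, nf, X)
            fits = fit_models(voom, X, ccol)
            outs.append(moderate(fits).table)
        pd.testing.assert_frame_equal(outs[0], outs[1])

    def test_power_and_fdp_with_de(self):
        cfg = SimConfig(n_genes=2000, frac_de=0.1, lfc_magnitude=2.0,
                        dispersion_mean=0.1, baseline_mean=np.log(1e6 / 2000 / 1.65),
                        baseline_sd=1.0, seed=55)
        res_sim = simulate_counts(cfg)
        nf = tmm_factors(res_sim.counts)
        X, ccol, _ = build_design(res_sim.meta)
        voom = voom_transform(res_sim.counts, nf, X)
        fits = fit_models(voom, X, ccol)
        res = moderate(fits)
        truth = res_sim.truth.table.set_index("gene_id")["true_log2fc"] != 0
        sig = res.table["q"] <= 0.01
        tpr = (sig & truth).sum() / truth.sum()
        fdp = (sig & ~truth).sum() / max(1, sig.sum())
        assert tpr >= 0.6
        assert fdp <= 0.05  # single dataset; the 100-replicate mean is in acceptance
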