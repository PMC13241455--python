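"""SPM engine: GLM t-fields, smoothness estimation, RFT thresholds, clusters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from fatmap.spm import (DesignMatrix, build_design, estimate_fwhm, extract_clusters,
                        fit_glm_field, rft_threshold, spm_test)
from fatmap.synthetic import (CovariateSpec, EffectSpec, smooth_gaussian_curves,
                              synthetic_curve_cohort)


def per_node_ols_t(Y, X, j):
    """Independent oracle: one scipy lstsq regression per node."""
    n, p = X.shape
    ts = []
    for q in range(Y.shape[1]):
        beta, *_ = np.linalg.lstsq(X, Y[:, q], rcond=None)
        resid = Y[:, q] - X @ beta
        s2 = resid @ resid / (n - p)
        cov = s2 * np.linalg.inv(X.T @ X)
        ts.append(beta[j] / np.sqrt(cov[j, j]))
    return np.array(ts)


def random_design(rng, n=40):
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
    return DesignMatrix(X=X, columns=["intercept", "x", "a1", "a2"], target="x")


class TestFitGlmField:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_node_ols_oracle(self, seed):
        rng = np.random.default_rng(seed)
        design = random_design(rng)
        Y = rng.normal(size=(40, 31))
        t, resid, nu = fit_glm_field(Y, design)
        expected = per_node_ols_t(Y, design.X, design.target_index)
        assert np.abs(t - expected).max() < 1e-10
        assert nu == 40 - 4

    def test_orthogonal_target_gives_zero_field(self, rng):
        n = 30
        x = np.repeat([1.0, -1.0], n // 2)
        X = np.column_stack([np.ones(n), x])
        design = DesignMatrix(X=X, columns=["intercept", "x"], target="x")
        Y = rng.normal(size=(n, 11))
        Y = Y - np.outer(x, x @ Y) / (x @ x)  # project out the target
        t, _, _ = fit_glm_field(Y, design)
        assert np.abs(t).max() < 1e-10

    def test_exact_fit_yields_infinite_t(self, rng):
        design = random_design(rng, n=40)
        Y = np.tile(design.X[:, 1], (5, 1)).T  # response equals the target column
        t, _, _ = fit_glm_field(Y, design)
        assert np.isinf(t).all()

    def test_rank_deficient_design_names_columns(self):
        n = 30
        a = np.random.default_rng(0).normal(size=n)
        X = np.column_stack([np.ones(n), a, 2 * a])
        with pytest.raises(ValueError, match="collinear"):
            DesignMatrix(X=X, columns=["intercept", "x", "x2"], target="x")

    def test_missing_nodes_rejected(self, rng):
        design = random_design(rng)
        Y = rng.normal(size=(40, 11))
        Y[3, 5] = np.nan
        with pytest.raises(ValueError, match="missing|finite"):
            fit_glm_field(Y, design)


class TestEstimateFwhm:
    def test_white_noise_is_rough(self, rng):
        R = rng.standard_normal((100, 101))
        assert estimate_fwhm(R) < 3.0

    def test_monotone_in_kernel_width(self, rng):
        white = rng.standard_normal((80, 101))
        est = [estimate_fwhm(gaussian_filter1d(white, s, axis=1, mode="wrap"))
               for s in (1.5, 3.0, 6.0, 12.0)]
        assert est == sorted(est)

    def test_kernel_fwhm_recovered(self, rng):
        # smoothing white noise with a Gaussian kernel of FWHM w yields a
        # field of random-field smoothness w
        w = 10.0
        R = smooth_gaussian_curves(500, 101, fwhm=w, rng=rng)
        assert estimate_fwhm(R) == pytest.approx(w, rel=0.1)

    def test_rank_one_residuals_are_perfectly_smooth(self, rng):
        base = rng.standard_normal(101)
        R = np.outer(rng.standard_normal(20), base)
        with pytest.warns(UserWarning, match="perfectly correlated"):
            assert estimate_fwhm(R) == 100.0


class TestRftThreshold:
    def test_smooth_limit_equals_pointwise_quantile(self):
        t_crit = rft_threshold(100, fwhm=100.0, field_length=100.0, alpha=0.05)
        assert t_crit == pytest.approx(stats.t.isf(0.025, 100), rel=1e-6)

    def test_monotone_decreasing_in_fwhm(self):
        assert rft_threshold(50, 5.0) > rft_threshold(50, 20.0)

    def test_two_tailed_above_one_tailed(self):
        assert rft_threshold(50, 10.0, two_tailed=True) > rft_threshold(50, 10.0, two_tailed=False)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1])
    def test_alpha_domain(self, alpha):
        with pytest.raises(ValueError):
            rft_threshold(50, 10.0, alpha=alpha)

    def test_matches_permutation_max_t_quantile(self):
        """RFT threshold within simulation error of a 1000-permutation max-|t|
        95th percentile on smooth null cohorts."""
        rng = np.random.default_rng(2024)
        rels = []
        for _ in range(4):
            n = 60
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            design = DesignMatrix(X=X, columns=["intercept", "x"], target="x")
            Y = smooth_gaussian_curves(n, 101, fwhm=12.0, rng=rng)
            _, resid, nu = fit_glm_field(Y, design)
            t_crit = rft_threshold(nu, estimate_fwhm(resid), 100.0, 0.05)
            maxt = []
            for _ in range(1000):
                Xp = X.copy()
                Xp[:, 1] = rng.permutation(Xp[:, 1])
                dp = DesignMatrix(X=Xp, columns=["intercept", "x"], target="x")
                tp, _, _ = fit_glm_field(Y, dp)
                maxt.append(np.abs(tp).max())
            perm_crit = np.quantile(maxt, 0.95)
            rels.append(t_crit / perm_crit - 1.0)
        assert abs(np.mean(rels)) < 0.10
        assert np.abs(rels).max() < 0.20


class TestExtractClusters:
    def test_subthreshold_field_gives_no_clusters(self):
        t = np.zeros(101)
        assert extract_clusters(t, 3.0, nu=50, fwhm=10.0) == []

    def test_interpolated_endpoints_match_analytic_crossing(self):
        t = np.zeros(101)
        t[40], t[41], t[42], t[43] = 1.0, 4.0, 4.0, 1.0
        u = 2.5
        clusters = extract_clusters(t, u, nu=50, fwhm=10.0)
        assert len(clusters) == 1
        c = clusters[0]
        assert c.start_pct == pytest.approx(40 + (u - 1.0) / 3.0)
        assert c.end_pct == pytest.approx(42 + (4.0 - u) / 3.0)
        assert c.sign == 1 and c.peak_t == 4.0

    def test_two_signed_runs_ordered_by_start(self):
        t = np.zeros(101)
        t[10:15] = 5.0
        t[60:70] = -5.0
        clusters = extract_clusters(t, 3.0, nu=50, fwhm=10.0)
        assert [c.sign for c in clusters] == [1, -1]
        assert clusters[0].start_pct < clusters[1].start_pct

    def test_extent_shrinks_as_threshold_rises(self, rng):
        t = gaussian_filter1d(rng.standard_normal(101) * 4, 4)
        lo = extract_clusters(t, 1.0, nu=50, fwhm=10.0)
        hi = extract_clusters(t, 2.0, nu=50, fwhm=10.0)
        assert sum(c.extent for c in hi) <= sum(c.extent for c in lo)
        assert len(hi) >= 0  # raising u can only split/remove, never widen

    def test_wider_cluster_has_smaller_p(self):
        t = np.zeros(101)
        t[10:14] = 4.0
        t[50:70] = 4.0
        small, big = extract_clusters(t, 3.0, nu=50, fwhm=10.0)
        assert big.p < small.p


class TestSpmTest:
    def _cohort(self, n=150, effects=(), seed=0, noise_sd=4.0):
        spec = CovariateSpec(n_subjects=n, seed=seed)
        return synthetic_curve_cohort(spec, effects=list(effects), noise_sd=noise_sd,
                                      noise_fwhm=10.0)

    def test_target_rescaling_leaves_t_field_unchanged(self):
        cohort, curves = self._cohort(seed=5)
        r1 = spm_test(curves["L4L5"], cohort, "chronicity")
        cohort2 = cohort.copy()
        cohort2["chronicity_yr"] = cohort2["chronicity_yr"] * 12.0 + 7.0  # months, shifted
        r2 = spm_test(curves["L4L5"], cohort2, "chronicity")
        assert np.allclose(r1.t_field, r2.t_field, atol=1e-9)
        assert r1.t_crit == pytest.approx(r2.t_crit)

    def test_injected_window_recovered(self):
        eff = EffectSpec("chronicity", (0.0, 24.0), 1.5, "L4L5", +1)
        cohort, curves = self._cohort(n=223, effects=[eff], seed=42)
        res = spm_test(curves["L4L5"], cohort, "chronicity")
        pos = [c for c in res.clusters if c.sign > 0]
        assert pos, "expected a supra-threshold cluster in the injected window"
        grid = np.linspace(0, 100, 1001)
        det = np.zeros(grid.size, dtype=bool)
        for c in pos:
            det |= (grid >= c.start_pct) & (grid <= c.end_pct)
        truth = grid <= 24.0
        jac = (det & truth).sum() / (det | truth).sum()
        assert jac >= 0.5

    def test_permuting_target_destroys_detection(self):
        eff = EffectSpec("chronicity", (0.0, 24.0), 1.5, "L4L5", +1)
        cohort, curves = self._cohort(n=223, effects=[eff], seed=7)
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(20):
            perm = cohort.copy()
            perm["chronicity_yr"] = rng.permutation(perm["chronicity_yr"].to_numpy())
            res = spm_test(curves["L4L5"], perm, "chronicity")
            hits += bool(res.clusters)
        assert hits <= 4  # detections should occur at roughly the alpha rate

    def test_small_cohort_warns(self):
        cohort, curves = self._cohort(n=12, seed=3)
        with pytest.warns(UserWarning, match="fewer than 20"):
            spm_test(curves["L4L5"], cohort, "chronicity")
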