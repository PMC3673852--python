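import numpy as np
import pytest

from oracles import gls_channels

from sepchan import (
    MAData,
    SimConfig,
    TargetsTable,
    build_channel_design,
    contrast_fit,
    fit_gene_lm,
    fit_log_ratio,
    make_contrasts,
    rescale_ma,
    simulate_two_channel,
    to_ma,
    transform_design,
)
from sepchan.io_design import ChannelDesign
from sepchan.linear_model import EstimabilityError


def _random_case(rng, n=None, p=None):
    n = n or int(rng.integers(3, 9))
    p = p or int(rng.integers(1, min(4, 2 * n - 2) + 1))
    while True:
        X = rng.normal(size=(2 * n, p))
        if np.linalg.matrix_rank(X) == p:
            break
    design = ChannelDesign(X=X, coef_names=[f"c{j}" for j in range(p)], n_arrays=n)
    ych = rng.normal(size=2 * n)
    ma = MAData(
        probes=["g"],
        arrays=[f"a{i}" for i in range(n)],
        M=(ych[n:] - ych[:n])[None, :],
        A=((ych[n:] + ych[:n]) / 2)[None, :],
    )
    return design, ma, ych


class TestRescale:
    def test_divisors(self):
        t = TargetsTable(arrays=["a1", "a2"], cy3=["B", "B"], cy5=["C", "C"])
        Z = transform_design(build_channel_design(t))
        ma = MAData(probes=["p"], arrays=t.arrays, M=[[1.0, 1.0]], A=[[1.0, 1.0]])
        z_half, Z_half = rescale_ma(ma, Z, 0.5)
        np.testing.assert_allclose(z_half[0, :2], 1.0)  # M divisor 1 at rho=0.5
        np.testing.assert_allclose(z_half[0, 2:], 1.0 / np.sqrt(0.75))
        z0, _ = rescale_ma(ma, Z, 0.0)
        np.testing.assert_allclose(z0[0, :2], 1.0 / np.sqrt(2.0))
        np.testing.assert_allclose(z0[0, 2:], np.sqrt(2.0))

    def test_rho_domain(self):
        t = TargetsTable(arrays=["a1", "a2"], cy3=["B", "B"], cy5=["C", "C"])
        Z = transform_design(build_channel_design(t))
        ma = MAData(probes=["p"], arrays=t.arrays, M=[[0.0, 0.0]], A=[[0.0, 0.0]])
        with pytest.raises(ValueError):
            rescale_ma(ma, Z, 1.0)

    def test_homoscedastic_after_rescaling(self):
        sigma2, rho = 0.25, 0.85
        cfg = SimConfig(G=30000, n_arrays=2, layout="paired", rho=rho,
                        d0=np.inf, s0_2=sigma2, prop_de=0.0, seed=3)
        y, targets, _ = simulate_two_channel(cfg)
        Z = transform_design(build_channel_design(targets))
        z_star, _ = rescale_ma(to_ma(y), Z, rho)
        vM = np.var(z_star[:, 0], ddof=1)
        vA = np.var(z_star[:, 2] - z_star[:, 3], ddof=1) / 2  # de-mean A pair
        se = sigma2 * np.sqrt(2 / (cfg.G - 1))
        assert abs(vM - sigma2) < 3 * se
        assert abs(vA - sigma2) < 3 * se


class TestGLSEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_ols_on_rescaled_equals_channel_gls(self, seed):
        rng = np.random.default_rng(seed)
        design, ma, ych = _random_case(rng)
        rho = float(rng.uniform(-0.9, 0.95))
        Z = transform_design(design)
        z_star, Z_star = rescale_ma(ma, Z, rho)
        fit = fit_gene_lm(z_star, Z_star)
        beta_gls = gls_channels(ych, design.X, rho, design.n_arrays)
        np.testing.assert_allclose(fit.beta[0], beta_gls, atol=1e-10)

    def test_zero_noise_exact(self):
        t = TargetsTable(arrays=["a1", "a2", "a3", "a4"], cy3=["R"] * 4,
                         cy5=["B", "B", "C", "C"])
        design = build_channel_design(t)
        Z = transform_design(design)
        beta = np.array([8.0, 9.0, 7.5])
        ych = design.X @ beta
        ma = MAData(probes=["g"], arrays=t.arrays,
                    M=(ych[4:] - ych[:4])[None, :],
                    A=((ych[4:] + ych[:4]) / 2)[None, :])
        z_star, Z_star = rescale_ma(ma, Z, 0.6)
        fit = fit_gene_lm(z_star, Z_star)
        np.testing.assert_allclose(fit.beta[0], beta, atol=1e-10)
        assert fit.sigma[0] == pytest.approx(0.0, abs=1e-10)

    def test_common_reference_inverse_variance_combination(self, rng):
        """The separate-channel B-C estimate is the precision-weighted
        combination of the M-value and A-value estimators."""
        n, rho = 8, 0.7
        t = TargetsTable(arrays=[f"a{i}" for i in range(n)], cy3=["R"] * n,
                         cy5=["B"] * 4 + ["C"] * 4)
        design = build_channel_design(t)
        Z = transform_design(design)
        ych = rng.normal(8, 1, 2 * n)
        M = ych[n:] - ych[:n]
        A = (ych[n:] + ych[:n]) / 2
        ma = MAData(probes=["g"], arrays=t.arrays, M=M[None, :], A=A[None, :])
        z_star, Z_star = rescale_ma(ma, Z, rho)
        fit = contrast_fit(fit_gene_lm(z_star, Z_star),
                           make_contrasts(design, ["BvsC = B - C"]))
        gamma_M = M[:4].mean() - M[4:].mean()
        gamma_A = 2 * (A[:4].mean() - A[4:].mean())
        wM, wA = 1 / (1 - rho), 1 / (1 + rho)
        expected = (wM * gamma_M + wA * gamma_A) / (wM + wA)
        assert fit.beta[0, 0] == pytest.approx(expected, abs=1e-10)


class TestContrastFit:
    def test_identity_contrast_is_noop(self, rng):
        design, ma, _ = _random_case(rng, n=5, p=3)
        Z = transform_design(design)
        z_star, Z_star = rescale_ma(ma, Z, 0.3)
        fit = fit_gene_lm(z_star, Z_star)
        from sepchan import ContrastMatrix

        ident = ContrastMatrix(C=np.eye(3), names=fit.coef_names)
        out = contrast_fit(fit, ident)
        np.testing.assert_allclose(out.beta, fit.beta)
        np.testing.assert_allclose(out.cov_unscaled, fit.cov_unscaled)

    def test_bilinearity_of_contrast_variance(self, rng):
        design, ma, _ = _random_case(rng, n=6, p=3)
        Z = transform_design(design)
        z_star, Z_star = rescale_ma(ma, Z, 0.2)
        fit = fit_gene_lm(z_star, Z_star)
        from sepchan import ContrastMatrix

        c = ContrastMatrix(C=np.array([[1.0], [-1.0], [0.0]]), names=["d"])
        out = contrast_fit(fit, c)
        V = fit.cov_unscaled
        assert out.cov_unscaled[0, 0] == pytest.approx(
            V[0, 0] + V[1, 1] - 2 * V[0, 1]
        )

    def test_unconnected_cross_island_closed_form(self, rng):
        """The separate-channel cross-island contrast equals
        Mbar_BC/2 - Mbar_DE/2 + Abar_BC - Abar_DE with scaled variance 4/n."""
        n, rho = 8, 0.85
        t = TargetsTable(
            arrays=[f"a{i}" for i in range(n)],
            cy3=["B"] * 4 + ["D"] * 4,
            cy5=["C"] * 4 + ["E"] * 4,
        )
        design = build_channel_design(t)
        Z = transform_design(design)
        ych = rng.normal(8, 1, 2 * n)
        M = ych[n:] - ych[:n]
        A = (ych[n:] + ych[:n]) / 2
        ma = MAData(probes=["g"], arrays=t.arrays, M=M[None, :], A=A[None, :])
        z_star, Z_star = rescale_ma(ma, Z, rho)
        fit = contrast_fit(fit_gene_lm(z_star, Z_star),
                           make_contrasts(design, ["BvsD = B - D"]))
        # note M = C - B within the first island (red minus green)
        expected = -M[:4].mean() / 2 + M[4:].mean() / 2 + A[:4].mean() - A[4:].mean()
        assert fit.beta[0, 0] == pytest.approx(expected, abs=1e-10)
        assert fit.cov_unscaled[0, 0] == pytest.approx(4.0 / n, abs=1e-10)


class TestLogRatioFit:
    def test_paired_design_is_paired_t(self, rng):
        n = 6
        t = TargetsTable(arrays=[f"a{i}" for i in range(n)], cy3=["B"] * n,
                         cy5=["C"] * n)
        M = rng.normal(0.5, 1.0, (1, n))
        ma = MAData(probes=["g"], arrays=t.arrays, M=M, A=np.full((1, n), 8.0))
        fit = contrast_fit(fit_log_ratio(ma, t),
                           make_contrasts(build_channel_design(t), ["CvsB = C - B"]))
        assert fit.beta[0, 0] == pytest.approx(M.mean())
        t_stat = fit.beta[0, 0] / (fit.sigma[0] * fit.stdev_unscaled[0])
        from scipy import stats

        t_ref = stats.ttest_1samp(M[0], 0.0).statistic
        assert t_stat == pytest.approx(t_ref)
        assert fit.df_residual == n - 1

    def test_common_reference_variance_via_monte_carlo(self):
        """var(Mbar_B - Mbar_C) = 8 sigma^2 (1-rho)/n under simulation."""
        n, rho, sigma2 = 8, 0.85, 0.25
        cfg = SimConfig(G=20000, n_arrays=n, rho=rho, d0=np.inf, s0_2=sigma2,
                        prop_de=0.0, seed=15)
        y, targets, _ = simulate_two_channel(cfg)
        design = build_channel_design(targets)
        fit = contrast_fit(fit_log_ratio(to_ma(y), targets, design),
                           make_contrasts(design, ["BvsC = B - C"]))
        est = fit.beta[:, 0]
        expect = 8 * sigma2 * (1 - rho) / n
        se = expect * np.sqrt(2 / (cfg.G - 1))
        assert abs(np.var(est, ddof=1) - expect) < 3 * se

    def test_cross_island_contrast_not_estimable(self, rng):
        t = TargetsTable(
            arrays=["a1", "a2", "a3", "a4"],
            cy3=["B", "B", "D", "D"],
            cy5=["C", "C", "E", "E"],
        )
        design = build_channel_design(t)
        ma = MAData(probes=["g"], arrays=t.arrays,
                    M=rng.normal(size=(1, 4)), A=np.full((1, 4), 8.0))
        fit = fit_log_ratio(ma, t, design)
        with pytest.raises(EstimabilityError, match="BvsD"):
            contrast_fit(fit, make_contrasts(design, ["BvsD = B - D"]))

    def test_within_island_contrast_still_estimable(self, rng):
        t = TargetsTable(
            arrays=["a1", "a2", "a3", "a4"],
            cy3=["B", "B", "D", "D"],
            cy5=["C", "C", "E", "E"],
        )
        design = build_channel_design(t)
        ma = MAData(probes=["g"], arrays=t.arrays,
                    M=rng.normal(size=(1, 4)), A=np.full((1, 4), 8.0))
        fit = contrast_fit(fit_log_ratio(ma, t, design),
                           make_contrasts(design, ["CvsB = C - B"]))
        assert fit.beta[0, 0] == pytest.approx(ma.M[0, :2].mean())


def test_paired_design_point_estimates_agree_across_methods(rng):
    """Where A carries no contrast information, the separate-channel and
    log-ratio point estimates coincide exactly."""
    n = 6
    t = TargetsTable(arrays=[f"a{i}" for i in range(n)], cy3=["B"] * n, cy5=["C"] * n)
    design = build_channel_design(t)
    Z = transform_design(design)
    M = rng.normal(0.4, 1.0, (1, n))
    A = rng.normal(8.0, 0.5, (1, n))
    ma = MAData(probes=["g"], arrays=t.arrays, M=M, A=A)
    cm = make_contrasts(design, ["CvsB = C - B"])
    z_star, Z_star = rescale_ma(ma, Z, 0.65)
    sep = contrast_fit(fit_gene_lm(z_star, Z_star), cm)
    lr = contrast_fit(fit_log_ratio(ma, t, design), cm)
    assert sep.beta[0, 0] == pytest.approx(lr.beta[0, 0], abs=1e-12)
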