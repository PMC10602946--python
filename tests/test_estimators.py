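"""MR estimators against hand calculations and independent WLS/GLS oracles."""

import numpy as np
import pytest
import statsmodels.api as sm

from mr2s.estimators import (HeterogeneityStats, InsufficientInstrumentsError,
                             egger, funnel_data, ivw, ivw_correlated,
                             leave_one_out, median_estimator, mode_estimator,
                             single_variant_scan, wald_ratio)

from conftest import make_instruments


class TestWald:
    def test_direct_division(self):
        (h,) = make_instruments([0.5], [0.05], [0.01])
        est = wald_ratio(h)
        assert est.beta == pytest.approx(0.1) and est.se == pytest.approx(0.02)

    def test_sign_flip_invariance(self):
        (a,) = make_instruments([0.5], [0.05], [0.01])
        (b,) = make_instruments([-0.5], [-0.05], [0.01])
        assert wald_ratio(a).beta == wald_ratio(b).beta
        assert wald_ratio(a).se == wald_ratio(b).se

    def test_zero_exposure_effect_rejected(self):
        (h,) = make_instruments([0.0], [0.05], [0.01])
        with pytest.raises(ZeroDivisionError):
            wald_ratio(h)


class TestIVW:
    def test_hand_computed_two_instrument_case(self):
        ins = make_instruments([1.0, 1.0], [0.1, 0.3], [0.1, 0.1])
        est = ivw(ins)
        assert est.beta == pytest.approx(0.2)
        assert est.heterogeneity.q == pytest.approx(2.0)
        assert est.heterogeneity.df == 1
        assert est.scale_phi == pytest.approx(2.0)
        assert est.se == pytest.approx(0.1)

    def test_exact_fit_has_zero_q(self):
        b = np.array([0.2, 0.4, 0.6])
        ins = make_instruments(b, 0.3 * b, [0.05, 0.04, 0.03])
        est = ivw(ins)
        assert est.beta == pytest.approx(0.3)
        assert est.heterogeneity.q == pytest.approx(0.0, abs=1e-20)
        assert est.scale_phi == 1.0

    def test_matches_wls_oracle(self, random_instruments):
        est = ivw(random_instruments)
        b = np.array([h.beta_exp for h in random_instruments])
        g = np.array([h.beta_out for h in random_instruments])
        w = np.array([1 / h.se_out ** 2 for h in random_instruments])
        fit = sm.WLS(g, b, weights=w).fit()
        assert est.beta == pytest.approx(fit.params[0], abs=1e-10)
        q = fit.ssr  # weighted residual sum of squares
        se0 = 1 / np.sqrt(np.sum(w * b * b))
        assert est.se == pytest.approx(se0 * np.sqrt(max(1.0, q / (len(b) - 1))), abs=1e-10)
        assert est.heterogeneity.q == pytest.approx(q, abs=1e-10)

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(make_instruments([0.1], [0.01], [0.01]))

    def test_never_deflated_below_fixed_effect(self, rng):
        for _ in range(20):
            b = rng.uniform(0.05, 0.5, 6)
            ins = make_instruments(b, 0.1 * b + rng.normal(0, 0.001, 6),
                                   rng.uniform(0.01, 0.05, 6))
            est = ivw(ins)
            se0 = 1 / np.sqrt(sum(1 / h.se_out ** 2 * h.beta_exp ** 2 for h in ins))
            assert est.se >= se0 - 1e-15


class TestIVWCorrelated:
    def test_identity_correlation_reduces_to_ivw(self, random_instruments):
        plain = ivw(random_instruments)
        gls = ivw_correlated(random_instruments, np.eye(5))
        assert gls.beta == pytest.approx(plain.beta, abs=1e-10)
        assert gls.se == pytest.approx(plain.se, abs=1e-10)
        assert gls.heterogeneity.q == pytest.approx(plain.heterogeneity.q, abs=1e-10)

    def test_two_instrument_closed_form(self):
        # GLS for 2 correlated instruments solved symbolically:
        # beta = b' Om^-1 g / b' Om^-1 b with Om = [[s1^2, r s1 s2],[r s1 s2, s2^2]]
        b = np.array([1.0, 2.0])
        g = np.array([0.15, 0.22])
        s = np.array([0.1, 0.2])
        rho = np.array([[1.0, 0.5], [0.5, 1.0]])
        om = np.outer(s, s) * rho
        oinv = np.linalg.inv(om)
        expected = (b @ oinv @ g) / (b @ oinv @ b)
        est = ivw_correlated(make_instruments(b, g, s), rho)
        assert est.beta == pytest.approx(expected, rel=1e-12)

    def test_ar1_block_matches_gls_oracle(self, rng):
        j = 8
        b = rng.uniform(0.05, 0.3, j)
        g = 0.1 * b + rng.normal(0, 0.01, j)
        s = rng.uniform(0.01, 0.04, j)
        idx = np.arange(j)
        rho = 0.3 ** np.abs(idx[:, None] - idx[None, :])
        om = np.outer(s, s) * rho
        fit = sm.GLS(g, b, sigma=om).fit()
        est = ivw_correlated(make_instruments(b, g, s), rho)
        assert est.beta == pytest.approx(fit.params[0], abs=1e-10)

    def test_non_positive_definite_rejected(self):
        rho = np.array([[1.0, 1.2], [1.2, 1.0]])
        with pytest.raises(np.linalg.LinAlgError, match="eigenvalue"):
            ivw_correlated(make_instruments([0.1, 0.2], [0.01, 0.02], [0.01, 0.01]), rho)


class TestEgger:
    def test_exact_line_through_three_points(self):
        ins = make_instruments([1.0, 2.0, 3.0], [0.3, 0.5, 0.7], [0.1, 0.1, 0.1])
        est = egger(ins)
        assert est.beta == pytest.approx(0.2)
        assert est.intercept == pytest.approx(0.1)
        assert est.heterogeneity.q == pytest.approx(0.0, abs=1e-20)

    def test_matches_wls_oracle_with_intercept(self, random_instruments):
        est = egger(random_instruments)
        b = np.array([h.beta_exp for h in random_instruments])
        g = np.array([h.beta_out for h in random_instruments])
        w = 1 / np.array([h.se_out for h in random_instruments]) ** 2
        fit = sm.WLS(g, sm.add_constant(b), weights=w).fit()
        assert est.intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert est.beta == pytest.approx(fit.params[1], abs=1e-10)
        # statsmodels scales by Q/(J-2); ours additionally floors phi at 1
        phi = fit.ssr / (len(b) - 2)
        factor = np.sqrt(max(1.0, phi) / phi)
        assert est.se == pytest.approx(fit.bse[1] * factor, abs=1e-10)

    def test_orientation_invariance(self, random_instruments):
        est = egger(random_instruments)
        flipped = list(random_instruments)
        h = flipped[2]
        from dataclasses import replace
        flipped[2] = replace(h, beta_exp=-h.beta_exp, beta_out=-h.beta_out)
        est2 = egger(flipped)
        assert est2.beta == pytest.approx(est.beta, rel=1e-12)
        assert abs(est2.intercept) == pytest.approx(abs(est.intercept), rel=1e-12)

    def test_t_reference_is_wider(self, random_instruments):
        pn = egger(random_instruments, p_reference="normal")
        pt = egger(random_instruments, p_reference="t")
        assert pt.pvalue > pn.pvalue

    def test_collinear_exposures_rejected(self):
        ins = make_instruments([0.2, 0.2, 0.2], [0.1, 0.2, 0.3], [0.1, 0.1, 0.1])
        with pytest.raises(np.linalg.LinAlgError):
            egger(ins)

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_instruments([0.1, 0.2], [0.01, 0.02], [0.01, 0.01]))


class TestMedian:
    def test_symmetric_equal_weight_median(self):
        ins = make_instruments([1, 1, 1], [0.1, 0.2, 0.3], [0.1, 0.1, 0.1])
        est = median_estimator(ins, weighted=True, n_boot=100, seed=1)
        assert est.beta == pytest.approx(0.2)
        est_s = median_estimator(ins, weighted=False, n_boot=100, seed=1)
        assert est_s.beta == pytest.approx(0.2)
        assert est_s.method == "simple_median"

    def test_hand_interpolated_weighted_median(self):
        # ratios (0.1, 0.2, 0.3), normalized weights (0.6, 0.2, 0.2)
        # cumulative midpoints s = (0.3, 0.7, 0.9) -> interpolate at 0.5 -> 0.15
        se_out = np.array([0.1, 0.1, 0.1])
        w_target = np.array([0.6, 0.2, 0.2])
        b = np.sqrt(w_target * se_out ** 2)  # since w = b^2 / se^2
        g = np.array([0.1, 0.2, 0.3]) * b
        est = median_estimator(make_instruments(b, g, se_out), weighted=True,
                               n_boot=100, seed=1)
        assert est.beta == pytest.approx(0.15)

    def test_bootstrap_se_reproducible(self):
        ins = make_instruments([0.2, 0.3, 0.4, 0.5], [0.02, 0.04, 0.03, 0.06],
                               [0.02, 0.02, 0.03, 0.02])
        a = median_estimator(ins, weighted=True, n_boot=500, seed=7)
        b = median_estimator(ins, weighted=True, n_boot=500, seed=7)
        assert a.se == b.se
        c = median_estimator(ins, weighted=True, n_boot=500, seed=8)
        assert c.se != a.se


class TestMode:
    def test_degenerate_identical_ratios(self):
        b = np.array([0.2, 0.3, 0.4])
        est = mode_estimator(make_instruments(b, 0.1 * b, [0.1, 0.1, 0.1]),
                             n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.1, abs=1e-9)

    def test_mode_tracks_majority_cluster(self, rng):
        # 10 ratios near 0 and 3 outliers near 1: mode sits in the big cluster
        b = np.ones(13)
        g = np.concatenate([rng.normal(0.0, 0.01, 10), rng.normal(1.0, 0.01, 3)])
        est = mode_estimator(make_instruments(b, g, np.full(13, 0.05)),
                             n_boot=50, seed=1)
        assert abs(est.beta) < 0.1

    def test_grid_search_oracle(self, random_instruments):
        # argmax over a very fine grid agrees with the refined estimate
        b = np.array([h.beta_exp for h in random_instruments])
        g = np.array([h.beta_out for h in random_instruments])
        s = np.array([h.se_out for h in random_instruments])
        theta = g / b
        w = b ** 2 / s ** 2
        w = w / w.sum()
        sd = np.std(theta, ddof=1)
        iqr = np.subtract(*np.percentile(theta, [75, 25]))
        h_bw = 0.9 * min(sd, iqr / 1.349) * len(theta) ** -0.2
        grid = np.linspace(theta.mean() - 4 * sd, theta.mean() + 4 * sd, 200_001)
        dens = (w * np.exp(-0.5 * ((grid[:, None] - theta) / h_bw) ** 2)).sum(axis=1)
        expected = grid[np.argmax(dens)]
        est = mode_estimator(random_instruments, n_boot=10, seed=1)
        assert est.beta == pytest.approx(expected, abs=1e-4)

    def test_weight_scale_invariance(self, random_instruments):
        from dataclasses import replace
        est = mode_estimator(random_instruments, n_boot=10, seed=3)
        doubled = [replace(h, se_out=h.se_out / np.sqrt(2)) for h in random_instruments]
        est2 = mode_estimator(doubled, n_boot=10, seed=3)
        assert est2.beta == pytest.approx(est.beta, abs=1e-9)


class TestScansAndTables:
    def test_single_variant_scan_order_and_constant_ratio(self):
        b = np.array([0.2, 0.3, 0.5])
        ins = make_instruments(b, 0.25 * b, [0.01, 0.01, 0.01])
        scan = single_variant_scan(ins)
        assert [r for r, _ in scan] == [h.rsid for h in ins]
        assert all(est.beta == pytest.approx(0.25) for _, est in scan)

    def test_leave_one_out_count_and_membership(self, random_instruments):
        loo = leave_one_out(random_instruments)
        assert len(loo) == 5
        assert all(est.n_variants == 4 for _, est in loo)

    def test_explicit_exclusion_list(self, random_instruments):
        (label, est), = leave_one_out(random_instruments, exclude=("rs0", "rs1"))
        assert label == "rs0-rs1" and est.n_variants == 3

    def test_negligible_instrument_leaves_estimate_unchanged(self):
        ins = make_instruments([0.2, 0.3, 0.4], [0.02, 0.03, 0.04], [0.01, 0.01, 0.01])
        huge_se = make_instruments([0.5], [0.9], [1e6], rsids=["rsW"])
        est_with = ivw(ins + huge_se)
        est_without = ivw(ins)
        assert est_with.beta == pytest.approx(est_without.beta, abs=1e-9)

    def test_funnel_table_shape_and_precision(self, random_instruments):
        fd = funnel_data(random_instruments)
        assert list(fd.columns) == ["rsid", "wald_beta", "precision"]
        assert len(fd) == 5
        h = random_instruments[0]
        assert fd.loc[0, "precision"] == pytest.approx(abs(h.beta_exp) / h.se_out)


class TestEquivariance:
    @pytest.mark.parametrize("method", ["ivw", "egger", "median", "mode"])
    def test_scaling_exposure_divides_estimate(self, method, random_instruments):
        from dataclasses import replace
        c = 2.5
        scaled = [replace(h, beta_exp=c * h.beta_exp, se_exp=c * h.se_exp)
                  for h in random_instruments]
        run = {
            "ivw": lambda ins: ivw(ins).beta,
            "egger": lambda ins: egger(ins).beta,
            "median": lambda ins: median_estimator(ins, n_boot=10, seed=1).beta,
            "mode": lambda ins: mode_estimator(ins, n_boot=10, seed=1).beta,
        }[method]
        assert run(scaled) == pytest.approx(run(random_instruments) / c, rel=1e-6)


def test_heterogeneity_identity_holds_on_every_output(rng):
    for _ in range(10):
        b = rng.uniform(0.05, 0.5, 6)
        g = 0.1 * b + rng.normal(0, 0.02, 6)
        est = ivw(make_instruments(b, g, rng.uniform(0.01, 0.05, 6)))
        h = est.heterogeneity
        expected = max(0.0, (h.q - h.df) / h.q) * 100 if h.q > 0 else 0.0
        assert h.i2 == pytest.approx(expected, abs=1e-12)
        assert 0 <= h.i2 <= 100


def test_ci_brackets_or():
    est = ivw(make_instruments([1.0, 1.0], [0.1, 0.3], [0.1, 0.1]))
    assert est.ci_low < est.or_value < est.ci_high
    assert 0 < est.pvalue <= 1
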