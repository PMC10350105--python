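"""Classical Poisson-likelihood inversion of the edge shift."""

import numpy as np
import pytest
from sklearn.base import clone

from spread.classic_fit import (
    EdgeShiftMLE,
    FitParams,
    FreeCurveMLE,
    edge_shift_interval,
    fit,
    negative_log_likelihood,
)
from spread.forward import build_tables
from spread.simulator import simulate_dataset


@pytest.fixture(scope="module")
def exact_tables(exact_noisefree_dataset):
    ds, truth = exact_noisefree_dataset
    # linear curve interpolation matches the generator's tabulation exactly
    tables = build_tables(ds, curve_interp="linear")
    truth_params = FitParams(
        edge_shift=truth.edge_shift_ev,
        log_scales=np.log(truth.scales),
        log_backgrounds=np.log(np.full(tables.n_boxes, 2.0)),
    )
    return tables, truth, truth_params


class TestNLL:
    def test_minimum_at_observed_mean(self, exact_tables):
        """For one pixel with observed n, mu - n log mu is minimized at
        mu = n (the Poisson MLE)."""
        n = 5.0
        mus = np.linspace(1.0, 12.0, 400)
        vals = mus - n * np.log(mus)
        assert mus[np.argmin(vals)] == pytest.approx(5.0, abs=0.05)

    def test_matches_per_pixel_hand_sum(self, exact_tables):
        tables, truth, p = exact_tables
        val = negative_log_likelihood(p, tables)
        g_box = p.scales[tables.shot_index]
        mu = tables.expected(p.edge_shift, g_box, p.backgrounds)
        hand = 0.0
        for b in range(tables.n_boxes):
            for px in range(tables.npix):
                hand += mu[b, px] - tables.counts[b, px] * np.log(mu[b, px])
        assert val == pytest.approx(hand, rel=1e-10)

    def test_gradient_matches_finite_differences(self):
        ds, _ = simulate_dataset(n_shots=3, seed=21, edge_shift_ev=1.0)
        tables = build_tables(ds)
        p = FitParams.initial(tables)
        p.edge_shift = 0.4
        val, grad = negative_log_likelihood(p, tables, return_grad=True)
        theta = p.pack()
        for idx in (0, 1, 1 + tables.n_shots):
            t2 = theta.copy()
            t2[idx] += 1e-6
            v2 = negative_log_likelihood(FitParams.unpack(t2, tables.n_shots), tables)
            fd = (v2 - val) / 1e-6
            assert grad[idx] == pytest.approx(fd, rel=5e-3, abs=1e-4)


class TestFit:
    def test_noisefree_truth_is_fixed_point(self, exact_tables):
        """Noise-off data generated by the exact model: starting at the
        truth, the optimizer stays there."""
        tables, truth, p = exact_tables
        result = fit(tables, init=p)
        assert result.n_iter <= 1
        assert result.params.edge_shift == pytest.approx(truth.edge_shift_ev, abs=1e-6)
        assert result.grad_norm < 1e-4

    def test_recovers_injected_shift(self, small_noisy_dataset):
        ds, truth = small_noisy_dataset
        result = fit(build_tables(ds))
        assert result.converged
        assert result.params.edge_shift == pytest.approx(truth.edge_shift_ev, abs=0.5)

    def test_monotone_loss_trace(self, small_noisy_dataset):
        ds, _ = small_noisy_dataset
        result = fit(build_tables(ds))
        assert np.all(np.diff(result.loss_trace) <= 1e-6 * np.abs(result.loss_trace[:-1]))

    def test_scale_intensity_degeneracy(self, exact_noisefree_dataset):
        """Multiplying every shot's counts and scale estimate by c leaves
        the recovered edge shift unchanged: the shift enters only through
        the energy dependence."""
        import copy

        ds, truth = exact_noisefree_dataset
        shift0 = fit(build_tables(ds, curve_interp="linear"), ftol=1e-11, max_iter=4000).params.edge_shift
        scaled = copy.deepcopy(ds)
        for shot in scaled.shots:
            shot.metadata["scale_estimate"] *= 3.0
            for box in shot.shoeboxes:
                box.counts = np.asarray(box.counts) * 3.0
                box.metadata["scale_estimate"] *= 3.0
        shift1 = fit(build_tables(scaled, curve_interp="linear"), ftol=1e-11, max_iter=4000).params.edge_shift
        assert shift1 == pytest.approx(shift0, abs=0.02)

    def test_identifiability_noisefree(self, exact_tables):
        """NLL at the truth beats NLL with the edge mis-set by 2 eV."""
        tables, truth, p = exact_tables
        at_truth = negative_log_likelihood(p, tables)
        p_bad = FitParams(p.edge_shift + 2.0, p.log_scales, p.log_backgrounds)
        assert at_truth < negative_log_likelihood(p_bad, tables)

    def test_nonfinite_init_rejected(self, exact_tables):
        tables, _, p = exact_tables
        bad = FitParams(np.nan, p.log_scales, p.log_backgrounds)
        with pytest.raises(ValueError):
            fit(tables, init=bad)


class TestIntervals:
    def test_refuses_nonconverged_fit(self, exact_tables):
        tables, _, p = exact_tables
        result = fit(tables, init=p)
        result.converged = False
        with pytest.raises(RuntimeError):
            edge_shift_interval(tables, result)

    def test_profile_interval_contains_estimate_and_is_narrow_noisefree(self, exact_tables):
        tables, truth, p = exact_tables
        result = fit(tables, init=p)
        lo, hi = edge_shift_interval(tables, result, method="profile", level=0.9)
        assert lo <= result.params.edge_shift <= hi
        # nuisance compensation keeps some width even without noise, but the
        # interval is far tighter than the +/-1.5 eV scan range
        assert hi - lo < 1.2

    def test_bootstrap_interval_contains_estimate(self):
        ds, _ = simulate_dataset(n_shots=8, seed=33, edge_shift_ev=2.0)
        tables = build_tables(ds)
        result = fit(tables)
        lo, hi = edge_shift_interval(
            tables, result, method="bootstrap", level=0.9, n_boot=15, seed=0
        )
        assert lo <= result.params.edge_shift <= hi

    def test_unknown_method_rejected(self, exact_tables):
        tables, _, p = exact_tables
        result = fit(tables, init=p)
        with pytest.raises(ValueError):
            edge_shift_interval(tables, result, method="jackknife")

    def test_null_coverage_bootstrap(self):
        """90% parametric-bootstrap intervals over repeated null simulations
        cover the true value 0 most of the time (binomial slack).

        Run under a well-specified generating model (single mosaic domain,
        exact metadata): the Poisson parametric bootstrap only resamples
        counting noise, so mosaic-domain randomness — which it cannot see —
        would otherwise produce genuine undercoverage."""
        from spread.simulator import MosaicModel

        mos = MosaicModel(n_domains=1, angular_spread_mrad=0.0)
        hits = 0
        n_sims = 20
        for i in range(n_sims):
            ds, _ = simulate_dataset(
                n_shots=10, seed=5000 + i, edge_shift_ev=0.0, mosaic=mos,
                scale_est_sigma=0.0, orientation_est_mrad=0.0, cell_jitter=0.0,
            )
            tables = build_tables(ds)
            result = fit(tables)
            lo, hi = edge_shift_interval(
                tables, result, method="bootstrap", level=0.9, n_boot=40, seed=i
            )
            hits += lo <= 0.0 <= hi
        assert hits >= 14


class TestEstimatorFacade:
    def test_sklearn_contract(self):
        est = EdgeShiftMLE(max_iter=50)
        assert clone(est).get_params() == est.get_params()
        est.set_params(gtol=1e-5)
        assert est.get_params()["gtol"] == 1e-5

    def test_fit_sets_attributes(self, small_noisy_dataset):
        ds, truth = small_noisy_dataset
        est = EdgeShiftMLE().fit(ds)
        assert est.edge_shift_ == pytest.approx(truth.edge_shift_ev, abs=0.5)
        assert est.scales_.shape == (len(ds.shots),)
        assert np.all(est.backgrounds_ > 0)
        assert np.isfinite(est.score())


class TestFreeCurveMode:
    def test_recovers_shifted_curve_shape(self, small_noisy_dataset):
        """The free per-channel fit should place the absorption step near
        the shifted edge and keep f'' nonnegative."""
        ds, truth = small_noisy_dataset
        est = FreeCurveMLE(smoothness=10.0, max_iter=300).fit(ds)
        assert np.all(est.f_double_prime_ >= 0)
        tables = build_tables(ds)
        f1_ref, f2_ref = tables.curve_at(truth.edge_shift_ev)
        # correlation with the true (shifted) curve beats the unshifted one
        f1_0, f2_0 = tables.curve_at(0.0)
        err_true = np.mean((est.f_double_prime_ - f2_ref) ** 2)
        err_null = np.mean((est.f_double_prime_ - f2_0) ** 2)
        assert err_true < err_null


class TestNoiseModelsAndRobustness:
    def test_gaussian_noise_model_recovers_shift(self, small_noisy_dataset):
        """Gaussian (variance = mean) likelihood agrees with Poisson at
        these count levels."""
        ds, truth = small_noisy_dataset
        result = fit(build_tables(ds), noise_model="gaussian")
        assert result.params.edge_shift == pytest.approx(truth.edge_shift_ev, abs=0.5)

    def test_gaussian_gradient_matches_finite_differences(self):
        ds, _ = simulate_dataset(n_shots=2, seed=55, edge_shift_ev=1.0)
        tables = build_tables(ds)
        p = FitParams.initial(tables)
        p.edge_shift = 0.3
        val, grad = negative_log_likelihood(
            p, tables, return_grad=True, noise_model="gaussian"
        )
        theta = p.pack()
        for idx in (0, 1, 1 + tables.n_shots):
            t2 = theta.copy()
            t2[idx] += 1e-6
            v2 = negative_log_likelihood(
                FitParams.unpack(t2, tables.n_shots), tables, noise_model="gaussian"
            )
            assert grad[idx] == pytest.approx((v2 - val) / 1e-6, rel=5e-3, abs=1e-4)

    def test_unknown_noise_model_rejected(self, exact_tables):
        tables, _, p = exact_tables
        with pytest.raises(ValueError):
            negative_log_likelihood(p, tables, noise_model="cauchy")

    def test_robust_refit_limits_outlier_influence(self):
        """A handful of corrupted pixels (zingers) perturbs the Huberized
        fit less than the plain likelihood fit."""
        import copy

        ds, truth = simulate_dataset(n_shots=25, seed=66, edge_shift_ev=2.0)
        clean = fit(build_tables(ds)).params.edge_shift
        corrupted = copy.deepcopy(ds)
        rng = np.random.default_rng(1)
        boxes = [b for s in corrupted.shots for b in s.shoeboxes]
        for b in rng.choice(len(boxes), size=12, replace=False):
            counts = np.asarray(boxes[b].counts).copy()
            i, j = rng.integers(counts.shape[0]), rng.integers(counts.shape[1])
            counts[i, j] = 50000
            boxes[b].counts = counts
        tables_bad = build_tables(corrupted)
        plain = fit(tables_bad).params.edge_shift
        robust = fit(tables_bad, robust_delta=5.0).params.edge_shift
        assert abs(robust - clean) < abs(plain - clean)
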