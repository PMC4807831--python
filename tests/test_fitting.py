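import math

import numpy as np
import pytest

import petwashout as pw
from petwashout.kinetics import LN2


def tac_from_lambda(lam, a0=1e5, protocol=None, physical=None):
    """Noiseless frame-averaged TAC straight from the kinetic model."""
    protocol = protocol or pw.AcquisitionProtocol.default()
    total = lam + (physical or 0.0)
    values = a0 * pw.frame_averaged_exp(total, protocol.start_times, protocol.durations)
    prov = {"physical_lambda": physical, "physical_decay_in_data": physical is not None}
    return pw.TimeActivityCurve(
        times=protocol.mid_times,
        values=values,
        frame_starts=protocol.start_times,
        frame_durations=protocol.durations,
        decay_corrected=physical is None,
        provenance=prov,
    )


def point_tac(lam, times, a0=1.0):
    return pw.TimeActivityCurve(
        times=times, values=a0 * np.exp(-lam * np.asarray(times)), decay_corrected=True
    )


class TestSingleExponentialFit:
    @pytest.mark.parametrize("lam_T", [0.5, 1.0, 2.0, 5.0, 10.0])
    def test_noiseless_consistency_across_decay_scales(self, lam_T):
        # generative lambda spanning lambda * total_duration in [0.5, 10]
        lam = lam_T / 3600.0
        r = pw.fit_single_exponential(tac_from_lambda(lam))
        assert r.converged
        assert r.lambda_hat == pytest.approx(lam, rel=1e-6)

    def test_tissular_halflife_recovered(self):
        lam = pw.halflife_to_lambda(2878.0)
        r = pw.fit_single_exponential(tac_from_lambda(lam))
        assert r.halflife_hat == pytest.approx(2878.0, rel=1e-3)

    def test_constant_tac_degenerates_to_infinite_halflife(self):
        r = pw.fit_single_exponential(tac_from_lambda(0.0))
        assert r.lambda_hat == pytest.approx(0.0, abs=1e-12)
        assert r.halflife_hat == math.inf

    def test_loglinear_init_already_optimal_on_exact_data(self):
        # point-sampled exact exponential: the closed-form log-linear slope is
        # the optimum and the nonlinear pass must not move away from it
        lam = 2e-3
        times = np.array([0.0, 400.0, 900.0, 1500.0, 2200.0])
        r = pw.fit_single_exponential(point_tac(lam, times, a0=3.0))
        assert r.lambda_hat == pytest.approx(lam, rel=1e-10)
        assert r.amplitude_hat == pytest.approx(3.0, rel=1e-10)

    def test_physical_decay_aware_model(self):
        # uncorrected TAC with known physical constant: fitted lambda is biological
        lam, phys = pw.halflife_to_lambda(2878.0), pw.halflife_to_lambda(1223.4)
        r = pw.fit_single_exponential(tac_from_lambda(lam, physical=phys))
        assert r.lambda_hat == pytest.approx(lam, rel=1e-8)

    def test_window_excludes_early_transient(self):
        lam = pw.halflife_to_lambda(2019.0)
        tac = tac_from_lambda(lam)
        corrupted = tac.values.copy()
        corrupted[tac.times < 500.0] *= 1.5  # pressure re-equilibration transient
        bad = pw.TimeActivityCurve(
            times=tac.times,
            values=corrupted,
            frame_starts=tac.frame_starts,
            frame_durations=tac.frame_durations,
            decay_corrected=True,
        )
        r_full = pw.fit_single_exponential(bad)
        r_win = pw.fit_single_exponential(bad, window=(600.0, None))
        assert abs(r_win.halflife_hat - 2019.0) < abs(r_full.halflife_hat - 2019.0)
        assert r_win.halflife_hat == pytest.approx(2019.0, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 frames"):
            pw.fit_single_exponential(point_tac(1e-3, np.array([0.0, 10.0, 20.0, 30.0])), window=(0.0, 15.0))

    def test_poisson_weighting_runs(self):
        rng = np.random.default_rng(1)
        tac = tac_from_lambda(1e-3)
        noisy = pw.TimeActivityCurve(
            times=tac.times,
            values=tac.values * rng.normal(1.0, 0.01, tac.n_frames).clip(0.5),
            frame_starts=tac.frame_starts,
            frame_durations=tac.frame_durations,
            decay_corrected=True,
        )
        r = pw.fit_single_exponential(noisy, weighting="poisson")
        assert r.converged
        assert r.lambda_hat == pytest.approx(1e-3, rel=0.05)

    def test_standard_errors_reported(self):
        rng = np.random.default_rng(2)
        tac = tac_from_lambda(1e-3)
        noisy = pw.TimeActivityCurve(
            times=tac.times,
            values=tac.values * rng.normal(1.0, 0.01, tac.n_frames).clip(0.5),
            frame_starts=tac.frame_starts,
            frame_durations=tac.frame_durations,
            decay_corrected=True,
        )
        r = pw.fit_single_exponential(noisy)
        assert 0 < r.stderr_lambda < r.lambda_hat
        assert "half-life" in r.summary()


class TestDecomposition:
    def test_subtraction_recovers_washout(self):
        la = pw.halflife_to_lambda(1.0 / (1.0 / 2878.0 + 1.0 / 330.0))
        ld = pw.halflife_to_lambda(2878.0)
        fa = pw.fit_single_exponential(tac_from_lambda(la))
        fd = pw.fit_single_exponential(tac_from_lambda(ld))
        dec = pw.decompose(fa, fd, mode="subtraction")
        assert dec.mode == "subtraction"
        assert dec.halflife_wash == pytest.approx(330.0, rel=1e-6)
        assert dec.halflife_tiss == pytest.approx(2878.0, rel=1e-6)

    def test_equal_rates_flag_no_washout(self):
        lam = pw.halflife_to_lambda(2878.0)
        f = pw.fit_single_exponential(tac_from_lambda(lam))
        dec = pw.decompose(f, f)
        assert dec.no_detectable_washout
        assert dec.halflife_wash == math.inf

    def test_direct_mode_is_identity_on_alive_rate(self):
        la = pw.halflife_to_lambda(296.0)
        ld = pw.halflife_to_lambda(2878.0)
        fa = pw.fit_single_exponential(tac_from_lambda(la))
        fd = pw.fit_single_exponential(tac_from_lambda(ld))
        dec = pw.decompose(fa, fd, mode="direct")
        assert dec.lambda_wash_hat == fa.lambda_hat
        assert dec.halflife_wash == pytest.approx(296.0, rel=1e-6)

    def test_unconverged_fit_rejected(self):
        f = pw.fit_single_exponential(tac_from_lambda(1e-3))
        bad = pw.ExponentialFitResult(
            amplitude_hat=1.0,
            lambda_hat=1e-3,
            stderr_amplitude=0.0,
            stderr_lambda=0.0,
            fit_window=(0.0, 1.0),
            n_points=5,
            residual_rms=0.0,
            converged=False,
        )
        with pytest.raises(ValueError, match="converged"):
            pw.decompose(f, bad)

    def test_noiseless_pipeline_subtraction_identity(self, pair_recovery):
        # end to end: simulate alive (tiss+wash) and dead (tiss) images, fit,
        # subtract -- washout constant comes back exactly
        t_tiss, t_wash = pair_recovery(2878.0, 330.0)
        assert t_tiss == pytest.approx(2878.0, rel=1e-6)
        assert t_wash == pytest.approx(330.0, rel=1e-6)


class TestMizunoFit:
    def test_single_component_matches_single_exponential(self):
        lam = pw.halflife_to_lambda(2000.0)
        tac = tac_from_lambda(lam)
        r1 = pw.fit_single_exponential(tac)
        rm = pw.fit_mizuno(tac, n_components=1)
        assert rm.params.lambdas[0] == pytest.approx(r1.lambda_hat, rel=1e-8)
        assert rm.amplitude_hat == pytest.approx(r1.amplitude_hat, rel=1e-8)
        assert rm.params.fractions == (1.0, 0.0, 0.0)

    def test_three_component_recovery(self):
        M, lams = (0.5, 0.3, 0.2), (0.01, 0.001, 0.0001)
        p = pw.MizunoParams(M, lams)
        t = np.linspace(0.0, 30000.0, 100)
        tac = pw.TimeActivityCurve(
            times=t, values=4.0 * pw.eval_mizuno(p, t), decay_corrected=True
        )
        r = pw.fit_mizuno(tac, n_components=3)
        assert r.converged
        for got, want in zip(r.params.fractions, M):
            assert got == pytest.approx(want, abs=0.01)
        for got, want in zip(r.params.lambdas, lams):
            assert got == pytest.approx(want, rel=0.01)

    def test_fractions_sum_to_one_exactly(self):
        rng = np.random.default_rng(7)
        p = pw.MizunoParams((0.6, 0.4, 0.0), (0.005, 0.0005, 0.0))
        t = np.linspace(0.0, 10000.0, 60)
        y = pw.eval_mizuno(p, t) * rng.normal(1.0, 0.02, t.size).clip(0.2)
        tac = pw.TimeActivityCurve(times=t, values=y, decay_corrected=True)
        r = pw.fit_mizuno(tac, n_components=2)
        assert abs(sum(r.params.fractions) - 1.0) <= 1e-9
        assert r.params.lambdas[0] >= r.params.lambdas[1] >= r.params.lambdas[2]

    def test_identical_components_collapse(self):
        lam = 1e-3
        tac = tac_from_lambda(lam)
        r = pw.fit_mizuno(tac, n_components=2)
        # a single-exponential curve cannot support two distinct components
        assert r.collapsed or r.lambda_gap < 10.0
        assert sum(r.params.fractions) == pytest.approx(1.0, abs=1e-9)

    def test_insufficient_frames_rejected(self):
        tac = point_tac(1e-3, np.linspace(0, 100, 5))
        with pytest.raises(ValueError, match="frames"):
            pw.fit_mizuno(tac, n_components=3)


class TestGroupSummary:
    def test_identical_values(self):
        g = pw.summarize_group([330.0] * 4, "brain", "washout")
        assert (g.mean_halflife, g.sd_halflife, g.n) == (330.0, 0.0, 4)

    def test_two_point_sample_sd(self):
        g = pw.summarize_group([300.0, 360.0], "muscle", "washout")
        assert g.mean_halflife == pytest.approx(330.0)
        assert g.sd_halflife == pytest.approx(math.sqrt(2) * 30.0, abs=0.01)  # 42.43

    def test_single_animal_convention(self):
        g = pw.summarize_group([500.0], "tumor", "tissular")
        assert (g.n, g.sd_halflife) == (1, 0.0)
        assert "single animal" in str(g)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pw.summarize_group([], "brain", "washout")
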