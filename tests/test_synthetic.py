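import math

import numpy as np
import pytest
from scipy.integrate import quad

import petwashout as pw
from petwashout.synthetic import GAUSS_FWHM_PER_SIGMA, _source_weights


class TestProtocol:
    def test_default_binning(self, protocol):
        assert protocol.n_frames == 25
        assert protocol.total_duration == 3600.0
        d = protocol.durations
        assert list(d[:10]) == [30.0] * 10
        assert list(d[10:15]) == [60.0] * 5
        assert list(d[15:]) == [300.0] * 10

    def test_frame_times_consistent(self, protocol):
        assert protocol.start_times[0] == 0.0
        np.testing.assert_allclose(
            protocol.end_times, protocol.start_times + protocol.durations
        )
        np.testing.assert_allclose(
            protocol.mid_times, (protocol.start_times + protocol.end_times) / 2
        )

    def test_empty_or_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            pw.AcquisitionProtocol(())
        with pytest.raises(ValueError):
            pw.AcquisitionProtocol((30.0, 0.0))


class TestFrameAverageActivity:
    def test_constant_source(self, isotope, protocol):
        p = pw.TwoComponentParams(0.9e6, 0.0, 0.0)
        fa = pw.frame_average_activity(
            p, pw.Condition.ALIVE, isotope, protocol, include_physical_decay=False
        )
        np.testing.assert_allclose(fa, 0.9e6, rtol=1e-14)

    def test_single_exponential_closed_form(self, isotope, protocol):
        lam = pw.halflife_to_lambda(2878.0)
        p = pw.TwoComponentParams(1.0, lam, 0.0)
        fa = pw.frame_average_activity(
            p, pw.Condition.DEAD, isotope, protocol, include_physical_decay=False
        )
        assert fa[0] == pytest.approx((1 - math.exp(-30 * lam)) / (30 * lam), rel=1e-12)
        # numerical quadrature oracle on every frame
        for f in range(protocol.n_frames):
            t0, dt = protocol.start_times[f], protocol.durations[f]
            val, _ = quad(lambda t: math.exp(-lam * t), t0, t0 + dt, epsabs=1e-12)
            assert fa[f] == pytest.approx(val / dt, rel=1e-8)

    def test_physical_decay_included(self, isotope, protocol):
        p = pw.TwoComponentParams(1.0, 0.0, 0.0)
        fa = pw.frame_average_activity(
            p, pw.Condition.DEAD, isotope, protocol, include_physical_decay=True
        )
        expected = pw.frame_averaged_exp(
            isotope.lambda_phys, protocol.start_times, protocol.durations
        )
        np.testing.assert_allclose(fa, expected, rtol=1e-14)


class TestRenderFrames:
    def test_noiseless_activity_conservation(self, scanner, injection, protocol):
        fa = np.full(protocol.n_frames, 0.9e6)
        s = pw.render_frames(fa, scanner, injection, protocol, noise=False)
        sums = s.values.sum(axis=(1, 2, 3))
        expected = fa * scanner.sensitivity * protocol.durations
        np.testing.assert_allclose(sums, expected, rtol=1e-6)

    def test_expected_counts_budget(self, scanner, injection):
        # 0.9 MBq for 30 s at 10% sensitivity -> ~2.7e6 detected counts
        protocol = pw.AcquisitionProtocol((30.0,))
        s = pw.render_frames([0.9e6], scanner, injection, protocol, noise=False)
        assert s.values.sum() == pytest.approx(0.9e6 * 0.10 * 30.0, rel=1e-6)

    def test_seed_determinism(self, scanner, injection, protocol):
        fa = np.full(protocol.n_frames, 1e5)
        a = pw.render_frames(fa, scanner, injection, protocol, noise=True, seed=42)
        b = pw.render_frames(fa, scanner, injection, protocol, noise=True, seed=42)
        c = pw.render_frames(fa, scanner, injection, protocol, noise=True, seed=43)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_counts_are_integers_in_noise_mode(self, scanner, injection):
        protocol = pw.AcquisitionProtocol((30.0,))
        s = pw.render_frames([1e4], scanner, injection, protocol, noise=True, seed=0)
        assert np.array_equal(s.values, np.round(s.values))

    def test_boundary_source_rejected(self, scanner, protocol):
        inj = pw.InjectionSpec(position=(1.0, 8.0, 8.0))
        with pytest.raises(ValueError, match="truncat"):
            pw.render_frames(
                np.ones(protocol.n_frames), scanner, inj, protocol, noise=False
            )

    def test_poisson_mean_converges_to_expectation(self, small_scanner):
        # law of large numbers: per-voxel mean of seeded replicates vs expectation
        protocol = pw.AcquisitionProtocol((30.0,))
        inj = pw.InjectionSpec()
        expected = pw.render_frames(
            [2e4], small_scanner, inj, protocol, noise=False
        ).values[0]
        n_rep = 200
        acc = np.zeros_like(expected)
        for seed in range(n_rep):
            acc += pw.render_frames(
                [2e4], small_scanner, inj, protocol, noise=True, seed=seed
            ).values[0]
        mean = acc / n_rep
        hot = expected > 50
        z = (mean[hot] - expected[hot]) / np.sqrt(expected[hot] / n_rep)
        assert np.all(np.abs(z) < 4.5)
        assert np.abs(z).mean() < 1.5

    def test_dead_dominates_alive_in_expectation(self, scanner, injection, protocol, isotope):
        p = pw.TwoComponentParams.from_halflives(1e6, 2878.0, 330.0)
        series = {}
        for cond in pw.Condition:
            fa = pw.frame_average_activity(p, cond, isotope, protocol)
            series[cond] = pw.render_frames(fa, scanner, injection, protocol, noise=False)
        diff = series[pw.Condition.DEAD].values - series[pw.Condition.ALIVE].values
        assert np.all(diff[1:] > -1e-12)  # identical at t=0 frame boundary only in limit


class TestSourceGeometry:
    def test_measured_fwhm_matches_quadrature_sum(self, scanner, injection, protocol):
        fa = np.full(protocol.n_frames, 0.9e6)
        s = pw.render_frames(fa, scanner, injection, protocol, noise=False)
        fwhm = pw.measure_fwhm(s, frame=0)
        predicted = math.sqrt(
            scanner.psf_fwhm**2 + (GAUSS_FWHM_PER_SIGMA * injection.source_sigma) ** 2
        )
        assert fwhm == pytest.approx(predicted, rel=0.10)
        assert 2.0 <= fwhm <= 3.0  # the observed point-source blur band

    def test_fwhm_with_half_mm_source(self, scanner, protocol):
        inj = pw.InjectionSpec(source_sigma=0.5)
        fa = np.full(protocol.n_frames, 0.9e6)
        s = pw.render_frames(fa, scanner, inj, protocol, noise=False)
        predicted = math.sqrt(1.5**2 + (GAUSS_FWHM_PER_SIGMA * 0.5) ** 2)
        assert predicted == pytest.approx(1.9069, abs=1e-3)
        assert pw.measure_fwhm(s, 0) == pytest.approx(predicted, rel=0.10)

    def test_weights_normalized(self, scanner, injection):
        w = _source_weights(scanner, injection)
        assert w.sum() == pytest.approx(1.0, rel=1e-12)
        assert np.all(w >= 0)


class TestSimulateStudy:
    def test_zero_cv_shares_mean_parameters(self):
        p = pw.TwoComponentParams.from_halflives(0.9e6, 2878.0, 330.0)
        study = pw.simulate_study(
            pw.StudyDesign(p, n_animals=3, inter_animal_cv=0.0, seed=5),
            scanner=pw.ScannerModel(voxel_size=(1.0, 1.0, 1.0), grid_shape=(16, 16, 16)),
            noise=False,
        )
        assert np.allclose(study.truth["lambda_tiss"], p.lambda_tiss)
        assert np.allclose(study.truth["lambda_wash"], p.lambda_wash)

    def test_cardinality_and_determinism(self, small_scanner):
        p = pw.TwoComponentParams.from_halflives(0.9e6, 2000.0, 400.0)
        design = pw.StudyDesign(p, n_animals=4, inter_animal_cv=0.1, seed=11)
        a = pw.simulate_study(design, scanner=small_scanner, noise=True)
        b = pw.simulate_study(design, scanner=small_scanner, noise=True)
        assert len(a.series) == 8
        assert len(a.truth) == 4
        assert a.truth.equals(b.truth)
        for key in a.series:
            assert np.array_equal(a.series[key].values, b.series[key].values)

    def test_lognormal_cv_scale(self, small_scanner):
        p = pw.TwoComponentParams.from_halflives(0.9e6, 2878.0, 330.0)
        study = pw.simulate_study(
            pw.StudyDesign(p, n_animals=200, inter_animal_cv=0.1, seed=3),
            scanner=small_scanner,
            noise=False,
        )
        lt = study.truth["lambda_tiss"]
        assert lt.mean() == pytest.approx(p.lambda_tiss, rel=0.05)
        assert lt.std() / lt.mean() == pytest.approx(0.1, rel=0.3)

    def test_a0_within_calibrated_range(self, small_scanner):
        p = pw.TwoComponentParams.from_halflives(0.9e6, 2878.0, 330.0)
        study = pw.simulate_study(
            pw.StudyDesign(p, n_animals=8, seed=2), scanner=small_scanner, noise=False
        )
        for col in ("a0_alive", "a0_dead"):
            assert study.truth[col].between(0.7e6, 1.1e6).all()
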