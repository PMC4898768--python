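"""Spot detection and Gaussian-PSF fitting: candidates, sub-pixel fits,
amplitude significance, merging, secondary-channel readout, density."""

import numpy as np
import pytest

from endoquant import simgen, spotfit
from endoquant.psf import spot_image

from conftest import make_spot_patch

SIGMA = 1.4


class TestDetectCandidates:
    def test_constant_image_has_no_candidates(self):
        assert len(spotfit.detect_candidates(np.full((64, 64), 100.0), SIGMA)) == 0

    def test_single_noiseless_spot_yields_one_candidate_within_1px(self):
        image = np.full((64, 64), 100.0)
        image += spot_image(np.arange(64), np.arange(64), 30.3, 33.6, 500.0, SIGMA)
        cands = spotfit.detect_candidates(image, SIGMA)
        assert len(cands) == 1
        assert abs(cands[0][0] - 30.3) <= 1.0 and abs(cands[0][1] - 33.6) <= 1.0

    def test_candidate_recall_at_snr_10(self, quiet_noise):
        spec = simgen.SceneSpec(
            n_spots=30, min_separation=8.0, noise=quiet_noise,
            amplitude_distribution=("constant", {"value": 100.0}), seed=21,
        )
        channels, truth = simgen.render_spot_field(spec)
        cands = spotfit.detect_candidates(channels["ch1"], SIGMA)
        matched, _, _ = spotfit.match_detections(
            cands.astype(float), np.array([[t.x, t.y] for t in truth]), radius=2.0
        )
        assert matched >= 29

    def test_invalid_images_rejected(self):
        with pytest.raises(ValueError, match="2D"):
            spotfit.detect_candidates(np.zeros((4, 4, 4)), SIGMA)
        bad = np.full((64, 64), 1.0)
        bad[3, 3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            spotfit.detect_candidates(bad, SIGMA)


class TestFitSpot:
    def test_noiseless_spot_recovered_exactly(self):
        patch, (x0, y0) = make_spot_patch(500.0, sigma=1.5, size=9, background=100.0,
                                          offset=(0.3, -0.2))
        det = spotfit.fit_spot(patch, (4, 4), 1.5, window=9)
        assert det.status == "converged"
        assert abs(det.x - x0) < 1e-3 and abs(det.y - y0) < 1e-3
        assert det.amplitude == pytest.approx(500.0, abs=1e-6)
        assert det.local_background == pytest.approx(100.0, abs=1e-6)

    def test_noisy_amplitude_within_propagated_error(self, rng):
        patch, _ = make_spot_patch(300.0, noise_sd=10.0, rng=rng)
        det = spotfit.fit_spot(patch, (4, 4), SIGMA, window=9)
        assert abs(det.amplitude - 300.0) <= 3.0 * det.amplitude_se

    def test_flat_noise_patch_not_significant(self, rng):
        rejected = 0
        for _ in range(40):
            det = spotfit.fit_spot(100 + 10 * rng.standard_normal((7, 7)), (3, 3), SIGMA)
            det = spotfit.test_amplitude_significance(det, alpha=0.05)
            rejected += not det.accepted
        assert rejected >= 30  # ~95% expected

    def test_border_window_flagged(self):
        image = np.full((32, 32), 100.0)
        det = spotfit.fit_spot(image, (1, 15), SIGMA)
        assert det.status == "border"
        assert not spotfit.test_amplitude_significance(det).accepted

    def test_sigma_fitting_recovers_true_width(self):
        patch, _ = make_spot_patch(400.0, sigma=1.8, size=11)
        det = spotfit.fit_spot(patch, (5, 5), SIGMA, window=11, fit_sigma=True)
        assert det.sigma == pytest.approx(1.8, abs=1e-4)


class TestAmplitudeSignificance:
    def test_strong_spot_accepted_with_tiny_p(self, rng):
        patch, _ = make_spot_patch(200.0, noise_sd=1.0, rng=rng)  # A/sd = 200
        det = spotfit.fit_spot(patch, (4, 4), SIGMA, window=9)
        det = spotfit.test_amplitude_significance(det, alpha=0.05)
        assert det.accepted
        assert det.p_amplitude < 1e-4

    def test_p_monotone_decreasing_in_amplitude(self, rng):
        noise = rng.standard_normal((9, 9))
        ps = []
        for amp in (0.0, 20.0, 40.0, 80.0, 160.0):
            patch = 100 + 5 * noise + spot_image(np.arange(9), np.arange(9),
                                                 4.0, 4.0, amp, SIGMA)
            det = spotfit.fit_spot(patch, (4, 4), SIGMA, window=9)
            ps.append(spotfit.test_amplitude_significance(det).p_amplitude)
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_invalid_alpha_rejected(self):
        det = spotfit.fit_spot(np.full((32, 32), 7.0) , (16, 16), SIGMA)
        with pytest.raises(ValueError, match="alpha"):
            spotfit.test_amplitude_significance(det, alpha=1.5)


class TestDetectSpots:
    def test_blank_noisy_image_near_zero_detections(self, rng):
        image = 100 + 10 * rng.standard_normal((256, 256))
        dets = spotfit.detect_spots(image, SIGMA, alpha=0.05)
        assert len(dets.accepted()) <= max(1, len(dets.detections))
        assert len(dets.accepted()) <= 2

    def test_two_spots_below_merge_radius_give_one_detection(self):
        image = np.full((64, 64), 100.0)
        for dy, amp in ((0.0, 400.0), (1.0, 300.0)):
            image += spot_image(np.arange(64), np.arange(64), 32.0, 30.0 + dy,
                                amp, SIGMA)
        dets = spotfit.detect_spots(image, SIGMA)
        accepted = dets.accepted()
        assert len(accepted) == 1
        merged = [d for d in dets.detections if d.status == "merged"]
        assert all(d.amplitude <= accepted[0].amplitude for d in merged)

    def test_deterministic_given_image_and_parameters(self, quiet_noise):
        spec = simgen.SceneSpec(n_spots=15, noise=quiet_noise, seed=8)
        channels, _ = simgen.render_spot_field(spec)
        a = spotfit.detect_spots(channels["ch1"], SIGMA).to_frame()
        b = spotfit.detect_spots(channels["ch1"], SIGMA).to_frame()
        assert a.equals(b)

    def test_amplitude_monotone_in_true_amplitude(self, quiet_noise):
        """Mean detected amplitude is non-decreasing along a simulated
        amplitude ladder at fixed noise."""
        means = []
        for i, amp in enumerate((60.0, 120.0, 240.0, 480.0)):
            spec = simgen.SceneSpec(
                n_spots=20, noise=quiet_noise, min_separation=8.0,
                amplitude_distribution=("constant", {"value": amp}), seed=50 + i,
            )
            channels, _ = simgen.render_spot_field(spec)
            dets = spotfit.detect_spots(channels["ch1"], SIGMA)
            means.append(np.mean([d.amplitude for d in dets.accepted()]))
        assert all(a < b for a, b in zip(means, means[1:]))


class TestSecondaryChannel:
    def test_identical_channel_recovers_same_amplitudes(self, quiet_noise):
        spec = simgen.SceneSpec(n_spots=12, noise=quiet_noise, min_separation=10.0,
                                amplitude_distribution=("constant", {"value": 300.0}),
                                seed=13)
        channels, _ = simgen.render_spot_field(spec)
        dets = spotfit.detect_spots(channels["ch1"], SIGMA)
        dets = spotfit.measure_secondary_channel(dets, channels["ch1"], channel="same")
        for d in dets.accepted():
            assert d.channel_amplitudes["same"] == pytest.approx(d.amplitude, rel=0.05)

    def test_constant_channel_reads_near_zero(self, quiet_noise):
        spec = simgen.SceneSpec(n_spots=10, noise=quiet_noise, seed=14,
                                amplitude_distribution=("constant", {"value": 300.0}))
        channels, _ = simgen.render_spot_field(spec)
        dets = spotfit.detect_spots(channels["ch1"], SIGMA)
        dets = spotfit.measure_secondary_channel(dets, np.full_like(channels["ch1"], 50.0))
        for d in dets.accepted():
            assert abs(d.channel_amplitudes["ch2"]) < 1e-6

    def test_partial_colocalization_separates_carriers(self):
        """With half the spots carrying channel-2 signal, secondary
        amplitudes of non-carriers center on zero and carriers recover the
        truth within noise."""
        spec = simgen.SceneSpec(
            n_spots=20, min_separation=10.0, colocalization_fraction=0.5,
            amplitude_distribution=("constant", {"value": 400.0}),
            channel2_amplitude_distribution=("constant", {"value": 250.0}),
            noise=simgen.NoiseModel(read_noise_sd=5.0, photon_scale=0.0), seed=15,
        )
        channels, truth = simgen.render_spot_field(spec)
        dets = spotfit.detect_spots(channels["ch1"], SIGMA)
        dets = spotfit.measure_secondary_channel(dets, channels["ch2"])
        tpos = np.array([[t.x, t.y] for t in truth])
        carrier, noncarrier = [], []
        for d in dets.accepted():
            j = int(np.argmin((tpos[:, 0] - d.x) ** 2 + (tpos[:, 1] - d.y) ** 2))
            (carrier if truth[j].channel2_amplitude > 0 else noncarrier).append(
                d.channel_amplitudes["ch2"]
            )
        assert np.mean(carrier) == pytest.approx(250.0, rel=0.05)
        assert abs(np.mean(noncarrier)) < 10.0

    def test_shape_mismatch_rejected(self, quiet_noise):
        spec = simgen.SceneSpec(n_spots=5, noise=quiet_noise, seed=2)
        channels, _ = simgen.render_spot_field(spec)
        dets = spotfit.detect_spots(channels["ch1"], SIGMA)
        with pytest.raises(ValueError, match="shape"):
            spotfit.measure_secondary_channel(dets, np.zeros((64, 64)))


class TestSpotDensity:
    def test_density_arithmetic(self):
        det = spotfit.SpotDetection(x=1, y=1, sigma=SIGMA, amplitude=10,
                                    local_background=0, residual_sd=1,
                                    amplitude_se=1, dof=45, accepted=True)
        dets = spotfit.DetectionSet(detections=[det] * 50, cell_mask_area=10_000.0)
        assert spotfit.spot_density(dets) == pytest.approx(5e-3)

    def test_empty_set_zero_density(self):
        dets = spotfit.DetectionSet(detections=[], cell_mask_area=100.0)
        assert spotfit.spot_density(dets) == 0.0

    def test_missing_or_zero_area_rejected(self):
        dets = spotfit.DetectionSet(detections=[])
        with pytest.raises(ValueError):
            spotfit.spot_density(dets)
        dets.cell_mask_area = 0.0
        with pytest.raises(ValueError):
            spotfit.spot_density(dets)

    def test_density_recovered_across_count_sweep(self, quiet_noise):
        for i, n in enumerate((10, 30, 60)):
            spec = simgen.SceneSpec(
                n_spots=n, noise=quiet_noise, min_separation=8.0,
                amplitude_distribution=("constant", {"value": 100.0}), seed=70 + i,
            )
            channels, _ = simgen.render_spot_field(spec)
            dets = spotfit.detect_spots(channels["ch1"], SIGMA,
                                        cell_mask_area=float(channels["ch1"].size))
            assert spotfit.spot_density(dets) == pytest.approx(n / channels["ch1"].size,
                                                               rel=0.10)
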