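"""Droplet segmentation, ellipse shape measurement and relaxation fits."""

import numpy as np
import pytest

from phasekit.exceptions import ValidationError
from phasekit.fusion import (
    CapillaryVelocityModel,
    FusionRelaxationModel,
    FusionTrace,
    ellipse_aspect_ratio,
    segment_droplets,
    trace_from_stack,
)
from phasekit.simulate import gen_fusion_event, render_fusion_stack


def disc_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(yy - cy, xx - cx) <= r


def brute_force_aspect_ratio(mask):
    """Independent oracle: eigenvalues of the pixel-coordinate covariance."""
    coords = np.argwhere(mask).astype(float)
    cov = np.cov(coords.T, bias=True)
    eigvals = np.sort(np.linalg.eigvalsh(cov))
    return float(np.sqrt(eigvals[1] / eigvals[0]))


class TestSegmentDroplets:
    def test_uniform_frame_yields_nothing(self):
        assert segment_droplets(np.ones((64, 64))) == []

    def test_single_disc_area(self):
        img = np.zeros((64, 64))
        img[disc_mask((64, 64), 32, 32, 10)] = 1.0
        masks = segment_droplets(img)
        assert len(masks) == 1
        assert masks[0].sum() == pytest.approx(np.pi * 100, rel=0.03)

    def test_two_separated_discs(self):
        img = np.zeros((64, 128))
        img[disc_mask((64, 128), 32, 30, 8)] = 1.0
        img[disc_mask((64, 128), 32, 90, 8)] = 1.0
        assert len(segment_droplets(img)) == 2

    def test_min_area_filters_specks(self):
        img = np.zeros((64, 64))
        img[10, 10] = 1.0
        img[disc_mask((64, 64), 40, 40, 8)] = 1.0
        assert len(segment_droplets(img, min_area_px=20)) == 1


class TestEllipseAspectRatio:
    def test_circle_is_round(self):
        assert ellipse_aspect_ratio(disc_mask((101, 101), 50, 50, 30)) == pytest.approx(
            1.0, abs=0.02
        )

    def test_axis_aligned_ellipse(self):
        yy, xx = np.mgrid[0:201, 0:201]
        mask = ((xx - 100) / 40.0) ** 2 + ((yy - 100) / 20.0) ** 2 <= 1
        assert ellipse_aspect_ratio(mask) == pytest.approx(2.0, abs=0.02)

    def test_rotation_invariant(self):
        from skimage.transform import rotate

        yy, xx = np.mgrid[0:201, 0:201]
        mask = (((xx - 100) / 40.0) ** 2 + ((yy - 100) / 20.0) ** 2 <= 1).astype(float)
        rotated = rotate(mask, 30, order=0) > 0.5
        assert ellipse_aspect_ratio(rotated) == pytest.approx(
            ellipse_aspect_ratio(mask > 0.5), abs=0.03
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_covariance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = np.zeros((96, 96))
        # random blob: union of discs, includes tangent-disc shapes
        for _ in range(rng.integers(1, 4)):
            img[disc_mask((96, 96), rng.integers(25, 70), rng.integers(25, 70),
                          rng.integers(6, 14))] = 1.0
        mask = img > 0
        assert ellipse_aspect_ratio(mask) == pytest.approx(
            brute_force_aspect_ratio(mask), rel=1e-6
        )

    def test_tangent_discs_match_oracle(self):
        img = np.zeros((64, 128))
        img[disc_mask((64, 128), 32, 50, 10)] = 1.0
        img[disc_mask((64, 128), 32, 70, 10)] = 1.0
        mask = img > 0
        assert ellipse_aspect_ratio(mask) == pytest.approx(
            brute_force_aspect_ratio(mask), rel=1e-6
        )

    def test_collinear_mask_rejected(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[5, 3:20] = True
        with pytest.raises(ValidationError, match="degenerate"):
            ellipse_aspect_ratio(mask)


class TestFusionRelaxationFit:
    @pytest.mark.parametrize("tau", [0.5, 3.0, 12.0, 50.0])
    def test_noise_free_model_recovery(self, tau):
        trace = gen_fusion_event(tau=tau, a0=1.5, dt=tau / 20, noise=0.0)
        fit = FusionRelaxationModel.from_trace(trace).fit()
        assert fit.tau == pytest.approx(tau, rel=1e-6)
        assert fit.a0 == pytest.approx(1.5, rel=1e-6)

    def test_example_event_timescale(self):
        # a typical fusion event: A0 = 1.5 relaxing with tau = 3 s over 15 s
        trace = gen_fusion_event(tau=3.0, a0=1.5, dt=0.25, duration=15.0)
        fit = FusionRelaxationModel.from_trace(trace).fit()
        assert fit.tau == pytest.approx(3.0, rel=1e-6)
        assert fit.rsquared > 0.99

    def test_constant_trace_flagged(self):
        trace = FusionTrace("flat", np.arange(6.0), np.ones(6))
        fit = FusionRelaxationModel.from_trace(trace).fit()
        assert fit.a0 == 1.0
        assert np.isnan(fit.tau)
        assert "degenerate" in fit.flags

    def test_non_decaying_trace_flagged_not_raised(self):
        t = np.arange(8.0)
        a = 1.0 + 0.05 * t
        fit = FusionRelaxationModel(t, a).fit()
        assert "non_decaying" in fit.flags

    def test_summary_mentions_tau(self):
        trace = gen_fusion_event(tau=3.0, a0=1.5, dt=0.25, duration=15.0)
        assert "tau" in FusionRelaxationModel.from_trace(trace).fit().summary()


class TestCapillaryVelocity:
    def test_collinear_through_origin_exact(self):
        fit = CapillaryVelocityModel([0.92, 1.84, 2.76], [1.0, 2.0, 3.0]).fit()
        assert fit.slope == pytest.approx(0.92)
        assert fit.rsquared == pytest.approx(1.0)

    def test_with_intercept_mode(self):
        fit = CapillaryVelocityModel([1.92, 2.84, 3.76], [1.0, 2.0, 3.0]).fit(
            mode="with_intercept"
        )
        assert fit.slope == pytest.approx(0.92)
        assert fit.intercept == pytest.approx(1.0)

    def test_scale_equivariance(self, rng):
        tau = rng.uniform(1, 5, 10)
        ell = rng.uniform(1, 5, 10)
        s1 = CapillaryVelocityModel(tau, ell).fit().slope
        s2 = CapillaryVelocityModel(tau, 3.0 * ell).fit().slope
        assert s2 == pytest.approx(s1 / 3.0, rel=1e-12)

    def test_fewer_than_two_events_rejected(self):
        with pytest.raises(ValidationError):
            CapillaryVelocityModel([1.0], [1.0])

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValidationError):
            CapillaryVelocityModel([1.0, -1.0], [1.0, 2.0])

    def test_slope_estimator_unbiased_over_replicates(self):
        from phasekit.simulate import gen_fusion_cohort

        true_slope = 0.92
        estimates = []
        for seed in range(200):
            events = gen_fusion_cohort(16, true_slope, tau_noise=0.3, seed=seed)
            estimates.append(CapillaryVelocityModel.from_events(events).fit().slope)
        estimates = np.asarray(estimates)
        sem = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - true_slope) <= 2 * sem


class TestImagePipeline:
    def test_render_measure_round_trip(self):
        trace = gen_fusion_event(tau=3.0, a0=1.4, l_um=2.0, dt=0.5, duration=6.0)
        stack = render_fusion_stack(trace, pixel_size_um=0.1, shape=(128, 128))
        for frame, expected in zip(stack, trace.aspect_ratio):
            masks = segment_droplets(frame, method=0.5)
            assert len(masks) == 1
            assert ellipse_aspect_ratio(masks[0]) == pytest.approx(expected, rel=0.02)

    def test_trace_from_stack_finds_merge_and_length(self):
        # two discs for 3 frames, then a merged relaxing ellipse
        pre = np.zeros((3, 96, 160))
        for f in range(3):
            pre[f][disc_mask((96, 160), 48, 55, 15)] = 1.0
            pre[f][disc_mask((96, 160), 48, 95, 15)] = 1.0
        post_trace = gen_fusion_event(tau=1.0, a0=1.6, l_um=1.5, dt=0.25,
                                      duration=2.0)
        post = render_fusion_stack(post_trace, pixel_size_um=0.1, shape=(96, 160))
        stack = np.concatenate([pre, post])
        trace = trace_from_stack(stack, pixel_size_um=0.1, frame_interval_s=0.25)
        assert trace.times[0] == 0.0
        # mean pre-fusion radius: 15 px at 0.1 um/px
        assert trace.characteristic_length_um == pytest.approx(1.5, rel=0.03)
        fit = FusionRelaxationModel.from_trace(trace).fit()
        assert fit.tau == pytest.approx(1.0, rel=0.1)
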