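"""Seeded synthetic-data generators for every analysis stage.

Each generator produces inputs with exactly the statistical structure the
corresponding analyser assumes, so the whole pipeline is testable without
microscopy or AFM data:

* :func:`gen_fusion_event` — exponential aspect-ratio relaxation
  A(t) = 1 + (A0-1) exp(-t/tau) with additive Gaussian noise; optionally
  rendered as a time-lapse image stack of an area-preserving ellipse.
* :func:`gen_fusion_cohort` — (tau, l) pairs obeying tau = l * (eta/gamma)
  with multiplicative lognormal scatter on tau (relaxation times are
  positive, so the noise is multiplicative, not additive).
* :func:`gen_frap_trace` — pre-bleach plateau, bleach drop of given depth,
  exponential recovery to the mobile-fraction plateau, exponential
  reference photofading shared by ROI and reference, and Gaussian noise
  whose s.d. scales with the instantaneous signal (shot-noise-like).
* :func:`gen_force_curve` — approach/retract pair with a linear repulsive
  contact regime and a parabolic adhesive well whose integrated area equals
  W_adh * (tip contact area).
* :func:`gen_onset_trace` — baseline plus a sharp sigmoidal step at t*.
* :func:`gen_droplet_field` — additive bright discs, Gaussian blur, noise.

Determinism: every generator takes a seed and is bit-identical under the
same seed. A single top-level seed can be fanned out to per-stage
substreams with :func:`stage_rng`, so stages can be regenerated
independently without correlated streams.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import gaussian_filter

from .adhesion import ForceCurve
from .exceptions import ValidationError
from .frap import FrapTrace
from .fusion import FusionTrace
from .phase import OnsetTrace

__all__ = [
    "stage_rng",
    "gen_fusion_event",
    "render_fusion_stack",
    "gen_fusion_cohort",
    "gen_frap_trace",
    "gen_force_curve",
    "gen_onset_trace",
    "gen_droplet_field",
]

#: Fixed per-stage stream offsets so one top-level seed yields independent,
#: individually reproducible substreams.
STAGE_CODES = {
    "fusion": 1,
    "fusion_cohort": 2,
    "frap": 3,
    "force": 4,
    "onset": 5,
    "droplets": 6,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage substream of a single top-level seed."""
    if stage not in STAGE_CODES:
        raise ValidationError(f"unknown stage {stage!r}; know {sorted(STAGE_CODES)}")
    return np.random.default_rng([int(seed), STAGE_CODES[stage]])


def gen_fusion_event(
    tau: float,
    a0: float = 1.5,
    l_um: float = 2.0,
    dt: float = 0.25,
    duration: float | None = None,
    noise: float = 0.0,
    seed: int = 0,
    event_id: str = "synthetic",
) -> FusionTrace:
    """Synthetic aspect-ratio relaxation trace for one fusion event.

    A(t) = 1 + (a0 - 1) exp(-t/tau) sampled every ``dt`` seconds over
    ``duration`` (default 5 tau), plus additive Gaussian noise with s.d.
    ``noise`` (absolute, in aspect-ratio units — the decaying signal
    A - 1 has magnitude <= a0 - 1 ~ O(0.5)).
    """
    if tau <= 0 or l_um <= 0 or dt <= 0:
        raise ValidationError("tau, l and dt must be > 0")
    if a0 < 1:
        raise ValidationError("a0 must be >= 1")
    if dt >= tau:
        warnings.warn(
            f"dt={dt} >= tau={tau}: the relaxation is undersampled", stacklevel=2
        )
    duration = 5.0 * tau if duration is None else duration
    t = np.arange(0.0, duration + dt / 2, dt)
    a = 1.0 + (a0 - 1.0) * np.exp(-t / tau)
    if noise > 0:
        rng = np.random.default_rng(seed)
        a = a + rng.normal(0.0, noise, size=a.shape)
    return FusionTrace(event_id=event_id, times=t, aspect_ratio=a,
                       characteristic_length_um=l_um)


def render_fusion_stack(
    trace: FusionTrace,
    pixel_size_um: float = 0.1,
    shape: tuple[int, int] = (128, 128),
) -> np.ndarray:
    """Render a fusion trace as a (T, H, W) stack of area-preserving ellipses.

    Each frame holds one bright ellipse with aspect ratio A(t) and constant
    area pi r^2, where r is the trace's characteristic length; the ellipse
    semi-axes are r sqrt(A) and r / sqrt(A) (in pixels via the pixel size).
    """
    if trace.characteristic_length_um is None:
        raise ValidationError("trace needs characteristic_length_um to render")
    r_px = trace.characteristic_length_um / pixel_size_um
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    frames = []
    for a_ratio in trace.aspect_ratio:
        sa = r_px * np.sqrt(a_ratio)   # semi-major, along x
        sb = r_px / np.sqrt(a_ratio)   # semi-minor, along y
        if sa >= w / 2 or sb >= h / 2:
            raise ValidationError("ellipse does not fit in the frame; enlarge shape")
        inside = ((xx - cx) / sa) ** 2 + ((yy - cy) / sb) ** 2 <= 1.0
        frames.append(inside.astype(float))
    return np.stack(frames)


def gen_fusion_cohort(
    n: int,
    inv_cap_velocity: float,
    radius_range: tuple[float, float] = (1.0, 5.0),
    tau_noise: float = 0.3,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Synthetic (tau, l) cohort obeying tau = l * (eta/gamma).

    Radii are uniform in ``radius_range`` (um); each tau is multiplied by a
    unit-mean lognormal factor with coefficient of variation ``tau_noise``.
    """
    if n < 2:
        raise ValidationError("need n >= 2 events")
    if inv_cap_velocity <= 0:
        raise ValidationError("inverse capillary velocity must be > 0")
    if not (0 < radius_range[0] < radius_range[1]):
        raise ValidationError("radius_range must be increasing and positive")
    if tau_noise < 0:
        raise ValidationError("tau_noise must be >= 0")
    rng = np.random.default_rng(seed)
    l = rng.uniform(radius_range[0], radius_range[1], size=n)
    if tau_noise > 0:
        sigma2 = np.log1p(tau_noise**2)
        factors = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=n)
    else:
        factors = np.ones(n)
    tau = l * inv_cap_velocity * factors
    return list(zip(tau.tolist(), l.tolist()))


def gen_frap_trace(
    mobile_fraction: float,
    tau: float,
    bleach_depth: float = 0.8,
    fade_rate: float = 0.0,
    noise: float = 0.0,
    seed: int = 0,
    dt: float = 5.0,
    duration: float = 360.0,
    n_prebleach: int = 5,
    plateau: float = 1.0,
    reference_level: float = 1.0,
) -> FrapTrace:
    """Synthetic FRAP trace with bleach depth, immobile fraction and fading.

    The ROI sits at ``plateau`` before the bleach, drops to
    ``plateau * (1 - bleach_depth)`` and recovers exponentially (time
    constant ``tau``) towards bleach + mobile_fraction * (plateau - bleach).
    Both ROI and reference decay by exp(-fade_rate * t) from the first
    frame (acquisition photofading). Gaussian noise with s.d. equal to
    ``noise`` times the instantaneous signal value is added to the ROI.
    """
    if not (0.0 <= mobile_fraction <= 1.0):
        raise ValidationError("mobile_fraction must be in [0, 1]")
    if tau <= 0 or dt <= 0 or duration <= 0:
        raise ValidationError("tau, dt, duration must be > 0")
    if not (0.0 < bleach_depth <= 1.0):
        raise ValidationError("bleach_depth must be in (0, 1]")
    if fade_rate < 0 or noise < 0:
        raise ValidationError("fade_rate and noise must be >= 0")
    if n_prebleach < 1:
        raise ValidationError("need >= 1 pre-bleach sample")
    t_post = np.arange(0.0, duration + dt / 2, dt)
    t_pre = -dt * np.arange(n_prebleach, 0, -1)
    t = np.concatenate([t_pre, t_post])
    bleach = plateau * (1.0 - bleach_depth)
    roi = np.empty_like(t)
    roi[:n_prebleach] = plateau
    roi[n_prebleach:] = bleach + mobile_fraction * (plateau - bleach) * (
        1.0 - np.exp(-t_post / tau)
    )
    ref = np.full_like(t, reference_level)
    fade = np.exp(-fade_rate * (t - t[0]))
    roi = roi * fade
    ref = ref * fade
    if noise > 0:
        rng = np.random.default_rng(seed)
        roi = roi + rng.normal(0.0, 1.0, size=roi.shape) * noise * roi
        roi = np.clip(roi, 0.0, None)
    return FrapTrace(times=t, roi=roi, reference=ref, bleach_index=n_prebleach)


def gen_force_curve(
    w_adh: float,
    tip_radius_nm: float = 10.0,
    contact_stiffness: float = 1.0,
    well_width_nm: float = 20.0,
    noise: float = 0.0,
    seed: int = 0,
    n_well_samples: int = 500,
    spring_constant_N_m: float = 0.4,
) -> tuple[ForceCurve, ForceCurve]:
    """Synthetic approach/retract pair with a calibrated adhesive well.

    The retract curve has a linear repulsive contact regime (slope
    ``contact_stiffness`` nN/nm below the 10-nm contact point) and a
    parabolic adhesive well of full width ``well_width_nm`` whose integrated
    area equals ``w_adh * pi * tip_radius_nm^2`` (so the analysis pipeline
    should recover ``w_adh`` in J/m^2 with the circular contact-area model).
    Sampling density puts ``n_well_samples`` samples across the well.
    Gaussian noise s.d. is ``noise`` times the well depth.
    """
    if w_adh <= 0 or tip_radius_nm <= 0 or well_width_nm <= 0:
        raise ValidationError("w_adh, tip radius and well width must be > 0")
    if contact_stiffness <= 0 or n_well_samples < 10:
        raise ValidationError("contact_stiffness must be > 0, n_well_samples >= 10")
    contact_nm = 10.0
    gap_nm = 10.0
    well_start = contact_nm + gap_nm
    well_end = well_start + well_width_nm
    d_max = well_end + 40.0
    h = well_width_nm / n_well_samples
    d = np.arange(0.0, d_max + h / 2, h)

    # area under the parabolic well, in nN*nm (1 nN*nm = 1e-18 J)
    area_J = w_adh * np.pi * (tip_radius_nm * 1e-9) ** 2
    area_nNnm = area_J * 1e18
    depth_nN = area_nNnm / ((2.0 / 3.0) * well_width_nm)

    contact_force = np.where(d < contact_nm, contact_stiffness * (contact_nm - d), 0.0)
    centre = (well_start + well_end) / 2.0
    half = well_width_nm / 2.0
    x = (d - centre) / half
    well = np.where(np.abs(x) <= 1.0, -depth_nN * (1.0 - x**2), 0.0)

    approach_f = contact_force.copy()
    retract_f = contact_force + well
    if noise > 0:
        rng = np.random.default_rng(seed)
        approach_f = approach_f + rng.normal(0.0, noise * depth_nN, size=d.shape)
        retract_f = retract_f + rng.normal(0.0, noise * depth_nN, size=d.shape)
    metadata = {
        "spring_constant_N_m": spring_constant_N_m,
        "tip_radius_nm": tip_radius_nm,
        "true_w_adh_J_m2": w_adh,
    }
    approach = ForceCurve(segment="approach", distance_nm=d.copy(),
                          force_nN=approach_f, metadata=metadata)
    retract = ForceCurve(segment="retract", distance_nm=d.copy(),
                         force_nN=retract_f, metadata=metadata)
    return approach, retract


def gen_onset_trace(
    t_star: float,
    step_height: float = 1.0,
    noise: float = 0.0,
    dt: float = 0.5,
    duration: float | None = None,
    baseline: float = 1.0,
    rise_width: float | None = None,
    seed: int = 0,
) -> OnsetTrace:
    """Baseline plus a sharp sigmoidal step centred at ``t_star`` (minutes).

    ``rise_width`` controls the 10–90% rise (default dt/2, i.e. within one
    sampling interval); noise is Gaussian with s.d. ``noise * baseline``.
    """
    if t_star <= 0 or dt <= 0 or step_height <= 0 or baseline <= 0:
        raise ValidationError("t_star, dt, step_height, baseline must be > 0")
    duration = 2.0 * t_star if duration is None else duration
    if duration <= t_star:
        raise ValidationError("duration must exceed t_star")
    rise = dt / 2.0 if rise_width is None else rise_width
    t = np.arange(0.0, duration + dt / 2, dt)
    y = baseline + step_height / (1.0 + np.exp(-(t - t_star) / (rise / 4.0)))
    if noise > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise * baseline, size=y.shape)
    return OnsetTrace(times_min=t, intensity=y)


def gen_droplet_field(
    n: int,
    radii_px: tuple[float, float] = (5.0, 12.0),
    blur_sigma: float = 1.0,
    noise: float = 0.0,
    shape: tuple[int, int] = (256, 256),
    n_frames: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Image stack of n well-separated bright discs on a dark background.

    Disc centres are drawn rejection-wise so discs never touch; amplitude 1
    before Gaussian blur (``blur_sigma`` px) and additive noise (s.d.
    ``noise``). Returns a (n_frames, H, W) float stack (frames identical
    before noise).
    """
    if n < 1 or n_frames < 1:
        raise ValidationError("n and n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    h, w = shape
    radii = rng.uniform(radii_px[0], radii_px[1], size=n)
    centres: list[tuple[float, float]] = []
    max_tries = 10000
    for r in radii:
        for _ in range(max_tries):
            cy = rng.uniform(r + 2, h - r - 2)
            cx = rng.uniform(r + 2, w - r - 2)
            if all(
                np.hypot(cy - oy, cx - ox) > r + orr + max(4, 3 * blur_sigma)
                for (oy, ox), orr in centres
            ):
                centres.append(((cy, cx), r))
                break
        else:
            raise ValidationError(
                f"could not place {n} non-overlapping discs in {shape}"
            )
    yy, xx = np.mgrid[0:h, 0:w]
    base = np.zeros((h, w))
    for (cy, cx), r in centres:
        base[np.hypot(yy - cy, xx - cx) <= r] = 1.0
    if blur_sigma > 0:
        base = gaussian_filter(base, blur_sigma)
    frames = np.repeat(base[None, :, :], n_frames, axis=0)
    if noise > 0:
        frames = frames + rng.normal(0.0, noise, size=frames.shape)
    return frames
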