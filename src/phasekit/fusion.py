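"""Droplet-fusion relaxation analysis and the inverse capillary velocity.

When two liquid condensate droplets touch, surface tension drives their
coalescence into a single sphere. Tracking the aspect ratio A(t) of the
fusing pair gives an exponential relaxation

    A(t) = 1 + (A0 - 1) exp(-t / tau),

and for simple liquids the relaxation time scales with droplet size,
tau ~ l * (eta / gamma), where l is a characteristic length (here: the mean
pre-fusion droplet radius), eta the droplet viscosity and gamma its surface
tension. The slope of tau against l over a cohort of fusion events is the
*inverse capillary velocity* eta/gamma in s/um — one of the two measurable
quantities needed to separate viscosity from surface tension.

The module covers the whole path from time-lapse imagery to that slope:

* :func:`segment_droplets` / :func:`ellipse_aspect_ratio` — threshold-based
  segmentation and moment-equivalent-ellipse shape measurement.
* :func:`trace_from_stack` — reduce a fusion movie to a FusionTrace, with the
  time origin at the first frame where the two droplets merge into one
  connected component.
* :class:`FusionRelaxationModel` — fits the exponential relaxation to one
  event; :meth:`~FusionRelaxationModel.fit` returns a
  :class:`FusionRelaxationResults` with A0, tau, their standard errors and R².
* :class:`CapillaryVelocityModel` — regresses tau on l over a cohort
  (through the origin by default, since the physical relation has no
  intercept) and returns a :class:`CapillaryVelocityResults`.
"""

from __future__ import annotations


from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lmfit import Model as LmfitModel
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label

from .exceptions import ValidationError

__all__ = [
    "FusionTrace",
    "segment_droplets",
    "ellipse_aspect_ratio",
    "trace_from_stack",
    "FusionRelaxationModel",
    "FusionRelaxationResults",
    "CapillaryVelocityModel",
    "CapillaryVelocityResults",
]


@dataclass(frozen=True)
class FusionTrace:
    """Aspect-ratio time series for a single fusion event.

    times are seconds from droplet contact (strictly increasing, >= 5
    samples); aspect_ratio is dimensionless and >= 1 for physical shapes;
    characteristic_length_um is the mean pre-fusion droplet radius by the
    package's default convention (see CapillaryVelocityModel notes).
    """

    event_id: str
    times: np.ndarray
    aspect_ratio: np.ndarray
    characteristic_length_um: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.aspect_ratio, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "aspect_ratio", a)
        if t.shape != a.shape or t.ndim != 1:
            raise ValidationError("times and aspect_ratio must be equal-length 1-D")
        if len(t) < 5:
            raise ValidationError(f"fusion trace needs >= 5 samples, got {len(t)}")
        if not np.all(np.diff(t) > 0):
            raise ValidationError("times must be strictly increasing")
        if not np.all(np.isfinite(a)):
            raise ValidationError("aspect_ratio contains non-finite values")
        if self.characteristic_length_um is not None and self.characteristic_length_um <= 0:
            raise ValidationError("characteristic_length_um must be > 0")


def segment_droplets(
    frame: np.ndarray,
    method: str = "otsu",
    min_area_px: int = 20,
) -> list[np.ndarray]:
    """Segment bright droplets in a single-channel image into binary masks.

    Thresholds the frame (Otsu by default, or a fixed ``method=float``
    value), labels connected components and returns one boolean mask per
    component with area >= ``min_area_px``, largest first. A uniform frame or
    one with no sufficiently large component yields an empty list.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValidationError(f"expected a 2-D single-channel image, got ndim={img.ndim}")
    if np.ptp(img) == 0:
        return []
    if isinstance(method, (int, float)) and not isinstance(method, bool):
        thresh = float(method)
    elif method == "otsu":
        thresh = threshold_otsu(img)
    else:
        raise ValidationError(f"unknown segmentation method {method!r}")
    binary = img > thresh
    labels = sk_label(binary, connectivity=2)
    masks = []
    for lab in range(1, labels.max() + 1):
        mask = labels == lab
        if mask.sum() >= min_area_px:
            masks.append(mask)
    masks.sort(key=lambda m: m.sum(), reverse=True)
    return masks


def ellipse_aspect_ratio(mask: np.ndarray) -> float:
    """Aspect ratio of the moment-equivalent ellipse of a binary mask.

    Computed from the second central moments of the foreground pixel
    coordinates: the ratio of the square roots of the covariance eigenvalues
    (major/minor axis ratio). Rotation invariant up to pixelation; always
    >= 1. Degenerate (collinear) masks raise.
    """
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask).astype(float)
    if len(coords) < 5:
        raise ValidationError(f"mask needs >= 5 foreground pixels, got {len(coords)}")
    centered = coords - coords.mean(axis=0)
    # population (ddof=0) second central moments of the pixel centres
    mu20, mu02 = (centered**2).mean(axis=0)
    mu11 = (centered[:, 0] * centered[:, 1]).mean()
    common = np.sqrt((mu20 - mu02) ** 2 + 4 * mu11**2)
    lam_max = (mu20 + mu02 + common) / 2
    lam_min = (mu20 + mu02 - common) / 2
    if lam_min <= 0:
        raise ValidationError("degenerate (collinear) mask: minor axis is zero")
    return float(np.sqrt(lam_max / lam_min))


def trace_from_stack(
    stack: np.ndarray,
    pixel_size_um: float,
    frame_interval_s: float,
    event_id: str = "event",
    min_area_px: int = 20,
) -> FusionTrace:
    """Reduce a fusion time-lapse to a FusionTrace.

    The time origin is the first frame where the droplets have merged into a
    single connected component; aspect ratios are measured on the largest
    component of each subsequent frame (ties broken by area). The
    characteristic length is the mean equivalent-circle *radius* of the two
    components in the last pre-merge frame, in micrometres.
    """
    if pixel_size_um <= 0 or frame_interval_s <= 0:
        raise ValidationError("pixel_size_um and frame_interval_s must be > 0")
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValidationError("expected a (T, H, W) image stack")
    counts = []
    per_frame_masks = []
    for frame in stack:
        masks = segment_droplets(frame, min_area_px=min_area_px)
        per_frame_masks.append(masks)
        counts.append(len(masks))
    merge_idx = None
    for i in range(1, len(counts)):
        if counts[i] == 1 and counts[i - 1] >= 2:
            merge_idx = i
            break
    if merge_idx is None:
        raise ValidationError("no merge (2 components -> 1) found in stack")
    pre_masks = per_frame_masks[merge_idx - 1][:2]
    radii_px = [np.sqrt(m.sum() / np.pi) for m in pre_masks]
    l_um = float(np.mean(radii_px)) * pixel_size_um
    times, ratios = [], []
    for i in range(merge_idx, len(stack)):
        if counts[i] < 1:
            continue
        times.append((i - merge_idx) * frame_interval_s)
        ratios.append(ellipse_aspect_ratio(per_frame_masks[i][0]))
    return FusionTrace(
        event_id=event_id,
        times=np.array(times),
        aspect_ratio=np.array(ratios),
        characteristic_length_um=l_um,
    )


def _relaxation(t, a0, tau):
    return 1.0 + (a0 - 1.0) * np.exp(-t / tau)


@dataclass(frozen=True)
class FusionRelaxationResults:
    """Fit of A(t) = 1 + (A0 - 1) exp(-t/tau) to one fusion event."""

    event_id: str
    a0: float
    tau: float
    a0_stderr: float | None
    tau_stderr: float | None
    rsquared: float
    nobs: int
    flags: tuple = ()

    @property
    def converged(self) -> bool:
        return np.isfinite(self.tau) and "degenerate" not in self.flags

    def summary(self) -> str:
        lines = [
            f"Fusion relaxation fit — event {self.event_id}",
            f"  model: A(t) = 1 + (A0 - 1) exp(-t/tau)   n = {self.nobs}",
            f"  A0  = {self.a0:.4f}"
            + (f" +/- {self.a0_stderr:.4f}" if self.a0_stderr is not None else ""),
            f"  tau = {self.tau:.4g} s"
            + (f" +/- {self.tau_stderr:.4g} s" if self.tau_stderr is not None else ""),
            f"  R^2 = {self.rsquared:.4f}",
        ]
        if self.flags:
            lines.append(f"  flags: {', '.join(self.flags)}")
        return "\n".join(lines)

    def to_report_dict(self) -> dict:
        return {
            "event_id": self.event_id,
            "a0": self.a0,
            "tau_s": self.tau,
            "a0_stderr": self.a0_stderr,
            "tau_stderr_s": self.tau_stderr,
            "rsquared": self.rsquared,
            "nobs": self.nobs,
            "flags": list(self.flags),
        }


class FusionRelaxationModel:
    """Exponential relaxation model for a single droplet-fusion event.

    Build from arrays or :meth:`from_trace`; :meth:`fit` performs nonlinear
    least squares (Levenberg–Marquardt via lmfit) with data-driven starting
    values: A0 from the first sample, tau from the time at which the trace
    first decays to 1 + (A0 - 1)/e.
    """

    def __init__(self, times: Sequence[float], aspect_ratio: Sequence[float],
                 event_id: str = "event"):
        self.trace = FusionTrace(
            event_id=event_id,
            times=np.asarray(times, dtype=float),
            aspect_ratio=np.asarray(aspect_ratio, dtype=float),
        )

    @classmethod
    def from_trace(cls, trace: FusionTrace) -> "FusionRelaxationModel":
        obj = cls.__new__(cls)
        obj.trace = trace
        return obj

    @classmethod
    def from_dataframe(cls, df, time_col: str = "time_s",
                       value_col: str = "aspect_ratio",
                       event_id: str = "event") -> "FusionRelaxationModel":
        return cls(df[time_col].to_numpy(), df[value_col].to_numpy(), event_id=event_id)

    def _initial_guesses(self) -> tuple[float, float]:
        t = self.trace.times
        a = self.trace.aspect_ratio
        a0 = max(a[0], 1.0 + 1e-9)
        target = 1.0 + (a0 - 1.0) / np.e
        below = np.nonzero(a <= target)[0]
        tau0 = t[below[0]] if len(below) and t[below[0]] > 0 else (t[-1] - t[0]) / 3
        return float(a0), float(max(tau0, 1e-9))

    def fit(self) -> FusionRelaxationResults:
        t = self.trace.times - self.trace.times[0]
        a = self.trace.aspect_ratio
        flags: list[str] = []
        if a[-1] >= a[0]:
            flags.append("non_decaying")
        if np.ptp(a) < 1e-12:
            # constant trace: tau is unidentifiable
            flags.append("degenerate")
            return FusionRelaxationResults(
                event_id=self.trace.event_id,
                a0=float(a[0]), tau=float("nan"),
                a0_stderr=None, tau_stderr=None,
                rsquared=1.0, nobs=len(t), flags=tuple(flags),
            )
        a0_init, tau_init = self._initial_guesses()
        model = LmfitModel(_relaxation)
        params = model.make_params(a0=a0_init, tau=tau_init)
        params["a0"].set(min=1.0)
        params["tau"].set(min=1e-12)
        res = model.fit(a, params, t=t)
        ss_res = float(np.sum(res.residual**2))
        ss_tot = float(np.sum((a - a.mean()) ** 2))
        rsq = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        if not res.success:
            flags.append("fit_not_converged")
        return FusionRelaxationResults(
            event_id=self.trace.event_id,
            a0=float(res.params["a0"].value),
            tau=float(res.params["tau"].value),
            a0_stderr=(float(res.params["a0"].stderr)
                       if res.params["a0"].stderr is not None else None),
            tau_stderr=(float(res.params["tau"].stderr)
                        if res.params["tau"].stderr is not None else None),
            rsquared=rsq,
            nobs=len(t),
            flags=tuple(flags),
        )


@dataclass(frozen=True)
class CapillaryVelocityResults:
    """Regression of relaxation time on characteristic length over a cohort.

    slope is the inverse capillary velocity eta/gamma in s/um.
    """

    slope: float
    slope_stderr: float | None
    intercept: float
    mode: str
    rsquared: float
    nobs: int

    @property
    def inverse_capillary_velocity(self) -> float:
        return self.slope

    def summary(self) -> str:
        return "\n".join([
            "Inverse capillary velocity fit (tau vs l)",
            f"  mode: {self.mode}   n = {self.nobs}",
            f"  eta/gamma = {self.slope:.4g} s/um"
            + (f" +/- {self.slope_stderr:.2g}" if self.slope_stderr is not None else ""),
            f"  intercept = {self.intercept:.4g} s",
            f"  R^2 = {self.rsquared:.4f}",
        ])

    def to_report_dict(self) -> dict:
        return {
            "inverse_capillary_velocity_s_per_um": self.slope,
            "slope_stderr": self.slope_stderr,
            "intercept_s": self.intercept,
            "mode": self.mode,
            "rsquared": self.rsquared,
            "nobs": self.nobs,
        }


class CapillaryVelocityModel:
    """Least-squares model tau = l * (eta/gamma) over a cohort of events.

    The physical relation has no intercept, so the default fit is through
    the origin; ``mode="with_intercept"`` is available for comparison. The
    length convention matters: this package takes l as the mean pre-fusion
    droplet *radius*; if your lengths are diameters the slope rescales by 2.
    """

    def __init__(self, tau_s: Sequence[float], length_um: Sequence[float]):
        tau = np.asarray(tau_s, dtype=float)
        ell = np.asarray(length_um, dtype=float)
        if tau.shape != ell.shape or tau.ndim != 1:
            raise ValidationError("tau and length must be equal-length 1-D")
        if len(tau) < 2:
            raise ValidationError("need >= 2 fusion events")
        if np.any(tau <= 0) or np.any(ell <= 0):
            raise ValidationError("all tau and l must be > 0")
        self.tau = tau
        self.length = ell

    @classmethod
    def from_events(cls, events: Sequence[tuple]) -> "CapillaryVelocityModel":
        """Build from an iterable of (tau_s, l_um) pairs."""
        arr = np.asarray(list(events), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValidationError("events must be (tau, l) pairs")
        return cls(arr[:, 0], arr[:, 1])

    @classmethod
    def from_fits(cls, fits: Sequence[FusionRelaxationResults],
                  lengths_um: Sequence[float]) -> "CapillaryVelocityModel":
        return cls([f.tau for f in fits], lengths_um)

    def fit(self, mode: str = "through_origin") -> CapillaryVelocityResults:
        tau, ell = self.tau, self.length
        n = len(tau)
        if mode == "through_origin":
            slope = float(np.sum(tau * ell) / np.sum(ell**2))
            intercept = 0.0
            resid = tau - slope * ell
            dof = n - 1
        elif mode == "with_intercept":
            slope, intercept = (float(c) for c in np.polyfit(ell, tau, 1))
            resid = tau - (slope * ell + intercept)
            dof = n - 2
        else:
            raise ValidationError(f"unknown fit mode {mode!r}")
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((tau - tau.mean()) ** 2))
        rsq = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        if dof > 0:
            sigma2 = ss_res / dof
            if mode == "through_origin":
                stderr = float(np.sqrt(sigma2 / np.sum(ell**2)))
            else:
                sxx = float(np.sum((ell - ell.mean()) ** 2))
                stderr = float(np.sqrt(sigma2 / sxx)) if sxx > 0 else None
        else:
            stderr = None
        return CapillaryVelocityResults(
            slope=slope, slope_stderr=stderr, intercept=intercept,
            mode=mode, rsquared=rsq, nobs=n,
        )
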