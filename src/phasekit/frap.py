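"""FRAP normalisation, recovery fitting and condensate material properties.

Fluorescence recovery after photobleaching (FRAP) inside a condensate
reports molecular mobility. The analysis chain implemented here:

1. **Double normalisation** (:func:`normalize_frap`): the bleached-ROI
   intensity I(t) is corrected for acquisition photofading with a reference
   region R(t), C(t) = R(0)/R(t), I_corr = C(t) I(t), then rescaled so the
   pre-bleach level maps to 1 and the immediately-post-bleach floor to 0:

       f(t) = (I_corr(t) - floor) / (I_corr(0) - floor).

2. **Recovery fit** (:class:`FrapRecoveryModel`): f(t) = A (1 - exp(-t/tau))
   on the post-bleach samples, time re-zeroed at the bleach. A is the mobile
   fraction, tau the recovery relaxation time, t_half = ln(2) tau.

3. **Material properties**: D_app = omega^2 / t_half (omega^2 = bleach-ROI
   area), viscosity from Stokes–Einstein eta = k_B T / (6 pi D R_h), and
   interfacial tension gamma = eta / (eta/gamma) using the inverse capillary
   velocity measured from droplet-fusion events (see :mod:`phasekit.fusion`).

Conventions that matter (all switchable): I_corr(0) defaults to the mean of
the pre-bleach samples; the floor defaults to the first post-bleach sample
(the value obtained immediately after bleaching) rather than the global
post-bleach minimum, because under noise a global minimum is an extreme-value
statistic that biases the mobile fraction upward; omega^2 defaults to the
ROI *area*, with the squared-half-width convention also reported by the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lmfit import Model as LmfitModel
from scipy import constants

from .exceptions import DegenerateTraceError, ValidationError

__all__ = [
    "FrapTrace",
    "normalize_frap",
    "average_recovery",
    "FrapRecoveryModel",
    "FrapRecoveryResults",
    "MaterialInputs",
    "MaterialProperties",
    "apparent_diffusion",
    "viscosity_stokes_einstein",
    "interfacial_tension",
]

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class FrapTrace:
    """Raw FRAP time series: bleached-ROI and reference intensities.

    ``bleach_index`` is the index of the first post-bleach sample; at least
    one pre-bleach sample must precede it.
    """

    times: np.ndarray
    roi: np.ndarray
    reference: np.ndarray
    bleach_index: int

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        i = np.asarray(self.roi, dtype=float)
        r = np.asarray(self.reference, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "roi", i)
        object.__setattr__(self, "reference", r)
        if not (t.shape == i.shape == r.shape) or t.ndim != 1:
            raise ValidationError("times, roi, reference must be equal-length 1-D")
        if not np.all(np.diff(t) > 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(i < 0) or np.any(r < 0):
            raise ValidationError("intensities must be >= 0")
        if not (1 <= self.bleach_index < len(t)):
            raise ValidationError(
                f"bleach_index {self.bleach_index} needs >= 1 pre-bleach sample "
                f"and must lie within the series (length {len(t)})"
            )

    @property
    def post_times(self) -> np.ndarray:
        """Times since bleach for the post-bleach samples."""
        return self.times[self.bleach_index:] - self.times[self.bleach_index]


def normalize_frap(
    trace: FrapTrace,
    prebleach: str = "mean",
    floor: str = "first",
) -> np.ndarray:
    """Double-normalise a FRAP trace to f(t) on a 0–1 scale.

    Parameters
    ----------
    trace : FrapTrace
    prebleach : {"mean", "first"}
        Whether I_corr(0) is the mean of all pre-bleach samples (default) or
        the first sample only.
    floor : {"first", "min"}
        The post-bleach floor: the first post-bleach sample (default; the
        value immediately after bleaching) or the global minimum over all
        post-bleach samples.

    Returns
    -------
    ndarray
        f(t) for every sample of the trace (pre-bleach values hover near 1).
        The floor sample maps exactly to 0.
    """
    if np.any(trace.reference == 0):
        raise ValidationError("reference trace contains zeros; cannot correct fading")
    b = trace.bleach_index
    r0 = trace.reference[:b].mean() if prebleach == "mean" else trace.reference[0]
    corr = (r0 / trace.reference) * trace.roi
    i0 = corr[:b].mean() if prebleach == "mean" else corr[0]
    if floor == "first":
        fl = corr[b]
    elif floor == "min":
        fl = corr[b:].min()
    else:
        raise ValidationError(f"unknown floor convention {floor!r}")
    if prebleach not in ("mean", "first"):
        raise ValidationError(f"unknown prebleach convention {prebleach!r}")
    if i0 <= fl:
        raise DegenerateTraceError(
            "pre-bleach level does not exceed the post-bleach floor; "
            "no bleach contrast to normalise"
        )
    return (corr - fl) / (i0 - fl)


def average_recovery(
    traces: Sequence[FrapTrace],
    prebleach: str = "mean",
    floor: str = "first",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean (and s.d.) of the normalised recoveries of several condensates.

    FRAP studies typically report the mean +/- s.d. recovery over n
    condensates and fit the recovery model to that mean curve; this helper
    normalises each trace independently and averages on the common
    post-bleach time grid (all traces must share it).

    Returns
    -------
    (times_since_bleach, mean_f, sd_f)
    """
    if not traces:
        raise ValidationError("need at least one trace")
    grid = traces[0].post_times
    fs = []
    for tr in traces:
        if tr.post_times.shape != grid.shape or not np.allclose(tr.post_times, grid):
            raise ValidationError("traces do not share a post-bleach time grid")
        f = normalize_frap(tr, prebleach=prebleach, floor=floor)
        fs.append(f[tr.bleach_index:])
    arr = np.vstack(fs)
    return grid, arr.mean(axis=0), arr.std(axis=0, ddof=1) if len(fs) > 1 else np.zeros_like(grid)


def _recovery(t, a, tau):
    return a * (1.0 - np.exp(-t / tau))


@dataclass(frozen=True)
class FrapRecoveryResults:
    """Fit of f(t) = A (1 - exp(-t/tau)) to a normalised recovery."""

    mobile_fraction: float
    tau: float
    mobile_fraction_stderr: float | None
    tau_stderr: float | None
    rsquared: float
    nobs: int
    flags: tuple = ()

    @property
    def mobile_fraction_pct(self) -> float:
        return 100.0 * self.mobile_fraction

    @property
    def t_half(self) -> float:
        """Half-recovery time t_1/2 = ln(2) tau, seconds."""
        return LN2 * self.tau

    def material_properties(
        self,
        inputs: "MaterialInputs",
        inverse_capillary_velocity_s_per_um: float,
    ) -> "MaterialProperties":
        """Chain tau -> D_app -> eta -> gamma for this fit."""
        d = apparent_diffusion(self.tau, inputs.omega_sq_um2)
        eta = viscosity_stokes_einstein(
            d, temperature_K=inputs.temperature_K,
            hydrodynamic_radius_m=inputs.hydrodynamic_radius_m,
        )
        gamma = interfacial_tension(eta, inverse_capillary_velocity_s_per_um)
        return MaterialProperties(d_app_um2_s=d, viscosity_pa_s=eta,
                                  interfacial_tension_n_m=gamma)

    def summary(self) -> str:
        lines = [
            "FRAP recovery fit — f(t) = A (1 - exp(-t/tau))",
            f"  mobile fraction A = {self.mobile_fraction:.4f} "
            f"({self.mobile_fraction_pct:.1f}%)"
            + (f" +/- {self.mobile_fraction_stderr:.4f}"
               if self.mobile_fraction_stderr is not None else ""),
            f"  tau = {self.tau:.4g} s"
            + (f" +/- {self.tau_stderr:.3g} s" if self.tau_stderr is not None else ""),
            f"  t_1/2 = {self.t_half:.4g} s",
            f"  R^2 = {self.rsquared:.4f}   n = {self.nobs}",
        ]
        if self.flags:
            lines.append(f"  flags: {', '.join(self.flags)}")
        return "\n".join(lines)

    def to_report_dict(self) -> dict:
        return {
            "mobile_fraction": self.mobile_fraction,
            "mobile_fraction_pct": self.mobile_fraction_pct,
            "tau_s": self.tau,
            "t_half_s": self.t_half,
            "mobile_fraction_stderr": self.mobile_fraction_stderr,
            "tau_stderr_s": self.tau_stderr,
            "rsquared": self.rsquared,
            "nobs": self.nobs,
            "flags": list(self.flags),
        }


class FrapRecoveryModel:
    """Single-exponential recovery model for a normalised FRAP trace.

    Construct from (times-since-bleach, f) arrays, or with
    :meth:`from_trace` which performs the double normalisation first.
    Requires >= 6 post-bleach samples.
    """

    def __init__(self, times_since_bleach: Sequence[float], f: Sequence[float]):
        t = np.asarray(times_since_bleach, dtype=float)
        y = np.asarray(f, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValidationError("times and f must be equal-length 1-D")
        if len(t) < 6:
            raise ValidationError(f"need >= 6 post-bleach samples, got {len(t)}")
        if not np.all(np.diff(t) > 0):
            raise ValidationError("times must be strictly increasing")
        self.times = t
        self.f = y

    @classmethod
    def from_trace(cls, trace: FrapTrace, prebleach: str = "mean",
                   floor: str = "first") -> "FrapRecoveryModel":
        f = normalize_frap(trace, prebleach=prebleach, floor=floor)
        return cls(trace.post_times, f[trace.bleach_index:])

    def fit(self) -> FrapRecoveryResults:
        t, y = self.times, self.f
        flags: list[str] = []
        span = float(np.ptp(y))
        if span < 1e-12:
            # flat trace: no recovery, tau unidentifiable
            flags.extend(["no_recovery", "degenerate_tau"])
            return FrapRecoveryResults(
                mobile_fraction=float(np.clip(y.mean(), 0.0, 1.0)),
                tau=float("nan"), mobile_fraction_stderr=None, tau_stderr=None,
                rsquared=1.0, nobs=len(t), flags=tuple(flags),
            )
        a_init = float(np.clip(y[-max(3, len(y) // 10):].mean(), 1e-6, 1.5))
        target = a_init * (1 - 1 / np.e)
        above = np.nonzero(y >= target)[0]
        tau_data = t[above[0]] if len(above) and t[above[0]] > 0 else (t[-1] / 3 or 1.0)
        model = LmfitModel(_recovery)
        # Multi-start over tau: a nearly flat trace makes (A, tau) a ridge
        # (A/tau fixed, both unbounded), so a single start can wander off.
        # The mobile fraction is physically <= 1 (bound leaves noise slack).
        # tau is constrained to the observed time span: a recovery slower
        # than the acquisition window is not identifiable from the data, and
        # letting tau run beyond it turns slow noise drifts into arbitrarily
        # inflated amplitudes. Estimates at the bound are flagged.
        res = None
        t_span = t[-1] if t[-1] > 0 else 1.0
        for tau_init in {float(tau_data), t_span / 10.0, t_span / 3.0}:
            params = model.make_params(a=a_init, tau=min(max(tau_init, 1e-9),
                                                         0.99 * t_span))
            params["a"].set(min=0.0, max=1.5)
            params["tau"].set(min=1e-9, max=t_span)
            cand = model.fit(y, params, t=t)
            if res is None or cand.chisqr < res.chisqr:
                res = cand
        a_hat = float(res.params["a"].value)
        tau_hat = float(res.params["tau"].value)
        a_err = res.params["a"].stderr
        tau_err = res.params["tau"].stderr
        ss_res = float(np.sum(res.residual**2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        rsq = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        if a_hat <= 0.02:
            flags.append("low_recovery")
        if tau_hat >= 0.999 * t_span:
            flags.append("tau_at_window_bound")
        if tau_err is not None and tau_hat > 0 and tau_err / tau_hat > 1.0:
            flags.append("wide_uncertainty")
        if not res.success:
            flags.append("fit_not_converged")
        return FrapRecoveryResults(
            mobile_fraction=a_hat, tau=tau_hat,
            mobile_fraction_stderr=float(a_err) if a_err is not None else None,
            tau_stderr=float(tau_err) if tau_err is not None else None,
            rsquared=rsq, nobs=len(t), flags=tuple(flags),
        )


@dataclass(frozen=True)
class MaterialInputs:
    """Physical inputs for the D_app -> eta -> gamma chain.

    omega_sq_um2 is the bleach-ROI area in um^2 (default 1.5 x 0.5 um ROI);
    temperature in kelvin; hydrodynamic radius in metres (~2.5 nm for an
    unfolded ~8 kDa protein).
    """

    omega_sq_um2: float = 0.75
    temperature_K: float = 298.0
    hydrodynamic_radius_m: float = 2.5e-9

    def __post_init__(self) -> None:
        if min(self.omega_sq_um2, self.temperature_K, self.hydrodynamic_radius_m) <= 0:
            raise ValidationError("all material inputs must be strictly positive")


@dataclass(frozen=True)
class MaterialProperties:
    """Derived condensate material properties."""

    d_app_um2_s: float
    viscosity_pa_s: float
    interfacial_tension_n_m: float

    @property
    def interfacial_tension_un_m(self) -> float:
        """Interfacial tension in micronewtons per metre."""
        return self.interfacial_tension_n_m * 1e6

    def to_report_dict(self) -> dict:
        return {
            "d_app_um2_per_s": self.d_app_um2_s,
            "viscosity_pa_s": self.viscosity_pa_s,
            "interfacial_tension_n_per_m": self.interfacial_tension_n_m,
            "interfacial_tension_un_per_m": self.interfacial_tension_un_m,
        }


def apparent_diffusion(tau_s: float, omega_sq_um2: float) -> float:
    """Apparent diffusion coefficient D_app = omega^2 / t_half in um^2/s.

    With t_half = ln(2) tau. omega^2 is the bleached-region area (um^2); a
    squared-half-width convention is obtained by passing that quantity
    instead — the two differ by the geometric factor of the ROI.
    """
    if tau_s <= 0 or omega_sq_um2 <= 0:
        raise ValidationError("tau and omega^2 must be > 0")
    return omega_sq_um2 / (LN2 * tau_s)


def viscosity_stokes_einstein(
    d_app_um2_s: float,
    temperature_K: float = 298.0,
    hydrodynamic_radius_m: float = 2.5e-9,
) -> float:
    """Viscosity (Pa s) from Stokes–Einstein: eta = k_B T / (6 pi D R_h)."""
    if min(d_app_um2_s, temperature_K, hydrodynamic_radius_m) <= 0:
        raise ValidationError("all inputs must be > 0")
    d_si = d_app_um2_s * 1e-12  # um^2/s -> m^2/s
    return constants.k * temperature_K / (6.0 * np.pi * d_si * hydrodynamic_radius_m)


def interfacial_tension(
    viscosity_pa_s: float,
    inverse_capillary_velocity_s_per_um: float,
) -> float:
    """Interfacial tension (N/m) from gamma = eta / (eta/gamma).

    The inverse capillary velocity is given in s/um (as measured from fusion
    events); 1 s/um = 1e6 s/m.
    """
    if viscosity_pa_s <= 0 or inverse_capillary_velocity_s_per_um <= 0:
        raise ValidationError("viscosity and inverse capillary velocity must be > 0")
    return viscosity_pa_s / (inverse_capillary_velocity_s_per_um * 1e6)
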