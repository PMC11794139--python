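"""Work of adhesion from AFM force–distance retract curves.

When a probe tip is retracted from an adhesive surface the force–distance
curve shows an adhesive well: a contiguous region of negative (attractive)
force ending in a pull-off event. The work of adhesion is

    W_adh = (area of the adhesive well) / (tip contact area),

with the well area integrated by the trapezoidal rule over distance and the
contact area modelled as a circle pi R_tip^2 by default (R_tip = 10 nm); a
hemispherical-cap convention 2 pi R_tip^2 is switchable, since the two
differ by exactly 2x and published values rarely state which was used.

Input curves are delimited text with a ``segment, distance_nm, force_nN``
layout plus ``# key: value`` metadata headers (spring constant, tip radius).
:func:`baseline_correct` removes constant offset and linear drift using the
far-from-surface tail before integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

__all__ = [
    "ForceCurve",
    "AdhesionResult",
    "read_force_curve",
    "baseline_correct",
    "work_of_adhesion",
]


@dataclass(frozen=True)
class ForceCurve:
    """One segment (approach or retract) of a force–distance measurement."""

    segment: str
    distance_nm: np.ndarray
    force_nN: np.ndarray
    metadata: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.segment not in ("approach", "retract"):
            raise ValidationError(f"segment must be approach/retract, got {self.segment!r}")
        d = np.asarray(self.distance_nm, dtype=float)
        f = np.asarray(self.force_nN, dtype=float)
        object.__setattr__(self, "distance_nm", d)
        object.__setattr__(self, "force_nN", f)
        if d.shape != f.shape or d.ndim != 1:
            raise ValidationError("distance and force must be equal-length 1-D")
        if len(d) < 10:
            raise ValidationError(f"segment needs >= 10 samples, got {len(d)}")
        diffs = np.diff(d)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise FormatError(f"{self.segment} distances are not strictly monotone")

    def ascending(self) -> "ForceCurve":
        """Return the segment ordered by increasing distance."""
        if self.distance_nm[0] <= self.distance_nm[-1]:
            return self
        return replace(self, distance_nm=self.distance_nm[::-1].copy(),
                       force_nN=self.force_nN[::-1].copy())


@dataclass(frozen=True)
class AdhesionResult:
    """Work of adhesion and related quantities for one retract curve."""

    pull_off_force_nN: float
    adhesion_energy_J: float
    contact_area_m2: float
    work_of_adhesion_J_m2: float
    tip_radius_nm: float
    contact_area_model: str
    secondary_well_energies_J: tuple = ()
    flags: tuple = ()

    def summary(self) -> str:
        lines = [
            "Work of adhesion (retract force–distance curve)",
            f"  pull-off force   = {self.pull_off_force_nN:.4g} nN",
            f"  adhesion energy  = {self.adhesion_energy_J:.4g} J",
            f"  contact area     = {self.contact_area_m2:.4g} m^2 "
            f"({self.contact_area_model}, R_tip = {self.tip_radius_nm:g} nm)",
            f"  W_adh            = {self.work_of_adhesion_J_m2:.4g} J/m^2",
        ]
        if self.secondary_well_energies_J:
            lines.append(
                f"  secondary wells  = {len(self.secondary_well_energies_J)} "
                f"(energies {['%.3g' % e for e in self.secondary_well_energies_J]})"
            )
        if self.flags:
            lines.append(f"  flags: {', '.join(self.flags)}")
        return "\n".join(lines)

    def to_report_dict(self) -> dict:
        return {
            "pull_off_force_nN": self.pull_off_force_nN,
            "adhesion_energy_J": self.adhesion_energy_J,
            "contact_area_m2": self.contact_area_m2,
            "work_of_adhesion_J_per_m2": self.work_of_adhesion_J_m2,
            "tip_radius_nm": self.tip_radius_nm,
            "contact_area_model": self.contact_area_model,
            "secondary_well_energies_J": list(self.secondary_well_energies_J),
            "flags": list(self.flags),
        }


def read_force_curve(
    path: str | Path,
    retract_only: bool = False,
) -> tuple[ForceCurve | None, ForceCurve]:
    """Read a force–distance text file into (approach, retract) segments.

    Format: optional ``# key: value`` metadata lines, then a delimited table
    with columns ``segment, distance_nm, force_nN``. The retract segment is
    returned ordered by increasing distance. With ``retract_only`` a file
    holding only a retract segment is accepted (approach returned as None).
    """
    path = Path(path)
    metadata: dict[str, float] = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header_lines += 1
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    try:
                        metadata[key.strip()] = float(val.strip())
                    except ValueError:
                        metadata[key.strip()] = val.strip()
            else:
                break
    try:
        df = pd.read_csv(path, skiprows=header_lines, sep=None, engine="python")
    except Exception as exc:  # noqa: BLE001 - re-raise as format error
        raise FormatError(f"{path}: cannot parse force-curve table ({exc})") from exc
    required = {"segment", "distance_nm", "force_nN"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")

    segments = {}
    for name, group in df.groupby("segment", sort=False):
        segments[name] = ForceCurve(
            segment=str(name),
            distance_nm=group["distance_nm"].to_numpy(dtype=float),
            force_nN=group["force_nN"].to_numpy(dtype=float),
            metadata=metadata,
        )
    if "retract" not in segments:
        raise FormatError(f"{path}: no retract segment found")
    retract = segments["retract"].ascending()
    approach = segments.get("approach")
    if approach is None and not retract_only:
        raise FormatError(
            f"{path}: missing approach segment (pass retract_only=True to accept)"
        )
    return approach, retract


def baseline_correct(curve: ForceCurve, tail_fraction: float = 0.2) -> ForceCurve:
    """Subtract a straight line fitted to the far-from-surface tail.

    The tail is the ``tail_fraction`` of samples at the largest distances,
    where no tip–sample interaction remains; fitting force ~ distance there
    and subtracting removes both constant offset and linear drift, leaving
    the far-field force at ~0.
    """
    if not (0.0 < tail_fraction <= 0.5):
        raise ValidationError(f"tail_fraction must be in (0, 0.5], got {tail_fraction}")
    asc = curve.ascending()
    n_tail = int(round(tail_fraction * len(asc.distance_nm)))
    if n_tail < 3:
        raise ValidationError(
            f"tail too short ({n_tail} samples) for a linear baseline fit"
        )
    d_tail = asc.distance_nm[-n_tail:]
    f_tail = asc.force_nN[-n_tail:]
    slope, intercept = np.polyfit(d_tail, f_tail, 1)
    corrected = asc.force_nN - (slope * asc.distance_nm + intercept)
    return replace(asc, force_nN=corrected)


def _negative_runs(force: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous index runs (start, stop exclusive) where force < 0."""
    neg = force < 0
    runs = []
    start = None
    for i, flag in enumerate(neg):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(force)))
    return runs


def work_of_adhesion(
    retract: ForceCurve,
    tip_radius_nm: float = 10.0,
    contact_area_model: str = "circle",
) -> AdhesionResult:
    """Integrate the adhesive well of a baseline-corrected retract curve.

    The adhesion energy is the trapezoidal integral of |force| over the
    contiguous negative-force region containing the global force minimum
    (nN·nm -> joules); other negative regions are reported as secondary
    wells. W_adh = energy / contact area, pull-off force = |global minimum|.
    A curve with no negative force yields W_adh = 0 with a ``no_adhesion``
    flag rather than an error.
    """
    if tip_radius_nm <= 0:
        raise ValidationError("tip radius must be > 0")
    if contact_area_model == "circle":
        area_m2 = np.pi * (tip_radius_nm * 1e-9) ** 2
    elif contact_area_model == "hemisphere":
        area_m2 = 2.0 * np.pi * (tip_radius_nm * 1e-9) ** 2
    else:
        raise ValidationError(f"unknown contact-area model {contact_area_model!r}")

    asc = retract.ascending()
    d, f = asc.distance_nm, asc.force_nN
    runs = _negative_runs(f)
    if not runs:
        return AdhesionResult(
            pull_off_force_nN=0.0, adhesion_energy_J=0.0,
            contact_area_m2=area_m2, work_of_adhesion_J_m2=0.0,
            tip_radius_nm=tip_radius_nm, contact_area_model=contact_area_model,
            flags=("no_adhesion",),
        )
    i_min = int(np.argmin(f))
    energies = {
        run: float(np.trapezoid(np.abs(f[run[0]:run[1]]), d[run[0]:run[1]])) * 1e-18
        for run in runs
    }
    main = next(run for run in runs if run[0] <= i_min < run[1])
    secondary = tuple(e for run, e in energies.items() if run != main)
    energy_J = energies[main]
    return AdhesionResult(
        pull_off_force_nN=float(-f[i_min]),
        adhesion_energy_J=energy_J,
        contact_area_m2=area_m2,
        work_of_adhesion_J_m2=energy_J / area_m2,
        tip_radius_nm=tip_radius_nm,
        contact_area_model=contact_area_model,
        secondary_well_energies_J=secondary,
        flags=(),
    )
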