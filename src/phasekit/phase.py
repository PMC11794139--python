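"""Coacervation-onset timing and phase-diagram grids.

In an evaporating sessile droplet the protein concentrates at the contact
line until it crosses the binodal and a rim of condensates appears. The
onset time t_i is the interval between droplet deposition and rim
formation. Experimentally t_i is identified by eye; :func:`detect_onset`
operationalises it as a z-score change point: the earliest time at which a
rim-region intensity (or turbidity) trace exceeds

    baseline mean + z * baseline s.d.

for at least ``min_run`` consecutive samples, with the baseline taken from
the first 20% of samples. The detector is invariant to affine rescaling of
the intensity.

Phase diagrams (condensation yes/no on a concentration x time or
crowder x salt lattice) are assembled by :func:`build_phase_grid` into a
:class:`PhaseGrid`, with a per-level regime boundary (minimal axis-1 value
with a positive call) extracted under a monotonicity assumption —
violations are reported, never silently corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["OnsetTrace", "detect_onset", "PhaseGrid", "build_phase_grid"]


@dataclass(frozen=True)
class OnsetTrace:
    """Rim-region mean intensity (or turbidity proxy) versus time (minutes)."""

    times_min: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "intensity", y)
        if t.shape != y.shape or t.ndim != 1:
            raise ValidationError("times and intensity must be equal-length 1-D")
        if len(t) < 10:
            raise ValidationError(f"onset trace needs >= 10 samples, got {len(t)}")
        if not np.all(np.diff(t) > 0):
            raise ValidationError("times must be strictly increasing")


def detect_onset(
    trace: OnsetTrace,
    z_threshold: float = 5.0,
    min_run: int = 3,
    baseline_fraction: float = 0.2,
) -> float | None:
    """Earliest onset time t_i (minutes), or None if no onset is detected.

    The baseline mean and s.d. come from the first ``baseline_fraction`` of
    samples; onset is the first time the intensity exceeds
    mean + z_threshold * s.d. for >= ``min_run`` consecutive samples.
    """
    if z_threshold <= 0 or min_run < 1:
        raise ValidationError("z_threshold must be > 0 and min_run >= 1")
    y = trace.intensity
    n_base = max(2, int(round(baseline_fraction * len(y))))
    base = y[:n_base]
    mu = base.mean()
    sd = base.std(ddof=1)
    threshold = mu + z_threshold * sd
    above = y > threshold
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= min_run:
            return float(trace.times_min[i - min_run + 1])
    return None


@dataclass(frozen=True)
class PhaseGrid:
    """Boolean condensation calls on a complete rectangular lattice.

    axis1 is the quantity the regime boundary is extracted over (e.g.
    protein concentration); axis2 indexes the levels (e.g. incubation time
    or salt concentration).
    """

    axis1_values: np.ndarray
    axis2_values: np.ndarray
    calls: np.ndarray  # shape (len(axis1), len(axis2)); NaN-free boolean
    axis1_name: str = "axis1"
    axis2_name: str = "axis2"
    missing_cells: tuple = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.calls,
            index=pd.Index(self.axis1_values, name=self.axis1_name),
            columns=pd.Index(self.axis2_values, name=self.axis2_name),
        )

    def boundary(self) -> tuple[dict, list[str]]:
        """Per-axis-2-level regime boundary and monotonicity violations.

        For each axis-2 level, the boundary is the minimal axis-1 value with
        a positive call (None if the level has no positives). Assuming the
        condensation regime is monotone (calls non-decreasing in axis1 and
        axis2), any negative call above a level's boundary and any level
        whose boundary rises while axis2 increases is reported as a
        violation string; the data are never modified.
        """
        bounds: dict = {}
        violations: list[str] = []
        for j, lvl in enumerate(self.axis2_values):
            col = self.calls[:, j]
            pos = np.nonzero(col)[0]
            if len(pos) == 0:
                bounds[lvl] = None
                continue
            b_idx = pos[0]
            bounds[lvl] = float(self.axis1_values[b_idx])
            for i in range(b_idx + 1, len(col)):
                if not col[i]:
                    violations.append(
                        f"non-monotone in {self.axis1_name} at "
                        f"{self.axis2_name}={lvl}: negative call at "
                        f"{self.axis1_values[i]} above boundary {bounds[lvl]}"
                    )
        prev = None
        for lvl in self.axis2_values:
            b = bounds[lvl]
            if b is not None:
                if prev is not None and b > prev:
                    violations.append(
                        f"boundary rises from {prev} to {b} at {self.axis2_name}={lvl}"
                    )
                prev = b
        return bounds, violations


def build_phase_grid(
    observations: Iterable[tuple] | pd.DataFrame,
    axis1_name: str = "axis1",
    axis2_name: str = "axis2",
) -> PhaseGrid:
    """Assemble (axis1, axis2, call) observations into a PhaseGrid.

    The design should be rectangular; cells never observed are flagged in
    ``missing_cells`` (and hold False). Replicated consistent calls are
    accepted; conflicting duplicate calls for one cell raise, naming it.
    """
    if isinstance(observations, pd.DataFrame):
        df = observations.rename(
            columns={axis1_name: "axis1", axis2_name: "axis2"}
        )[["axis1", "axis2", "call"]]
    else:
        df = pd.DataFrame(list(observations), columns=["axis1", "axis2", "call"])
    if df.empty:
        raise ValidationError("no observations given")
    df["call"] = df["call"].astype(bool)

    conflicts = (
        df.groupby(["axis1", "axis2"])["call"].nunique().loc[lambda s: s > 1]
    )
    if len(conflicts):
        cells = ", ".join(f"({a}, {b})" for a, b in conflicts.index)
        raise ValidationError(f"conflicting duplicate calls for cells: {cells}")

    a1 = np.array(sorted(df["axis1"].unique()))
    a2 = np.array(sorted(df["axis2"].unique()))
    calls = np.zeros((len(a1), len(a2)), dtype=bool)
    observed = np.zeros_like(calls)
    cell_call = df.groupby(["axis1", "axis2"])["call"].first()
    for (x1, x2), call in cell_call.items():
        i = int(np.searchsorted(a1, x1))
        j = int(np.searchsorted(a2, x2))
        calls[i, j] = call
        observed[i, j] = True
    missing = tuple(
        (float(a1[i]), float(a2[j]))
        for i in range(len(a1))
        for j in range(len(a2))
        if not observed[i, j]
    )
    return PhaseGrid(
        axis1_values=a1, axis2_values=a2, calls=calls,
        axis1_name=axis1_name, axis2_name=axis2_name,
        missing_cells=missing,
    )
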