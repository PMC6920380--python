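"""Rotational behavior scoring and outlier screening.

Amphetamine-elicited rotation testing quantifies hemispheric imbalance
of the nigrostriatal pathway: a unilateral increase in dopamine release
biases the animal toward rotating in one direction. From a tracked
heading trace this module counts full clockwise (CW) and
counterclockwise (CCW) rotations and reports net rotations = CW - CCW.
Group values can be screened for a single outlier with the two-sided
Grubbs test.

Counting uses the cumulative-accumulator rule: the heading series is
unwrapped into a continuous angle; a CW rotation is registered each
time the cumulative angle falls a further 360 deg below its running
reference (the reference then steps down 360 deg), and symmetrically
for CCW. Clockwise is, by default, decreasing heading in image
coordinates; the convention is a flag since camera mounting flips
chirality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "RotationTrace",
    "RotationCounts",
    "GrubbsResult",
    "unwrap_heading",
    "wrap_heading",
    "count_rotations",
    "grubbs_critical",
    "grubbs_test",
]


@dataclass
class RotationTrace:
    """Time-stamped heading series for one session.

    Headings are wrapped to [0, 360) on construction; time stamps must be
    strictly increasing.
    """

    time_s: np.ndarray
    heading_deg: np.ndarray
    mouse_id: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.heading_deg = np.asarray(self.heading_deg, dtype=float) % 360.0
        if self.time_s.size != self.heading_deg.size:
            raise ValueError("time and heading must have equal length")
        if self.time_s.size < 2:
            raise ValueError("trace needs at least 2 samples")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time stamps must be strictly increasing")

    def window(self, t0: float, t1: float) -> "RotationTrace":
        """Restrict to the half-open analysis window [t0, t1)."""
        sel = (self.time_s >= t0) & (self.time_s < t1)
        if sel.sum() < 2:
            raise ValueError(f"analysis window [{t0}, {t1}) holds < 2 samples")
        return RotationTrace(
            time_s=self.time_s[sel],
            heading_deg=self.heading_deg[sel],
            mouse_id=self.mouse_id,
            session=self.session,
        )


@dataclass(frozen=True)
class RotationCounts:
    """Full-turn counts; net = CW - CCW."""

    cw: int
    ccw: int

    def __post_init__(self) -> None:
        if self.cw < 0 or self.ccw < 0:
            raise ValueError("counts must be non-negative")

    @property
    def net(self) -> int:
        return self.cw - self.ccw


def unwrap_heading(trace: RotationTrace) -> np.ndarray:
    """Cumulative continuous angle starting at the first heading.

    Successive differences are mapped to (-180, +180] deg, so a step from
    350 to 10 deg reads as +20 deg. Re-wrapping with
    :func:`wrap_heading` recovers the input exactly.
    """
    h = trace.heading_deg
    diffs = (np.diff(h) - 180.0) % -360.0 + 180.0
    return np.concatenate([[h[0]], h[0] + np.cumsum(diffs)])


def wrap_heading(cumulative: np.ndarray) -> np.ndarray:
    return np.asarray(cumulative, dtype=float) % 360.0


def count_rotations(
    trace: RotationTrace,
    *,
    cw_is_decreasing: bool = True,
    window: tuple[float, float] | None = None,
) -> RotationCounts:
    """Count full CW/CCW rotations by the accumulator rule.

    ``window`` optionally trims the trace to an analysis window (e.g.
    excluding an acclimation period) before counting.
    """
    if window is not None:
        trace = trace.window(*window)
    theta = unwrap_heading(trace)
    if not cw_is_decreasing:
        theta = -theta
    ref = theta[0]
    cw = ccw = 0
    # tolerance keeps exact-boundary crossings robust to unwrap round-off
    full_turn = 360.0 - 1e-9
    for value in theta[1:]:
        while value - ref <= -full_turn:
            cw += 1
            ref -= 360.0
        while value - ref >= full_turn:
            ccw += 1
            ref += 360.0
    return RotationCounts(cw=cw, ccw=ccw)


@dataclass(frozen=True)
class GrubbsResult:
    """Outcome of a single-pass two-sided Grubbs screen."""

    statistic: float
    critical: float
    outlier_index: int | None
    n: int
    alpha: float

    @property
    def is_outlier(self) -> bool:
        return self.outlier_index is not None


def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value.

    ``G_crit = (n-1)/sqrt(n) * sqrt(t^2 / (n - 2 + t^2))`` with t the
    upper alpha/(2n) quantile of Student's t with n-2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must lie in (0, 0.5)")
    t = sps.t.isf(alpha / (2.0 * n), df=n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_test(values: Sequence[float], alpha: float = 0.05) -> GrubbsResult:
    """Single-pass two-sided Grubbs outlier test.

    G = max |x_i - mean| / s (sample SD); the most extreme value is
    declared an outlier iff G exceeds the critical value. At most one
    outlier is flagged per call (no iterative removal).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("Grubbs test undefined: zero sample SD")
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = float(dev[idx] / s)
    crit = grubbs_critical(n, alpha)
    return GrubbsResult(
        statistic=g,
        critical=crit,
        outlier_index=idx if g > crit else None,
        n=n,
        alpha=alpha,
    )
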