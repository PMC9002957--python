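"""Resampling, zero-lag filtering, gait events, and cycle normalization.

The agreement statistics downstream are phase-sensitive, so the default
low-pass filter is a zero-phase (forward-backward) Butterworth whose cutoff
is pre-warped so that the dual-pass cascade is exactly -3 dB at the nominal
cutoff frequency.  Heel strikes are detected with the coordinate-based
method: local maxima of the heel's position relative to the sacrum along the
progression axis, in the direction of travel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

__all__ = [
    "FilterSpec",
    "CycleSet",
    "resample",
    "butterworth_lowpass",
    "detect_heel_strikes",
    "detect_vertical_peaks",
    "segment_and_normalize",
    "build_cycles",
]


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth design.

    ``order`` is the per-pass design order (the conventional way the filter
    is quoted); with ``zero_phase`` the signal is filtered forward and
    backward and the design cutoff is pre-warped by ``(sqrt(2)-1)**(-1/(2n))``
    so the cascade's -3 dB point lands on ``cutoff``.
    """

    order: int = 4
    cutoff: float = 6.0
    sample_rate: float = 30.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.order < 2 or self.order % 2:
            raise ValueError("filter order must be even and >= 2")
        if not 0 < self.cutoff < self.sample_rate / 2:
            raise ValueError("cutoff must lie in (0, sample_rate/2)")

    @property
    def design_cutoff(self) -> float:
        """Cutoff used in the design, corrected for the dual pass.

        The forward-backward cascade squares the magnitude response, so the
        single-pass design cutoff is raised until the cascade is exactly
        -3 dB at the nominal cutoff.  The analog-domain correction factor
        ``(sqrt(2)-1)**(-1/(2n))`` is refined against the actual digital
        (bilinear-transform) response, which deviates appreciably when the
        cutoff is a sizeable fraction of the Nyquist rate.
        """
        if not self.zero_phase:
            return self.cutoff
        from scipy.optimize import brentq

        nyq = self.sample_rate / 2.0
        target = 2.0 ** -0.5

        def cascade_gain_minus_target(fd: float) -> float:
            sos = sps.butter(self.order, fd, btype="low", fs=self.sample_rate, output="sos")
            _, h = sps.sosfreqz(sos, worN=[self.cutoff], fs=self.sample_rate)
            return abs(h[0]) ** 2 - target

        hi = 0.999 * nyq
        if cascade_gain_minus_target(hi) < 0:
            return hi  # cutoff so close to Nyquist that no correction reaches -3 dB
        return float(brentq(cascade_gain_minus_target, self.cutoff, hi, xtol=1e-9))


def resample(x: np.ndarray, from_rate: float, to_rate: float) -> np.ndarray:
    """Band-limited (Fourier) resampling along the first axis.

    Appropriate for the near-periodic signals this package handles; output
    length is ``round(len(x) * to_rate / from_rate)``.  Upsampling past the
    information already present cannot create content and only warns.
    """
    if from_rate <= 0 or to_rate <= 0:
        raise ValueError("sampling rates must be positive")
    x = np.asarray(x, dtype=float)
    if from_rate == to_rate:
        return x.copy()
    if to_rate > from_rate:
        warnings.warn(
            "upsampling cannot restore content above the original Nyquist rate",
            stacklevel=2,
        )
    ratio = Fraction(to_rate / from_rate).limit_denominator(1000)
    n_out = int(round(len(x) * ratio))
    return sps.resample(x, n_out, axis=0)


def butterworth_lowpass(x: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Apply the (optionally zero-phase) Butterworth low-pass along axis 0.

    DC gain is exactly 1.  Signals shorter than ~3x the filter order cannot
    be padded for the dual pass and raise a length error.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] <= 3 * spec.order:
        raise ValueError(
            f"signal length {x.shape[0]} too short for an order-{spec.order} filter"
        )
    sos = sps.butter(
        spec.order, spec.design_cutoff, btype="low", fs=spec.sample_rate, output="sos"
    )
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x, axis=0)
    return sps.sosfilt(sos, x, axis=0)


def _relative_progression(
    heel: np.ndarray, sacrum: np.ndarray, progression_axis: int, direction: float
) -> np.ndarray:
    heel = np.asarray(heel, dtype=float)
    sacrum = np.asarray(sacrum, dtype=float)
    if heel.shape[0] != sacrum.shape[0]:
        raise ValueError("heel and sacrum trajectories must share the frame axis")
    h = heel if heel.ndim == 1 else heel[:, progression_axis]
    s = sacrum if sacrum.ndim == 1 else sacrum[:, progression_axis]
    return direction * (h - s)


def detect_heel_strikes(
    heel: np.ndarray,
    sacrum: np.ndarray,
    progression_axis: int = 0,
    direction: float = 1.0,
    cadence: float | None = None,
    frame_rate: float = 30.0,
    return_toe_offs: bool = False,
    toe: np.ndarray | None = None,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Coordinate-based gait events.

    Heel strikes are the local maxima of ``direction * (heel - sacrum)``
    along the progression axis; toe-offs (exposed for completeness, unused
    downstream) are the corresponding local minima computed with the toe
    marker.  When the cadence is known (from the metronome), peaks closer
    than half a stride are rejected.
    """
    rel = _relative_progression(heel, sacrum, progression_axis, direction)
    span = np.ptp(rel)
    if span < 1e-9:
        warnings.warn("no gait detected: heel-sacrum distance is constant", stacklevel=2)
        empty = np.array([], dtype=int)
        return (empty, empty) if return_toe_offs else empty
    distance = None
    if cadence:
        distance = max(1, int(round(0.5 * frame_rate / cadence)))
    strikes, _ = sps.find_peaks(rel, distance=distance, prominence=0.05 * span)
    if not return_toe_offs:
        return strikes
    rel_toe = (
        _relative_progression(toe, sacrum, progression_axis, direction)
        if toe is not None
        else rel
    )
    toe_offs, _ = sps.find_peaks(-rel_toe, distance=distance, prominence=0.05 * span)
    return strikes, toe_offs


def detect_vertical_peaks(
    marker: np.ndarray,
    vertical_axis: int = 1,
    cadence: float | None = None,
    frame_rate: float = 30.0,
) -> np.ndarray:
    """Cycle events for pedaling tasks: peaks of a marker's vertical position.

    Pedaling has no heel strikes; the top of the ankle's vertical excursion
    is a crank-angle proxy that segments cycles the same way.
    """
    m = np.asarray(marker, dtype=float)
    y = m if m.ndim == 1 else m[:, vertical_axis]
    span = np.ptp(y)
    if span < 1e-9:
        warnings.warn("no cyclic motion detected on the vertical axis", stacklevel=2)
        return np.array([], dtype=int)
    distance = None
    if cadence:
        distance = max(1, int(round(0.5 * frame_rate / cadence)))
    peaks, _ = sps.find_peaks(y, distance=distance, prominence=0.05 * span)
    return peaks


@dataclass
class CycleSet:
    """Cycle segmentation: event frames and the normalization grid."""

    event_frames: np.ndarray
    cycles: list  # [(start, end)] frame intervals, end exclusive of next event
    normalized_length: int = 101
    direction_per_cycle: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.event_frames = np.asarray(self.event_frames, dtype=int)
        for (s0, e0), (s1, _) in zip(self.cycles, self.cycles[1:]):
            if e0 > s1:
                raise ValueError("cycles must be non-overlapping and ordered")
        if self.direction_per_cycle is None:
            self.direction_per_cycle = np.ones(len(self.cycles))


def build_cycles(
    event_frames: np.ndarray,
    normalized_length: int = 101,
    direction_per_cycle: np.ndarray | None = None,
) -> CycleSet:
    """Consecutive events delimit cycles; N events give N-1 cycles."""
    events = np.asarray(event_frames, dtype=int)
    cycles = [(int(a), int(b)) for a, b in zip(events, events[1:])]
    if direction_per_cycle is not None:
        direction_per_cycle = np.asarray(direction_per_cycle)[: len(cycles)]
    return CycleSet(events, cycles, normalized_length, direction_per_cycle)


def segment_and_normalize(x: np.ndarray, cycles: CycleSet) -> np.ndarray:
    """Time-normalize each cycle to ``normalized_length`` samples (0-100%).

    Each cycle is linearly warped onto the percentage grid with its endpoint
    samples preserved exactly.  Partial leading/trailing data outside the
    events are discarded.  Returns shape ``(n_cycles, normalized_length)``.
    """
    x = np.asarray(x, dtype=float)
    if not cycles.cycles:
        warnings.warn("no complete cycles to normalize", stacklevel=2)
        return np.empty((0, cycles.normalized_length))
    out = np.empty((len(cycles.cycles), cycles.normalized_length))
    for i, (start, end) in enumerate(cycles.cycles):
        if end >= len(x):
            raise ValueError(f"cycle ({start}, {end}) exceeds signal length {len(x)}")
        grid = np.linspace(start, end, cycles.normalized_length)
        out[i] = np.interp(grid, np.arange(start, end + 1), x[start : end + 1])
    return out
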