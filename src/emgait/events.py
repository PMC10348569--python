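"""Gait-event detection and stride handling from the pelvis marker.

At trot the mid-pelvis (tubera sacrale) marker bounces twice per stride;
its vertical-displacement maxima mark hindlimb impacts, alternating between
the left and right hindlimb.  Because left- and right-side muscles are
analysed separately, a side's sEMG is segmented by *contralateral* hindlimb
impacts: left-muscle strides run from one right-hind impact to the next.

Per-stride forward speed comes from smoothed differentiation of the
marker's horizontal coordinates, averaged over the stride interval.
Conventions: time in seconds from recording start; stride intervals are
half-open [start, end).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from emgait.processing import FilterSpec, butterworth_filter

CONTRALATERAL = {"left": "right_hind", "right": "left_hind"}


@dataclass
class StrideEvents:
    """Ordered hindlimb impacts with alternating limb labels."""

    impact_times: np.ndarray  # s, strictly increasing
    limb_labels: list[str]  # "left_hind" / "right_hind", alternating
    source: str = "tubera_sacrale"

    def __post_init__(self) -> None:
        self.impact_times = np.asarray(self.impact_times, dtype=float)
        if len(self.impact_times) != len(self.limb_labels):
            raise ValueError("impact_times and limb_labels length mismatch")
        if np.any(np.diff(self.impact_times) <= 0):
            raise ValueError("impact times must be strictly increasing")

    def times_for(self, limb: str) -> np.ndarray:
        return self.impact_times[[i for i, l in enumerate(self.limb_labels) if l == limb]]


@dataclass
class Stride:
    """One full stride cycle [start, end) of the segmenting hindlimb."""

    start_time: float
    end_time: float
    limb: str
    velocity: float = float("nan")
    index: int = 0  # order within the trial

    def __post_init__(self) -> None:
        if self.end_time <= self.start_time:
            raise ValueError("stride end must be after start")

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


def detect_hindlimb_impacts(
    z: np.ndarray,
    sampling_rate: float,
    min_separation: float = 0.25,
    prominence_fraction: float = 0.25,
    first_limb: str = "left_hind",
    source: str = "tubera_sacrale",
    refine: bool = True,
) -> StrideEvents:
    """Detect hindlimb impacts at vertical-displacement maxima.

    Local maxima of ``z`` separated by at least ``min_separation`` seconds,
    with prominence above ``prominence_fraction`` of the interquartile range
    of ``z``, are taken as impacts.  The default separation of 0.25 s is
    below half a typical 0.75 s trot stride, so both per-stride maxima are
    kept.  With ``refine`` (default) each peak time is sharpened to
    sub-sample precision by a parabola through the peak sample and its
    neighbours.  Limb labels alternate starting from ``first_limb`` —
    attributing the first maximum to a limb requires outside information
    (metadata, ground truth, or an explicit flag).
    """
    z = np.asarray(z, dtype=float)
    if min_separation <= 0:
        raise ValueError("min_separation must be > 0")
    if z.size <= 2 * min_separation * sampling_rate:
        raise ValueError("signal shorter than two min_separation windows")
    q1, q3 = np.percentile(z, [25, 75])
    prominence = prominence_fraction * (q3 - q1)
    distance = max(1, int(round(min_separation * sampling_rate)))
    peaks, _ = sps.find_peaks(z, distance=distance, prominence=prominence if prominence > 0 else None)
    if len(peaks) < 2:
        raise ValueError("no strides detectable: fewer than 2 vertical-displacement maxima")
    times = peaks / sampling_rate
    if refine:
        inner = (peaks > 0) & (peaks < z.size - 1)
        p = peaks[inner]
        denom = z[p - 1] - 2.0 * z[p] + z[p + 1]
        ok = denom < 0
        shift = np.zeros(p.size)
        shift[ok] = 0.5 * (z[p - 1] - z[p + 1])[ok] / denom[ok]
        times[inner] += np.clip(shift, -0.5, 0.5) / sampling_rate
    other = "right_hind" if first_limb == "left_hind" else "left_hind"
    labels = [first_limb if i % 2 == 0 else other for i in range(len(peaks))]
    return StrideEvents(impact_times=times, limb_labels=labels, source=source)


def segment_strides(events: StrideEvents, muscle_side: str) -> list[Stride]:
    """Full stride cycles for one muscle side, from contralateral impacts.

    A left-side muscle's strides run from each right-hind impact to the
    next right-hind impact (and vice versa).  Yields (count of
    contralateral impacts − 1) half-open intervals that tile the event span.
    """
    if muscle_side not in CONTRALATERAL:
        raise ValueError("muscle_side must be 'left' or 'right'")
    limb = CONTRALATERAL[muscle_side]
    times = events.times_for(limb)
    if len(times) < 2:
        warnings.warn(f"insufficient {limb} impacts to segment strides", stacklevel=2)
        return []
    return [
        Stride(start_time=float(t0), end_time=float(t1), limb=limb, index=i)
        for i, (t0, t1) in enumerate(zip(times[:-1], times[1:]))
    ]


def stride_velocity(
    x: np.ndarray,
    y: np.ndarray,
    sampling_rate: float,
    stride: Stride,
    smooth_cutoff: float = 6.0,
) -> float:
    """Mean forward speed over one stride from the horizontal marker path.

    Positions are zero-phase low-pass filtered at ``smooth_cutoff`` (default
    6 Hz, conventional for kinematic smoothing), differentiated by central
    differences, and the Euclidean speed is averaged over [start, end).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    i0 = int(np.ceil(stride.start_time * sampling_rate - 1e-9))
    i1 = int(np.ceil(stride.end_time * sampling_rate - 1e-9))
    if i0 < 0 or i1 > n or i0 >= i1:
        raise ValueError("stride interval outside the marker record")
    spec = FilterSpec("low_pass", smooth_cutoff, 4)
    xs = butterworth_filter(x, spec, sampling_rate)
    ys = butterworth_filter(y, spec, sampling_rate)
    vx = np.gradient(xs, 1.0 / sampling_rate)
    vy = np.gradient(ys, 1.0 / sampling_rate)
    speed = np.hypot(vx, vy)
    return float(speed[i0:i1].mean())


def attach_velocities(
    strides: list[Stride],
    markers,
    sampling_rate: float,
    smooth_cutoff: float = 6.0,
) -> list[Stride]:
    """Fill the ``velocity`` field of each stride from a markers table."""
    x = np.asarray(markers["x"], dtype=float)
    y = np.asarray(markers["y"], dtype=float)
    out = []
    for s in strides:
        v = stride_velocity(x, y, sampling_rate, s, smooth_cutoff)
        out.append(Stride(s.start_time, s.end_time, s.limb, velocity=v, index=s.index))
    return out
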