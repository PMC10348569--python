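"""The sEMG signal-conditioning chain.

Stages, applied in fixed order to each raw channel:

1. DC-offset removal (mean subtraction),
2. zero-phase Butterworth high-pass, 4th-order design, 40 Hz cutoff
   (movement-artifact suppression),
3. full-wave rectification,
4. zero-phase Butterworth low-pass, 4th-order design, 25 Hz cutoff
   (the linear envelope).

Filters are applied forward and backward (``filtfilt`` with reflective
padding), so burst timing is preserved relative to gait events; the price is
that the effective magnitude response is the single-pass response squared —
gain 0.5, not 1/√2, at the design cutoff.  "4th order" names the designed
prototype, as conventional in gait reports.  The final low-pass may leave
small negative excursions in the envelope; they are retained, not clipped,
and the processing log notes this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class FilterSpec:
    """A zero-phase Butterworth filter specification."""

    kind: str  # "high_pass" | "low_pass"
    cutoff: float  # Hz
    order: int = 4  # design order, before bidirectional application

    def __post_init__(self) -> None:
        if self.kind not in ("high_pass", "low_pass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if self.order < 1:
            raise ValueError("order must be >= 1")


@dataclass
class ConditionedSignal:
    """An enveloped channel plus the ordered log of applied stages."""

    samples: np.ndarray
    sampling_rate: float
    processing_log: list[dict] = field(default_factory=list)


def remove_dc_offset(x: np.ndarray) -> np.ndarray:
    """Subtract the signal mean; output mean is zero to numerical tolerance."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    return x - x.mean()


def butterworth_filter(x: np.ndarray, spec: FilterSpec, sampling_rate: float) -> np.ndarray:
    """Zero-phase (forward + backward) Butterworth filter.

    Edges are handled by reflective padding of the default ``filtfilt``
    length (3×(filter length − 1), well above 3× the design order), trimmed
    after filtering.
    """
    x = np.asarray(x, dtype=float)
    nyq = sampling_rate / 2.0
    if spec.cutoff >= nyq:
        raise ValueError(f"cutoff {spec.cutoff} Hz is at or above Nyquist ({nyq} Hz)")
    if x.size <= 3 * spec.order:
        raise ValueError(f"signal too short ({x.size} samples) for order-{spec.order} filtering")
    btype = "highpass" if spec.kind == "high_pass" else "lowpass"
    b, a = signal.butter(spec.order, spec.cutoff / nyq, btype)
    return signal.filtfilt(b, a, x, padtype="even")


def full_wave_rectify(x: np.ndarray) -> np.ndarray:
    """Elementwise absolute value."""
    return np.abs(np.asarray(x, dtype=float))


def condition_channel(
    raw: np.ndarray,
    sampling_rate: float,
    hp_cutoff: float = 40.0,
    lp_cutoff: float = 25.0,
    order: int = 4,
) -> ConditionedSignal:
    """Run the full conditioning chain on one raw channel.

    Returns the linear envelope with a processing log listing the four
    stages in order.  Length is preserved through every stage.
    """
    raw = np.asarray(raw, dtype=float)
    log: list[dict] = []
    x = remove_dc_offset(raw)
    log.append({"stage": "dc_offset_removal", "method": "mean_subtraction"})
    hp = FilterSpec("high_pass", hp_cutoff, order)
    x = butterworth_filter(x, hp, sampling_rate)
    log.append(
        {"stage": "high_pass", "order": order, "cutoff_hz": hp_cutoff, "application": "zero_phase_bidirectional"}
    )
    x = full_wave_rectify(x)
    log.append({"stage": "full_wave_rectification"})
    lp = FilterSpec("low_pass", lp_cutoff, order)
    x = butterworth_filter(x, lp, sampling_rate)
    log.append(
        {
            "stage": "low_pass_envelope",
            "order": order,
            "cutoff_hz": lp_cutoff,
            "application": "zero_phase_bidirectional",
            "negative_excursions_retained": True,
        }
    )
    return ConditionedSignal(samples=x, sampling_rate=sampling_rate, processing_log=log)
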