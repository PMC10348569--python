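"""Stride quality control, normalization, and ensemble profiles.

Per muscle, session and side the processing order is fixed:

1. screen per-stride envelope peaks for outliers (Tukey fences),
2. compute the RVC — the reference peak: the maximum envelope amplitude
   over all surviving strides of that muscle and session,
3. divide every stride's envelope by the RVC (peak amplitude
   normalization; the defining sample becomes exactly 1),
4. reduce to ten strides by dropping those whose velocity deviates most
   from the session-mean stride velocity,
5. linearly interpolate each stride onto the 101-point 0–100% stride grid.

Ensemble profiles are the per-point mean and sample SD (n − 1) across the
rows of a stride matrix.  Pooling stacks matrices across sessions
(between-session scope, one horse) or across horses (inter-subject scope);
rows keep the RVC of their own session, so pooled matrices mix strides
normalized by session-specific references — matching the acquisition-order
convention of test–retest designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from emgait.events import Stride

N_POINTS = 101

INTRA_SESSION = "intra_session"
BETWEEN_SESSION = "between_session"
INTER_SUBJECT = "inter_subject"


@dataclass
class RVC:
    """Reference peak amplitude for one muscle/side/horse/session."""

    value: float
    muscle: str = ""
    side: str = ""
    horse: str = ""
    session: str = ""
    excluded_peaks: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError("RVC must be > 0 (all-zero or negative envelopes)")


@dataclass
class StrideMatrix:
    """Included strides × 101 time/amplitude-normalized envelope samples."""

    muscle: str
    side: str
    scope: str
    values: np.ndarray  # (n_strides, 101)
    stride_index: list[tuple[str, str, int]]  # (horse, session, stride id) per row

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != N_POINTS:
            raise ValueError(f"stride matrix must have {N_POINTS} columns")
        if self.values.shape[0] != len(self.stride_index):
            raise ValueError("row count and stride_index length differ")

    @property
    def n_strides(self) -> int:
        return self.values.shape[0]


@dataclass
class EnsembleProfile:
    """101-point mean ± SD waveform with provenance."""

    mean_curve: np.ndarray
    sd_curve: np.ndarray | None
    n_strides: int
    muscle: str = ""
    side: str = ""
    scope: str = INTRA_SESSION
    provenance: list[tuple[str, str, int]] = field(default_factory=list)


def detect_outlier_strides(per_stride_peaks: np.ndarray, k: float = 1.5) -> np.ndarray:
    """Flag strides whose envelope peak falls outside the Tukey fences.

    Fences are [Q1 − k·IQR, Q3 + k·IQR] over the per-stride peaks.  With
    fewer than four strides the quartiles are too unstable to screen;
    nothing is flagged and a warning is issued.
    """
    peaks = np.asarray(per_stride_peaks, dtype=float)
    if peaks.size < 4:
        warnings.warn("fewer than 4 strides: outlier screening skipped", stacklevel=2)
        return np.zeros(peaks.size, dtype=bool)
    q1, q3 = np.percentile(peaks, [25, 75])
    iqr = q3 - q1
    return (peaks < q1 - k * iqr) | (peaks > q3 + k * iqr)


def select_strides_by_velocity(strides: list[Stride], target_n: int = 10) -> list[Stride]:
    """Keep the ``target_n`` strides closest to the mean stride velocity.

    The mean is computed once over all input strides (not recomputed after
    removals).  Ties break in favour of the earlier stride; input order is
    preserved in the output.  If fewer than ``target_n`` strides are
    available, all are returned with a warning.
    """
    if target_n < 1:
        raise ValueError("target_n must be >= 1")
    if len(strides) <= target_n:
        if len(strides) < target_n:
            warnings.warn(
                f"only {len(strides)} strides available, fewer than target {target_n}",
                stacklevel=2,
            )
        return list(strides)
    v = np.array([s.velocity for s in strides], dtype=float)
    dev = np.abs(v - v.mean())
    keep = np.sort(np.argsort(dev, kind="stable")[:target_n])
    return [strides[i] for i in keep]


def normalize_amplitude(segments: list[np.ndarray], rvc: RVC) -> list[np.ndarray]:
    """Divide every sample of every segment by the RVC value."""
    return [np.asarray(seg, dtype=float) / rvc.value for seg in segments]


def time_normalize(segment: np.ndarray, n_points: int = N_POINTS) -> np.ndarray:
    """Linearly interpolate a stride segment onto the 0–100% grid.

    The segment's samples are taken as equally spaced over the stride; the
    output holds the value at 0, 1, …, 100% (101 points), so the first
    output equals the first sample and the last the final sample.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.size < 2:
        raise ValueError("segment too short to time-normalize (need >= 2 samples)")
    src = np.linspace(0.0, 100.0, seg.size)
    return np.interp(np.linspace(0.0, 100.0, n_points), src, seg)


def build_ensemble(matrix: StrideMatrix) -> EnsembleProfile:
    """Per-point mean and sample SD (ddof = 1) across strides."""
    n = matrix.n_strides
    if n < 1:
        raise ValueError("empty stride matrix")
    mean = matrix.values.mean(axis=0)
    if n >= 2:
        sd = matrix.values.std(axis=0, ddof=1)
    else:
        warnings.warn("single stride: SD undefined, mean-only profile", stacklevel=2)
        sd = None
    return EnsembleProfile(
        mean_curve=mean,
        sd_curve=sd,
        n_strides=n,
        muscle=matrix.muscle,
        side=matrix.side,
        scope=matrix.scope,
        provenance=list(matrix.stride_index),
    )


def pool_strides(matrices: list[StrideMatrix], scope: str) -> StrideMatrix:
    """Stack stride matrices of the same muscle/side under a wider scope."""
    if not matrices:
        raise ValueError("nothing to pool")
    m0 = matrices[0]
    for m in matrices[1:]:
        if (m.muscle, m.side) != (m0.muscle, m0.side):
            raise ValueError(
                f"cannot pool {m.muscle}/{m.side} with {m0.muscle}/{m0.side}"
            )
    values = np.vstack([m.values for m in matrices])
    index = [t for m in matrices for t in m.stride_index]
    return StrideMatrix(m0.muscle, m0.side, scope, values, index)


def _slice_stride(env: np.ndarray, sampling_rate: float, stride: Stride) -> np.ndarray:
    i0 = int(np.ceil(stride.start_time * sampling_rate - 1e-9))
    i1 = int(np.ceil(stride.end_time * sampling_rate - 1e-9))
    if i0 < 0 or i1 > env.size or i1 - i0 < 2:
        raise ValueError("stride interval outside the EMG record")
    return env[i0:i1]


def build_stride_matrices(
    envelopes: dict[str, np.ndarray],
    sampling_rate: float,
    strides_by_side: dict[str, list[Stride]],
    channel_map: dict[str, tuple[str, str]],
    horse: str,
    session: str,
    target_n: int = 10,
    outlier_k: float = 1.5,
    per_muscle_exclusion: bool = False,
) -> tuple[dict[str, StrideMatrix], dict]:
    """Run the QC + normalization chain for one recording.

    ``envelopes`` maps channel name to its conditioned envelope; strides
    come pre-segmented per side with velocities attached.  By default a
    stride flagged as a peak outlier for *any* muscle of a side is excluded
    for all muscles of that side (one stride count per side); set
    ``per_muscle_exclusion`` for independent per-muscle screening.

    Returns one intra-session StrideMatrix per channel and a QC record
    (strides detected / outliers removed / strides selected / RVC per
    channel).
    """
    matrices: dict[str, StrideMatrix] = {}
    qc: dict = {"horse": horse, "session": session, "sides": {}, "channels": {}}
    for side, strides in strides_by_side.items():
        side_channels = [ch for ch, (_m, s) in channel_map.items() if s == side]
        if not side_channels or not strides:
            qc["sides"][side] = {"detected": len(strides), "outliers_removed": 0, "selected": 0}
            continue
        segs = {ch: [_slice_stride(envelopes[ch], sampling_rate, s) for s in strides] for ch in side_channels}
        peaks = {ch: np.array([seg.max() for seg in segs[ch]]) for ch in side_channels}
        flags = {ch: detect_outlier_strides(peaks[ch], k=outlier_k) for ch in side_channels}
        if per_muscle_exclusion:
            excluded = flags
        else:
            union = np.logical_or.reduce([flags[ch] for ch in side_channels])
            excluded = {ch: union for ch in side_channels}
        for ch in side_channels:
            muscle, _ = channel_map[ch]
            keep_mask = ~excluded[ch]
            kept = [s for s, k in zip(strides, keep_mask) if k]
            if not kept:
                raise ValueError(f"all strides excluded as outliers for {ch}")
            rvc = RVC(
                value=float(peaks[ch][keep_mask].max()),
                muscle=muscle,
                side=side,
                horse=horse,
                session=session,
                excluded_peaks=[float(p) for p in peaks[ch][~keep_mask]],
            )
            kept_segs = [seg for seg, k in zip(segs[ch], keep_mask) if k]
            normed = normalize_amplitude(kept_segs, rvc)
            selected = select_strides_by_velocity(kept, target_n=target_n)
            sel_ids = {s.index for s in selected}
            rows = [
                time_normalize(seg)
                for s, seg in zip(kept, normed)
                if s.index in sel_ids
            ]
            index = [(horse, session, s.index) for s in kept if s.index in sel_ids]
            matrices[ch] = StrideMatrix(muscle, side, INTRA_SESSION, np.vstack(rows), index)
            qc["channels"][ch] = {
                "rvc": rvc.value,
                # peak of the normalized included strides; 1 at the
                # RVC-defining sample before any velocity-based reduction
                "norm_peak_max": float(max(seg.max() for seg in normed)),
                "outliers_removed": int(excluded[ch].sum()),
                "selected": len(index),
            }
        n_out = int(excluded[side_channels[0]].sum())
        qc["sides"][side] = {
            "detected": len(strides),
            "outliers_removed": n_out,
            "selected": len(matrices[side_channels[0]].stride_index),
        }
    return matrices, qc


def relabel_scope(matrix: StrideMatrix, scope: str) -> StrideMatrix:
    """Copy of a matrix under a different scope label."""
    return replace(matrix, scope=scope, values=matrix.values.copy(), stride_index=list(matrix.stride_index))
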