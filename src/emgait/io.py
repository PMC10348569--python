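"""Delimited-file dialects for recordings, envelopes, matrices and profiles.

A recording is stored as four files under one directory, named
``{horse}_{session}_{kind}``:

* ``*_emg.tsv``      — time column plus one column per sEMG channel (2000 Hz)
* ``*_markers.tsv``  — time, x, y, z of the tubera-sacrale marker (200 Hz)
* ``*_meta.json``    — horse, session, sampling rates, channel → muscle/side
  map, first hindlimb label
* ``*_truth.json``   — generator ground truth (impact times/limbs, per-stride
  duration/velocity/amplitude/outlier flags, templates); absent for real data

Stride matrices and ensemble profiles are written as 102-column TSVs:
percent stride 0–100 in the header, one row per stride (matrix) or
mean/SD rows (profile).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from emgait.ensemble import EnsembleProfile, StrideMatrix
from emgait.synthetic import (
    Burst,
    MuscleArchetype,
    RecordingSession,
    SessionTruth,
)

_FLOAT_FMT = "%.10g"


def session_basename(horse: str, session: str) -> str:
    return f"{horse}_{session}"


def write_session(rec: RecordingSession, outdir: str | Path) -> dict[str, Path]:
    """Write one recording as emg/markers/meta(/truth) files; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = session_basename(rec.horse_id, rec.session_id)
    paths = {
        "emg": outdir / f"{base}_emg.tsv",
        "markers": outdir / f"{base}_markers.tsv",
        "meta": outdir / f"{base}_meta.json",
    }
    rec.emg.to_csv(paths["emg"], sep="\t", index=False, float_format=_FLOAT_FMT)
    rec.markers.to_csv(paths["markers"], sep="\t", index=False, float_format=_FLOAT_FMT)
    meta = {
        "horse_id": rec.horse_id,
        "session_id": rec.session_id,
        "emg_rate_hz": rec.emg_rate,
        "marker_rate_hz": rec.marker_rate,
        "channel_map": {ch: {"muscle": m, "side": s} for ch, (m, s) in rec.channel_map.items()},
        "first_limb": rec.first_limb,
    }
    paths["meta"].write_text(json.dumps(meta, indent=1))
    if rec.truth is not None:
        paths["truth"] = outdir / f"{base}_truth.json"
        paths["truth"].write_text(json.dumps(_truth_to_dict(rec.truth), indent=1))
    return paths


def read_session(outdir: str | Path, horse: str, session: str) -> RecordingSession:
    """Read a recording previously written by :func:`write_session`."""
    outdir = Path(outdir)
    base = session_basename(horse, session)
    meta = json.loads((outdir / f"{base}_meta.json").read_text())
    emg = pd.read_csv(outdir / f"{base}_emg.tsv", sep="\t")
    markers = pd.read_csv(outdir / f"{base}_markers.tsv", sep="\t")
    truth_path = outdir / f"{base}_truth.json"
    truth = _truth_from_dict(json.loads(truth_path.read_text())) if truth_path.exists() else None
    return RecordingSession(
        horse_id=meta["horse_id"],
        session_id=meta["session_id"],
        emg=emg,
        markers=markers,
        emg_rate=float(meta["emg_rate_hz"]),
        marker_rate=float(meta["marker_rate_hz"]),
        channel_map={ch: (d["muscle"], d["side"]) for ch, d in meta["channel_map"].items()},
        first_limb=meta["first_limb"],
        truth=truth,
    )


def list_sessions(outdir: str | Path) -> list[tuple[str, str]]:
    """(horse, session) pairs present in a directory, sorted."""
    pairs = set()
    for p in Path(outdir).glob("*_meta.json"):
        meta = json.loads(p.read_text())
        pairs.add((meta["horse_id"], meta["session_id"]))
    return sorted(pairs)


def _truth_to_dict(t: SessionTruth) -> dict:
    return {
        "impact_times": t.impact_times.tolist(),
        "impact_limbs": t.impact_limbs,
        "stride_durations": t.stride_durations.tolist(),
        "stride_velocities": t.stride_velocities.tolist(),
        "amp_factors": t.amp_factors.tolist(),
        "timing_shifts": t.timing_shifts.tolist(),
        "outlier_flags": [bool(f) for f in t.outlier_flags],
        "templates": {
            ch: {
                "name": a.name,
                "baseline": a.baseline,
                "bursts": [[b.center, b.width, b.amplitude] for b in a.bursts],
            }
            for ch, a in t.templates.items()
        },
        "session_scale": t.session_scale,
        "session_shift": t.session_shift,
    }


def _truth_from_dict(d: dict) -> SessionTruth:
    return SessionTruth(
        impact_times=np.asarray(d["impact_times"], dtype=float),
        impact_limbs=list(d["impact_limbs"]),
        stride_durations=np.asarray(d["stride_durations"], dtype=float),
        stride_velocities=np.asarray(d["stride_velocities"], dtype=float),
        amp_factors=np.asarray(d["amp_factors"], dtype=float),
        timing_shifts=np.asarray(d["timing_shifts"], dtype=float),
        outlier_flags=np.asarray(d["outlier_flags"], dtype=bool),
        templates={
            ch: MuscleArchetype(
                a["name"], tuple(Burst(*b) for b in a["bursts"]), a["baseline"]
            )
            for ch, a in d["templates"].items()
        },
        session_scale=dict(d["session_scale"]),
        session_shift=dict(d["session_shift"]),
    )


def _pct_header() -> list[str]:
    return [f"pct{i}" for i in range(101)]


def write_stride_matrix(matrix: StrideMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.values, columns=_pct_header())
    df.insert(0, "horse", [i[0] for i in matrix.stride_index])
    df.insert(1, "session", [i[1] for i in matrix.stride_index])
    df.insert(2, "stride", [i[2] for i in matrix.stride_index])
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_profile(profile: EnsembleProfile, path: str | Path) -> None:
    rows = {"mean": profile.mean_curve}
    if profile.sd_curve is not None:
        rows["sd"] = profile.sd_curve
    df = pd.DataFrame.from_dict(rows, orient="index", columns=_pct_header())
    df.insert(0, "n_strides", profile.n_strides)
    df.index.name = "curve"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
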