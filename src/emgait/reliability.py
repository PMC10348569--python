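"""Waveform-similarity statistics for cyclic envelope profiles.

Two statistics quantify test–retest reliability of time-normalized
waveforms:

*Ensemble coefficient of variation* (Winter).  For a strides × 101 matrix
with per-point sample SD σ_i and per-point ensemble mean X̄_i,

    CV = sqrt( (1/N) Σ_i σ_i² ) / ( (1/N) Σ_i X̄_i ),   N = 101,

the root-mean-square of the point SDs over the stride divided by the mean
of the ensemble average — a variability-to-signal ratio that tends to zero
for identical waveforms.  CV is scale-invariant but *not* shift-invariant:
adding baseline activity lowers it, so muscles with quiescent baselines
read out higher CVs for the same absolute variability.

*Adjusted coefficient of multiple correlation* (Kadaba).  For D session
curves Y_d of T points each, with per-point across-session mean Ȳ_t and
grand mean Ȳ,

    CMC = sqrt( 1 − [ Σ_d Σ_t (Y_dt − Ȳ_t)² / (T(D−1)) ]
                  / [ Σ_d Σ_t (Y_dt − Ȳ)² / (DT−1) ] ),

the between-session variance normalized by total variance.  1 for
identical sessions; when between-session variance exceeds total variance
(anti-phase curves) the radicand is negative and the result is flagged
undefined rather than clipped.  Interpretation bands: > 0.90 excellent,
(0.75, 0.90] good, [0.50, 0.75] moderate, below 0.50 below-moderate — a
value sitting exactly on an edge goes to the lower band, matching the
verbal convention ("excellent > 0.90").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from emgait.ensemble import StrideMatrix

CMC_BANDS = ((0.90, "excellent"), (0.75, "good"), (0.50, "moderate"))


@dataclass
class CVResult:
    cv: float
    scope: str
    n_strides: int
    muscle: str = ""
    side: str = ""
    horse: str = ""
    session: str = ""
    undefined: bool = False


@dataclass
class CMCResult:
    cmc: float  # nan when undefined
    n_sessions: int
    n_points: int
    band: str
    muscle: str = ""
    side: str = ""
    horse: str = ""
    undefined: bool = False


@dataclass
class SummaryRow:
    muscle: str
    side: str
    statistic: str  # "cv" | "cmc"
    scope: str
    mean: float
    sd: float  # nan when n < 2
    n: int
    n_undefined: int = 0


def ensemble_cv(
    matrix: StrideMatrix,
    horse: str = "",
    session: str = "",
) -> CVResult:
    """Winter's ensemble CV of a stride matrix."""
    if matrix.n_strides < 2:
        raise ValueError("CV needs at least 2 strides")
    # SD on row-shifted values: shift-invariant, better conditioned, and
    # exactly zero when all strides are identical
    sd = (matrix.values - matrix.values[0]).std(axis=0, ddof=1)
    mean = matrix.values.mean(axis=0)
    denom = mean.mean()
    rmsd = math.sqrt(float(np.mean(sd**2)))
    if denom == 0:
        return CVResult(
            cv=float("nan"), scope=matrix.scope, n_strides=matrix.n_strides,
            muscle=matrix.muscle, side=matrix.side, horse=horse, session=session,
            undefined=True,
        )
    return CVResult(
        cv=rmsd / float(denom),
        scope=matrix.scope,
        n_strides=matrix.n_strides,
        muscle=matrix.muscle,
        side=matrix.side,
        horse=horse,
        session=session,
    )


def classify_cmc(cmc: float) -> str:
    """Reliability band of a CMC value; band edges belong to the lower band."""
    if math.isnan(cmc):
        return "undefined"
    for lo, name in CMC_BANDS:
        if cmc > lo:
            return name
    return "moderate" if cmc >= 0.50 else "below_moderate"


def adjusted_cmc(
    session_curves: np.ndarray,
    muscle: str = "",
    side: str = "",
    horse: str = "",
) -> CMCResult:
    """Kadaba's adjusted CMC of D session curves × T time points.

    Undefined (cmc = nan, flagged) when total variance is zero or when
    between-session variance exceeds total variance (negative radicand).
    """
    Y = np.atleast_2d(np.asarray(session_curves, dtype=float))
    D, T = Y.shape
    if D < 2:
        raise ValueError("CMC needs at least 2 session curves")
    if T < 2:
        raise ValueError("CMC needs at least 2 time points")
    ybar_t = Y.mean(axis=0)
    ybar = Y.mean()
    num = float(np.sum((Y - ybar_t) ** 2)) / (T * (D - 1))
    den = float(np.sum((Y - ybar) ** 2)) / (D * T - 1)
    if den == 0 or num / den > 1:
        return CMCResult(
            cmc=float("nan"), n_sessions=D, n_points=T, band="undefined",
            muscle=muscle, side=side, horse=horse, undefined=True,
        )
    cmc = math.sqrt(1.0 - num / den)
    return CMCResult(
        cmc=cmc, n_sessions=D, n_points=T, band=classify_cmc(cmc),
        muscle=muscle, side=side, horse=horse,
    )


def summarize(results: list[CVResult] | list[CMCResult]) -> list[SummaryRow]:
    """Mean ± sample SD per muscle/side group, across horses/sessions.

    Undefined-flagged results are excluded from the mean/SD; their count is
    reported per group.  Output rows are sorted by (muscle, side), so
    permuting the input leaves the output unchanged.
    """
    if not results:
        raise ValueError("no results to summarize")
    groups: dict[tuple[str, str], list] = {}
    order: list[tuple[str, str]] = []
    for r in results:
        key = (r.muscle, r.side)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(r)
    order.sort()
    rows: list[SummaryRow] = []
    for key in order:
        rs = groups[key]
        stat = "cv" if isinstance(rs[0], CVResult) else "cmc"
        scope = rs[0].scope if stat == "cv" else "between_session"
        vals = np.array([r.cv if stat == "cv" else r.cmc for r in rs if not r.undefined])
        n_undef = sum(r.undefined for r in rs)
        mean = float(vals.mean()) if vals.size else float("nan")
        sd = float(vals.std(ddof=1)) if vals.size >= 2 else float("nan")
        rows.append(
            SummaryRow(
                muscle=key[0], side=key[1], statistic=stat, scope=scope,
                mean=mean, sd=sd, n=int(vals.size), n_undefined=n_undef,
            )
        )
    return rows


def summary_frame(rows: list[SummaryRow]) -> pd.DataFrame:
    """Summary rows as a tidy table (the per-muscle, per-side report layout)."""
    return pd.DataFrame(
        [
            {
                "muscle": r.muscle, "side": r.side, "statistic": r.statistic,
                "scope": r.scope, "mean": r.mean, "sd": r.sd, "n": r.n,
                "n_undefined": r.n_undefined,
            }
            for r in rows
        ]
    )
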