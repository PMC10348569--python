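"""Synthetic multi-horse trot recordings with retained ground truth.

Emulates the output of a synchronized surface-EMG (2000 Hz) + optical motion
capture (200 Hz) acquisition during in-hand trot: burst-patterned sEMG per
muscle channel and a tubera-sacrale (mid-pelvis) marker whose vertical
coordinate oscillates twice per stride, with maxima at hindlimb impacts.

The statistical structure mirrors a test–retest study design:

* each *horse* perturbs the population muscle archetypes (burst centres,
  widths, amplitudes, baseline) — inter-subject variability;
* each *session* applies an amplitude scale and a burst-timing shift to a
  horse's templates, emulating sensor re-application error;
* each *stride* draws its own duration and velocity and jitters burst
  amplitude and timing — stride-to-stride (intra-subject) variability;
* occasional *outlier* strides have their amplitude inflated ≥ 3×, feeding
  the downstream peak-based outlier screen.

Raw sEMG is the ground-truth activation envelope multiplying a
constant-amplitude carrier whose instantaneous frequency wanders smoothly
within the 20–450 Hz hardware band, plus band-limited Gaussian noise and a
constant DC offset.  The constant-amplitude carrier is what makes the
generator testable: full-wave rectification followed by the 25 Hz low-pass
recovers the envelope up to the known factor 2/π with < 3% ripple, so the
conditioning chain can be checked against the stored truth.  All randomness
flows from a single seed; identical config + seed gives bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

EMG_RATE = 2000.0
MARKER_RATE = 200.0

#: % stride of burst-centre displacement per unit of a "relative" SD parameter
TIMING_SCALE = 10.0
#: amplitude multiplier applied to outlier strides (peak-inflation model)
OUTLIER_FACTOR = 3.5
#: lead-in/out (s) of extrapolated gait on either side of the first/last
#: impact; kept below half a stride so no extra pelvis maximum precedes the
#: first recorded impact
EDGE_MARGIN = 0.3

_CARRIER_F_CENTER = 225.0  # Hz
_CARRIER_F_DEV = 100.0  # Hz; instantaneous frequency stays in ~[125, 325]
_Z_BASE = 1.45  # m, approximate tubera-sacrale height
_Z_HALF_RANGE = 0.03  # m, vertical oscillation amplitude at trot
_Y_SWAY = 0.01  # m, lateral sway once per stride


@dataclass(frozen=True)
class Burst:
    """One Gaussian activation bump on the circular 0–100% stride axis."""

    center: float  # % stride in [0, 100)
    width: float  # % stride (SD of the bump)
    amplitude: float  # relative units


@dataclass(frozen=True)
class MuscleArchetype:
    """Activation-shape template for one muscle type.

    ``mono_burst`` muscles show one main burst from late swing into stance
    over a quiescent baseline (triceps/hamstring-like); ``multi_burst``
    muscles show repeated bursts over a higher tonic baseline
    (longissimus-like).
    """

    name: str
    bursts: tuple[Burst, ...]
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if not self.bursts:
            raise ValueError("archetype needs at least one burst")
        for b in self.bursts:
            if not (0 <= b.center < 100):
                raise ValueError(f"burst center {b.center} outside [0, 100)")
            if b.width <= 0:
                raise ValueError("burst width must be > 0")
            if b.amplitude < 0:
                raise ValueError("burst amplitude must be >= 0")
        if self.baseline < 0:
            raise ValueError("baseline must be >= 0")

    def evaluate(self, pct: np.ndarray, center_shift: float | np.ndarray = 0.0) -> np.ndarray:
        """Envelope value at stride percentages ``pct`` (circular axis)."""
        pct = np.asarray(pct, dtype=float)
        out = np.full(pct.shape, float(self.baseline))
        for b in self.bursts:
            d = np.abs((pct - (b.center + center_shift)) % 100.0)
            d = np.minimum(d, 100.0 - d)
            out += b.amplitude * np.exp(-0.5 * (d / b.width) ** 2)
        return out


def default_archetypes() -> dict[str, MuscleArchetype]:
    """The two archetypes shipped as defaults.

    ``mono_burst``: a single burst wrapping the stride boundary (late swing
    → mid-stance, centred ~10% with the tail reaching back past 95%), low
    baseline.  ``multi_burst``: two bursts per stride over a higher tonic
    baseline, as axial muscles show at two-beat gaits.
    """
    return {
        "mono_burst": MuscleArchetype(
            "mono_burst", (Burst(center=10.0, width=9.0, amplitude=1.0),), baseline=0.05
        ),
        "multi_burst": MuscleArchetype(
            "multi_burst",
            (Burst(center=5.0, width=10.0, amplitude=0.7), Burst(center=55.0, width=10.0, amplitude=0.7)),
            baseline=0.30,
        ),
    }


@dataclass(frozen=True)
class PopulationConfig:
    """Study-design parameters for a synthetic population.

    Defaults mirror the reference study conditions: 8 horses, 2 sessions a
    day or two apart, trot at 3.09 ± 0.29 m/s with 0.75 ± 0.03 s strides.
    ``strides_per_trial`` is set so that, after outlier screening, at least
    ten strides per session and side survive for the reduction step.
    """

    n_horses: int = 8
    n_sessions: int = 2
    strides_per_trial: int = 15
    stride_duration_mean: float = 0.75  # s
    stride_duration_sd: float = 0.03  # s
    velocity_mean: float = 3.09  # m/s
    velocity_sd: float = 0.29  # m/s
    inter_horse_sd: float = 0.15  # relative; perturbs archetype parameters per horse
    intra_horse_sd: float = 0.08  # relative; stride-to-stride amplitude/timing jitter
    session_effect_sd: float = 0.08  # relative; per-session scale + timing shift
    noise_floor: float = 0.03  # relative; band-limited additive noise level
    marker_noise_sd: float = 1e-4  # m; optical-capture residual
    outlier_rate: float = 0.03  # probability per stride
    first_limb: str = "left_hind"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_horses, self.n_sessions, self.strides_per_trial) < 1:
            raise ValueError("zero-length recording requested: counts must be >= 1")
        for name in (
            "stride_duration_sd",
            "velocity_sd",
            "inter_horse_sd",
            "intra_horse_sd",
            "session_effect_sd",
            "noise_floor",
            "marker_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.outlier_rate < 1):
            raise ValueError("outlier_rate must be in [0, 1)")
        if self.first_limb not in ("left_hind", "right_hind"):
            raise ValueError("first_limb must be 'left_hind' or 'right_hind'")

    def replace(self, **kw) -> "PopulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SessionTruth:
    """Ground truth retained for one recording, for recovery tests."""

    impact_times: np.ndarray  # all hindlimb impacts (s), strictly increasing
    impact_limbs: list[str]  # alternating left_hind / right_hind
    stride_durations: np.ndarray  # per generator stride (s)
    stride_velocities: np.ndarray  # per generator stride (m/s)
    amp_factors: np.ndarray  # per-stride envelope amplitude multipliers
    timing_shifts: np.ndarray  # per-stride burst-centre shifts (% stride)
    outlier_flags: np.ndarray  # per-stride bool
    templates: dict[str, MuscleArchetype]  # channel -> horse-level archetype
    session_scale: dict[str, float]  # channel -> session amplitude factor
    session_shift: dict[str, float]  # channel -> session timing shift (% stride)

    def template_curve(self, channel: str, n_points: int = 101) -> np.ndarray:
        """Session-effective activation template on an n-point stride grid."""
        pct = np.linspace(0.0, 100.0, n_points)
        tpl = self.templates[channel]
        return self.session_scale[channel] * tpl.evaluate(pct, self.session_shift[channel])

    def mean_velocity(self, start: float, end: float) -> float:
        """Exact mean forward speed over [start, end) of the piecewise-constant truth."""
        # breakpoints at same-limb impacts (stride boundaries)
        knots = self.impact_times[::2]
        v = self.stride_velocities
        edges = np.concatenate(([min(start, knots[0])], knots, [max(end, knots[-1], start + 1e-9)]))
        vals = np.concatenate(([v[0]], v, [v[-1]]))[: len(edges) - 1]
        lo = np.clip(edges[:-1], start, end)
        hi = np.clip(edges[1:], start, end)
        w = np.maximum(hi - lo, 0.0)
        return float(np.sum(w * vals) / (end - start))


@dataclass
class RecordingSession:
    """One horse/session recording: raw sEMG + marker trajectory + metadata."""

    horse_id: str
    session_id: str
    emg: pd.DataFrame  # columns: time + one per channel
    markers: pd.DataFrame  # columns: time, x, y, z
    emg_rate: float = EMG_RATE
    marker_rate: float = MARKER_RATE
    channel_map: dict[str, tuple[str, str]] = field(default_factory=dict)  # channel -> (muscle, side)
    first_limb: str = "left_hind"
    truth: SessionTruth | None = None

    @property
    def channels(self) -> list[str]:
        return [c for c in self.emg.columns if c != "time"]


def _smooth_fm_carrier(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Constant-amplitude cosine with slowly wandering in-band frequency."""
    white = rng.standard_normal(n)
    b, a = signal.butter(2, 5.0 / (fs / 2.0), "lowpass")
    drift = signal.filtfilt(b, a, white)
    f_inst = _CARRIER_F_CENTER + _CARRIER_F_DEV * np.tanh(2.0 * drift)
    phase = 2.0 * np.pi * np.cumsum(f_inst) / fs + rng.uniform(0.0, 2.0 * np.pi)
    return np.cos(phase)


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-SD Gaussian noise band-passed to the 20–450 Hz hardware band."""
    white = rng.standard_normal(n)
    b, a = signal.butter(4, [20.0 / (fs / 2.0), 450.0 / (fs / 2.0)], "bandpass")
    out = signal.filtfilt(b, a, white)
    sd = out.std()
    return out / sd if sd > 0 else out


def _perturb_archetype(base: MuscleArchetype, rng: np.random.Generator, sd: float) -> MuscleArchetype:
    """Per-horse template: jitter centres, log-scale widths/amplitudes/baseline."""
    bursts = tuple(
        Burst(
            center=(b.center + rng.normal(0.0, TIMING_SCALE * sd)) % 100.0,
            width=b.width * np.exp(rng.normal(0.0, sd)),
            amplitude=b.amplitude * np.exp(rng.normal(0.0, sd)),
        )
        for b in base.bursts
    )
    baseline = base.baseline * np.exp(rng.normal(0.0, sd))
    return MuscleArchetype(base.name, bursts, baseline)


def _interp_extrap(t: np.ndarray, xk: np.ndarray, yk: np.ndarray) -> np.ndarray:
    """Linear interpolation with linear (edge-slope) extrapolation."""
    out = np.interp(t, xk, yk)
    s0 = (yk[1] - yk[0]) / (xk[1] - xk[0])
    s1 = (yk[-1] - yk[-2]) / (xk[-1] - xk[-2])
    lo = t < xk[0]
    hi = t > xk[-1]
    out[lo] = yk[0] + s0 * (t[lo] - xk[0])
    out[hi] = yk[-1] + s1 * (t[hi] - xk[-1])
    return out


def _generate_session(
    horse_id: str,
    session_id: str,
    config: PopulationConfig,
    horse_templates: dict[str, MuscleArchetype],
    channel_map: dict[str, tuple[str, str]],
    rng: np.random.Generator,
) -> RecordingSession:
    S = config.strides_per_trial
    # S full strides plus a trailing half stride so both hindlimbs register
    # strides_per_trial + 1 impacts (strides_per_trial strides per side).
    durations = np.clip(
        rng.normal(config.stride_duration_mean, config.stride_duration_sd, S + 1), 0.3, None
    )
    velocities = np.clip(rng.normal(config.velocity_mean, config.velocity_sd, S + 1), 0.5, None)

    knots = np.empty(2 * S + 2)
    knots[0] = EDGE_MARGIN
    half = np.repeat(durations, 2)[: 2 * S + 1] / 2.0
    knots[1:] = EDGE_MARGIN + np.cumsum(half)
    total = knots[-1] + EDGE_MARGIN

    limbs = ["left_hind", "right_hind"] if config.first_limb == "left_hind" else ["right_hind", "left_hind"]
    impact_limbs = [limbs[k % 2] for k in range(len(knots))]

    # per-stride effects (index 0..S, last drives the trailing half stride)
    amp_factors = np.exp(rng.normal(0.0, config.intra_horse_sd, S + 1))
    timing_shifts = rng.normal(0.0, TIMING_SCALE * config.intra_horse_sd, S + 1)
    outlier_flags = rng.random(S + 1) < config.outlier_rate
    amp_eff = amp_factors * np.where(outlier_flags, OUTLIER_FACTOR, 1.0)

    session_scale: dict[str, float] = {}
    session_shift: dict[str, float] = {}
    for ch in channel_map:
        session_scale[ch] = float(np.exp(rng.normal(0.0, config.session_effect_sd)))
        session_shift[ch] = float(rng.normal(0.0, TIMING_SCALE * config.session_effect_sd))

    t_emg = np.arange(0.0, total, 1.0 / EMG_RATE)
    t_mark = np.arange(0.0, total, 1.0 / MARKER_RATE)

    # stride phase: k/2 at impact knot k, extrapolated at the edges
    phase_emg = _interp_extrap(t_emg, knots, np.arange(len(knots)) / 2.0)
    phase_mark = _interp_extrap(t_mark, knots, np.arange(len(knots)) / 2.0)
    pct = (phase_emg % 1.0) * 100.0
    stride_idx = np.clip(np.floor(phase_emg).astype(int), 0, S)

    emg_cols: dict[str, np.ndarray] = {"time": t_emg}
    for ch in channel_map:
        tpl = horse_templates[ch]
        shift = session_shift[ch] + timing_shifts[stride_idx]
        env = tpl.evaluate(pct, shift) * session_scale[ch] * amp_eff[stride_idx]
        carrier = _smooth_fm_carrier(rng, len(t_emg), EMG_RATE)
        raw = env * carrier
        if config.noise_floor > 0:
            raw = raw + config.noise_floor * _bandlimited_noise(rng, len(t_emg), EMG_RATE)
        raw = raw + rng.normal(1.0, 0.2)  # constant DC offset
        emg_cols[ch] = raw
    emg = pd.DataFrame(emg_cols)

    # markers: z peaks twice per stride, exactly at the impact knots
    z = _Z_BASE + _Z_HALF_RANGE * np.cos(4.0 * np.pi * phase_mark)
    stride_edges = knots[::2]
    cum = np.concatenate(([0.0], np.cumsum(velocities[:-1] * durations[:-1] )))
    # trailing half stride continues at the last stride's velocity
    cum_knots = np.concatenate((cum, [cum[-1] + velocities[-1] * durations[-1] / 2.0]))
    x_knots = np.concatenate((stride_edges, [knots[-1]]))
    x = _interp_extrap(t_mark, x_knots, cum_knots)
    y = _Y_SWAY * np.sin(2.0 * np.pi * phase_mark)
    if config.marker_noise_sd > 0:
        x = x + rng.normal(0.0, config.marker_noise_sd, len(t_mark))
        y = y + rng.normal(0.0, config.marker_noise_sd, len(t_mark))
        z = z + rng.normal(0.0, config.marker_noise_sd, len(t_mark))
    markers = pd.DataFrame({"time": t_mark, "x": x, "y": y, "z": z})

    truth = SessionTruth(
        impact_times=knots,
        impact_limbs=impact_limbs,
        stride_durations=durations,
        stride_velocities=velocities,
        amp_factors=amp_eff,
        timing_shifts=timing_shifts,
        outlier_flags=outlier_flags,
        templates=dict(horse_templates),
        session_scale=session_scale,
        session_shift=session_shift,
    )
    return RecordingSession(
        horse_id=horse_id,
        session_id=session_id,
        emg=emg,
        markers=markers,
        channel_map=dict(channel_map),
        first_limb=config.first_limb,
        truth=truth,
    )


def generate_population(
    config: PopulationConfig,
    archetypes: dict[str, MuscleArchetype] | None = None,
    sides: tuple[str, ...] = ("left", "right"),
) -> list[RecordingSession]:
    """Generate ``n_horses × n_sessions`` recordings with retained truth.

    One channel is created per (archetype, side); the channel map records
    the muscle/side of each.  Deterministic: the same config (including its
    seed) always yields bit-identical recordings.
    """
    archetypes = archetypes if archetypes is not None else default_archetypes()
    channel_map = {f"{m}_{s}": (m, s) for m in archetypes for s in sides}
    rng = np.random.default_rng(config.seed)
    sessions: list[RecordingSession] = []
    for h in range(config.n_horses):
        horse_id = f"horse{h + 1:02d}"
        horse_templates = {
            ch: _perturb_archetype(archetypes[m], rng, config.inter_horse_sd)
            for ch, (m, _s) in channel_map.items()
        }
        for s in range(config.n_sessions):
            sessions.append(
                _generate_session(
                    horse_id, f"session{s + 1}", config, horse_templates, channel_map, rng
                )
            )
    return sessions
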