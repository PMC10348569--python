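# Methods

## Scope and data model

The package analyses cyclic muscle-activation waveforms at trot. A
*recording* is one horse/session: multi-channel raw sEMG at 2000 Hz plus
the 3D trajectory of a mid-pelvis (tubera-sacrale) marker at 200 Hz,
sharing a time origin. The analysis produces, per muscle and side, stride
matrices (included strides × 101 time-normalized, RVC-normalized envelope
samples), ensemble profiles (per-point mean ± SD), and reliability
statistics at three scopes: intra-session (strides of one horse/session),
inter-subject (strides pooled across horses within a session), and
between-session (one horse's strides pooled across sessions).

## Signal conditioning

Stages run in fixed order: mean subtraction; high-pass Butterworth, 4th
order, 40 Hz; full-wave rectification; low-pass Butterworth, 4th order,
25 Hz. Both filters are applied forward and backward (`scipy.signal.filtfilt`
with reflective padding of the default length, well above 3× the design
order), so the chain is zero-phase: burst timing is preserved relative to
gait events, at the cost that the effective magnitude response is the
single-pass response squared — gain 0.5 rather than 1/√2 at the design
cutoff. "4th order" names the designed prototype, as in gait-lab
convention. Two deliberate choices are worth flagging:

* **Negative envelope excursions are retained.** The final low-pass can
  undershoot slightly around sharp bursts; clipping would bias ensemble
  means, and downstream peak/ensemble arithmetic is indifferent. The
  processing log records this.
* **The hardware front end is not modelled.** Amplifier gain and the
  20–450 Hz analog band-pass are upstream of this package; the synthetic
  generator emulates their *output*.

## Gait events, strides, velocity

Hindlimb impacts are local maxima of the marker's vertical coordinate —
at trot the pelvis bounces twice per stride, maxima alternating between
hindlimbs. Peaks must be ≥ 0.25 s apart (below half a 0.75 s stride, so
both per-stride maxima survive) with prominence above 25% of the signal's
interquartile range; each peak time is refined to sub-sample precision by
a parabola through its three samples. Attributing the *first* maximum to a
limb cannot be done from this marker alone; the alternation is anchored by
metadata, ground truth, or an explicit flag.

Side-specific strides run between consecutive *contralateral* hindlimb
impacts (half-open `[start, end)` intervals, which tile the event span).
Stride velocity is the mean Euclidean speed of the horizontal marker
coordinates, low-pass filtered at 6 Hz (standard kinematic smoothing;
configurable) and differentiated by central differences.

## Stride QC, normalization, time grid

Per session and side, in order:

1. **Outlier screen**: per-stride envelope peaks outside Tukey fences
   (Q1 − 1.5·IQR, Q3 + 1.5·IQR) are excluded. The fence rule is a
   transparent stand-in for peak-outlier screening; `k` is configurable,
   and with fewer than four strides nothing is flagged. By default a
   stride flagged for any muscle of a side is dropped for all muscles of
   that side (one stride count per side); per-muscle exclusion is an
   option.
2. **RVC**: the reference peak is the maximum envelope amplitude over the
   surviving strides of that muscle and session. Dividing by it puts every
   stride nominally in [0, 1] with the defining sample exactly 1.
3. **Velocity-based reduction**: the ten strides closest to the session
   mean velocity are kept. The mean is computed once over all surviving
   strides, not recomputed after removals; ties break toward the earlier
   stride. Because this step follows normalization, the RVC-defining
   stride can itself be dropped, in which case the *selected* rows peak
   slightly below 1 — the QC report records the pre-reduction peak (always
   exactly 1).
4. **Time normalization**: each stride segment is linearly interpolated
   onto 0, 1, …, 100% of the stride (101 points). Linear interpolation of
   a ~1500-sample segment reproduces band-limited envelopes to ≪ 0.1%;
   the 101-point grid slightly attenuates peaks that fall between grid
   points (< 0.3% in practice).

Between-session matrices concatenate rows normalized by their own
session's RVC — deliberately, since a session's reference is all a
longitudinal protocol has at acquisition time.

## Reliability statistics

For a stride matrix with per-point sample SD σᵢ (n − 1 denominator
throughout) and ensemble mean X̄ᵢ:

    CV = sqrt((1/101) Σ σᵢ²) / ((1/101) Σ X̄ᵢ)

The SD is computed on row-shifted values (subtracting the first stride),
which is algebraically identical, better conditioned, and returns an exact
0 for identical strides. CV is scale-invariant but not shift-invariant:
added baseline activity lowers it, so muscles with quiescent baselines
read out higher CVs at equal absolute variability — a property the test
suite asserts rather than hides.

The between-session CMC is computed on the D = 2 session ensemble-mean
curves (T = 101), not on stride-level data:

    CMC = sqrt(1 − [Σ_d Σ_t (Y_dt − Ȳ_t)² / (T(D−1))] / [Σ_d Σ_t (Y_dt − Ȳ)² / (DT−1)])

When the radicand is negative (between-session variance exceeding total
variance, e.g. near-anti-phase or near-flat curves) the result is flagged
undefined rather than clipped to 0 or made complex; summaries exclude and
count these cases. Band edges go to the lower band: > 0.90 excellent,
> 0.75 good, ≥ 0.50 moderate, else below moderate. Summary tables report
mean ± sample SD across horses per muscle/side.

## The synthetic-population generator

No public corpus of synchronized equine sEMG + motion-capture trot
recordings exists, so the generator emulates the study design the analysis
assumes, with every latent variable retained as ground truth:

* **Archetypes.** Two default activation shapes on the circular 0–100%
  stride axis: `mono_burst` (one Gaussian burst wrapping the stride
  boundary — late swing into stance — over a 0.05 baseline) and
  `multi_burst` (two bursts over a 0.30 tonic baseline). These are
  qualitative reconstructions of triceps/hamstring-like vs
  longissimus-like patterns; no numeric burst timings are published to
  calibrate against, which is why they are configurable inputs rather
  than fixed truths.
* **Hierarchy of variability.** Per horse, archetype parameters are
  perturbed (centres jittered, widths/amplitudes/baseline log-normally
  scaled) with SD `inter_horse_sd` = 0.15; per session, an amplitude scale
  and a burst-timing shift with SD `session_effect_sd` = 0.08 emulate
  sensor re-application; per stride, amplitude and timing jitter with SD
  `intra_horse_sd` = 0.08. One unit of a "relative" SD moves burst centres
  by 10% stride. Outlier strides (probability 0.03) have amplitude
  inflated 3.5× — an amplitude-only model chosen because the downstream
  screen operates on peaks.
* **Gait.** Stride durations ~ N(0.75, 0.03) s and velocities
  ~ N(3.09, 0.29) m/s, the values reported for in-hand trot in the study
  population this emulates. Each trial holds 15 full strides plus a
  trailing half stride, so both hindlimbs register 16 impacts and each
  side yields 15 strides — enough to survive outlier screening and still
  feed the ten-stride reduction.
* **Waveform synthesis.** Raw sEMG = envelope × carrier + noise-floor
  noise + constant DC offset. The carrier is a constant-amplitude cosine
  whose instantaneous frequency wanders smoothly within ~125–325 Hz
  (inside the 20–450 Hz hardware band): rectifying it and low-passing at
  25 Hz returns the envelope times 2/π with < 3% ripple, making the
  conditioning chain verifiable against the stored template. A plain
  band-limited Gaussian carrier was rejected for this role because its
  rectified envelope keeps ~40% ripple after a 25 Hz low-pass, which
  would make template-recovery tests meaningless; Gaussian 20–450 Hz
  noise still enters through the additive `noise_floor` term (default
  0.03 of template scale).
* **Markers.** The vertical coordinate is a cosine in stride phase with
  two maxima per stride, exactly at the truth impact times; the forward
  coordinate integrates the per-stride velocities; lateral sway is a
  1-cycle/stride sinusoid; all coordinates carry N(0, 0.1 mm) optical
  noise.

Determinism: all randomness flows from one `numpy` generator seeded by the
config; identical config ⇒ bit-identical recordings, and the pipeline
itself is deterministic, so full reports reproduce exactly.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: electrode-skin impedance drift, crosstalk
between muscles, motion artifact correlated with hoof impacts, gait
asymmetry or lameness, surface and handler effects, non-stationary fatigue
trends, and marker occlusion/gaps. Results on synthetic data validate the
*computational* chain, not the biological claims.

## Problem sizes used in checks

The default population (8 horses × 2 sessions × 4 channels, 15+½ strides
per trial) drives the end-to-end contract checks and the acceptance
script. Stochastic ordering checks (intra vs inter CV, within- vs
between-session CV, CMC vs session effect) use 20 replicates of a
4-horse × 2-session, 12-strides-per-trial population — large enough that
the orderings are stable in the median, small enough to keep the suite
fast. Noise-recovery checks use 200 strides per matrix.

## Known limitations

* Limb attribution of the first impact requires external anchoring; a
  wrong anchor swaps left/right stride sets (waveforms and statistics are
  computed per channel regardless, but side labels would be exchanged).
* The Tukey-fence outlier screen and the 6 Hz velocity smoothing are
  reasoned defaults, not published constants; both are configurable.
* An inflated burst's envelope tail can bleed past a stride boundary
  after 25 Hz smoothing, so a neighbouring stride's measured peak is
  mildly contaminated; with the 3.5× inflation model this does not move
  fences enough to matter.
* CMC on two near-flat or strongly shifted curves is frequently
  undefined; this is a property of the statistic (documented in the gait
  literature), not of the implementation. Counts of undefined cases are
  reported alongside summaries.
* C3D ingestion is not implemented; recordings enter as delimited files.
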