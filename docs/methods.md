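# Methods

## Signal model and pipeline

A record is four simultaneously sampled PPG channels `S_i[n]` (i = 1..4) at
`fs` = 200 Hz. Each channel sees the same cardiac pulse train through
different palm vasculature, so channels share beat times but differ in
amplitude, noise and artifact load. The pipeline is: per-channel low-pass
FIR filtering → channel fusion (average or quality-weighted average) → slope
based peak detection with PPI gating on the fused waveform → pulse rate
`PR = 60·fs/PPI`.

## Preprocessing

`design_lowpass_fir(order, cutoff_hz, fs)` builds a type-I (even-order,
symmetric) windowed-sinc FIR with a Hamming window, renormalized to exact
unit DC gain. Defaults: order 40, cutoff 5 Hz at 200 Hz. The method
description fixes order and cutoff but not the design procedure or DC gain;
windowed-sinc/Hamming is the standard closed-form reproducible choice.
Symmetry makes the phase exactly linear, so every in-band feature is delayed
by exactly `order/2 = 20` samples; scoring shifts detections back by this
group delay rather than compensating inside the filter. Filtering is causal
(`scipy.signal.lfilter`) with a zero initial state; the first `order`
output samples are transient, which is harmless because the scoring window
discards the first 5 s (1000 samples ≫ 40).

## Peak detection

The slope is the first backward difference `slope[n] = S[n] − S[n−1]`
(`slope[0] = 0`) — the simplest causal estimator consistent with a
sample-by-sample MCU loop. The state machine:

* **Arm:** `slope > Th` (strict) sets the flag and starts buffering slopes.
* **Fire:** while armed, the first `slope ≤ 0` records a peak candidate at
  the previous sample (the local maximum), updates
  `Th ← threshold_fraction × max(buffer)`, clears the buffer and disarms.
* **Gate:** the candidate's interval to the previous candidate must lie
  strictly inside `(ppi_low_factor, ppi_high_factor) × last accepted PPI`
  (defaults 0.7 / 1.3). The first two candidates are accepted
  unconditionally to seed the gate. A rejected candidate updates `Th` but
  never the accepted PPI.

Choices taken where the scheme is underdetermined:

* **Threshold update fraction** `threshold_fraction = 0.6`: refreshing Th to
  the full buffer maximum would ratchet upward and miss smaller beats; a
  fraction of the latest upstroke's maximum slope is the conventional
  adaptive scheme. Exposed in `RunConfig`.
* **Initialization:** `Th₀ = threshold_fraction × max slope` over the first
  `threshold_init_s = 2` s (calibration window; no peaks emitted inside it).
  A flat calibration window floors Th at 1e-12 so Th stays positive without
  ever arming on a truly constant signal.
* **Threshold decay:** Th refreshes only at candidates, so one steep
  artifact could park it above every subsequent pulse slope and silence the
  detector permanently. After `th_decay_grace_s = 2` s without a candidate,
  Th decays exponentially with half-life `th_halflife_s = 1` s until the
  signal arms it again. The grace period is longer than any plausible
  resting PPI, so the decay never engages on clean signals.
* **Gate cold restart:** a rejected candidate never updates the accepted
  PPI, so a gate seeded on an artifact burst (or stranded by a posture
  change) would otherwise reject every true beat forever. After
  `gate_reset_after = 3` consecutive rejections the gate discards its
  expected interval and re-seeds from the next two candidates.
* **Ties:** slope exactly equal to Th does not arm (strict `>`); slope
  exactly 0 while armed fires (`≤ 0`).
* **No extra refractory period:** after a candidate the detector must simply
  re-arm.

The detector is deterministic: identical input and config give an identical
peak train bit for bit.

## Fusion and weight dynamics

`mix_average` is the per-sample mean. For the weighted method an
independent detector state machine runs on every *filtered* channel (the
pipeline order is: filter → per-channel detection for weights → mix → final
detection on the mix; per-channel detections are not part of the output).
At each sample a channel experiences one event:

| event | condition | update |
|---|---|---|
| `valid_peak` | candidate accepted by the channel's PPI gate | `W += α` |
| `invalid_peak` | candidate rejected by the gate | `W −= α` |
| `missed_window` | > `ppi_high_factor ×` last accepted PPI elapsed since the channel's last accepted peak with no candidate | `W −= α`, clock resets |
| `none` | otherwise | unchanged |

with `α = 2` and clamping to `[weight_min, weight_max] = [2, 20]`. Weights
start at `weight_min` (the cold-start mix is then exactly the plain
average), change only at event samples and are piecewise constant between
them. With an integer start and integer α they stay integral. The
`missed_window` cadence (one decrement per elapsed window, clock anchored at
the last accepted peak or last expiry) cannot fire before the channel's gate
has been seeded — there is no expected interval to miss yet.

**Mixing ramp.** The event-driven weight schedule is a step function, and
each step puts a discontinuity into the weighted mix whose one-sample slope
can dwarf a pulse upstroke, derailing the downstream slope detector. Before
mixing, `detect_on_mixed` therefore passes the schedule through a causal
moving average of `weight_ramp_s = 0.3` s (`smooth_trace`). Smoothed values
are convex combinations of in-bound values, so the weight bounds and the
convexity of the mix are preserved, and a constant schedule is unchanged.
The piecewise-constant schedule remains the quantity of record
(`MixedSignal.trace`); only the mix consumes the smoothed copy.

`method="channel:k"` bypasses mixing and detects on filtered channel k — the
single-sensor comparison baseline.

## Evaluation

Both trains are restricted to the trimmed window `[trim_s·fs,
n_samples − trim_s·fs)` (default 5 s each end — device warm-up discard),
detections are shifted back by the filter group delay, and matched
one-to-one within `match_tolerance_s = 0.15` s (30 samples at 200 Hz —
half of the shortest plausible PPI at ordinary heart rates; the source
description names no tolerance). The matcher is an in-order sweep over the
two sorted trains; for point trains with a common tolerance this attains the
maximum possible number of pairs, verified against an exhaustive optimal
assignment (`scipy.optimize.linear_sum_assignment`) in the tests. Undefined
ratios (e.g. FDR with zero TP) are reported as NaN, never as 0.

The reference annotations produced by the simulator mark the PPG pulse peak
itself, so no pulse-transit-time offset is needed; `evaluate_detection`
exposes a constant `reference_offset` for scoring against ECG-style
references.

## Synthetic data

Each channel is `amp_i · pulse(beats) · dropout_mask + wander + artifacts +
white noise`:

* **Beat times:** inter-beat intervals are `60/hr_bpm` s plus zero-mean
  Gaussian jitter of sd `60·hr_sd_bpm/hr_bpm²` s (first-order propagation of
  a rate sd into an interval sd), floored at 0.3 s; the first beat falls
  half an interval into the record. Annotations mark the template maximum.
* **Pulse template:** difference of two exponentials (rise constant
  width/12, decay width/5, width 0.6 s), peak-normalized — a fast upstroke
  and slow decay so the slope criterion is exercised. It is deliberately
  schematic: no dicrotic notch, no respiratory amplitude modulation.
* **Baseline wander:** one sinusoid (default 0.15 units at 0.25 Hz, random
  phase per channel).
* **Artifacts:** Poisson-arriving bursts of 0.5–8 Hz band-limited noise,
  Hann-windowed, with per-condition rate/amplitude/duration.
* **Dropouts:** Poisson-arriving intervals where the pulsatile component
  collapses to baseline (contact loss during clicks), with a 50 ms taper.
* **Seeding:** the record is a pure function of its `ScenarioConfig`;
  channel i uses sub-seed `seed XOR i`.

Default channel amplitudes (1.0, 0.8, 1.2, 0.6) encode that palm vasculature
favors some sensor positions. The resting heart-rate default of 89 bpm
matches a typical young-adult seated resting rate. The six condition
presets order artifact severity rest < slow < rapid and add dropouts for
browsing (about one click per 10 s page flip); the severities are this
simulator's own calibration, chosen to exercise the algorithm — no
quantitative artifact statistics exist for the original conditions.
Consequently, passing tests demonstrate correct mechanics and the
*qualitative* structure (severity ordering; the weighted mix outperforming
the plain average when channel quality is heterogeneous), not numeric
agreement with any human cohort.

## Problem sizes and numerical choices

Cohort-level checks use 60 s records: 50 seeds for the fusion-contrast
cohort and 20 seeds per condition for severity ordering; the weight-dynamics
invariants run over 200 randomized 10 s records. These sizes give stable
pooled metrics for the qualitative comparisons involved. Cohort metrics are
pooled (counts summed before forming percentages) so that records with zero
true positives cannot inject undefined per-record ratios into an average.
Equality of the equal-weight weighted mix with the plain average holds to
1e-12 (floating-point summation order differs); convexity bounds are
asserted with 1e-9 slack after filtering.

## Known limitations

* The simulator's morphology, artifact and dropout processes are inventions;
  absolute Se/+P/FDR values depend strongly on the chosen severities and do
  not transfer to real palms.
* The gate cold restart and threshold decay are recovery mechanisms this
  implementation adds to make the published scheme robust to sustained
  artifacts; their parameters (3 rejections, 2 s grace, 1 s half-life) are
  pragmatic defaults, all exposed in `RunConfig`.
* All-channel degradation (the movement presets) gives the weighted method
  little room to improve on the average — its advantage appears when channel
  quality is heterogeneous, as in the contrast cohort.
* Weights are updated from detections on filtered channels; updating from
  raw channels is untested.
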