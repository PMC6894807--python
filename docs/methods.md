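# Methods

## Signal model and preprocessing

All analysis runs on a common 20 Hz timebase; native channels (nasal
pressure 200 Hz, RIP bands and RIP flow 25 Hz, audio 100 Hz, accelerometer
20 Hz, SpO2 3 Hz) are decimated with a zero-phase polyphase FIR so breath
onsets are not phase-shifted, then smoothed with a Savitzky–Golay filter
(1 s window forced odd — 21 samples — polynomial order 3). SpO2 and any
channel below 20 Hz are carried as metadata only; no processing step
consumes them. Nasal airflow is estimated as the *signed* square root of
nasal pressure, `sign(p)·sqrt(|p|)`: the square-root linearization of a
cannula pressure signal is standard, and the sign convention preserves
inspiratory/expiratory polarity on a bipolar signal. Under this transform a
90% pressure reduction (the AASM apnea criterion) becomes a
`1 − sqrt(0.1) = 68.4%` airflow reduction; the scoring literature quotes the
bound as 66.7%, and the pipeline honors the bound as quoted while the exact
value used internally is `sqrt(0.10) ≈ 31.6%` residual excursion.

## Stable-period segmentation

Accelerometer-norm energy is computed in 5 s frames (100 samples) with 50%
overlap. The movement/rest threshold is adaptive: energies are sorted,
resampled to exactly 1080 points (nearest-rank selection; recordings shorter
than ~1.5 h are linearly interpolated up so the machinery is unchanged), a
least-squares slope is taken on every 6 consecutive points with hop 3 (359
slopes), and the scan for the change point starts at slope index 90 —
i.e. 25% of the array, encoding the assumption that at least a quarter of
the recording is at rest. The first slope exceeding 5.8× the running mean of
all previous slopes marks the transition; the threshold is the median of
that window's six energies. The ratio 5.8 is an empirical constant and is
exposed in the config, not re-derived. The procedure is scale-equivariant
and order-invariant by construction. Stable frames merge into intervals;
movement gaps shorter than 2 minutes are absorbed (and flagged) to keep the
respiratory signals contiguous. Each stable period is analyzed
independently so no baseline ever straddles a movement gap.

## Breath detection

Inspiratory peaks and expiratory valleys come from AMPD applied in 3-minute
windows hopping by 90 s (a window holds roughly 45–72 cycles at
physiological rates). The implementation is the deterministic variant of the
local-maxima-scalogram method: each window is linearly detrended (the
scalogram construction assumes it), the scale with the most local maxima
fixes the row band, and peaks are samples maximal at every scale up to it.
Two departures from the textbook form, both forced by observed failure
modes: (i) the window is padded antisymmetrically (point reflection) by one
scale depth — without padding any extremum within λ samples of a window edge
is structurally undetectable, and *even* (mirror) padding reflects an edge
peak onto itself, defeating the strict comparison; (ii) the scale range is
capped at 12.5 s of samples, since breathing periods beyond that carry no
information and the cap keeps the per-window cost linear. Duplicate extrema
from overlapping windows are suppressed within 0.25 s. Strict peak/valley
alternation is then enforced by *inserting* the missing opposite extremum
(the most extreme sample between two same-type neighbours) rather than
deleting a detection — deleting was observed to discard the first recovery
breath after an apnea whenever its valley was missed.

A rescue pass scans gaps longer than 1.5× the recent median cycle time for
zero-crossing oscillations exceeding 20% of the recent mean amplitude and
inserts them as peak/valley pairs; both thresholds exist in the method
description without published values, so they are config parameters with
these defaults.

Envelopes are PCHIP interpolants through peaks and valleys
(constant-extrapolated at edges); excursion is their difference clipped at
zero. Highly reduced excursion segments — ≤ 35% of the rolling 2-minute
pre-event baseline for more than 4 s — switch onset detection from the
airflow (last negative-to-positive crossing between a valley and the next
peak, maximum-slope fallback) to the valleys of the reference RIP band (the
band with the larger segment excursion relative to its own 2-minute
baseline; ties go to the thorax). The excursion baseline is causal and
freezes while inside a candidate segment, so a long event cannot erode its
own reference. Onsets closer than 1 s are treated as duplicates of one
breath and the later one is dropped.

## Event scoring

Apneas: residual excursion ≤ 31.6% of the 2-minute baseline, duration
10–180 s. The 10 s floor is the AASM 2012 minimum (the 4 s constant above
belongs to the *segmentation* rule, not to scoring); the 180 s cap guards
against sensor displacement and mouth breathing. A candidate is confirmed
only if a secondary flow channel (naso-buccal thermistance when present,
else RIP flow) drops by more than 20% against its 1-minute pre+post
baselines. Classification counts breathing attempts — RIP peaks inside the
event — as significant when the RIP excursion at the peak reaches 10% of the
1-minute pre+post excursion baseline; one significant attempt makes the
event obstructive (mixed events are labelled obstructive, per-attempt flags
are kept), none makes it central.

Hypopneas: excursion reduction ≥ 30% but above the apnea level, same
duration bounds, confirmed by a ≥ 10% secondary-channel drop; intervals
overlapping an apnea are not candidates. An event is obstructive if any of
its cycles shows snoring (inspiratory audio power > 2× expiratory — the
factor is unpublished and configurable), thoracoabdominal paradox (the
thorax peak is closer in time to the abdomen valley than to the abdomen
peak), or inspiratory flow limitation; otherwise central.

The flow-limitation detector is a 7-14-14-1 network (scikit-learn
MLPClassifier, logistic activations, training seed 42) over seven limb-shape
features with local definitions: peak count; peak amplitude normalized by
the 2-minute baseline; scooping index = 1 − mean(middle 50%)/peak;
kurtosis and skewness of the flow-versus-time curve; deviation index = RMS
residual from the least-squares half-sine, normalized by the peak;
flattening index = fraction of the limb within 15% of the peak. The network
trains on a synthetic corpus of rounded versus plateau-clipped inspirations
generated through the *same* path the pipeline applies to real limbs
(square to pressure, add sensor noise, smooth, square-root back, cut at zero
crossings) — training on idealized limbs was observed to misclassify real
rounded limbs, whose moments are shifted by that shaping. The normalized
amplitude feature is drawn independently of class in the corpus so that
"small" does not leak "flow-limited"; a hypopnea's rounded limbs are small
too.

## Command synthesis

V̇cc copies the recorded airflow for normal and central cycles. Obstructive
cycles are reconstructed as one full sine over the cycle with amplitude half
the event's pre-event baseline excursion. The sinusoidal form follows the
bench-command convention for obstructed cycles; using equal inspiratory and
expiratory phases (rather than the asymmetric Ti/Ttot ≈ 0.4 of the natural
template) makes the cycle volume-balanced by construction and the
attenuation inversion exact per phase. Cycle timing comes from the cycle
boundaries themselves, which are airflow-derived for obstructive hypopneas
and RIP-derived for obstructive apneas. Cycles overlap an event when at
least half the cycle lies inside it; a cycle straddling the event end keeps
its normal label and is replayed as recorded.

Each cycle's inspired and expired volumes are then equilibrated (the bench
piston must return to its start each cycle): the lesser-volume phase is
scaled by a single factor, which leaves extremum positions unchanged;
single-phase (apneic) cycles pass through. ΔP_mus applies the lung equation
with the trapezoidal running integral of V̇cc, reset to zero at every cycle
trigger so integration drift cannot accumulate over a night. Units are L/s,
L, cmH2O; the published compliance (80 mL/cmH2O) is converted at the
boundary; R = 7.25 cmH2O/(L/s); R·C = 0.58 s.

The Starling chamber pressure is read off a calibration measured on the
virtual bench exactly as one would calibrate hardware: sweep the chamber
pressure over a grid, drive the model with reference sinusoids at several
amplitudes, record the output/input amplitude ratio separately for
inspiration and expiration, and keep the monotone admissible-peak-flow
tables. The inverse maps a target/V̇cc amplitude ratio to the chamber
pressure; the zero-flow plateau collapses onto the largest swept pressure so
a full-occlusion command saturates the lagging regulator quickly. Ratios
above 1 clamp to fully open with a warning. Normal and central cycles
command the chamber minimum ("tube fully open").

## Virtual bench

The lung solver inverts the command generator's discretization exactly: the
implicit trapezoidal (Crank–Nicolson) step on `R·V̇ + V/C = −ΔP_mus`, with
per-cycle volume resets, is the algebraic inverse of the trapezoidal
integral used in ΔP_mus — the round trip is exact to round-off, and the
scheme is A-stable at 20 Hz for the 0.58 s time constant. The Starling
surrogate is a memoryless waterfall: flow is unrestricted while the chamber
is vented; above that, instantaneous flow is clipped at
`max(0, (P_us − P_ch)/R_us)` with P_us = 4 cmH2O (the minimal APAP delivery
pressure) and R_us = 4 cmH2O/(L/s) by default. The chamber-pressure command
steps at each cycle trigger (the TTL analogue) and passes through a
first-order regulator (τ = 0.3 s by default; the true regulator dynamics are
uncharacterized, so τ is configurable). The physical tube's prompt-collapse
flow artifact can be emulated as a spike proportional to the commanded
pressure step (off by default). The surrogate is memoryless beyond the
regulator lag; tube hysteresis is not modelled.

## Evaluation

Cycles of the two traces pair greedily by nearest onset within 1.5 s (the
pairing rule is unpublished; this is the package's choice). Relative
amplitude normalizes each cycle by the *median* amplitude of its own trace's
cycles in the preceding 2 minutes: the median keeps the baseline anchored to
unobstructed breathing when the window contains an apnea, and the per-trace
normalization deliberately makes a uniform bench gain invisible — the
statistic measures per-breath fidelity, not absolute calibration. Reported
per quantity: mean, SD, 2.5/50/97.5 percentiles, the same after trimming to
the central 95%, regression slope/intercept, and Bland–Altman limits
(mean ± 1.96 SD). Morphology is the per-pair Pearson r on waveforms
resampled to the shorter cycle, requiring ≥ 40 samples (2 s), reported
separately for obstructed and unobstructed cycles. Apneas match at ≥ 50%
overlap of the shorter event; sensitivity, PPV, onset-difference mean/SD and
duration agreement follow. No specificity is computed (normal breathing
dominates the night, making it uninformative), and hypopnea-level
sensitivity is out of scope. Amplitude/Ttot and morphology statistics cover
the non-apneic matched cycles; apneas are compared at the event level. The
bench trace is re-analyzed flow-only — a pneumotachograph has no effort
bands — so its apnea candidates are scored without the confirmation channel,
as they must be on physical hardware.

## Synthetic nights

The generator emulates what the pipeline consumes: a half-sine inspiration
(Ti/Ttot = 0.4) with an exponential-decay expiration scaled to zero cycle
volume, Ttot jitter N(4.0, 0.3) s, log-normal amplitude jitter (σ = 10%)
around a 0.5 L/s inspiratory peak; nasal pressure is the signed square of
the flow plus sensor noise; RIP bands follow the cycle volume (anti-phase
abdomen during scripted paradox, attempts retained at 80% during obstructive
apneas and suppressed to 5% during central ones); RIP flow drops 50/90/25/30%
during OA/CA/OH/CH; audio gains inspiratory bursts during scripted snoring;
the accelerometer has a unit-gravity noise floor with high-energy bursts
during scripted movement. Obstructive hypopnea inspirations are
plateau-clipped at 70% to exercise the flow-limitation detector. Events
snap to cycle boundaries and are recorded in the ground truth with their
realized extents. Channels are written at native rates to standard 16-bit
EDF by the package's own writer (the environment provides EDF reading via
mne but no writing).

What the generator does not emulate — cardiogenic oscillations, sighs,
REM-specific patterns, sensor drift, real upper-airway flow shapes — bounds
what passing tests show: they demonstrate the pipeline's rules are
implemented correctly and the closed loop is faithful under controlled
conditions, not clinical scoring performance.

The standard study night used by the test suite is 7680 s (2 h 08) with 12
events of each of the four kinds at 150 s spacing (≈ 22.5 events/h, a
moderate-to-severe profile), hypopnea depth 0.5, apnea residual 5%, and two
20 s movement bursts. Problem sizes throughout (a 2-hour night, 41-point
calibration grids, a 1200-limb training corpus) were chosen as the smallest
that exercise every rule with comfortable statistical margins.

## Numerical choices and degenerate inputs

* Sub-20 Hz channels upsample by sample-and-hold, logged (the resampling
  step is otherwise strictly a downsampler).
* Series shorter than the smoothing window return unchanged with a warning;
  accelerometer series shorter than one frame yield an empty energy track.
* A flat excursion track (fewer than two peaks or valleys) is an unusable
  segment and raises; segments shorter than 60 s are skipped.
* If no slope qualifies in the threshold scan the whole night is treated as
  stable, with a warning.
* Tie-breaks: first qualifying slope window; thorax over abdomen; the later
  of two duplicate onsets is dropped.
* Volume equilibration tolerance is 1e-6 L; the lung round trip is exact by
  construction, so the 2% tolerance on it is pure slack.
* All randomness flows from explicit seeds (generator scenario seed, network
  training seed); outputs are byte-identical across runs.

## Known limitations

* The obstructed-cycle Pearson r is moderate (≈ 0.6 on synthetic nights):
  once the tube clips, the bench waveform is a truncated sine whatever the
  recorded shape. Only amplitude, not morphology, is controllable under
  occlusion — a physical-bench limitation the surrogate shares.
* The first cycle of each obstructive event leaks flow while the regulator
  charges (τ = 0.3 s), mirroring the transition artifact of the physical
  tube; event-level detection is unaffected but the first-cycle amplitude
  bias is visible in the SD.
* Two future simulation modes for flow-limited cycles outside events
  (obstruct them / replay them open) exist as a config hook
  (`ifl_simulation_mode`) only; the default mode is implemented.
* The closed loop is exposed through a constant-pressure controller stub;
  no APAP algorithm is implemented or evaluated.
* SpO2 is carried but unused; desaturation-linked hypopnea criteria, RERA
  and arousal scoring are out of scope.
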