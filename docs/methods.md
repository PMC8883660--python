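# Methods

This note documents the models, defaults and design choices behind
`adspipe`, and what its synthetic benchmarks do and do not establish about
real recordings.

## Ground-truth spike-train generation

All analysis stages consume spike times only, so the generator is a
renewal / doubly-stochastic point-process model rather than a biophysical
simulation — the minimal model sufficient to exercise the pipeline.

**ISI families.** `gamma` draws interspike intervals as
`refractory_floor + Gamma(κ, θ)` with θ chosen so the mean ISI is exactly
1/rate; κ > 1 is more regular than Poisson, κ < 1 burstier, and `poisson`
pins κ = 1. `bursty_doubly_stochastic` simulates a symmetric two-state
telegraph rate (dwell times exponential with the switching rate, default
0.5 /s) alternating between a high intra-burst rate and a low quiescent
rate, with the refractory floor enforced by greedy pruning. The slow
(sub-1 Hz) cyclic bursting that closed-loop stimulation induces is emulated
by this switching; no measured value constrains the switching rate, so it
is an exposed parameter rather than a calibrated one.

**Refractory floor: 1 ms.** The floor models the absolute refractory
period of a cortical neuron, which is about 1 ms. It is deliberately *not*
set equal to the detector's 2 ms peak-lifetime/dead-time window: "at most
one spike per 2 ms" is a property of the detection stage, which keeps its
own 2 ms dead time. The distinction matters quantitatively — at a 50
spikes/s intra-burst rate, a 2 ms ground-truth floor regularises ISIs
enough to pull LvR down to ~1.22, below the Bursty band the generator must
be able to reach, whereas a 1 ms floor leaves the bursty family at
LvR ≈ 1.46 and the Poisson family at ≈ 1.07.

**Band calibration shapes.** Gamma shapes κ = 4, 1 and 0.5 place mean LvR
(R = 5 ms) inside the Regular, Random and Bursty bands respectively
(`BAND_SHAPES`). The choice follows from Lv = 3/(2κ + 1) for a gamma
renewal process: κ = 0.5 targets the Bursty centre 1.5; shapes much below
0.5 (e.g. 0.35 → Lv ≈ 1.76) land *above* the band once the refractoriness
correction inflates them and are therefore not usable as a Bursty
calibration point.

**Phase modulation.** Per-phase rate multipliers emulate the lesion and
stimulation effects (premotor RFA up, somatosensory S1 down after the
lesion; both up after stimulation): within a phase, spikes are thinned with
probability m (m ≤ 1) or superposed with extra homogeneous Poisson spikes
at rate (m − 1)·base (m > 1), so the expected phase rate is m·base. The
refractory floor is re-imposed after superposition, so the ISI family is
preserved only approximately under modulation. Default multipliers are the
ratios of reported per-phase group medians to baseline, and default
baseline rates the group/region baseline medians (RFA 1.54, S1 4.49
spikes/s for the control arm; 0.96 and 0.54 for the stimulated arm), with
per-unit rates log-normally dispersed (log-SD 0.5) around them.

**Rendering.** Each spike adds a stereotyped biphasic template
(negative-first, ~0.25 ms lobe width so its energy lies in the 300–3000 Hz
band) at the nearest sample, on top of zero-mean Gaussian white noise.
Sub-sample jitter, 1/f and line noise, electrode drift and amplitude
adaptation during bursts are not modelled; consequences: detection and
sorting scores on this benchmark are upper bounds relative to real data,
where drift and correlated noise degrade both. Rendering is exactly
additive over units, which the tests exploit.

## Closed-loop (ADS) simulation

The gating rule is stimulus-anchored: a trigger emits a pulse unless it
falls within the blanking period (default 28 ms) after the previously
*emitted* stimulus. This matches a blanking window that follows each
stimulus and caps the rate at 1/0.028 ≈ 35.7 Hz; trigger-anchored blanking
would not. Triggers are taken at spike-time resolution — the detected
train of the chosen trigger channel stands in for the hardware's voltage
threshold, whose numeric value was an experimenter's judgement call and is
therefore an explicit parameter here. Pulse shape (charge-balanced
biphasic, cathodal-leading, 200 µs per phase) is metadata only. Evoked
responses are modelled per pulse and target unit as a Bernoulli event
(default p = 0.3) at a truncated-normal latency (5 ± 2 ms); the study
premise is that pulses evoke activity, but per-pulse response statistics
were not measured, so these are generator choices. At 0 µA (the control
condition) the effect stage is an exact identity.

## Filtering

4th-order elliptic bandpass, 300–3000 Hz. Ripple and attenuation are not
dictated by anything upstream; defaults are 0.1 dB passband ripple and
40 dB stopband attenuation, both exposed. Offline analysis uses zero-phase
(forward–backward) application so spike peak times are unshifted; this
doubles the effective order, which is documented rather than compensated.
Edge transients are handled by scipy's odd-reflection padding.

## Spike detection (PTSD)

Consecutive local extrema of a band-limited trace alternate in sign, so
the peak-to-peak differential is evaluated on consecutive extremum pairs
whose gap fits within one PLP (2 ms). The threshold is
`threshold_factor × σ̂` with σ̂ from the spike-robust median estimator
(median(|x|)/0.6745); the plain sample SD is available but biased high
when spikes are present. The multiplier is not dictated by anything
measurable here; the default 8 (≈ 4 SD per phase of a biphasic spike)
yields ≥ 0.95 recall and precision on the rendered benchmark at the
default amplitudes, and all results that depend on it are validated only
on synthetic ground truth. Events are timed at the larger-magnitude
extremum of the pair (the first on ties) — alignment to the first extremum
regardless of magnitude was rejected as more jitter-prone. A dead time
equal to the PLP suppresses secondary candidates. Conventions throughout:
seconds from recording start, 0-based samples, half-open intervals
`[start, end)`.

## Sorting

The original sorting stage (superparamagnetic clustering plus supervised
visual curation) is not re-implemented: it is external published work and
manual judgement respectively. The stand-in is deterministic: cutouts are
realigned by up to ±2 samples onto the channel's mean waveform (threshold
detection quantises event times to samples, and the resulting one-sample
jitter otherwise splits one unit into discrete shape clusters), projected
onto 3 principal components, and partitioned by k-means with k chosen by
the silhouette criterion over 1..5. k = 1 wins unless a split clears a
silhouette of 0.5 — a single Gaussian cloud does not — and candidate
partitions carving off fewer than `min_cluster_size` (20) events are
rejected as overlap artifacts. Noise clusters are labelled by two rules:
more than 2% of ISIs under 1 ms, or mean peak-to-peak below 10× the noise
SD (slightly above the detection threshold, so clusters hugging the
threshold are rejected). These automated rules approximate, not reproduce,
the original curation; externally sorted trains can be imported via CSV,
bypassing the stage entirely.

## Phases and rates

Control timelines run PreL, PoL1–3 (the post-lesion hour in consecutive
20-min thirds), PreS, Stim (60 min at 0 µA) and PoS; stimulated animals,
implanted after lesion induction, have PreS/Stim/PoS only. The
0.01 spikes/s inclusion filter is applied globally — a unit counts if it
reaches the threshold in any analysed phase — so the unit set is identical
across compared phases, which the per-unit pre/post comparisons require; a
per-phase filter would silently change the population between panels.
Because the phase pooling across animals for the group rate statistics is
not uniquely determined, the pipeline reports both unit-pooled and
animal-averaged summaries.

## Change classification

The default shuffle re-partitions the pooled 1-min bins *without*
replacement into groups of the original sizes — a permutation null, the
most direct reading of shuffling bins into two groups; a with-replacement
bootstrap variant is exposed as a flag. Each re-partition contributes both
the difference of group means and its negation (the group swap is itself a
valid shuffle), making the null exactly symmetric; together with sorting
the pool before permuting, this makes phase-swap antisymmetry exact: the
reversed comparison negates the observed difference and mirrors the
interval bit-for-bit. Equal-tail empirical quantiles define the 95%
interval, values on a boundary resolve to *no change* (conservative), and
trailing partial bins are dropped (none occur with 20-min phases and 1-min
bins). No multiple-testing correction is applied across units — per-unit
labels are reported as such, not as corrected discoveries. Measured null
coverage is ~95–96% (the slight conservatism comes from the discreteness
of binned counts).

## LvR

The statistic is evaluated exactly as defined, summing over adjacent ISI
pairs i = 1..n−1 with n the number of ISIs; the variability factor is
clamped at zero where floating-point cancellation on near-equal ISIs would
produce values like −3e−16. Fewer than 10 ISIs (a documented default — no
minimum is dictated by the definition) reports `undefined`. The bands
Regular/Random/Bursty do not cover [0, ∞); values outside every band are
reported `unclassified` rather than force-assigned, and a value on a
shared boundary goes to the lower band. The pre/post ratio direction is
configurable: the study names a pre/post ratio yet reports the stimulated
group's burstiness shift as an *increase*, which matches the post/pre
orientation; post/pre is therefore the default and the discrepancy is
surfaced here rather than resolved silently.

## Group statistics

Deliberately thin delegations to standard routines: Lilliefors-corrected
KS for the normality screen, Friedman across phases, a Tukey-type
comparison of Friedman mean ranks (critical difference
q_{α;k,∞}·√(k(k+1)/12n)) run only when the omnibus is significant,
Wilcoxon signed-rank within group and Wilcoxon rank-sum between groups,
α = 0.05. The report names each test, statistic, p-value and the
correction applied (none for the per-unit bootstrap labels; the rank
post-hoc for the omnibus).

## Problem sizes and determinism

The calibration script and test suite use desk-scale problem sizes chosen
as the package's own benchmarks: 200 × 1200 s trains for the LvR
calibration, 2,000 simulated units at 2,000 shuffles (plus a 200-unit spot
check at the full 10,000) for null coverage, a 20-unit/60 s rendered
benchmark for detection scores, and a 1/60 time-scaled schedule when the
full pipeline renders voltages end-to-end (`time_scale` shrinks every
phase uniformly; the canonical experiment is `time_scale=1`, and the
1-min shuffle bins scale with it to keep 20 bins per phase). Every random
stage derives child seeds from one master seed via `SeedSequence`, and
repeated runs are byte-identical, manifest included.

## Known limitations

Waveform overlaps between near-coincident spikes are neither resolved nor
modelled beyond what the dead time implies, so recall degrades at high
collision rates; the sorter assumes one dominant footprint channel per
unit (no tetrode-style cross-channel sorting, no drift correction); the
evoked-response model is a premise, not a fit; and passing the synthetic
benchmarks demonstrates correctness of the implementations under the
generator's assumptions (stationary noise, stereotyped waveforms), not
performance on in vivo data.
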