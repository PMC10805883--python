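# Methods

This note documents the models, defaults and numerical choices behind
`stopcancel`, and what the synthetic-data generator does and does not
emulate.

## Task design

Four conditions with their published trial numbers (test + practice):
choice reaction time CRT 32 + 8 (1 block), flanker 180 + 12 (2 blocks),
stop-signal task SST 120 + 8 (2 blocks), combined stop-signal flanker
task SSFT 360 + 16 (4 blocks). Left/right targets and (where present)
congruent/incongruent/neutral flankers occur with equal frequency; stop
signals occur on 30% of SST/SSFT trials, balanced over every
hand × congruency cell. Custom trial counts are accepted when the cell
structure stays integral; anything else raises a design error.

Fixation intervals are drawn from an exponential truncated to
[0.6, 1.1] s. The rate before truncation is not a design constraint;
the package defaults to 2.0 s⁻¹ (configurable) — only the support is
normative. Sampling uses the exact inverse CDF.

The SSD staircase is one-up/one-down with 50 ms steps from a 200 ms
initial value, tracked independently per hand (SST) and per
hand × congruency (SSFT; each cell initialises at 200 ms rather than
inheriting the SST endpoint). The floor is 0 ms (failures at the floor
leave the SSD unchanged); no ceiling is imposed because the SSD cannot
usefully exceed the response deadline (default 1,500 ms). Staircase
state persists across blocks, and practice trials drive the staircase
(warm-up) while being excluded from every analysis. Trial order is a
plain seeded permutation; no constraint on identical consecutive
outcomes is imposed. Slow-response feedback is flagged when a go RT
exceeds the participant's reference mean by strictly more than 150 ms
(CRT mean for the SST; congruency-matched flanker-task mean for the
SSFT).

## Horse-race generator

Go finishing times are ex-Gaussian — the standard positively skewed RT
model — with young-adult defaults μ = 300 ms, σ = 40 ms, τ = 80 ms (an
older group can be emulated with e.g. μ = 360, σ = 50, τ = 110). These
are qualitative, configurable choices, not fitted values. Additive
shifts implement flanker effects (defaults: incongruent +57 ms,
congruent −8 ms, neutral 0 — the incongruency cost matching the young
flanker-task effect the recovery tests target) and optional proactive
slowing in stop-expectation contexts (default 0, so context independence
holds by construction). Choice errors (2%) and go omissions (1%) occur
at fixed rates.

On a stop trial, a stop process of duration `stop_latency_ms`
(default 250 ms) starts at the SSD and races the go process. With press
time g, EMG onset o = g − `emg_onset_to_press_ms`, and stop finish
s = SSD + `stop_latency_ms`:

* s ≤ o — successful stop with no muscle response (NO_EMG);
* o < s < g — successful stop with a partial burst (PARTIAL), whose
  envelope peaks at SSD + `cancel_peak_latency_ms` (default 155 ms, the
  young-group mean Cancel Time in the simple stop task);
* s ≥ g — failed stop, button pressed (FULL_PRESS; ties go to the
  press).

Two deliberate model choices here:

1. **Electromechanical delay 100 ms.** The RT-burst rule accepts bursts
   starting at least 50 ms before the press. A generator delay of
   exactly 50 ms would park every true onset on that decision boundary,
   making classification depend on detection jitter; 100 ms is a typical
   onset-to-press interval for button presses and keeps the rule
   decisive.
2. **Partial bursts are anchored to the cancellation time.** Empirically
   the cancellation latency (~155 ms) is far shorter than the
   behavioural stop latency (~250 ms), so an onset derived from the
   never-occurring press would fall *after* the prescribed envelope
   peak. Partial bursts are therefore generated as symmetric Gaussian
   bumps (σ = `burst_rise_ms`, support ±3.5 σ) centred on
   SSD + `cancel_peak_latency_ms`, with amplitude a uniform 0.3–0.8
   fraction of the full-burst amplitude. Symmetry makes the stated peak
   latency well defined under any zero-phase smoothing.

EMG traces span −0.5 to +1.5 s around the go signal at 2,000 Hz. The
cued hand carries envelope × white-Gaussian carrier plus baseline noise
(SD 0.02 relative to a unit burst amplitude); the non-cued hand is
baseline noise only. Go bursts rise (raised cosine, 20 ms), hold until
the press and decay exponentially (60 ms time constant). The white
carrier spans the recorded band, so the 20–1,000 Hz acquisition
filtering is implicit; the analysis band-pass re-applies the 20 Hz
high-pass edge. Burst shapes are stipulated, not inferred from data.

## EMG analysis

All filters are zero-phase (forward–backward `sosfiltfilt`), so detected
onsets and peaks carry no group delay — peak-timing fidelity is what
Cancel Time needs. Filter "order" refers to the designed Butterworth
order (4th for the 20–500 Hz band-pass and the 10 Hz envelope low-pass);
forward–backward application doubles the effective order.

Burst detection: the baseline is the 100 ms sliding window of the
envelope with minimal mean ("the quietest activity in the trial"); the
threshold is baseline mean + 3 SD; supra-threshold runs separated by
less than 20 ms are merged; crossings are resolved at the sample level
only, and peak ties break to the earliest sample. A consequence of
zero-phase smoothing worth knowing: the 10 Hz envelope spreads a burst's
rising edge ~25 ms backward, so detected onsets run systematically
~20 ms *early* relative to the raw envelope's support at default SNR.
Peak times — and hence Cancel Times — are unbiased (mean error ≈ 0.1 ms,
SD ≈ 2 ms in the recovery suite).

prEMG criteria are applied literally: onset after the go signal, peak
strictly after the SSD (no extra margin), peak above 10% of the
participant's mean RT-burst peak over successful CRT go trials — the CRT
reference is also the normalisation denominator, which is the reading
consistent with profile normalisation (configurable). A trial with a
press is a failed stop and never prEMG; the phenotype trichotomy
FULL_PRESS / PARTIAL / NO_EMG is exhaustive and exclusive.

## Stopping summaries

Integration-method SSRT with go omissions replaced by the subject's
slowest RT; the quantile rank is ⌈p·N⌉ with 1-based semantics and ties
inheriting sorted order. Cells pool hands; the mean SSD is computed per
hand first and then averaged (staircases run per hand). Choice-error and
anticipatory go trials are excluded from the go-RT distribution first.
Validity: mean failed-stop RT strictly below mean go RT (undefined
without failed stops → invalid) and stop success within 25–75%,
endpoints inclusive. Invalid cells are logged with the reason and carry
no SSRT.

## fNIRS chain

Forward model and inverse share one extinction-coefficient table
(natural-log convention, values following the compiled Gratzer/Cope
whole-blood spectra) and one canonical double-gamma HRF (response gamma
shape 6, scale 0.9 s; undershoot shape 16, scale 0.9 s, ratio 1/6;
normalised to unit peak; support truncated at 30 s so well-separated
events are exactly non-overlapping). Sharing the constants makes the
noiseless round-trip — intensities → OD → MBLL → epoch → peak — exact to
machine precision, which the tests assert.

DPF defaults are 6.0 (760 nm) and 5.2 (850 nm), configurable; the
montage is 10 channels per lateral prefrontal hemisphere plus midline
channels (excluded from hemisphere averages) at 30 mm separation.
Pruning applies the dRange bounds literally to raw intensities in
recorded units (baseline intensity defaults to 2.0, inside [1, 3]) and
uses raw-intensity SNR. Motion detection operates on windowed OD
excursions against 9 × the SD of the OD first difference (or an absolute
100 OD-unit bound), dilating flags by 1 s per side; correction removes
principal components up to 97% cumulative variance from the flagged
segments only, offset-corrects for continuity, re-detects and iterates
at most 5 times; flagged segments smaller than the channel count skip
PCA with a warning. The haemodynamic low-pass is a 3rd-order zero-phase
Butterworth at 0.5 Hz. Epochs span 0–10 s from stimulus onset, zeroed
over 0–2 s (inclusive bounds), and the summary is the signed maximum
HbO₂ change in 4–7 s (inclusive). No short-separation regression,
wavelet correction or GLM-based HRF estimation: block averaging only,
and bit-parity with any particular toolbox is not a goal.

The simulated physiological noise is sinusoidal (cardiac ~1 Hz,
respiratory ~0.3 Hz, Mayer waves ~0.1 Hz, random phase per channel) plus
white noise; motion spikes are common-mode exponentials (rank-1 across
channels). Event amplitudes are per-condition HbO₂ changes in µM with
HbR at −1/3 the HbO₂ amplitude.

## What the generator does not emulate

Trigger failures, violations of context independence (beyond explicit
proactive slowing), RT-dependent stop latencies, EMG cross-talk between
hands, motor-evoked potentials, realistic EMG spectra (the carrier is
white), optode-scalp coupling drift, serially correlated (1/f) NIRS
noise, and superficial/systemic physiology that differs between short
and long channels. Passing recovery tests therefore demonstrates that
the analysis chain is correct and unbiased under the stated model, not
that it is robust to every failure mode of real recordings.

## Problem sizes in the test and acceptance suites

The suites use sessions of 1,000–13,400 trials (traces synthesised only
on stop trials where possible), chosen so that Monte-Carlo error is
small against each assertion's tolerance: ≥ 2,000 staircased stop trials
per hand for the 50% tracking check (±3 percentage points), ≥ 500
partial trials for Cancel-Time recovery (±10 ms), 1,000 random instances
for the SSRT oracle, 500 random envelopes for the burst-detector oracle.
Group-level RT metrics use subject means, matching descriptive practice
for mixed-model analyses; the GLMM/LMM machinery itself is out of scope.
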