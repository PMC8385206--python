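# Methods

This note documents the models, parameter choices and numerical decisions
behind `freqtag`, and what the simulation-based validation does and does
not establish.

## Paradigm model

A trial is a continuous stream of 12 four-word sequences of isochronous
320 ms words (15.36 s of stimulus), preceded by 1 s of silence. Word,
phrase and sentence rates are exact reciprocals of the timing:
1/0.320 = 3.125 Hz, and 0.78125 = 3.125/4 Hz for sentences, twice that
(1.5625 Hz) for two-word phrases. Rounding to 3.125 / 1.56 / 0.78 Hz
happens only in reports. Sentential trials are
adjective–noun–verb–noun sequences with no four-word sentence repeated
within a trial; scrambled trials contain exactly six noun–noun–
adjective–verb and six adjective–verb–noun–noun sequences in shuffled
order, which destroys phrase/sentence structure while preserving
word-rate acoustics. Sessions: passive and word-task groups hear 50
sentential and 50 scrambled trials randomly interleaved; the
sentence-task group hears 50 sentential trials of which 10% contain
exactly one grammatically ill-formed sequence at a uniformly random
position (the behavioural target; the violating order is drawn
equiprobably from the two scrambled templates). Inter-trial intervals are
uniform on [1.0, 1.5] s — the jitter range is specified, the
distribution is our choice; nothing downstream depends on it. Word
labels are synthetic category-prefixed placeholders (144 nouns, 72
adjectives, 72 verbs by default); labels never enter any numeric
computation, so the real lexicon is not reproduced. Cross-session
play-count balancing of individual sentences is not enforced (only the
within-trial no-repeat rule); it has no effect on any computed
statistic.

## Envelope model

Each word is rendered as a Hann-windowed amplitude burst with i.i.d.
peak jitter N(1, 0.05²), and the whole trial is multiplied by
(1 + m(t)) where m is band-limited (< 8 Hz) Gaussian noise of sd 0.1,
i.i.d. across trials — the aperiodic loudness fluctuation of any natural
recording. Expected spectral energy is then confined to the word rate
and its harmonics; phrase/sentence bins sit at the noise floor.

The multiplicative modulation is load-bearing for *phase* statistics,
not just power: with per-word amplitude jitter alone, the jitter
contribution at exactly half the word rate combines the 48 word phasors
in strict antiphase (e^{-iπk} = ±1), so trial phases at the phrase bin
are bimodal-antipodal rather than uniform, the resultant length falls
*below* that of generic chance frequencies, and the Monte-Carlo p at
the phrase rate degenerates to 1. The broadband modulation restores an
isotropic (phase-uniform) perturbation at every non-harmonic bin.

## Synthetic EEG

Per trial and channel:

    x(t) = Σ_r a_r · g_r(ch) · cos(2π f_r t + φ_r + ε_{r,k}) + σ · n(t),
    r ∈ {word, phrase, sentence},

active only during the stimulus (the 1 s pre-stimulus interval is noise
only). g_r are Gaussian bumps on the sphere (word: central;
phrase/sentence: left temporal; width 0.8 chord units) — smooth,
left-lateralised topographies of the kind sensor-level cluster analyses
localise. φ_r is a per-participant base phase, ε trial-wise jitter
(default sd 0.4 rad, settable per rate). Scrambled trials have
a_phrase = a_sentence = 0. For sentence-group participants the
sentence-rate amplitude is multiplied by `sentence_attention_gain`
(default 2.0) on the `left_frontotemporal` region, a binary mask — this
makes the injected ground-truth region exact, which the recovery
experiment exploits. Background noise is 1/f (exponent 1, synthesized
directly in the frequency domain with a 0.1 Hz low-frequency floor, no
DC), half channel-independent and half shared through six smoothly
projected sources, giving electrode maps realistic spatial correlation.
Default amplitudes (a_word = 1.0, a_phrase = a_sentence = 0.55,
σ = 18) put 50-trial electrode-averaged ITPC near 0.3 at the word bin
and 0.17 at the phrase/sentence bins over a 0.125 floor — the scale seen
in group-level ITPC spectra of frequency-tagging studies.

The default sampling rate is 250 Hz rather than a typical 1000 Hz
recording rate: every frequency-bin bookkeeping quantity derives from
the 14.08 s analysed duration, not the sampling rate, and the one
property that does depend on it (7041 one-sided bins) is checked on a
single 1000 Hz epoch. Epochs are generated in float32; one participant
at recording rate in double precision would be ~1.6 GB, and nothing
downstream needs better than single precision before filtering.
Cohorts are processed streaming: no stage holds more than one
participant's raw epochs.

Layouts are Fibonacci-spiral quasi-uniform montages on the upper unit
hemisphere (+x right, +y anterior), projected to 2-D by the
azimuthal-equidistant map; regions are geometric caps
(`left_frontotemporal`: x < −0.25, y > 0.05, below the vertex;
`left_parietotemporal` mirrored posteriorly).

## Preprocessing

Epochs span [−1.0, +15.36] s around stimulus onset. A 4th-order
zero-phase (forward–backward) Butterworth low-pass at 25 Hz is applied
first (only family and cutoff are prescribed by the analysis it mirrors;
4th order zero-phase is the common default), then the first 2.28 s are
discarded, leaving 14.08 s = 11 sentence periods. Seconds-to-samples
conversions round half to even, once per epoch edge. Average referencing
optionally reconstructs the original recording reference as an all-zero
channel first (124 recorded channels → 125 analysed); after averaging
the per-sample channel mean is zero to numerical precision. Broadband
FIR filtering, notch filters, ICA and channel interpolation are not
implemented — synthetic data contain no line noise or artifacts; cleaned
external epochs can be imported from EDF instead.

## ITPC conventions

The coherence of K trial phases is reported as the resultant length
R = |K⁻¹ Σ e^{iθ_k}| by default, with `squared_resultant` (R²) and
`literal_eq1` (K·R², the sum-formula variant (Σcos)²/K + (Σsin)²/K)
selectable. The literal form is unbounded above 1 (it equals K for
perfect coherence), which cannot match ITPC plotted on [0, 1]; since
which normalisation is intended is ambiguous in parts of the
literature, all three are provided and every identity between them is
tested (literal = K × squared; squared = R² exactly). Under uniform
phases E[R] = √π/(2√K) and E[R²] = 1/K — both are used as closed-form
oracles.

## Bootstrap chance-frequency control

Per repetition (default 1000), 50 trials are drawn with replacement per
participant (implemented as multinomial resampling counts, which is
distribution-identical and vectorises); ITPC is computed at the target
bins and at 500 chance frequencies, averaged over repetitions and
participants, and each target's p is its rank in the chance
distribution with the +1 correction: p = (1 + #{chance ≥ target})/501,
never exactly 0 — the attainable floor is 1/501 ≈ 0.002. A reported
"p < 0.001" is therefore not attainable from 500 chance frequencies
under a plain rank statistic; the implementation flags floor values
explicitly (`BootstrapResult.at_floor`).

Chance frequencies are DFT bins in (0.3, 5.0) Hz excluding every
target, all integer harmonics of each target, and one guard bin on
either side. At 0.071 Hz resolution only ~48 eligible bins exist, so
the 500 chance frequencies are sampled from them *with replacement*;
evaluating off-bin frequencies instead would leak the dominant
word-rate component into every chance frequency (sidelobe decay is only
1/(πΔfT)) and bias the null distribution upward.

For EEG the control runs on channel-wise ITPC averaged over a spaced
subset of electrodes (default 16 of 125). Averaging the *signal* over
channels is not an option: after average referencing the channel mean
is identically zero.

A genuinely null target frequency is exchangeable with the chance
frequencies, so its single-run Monte-Carlo p is uniformly distributed
over seeds — a mid-range value in any one run is luck, not calibration.
Interval statements about the envelope's phrase/sentence p are
therefore made about the **median over independent seeded sessions**
(`envelope_control_pvalues`); the word-rate p, by contrast, is at the
floor in every run.

## Cluster-mass permutation tests

Electrode adjacency is the Delaunay triangulation of the projected
montage (edges = triangle sides). Electrode-wise t-maps (paired:
one-sample on differences; independent: pooled-variance two-sample) are
thresholded at the per-tail alpha (one-tailed 0.05; two-tailed 0.025
per tail with positive and negative clusters tracked separately);
connected supra-threshold components of ≥ 4 electrodes are scored by
summed t. The null statistic is the maximum |cluster mass| over the
scalp per permutation — strong family-wise control; paired designs
permute by sign-flipping difference maps, independent designs by full
label reshuffles (the toolbox this mirrors leaves the randomisation
unspecified; these are the standard choices). Cluster
p = (1 + #{null ≥ |mass|})/(n_perm + 1).

## ANOVA and Bayes factors

The attention × frequency ANOVA takes, per participant of the word and
sentence groups, ITPC averaged over the individually selected top-5%
electrodes (6/125; k = floor(fraction·n), ties broken by electrode
index) at the word and sentence bins. The default formulation treats
frequency as within-subject (each participant contributes both bins);
with 23 + 22 participants the interaction df are (1, 43). A
fully-between formulation, df (1, 86), is provided for comparison —
the choice of model determines the df, and neither is forced to match
any particular published value. Effect size is classical eta²
(SS_interaction/SS_total). Post-hoc contrasts are pooled-variance
two-sample t-tests with mean difference and 95% CI.

Two-sample JZS Bayes factors use the default Cauchy prior (r = √2/2) on
the standardised effect, computed by numerical quadrature of the JZS
mixing integral; the implementation is cross-checked against an
independent library implementation in the tests. A structural fact
worth knowing: BF₁₀ at t = 0 is 0.353 for n = 14 per group and 0.295 at
23/22 — i.e. "substantial evidence for the null" (BF₁₀ < 1/3) at a
*majority* of electrodes is not attainable in expectation below ~28 per
group, because P(|t| < t*) with BF₁₀(t*) = 1/3 only exceeds ½ there.
The recovery experiment therefore evaluates the Bayes-factor map at 32
per group.

## Validation experiments and problem sizes

All calibration/recovery studies live in `freqtag.validation`, take
explicit seeds, and are sized to finish in minutes on one core:

* **Envelope control**: 10 sessions × 50 trials, 200 bootstrap
  repetitions, 500 chance frequencies, 15–21 seeded runs; word-rate p at
  the floor every run, phrase/sentence medians mid-range.
* **Peak-test level**: ≥500 cohorts of 20 participants × 50
  phase-uniform trials, ITPC averaged over 32 independent electrodes
  (the test consumes electrode-averaged spectra; single-electrode
  resultants are skewed enough to inflate the paired t slightly).
* **Cluster-test level**: ≥500 cohorts of spatially smooth exchangeable
  null maps (Gaussian random fields, squared-exponential covariance,
  length scale 0.6 on the unit-disc projection, 10% white nugget, 64
  channels, 200 permutations). Spatial smoothness matters: with
  spatially white maps, ≥4-electrode supra-threshold clusters almost
  never form and the measured rate collapses far below the nominal
  level for lack of rejections, telling nothing about calibration in
  the regime the test is used in.
* **ANOVA level**: ≥500 simulated null tables (within-subject
  correlation 0.5).
* **Effect recovery**: word vs sentence group, 32 participants each,
  sentential-only 50-trial sessions, 64 channels at 100 Hz, gain 2.0 on
  the left fronto-temporal region, independent two-tailed cluster test
  (α = 0.025, 400 permutations). Success = a significant positive
  sentence-bin cluster with Jaccard ≥ 0.5 against the injected region;
  alongside, the word-bin Bayes-factor map shows BF₁₀ < 1/3 at a
  majority of electrodes (asserted on the median fraction over runs —
  per-run fractions fluctuate because electrodes are spatially
  correlated).

## What passing does and does not show

The generator realises phase-locked sinusoids in 1/f noise with smooth
topographies — it contains no eye blinks, muscle or line-noise
artifacts, no bad channels, no inter-individual anatomy, and its
scrambled condition nulls the higher rates exactly. Passing therefore
certifies the *analysis chain* — correctness of the spectral
bookkeeping, calibration of every test at its nominal level, and
sensitivity to effects of plausible size and topography — not any claim
about real recordings, whose effect sizes and artifact structure the
synthetic conditions do not emulate. Statistics that require the
original recordings (real-data t/F values, cluster p's, behavioural
accuracies) are intentionally outside what the simulations report; the
pipeline reproduces their formats.

## Known limitations

* EDF export writes 16-bit EDF+C (quantisation ~range/65535 per
  channel); annotations carry trial onsets and condition labels only.
* The literal-equation ITPC convention propagates through peak tests
  unchanged (monotone transform per K), but bootstrap and cluster
  statistics are defined on the resultant length.
* Source-space analysis (beamforming), artifact correction and
  behavioural modelling are out of scope.
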