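# Methods

## Signal model

Each simulated continuous record follows the additive evoked-response
model: the voltage at channel c and time t is

```
X_c(t) = Σ_events s_c(t − t_event; category) + n_c(t)
```

where `s` is a deterministic stimulus-locked signal and `n` is background
EEG. The signal is a sum of component templates, each defined by a Gaussian
time course (peak latency, temporal sd), a scalp pattern (weight 1 at its
center electrodes, Gaussian falloff with projected scalp distance, sigma
0.18 head-disc units; 0.15 for the tightly focal mesial-occipital N80), and
a signed peak amplitude per category. Sixteen templates cover the marker
set; the occipitotemporal N170 is split into left and right half-templates
so the word-reading left-hemisphere advantage is a genuine
category × hemisphere interaction rather than a label. The cross-modal
PN300 template is injected on every trial with amplitude −4 µV (pictures)
or +4 µV (sounds).

Absolute template amplitudes are design constants on a 1–8 µV scale. What
the study constrains is the *ordering* of category amplitudes per marker
(e.g. human faces > animal faces for N170; checkerboards > words/objects
for N80; music > voice for the auditory P300), not their magnitudes.
Because overlapping components leak into each other's measurement windows
(e.g. the anterior N2 into the centroparietal P2 window, the frontal P300
into the AN window), the orderings are validated on the *noiseless evoked
responses* — cross-talk included — by `validate_template_orderings`, which
is part of the test suite. Between-category gaps of ≥ 1 µV were chosen so
that every ordering survives this superposition with a comfortable margin.

## Paradigm constants

10 categories (7 visual: infant/adult/animal faces, bodies, written words,
checkerboards, objects; 3 auditory: spoken words, affective vocalizations,
music), 40 trials each → 400 events per subject; visual trials in 8 runs of
35 (5 per category), auditory in 4 runs of 30 (10 per category), shuffled
within run; 1,500 ms stimulus duration; ISI uniform in 500 ± 100 ms (every
inter-onset interval lies in [1900, 2100] ms); 512 Hz sampling; 126-channel
10/5 montage referenced to averaged ears, plus synthetic bipolar HEOG/VEOG.
The default cohort is 20 subjects (the analysed sample size; 30 were
recorded before artifact-based exclusions, a count the package keeps as
`N_RECRUITED` for design arithmetic).

## Background noise and artifacts

Background EEG is a per-channel mixture of 1/f^a noise (default a = 1) and
white noise (white fraction 0.35), scaled channel-wise to `noise_sd`
(default 7 µV — typical awake scalp EEG amplitude, small enough that the
background alone rarely trips the 50 µV rejection rule), plus a 10 Hz alpha
rhythm (2 µV peak, random phase per channel). For long records the
power-law component is synthesized at fs/4 and linearly upsampled; its
spectrum is unaffected below ~64 Hz, which covers the entire analysis band.
Per-subject variability is a log-normal gain (sd 0.15) drawn independently
per component, emulating stable inter-individual amplitude differences with
preserved marker structure.

Ocular artifacts are 300 ms biphasic blinks, 120 µV peak-to-peak on VEOG,
decaying toward posterior scalp, at Poisson-distributed times. The default
rate (1.5/min — participants are instructed to suppress blinking) is
calibrated so the downstream 50 µV criterion rejects ≈ 5 % of epochs; the
acceptance band is 3–7 % for the mean across cohorts. Individual subjects
scatter by ± 1–2 percentage points (Poisson counting), so the band is a
property of the cohort mean, not of single subjects.

## Preprocessing conventions

* Millisecond-to-sample conversion floors (`floor(ms/1000·fs)`); every
  window is half-open `[start, end)`. One convention, used by epoching,
  baseline and feature windows alike.
* Epoch = 51 baseline samples ([−100, 0) ms) + 768 post-stimulus samples
  ([0, 1500) ms) at 512 Hz. The 768-sample block is the per-trial vector
  that averaging operates on.
* Band-pass: order-2 Butterworth applied forward–backward
  (`sosfiltfilt`), corners 0.016 and 30 Hz. Applied twice, the gain at
  each corner is exactly 0.5 — the corners are half-amplitude points, which
  is the convention the acquisition specification uses. The sub-hertz pole
  has a seconds-long impulse response, so the record is even-reflection
  padded by 5 s to keep the start-up transient out of the data.
* Rejection: an epoch is discarded iff max-minus-min within the epoch on
  *any* channel — EOG included, since blinks are what the rule is for —
  strictly exceeds 50 µV; a swing of exactly 50.0 µV is kept ("exceeding"
  read literally, so boundary behavior is pinned for tests). The rejected
  tensor is retained and each rejection logs its worst channel, so the
  scalp-only or EOG-only subsets can be audited.
* Baseline: subtract the per-channel mean over [−100, 0) ms; idempotent.

## Statistics

The repeated-measures ANOVA is a balanced fully-crossed within-subject
decomposition (subject as random blocking factor): every within effect is
tested against its own effect-by-subject interaction; sums of squares are
computed by inclusion–exclusion over marginal means. Per effect we report
F, degrees of freedom, Greenhouse–Geisser ε (from the
orthonormal-contrast-projected condition covariance, clipped to
[1/df, 1]; identically 1 for two-level factors), the ε-adjusted p (applied
to both dfs), and partial η² = SS_effect / (SS_effect + SS_error). The
implementation is checked against an explicit design-matrix projection
oracle (agreement to 1e-8) and against pingouin on two-factor designs, and
its GG-adjusted type-I error rate is verified at the nominal α over 500
null simulations.

Tukey HSD post hocs use the studentized-range distribution with the
repeated-measures error term (MS and df of the one-way category ANOVA on
cell means — the least-surprising pairing of HSD with an RM design, stated
here because the convention is not unique). The p-values are cross-checked
against a direct double-quadrature oracle for the studentized-range tail
probability.

The fixed battery runs one ANOVA per marker: category × hemisphere when
the marker's electrodes are homologous lateral pairs, category × electrode
otherwise, modality × electrode for the cross-modal PN300. "Larger" for
negative components means more negative, so contrast verdicts compare
magnitudes for N80/N170/N2/N400/AN and signed values for positive
components; signed amplitudes are what the feature table stores. The
non-living N170 verdict additionally requires a significant
category × hemisphere interaction with the word advantage confined to the
left hemisphere.

## Decoder

Classification operates on per-subject averaged evoked features
(m ≈ 40 kept trials), not single trials — the markers are average-level
signals. Stage 1 gates on the sign of the pooled PN300 amplitude
(negative → visual, else auditory); stage 2 is nearest centroid over the
gated modality's markers, z-scored with training-set statistics only.
Nearest centroid was chosen over trained discriminants deliberately: the
claim under test is that the *markers* separate the categories, not that a
flexible classifier can. Exact ties break lexicographically and are
logged. If an evoked is misrouted by the gate (possible only when noise
swamps the modality signature), its vector carries no features for the
gated branch; the decoder then returns that branch's first category,
logged as a gate fallback — necessarily an error, which keeps
fully-null-cohort accuracy at the 10 % ten-class chance level (gate right
half the time × 1/7 or 1/3 within branch). Evaluation is
leave-one-subject-out over the per-subject category evokeds (200
predictions for the default cohort).

## Feature-table scope

Each marker is measured on every category of its modality (the cross-modal
marker on all ten), giving the dense per-modality feature matrix the
decoder needs; the ANOVA battery restricts each marker to its analysis
categories (e.g. the living-set N170 to the three face categories, whose
three levels match the reported two-numerator-df tests). The serialized CSV
carries `subject, category, marker, electrode, amplitude_uv`.

## Problem sizes used by tests and the acceptance script

The rejection-calibration measurement uses 10 independent cohort seeds
with 4 subjects each (16,000 epochs): the rejected fraction is already a
mean over 400 epochs per subject, so 40 subjects estimate the cohort mean
to ~0.2 percentage points, far inside the 3–7 % band. The decoding
benchmark uses the full default 20-subject cohort. Monte-Carlo property
tests (averaging 1/√m law, type-I calibration, chance-level decoding) run
on direct feature-level simulations, which is what they test; the
noise-accuracy monotonicity ladder uses a reduced cohort (5 subjects,
8 trials/category, rejection disabled so the high-noise rung keeps its
epochs).

## What the synthetic data does and does not show

The generator reproduces the paradigm's design constants, realistic
spectra, blink morphology and between-subject gain variability, and its
ground-truth orderings realize every expected category contrast. It does
not model volume-conducted source geometry (scalp patterns are Gaussian
falloffs, not forward-model fields), latency jitter across trials or
subjects, muscle/movement artifacts other than blinks, channel drop-outs,
or any overlap of late components with the next trial's baseline. Passing
tests therefore demonstrate that the pipeline, statistics and decoder are
correct and calibrated — that the marker machinery *recovers what is
present* — not that human data would yield these effect sizes or decoding
accuracies; on real recordings the gaps between categories, and hence the
decoder's margin over the 70 % benchmark, are an empirical question.

## Known limitations

* The exact 126-channel subset used in the original montage is not
  recoverable; the frozen asset is a standard 10/5 subset guaranteed to
  contain all 26 analysis electrodes (vertex-centered idealized spherical
  positions, homolog-closed). Topography is qualitative.
* EDF files are written by a minimal 16-bit encoder (1 s records,
  per-channel symmetric physical ranges rounded up at two decimals); reads
  go through MNE. Round-trip error is bounded by 16-bit quantization.
* `rm_anova` requires balanced, fully-crossed designs and raises on
  missing cells rather than imputing.
* Greenhouse–Geisser is the only sphericity correction offered (no
  Huynh–Feldt), and it is reported even when ε = 1.
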