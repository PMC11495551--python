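# Methods

`nadnirs` implements, end to end, an infant fNIRS analysis for a nonadjacent-
dependency (NAD) artificial-grammar-learning experiment: stimulus
construction, a generative model of the recordings, a task-activation branch,
and a functional-connectivity (FC) network-discovery branch. This note
documents the models, the parameters that matter, and the design decisions
taken where the procedure left room.

## Experimental design encoded in `stimuli`

Triplets of frequency-modulated sine tones carry an A–X–B dependency: the
first and third elements' categories are linked (grammar 1a: A→B, 1b: C→D;
grammar 2 reverses the pairing: 2a: A→D, 2b: C→B) across a freely varying
middle element (X1/X2). Elements last 1.5 s with 0.25-s gaps (5-s triplets).
Categories A–D have 10 pitch variants (500–700 Hz in 50-Hz steps, then a
200-Hz gap, then 900–1,100 Hz); X1/X2 have 16 variants (500–710 Hz in 30-Hz
steps, a 190-Hz gap, then 30-Hz steps from 900 Hz). For the upper X range the
printed endpoint (1,100 Hz) and step (30 Hz) are mutually inconsistent; the
default keeps the step (endpoint 1,110 Hz) and an endpoint-matched encoding is
available via `x_high_encoding="endpoint1100"`.

Pitch contours are only named by the design (rising, slow wave, fast wave,
falling, big/small spike); the parameterisations here are fixed so outputs are
reproducible: linear glides over ±20 % of the base frequency, sinusoidal FM at
1 vs 3 cycles per element, and Gaussian frequency excursions of 50 % vs 20 %
centred mid-element (width 8 % of the element). 10-ms raised-cosine amplitude
ramps avoid clicks. None of these choices affect the numerical analysis
downstream; they matter only for the rendered WAV output.

Sessions: 60 standard triplets with 1.5-s gaps (388.5 s learning), then a
test phase of 10 Correct and 10 Incorrect target trials (2 triplets each,
11.5 s), interleaved with baseline trials of 2–4 standard triplets
(11.5/18/24.5 s, drawn with weights 0.7/0.2/0.1 so the test phase lasts
roughly 8–9 min), never more than 2 consecutive same-condition targets.
Neonate sessions add Pre-Rest (240 s) and Post-Rest (230 s) phases — the
upper ends of the usable ranges reported for such recordings. Test triplets
draw only pitch variants never heard during learning (the variant grid is
split into low/high halves per list; 4 lists counterbalance grammar family ×
familiarised half).

## The generative model (`synthdata`)

Per subject, channel-wise ΔHbO (mM·mm, concentration × path length) is built
as a sum of:

- **Task activation.** Condition boxcars convolved with a canonical
  double-gamma HRF (peak 6 s, so the 7.5–12.5-s analysis window brackets the
  peak of an 11.5-s stimulation block), peak-normalised so planted amplitudes
  are in mM·mm at the single-trial response peak. Defaults: Correct
  −0.04 (habituation-like deactivation), Incorrect +0.06, on the six
  prefrontal channels (30, 34, 35, 38, 39, 43 of the 46-channel layout).
- **Latent-factor network.** Channel cliques share one band-limited
  (0.01–0.1 Hz) unit-variance factor each; every within-component pair is a
  planted FC edge. The default components — {30, 34, 2, 9} plus {35, 17},
  {38, 19}, {39, 22}, {43, 40} — give 9 seed-touching edges and one edge
  between two non-seed channels (2–9), the topology the network-assembly
  stage is designed to find. Per-phase loadings (0.03 Pre-Rest, 0.18×s
  during Learning, 0.08 Post-Rest, amplitude 0.13 mM·mm) ramp over ~45 s
  inside the learning phase; a step at the boundary would bleed into the
  rest phases under the zero-phase band-pass used downstream.
- **Physiology and noise.** Cardiac (2.5 Hz ≈ 150 bpm), respiratory (0.7 Hz)
  and Mayer-wave (0.1 Hz) sinusoids with per-channel random phase *and* ~5 %
  frequency jitter (equal-frequency sinusoids would correlate across channels
  as cos Δφ and plant spurious connectivity), 1/f drift, and white noise.
- **Artifacts.** Biphasic (zero-area) motion spikes of 0.3–1.0 mM·mm —
  monophasic spikes would leak low-frequency energy through the FC band-pass —
  at probability 0.2 per target trial plus a background rate of 1 per 300 s,
  and rare 2-s saturation episodes clamped at 6 mM·mm. Every planted spike
  exceeds the 0.15 mM·mm rejection criterion by construction; every
  saturation exceeds the 5 mM·mm ceiling.

ΔHbR is −0.4 × the signal components plus its own noise. Both chromophores
are pushed through the forward modified Beer–Lambert model (2×2 extinction
matrix; standard literature coefficients shipped for 695/780/830 nm) to give
two-wavelength ΔOD at 10 Hz on the study layouts: one 3×5 + two 3×3 pads
(46 channels) for neonates, two 3×5 pads (22 channels each) for infants, all
at 20-mm source–detector separation with alternating optode roles. The
channel→region lookup is a fixed synthetic stand-in for atlas-based virtual
registration, anchored to the published channel positions (frontal midline
channels 31/40, temporal-pad reference midpoints, the prefrontal seed set and
its partners).

**Subject coupling.** A standard-normal latent u per subject drives both
sides of the brain–behaviour analysis: the learning-phase loading scales by a
lognormal s = exp(1.1·u) (so Fisher z, which responds roughly
logarithmically to factor amplitude, is ~linear in u), and the Incorrect
amplitude offset is 0.07·(ρ·u + √(1−ρ²)·η) with planted coupling ρ = −0.7.
The residual η is 70 % shared across activation channels (prefrontal
responses co-fluctuate) and 30 % channel-specific. The generator's amplitude
and spread defaults were calibrated once for statistical power of the
recovery analyses, not for physiological fidelity — infant response
amplitudes in mM·mm are not standardised in the literature — and are part of
the simulated study conditions.

**What the generator does not emulate.** Real optical recordings have
heterogeneous channel gains and coupling, sleep-state transitions, rich
resting-state network structure beyond the planted edges (real group FC tests
find hundreds of Bonferroni-significant pairs; here only planted structure
can be significant), serially correlated artifact bursts, and infant-specific
HRF variability. Passing tests therefore demonstrate that the *pipeline*
recovers known structure under controlled conditions — not that it would
behave identically on real cohort data.

## Task branch (`preproc_task`, `activation_stats`)

OD → ΔHb by solving the 2×2 Beer–Lambert system per sample (no pathlength
division; units stay mM·mm). Trial rejection operates on the unfiltered
series: a trial is invalid per channel if |Δ(ΔHbO+ΔHbR)| between two
consecutive samples exceeds 0.15 mM·mm (strict >) anywhere in its 28-s epoch
span, or any |ΔHb| sample exceeds 5 mM·mm. Filtering is a zero-phase
third-order Butterworth band-pass, 0.02–0.5 Hz (zero-phase so window means
are not latency-shifted; phase handling was unspecified). Blocks are 5-s
pre-baseline + 11.5-s stimulation + 11.5-s post-stimulus (280 samples);
time t maps to sample ⌊t·fs⌋ and windows are half-open. The linear baseline
connects the mean levels of the first and last 5 s, anchored at the windows'
temporal midpoints, so both anchor means are exactly zero afterwards.
Averaging uses valid blocks only; a channel is valid with ≥2 valid trials per
condition, and a subject is excluded when more than half of the channels are
invalid.

Window means (7.5–12.5 s post-onset for neonates, 10.5–15.5 s for infants)
feed paired permutation t tests (default 50,000 sign-flips of the per-subject
differences; exact 2ⁿ enumeration doubles as the test oracle for n ≤ 20).
The two-sided add-one estimator p = (1+#{|t*| ≥ |t|})/(1+n_perm) keeps p
strictly positive; the design reports effects of both signs, implying a
two-sided test. Condition-vs-baseline pairs the window mean against the same
condition's 5-s pre-stimulus mean (the alternative — testing against zero
post-baseline-correction — is available by passing zeros). Seeds are
recomputed from the data as prefrontal channels significant on the HbO
Incorrect−Correct contrast; the published six-channel set is available as a
preset (`PipelineConfig.seed_channels`). Permutation seeding is counter-based
per (channel, contrast, chromophore) so results are order-independent.

## Connectivity branch (`preproc_fc`, `fc_network`)

Fixed order: wavelet motion correction of ΔOD per channel → Homer-style
sliding-window masking → 0.01–0.1 Hz band-pass → concentration conversion
with DPF = 5 over the 20-mm separation → per-phase extraction of the longest
span that is artifact-free on *every* channel, requiring ≥ 90 s (900 samples).

Wavelet correction (Daubechies-2) zeroes detail coefficients outside
[Q1 − 0.5·IQR, Q3 + 0.5·IQR] of their level's distribution. The decomposition
depth is 6: at 10 Hz sampling, detail levels then cover ≳0.078 Hz, so the
outlier rule removes spike energy (89 % amplitude reduction on a planted
10-sample spike) while the 0.01–0.1 Hz band the connectivity analysis depends
on stays almost entirely in the untouched approximation (clean 0.05-Hz
sinusoid distorted by 0.8 % RMSE; at full dyadic depth the same sinusoid is
distorted by 13 %, which is why full depth is not used). Masking flags any
1-s window whose excursion exceeds 15× a robust noise scale (1.4826×MAD of
the first-differenced series) or 0.4 OD, padded by 1 s each side; these
semantics are property-tested, with no claim of bit-compatibility with any
particular Homer release.

FC is Pearson r over the whole extracted HbO segment for all C(n,2) pairs
(1,035 for 46 channels), Fisher-transformed with r clipped at ±(1−10⁻⁷) so z
stays finite; degenerate pairs are flagged, never silently dropped. Group
tests: one-sample t of z against zero per phase, Bonferroni-corrected at five
family-wise levels (0.05, 5e-6, 5e-7, 5e-8, 5e-9; per-pair threshold =
level/1,035 ≈ 4.83e-5 at the loosest). Phase contrasts are paired t tests on
z differences at uncorrected p < 0.05. Unequal per-subject segment lengths are
allowed (learning segments run longer than rest segments); n_samples is
recorded per matrix for audit.

**Network assembly.** Eligible pairs are those with a significant
Learning−Pre-Rest change that touch at least one seed. Each is correlated
(Pearson, across subjects) with the Incorrect−Correct window-mean activation
of *every* seed; a pair enters the network when any seed correlation reaches
p < 0.05 (the metadata records which seed and r). Non-seed channels appearing
in those seed edges define the candidate set for non-seed edges, which must
correlate significantly with *all* seeds' activations. No multiplicity
correction is applied across the (pair × seed) grid, matching the reference
procedure; an FDR switch exists but is off by default.

**Baseline dependence.** Correlating Pre-Rest z with (Learning − Pre-Rest) z
carries a built-in regression-to-baseline bias: for i.i.d. phase matrices
corr(X, Y−X) = −1/√2 ≈ −0.71. The module reports the statistic as defined
and surfaces this analytic null in its docstring; observed negative values
should be read against it.

## Problem sizes and tolerances

- Beer–Lambert round trips are exact to ≤ 1e-9 (linear algebra only).
- Permutation-test calibration runs 2,000 null cohorts (n = 15) at
  n_perm = 2,000; the rejection rate at α = 0.05 lands in [0.040, 0.060].
- End-to-end network recovery is measured over 100 simulated cohorts of
  n = 15 paired subjects with permutation count reduced to 500 for seed
  selection (ample for the planted effect size of d ≈ 1.3); activation power
  over cohorts of n = 21. `scripts/acceptance.py` reports the same
  quantities over 30 cohorts (network) and 8 cohorts (power), sizes chosen to
  keep a single run in a few minutes on one CPU; the cohort counts are
  recorded in the JSON's `n` fields.
- Recovery at these conditions averages recall ≈ 0.8 and precision ≈ 0.8,
  with large cohort-to-cohort spread (single cohorts range from ~0.2 to 1.0):
  with 15 subjects, the sample correlation between a planted coupling of
  −0.7 and its measured proxies fluctuates by ±0.15–0.2, and whole cohorts
  can draw weak couplings by chance. This mirrors the fragility of
  seed-based brain–behaviour correlations at this sample size.

## Known limitations

- The region lookup is positional and synthetic; no claim of anatomical
  registration accuracy is made.
- The FC branch assumes one contiguous artifact-free segment suffices per
  phase; stitching multiple clean segments is not implemented (the reference
  procedure likewise used continuous spans).
- Group FC tests at the generator's defaults detect the homogeneous Post-Rest
  elevation but not the deliberately heterogeneous Learning elevation at
  Bonferroni levels; the heterogeneity is what the coupling analysis needs.
- Exact enumeration of sign patterns is capped at n = 20 (2²⁰ patterns).
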