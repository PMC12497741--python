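# Methods

This note documents the models, conventions and numerical choices behind
`actionfx`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The design

All analyses assume a fully within-subject 2×2×2 factorial visual-search
design: prime **congruency** (congruent / incongruent Stroop color-word),
**action** (key press on the prime / passive viewing), and target
**validity** (target color matches / mismatches the prime color). Target
hemifield (left/right) and target orientation (left/right tilt) are
balanced nuisance/label factors nested in every cell. The canonical study
size is 26 subjects with 60 trials per design cell (480 per subject), 60
scalp channels at 500 Hz, epochs −200..800 ms around search-array onset,
in microvolts throughout.

## Synthetic data generator

The generator is first-class, tested code: it defines the conditions under
which every downstream contract is verified.

**Noise.** Additive Gaussian noise with power spectral density ∝ 1/f^γ
(default γ = 1, the dominant scalp-EEG background slope), synthesized by
spectral shaping of white noise with an exact Parseval normalisation so the
per-channel variance equals `noise_sd²` (default 10 μV, a realistic
single-trial epoch SD after 0.1–30 Hz bandpass) in expectation; the DC
component is removed. Channel correlation is induced by a shared-noise
component: channel *i* = √(1−s)·own + √s·common, so every pair of channels
correlates at `spatial_smoothing` (default 0.2) without changing the
per-channel variance.

**ERP components.** Each component is a raised-cosine (Hann) temporal bump
confined to its window, scaled so the *mean over the window's samples*
equals the configured cell amplitude exactly — this makes noise-free
parameter recovery an identity rather than an approximation, and the Hann
edge (zero at both endpoints) keeps adjacent windows that share an endpoint
sample (N2pc 180–300 and P300b 300–500) from contaminating each other.
Lateralized components (N2pc) are written only to the electrode of the
homolog pair contralateral to the target hemifield: a left-hemifield target
drives the right electrode. Injected default amplitudes are the study's
reported condition means: the N2pc contra−ipsi cell means (−1.69/+1.01 μV
in congruent action valid/invalid, etc.), late-LPC cell means, and P300b
cells reconstructed around a 4 μV parieto-occipital base carrying the
reported validity effects (only effects, not cell means, are published for
P300b; the base level cancels from every contrast the pipeline computes).

**Multivariate patterns.** Decodable class information is injected as a
fixed unit-norm random spatial weight vector per labeling, added with sign
+1/−1 for the two classes, constant over the pattern window, with amplitude
`snr × noise_sd` μV. By default the validity pattern is present only in
action cells over 320–790 ms (the qualitative result pattern to recover:
validity decodable after an action, not after passive viewing) and the
orientation pattern in all cells over 200–790 ms, both at snr 0.6. Pattern
vectors are drawn orthogonal to the parieto-occipital montage average so
that the injected multivariate signal cannot bias the univariate component
means; the N2pc is additionally protected by hemifield balance (the pattern
does not depend on hemifield, so contra−ipsi differences cancel over a
balanced cell).

**Behavior.** RTs are drawn per cell from a zero-truncated normal at the
reported condition means/SDs (e.g. 522 ± 59 ms congruent/action/valid vs
620 ± 81 ms invalid, giving the 98 ms validity effect in expectation); a
truncated normal rather than a lognormal keeps recovery tests analytic. The
reported SDs are used as trial-level scale; between-subject variance is not
modelled separately, so group-level t-statistics on synthetic data are
larger than in real data — immaterial for the arithmetic and recovery
contracts tested, but worth remembering when eyeballing simulated F values.
Correctness is Bernoulli per cell (defaults 0.984/0.954 action
valid/invalid, 0.968/0.978 no-action).

**Reproducibility.** One master seed; per-subject and per-purpose streams
(design, noise, behavior, patterns) are spawned with fixed `SeedSequence`
spawn keys, so identical configs are bit-identical and disabling one
ingredient does not perturb the others.

**What the generator does not emulate:** forward-model scalp topographies
(channel identity is only meaningful through the layout's homolog pairs),
ocular/muscle artifacts, trial-to-trial latency jitter, autocorrelated
behavior (sequential effects), or between-subject amplitude variability.
Passing tests therefore demonstrate correctness of the *analysis
machinery* under a known generative model, not robustness to every
pathology of real recordings.

## Epoch processing conventions

* Window selections are inclusive of both endpoints: a sample at exactly
  300 ms belongs to both the N2pc and P300b windows, matching the printed
  window bounds.
* Threshold rejection drops a trial iff any sample on any channel
  **exceeds** ±80 μV (strict inequality; exactly 80 survives). Rejection
  decisions are a pure function of the raw amplitudes.
* Baseline correction subtracts the per-trial, per-channel mean over
  −200..0 ms; it is applied after rejection and before both ERP
  measurement and decoding (one convention, configurable).
* Downsampling averages consecutive non-overlapping blocks (500 → 100 Hz =
  blocks of 5); the new timestamp is the mean of the block's timestamps and
  a trailing remainder is dropped, never padded. Block-aligned interval
  means are preserved exactly.
* Storage is one HDF5 file per subject (`/data` float32 μV, `/times` ms,
  `/channels`, `/homolog_pairs`, embedded `/table`, format version
  attribute), with explicit errors for missing groups and version
  mismatches.

## ERP components

N2pc is measured per trial as contra-minus-ipsi at PO7/PO8 (contra/ipsi
resolved per trial from the target hemifield, before any averaging), then
averaged over 180–300 ms; P300b and late LPC as plain mean amplitude over
the ten parieto-occipital electrodes in 300–500 / 500–700 ms. Cell means
use correct-response trials only by default (the stricter convention;
configurable). Validity effects: invalid − valid for N2pc (an attentional
contralateral negativity on valid trials yields a positive effect),
valid − invalid for P300b and late LPC.

## Within-subject ANOVA

Every effect in a 2×2×2 within design is a 1-df contrast; the package
computes per-subject contrast scores (cells weighted ±1, divided by 4, so
a main-effect score is a difference of two 4-cell means, oriented so the
validity score equals the behavioral validity effect) and uses the exact
identities F = t², df = (1, n−1), η²p = F/(F+df_e). This is algebraically
identical to the classical sums-of-squares decomposition — the test suite
verifies equivalence against statsmodels' AnovaRM to 1e−8 on random
datasets — while staying transparent and oracle-checkable. Zero contrast
variance raises an error rather than returning a silent 0. Simple effects
are paired t-tests within a slice; the Bonferroni family is the set of
comparisons produced by one follow-up call, with p capped at 1. Cohen's d
is returned in both paired conventions (d_z = mean/SD of differences;
d_av = mean difference / mean condition SD) because published values are
often ambiguous between them.

## Decoding

Two-class linear decoding per subject per timepoint on the pattern across
all channels: trials of each class are randomly partitioned into 8
near-equal bins and averaged into pseudo-trials; fold k of the 8-fold CV
tests on bin k of *each* class and trains on the remaining 7+7; the whole
procedure is repeated over random binnings (default 100 iterations) and
accuracy averaged. The classifier is a soft-margin linear SVM (C = 1,
`SVC(kernel="linear", shrinking=False)` — shrinking off is ~3× faster at
these problem sizes with an identical solution). No feature scaling by
default (per-fold z-scoring available). Binnings are redrawn per iteration
and shared across timepoints within an iteration; since the classifier sees
one timepoint at a time this is statistically identical to per-timepoint
redraws and substantially faster. Degenerate training sets (all feature
vectors identical) yield a documented fixed-class fallback prediction
rather than a crash. Decoding uses all kept trials (correct and incorrect)
by default; class imbalance after cell filtering raises an explicit error
naming the counts (the design is balanced by construction).

A practical note on chance-level behavior: with a finite trial set, the
cross-validated accuracy of a single subject has a large irreducible
spread around 0.5 even on pure noise (the realized class-mean separation
of the subject's own trials is shared between training and test bins; with
60 channels the per-subject SD is ≈ 0.12 and is *not* reduced by more
binning iterations). Group means over 26 subjects therefore fluctuate by
roughly ±0.02–0.05 around chance at single timepoints. This is a known
property of cross-validated decoding at these sample sizes, not an
implementation artifact; it is why group-level inference uses the cluster
permutation test rather than eyeballing the chance band.

## Cluster permutation inference

Stage 1: pointwise one-sample t vs chance (or paired t via difference
curves), df = n−1; zero-variance timepoints get ±inf t, flagged as
suprathreshold. Stage 2: maximal contiguous runs beyond the
cluster-forming threshold (default: the two-sided pointwise p < 0.05
t-quantile — the dominant convention; the study itself does not state one)
with summed-t mass; two-sided clustering never mixes signs. Null: each
permutation flips the sign of each subject's deviation curve independently
(exact exchangeability move for a symmetric null), recording the maximum
absolute cluster mass; the t computation over permutations is vectorised
using the invariance of Σx² under sign flips. Cluster p = (1 + #{null ≥
observed}) / (1 + n_permutations), so p is never 0 and the test is valid at
finite permutation counts (default 10,000). Tails: one-sided (greater) vs
chance, two-sided for condition comparisons; both configurable. Adjacency
is temporal only.

## Pipeline

`run_pipeline` executes simulate → clean → behavior → ERP → ANOVA →
decode → cluster from a single `PipelineConfig` (YAML-loadable) under one
master seed, writing every table as CSV plus a JSON run report with SHA-256
digests of all artifacts; identical configs reproduce identical digests.
The analysis surface per run: 8 behavioral cells, 3 components × 8 cells,
validity decoding in the 4 congruency × action cells, orientation decoding
in the 8 full cells, vs-chance cluster tests for each decoding analysis,
and action vs no-action comparisons within congruency.

## Problem sizes in the test and acceptance suites

The default test run keeps simulations small (2–6 subjects, 8–24
trials/cell, 10–100 Hz) except where a contract is about the study scale
itself: chance-level decoding and design recovery run at the full 26
subjects with reduced sampling rates (20–25 Hz) and iteration counts
(3–15), sizes chosen so the whole suite completes in a few minutes while
keeping every statistical margin (SEM-based bounds, permutation SEs) at the
stated strength. The acceptance script uses similar scaled-down sizes and
derives every stream from its `--seed`.

## Known limitations

* No between-subject variance components in the generator (see above).
* The SVM's chance-level spread makes single-timepoint accuracy bands at
  n = 26 a coin flip at ±0.02 resolution; cluster-level inference is the
  supported decision procedure.
* No spatiotemporal (channel-adjacency) clustering; decoding yields one
  curve per analysis.
* The 2×2×2 ANOVA machinery is exact only for 2-level factors (1-df
  effects); designs with more levels need a general mixed-model engine.
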