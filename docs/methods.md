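# Methods

## The analysis being reproduced

Two decoding experiments run on epoched, labelled EEG trials from a
flanker task administered to six age groups (children, young, early
middle-aged, late middle-aged, old < 75, very old > 75):

1. **Between participants** — can a single trial be assigned to its
   participant's age group? Trials of all participants are pooled;
   participant-wise stratified 10-fold cross-validation guarantees that no
   participant contributes to both training and test. Training data are
   randomly subsampled to the minority class per fold so each of the six
   groups is equally represented. Performance is the pooled-confusion
   accuracy (plus per-class precision/recall), compared against the
   binomial chance threshold.
2. **Within participants** — can congruent and incongruent trials be told
   apart from a participant's own EEG? Ten stratified random 80/20
   train/test splits per participant; performance is the midrank AUC per
   sliding window, and each participant is summarized by the maximum
   fold-mean AUC and its latency. Significance uses a label-permutation
   null; group differences in the peak metrics are tested downstream.

Both experiments share a per-fold front end: xDAWN spatial filters are fit
on the training partition only (5 components per class), both partitions
are projected to virtual channels, features are standardized by
training-set mean/sd, and an RBF-kernel SVM (C = 1, γ = `scale`) is
trained. In the time-resolved variant, xDAWN is fit once per fold on the
full-length epochs and the windows are cut from the filtered signal;
refitting the filters inside every window would also be defensible, but
fitting on the full epoch matches the description of filters trained on
the preprocessed segments and is far cheaper. A window is stamped with the
midpoint of its first and last sample times.

## Preprocessing

Band-pass 1–40 Hz (zero-phase Hamming-window FIR via MNE-Python's default
design; transition bandwidths min(max(f·0.25, 2), …)), downsample to
256 Hz, re-window to −100..800 ms. Because the 1 Hz edge implies an
845-tap kernel — longer than a 231-sample epoch — each trial is
reflect-padded by the kernel length before filtering; this preserves the
designed passband (10 Hz sinusoid attenuated < 1%) and stopband (60 Hz
attenuated > 99%) on short epochs. No baseline correction is applied; the
1 Hz high-pass removes drift and DC.

The −100 ms edge is not on the 256 Hz sample grid, so epoch windows are
snapped by flooring both edges onto the grid: samples k = −26…204
relative to onset, i.e. 231 samples spanning −101.56…796.88 ms. Reported
times are the exact grid times.

Trial selection keeps correct responses with reaction times in
[100, 1200] ms (both bounds inclusive — the verbal rule "between … and …"
is ambiguous, and inclusivity is the convention here) and only the
congruent/incongruent conditions. Participants with fewer than 35 correct
trials in either condition are excluded (strict "less than"); the rule is
applied after trial selection, since that is what defines a correct trial.
A "poor data quality" exclusion has no algorithmic definition and exists
only as a manual flag in the QC report.

## The simulator

Every trial is a participant-level template plus fresh noise:

    x_i(t) = Σ_k a_k · g(t; τ_k, w_k) · m_k + ε_i(t)

with Gaussian envelopes g, fixed unit-norm topographies m_k (smooth
spatial gradients over the 32-channel 10–20 layout), participant-level
draws of amplitude a_k and latency τ_k, and 1/f Gaussian noise ε rescaled
to a per-channel standard deviation of 3 µV (spectral exponent 1). This
additive evoked-response form is exactly the model xDAWN assumes, which
is what makes the simulator a ground-truth test bed for the pipeline.

Default components and their age/condition structure:

| component | latency | amplitude | width | topography |
|-----------|---------|-----------|-------|------------|
| P1 | 100 ms | +5 µV | 25 ms | occipital (Oz) |
| N1 | 160 ms | −6 µV | 30 ms | occipital (O2) |
| N2 | 250 ms | −4 µV | 40 ms | fronto-central (Fz) |
| P3 | 400 ms | +8 µV | 80 ms | parietal (Pz) |

Between-participant jitter: latency sd 8–20 ms, amplitude sd 1–1.5 µV per
component. Children and the two oldest groups receive +80 ms latency and
×1.4 amplitude on P1/N1 — the u-shaped lifespan pattern in which early
components are larger and later at both ends of life. The
condition-discriminative signature (incongruent N2 delta of −3 µV;
incongruent P3 delayed 30 ms) is translated +150 ms in those same groups,
so the qualitative finding that conflict information arrives later in
children and older adults is recoverable by construction. The N2 delta
was calibrated once so that the condition effect is reliably decodable at
realistic noise (peak AUCs ≈ 0.7–0.9), mirroring a study in which ~96% of
participants decoded above chance; a −2 µV delta left too many simulated
participants near threshold for the peak-latency statistics to behave as
the full-scale study reports. Group sizes (46, 39, 21, 25, 40, 38) and
per-condition trial-count distributions (truncated normals with the
published mean/sd/min/max) follow the study's sample table. Reaction
times are log-normal around group-specific medians (450–650 ms, ×1.08 on
incongruent trials) and errors are Bernoulli (4% congruent, 8%
incongruent), so the QC stages have realistic work.

What the simulator does **not** emulate: ocular/muscle artifacts, volume
conduction from dipolar sources, non-stationary noise, trial-to-trial
latency jitter within a participant, or between-channel noise
correlation. Passing tests therefore demonstrate that the pipeline's
machinery is correct under its own model assumptions — not that real EEG
of these populations would yield the published effect sizes.

## Chance levels and statistics

* **Binomial threshold**: smallest k with CDF(k; n, 1/c) ≥ 1 − α, divided
  by n. For the group experiment n is the dataset's total trial count
  (the per-fold training + test sums, ≈24 520), because that reproduces
  the printed 0.17 chance level; the per-fold test count alone would give
  0.18.
* **Permutation null**: labels are reassigned to trials by a seeded
  shuffle *before* splitting; each permutation re-runs splits → xDAWN →
  windows → AUC with an independent split seed. The null statistic is the
  maximum over windows of the fold-mean AUC — the same statistic as the
  observed "peak performance" it gates. Per-participant nulls are pooled
  and the nearest-rank 95th percentile becomes the group threshold.
* **Group statistics**: Shapiro–Wilk per group at α = 0.05 (all groups
  must pass) routes to ANOVA + all-pairs Welch t tests, otherwise to
  tie-corrected Kruskal–Wallis + Dunn's large-sample z tests on mean
  ranks. Post-hoc p-values are Benjamini–Hochberg adjusted within the
  family of one omnibus test, and post-hocs are only reported when the
  omnibus rejects. Peak-time ties break to the earliest window
  (deterministic, conservatively favoring earlier processes).

## Numerical choices

* xDAWN solves the generalized eigenproblem by Cholesky-whitening the
  total covariance with diagonal loading ε = 1e−10 · tr(Σ)/n_ch, then an
  ordinary symmetric eigendecomposition; stable on the near-singular
  covariances produced by noise-free test data. Filter rows are unit-norm
  with a deterministic sign (largest-magnitude coefficient positive);
  patterns are Σw, row-normalized. The eigenvalue range [0, 1] holds in
  the EEG regime where single-trial power dominates evoked power; on
  artificial high-SNR data the Rayleigh quotient can legitimately
  exceed 1.
* Per-class participant folds are balanced by assigning each group's
  remainder participants greedily to the currently smallest folds, so 209
  participants in 10 folds give nine test folds of 21 and one of 20
  (188/189 training) rather than the front-loaded allocation of common
  library implementations.
* Trial counts are truncated-normal by redraw (clipping only as a
  1000-iteration fallback); RT log-normal shape derives from the
  coefficient of variation.
* All randomness flows from one master seed through named substreams
  (simgen, cv, subsample, permutation); participant seeds derive from
  (master, group index, participant index), so datasets are reproducible
  under parallel or partial generation.

## Problem sizes used by the validation suites

Full-scale runs (209 participants × ~130 trials × 32 channels × 231
samples, 212 windows, 1000 permutations) are not needed to validate the
machinery; the suites use desk-scale study conditions chosen once:

* **Type-I calibration (within)**: 40 participants, 100 null trials each,
  32 Hz, 8 channels, windows 8/4, 5 splits, 100 permutations. The
  fraction of participants whose observed peak AUC exceeds the pooled
  permutation threshold must lie in the binomial 95% band around 0.05.
* **Type-I calibration (between)**: 6 identical groups × 10 participants
  × 20 trials; whole-trial accuracy must lie in the binomial band
  around 1/6.
* **Effect-latency recovery**: 6 groups × 12 participants × 100 trials at
  64 Hz, windows 10/2, 10 splits, condition effect at 200 ms (adult
  groups) vs 400 ms (children/old). Group medians of peak latency must
  recover the injected latencies within ±40 ms, and Kruskal–Wallis +
  FDR-corrected Dunn tests must separate shifted from unshifted groups.

At these scaled-down sizes the proportion of individual participants
exceeding the permutation threshold is necessarily lower than in the
full-scale study (fewer trials per split and a max statistic over fewer,
coarser windows raise the threshold), so no fixed fraction-above-chance
is asserted at desk scale; the calibration suite instead verifies that
the threshold is honest (5% false-positive rate on null data).

## Known limitations

* The epoched-data xDAWN variant coincides with the original
  least-squares formulation only when stimulus responses do not overlap
  across epochs; overlapping designs would need the Toeplitz
  construction.
* "Five spatial filters" is read as five components per class (the common
  toolbox convention), giving 5 × n_classes virtual channels.
* The peak-statistic choice for the permutation null (max over windows of
  fold-mean AUC) is one defensible reading of thresholding "peak
  performance"; per-window thresholds would require a multiplicity
  correction across time that is out of scope.
* No artifact rejection, re-referencing, channel interpolation,
  hyperparameter search, temporal-generalization matrices, or
  cluster-based permutation correction.
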