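# Methods

## Problem

3D MR spectroscopic imaging (MRSI) of the brain yields hundreds of voxels per
examination, each carrying a short-echo proton spectrum. Before metabolite
maps can be interpreted, every voxel must pass quality control: artifacts such
as low SNR, broad linewidth, scalp-lipid contamination, and incomplete water
suppression make a spectrum unusable. Expert raters do this by visual
inspection, voxel by voxel. `specqc` implements automated voxel-wise QC as a
binary classification of the spectrum — "good" versus "bad" — with five
classifier variants, subject-grouped cross-validation, and attribution maps
that show which spectral regions drove a network's decision.

## Input representation

Spectra enter as complex or real intensities on a ppm axis. The model input
chain is: real-part extraction, cropping to the closed window
[1.4, 4.1] ppm (the metabolite region between the lipid resonances and the
water resonance), and per-voxel z-normalization to mean 0 and standard
deviation 1, giving an 850-point vector. Choices the contract leaves open and
how this package resolves them:

* the crop interval is closed on both sides;
* z-normalization uses the population (divide-by-n) standard deviation;
* zero-variance spectra are rejected rather than zero-filled — a constant
  spectrum cannot satisfy the normalization contract and carries no signal;
* the canonical axis is 850 *uniform* points on [1.4, 4.1]; real data on
  other grids are cropped and then linearly resampled onto it (a documented
  extension of the contract, needed because the networks take a fixed input
  length);
* the axis is stored ascending; the NMR display convention (ppm decreasing
  left-to-right) is applied only when plotting.

Two raters label each voxel; the consensus is "good" only if both say good —
the conservative rule used when aggregating expert labels.

## Classifiers

* **RF** — random forest with 200 trees on the raw 850-point normalized
  spectrum. Features per split default to floor(sqrt(850)) = 29; 30 is
  selectable through `ModelSpec.rf_max_features` since either rounding of
  sqrt(850) ≈ 29.2 is defensible.
* **CNN** — six blocks of (1D convolution → ReLU → max-pool 2) followed by
  two fully connected layers (256, then 64) and a 2-way softmax head.
  Kernel size 5 and channels doubling 16 → 512 across the six blocks are this
  package's choices (conventional 1D-CNN scaling); the layer counts and the
  64-node penultimate width are fixed contracts. No dropout or batch
  normalization.
* **ICNN** — two convolution/pool blocks (16 → 32 channels), then two
  inception modules, each a channel-concatenation of parallel kernel-1, -3,
  and -5 convolution branches plus a pooled 1×1-convolution branch (16
  channels per branch), each module followed by max pooling, then the same
  two fully connected layers and softmax head.
* **CNN+RF / ICNN+RF** — the trained network's 64-node penultimate
  activations are extracted for every training voxel and a 200-tree random
  forest (floor(sqrt(64)) = 8 features per split) is fitted on them; the
  forest makes the final call.

The network engine (forward, backward, Adam) is implemented in NumPy inside
the package (`specqc._nn`), vectorized through im2col so convolutions are
BLAS matrix products. It also exposes gradients with respect to the *input*,
which the attribution module requires. Training is full-batch-shuffled
mini-batch SGD with Adam at learning rate 1e-4, categorical cross-entropy,
batch size 64, 15 epochs by default, no early stopping: final-epoch weights
are used, and per-epoch loss/accuracy on the training and validation sets are
recorded as diagnostics only. "Good" is class 1 (the positive class) in every
probability and metric; accuracy thresholds the good-probability at 0.5,
identical to argmax for a two-class softmax.

## Cross-validation

Both schemes split at the *subject* level, never the voxel level, so no
spectra from a test subject leak into training or validation:

* **ND rotating** — for cohorts spanning the four neuro/control tags
  (healthy, MDD, MS, PD): each fold reserves one test subject and one
  validation subject per tag; the rest train. Ten folds by default, with test
  subjects drawn by a seeded per-tag permutation *without replacement*, so a
  subject is tested at most once across the rotation.
* **BT leave-one-out** — for tumor cohorts: one fold per subject, that
  subject testing, two randomly drawn subjects validating, the rest training.
  Validation pairs are redrawn per fold from a seeded generator.

Metrics per fold are ROC-AUC (Mann–Whitney concordance, ties credited 0.5),
PR-AUC (average precision with step interpolation — trapezoidal PR
interpolation is biased and deliberately avoided — with tied scores processed
as one threshold group), and accuracy. Folds aggregate as mean ± sample
(n−1) standard deviation; a single fold reports std 0 by convention. For
tumor cohorts the same metrics are additionally computed on the
lesion-flagged voxels only, whenever the test fold contains lesion voxels of
both classes.

## Integrated gradients

Attribution uses integrated gradients on the predicted-class softmax
probability: the straight path from a baseline to the input is discretized
with a midpoint Riemann rule (default 256 steps) and each point's attribution
is (x_i − b_i) times the path-averaged gradient. The default baseline is the
all-zero spectrum in normalized space (a dataset-mean baseline can be
passed). The completeness axiom — attributions summing to the prediction
swing F(x) − F(b) — is recorded on every result as `completeness_gap`, not
assumed; with ReLU activations the midpoint rule typically closes the gap to
well under 1% of the swing at 256 steps. Attribution is computed for the
*predicted* class so that masks on mispredicted voxels explain the prediction
actually made. Masks are |attributions| rescaled to maximum 1, with an
all-zero attribution vector mapping to an all-zero mask. Forests have no
gradients; attribution is defined only for the network kinds.

## Synthetic cohorts

Clinical 7T MRSI with expert labels is not shareable, so the package ships a
generator that emulates the features the classifiers must discriminate.

*Clean spectra* are sums of Lorentzian resonances — NAA (2.01 ppm, reference
height 1.0), Glx (2.35), Cr (3.03), Cho (3.22), mI (3.56), Cr-CH2 (3.92) —
with FWHM 0.035–0.06 ppm. A tumor mode emulates lesion metabolism (NAA × 0.4,
Cho × 1.6) for a configurable fraction of voxels, which also receive the
lesion flag. Lorentzian (not Voigt) lineshapes are used deliberately: the
classifiers need shape variation, not quantitative fidelity.

*Artifacts* are applied in a fixed order: circular frequency shift (rounded
to the grid), linewidth broadening by convolution with a unit-area Lorentzian
kernel (Lorentzian widths add, so a kernel of (factor−1) × nominal width
scales a nominal peak's FWHM by the factor), lipid contamination (broad
resonance at 1.3 ppm entering the window at its 1.4 ppm edge), a
residual-water tail (broad resonance at 4.7 ppm entering at the 4.1 ppm
edge, monotone inside the window), and additive Gaussian noise.

*Labels.* Each voxel has four signed criterion severities — SNR, effective
linewidth, lipid ratio, water-tail ratio — normalized so 0 is exactly the
quality threshold (defaults: SNR ≥ 8, linewidth ≤ 0.07 ppm, lipid ≤ 1.2 and
water ≤ 1.5 relative to the reference peak height). Truth is "bad" iff any
severity is positive. Simulated raters report the severity sign outside a
±0.05 dead band; inside the band the spectrum is genuinely ambiguous and each
rater draws an independent biased coin whose bias is calibrated so the
consensus bad-fraction matches the configured target. On top, verdicts flip
with probability `rater_noise` decaying with distance from the threshold,
emulating rater disagreement on borderline spectra. `severity_separation`
scales the class margins: at 1 the classes are cleanly separable by
thresholding the severity score; at 0 every voxel sits at the threshold
(up to sub-band jitter), labels are pure calibrated coin flips independent of
the spectral content, and any classifier must score at chance. This dead-band
construction is what lets the generator honor the target class balance *and*
label-independence simultaneously at zero separation — a deterministic
threshold label could not do both.

Seeding is hierarchical (`SeedSequence` children per subject, grandchildren
per voxel), so cohorts are bit-reproducible and subjects can be regenerated
independently.

What the generator does **not** emulate: J-coupling multiplets, baseline roll
from macromolecules, B1 inhomogeneity, chemical-shift misregistration, and
spatial correlation between neighboring voxels. Passing tests on synthetic
cohorts therefore demonstrate that the pipeline is correct and that the
models can learn artifact signatures of this kind — not that the reported
clinical-data accuracies transfer.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: the separable-cohort sweep
uses 12 tag-balanced subjects × 100 voxels with a 3-fold rotation at 5
epochs (12 is the smallest tag-balanced size supporting 3 without-replacement
repeats); the at-chance check uses 10 subjects × 400 voxels with a single
grouped split leaving 2,000 test voxels; label-balance checks use a
40 × 419-voxel cohort. Network arithmetic is float32 with float64 metric
and softmax-loss reductions; forests and split plans are integer-seeded, so
reruns are bit-identical, while network probabilities are reproducible to
well below 1e-5 across reruns on one platform. Max pooling drops a trailing
odd point; convolutions use zero same-padding; ties in ROC ranking receive
half credit, and tied PR scores are processed as one group.

## Known limitations

* The NumPy network engine is single-threaded BLAS at heart; it is sized for
  hundreds-to-thousands of voxels, not for large-scale hyperparameter
  sweeps (which are out of scope).
* Exact kernel sizes and channel counts of the reference architectures are
  not fixed by the layer-count contracts; the defaults here are conventional
  choices and are all exposed in `ModelSpec`.
* Hybrid and forest models have no attribution path (no gradients); tree
  importances are deliberately not offered as a substitute.
* The simulator's rater model is a stylized mechanism for producing
  consensus labels with controllable noise and balance; its thresholds are
  simulator parameters, not claims about how clinical raters weight criteria.
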