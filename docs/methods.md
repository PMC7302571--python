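# Methods

This note documents the model, the numerical choices, and the synthetic
data the package is validated on — including what passing tests do and
do not establish about real field spectra.

## Problem and data model

A female mosquito's NIR absorbance spectrum is a smooth, highly
collinear curve over ~350–2500 nm sampled at 1 nm. Parity (parous = 1,
nulliparous = 0) correlates with subtle compositional differences
(lipid reserves, cuticular changes) that perturb a few absorption bands
by small amounts; there is no single diagnostic wavelength. Field
collections are small and imbalanced — parous specimens are the scarce
class — so a classifier facing 1851 raw features overfits easily. The
package's central device is unsupervised feature reduction (a stacked
autoencoder) before supervised training.

## Pipeline stages

**Windowing.** The analysis window is 500–2350 nm inclusive, 1851
points. Only the count is fixed by the protocol; the bounds are
configurable (`PreprocessSpec`). Replicate scans sharing a sample id
are averaged (policy `"forbid"` available). Windowing + replicate
merging is idempotent.

**Scaling.** Per-wavelength min–max to [0, 1], fitted on the training
partition only; test values are clipped into [0, 1]; a constant
training feature maps to 0. Logistic encoder units need bounded inputs,
and train-only fitting avoids leaking the test range. `fit_scaler`
refuses a dataset tagged as a test partition unless explicitly
overridden.

**Stacked autoencoder.** Default step dimensions (256, 64, 10),
geometric spacing between the 1851-point input and the 10-dimensional
target. Greedy layer-wise training: step *i* reconstructs the codes of
step *i − 1*. Encoder units are logistic, decoder outputs linear
(reconstruction targets need not be bounded); both configurable —
linear/linear steps make a single step a PCA-equivalent problem, which
the tests exploit as an optimality oracle. Weights initialise
uniform(−0.1, 0.1) from a per-step seeded generator; encoders and
decoders are untied. `step_mse[i]` is the MSE of reconstructing the
original training matrix through steps 1..*i* (encode down, decode
back), the per-step reconstruction-accuracy report.

*Optimiser.* Full-batch gradient descent with momentum 0.9 and a
multiplicative step-size adaptation: an epoch that increases the loss
is rolled back (velocity zeroed) and the rate halved; an accepted epoch
grows the rate by 2 %. This removes per-problem learning-rate tuning,
guarantees a monotone non-increasing loss trace, and is deterministic
from the seed. Levenberg–Marquardt is not used here: with an 1851-wide
layer the Jacobian would have millions of columns. Default epoch budget
1000 per step.

**Classifier.** One hidden layer, ten logistic units, logistic output;
score > 0.5 (strict) ⇒ parous, so a tie at exactly 0.5 is called
nulliparous. Weights initialise uniform(−0.5, 0.5)/√fan-in, seeded.
Training is exact Levenberg–Marquardt on the per-sample residuals with
the full N × P Jacobian assembled by backpropagation (P = 121 on
10-dimensional codes; raw-spectrum training is supported but slow,
P ≈ 18.5 k). Damping starts at 1e−3, ×10 on rejection, ×0.1 on
acceptance, bounded to [1e−12, 1e12]; stopping is the first of
max-iterations (200), gradient infinity-norm < 1e−7, or accepted MSE
improvement < 1e−9. Accepted steps never increase the SSE by
construction; the trace (SSE, μ, accept flag per iteration) is
returned. No internal validation split or early stopping: the 75/25
protocol reserves all held-out data for testing.

**Evaluation.** Splits are uniform random, unstratified (the protocol
randomises the merged dataset), train size = floor(0.75 N); a
stratified option exists but is off by default. Monte-Carlo CV runs ten
repeats with child seed = base seed + repeat index; each repeat fits
scaler, autoencoder and classifier on its own training partition
(leakage mode `"repeat-internal"`). The alternative
`"paper-faithful"` mode fits scaler + autoencoder once on the full
dataset before splitting — the encode-then-split ordering some studies
use — and is kept for comparison, not as the default, because it leaks
unsupervised statistics. Summaries are mean ± sample (n−1) sd across
repeats. Precision is reported as undefined (None) when nothing is
predicted parous, never as 0. ROC sweeps thresholds over distinct
score values; grouping ties makes the trapezoidal AUC equal the
pairwise-concordance statistic with ties worth ½ (property-tested
exhaustively at small n). Cross-cohort evaluation fits everything on
the full training cohort and applies that cohort's scaler + encoder to
the test cohort — the only deployable choice.

## Synthetic data

`generate` emulates: per-sample smooth continuum (quadratic in
normalised wavelength, coefficients jittered per sample), twelve fixed
Gaussian absorption bands at plausible NIR positions with ±5 % depth
jitter, three of which carry the class effect (parous depth ×
(1 + effect_size)), additive Gaussian noise (sd 0.01), absorbance kept
in 0–2. Class imbalance, cohort shift (constant baseline offset plus a
rigid band-centre displacement) and all sizes are knobs; presets cover
a balanced separable draw (400 samples, effect 2), a zero-effect null,
and a 119:21 imbalanced field profile. effect_size = 0 makes classes
exchangeable by construction.

What this does **not** model: instrument line-shape and detector
seams, scatter effects, humidity/temperature drift, within-class
biological heterogeneity beyond band-depth jitter, or any real
relationship between parity and specific wavelengths. Passing tests
therefore demonstrate that the pipeline recovers a weak multivariate
band signal from smooth correlated spectra at realistic sample sizes
and imbalance — not that any particular field accuracy will be
attained.

## Problem sizes used in the shipped experiments

The default autoencoder budget is 1000 epochs/step. The shipped
end-to-end experiments (acceptance tests and `scripts/acceptance.py`)
use the default (256, 64, 10) stack at 300 epochs/step, where training
on ~300-sample cohorts is converged (step MSEs plateau near 3 × 10⁻³);
the linear-autoencoder optimality check uses 20 000 epochs on a 200 × 50
problem; contract/plumbing tests use deliberately tiny stacks
((32, 10), a few epochs) where only shapes and determinism matter.

## Numerical notes and edge cases

- Logistic functions are evaluated in the numerically stable split form;
  scores are strictly inside (0, 1) for finite inputs.
- The LM normal matrix is solved by dense `solve`; on singularity the
  damping is raised and, if the matrix is still singular at μ = 1e12,
  training aborts with diagnostics rather than silently regularising.
- Non-finite losses abort with diagnostics (`TrainingDivergedError`);
  NaN inputs are rejected up front.
- Min–max scaling of a constant feature yields 0, never a division by
  zero.
- CSV round-trips are bit-exact (shortest-repr floats); model bundles
  are JSON with sorted keys, so serialise → deserialise → serialise is
  byte-identical.
- Replicate scans may share a sample id before preprocessing; ids are
  unique afterwards. Replicates disagreeing on label or cohort are an
  error, not a silent merge.

## Known limitations

- Levenberg–Marquardt on raw 1851-point spectra is supported but slow
  (explicit N × 18 531 Jacobian); the encoded pipeline is the intended
  path.
- The stacked autoencoder is trained greedily only; no end-to-end
  fine-tuning of the unrolled stack.
- No scatter correction, derivatives or smoothing are applied — the
  modelled protocol does not use them — so spectra preprocessed by
  other conventions should be converted before use.
- AUC is omitted (not extrapolated) for single-class test cohorts.
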