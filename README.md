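# nirparity

Estimating the **parity status** of wild female mosquitoes — parous (has
laid eggs at least once) versus nulliparous (never) — from near-infrared
spectra. Parity is a proxy for age and potential infectiousness, so the
parity structure of an *Anopheles* population is a key indicator when
evaluating malaria interventions. The reference method, ovary dissection,
is slow and needs rare expertise; near-infrared spectroscopy (NIRS) scans
hundreds of mosquitoes a day, and this package provides the chemometric
model that turns a scan into a parity call.

## Method

Each mosquito yields one absorbance spectrum on a 1 nm grid over roughly
350–2500 nm. The pipeline is:

1. **Preprocessing** — window the spectrum to the analysis range
   (500–2350 nm inclusive → **1851 features**), average replicate scans,
   and min–max scale each wavelength to [0, 1] using statistics from the
   training partition only.
2. **Stepwise stacked autoencoder** — compress 1851 → 256 → 64 → **10**
   features by greedy layer-wise training: each step is a single-hidden-
   layer autoencoder (logistic encoder, linear decoder) trained to
   reconstruct the previous step's codes, minimising reconstruction MSE.
   Compressing the feature space shrinks the hypothesis space a classifier
   must learn, which matters because parous field specimens are scarce
   and classes are badly imbalanced.
3. **Classifier** — a one-hidden-layer, ten-neuron feed-forward network
   with logistic activations, producing a parity score in (0, 1);
   score > 0.5 ⇒ parous. It is trained by **Levenberg–Marquardt**
   optimisation on the squared residuals *e = y − f(x)*:

   (JᵀJ + μI) δ = Jᵀe

   with J the residual Jacobian assembled by backpropagation and the
   damping μ adapted by step acceptance.
4. **Evaluation** — ten-repeat Monte-Carlo cross-validation (random
   75/25 splits), confusion matrices, sensitivity = TP/P,
   specificity = TN/N, accuracy = (TP+TN)/(P+N), precision = TP/(TP+FP),
   and ROC/AUC by threshold sweep (the trapezoidal area equals the
   pairwise-concordance statistic). Cross-cohort testing trains on one
   collection site and tests on another, re-using the training cohort's
   scaler and encoder.

A synthetic generator produces labeled NIR-like spectra (smooth
continuum + Gaussian absorption bands + noise) with tunable class effect,
imbalance and cohort shift, so the whole pipeline is testable without
field data.

## Worked example

```bash
nirparity simulate --preset separable --seed 1 --out separable.csv
nirparity evaluate separable.csv --report-out report.json \
    --epochs 300 --repeats 10 --seed 1
```

The evaluate command logs

```
evaluate separable.csv: accuracy 100.0 ± 0.0 % over 10 repeats (186.85s)
```

and `report.json` contains one record per repeat (confusion counts plus
the four metrics and AUC, all on the held-out 25 %) and a mean ± sd
summary. On this strongly separable synthetic preset (400 samples,
effect size 2) every repeat classifies the held-out quarter perfectly;
with `--preset null` (no class effect) mean accuracy stays at chance —
the pipeline does not hallucinate signal. Real field cohorts sit in
between: expect accuracy in the 90s with the encoder versus the 70–80s
without it, with the gap widest for small, imbalanced cohorts.

The same workflow runs from Python via `nirparity.generate`,
`nirparity.monte_carlo_cv` and friends; trained pipelines round-trip
through portable JSON bundles (`nirparity train` / `nirparity predict`).

Spectral tables are plain CSV with a header of `id[,label][,cohort]`
followed by wavelength columns named in nm; labels are coded
0 = nulliparous, 1 = parous (the words are accepted as aliases on read).

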