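# pdcr — sparse primal-dual classification with rejection

`pdcr` is a Python library (with a thin CLI) for supervised
classification and feature selection on LC-MS feature tables —
sample-by-feature intensity matrices from untargeted metabolomics or
proteomics, where the number of features (thousands of m/z × retention
time peaks) dwarfs the number of samples, features come in highly
correlated adduct/isotopologue blocks, and clinicians want to know not
just the predicted class but how much to trust each call.

## The model

Given an autoscaled data matrix `X (m × d)` and one-hot labels
`Y (m × k)`, training jointly learns a sparse projection `W (d × k)`
and a centroid matrix `μ (k × k)` by solving

```
min_{W, μ}  h_δ(Yμ − XW) + (ρ/2) ‖I_k − μ‖_F²   s.t.  ‖W‖₁ ≤ η
```

where `h_δ` is the Huber function (quadratic for |t| ≤ δ, linear
beyond — robust to outlier samples), `‖W‖₁` is the entrywise sum of
absolute values (the constraint that zeroes out uninformative feature
rows), and the ridge on `μ` anchors the centroids near the identity so
the trivial solution is excluded. The problem is convex and is solved
with a Chambolle–Pock primal-dual splitting whose three proximal steps
(clipped shrinkage for the Huber conjugate, exact sort-based projection
onto the ℓ1 ball, closed-form quadratic step for `μ`) are each
independently tested against oracles.

A new sample `x` is assigned to the class `j* = argmin_j ‖μ_j − xW‖₁`,
with a confidence score for the prediction (CSP)

```
ρ(x) = (d₁ − d₂) / (d₁ + d₂)            (binary, in [−1, 1])
ρ(x) = 1 − k · min_j d_j / Σ_j d_j      (k > 2 classes, in [0, 1])
```

Calls with |CSP| below a threshold ε are *rejected* ("I don't know"),
which lowers the misclassification load FDR = (errors among accepted) /
(all samples) at the price of a rejection rate RRS. Feature importance
is read directly off `W`: `score_f = Σ_j |W[f, j]|`.

Only `η` normally needs tuning — it sets how many features survive.

## Worked example

```python
import numpy as np, pdcr

table, truth = pdcr.generate(pdcr.SyntheticSpec(
    m=40, d=80, s=3, log2_fold_change=3.0, dropout_prob=0.0, seed=0))
model = pdcr.fit(table, truth.labels, pdcr.SolverConfig(eta=3.0))
for r, t in list(zip(pdcr.predict(model, table), truth.labels.labels))[:3]:
    print(r.sample_id, t, r.predicted_label, round(r.csp, 2))
```

prints

```
S0000 class1 class1 -0.99
S0001 class1 class1 -0.99
S0002 class2 class2 0.99
```

43 of the 80 feature rows of `W` are nonzero (the ℓ1 budget η = 3
discarded the rest), every training sample lands on the correct side,
and |CSP| ≈ 1 means each projected sample sits essentially on top of
one centroid. The scripts in `examples/` walk through the other
capabilities — feature ranking (`02`), the stratified 4-fold
cross-validation protocol (`03`) and the rejection curve (`04`), which
on held-out synthetic data prints

```
  eps    FDR    RRS
 0.00  0.040  0.000
 0.10  0.000  0.080
```

i.e. rejecting the 8% least-confident calls removes all 4% of errors.

## Command line

```bash
pdcr simulate --out sim --m 100 --d 1000 --seed 0
pdcr fit --data sim_data.csv --labels sim_labels.csv --model model.json \
         --eta 5 --pseudocount auto
pdcr predict --data sim_data.csv --model model.json --out pred.csv --epsilon 0.2
pdcr cv --data sim_data.csv --labels sim_labels.csv --out cv.json --folds 4
pdcr curve --data sim_data.csv --labels sim_labels.csv --model model.json \
         --out curve.csv
```

Input tables are CSV with a header of feature names and a first column
of sample ids (`--orientation features-rows` for the transposed
layout); labels are two-column CSV (`sample_id,label`). Models are
human-inspectable JSON (the weights in `W` are a headline output).

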