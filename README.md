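# icdep — residual dependencies of spatial ICA components in fMRI

Spatial independent component analysis (ICA) decomposes an fMRI sequence
x(ν) = A s(ν) into spatial maps s_i (random variables over voxels ν) mixed
by time courses (the columns of A = W⁻¹).  Because the model order n must be
chosen in advance, overestimating it can *split* one true activation source
across several components — and the offspring components then retain
residual statistical dependence on each other.

`icdep` turns that residue into a diagnostic.  For every component pair it
estimates the **variation of information**

    D(s_i, s_j) = H(s_i, s_j) − I(s_i, s_j)

(H joint entropy, I mutual information; natural log, values in nats), which
unlike I itself is a true metric on random variables.  Components are then
clustered agglomeratively with the **Ward criterion** (merging the pair that
least increases the within-cluster error sum of squares); components that
were split off the same source merge low in the dendrogram, below any merge
with components of other sources.

Two D estimators are provided and can be compared:

* **histogram** — rank-order each map (adaptive partitioning; makes the
  marginals uniform and the result invariant to monotone transforms), bin
  into M = round(1 + log₂ N) equal-population bins per axis, and plug the
  joint frequency table into the entropy sums;
* **kde** — Gaussian kernel density estimates at the Silverman bandwidths
  h = 1.06 σ N^(−1/5) (marginals) and h = σ N^(−1/6) (joint, isotropic),
  integrated by adaptive Simpson quadrature.

Validation runs on simulated single-slice block-design datasets with known
ground truth: two non-overlapping ~2 cm ROIs (3 mm FWHM smoothed), a
gamma-variate HRF h(t) = k·t^8.60·e^(−t/0.547), 15 s ON / 15 s OFF blocks,
TR = 3 s, 60 scans, 2 % peak signal change, and i.i.d. Gaussian noise at
σ ∈ {0.33, 0.66, 1.00, 1.33} % of the mean baseline (CNR ≈ 6, 3, 2, 1.5).
Component maps are scored by ROC/AUC against the ROI masks and labelled
consistently (CTR) or transiently (TTR) task-related from their time-course
correlation ρ with the expected hemodynamic response.  It is aimed at
methods researchers studying model-order selection and component stability
in exploratory fMRI analysis.

## Worked example

A splitting regime: noise σ = 0.66 %, 2.5 s delay between the two ROIs'
activations, model order 10 (deliberately above the effective dimension).

```python
from icdep import ResidualDependenceICA, config_for_cell

model = ResidualDependenceICA.from_simulation(
    config_for_cell(delay=2.5, noise_sigma=0.0066, seed=1047097653),
    model_order=10,
    distance_methods=("histogram",),
)
res = model.fit(seed=1047097653)
print(res.summary())
```

```
Residual-dependency ICA results
=============================================
scans: 60    in-mask voxels: 1640
model order: 10    seed: 1047097653
FastICA attempts: 2 (iterations: [1000, 277])
distance estimators: histogram

 IC    rho label  AUC_ROI1  AUC_ROI2 assigned
  0  0.013 other     0.540     0.551
  1  0.974   CTR     1.000     0.987      1,2
  2  0.028 other     0.539     0.571
  3 -0.287 other     0.153     0.115
  4  0.022 other     0.455     0.494
  5  0.303   TTR     0.607     1.000      1,2
  6  0.018 other     0.504     0.524
  7 -0.019 other     0.430     0.406
  8  0.101 other     0.504     0.391
  9  0.044 other     0.435     0.540

[histogram] merge heights: first=11.0967 last=12.7058 (nats^2/2 scale)
[histogram] split ROIs [1, 2]: same-ROI components merge before cross-ROI task components
```

Reading this: the activation is split across two task-related components —
IC 1 (CTR, ρ = 0.97) and IC 5 (TTR, ρ = 0.30) — each scoring AUC > 0.6 on
both ROIs, while the remaining eight components are noise (ρ ≈ 0,
chance-level AUC).  The merge report shows the split components joined at
the lowest dendrogram level (first merge height 11.10) before any other
component reached them — the residual dependence between the offspring of
one source is visible to the MI metric.  `res.plot_dendrogram()` draws the
tree; `res.distances["histogram"]` holds the D matrix.

The same machinery runs from the shell: `icdep simulate`, `icdep decompose`,
`icdep distances`, `icdep cluster`, `icdep evaluate`, and
`icdep run-all --out DIR` for the full 3 delays × 4 noise levels × 4 model
orders experiment grid.

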