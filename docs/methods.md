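# Methods

## The problem and the model

A spatial ICA of an fMRI run treats each scan as one random variable
observed over voxels and seeks maps s̃_i = w_iᵀ x that are maximally
independent; the time course of map i is the i-th column of the inverse
unmixing matrix.  Independence is only ever approximate — noise, finite
samples, and a mis-chosen model order all leave residual dependence between
the estimated components.  This package quantifies that residue with the
variation of information D = H − I and clusters the components with Ward's
criterion, to test a specific hypothesis: components produced by *splitting*
one source (model-order overestimation) are more mutually dependent than
unrelated components, and therefore merge earliest in the dendrogram.

## Simulated data

The generator emulates a single-slice block-design acquisition:

* **Baseline.** A synthetic 2D "brain": a 64 × 64 elliptical phantom
  (semi-axes 20 × 26 voxels) with a smooth radial intensity profile
  (1000·(1 − 0.4ρ²) inside, 0 outside) and its ellipse as the in-brain mask
  (N = 1640 voxels).  A user-supplied baseline image can replace it.  The
  phantom is deliberately structureless; real grey/white/CSF contrast is not
  modelled.
* **Task.** 15 s ON / 15 s OFF boxcar (starting ON at t = 0), 180 s total,
  TR = 3 s → 60 scans.  The response is the boxcar convolved with the
  gamma-variate HRF h(t) = k·t^8.60·e^(−t/0.547)·u(t) (shape 8.60
  dimensionless, scale 0.547 s, peak at shape·scale ≈ 4.7 s).  h is
  normalised to unit peak; its amplitude constant k is absorbed into the
  per-ROI peak signal change, since only the product is identifiable.
  Time courses are built on a 0.25 s supersampled grid so the sub-TR
  activation delays (1.25, 2.5, 5 s between the two ROIs) are represented
  exactly, then sampled at TR.
* **ROIs.** Two discs of 20 mm diameter (voxel size 3.75 mm, i.e. a 240 mm
  field of view over a 64 matrix), placed symmetrically at (32, 21) and
  (32, 43) so both see the same baseline; each disc is smoothed with a 2D
  Gaussian of 3 mm FWHM (σ = FWHM/2.3548 ≈ 0.34 voxel) and renormalised to
  unit peak.  The supports stay disjoint (asserted).  ROI #1 activates at
  t = 0, ROI #2 after the configured delay.
* **Signal and noise.** data(v,t) = baseline(v)·(1 + Σ_r 0.02·m_r(v)·tc_r(t))
  + ε(v,t), with ε i.i.d. Gaussian, σ = noise_sigma × mean in-mask baseline,
  noise_sigma ∈ {0.33, 0.66, 1.00, 1.33} % → CNR = ΔS/σ ≈ 6, 3, 2, 1.5.
  One master seed feeds named substreams (noise, ICA initialisation), so a
  configuration is bit-reproducible.

Not modelled: physiological noise, motion, temporal autocorrelation,
multi-subject variability, 3D geometry.  Consequences for interpretation are
discussed under "What the simulations show" below.

## ICA stage

Centering removes the spatial mean of each image — each variable's mean over
its observations — and nothing else.  The static baseline pattern therefore
stays in the data and, together with the task-locked fluctuation of the
spatial mean, is absorbed by one component whose map mirrors the overall
intensity distribution and has a flat (sub-Gaussian) histogram; it appears
at every model order and is a known artefact of this centering convention,
reported by the labelling stage but excluded from merge scoring.

PCA reduces to the requested model order n (5, 10, 15 or 20 in the study
grid) and whitens; symmetric (parallel) FastICA with the tanh contrast
(scikit-learn's implementation, fun="logcosh", on our whitened rows) then
estimates the rotation.  Symmetric rather than deflationary updates avoid
order-dependent error accumulation.  Defaults: tol 1e-4, max 1000
iterations, 5 restarts from fresh random initialisations (seeded).  When two
sources are nearly identical — activation delay 1.25 s makes the two ROI
time courses correlate above 0.99 — the fixed point genuinely has no stable
solution at this tolerance; after exhausting restarts the last orthonormal
rotation is returned with a warning and a `converged: False` flag rather
than an exception, because the short-delay third of the experiment grid
lives in exactly this regime (`on_failure="raise"` restores strictness).
Each map is sign-flipped to non-negative skewness for stable display; every
quantitative step downstream is sign-invariant (asserted by tests).

## Distance estimation

D(s_i, s_j) = H(s_i, s_j) − I(s_i, s_j), natural logarithm, computed over
in-mask voxels.  D is a metric on (equivalence classes of) random variables,
which the histogram path inherits up to estimation error; metric axioms are
verified against exact small-alphabet joints in the tests.

**Histogram path.**  Maps are rank-transformed (average ranks on ties), then
binned into M = round(1 + log₂ N) equal-population bins per axis (on ranks,
quantile bins equal equal-width bins up to ties; N = 1640 gives M = 12).
H and I are plug-in sums with 0·log 0 = 0.  Rank ordering makes the estimate
exactly invariant to monotone transforms of either map, so raw maps and
z maps give identical distances.

**KDE path.**  Maps are standardised (so σ = 1 in the bandwidth rules);
marginal densities use h₁ = 1.06·N^(−1/5), the joint density an isotropic
h₂ = N^(−1/6) (the d = 2 Silverman rule's prefactor (4/(d+2))^(1/(d+4)) is
exactly 1).  H and I are integrals of the Gaussian-mixture densities,
evaluated by an adaptive Simpson rule: intervals are bisected until the
local Richardson estimate meets a length-proportional share of the absolute
tolerance (1e-6 by default), with both integrands sharing one grid, batched
evaluation of pending midpoints, and the 2D integral as a nested adaptive
rule whose inner tolerance is scaled so the total error stays within budget.
Integration runs over the data range padded by 5 bandwidths; a 1e-12 floor
inside the logarithms avoids −∞; exhausting the depth or evaluation budget
raises a diagnostic error.  Small negative I or D from quadrature are
clamped to zero with a warning.

Two estimator properties worth knowing, both asserted in the tests:

* the KDE plug-in estimate converges to the MI of the *kernel-smoothed*
  distribution, not of the raw one.  For a bivariate Gaussian the limit is
  available in closed form, and at N = 2000 and ρ = 0.9 it sits ≈ 0.23 nats
  below the true −½ln(1−ρ²); the histogram estimate is within ≈ 0.07 nats
  there.  The often-quoted better convergence of KDE density estimates does
  not transfer to the MI functional at these rule-of-thumb bandwidths.
* the KDE self-distance D(x, x) has a finite-bandwidth floor
  (≈ 2·ln(h√(2πe)) + marginal corrections ≈ 0.96 at N = 2000) that shrinks
  with N; the diagonal of a distance matrix is therefore zero by definition,
  not by quadrature.

## Clustering

Ward's criterion merges, at each step, the cluster pair whose union least
increases the within-cluster error sum of squares, ESS(C) = Σ‖x − m_C‖².
Without a coordinate embedding for the MI distances, the matrix entries are
treated as Euclidean distances and propagated with the Lance–Williams
recurrence for Ward on squared distances — the universal convention for
"Ward on a precomputed distance matrix".  Distances enter as given (not
re-squared; recorded in the provenance sidecar).  Reported merge heights are
the pseudo-ESS increments d²/2 (two singletons at distance d cost exactly
d²/2), which are non-decreasing, so the tree renders directly.  Ties are
broken toward the lexicographically smallest cluster-index pair, making the
output deterministic.  The implementation is cross-checked in the tests
against scipy's Ward linkage and against a brute force that re-evaluates ESS
from coordinates on small Euclidean instances.

## Evaluation

* **ROC/AUC.**  Component z maps (z = (s−m)/σ over the mask) are scored
  against each ROI by sweeping thresholds on |z| (absolute value, because IC
  sign is arbitrary); truth voxels are those with smoothed-mask weight
  > 0.5, the half-maximum convention.  AUC > 0.6 assigns a component to a
  ROI (0.6–0.7 is conventionally "poor", 0.7–0.8 "fair" accuracy).
* **CTR/TTR.**  ρ = Pearson correlation of the component time course with
  the zero-delay expected response (boxcar ⊛ HRF).  |ρ| ≥ 0.6 → CTR,
  0.3 ≤ |ρ| < 0.6 → TTR, else "other"; the cutoffs bracket typical reported
  CTR (≈ 0.7–0.9) and TTR (≈ 0.4–0.6) values and are configurable.  Note a
  ROI delayed by 5 s lands in the TTR band by construction.
* **Split-merge assessment.**  For each ROI to which ≥ 2 *task* components
  (CTR or TTR) are assigned, the maximum within-group cophenetic distance is
  compared with the minimum cophenetic distance to any task component
  assigned to a different ROI (and not to this one).  Restricting to task
  components matters: noise components incidentally crossing AUC 0.6 with
  ρ ≈ 0 would otherwise contaminate the groups.  With no split ROI the
  verdict is vacuously true and flagged.
* **GLM comparator.**  Mass-univariate OLS of intercept + expected response
  (the best linear unbiased estimator under i.i.d. Gaussian errors), t test
  of zero slope with T − 2 df; |t| ≥ 2.6 ≈ uncorrected p < 0.01.  Standard
  errors are floored at numerical scale so noise-free simulated voxels yield
  a large capped t instead of 0/0.

## What the simulations show — and do not

The split-merge property replicates robustly: in the splitting regime
(e.g. σ = 0.66 %, delay 2.5 s, order 10) the same-source components merge
first in every split run we observe, for both estimators.  Detection
degrades with noise, and at delay 1.25 s with σ > 0.33 % single components
span both ROIs, as expected when the two time courses are nearly collinear.

Two quantitative caveats.  First, with the stated generative parameters
(CNR 6, 60 scans) and the half-maximum truth convention, the best
component's AUC at low noise saturates near 1.0 — detection of the core ROI
voxels is essentially perfect, and any lower published figure implies a more
permissive truth region (scoring against the *full* smoothed support instead
yields ≈ 0.72–0.75, because the far smoothing tail is undetectable at any
noise level).  AUC levels are therefore convention-dependent in a way the
qualitative conclusions are not.  Second, the KDE estimator's bandwidth bias
(above) makes its absolute MI values sit below the histogram's at strong
dependence; comparisons *between* component pairs, which is all the
clustering consumes, are unaffected in our runs.

Passing these simulations does not establish performance on real data: the
phantom lacks anatomical structure and physiological noise, all sources are
exactly disjoint discs with identical (delayed) time courses, and noise is
white.  Real-data use should treat the dendrogram as exploratory, and the
choice of a cut level is deliberately left open.

## Problem sizes and defaults

Tests and the acceptance script use the study's native sizes throughout —
64 × 64 single slice (1640 in-mask voxels), 60 scans, model orders 5–20,
10 seeded replicates per reported cell; a full single run (simulate → ICA →
both distance matrices → Ward → evaluation) takes a few seconds, dominated
by the KDE quadrature (≈ 0.1 s per component pair).
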