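# Methods

## Data model

A spectral CT volume is a 4D array of Hounsfield units indexed
(i₁, i₂, i₃, e), with a strictly increasing energy axis in keV. For
analysis it is flattened to n observations {vᵢ, x, yᵢ}: vᵢ the voxel's
3D coordinates, x the shared m-point energy grid, yᵢ the voxel's decay
curve. Coordinates are 0-based voxel indices cast to reals; physical
spacing is carried as metadata but not applied, because the spatial
shrinkage scale λ (below) interacts with the coordinate scale and its
default was calibrated on index-scale coordinates. Curves with NaN values
are rejected at load time rather than imputed. Air voxels are masked out
before clustering by thresholding the 65 keV image (the virtual
monochromatic image closest to a conventional CT) at −500 HU; both
threshold and reference energy are configurable.

## Functional basis

Curves are represented on a shared design matrix B(x) of size m×r:
monomials of degree p (r = p+1) or a clamped B-spline basis of degree p
with q equally spaced interior knots (r = p+q+1) on the affinely
normalized energy range [0, 1]. The default is a cubic B-spline with
q = 4 (r = 8 for m = 21): enough flexibility for the smooth, monotone-ish
decay shapes seen in tissue while keeping r ≪ m. Clamped knots make the
basis a partition of unity, so constants lie in its span — used to undo
internal HU standardization exactly. Least-squares solves use
`numpy.linalg.lstsq` (SVD), never explicit normal-equation inverses.

## Mixture models

Four variants share the same structure: mixture weights are *spatial
gates* πₖ(v) and components describe the spectral content.

One-stage functional models:
* **SgMFR** — Gaussian gates πₖ(v) ∝ wₖ φ₃(v; μₖ, Rₖ) with functional
  Gaussian regression components φₘ(y; Bβₖ, σₖ²I). EM maximizes the joint
  log-likelihood of (v, y); all M-steps are closed-form: the gate update
  is the weighted-GMM step (responsibility-weighted weights, means,
  scatters), the regression update is responsibility-weighted least
  squares for βₖ and the weighted mean squared residual (denominator
  m·Σᵢτᵢₖ) for σₖ².
* **SsMFR** — softmax gates over v augmented with an intercept. The gate
  M-step has no closed form; a damped Newton–Raphson (IRLS) inner loop
  (max 10 iterations, gradient tolerance 1e−6, step-halving to force
  ascent) maximizes the weighted multinomial-logistic likelihood. EM then
  maximizes the *conditional* likelihood of y given v; the softmax update
  only ascends its Q-term, so the fit is a generalized EM. The intercept
  is on by default (gates through the origin are severely restricted
  without one) and can be disabled.

Two-fold vectorized models (**SgMVFR**, **SsMVFR**): stage 1 projects
every curve onto the basis by OLS; stage 2 clusters the coefficient
vectors β̂ᵢ with the same spatial gates and full-covariance multivariate
Gaussian components φ_r(β̂; mₖ, Cₖ), whose M-steps are the classical
weighted mean and scatter. No standardization is applied to coefficient
vectors — the full covariances absorb scale.

The two gate families report objectives on different scales (joint vs
conditional); `FitResult.objective` records which one the trace holds, and
the traces must never be compared across gate families.

## Spatial-covariance shrinkage λ

At every Gaussian-gate M-step the spatial covariance is replaced by
R̃ₖ = λRₖ, λ ∈ (0, 1], then floored (add ε·tr(R̃)/3·I, ε = 1e−6) to stay
positive definite. Since det(λR) = λ³ det(R), λ directly scales the
spatial volume a cluster claims: small λ forces compact clusters
(appropriate for tumors), λ = 1 recovers plain maximum likelihood.
Default λ = 0.075. Because λ < 1 replaces the M-step maximizer with a
shrunk estimate, the strict EM monotonicity guarantee holds only at
λ = 1; empirically the trace at λ = 0.075 is still monotone to ~1e−13
relative on phantom fits, but ascent tests are run at λ = 1 where the
guarantee is exact. λ applies identically in the vectorized models, which
reuse the same gate update.

## Numerical choices

* All gate and component densities are evaluated in log space with
  log-sum-exp normalization; gate evaluations return exact row-stochastic
  matrices.
* HU curves are standardized to zero mean / unit variance inside
  `fit` (option `standardize`, default on) and the parameters and
  log-likelihood are mapped back exactly afterwards (constants are in the
  basis span; the Jacobian adds −n·m·log s to the objective). The σ²
  floor of 1e−8 lives on the standardized scale.
* Convergence: relative objective change below 1e−6 (default), max 500
  iterations.
* Empty-cluster policy: a component whose total responsibility falls
  below r+1 is pruned, responsibilities renormalized, and the fit
  continues with `active_K` decremented (softmax gates can exhibit
  vanishing clusters; pruning keeps the remaining problem identified).
  Pruning the softmax reference class re-references the gate by
  subtracting the last remaining class's coefficients.
* Covariance floors: gates ε·tr/3·I, vectorized components ε·tr/r·I
  (ε = 1e−6); degenerate zero-trace scatters get an absolute ε floor.
* Bayes allocation breaks ties toward the lowest cluster index.

## Initialization and hyper-parameter search

EM starts from a Voronoi partition: seeded k-means (k-means++ with 5
restarts, all driven by one integer seed) on the spatial coordinates
only; one-hot responsibilities then drive a single M-step of the target
model. Initial clusters smaller than r+1 voxels are merged into their
nearest neighbor by centroid distance. `grid_search` fits a small (K, λ)
grid per dataset and picks, when truth masks exist, the cell maximizing
merged-tumor Dice with spatial DBt as tiebreaker, otherwise the cell
minimizing the mean of spatial and spectral Davies–Bouldin; per-dataset
optima are averaged (λ arithmetically, K by rounded mean). Note that
K values above the true cluster count can tie on Dice (merging repairs
oversplits) and win the tiebreaker — the search bounds K from below, not
exactly.

## Evaluation metrics

Davies–Bouldin: DB = (1/|C|) Σₖ max_{l≠k} (S(cₖ)+S(c_l))/d(c̄ₖ, c̄_l)
with S the mean Euclidean distance to the cluster centroid; computed on
spatial content (coordinates) and spectral content (raw m-point curves —
a model-agnostic choice valid across all variants; a coefficient-space
variant is a one-line change of features). The tumor variant DBt applies
the same ratio between the merged tumor region and every other cluster.
Dice = 2|A∩B|/(|A|+|B|), with dice(∅, ∅) = 0 by policy. Tumor clusters
are selected by greedy forward Dice maximization over clusters; the
greedy result matches an exhaustive 2^K search in ≥95% of random
instances (verified in tests) at polynomial instead of exponential cost.

## Synthetic data

Direct samplers draw (label, position, curve) triples from the generative
models: Gaussian gates sample positions from the gate mixture; softmax
gates sample positions uniformly over a box and labels from the gate
probabilities. The two-fold sampler draws coefficient vectors from the
component Gaussians and reconstructs noise-free curves Bβᵢ, so stage-1
OLS recovers exactly the assumed coefficient mixture.

The phantom generator emulates the structure of a cropped spectral VOI:
default 40×40×4 voxels × 21 energies (40–140 keV), five tissue classes —
soft tissue, fat, enhancing muscle, bone (steeply decaying ~1300→400 HU)
and a contrast-enhancing tumor — with per-voxel Gaussian HU noise
(σ = 15 HU, 25 for bone; typical soft-tissue DECT noise), a central
ellipsoidal tumor blob, optional air shell at −1000 HU, and non-tumor
regions laid out as Voronoi tiles seeded on a jittered ring around the
centre. The ring placement makes every tile a compact convex region that
a single Gaussian gate can represent, i.e. a *well-separated* phantom on
which a K = K_true fit is expected to recover the layout; fully random
seeds produce elongated wedge tiles that demand more components than
tissue classes, which is a capacity question, not a recovery question.
Tile boundaries are warped by a smooth sinusoidal displacement field
(default amplitude 2 voxels) for organ-like irregularity. Optionally each
tissue family occupies several disconnected tiles (`sites_per_family`),
mimicking tissues like bone or muscle that appear at multiple anatomical
sites.

`lambda_study_spec` defines a dedicated phantom for measuring the λ
trade-off. λ arbitrates allocation only where spatial and spectral
information disagree — near irregular boundaries between tissues whose
spectra overlap at noise level; with the default (≥4σ-separated) families
the allocation is λ-invariant and no trade-off is measurable. The λ-study
phantom therefore uses four soft-tissue families ~12 HU apart at 40 keV
(≈1σ of the per-energy noise), a moderately enhancing tumor, and strong
boundary warp. On it, small λ yields spatially tighter clusters (lower
spatial DB) and larger λ spectrally purer clusters (lower spectral DB),
monotonically over λ ∈ {0.02, 0.075, 0.3} in the mean over seeds.

What passing phantom tests does *not* show about clinical data: phantoms
have piecewise-constant true spectra with Gaussian noise, no beam
hardening, metal artifacts, partial-volume mixing, contrast-timing
variation or inter-patient anatomy variation; tissue regions are far
cleaner than real anatomy, so phantom Dice scores are upper bounds on
what the same configuration achieves clinically.

## Problem sizes

Recovery experiments use n = 3000 voxels (K = 3, 10 seeds); ascent checks
cover all four variants at K ∈ {2,3,5}, n ∈ {500, 2000}; phantom
segmentation runs the full 6400-voxel default phantom over 5 seeds. These
sizes give stable statistics while keeping the full suite around a minute
on one CPU.

## Known limitations

* Ragged curve supports (per-voxel mᵢ) are not implemented; all voxels
  share one energy grid.
* No information-criterion model selection (BIC/ICL); K is chosen by the
  Dice/DB grid search or domain knowledge.
* The softmax-gate fit maximizes a conditional objective and can prune
  aggressively on spatially diffuse data; the Gaussian-gate variants are
  the recommended default, matching their better numerical behavior.
* DICOM ingestion and VMI reconstruction are out of scope; inputs are 4D
  NIfTI volumes with a JSON energy sidecar.
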