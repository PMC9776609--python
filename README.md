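# spectclust

Unsupervised clustering of 4D dual-energy CT (DECT) volumes with spatially
gated functional mixture models, for tissue and tumor segmentation research.

A DECT scan reconstructed at many virtual monochromatic energies is a 4D
image: at each voxel *i* with 3D position **v**ᵢ, the scan provides an
*energy decay curve* — Hounsfield-unit attenuation **y**ᵢ = (y<sub>i1</sub>,
…, y<sub>im</sub>) measured at energies **x** = (x₁, …, x<sub>m</sub>)
(typically 40–140 keV in 5 keV steps, m = 21). Different tissues have
characteristically different decay curves (bone falls steeply from high HU;
contrast-enhancing tumor falls moderately; fat sits below water), and
anatomically meaningful clusters are spatially coherent. `spectclust`
models both facts at once and is aimed at researchers in quantitative CT /
radiomics who want model-based, reproducible segmentations of spectral
volumes.

## The model

Each voxel's curve is modeled by a mixture of functional Gaussian
regressions whose weights are functions of the voxel's position ("gates"):

    f(y | x, v; θ) = Σₖ πₖ(v; α) · φₘ(y; B(x) βₖ, σₖ² I)

where B(x) is an m×r polynomial or B-spline design over the energy axis and
βₖ the cluster-k curve coefficients. Two gating families are provided:

* **normalized Gaussian gates** (models `sgmfr`, `sgmvfr`):
  πₖ(v) ∝ wₖ φ₃(v; μₖ, Rₖ) — fully closed-form EM updates;
* **softmax gates** (`ssmfr`, `ssmvfr`): multinomial-logistic weights,
  updated by an inner Newton–Raphson (IRLS) loop.

The `*mvfr` variants are *two-fold*: each curve is first projected onto the
basis by OLS (β̂ᵢ), and the coefficient vectors are clustered by a spatially
gated multivariate Gaussian mixture φ_r(β̂; mₖ, Cₖ).

All four variants are fit by EM from a reproducible spatial k-means
(Voronoi) initialization, with Bayes-rule hard allocation at the end. The
spatial covariance of the Gaussian gates is shrunk each M-step by a factor
λ ∈ (0, 1] (R̃ₖ = λRₖ), which controls cluster spatial compactness: small
λ favors tight clusters (tumors), λ = 1 is the plain maximum-likelihood
update. Evaluation metrics follow standard segmentation practice:
Davies–Bouldin indices on spatial and spectral content, a tumor-focused
variant (DBt), and the Dice overlap of greedily merged tumor clusters
against a ground-truth mask.

A synthetic-phantom generator (`spectclust.synth`) produces 4D spectral
phantoms with spatially coherent tissue regions, realistic decay-curve
families, an embedded tumor blob and optional air background, plus direct
samplers from the generative models for parameter-recovery experiments.

## Worked example

```python
import numpy as np
import spectclust as sc

# a 40x40x4 voxel phantom with 21 energies (40-140 keV), 5 tissue classes
vol, tissue, tumor, true_labels = sc.make_phantom(sc.PhantomSpec(seed=0))

dataset = sc.flatten(vol, tissue)               # n=6400 voxels x m=21 energies
design = sc.build_design_matrix(dataset.energies)   # cubic B-spline, r=8

result = sc.fit(dataset, design, sc.FitConfig(K=5, lambda_reg=0.075, seed=0))
print(result.active_K, result.n_iter, result.converged)

truth = set(np.flatnonzero(tumor.values[tuple(dataset.index_map.T)]).tolist())
report = sc.metrics_report(dataset, result.labels, truth)
print(report.to_dict())
```

Output (printed by the code above):

```
5 32 True
{'Dice': 1.0, 'spat-DB': 0.9275, 'spec-DB': 0.4177, 'spat-DBt': 0.9516,
 'spec-DBt': 0.3890, 'tumor_clusters': [5], 'n_clusters': 5}
```

The fit converged in 32 EM iterations with all 5 clusters active; the
greedily selected tumor cluster covers the ground-truth blob exactly
(Dice = 1), and both Davies–Bouldin indices are low (well-separated
clusters; lower is better).

The same pipeline is available from the shell:

```sh
spectclust phantom --out phantom/
spectclust fit --volume phantom/phantom.nii.gz --config config.yaml \
    --truth phantom/tumor_mask.nii.gz --out fit/
spectclust metrics --labels fit/labels.nii.gz --volume phantom/phantom.nii.gz \
    --truth phantom/tumor_mask.nii.gz
```

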