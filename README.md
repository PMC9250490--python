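# tautraj

Image-level trajectory inference for tau-PET-like volumes.

Tau pathology in Alzheimer's disease spreads through the brain in a broadly
stereotyped spatial sequence (Braak staging: transentorhinal I–II, limbic
III–IV, isocortical V–VI), but each scan is only a cross-section of that
process. `tautraj` reconstructs the underlying continuum directly from
images: a convolutional variational autoencoder (VAE) embeds normalized 3-D
volumes into a latent space, hierarchical agglomerative clustering organizes
the embeddings into stages, a minimum spanning tree (MST) over the cluster
centers orders the stages, and each subject's latent vector is projected
onto the resulting path to yield a **pseudo-time** in [0, 100] — a
continuous, whole-image index of disease progression. Subjects whose latent
vectors sit far from the path (e.g., strongly asymmetric uptake) are flagged
as atypical, and biomarker-versus-pseudo-time profiles are fitted with
four-parameter logistic onset curves.

The package is aimed at methods researchers in neuroimaging who want a
fully testable, self-contained version of this pipeline. Because real
amyloid/tau PET cohorts are not redistributable, `tautraj` ships a
phantom-cohort simulator with a known hidden progression variable, so every
stage of the pipeline can be validated against ground truth.

## The model

Each phantom subject carries a hidden progression value `s ~ U(0, 1)`.
Regional uptake follows a logistic onset curve

    u_r(s) = b_r + a_r · σ((s − τ_r) / w_r)

with onsets `τ_r` staggered in Braak order and a non-progressing
cerebellum-like reference region. Volumes acquire a per-subject global
scale, additive voxel noise, and isotropic Gaussian smoothing; a small
fraction of subjects get one hemisphere's cortical uptake multiplied by an
asymmetry factor ≥ 2 ("atypical"). Model inputs are normalized exactly as
in the imaging pipeline: divide by the mean reference-region uptake, then by
the global maximum.

The VAE encoder maps a volume to a Gaussian latent distribution `N(μ, diag
e^λ)`; training minimizes per-voxel squared reconstruction error plus a
weighted KL divergence from the standard normal prior (reparameterization
trick, Adam). Downstream stages use `μ`. Pseudo-time is the scalar
projection of `μ − c_k` (cluster center `c_k`) onto the incident MST path
edge with the largest projection, added to the center's arc-length position,
min–max rescaled to [0, 100]; the residual distance to the selected edge
drives 95th-percentile atypicality flagging.

## Worked example

```python
from tautraj import (CohortConfig, TauTrajectoryModel, VAEConfig,
                     build_phantom_atlas, generate_cohort)

atlas = build_phantom_atlas((32, 32, 32), n_regions_per_group=2, seed=7)
cohort = generate_cohort(atlas, CohortConfig(n=100), seed=1)
model = TauTrajectoryModel.from_cohort(
    cohort,
    vae_config=VAEConfig(latent_dim=12, base_channels=16, epochs=60, seed=0),
    k=5, seed=0)
results = model.fit()
print(results.summary())
print("Spearman(true progression, pseudo-time) =",
      round(results.spearman_vs(cohort.true_s), 3))
```

prints

```
Tau trajectory model results
============================================================
subjects: 100    latent dim: 12    conv layers: 3
VAE epochs: 60    train subjects: 50
reconstruction MSE  train: 1.053e-02   held-out: 9.851e-03
clusters (k): 5  linkage: ward
MST path: 4 -> 1 -> 2 -> 3 -> 0    total length: 2.107
pseudo-time range: [0.0, 100.0]
atypical flagged: 5/100 (>95th pct edge distance)
------------------------------------------------------------
logistic onset fits (ordered by midpoint):
  amyloid_like     midpoint=  16.68  rate=  0.065  pseudoR2= 0.930
  i_ii_0           midpoint=  46.92  rate=  0.061  pseudoR2= 0.783
  i_ii_1           midpoint=  47.19  rate=  0.061  pseudoR2= 0.784
  iii_iv_1         midpoint=  84.48  rate=  0.057  pseudoR2= 0.805
  iii_iv_0         midpoint=  84.84  rate=  0.058  pseudoR2= 0.804
  fdg_like         midpoint=  97.97  rate= -5.000  pseudoR2= 0.424
  mmse_like        midpoint=  98.05  rate= -5.000  pseudoR2= 0.730
  v_vi_0           midpoint= 100.00  rate=  0.095  pseudoR2= 0.598
  v_vi_1           midpoint= 100.00  rate=  0.094  pseudoR2= 0.596

Spearman(true progression, pseudo-time) = 0.895
```

Reading the output: the model was trained on a random half of the cohort
(the held-out reconstruction error checks overfitting), the five latent
clusters form a simple MST path, and pseudo-time spans exactly 0–100 with
5/100 subjects flagged atypical at the 95th percentile. The fitted onset
midpoints reproduce the planted cascade — the amyloid-like covariate rises
first, then Braak I–II regions, then III–IV, then V–VI (the late-stage
fits sit at the window edge at this cohort size: their transitions are only
partially observed, which also depresses their pseudo-R²). The derived
pseudo-time rank-correlates with the hidden progression at ρ ≈ 0.9.

The same pipeline is scriptable from the shell (`tautraj --config cfg.yaml
run-all`, plus per-stage verbs `simulate`, `preprocess`, `train`, `encode`,
`cluster`, `trajectory`, `curves`, and `replay` for manifest-driven
reproduction).

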