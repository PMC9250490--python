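# Methods

This note documents the models, parameter choices, and numerical decisions
behind `tautraj`, and what the phantom-based validation does and does not
show about real imaging data.

## 1. Phantom cohort generator

### Atlas geometry

`build_phantom_atlas` rasterizes mirror-symmetric ellipsoidal cortical
regions (one left and one right copy per region) onto a cubic grid, grouped
into Braak stages I–II, III–IV, V–VI, plus a single midline reference
region standing in for cerebellar gray matter. Two geometric constraints
matter:

- **The reference region is large** (~1,800 voxels on the default 32³
  grid, versus ~120 per cortical region). This mirrors real anatomy — the
  cerebellum dwarfs any single AD-vulnerable ROI — and it is load-bearing:
  the model-input normalization divides by the per-volume maximum, and
  without a dominant non-progressing compartment the normalized image
  manifold folds back on itself (late-stage images, with all regions
  re-brightened relative to the maximum, come to resemble early-stage
  images where everything sits at baseline). A large baseline compartment
  keeps the image trajectory injective in progression.
- **The reference is spatially separated from the cortical slab** by more
  than the truncated Gaussian smoothing kernel's support (scipy truncates
  at 4σ), so smoothing cannot bleed progression-dependent cortical signal
  into the reference. This is what makes the reference-region mean exactly
  constant across noiseless subjects.

Region placement uses a slot lattice; a grid too small for the requested
region count raises a sizing error naming the first region that failed.
Every region must rasterize to at least 8 voxels.

### Uptake model

Each subject has a hidden progression value `s ~ U(0, 1)` (uniform, to
maximize identifiability of the recovered ordering). Regional uptake is
`b + a·σ((s − τ)/w)` with, by default:

| group | onset τ | amplitude a | width w |
|-------|---------|-------------|---------|
| I–II  | 0.25    | 1.2         | 0.10    |
| III–IV| 0.45    | 1.0         | 0.10    |
| V–VI  | 0.65    | 0.7         | 0.10    |

baseline `b = 1` everywhere; the reference region has amplitude 0. All
regions of a group (and left/right copies) share parameters: Braak staging
orders *groups*, not individual regions, so the generator's planted
ordering is a group-level claim and recovery is assessed at that level.
Widths of 0.10 make transitions wide — uptake is still evolving at both
ends of the course, as biomarker-cascade models draw them — which keeps
the late course identifiable; amplitudes shrink with stage (the isocortical
increase is smallest). The earliest transitions (amyloid at 0.15 with
width 0.06, I–II at 0.25) start no earlier than ≈2.5 widths above `s = 0`,
so each onset lies essentially inside the observable window.

### Nuisance and covariates

Volumes are built as `scale · uptake + noise`, then Gaussian-smoothed and
clipped at zero, with defaults `scale ~ N(1, 0.1)` (clipped at 0.2), voxel
noise sd 0.05, smoothing 2.0 voxels FWHM (standing in for the uniform 8-mm
resolution of the source data on a desk-scale grid). Covariates follow the
canonical cascade: an amyloid-like marker rises before any tau region, an
MMSE-like score declines late (onset 0.70), an FDG-like marker is flat
with a very late decline (onset 0.85). Diagnoses are thresholded on `s`
(CN < 0.45 < MCI < 0.80 < AD) with 10% label noise. 5% of subjects are
"atypical": one hemisphere's cortical voxels are multiplied by 2.0,
emulating severely asymmetric deposition.

What the phantom does **not** emulate: anatomy-dependent smoothing, partial
volume effects, off-target binding, atrophy, registration error, scanner
batch effects, or longitudinal correlation. Passing recovery tests
therefore show the pipeline is correct and identifiable under its own
generative assumptions, not that it is robust to everything real data do.

## 2. Normalization and quantification

Model inputs follow the imaging pipeline exactly: divide by the mean
reference-region uptake, then by the global maximum (output max exactly 1;
the map is idempotent). Reported SUVr stays on the reference-normalized
scale — the max division applies to model inputs only. Braak-group
profiles average regions with equal weight (not voxel-count weight), a
declared convention since group definitions and weighting are not standard.

## 3. Variational autoencoder

Implemented in numpy with exact analytic gradients. Convolutions use
kernel 2 / stride 2 ("patch" convolutions): each layer is exactly a block
reshape plus a dense map, halving every spatial axis and doubling the
channel width; the generator mirrors the encoder with transposed patch
convolutions and a final sigmoid. Two affine heads produce the latent mean
and log-variance; training minimizes summed per-voxel squared error plus
`kl_weight ×` the closed-form KL to the standard normal, via the
reparameterization trick and Adam (lr 1e-3). Everything is float64 and
seeded, so training is bit-reproducible at a fixed thread count. A
paper-scale preset (6 layers, latent 512) exists for large grids; the desk
default is 3 layers.

The canonical study configuration is latent 12, base width 16 channels,
`kl_weight = 1.0`, 100 epochs, training on a random half of the cohort
with the other half scored for overfitting (held-out reconstruction error
is reported alongside the training error). The KL weight matters
qualitatively: too weak and the latent space spends dimensions encoding
per-subject noise, which contaminates the cluster geometry; too strong and
the posterior collapses. The encoder width matters for atypicality: a
too-narrow encoder cannot distinguish left- from right-lateralized
asymmetry, which collapses the atypical subgroup and weakens flagging.

## 4. Clustering and trajectory

Agglomerative clustering (scipy linkage; Ward default, Euclidean) on the
latent means, cut at `k` clusters. Automatic `k` selection uses the
largest *relative* gap between successive dendrogram merge heights
(cutting into `k` clusters is admissible between heights `h[n−k−1]` and
`h[n−k]`; the score is their ratio, smallest `k` on ties); all diagnostics
(merge heights, gap table, contingency) are emitted for manual inspection,
and an explicit `k` always overrides.

The MST over cluster centers (complete Euclidean graph, Kruskal with
lexicographic tie-breaking) is exact; tests cross-check it against
brute-force spanning-tree enumeration. A simple-path MST is oriented so
the endpoint cluster with the lower mean early-Braak (I–II) SUVr is the
root; branching trees raise an explicit error (an experimental backbone
mode takes the weighted diameter instead). Per-subject pseudo-time is the
scalar projection rule described in the README, with three declared
disambiguations: only edges incident to the subject's own cluster are
candidates, the incident edge with the largest (positive) projection is
selected (both-negative projections leave the subject at its center), and
positions are clamped to the path before cohort min–max rescaling to
[0, 100]. Atypicality uses the linear-interpolation percentile of the
edge-residual distances with strict-inequality flagging, so at an
in-sample 95th percentile exactly 5% of a 200-subject cohort is flagged.

**Cluster count in the canonical study.** The source pipeline identified
four clusters. In our phantom cohort the 5% strong-asymmetry subjects are
so far from the typical image manifold (the max normalization halves the
brightness of everything outside the boosted hemisphere) that they
reliably form their own cluster under any linkage. The canonical study
therefore uses `k = 5`: one cluster absorbs the atypicality mode and four
clusters span the typical trajectory, mirroring the original four. If the
MST at `k = 5` is not a simple path, the study applies the standard remedy
and retries with one cluster fewer. Planted-atypical recall is the one
seed-sensitive quantity of the study (typically 7–10 of 10 at the 95th
percentile; occasionally lower when the atypical cluster is compact),
because flagged-ness of an atypical subject depends on whether its
residual to its *own* cluster's edges exceeds the cohort threshold.

## 5. Onset curves

Biomarker and bilateral-region SUVr series are fitted against pseudo-time
with ordinary cubic polynomials (trend display) and a four-parameter
logistic `lower + (upper − lower)/(1 + e^{−rate(t − midpoint)})` by
nonlinear least squares (scipy `curve_fit`, trf) with multi-start midpoints
at the pseudo-time quartiles and pseudo-R² = 1 − SSE/SST. Two
identifiability guards are deliberate: the midpoint is bounded to the
observed pseudo-time window, and the asymptotes are bounded to within 10%
of the observed response range (standard dose-response practice).
Without them, series whose transition is truncated at a window edge — the
earliest tau region, whose lower plateau is compressed into pseudo-time
zero because pseudo-time is arc length and early arc length is generated
by that region's own rise — drive midpoints to meaningless extrapolated
values. Constant series are rejected with a flat-signal note;
non-convergence is always reported, and `onset_ordering` excludes
non-converged fits with a warning. Midpoints of curves censored at the
window edge (e.g., the FDG-like late decline) remain biased toward the
edge; their low pseudo-R² flags them.

## 6. Stage-regime study

Cluster-count recovery is validated on a cohort whose progression values
are drawn from four narrow stage regimes rather than a uniform prior. The
regime centers are placed at equal *arc-length* spacing along the
noiseless normalized-image curve (computed from the generator's own
parameters), with widths a fixed fraction (0.15) of the stage spacing —
uptake changes fastest early in the course, so equally distinct image-level
stages sit at unequal progression values. This cohort contains no
atypicals: it isolates the question "does the merge-gap rule count planted
stages correctly?". The automatic rule recovers `k = 4` with a clear gap
margin across seeds.

## 7. Problem sizes and defaults

The canonical studies use a 32³ grid with two bilateral regions per Braak
group, 200 subjects, and the VAE configuration above; one full study (data
generation through curve fits) takes 70–90 s on a single CPU core, and the
entire validation suite runs in a few minutes. The paper-scale grid
(160×160×96) and architecture are available as configuration presets but
are not exercised by the default tests.
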