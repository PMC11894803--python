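# Methods

## Data model and preprocessing

A gene expression matrix (GEM) is held samples × genes with FPKM-like
non-negative abundances and a binary phenotype label per sample (e.g.
`normal` / `tumor`). The transform chain is

1. missing cells (`NA`, empty) → 0 at read time, before any transform;
2. `v → log₂(v+1)`, so unexpressed genes stay at exactly 0;
3. per-gene min–max rescale to the closed interval [-1, 1].

The scaler is fitted on the **training split only** and applied with
clipping to held-out or inference data; this prevents information leakage
from evaluation rows into the normalization. Constant genes map to the
interval midpoint 0 (inert in model space) and are restored to their
constant on inversion. Both steps are exactly invertible elsewhere:
`invert(apply(x)) = x` to 1e-9 for non-constant, non-clipped genes, so
perturbed matrices can be reported on the original abundance scale.

Train/test splitting takes `floor(fraction·n)` training samples (default
fraction 0.67), allocated across labels by largest remainder so per-label
proportions are preserved to within one sample; the shuffle is seeded.

## Diffusion model

Forward process: `x_t = √ᾱ_t x₀ + √(1-ᾱ_t) ε` with `ᾱ_t` the cumulative
product of per-step retention coefficients `1-β_t`, strictly decreasing in
(0,1); `t = 0` is the clean-data boundary (`ᾱ_0 = 1`). Defaults follow
standard DDPM practice: linear `β ∈ [1e-4, 0.02]`, `T = 1000`; a cosine
schedule is available.

**Scaled-down schedules.** When `T` is cut for CPU-sized runs the β-range
must be scaled up so `ᾱ_T` stays ≈ 0 — with the default range at `T = 100`,
`ᾱ_T ≈ 0.37` and the chain never approaches its Gaussian prior, which
visibly degrades both ancestral sampling and the bridge. The packaged
`SMALL_PROFILE` therefore uses `T = 100`, `β ∈ [1e-3, 0.2]`
(`ᾱ_T ≈ 2e-5`, matching the full-size default).

Training minimizes the noise-prediction MSE with uniform `t ∈ [1, T]`,
fresh Gaussian noise each iteration, Adam (default learning rate 1e-4;
1e-3 in the small profile), and an exponential moving average of the
weights (decay 0.999 with the standard `(1+i)/(10+i)` warm-up) used for all
sampling. Without the warm-up the random initialisation retains ~14% weight
after 2000 iterations and conditional sample quality drops measurably.

Ancestral sampling runs the stochastic DDPM reverse chain from `N(0, I)`
with reverse variance `σ_t² = β_t` and no noise at the final step; outputs
are clipped to [-1, 1] (the data domain).

## Denoiser

`ε_θ(x_t, t, c)` is a pre-norm transformer encoder over **one token per
gene**: the scalar value is linearly projected to `embed_dim`, a learned
per-gene position embedding is added, and a context vector — projected
sinusoidal timestep features plus a learned phenotype embedding — is added
at the input *and re-injected before every block*, so the condition steers
generation even at high noise levels where `x_t` itself carries no class
information (conditioning only at the input measurably weakened
class-conditional sample quality). A final linear head returns one value
per gene; output shape always equals input shape. Defaults: 4 blocks,
embed 128, 4 heads, feed-forward 4×embed; the small profile uses 2 blocks
and embed 32.

No GPU framework is used: `gembridge.nn` is a ~300-line reverse-mode
autodiff over numpy arrays (broadcast-aware arithmetic, batched matmul,
softmax, layer-norm, GELU, embedding lookup) with Adam; its gradients are
verified against central finite differences in the test suite.

## Phenotype bridge

With `σ_t = 0` the reverse update becomes deterministic and, iterated over
a timestep grid, integrates the probability-flow ODE. Encoding runs the
recursion forward (0→T) conditioned on the source phenotype, producing a
row-paired latent; decoding runs it backward (T→0) conditioned on the
target phenotype. One shared conditional model serves both directions —
only the condition input changes. The grid is an evenly spaced integer
subsequence of `{0..T}` (default 100 steps); `ε_θ` is evaluated at
`max(t, 1)` since training never sees `t = 0`.

The per-gene **perturbation score** is the mean signed difference
`perturbed − original` in normalized units (direction = sign; magnitude
ranks genes). Scores from disjoint screened subsets are pooled; **core
genes** satisfy `|score − mean| > k·sd` with strict inequality, population
sd and `k = 2` by default (two-sided: strong moves in either direction
count). Only which-subsets-feed-the-pool is policy; by default the
high-cluster-potential subsets from screening do.

## Screening

Gene sets are shuffled (seeded) and cut into disjoint subsets of exactly
`subset_size` (default 16); a trailing remainder is dropped. For each
subset, samples restricted to those genes are embedded to 2-D by UMAP
(`n_neighbors = 90`, `min_dist = 0.3`, fixed seed; the neighborhood shrinks
with a warning when samples are scarce) and scored by the mean silhouette
against the phenotype labels. The silhouette is the classical per-sample
statistic — `a(i)` the mean distance to the other members of its own
cluster, `b(i)` the minimum over other clusters of the mean distance to
that cluster, singleton clusters contributing 0 — computed on the 2-D
embedding with Euclidean distance. Subsets beyond ±`k`·sd (population sd,
`k = 1`) of the screen-wide mean are flagged high/low cluster potential. A
random background repeats the screen on uniform gene draws and reports the
mean ± sd silhouette.

## Evaluation metrics

MMD uses the biased V-statistic (diagonal included, hence ≥ 0 and 0 for
identical inputs) with Gaussian kernel `exp(-‖x−y‖²/2σ²)`; σ defaults to
the median of the pooled pairwise distances, overridable. The classifier
check is an RBF SVM at fixed hyper-parameters (C = 1, bandwidth
`1/(d·var)`), trained on the training split; accuracy is reported in
percent on held-out rows (baseline) and on synthetic rows with their
intended labels. The report table carries per-feature-size baseline and
model columns.

Enrichment is a one-sided hypergeometric tail per annotation set with
Benjamini–Yekutieli FDR adjustment (valid under arbitrary dependence);
default significance threshold q < 1e-10.

## Synthetic data generator

The generator emulates co-normalized, FPKM-like bulk RNA-seq: per-gene
baseline means `μ_g ~ Uniform(2, 10)` in log₂ space, Gaussian per-gene
noise (sd 1.0 in log₂ space), a subset of signal genes shifted by
`effect_size` log₂ units in the tumor class, and values exponentiated back
(`2^x − 1`, clipped at 0) so the standard preprocessing recovers the
Gaussian structure. It deliberately does **not** model count dispersion
(negative binomial), batch effects, covariates, gene–gene correlation
beyond the class structure, or unbalanced class sizes — so passing tests
demonstrate that the machinery recovers a planted, well-separated signal,
not that it handles the full messiness of real cohorts. Default study
conditions used throughout testing: 16 genes with 4 signal genes at effect
size 3, 200 training samples per class.

## Problem sizes and numerical choices

The packaged small profile (`T = 100`, embed 32, 2 blocks, batch 32,
learning rate 1e-3, 4000 iterations, 100 ODE steps) trains in ~1.5 minutes
on one CPU core and is the size at which the test suite and the acceptance
script operate; the five replicate recovery runs use the same profile with
varying data and training seeds. The iteration count is a convergence
choice: the noise-prediction loss typically halves within the first ~2000
iterations, but the class-conditional means that drive bridging and
conditional sampling keep sharpening over the second half — stopping at
2000 leaves state transfer and synthetic-data classifier accuracy strongly
seed-dependent (observed gaps up to ~27 accuracy points on unlucky seeds,
vs ≤2 at convergence). Ties and degenerate inputs: constant
genes scale to 0; zero-variance score distributions yield no core genes;
silhouette singletons contribute 0; `select_extremes` and `pool_scores`
use strict inequalities, so an all-equal score vector never flags.
Checkpoints bundle weights (current + EMA), architecture, schedule, scaler
parameters, gene ids and the label vocabulary, so sampling after reload is
bit-identical given the same seeds.

## Known limitations

- The bridge's fidelity is bounded by denoiser accuracy; on under-trained
  models the per-gene scores shrink toward 0 and null genes can leak past
  the ±1 SD flag (observed in roughly 1 of 5 short-budget replicates).
- Silhouettes are computed on UMAP coordinates, inheriting UMAP's
  sensitivity to `n_neighbors` and its seed; scores are comparable only
  within a screen run with fixed parameters.
- The enrichment test uses a user-supplied background and local GMT
  collections; no identifier mapping (symbol ↔ Ensembl) is attempted.
- Gene-id matching is exact-string throughout.
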