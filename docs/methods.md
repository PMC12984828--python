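# Methods

This note records the modelling assumptions, parameter choices and known
limitations of the package. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The classification model

A sample is a multiset of per-taxon tokens; the classifier must be exactly
invariant to token order because taxon order in a count table is an
artifact. The architecture follows the set-transformer pattern:

* **Token construction.** For each taxon present in a sample (raw count
  > 0), the raw token is `concat(h_i, clr_i, w_i)`: the taxon's spectral
  phylogenetic features, its harmonized CLR abundance, and the
  compositional weight `w_i = log(1 + x*_i K̄_i)`, where `K̄_i` is the
  taxon's mean off-diagonal kernel similarity. Tokens are standardized per
  feature dimension with moments fitted on training samples only, then
  projected: `z_i = w_i (W_e ẽ_i + b_e + W_p h̃_i)`. The weight enters
  twice by design — as a feature (so it survives standardization) and as a
  multiplicative scale (so abundant, phylogenetically well-connected taxa
  carry proportionally larger attention values). `W_p`, acting on the
  phylogenetic slice, is the learnable taxon-embedding map; both
  projections receive gradients.
* **Set Attention Blocks.** Multihead scaled dot-product self-attention
  over the token set (`A_ij = Qz_i · Kz_j / √d_k`, row-softmax, value
  aggregation), head concatenation and output projection, then residual +
  layer norm and a per-token feed-forward sublayer (residual + layer norm
  again). The residual/layer-norm/feed-forward scaffolding is the standard
  set-transformer block: plain stacked attention layers neither train
  stably nor reach the intended parameter budget. SABs are
  permutation-equivariant.
* **Pooling by Multihead Attention.** S learnable seeds attend over the
  final token set; the pooled embedding is permutation-invariant because
  tokens enter only through softmax-weighted sums. Seed outputs are
  concatenated (default) or averaged before a two-layer feed-forward head
  with softmax over the label set.
* **Masking.** Variable-richness samples are padded; padded keys receive
  additive `-inf` attention logits, so they get exactly zero weight and
  padding provably never changes an output (tested).

The network, loss (class-weighted cross-entropy against cohort imbalance)
and Adam optimizer are implemented in NumPy on a small reverse-mode
autodiff engine written for this package; every gradient rule is checked
against central finite differences in the test suite. Float64 is used
throughout, which is why permutation invariance holds to ~1e-15 relative
rather than merely the 1e-5 contract.

### Default hyperparameters

| parameter | default | note |
| --- | --- | --- |
| token dimensionality | 128 | |
| SAB layers | 4 | |
| attention heads | 8 | `d_k = 16` |
| PMA seeds | 16 | concatenated → 2048-d pooled vector |
| feed-forward width | 2048 | the common transformer default; yields ≈3.51 M trainable parameters at the defaults above, matching the intended ≈3.2 M budget within 10% |
| classifier hidden | 256 | |
| dropout | 0.2 | |
| batch size / lr / epochs | 64 / 5e-4 / 200 | early stopping, patience 20, on a 10% validation split |
| CLR pseudo-count δ | 1e-6 | |
| empirical-Bayes λ | 0.01 | weak shrinkage (see below) |
| kernel decay λ_k | 1.0 per branch-length unit | |
| phylo feature dim m | 64 | |
| seed | 42 | governs splits, initialization and training |

### The scaled benchmark configuration

Desk-scale evaluation uses token dim 32, 2 SAB layers, 4 heads, 4 seeds,
30 epochs. The remaining knobs are sized for that small model: feed-forward
width 128, head hidden 64, batch 32, peak lr 4e-3 with a 60-step linear
warmup (small attention models pass through a chance-level plateau before
the attention maps differentiate; warmup is the standard remedy), m = 64
phylogenetic feature dimensions (with 100 taxa, fewer spectral dimensions
leave taxa insufficiently identifiable — the exponential kernel's spectrum
is flat beyond its leading eigenvalues, so m must be a sizable fraction of
the taxon count for tokens to carry taxon identity).

## Preprocessing

* **Error model.** `P_err(Q) = exp(-αQ)`; the default `α = ln(10)/10`
  makes this coincide with the Phred definition `10^(-Q/10)`. Reads are
  kept when `Σ_i P_err(Q_i) ≤ 2.0` expected errors.
* **Denoiser.** Greedy abundance-ranked partitioning: unique sequences in
  decreasing abundance, each either absorbed into the best same-length
  center (likelihood: `P_err/3` per mismatching position, `1 - P_err` per
  match, evaluated at the candidate's observed per-position mean quality)
  or promoted to a new center when its abundance is implausible as error
  copies — the binomial tail conditioned on being observed at all,
  `P(X ≥ a | X ≥ 1) ≤ ω` with `ω = 1e-6`. Conditioning means singletons
  never seed centers, which is what makes exact ASV recovery robust rather
  than a draw against rare multi-error reads. Substitutions only; indels
  and different-length merging are out of scope. Ties break toward the
  more abundant center, then the lexicographically smaller sequence.
* **Chimera removal.** An ASV is flagged when some split point gives a
  left segment from one ≥2×-more-abundant parent and a right segment from
  a different such parent, with combined identity exceeding the best
  single-parent identity by ≥0.02.
* **Normalization order.** counts → zero replacement → CLR feeds the
  model; CSS is available as an alternative (`--norm css`) but the token
  geometry assumes CLR coordinates, so CLR is the default path.
* **Harmonization.** Per (taxon, batch) location-scale standardization to
  pooled moments, with means shrunk as
  `μ̂_b = (n_b μ̄_b + λ μ_pool)/(n_b + λ)` and variances as
  `σ̂²_b = (σ̄²_b + λ σ²_pool)/(1 + λ)`; λ = 0.01 is weak shrinkage (a
  prior weight of 0.01 pseudo-samples), i.e. near-plain location-scale
  correction, and λ → ∞ recovers full shrinkage to the pool (identity
  correction). Labels never enter fitting. Batches with < 2 samples fall
  back to identity. The corrected matrix is a per-taxon affine image of
  CLR values: it preserves within-batch sample ordering exactly, at the
  cost of column zero-sums holding only approximately (the matrix is
  flagged accordingly). The alignment diagnostic is moment-matching:
  summed squared differences between batch-wise and pooled per-taxon
  (mean, SD) pairs — zero iff moments coincide; a second optimizer over an
  unspecified latent transformation would add nothing the correction does
  not already realize.
* **Phylogenetic features.** `K = exp(-λ_k d)` over patristic distances;
  `h` = top-m eigenvectors scaled by √eigenvalue, negative eigenvalues
  clipped, eigenvector signs fixed (largest-magnitude entry positive) for
  reproducibility. Without a tree the package degrades to one-hot taxon
  features with a near-identity kernel (logged prominently).

## Evaluation protocol

Two split modes: class-stratified 5-fold, and leave-study-out (the
headline), where whole studies are assigned to folds and no `study_id`
straddles a train/test boundary. Per fold, everything with fitted state —
batch model, token normalizer, network — is fitted on training samples
only and applied frozen to the held-out samples; zero replacement and CLR
are stateless per-sample maps and are applied up front. Every fitted
object carries its fitted-on sample list and the driver raises
`LeakageError` on any intersection with test IDs. For a held-out study the
batch is by construction unseen, so correction passes it through
unchanged (identity), which is the honest transform-only contract for
cross-cohort generalization. Reported summary metrics are arithmetic means
of per-fold values; AUC is rank-based.

## The synthetic generator

The generator emulates the structure of multi-study 16S case-control
collections: per-sample latent log-abundances from a multivariate normal
with tree covariance `exp(-d/ℓ)` (ℓ = 1), planted per-taxon log-fold
effects added to cases, per-study location/scale perturbations per taxon
(location SD 0.5, scale log-SD 0.1 in the benchmark), softmax closure,
and multinomial counts at log-normally overdispersed depths (mean 20 000,
σ = 0.3). A log-normal-plus-multinomial scheme (rather than
Dirichlet-multinomial) keeps planted log-fold effects exact on the latent
scale, which is the scale CLR approximately recovers. Batch shifts are
i.i.d. across taxa because a shift constant across taxa is annihilated by
the CLR's per-sample centering and would be unrecoverable by construction.

What the generator does **not** emulate: realistic zero-inflation patterns
beyond multinomial sampling, taxon-specific overdispersion, instrument
error profiles or read-length variation, longitudinal structure, or
covariate-confounded batches. Passing tests therefore demonstrate that the
pipeline recovers the signals this generative family produces — not
performance on any real collection.

The default benchmark: 5 studies × (40 cases + 40 controls), 100 taxa,
5 planted taxa at latent log-fold +1.5, batch shifts on — sizes mirror
public case-control studies (hundreds of samples each) scaled down so the
full benchmark runs in minutes on one CPU.

Read simulation flips a base with probability `exp(-αQ)` to a uniformly
random nucleotide (including itself), so the expected mismatch rate is
`(3/4)·exp(-αQ)`; the denoiser's scoring model uses the `P_err/3`-per-
alternative convention instead. The two conventions are deliberately
distinct — the generator is the oracle, not the model being tested.

## Numerical choices

* Attention masking by additive −inf; `exp(-inf) = 0` exactly, so masked
  weights are exactly zero (asserted).
* Eigen-decompositions via symmetric solvers; kernel eigenvalues clipped
  at 0 before feature extraction.
* SDs floored at 1e-6 wherever standardization divides (normalizer, batch
  model).
* Softmax shift-stabilization uses a detached maximum (value- and
  gradient-preserving).
* Invariance tests use a 1e-5 relative tolerance to allow for
  non-associative float summation, though float64 keeps observed
  differences near machine epsilon.

## Known limitations

* The denoiser is substitution-only; indel-containing reads form separate
  length classes and are never merged.
* The harmonization stage is the only cross-cohort alignment; no
  model-internal recalibration of token statistics is performed.
* The attribution scores are attention magnitudes: they carry no sign
  (direction is annotated from the data) and no causal interpretation.
* BIOM-HDF5, SAM/BAM and paired-end merging are out of scope; count
  tables travel as dense TSV.
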