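# Methods

## Model

The core object is an autoencoder over gene expression whose first layer
is "structure-primed": the encoder weight matrix W (TFs × genes) has its
support fixed to the transpose of a prior-knowledge network P (genes ×
TFs), so the latent activation φ = σ(Wx) of each TF is a learned,
weighted summary of exactly the genes the prior assigns to it. φ is
interpreted as transcription-factor activity (TFA): the variance of a
TF's activity is constrained to the variance of its reporter targets
rather than to the TF's own mRNA, which is known to correlate poorly
with protein-level activity. Masked entries of W are exactly zero at
initialization and after every optimizer step — the mask is re-applied
after each update, so the invariant is exact, not approximate.

Two architectures:

- **shallow** — `x̂ = Θ φ`, both layers linear by default. With linear
  activations the model is the composition of two linear maps, which
  makes it the analytically checkable baseline.
- **hierarchical** — `x̂ = Θ σ(Π φ)` inserts a meta-TF (mTF) layer whose
  features aggregate TFs into pathway-like groups. TF and mTF layers use
  the rectifier `ReLU₀(z) = max(0, z)` with the subgradient at z = 0
  defined as 1, so latent activities are non-negative (interpretable as
  activities) and units sitting exactly at zero still receive gradient.
  The number of mTFs defaults to the number of TFs.

**Joint representation learning (JRL)** keeps one encoder W_C per
biological context (cell type, growth condition, …), all sharing the TF
axis, with Π and Θ common. Observations are batched within context and
routed through their context's encoder. A single-context JRL model is
bit-identical to the hierarchical model with the same weights.

The decoder is initialized as the non-negative mirror (transpose) of the
encoder on the same support but is free thereafter — the prior
assumption being that TFA correlates positively with target expression
when nothing else is known — and this freedom is what lets the model
predict regulation absent from the prior. Nonzero encoder entries are
drawn uniformly in (0, 1/√fan-in) per TF (fan-in = the TF's prior
degree) and are non-negative by construction; the hierarchical Π starts
near identity with N(0, 0.01) noise, and Θ with small non-negative
values. No layer has a bias term: the model's equations are pure
weighted maps, so a zero input always reconstructs to zero.

## Training

Objective: mean squared reconstruction error (mean over observations and
genes) plus a ridge penalty ζ on the squared Frobenius norm of every
weight matrix present (ζ‖W‖² + ζ‖Π‖² + ζ‖Θ‖²). Optimization is
minibatch Adam (β₁ 0.9, β₂ 0.999). Defaults: batch size 256, learning
rate 1e-3, 400 epochs (100 for post-pruning refits) — these are
package defaults chosen for the synthetic problem sizes below, exposed
in `TrainingConfig`. Dropout (inverted scaling, train-time only) can be
applied to the input genes and to the TF latent layer; the benchmark
default is input 0.5 / latent 0. Grid search over
ζ ∈ {0, 10⁻¹⁰ … 10⁻¹} and dropout ∈ {0, 0.01, 0.05, 0.1, 0.2, 0.3,
0.4, 0.5} uses repeated 50/50 observation splits, reporting mean
held-out-edge AUPR and validation R²; the selection rule maximizes R²
with AUPR reported alongside. Training is bit-reproducible given a seed
(one RNG drives batching and dropout); a non-finite loss aborts with a
diagnostic rather than continuing silently.

## ERV

For a trained model, the explained relative variance of latent feature k
for output gene i is the coefficient of partial determination

    ξ²[i,k] = 1 − MSE_i(full) / MSE_i(feature k's activation set to 0),

computed by two forward passes and no retraining, always in evaluation
mode (no dropout). ξ² ≤ 1; a predictive link has ξ² > 0; a feature whose
removal changes nothing scores exactly 0 (including the 0/0 case, which
is defined as 0 since the full-model MSE can never exceed the perturbed
MSE from zero). Knockout means zeroing the latent activation, not
deleting the column. For the TF layer of a hierarchical model the
knockout propagates through Π and Θ, giving the *indirect* TF → gene
effect — this dense genes × TFs matrix is the extracted GRN, and is what
gets ranked and scored. For the shallow model the GRN is Θ's support
ranked by ξ².

**Interlayer ERV** scores a hidden weight π[m,k] by intersecting the
genes predictive for TF k (indirect ξ² > ε₁) with those predictive for
mTF m (ξ² > ε₂), then forming 1 − Σ MSE_full / Σ MSE_knockout-of-k over
that intersection; an empty intersection scores exactly 0. ε₁ = ε₂ = 0
by default.

**Relative ERV** normalizes each gene's row by its maximum ξ², so every
explainable gene has at least one feature at ξ̂² = 1 and other regulators
are ranked relative to it. Genes whose maximum ξ² ≤ 0 are flagged
unexplainable and their rows zeroed; no floor is applied when the
maximum is positive but small.

**Context ERV** recomputes ξ² within each labeled observation subset
using the unchanged trained model — context-specific networks are a
post-training analysis, so new contexts can be examined without
retraining. Contexts with fewer than two observations are skipped.

**Pruning** iterates: compute relative ERV for the decoder's input layer
and zero decoder weights with ξ̂² ≤ ε (ε = 0 keeps every predictive
link); for hierarchical models also zero π[m,k] with interlayer ξ² ≤ 0;
refit the survivors (warm start, `refit_epochs`); stop when an iteration
removes nothing, capped at 10 iterations. Removals are recorded in
support masks, so nonzero counts are non-increasing by construction.
Warm-starting was chosen over refitting from scratch (a flag away in the
config) because the surviving weights are already near their optimum and
the removed ones carried no predictive signal.

## Evaluation

- **AUPR** is average precision over a ranked edge list (sum of
  precision at each true-positive rank divided by the number of
  positives, no interpolation), computed against a gold standard of
  edges held out of the training prior, over a candidate universe of all
  TF × gene pairs minus the training prior's edges. Candidates missing
  from the ranking are appended at the bottom in deterministic
  (regulator, gene) order; ranking ties break the same way. The exact
  permutation-null expectation of average precision is slightly above
  the positive density at small candidate counts and converges to it as
  the universe grows — the tests check against the exact null formula.
- **R²** is 1 − SS_res/SS_tot pooled over all entries (per-gene variant
  available).
- **Context enrichment**: edges with ξ² above a floor (default 0.01) in
  at least one of two contexts are classified to the context with the
  higher ξ² (exact ties dropped and counted); the 2×2 table of
  classification × target-gene annotation is tested with a one-sided
  Fisher exact test for over-representation of concordant assignment.
- **NCA baseline**: stage one solves φ̂ = argmin‖Y − φPᵀ‖ by ordinary
  least squares against the fixed binary prior (requires full column
  rank; a ridge fallback is available), stage two solves
  Θ̂ = argmin‖Y − φ̂Θ‖ with no support constraint.

## Preprocessing

Single-cell counts: genes expressed in < 10 cells removed, zero-count
cells dropped, each cell scaled to a common total (the dataset median by
default — any constant works, the median is a scale-neutral choice),
then log(1 + x). Feature scaling is either standard z-scoring with
population (ddof 0) standard deviation — constant genes map to zero and
are flagged — or the sparsity-preserving robust scaler: divide each gene
by its 1st-to-99th percentile range (linear interpolation) and shift so
the per-gene minimum is 0, which leaves zero counts exactly zero.
Chromatin-accessibility masking zeroes expression entries whose gene has
no accessible peak in that cell (elementwise, no renormalization,
idempotent). Cell-cycle phases are called per cell as the argmax over
phases of the mean standardized marker-gene expression, with exact ties
resolved by the fixed order G1, S, G2, M, M/G1.

Prior construction from peaks: BED/narrowPeak intervals are 0-based
half-open, GTF is converted at parse time; a peak links to a gene when
its midpoint (chosen over the full span for determinism) lies in the
strand-oriented window [TSS − 50 kb, TSS + 2 kb] and no other gene body
overlaps the midpoint-to-TSS interval; peaks may first be intersected
with regulatory regions; signal values are summed per (gene, TF) pair,
and each TF column is then sparsified to its top ⌊fraction × n_genes⌋
entries (default 1.5%), ties at the cut broken by gene-identifier order.
A peak passing the window and blocking tests for several genes keeps all
those edges. Holdout splitting samples prior edges uniformly without
replacement; a TF column emptied by the split gets its lexicographically
first held-out edge back so every TF stays representable.

## Synthetic data

The generator emulates the model's own generative assumptions so every
stage is testable with known truth: a sparse signed TF → gene network
(constant out-degree, magnitudes uniform in [0.5, 1.5], equiprobable
signs, optionally activator-only), log-normal TFA (μ 0, σ 0.5 —
non-negative and right-skewed, matching rectified latents), expression
as the (optionally rectified) linear readout plus Gaussian noise, and a
count-like variant by treating exponentiated signal as multinomial rates
at log-normal sequencing depth. Context effects are planted by silencing
dedicated regulators outside their context. Prior corruption removes a
false-negative fraction of true edges (these become the gold standard,
disjoint from the prior by construction) and adds spurious edges
proportional to the true edge count.

Default study conditions: 20 TFs × 200 genes × 500 samples, out-degree
10, noise sd 0.5, fn 0.2 / fp 0.1. These sizes keep the full benchmark
(training, controls, pruning, context analysis) to seconds while leaving
clear margins between signal and the negative controls. What the
generator does **not** emulate: zero-inflation beyond multinomial
sampling, doublets, batch effects, TF-TF cooperativity beyond the linear
map, or priors whose errors are structured rather than uniform. Passing
tests therefore demonstrate correctness of the machinery and
recoverability under well-specified conditions, not performance on real
single-cell data.

## Numerical choices and edge cases

- Percentiles: linear interpolation. Standard deviation: population
  (ddof 0).
- ξ² with zero perturbed MSE is defined 0; relative ERV of an
  unexplainable gene (max ξ² ≤ 0) is 0 with a flag.
- Encoder support masking is enforced by zeroing after each Adam step;
  W entries may become negative during training (only the
  initialization is constrained non-negative).
- Model serialization writes weights as triplet TSV with `%.17g`
  formatting, which round-trips float64 bit-exactly.
- Pruning ε ≥ 1 is rejected (it would remove every weight).
- All RNG flows through `numpy.random.default_rng(seed)`; fits are
  bit-reproducible on a platform given the seed.

## Limitations

- One mTF layer only; no deeper hierarchies, variational or denoising
  variants.
- Priors are unsigned; sign annotation on extracted edges comes from the
  net weight path, not from the prior.
- The NCA baseline recovers per-TF activity up to scale only when
  regulon signs are consistent (signed regulons cancel in the
  binary-prior projection); the structure-primed model does not share
  this restriction since W is learned.
- Hyperparameter search is exhaustive over the configured grid; no
  early stopping or learning-rate schedules.
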