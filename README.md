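# primegrn

Structure-primed autoencoder inference of gene regulatory networks (GRNs),
with explained-relative-variance (ERV) interpretation, for systems
biologists who have expression data (bulk or single-cell), a noisy
prior-knowledge network, and want a predictive, interpretable model of
TF → gene regulation together with per-observation transcription-factor
activity (TFA).

## The model

Gene expression `x` is embedded on the transcription-factor manifold by an
autoencoder whose encoder support is fixed to a prior network `P`
(genes × TFs):

    φ  = σ(W x)        TF activity;  support(W) = support(Pᵀ)
    φ̂  = σ(Π φ)        meta-TF (pathway) activity     [hierarchical only]
    x̂  = σ(Θ φ̂)        reconstructed expression

The encoder can only read each TF's activity from the genes the prior
links to it, enforcing the causal flow regulator → target; the decoder Θ
is free, so the model can predict regulation absent from the prior. The
shallow variant (`x̂ = Θ φ`, linear) is the analytically transparent
baseline; the hierarchical variant uses the `ReLU₀` rectifier (gradient 1
at 0) so TFA and meta-TFA stay non-negative and interpretable. Joint
representation learning (JRL) trains one encoder per biological context
with Π and Θ shared. Training minimizes

    MSE(x, x̂) + ζ‖W‖² + ζ‖Π‖² + ζ‖Θ‖²

by minibatch Adam with optional dropout on the input and TF layers.

Interpretation uses **ERV**, a coefficient of partial determination
computed by latent-feature knockout without retraining:

    ξ²[i,k] = 1 − MSE_i(full model) / MSE_i(feature k zeroed)   ∈ (−∞, 1]

ERV ranks TF→gene edges for scoring against held-out gold standards
(AUPR), scores hidden-layer weights through intersection gene sets,
drives iterative pruning of non-predictive weights (relative ERV ≤ ε),
and — recomputed within observation subsets — yields context-specific
networks from one trained model. A two-stage least-squares network
component analysis (NCA) baseline and a synthetic ground-truth generator
round out the toolkit; nothing requires downloading external data.

## Worked example

`examples/01_infer_network.py` simulates a 20-TF × 200-gene network with
500 cells, corrupts the prior (20% of true edges held out as gold
standard, 10% spurious edges added), trains the hierarchical model, and
scores the ERV-ranked network:

```
prior: 200 genes x 20 TFs, 180 edges; gold standard: 40 held-out edges
training loss 2.078 -> 0.423 over 400 epochs
held-out edge AUPR = 0.959 (92x the random baseline of 0.0105)
reconstruction R^2 = 0.845
```

The AUPR is computed only over TF–gene pairs *not* in the training prior,
so 0.959 against a random-baseline density of 0.0105 means the model
ranks true regulatory edges it never saw far ahead of non-edges. The
other examples demonstrate the NCA baseline (per-TF activity correlation
≥ 0.995 on noise-free data), context-specific networks (Fisher odds
ratio 1.51, p = 1.9e-3 for planted regulons; permuted-label control at
1.03), iterative pruning (decoder shrinks to 65% of its weights while
validation R² improves from 0.793 to 0.842), and prior construction from
peak/annotation files.

A thin CLI mirrors the pipeline for shell use:

```sh
primegrn simulate --out sim --seed 1
primegrn fit --expression sim/expression.tsv --prior sim/prior.tsv \
    --architecture hierarchical --out run
primegrn interpret --model run/model --expression sim/expression.tsv --out interp
primegrn evaluate --network interp/network.tsv --gold sim/gold.tsv \
    --prior sim/prior.tsv --out eval
```

Every command writes a text manifest with config and content hashes;
models serialize to diffable TSV directories that round-trip bit-exactly.

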