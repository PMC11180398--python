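# Methods

## Problem and data model

`ddirisk` classifies drug pairs into ordinal interaction risk levels.  The
data are (a) a typed edge list of events — two drug identifiers and a risk
class — and (b) a drug table mapping identifiers to SMILES.  Internally the
events form a heterogeneous graph with one relation per risk class,
equivalently a symmetric risk-rating matrix with a sentinel (−1) for pairs
without a recorded event.  Conventions:

- node order is the lexicographic sort of drug identifiers, making the
  index space a deterministic function of the drug set, never of file row
  order;
- undirected edges are stored double-entry (both directed arcs), because
  message passing iterates directed arcs;
- in the four-level regime, *Unknown* is an ordinary class, mapped lowest
  (Unknown 0 < Minor 1 < Moderate 2 < Major 3) so larger coefficients mean
  higher risk; pairs with no recorded event are absent from the graph, not
  labelled;
- duplicate pairs with conflicting labels are a hard error: silent
  keep-first would hide corrupt input;
- drugs whose SMILES does not parse are dropped with a logged warning and
  counted in a drop report.

## Featurization

Node features are Morgan fingerprints (default radius 2, 2048 bits — the
ECFP4-equivalent standard) computed with RDKit, converted to 0/1 floats and
reduced by PCA.  The PCA convention is the covariance eigendecomposition
with 1/m scaling of the mean-centered data; eigenvector signs are fixed by
forcing each column's largest-magnitude entry positive, so projections are
reproducible across linear-algebra backends.  The default target dimension
is k = 300 (k is clipped to min(m, n) for small inputs; the desk-scale
study configuration uses k = 64, see below).  PCA is fit on all drugs by
default: features derive from chemistry only, never labels, so no label
leakage is possible; restricting the fit population to training drugs is
available for stricter protocols.  Edge attributes are the concatenation
of the two endpoint features in arc order, so each undirected edge is
represented by both orderings.

## Model

The encoder is a two-layer relational graph convolution.  Layer update for
node i:

    x_i' = σ( W₀ x_i + Σ_r Σ_{j∈N_i^r} (1/c_ij) W_r (x_j + E w_ij) )

- The fused message combines the neighbor state with a linear projection
  E of the arc's edge attribute into the layer's input space.  This is a
  documented interpretation: the propagation formula sums two per-neighbor
  feature components, and the companion message-passing formulation makes
  the message a function φ(x_v, x_u, w_e) of both endpoint states and the
  edge attribute.  The `no_ep` ablation drops the edge-attribute summand
  everywhere.
- c_ij = |N_i^r| (per-relation in-degree), the standard mean normalizer;
  the normalizer is otherwise unspecified in the method this follows.
- W₀ is a separate self-connection weight ("adding its feature to the
  aggregated features"); nodes without neighbors receive the self term
  only.
- σ = ReLU between layers (a standard default; configurable), identity at
  the top layer.

Per-relation weights are factorized to limit parameters on rare relations:
basis decomposition W_r = Σ_b a_rb V_b (only the coefficients a_rb depend
on r) or block-diagonal decomposition W_r = ⊕_b Q_br (B must divide both
layer dimensions; B = d yields a strictly diagonal W_r).  The default is
basis mode with B = R, one basis per risk level.  With B = R and identity
coefficients, basis mode reproduces unconstrained per-relation weights
exactly — a tested identity.

For classification, each query edge (i, j) is re-embedded from the encoder
output: z_e = h_i + h_j + P w_e ("edge propagation": the edge's own
attribute fused with its two adjacent node states).  The batch of edge
latents is refined by multi-head scaled dot-product attention,
softmax(QKᵀ/√d_k) per head.  Two value-path variants are implemented
behind a switch because the printed formula of the source method
post-multiplies the attention weights by the fused inputs (x₁ + x₂) rather
than a learned value projection: `sum_inputs` (default; values are the raw
latents) and `learned` (conventional V projection).  A residual connection
and layer normalization (post-norm) wrap the attention block; the exact
placement is unspecified in the source, so it is fixed here and
documented.  Softmax subtracts the row maximum before exponentiation for
overflow safety.  A final linear layer scores R classes.

Attention is applied within fixed-order batches of query edges (default
256).  Attention over edge latents is quadratic in batch length; batching
bounds that cost while preserving determinism.

Ablation variants: `no_fp` replaces node features with one-hot rows
(topology only), `no_at` replaces the attention block with the identity,
`no_ep` removes every edge-attribute term.  An autoencoder variant appears
once in the source's ablation table but is never described in its methods;
no autoencoder is implemented here.

### Baselines

GCN, GAT and GraphSAGE (mean and max-pooling aggregators) are provided as
single-relation encoders: they collapse the typed relation sets into one
untyped adjacency, since their formulations are single-relation; relation
information reaches them only through the shared edge-feature head (edge
re-embedding + linear scorer, no attention).  GAT adds self-loops so
isolated nodes attend to themselves; GraphSAGE's unsupervised
negative-sampling loss and LSTM aggregator are out of scope (the benchmark
task is supervised edge classification).  Baseline depth and width mirror
the main model for fairness; their values are not specified by the source
method.

## Training and evaluation

Training minimizes multi-class cross-entropy J = −(1/m) Σ log ŷ[y] with
AdamW (decoupled weight decay), full-graph and full-batch; probabilities
are clamped at 1e-12 in the probability-space loss, and the training path
uses a numerically stable log-softmax.  All randomness (initialization,
folds, splits) is seeded.  Non-finite losses abort with diagnostics.

Generic defaults: 300 epochs, lr 1e-3, weight decay 1e-2, no early
stopping.  The desk-scale study configuration (`TrainConfig.desk_scale()`)
used by the synthetic studies is lr 5e-3, weight decay 0.05, k = 64,
hidden 64, 4 heads, and early stopping: a stratified 15% slice of the
training edges is held out of the loss and the message-passing graph, the
epoch with the best holdout accuracy (patience 15, up to 80 epochs, ties
refresh the choice since holdout accuracy is coarse) selects the
schedule, and the model is refit from scratch on all training edges for
that many epochs.  The schedule adapts to the label signal: with clean
feature-determined labels nearly the full budget is used; with pure label
noise the selection stops within a few epochs, which collapses the fit to
the majority-class predictor instead of letting the over-parameterized
encoder memorize topology idiosyncrasies.  The smaller widths keep a
five-fold ablation study in CPU-minutes.

Cold-start protocol: a seeded uniform sample of ⌈novel_fraction·|V|⌉ drugs
(default fraction 0.2, a documented knob) is marked novel; events split
into Task 1 (both endpoints confirmed), Task 2 (exactly one novel), Task 3
(both novel).  Training uses Task 1 edges only, and the message-passing
graph is built from training edges only, so novel-endpoint edges can never
leak — asserted by tests over 100 random seeds.

Cross-validation: Task 1 folds over edges, stratified by class (the class
imbalance makes unstratified folds unstable at desk scale; falls back to
unstratified with a warning when a class has fewer members than folds);
Tasks 2/3 fold over the novel-drug sampling seed.  Reported metrics:
accuracy of argmax predictions; micro-averaged AUPR and AUC over the
one-vs-rest binarized label matrix; macro-averaged F1, precision and
recall.  The source states recall's averaging mode inconsistently, so both
macro and micro recall are computed (micro recall equals accuracy for
single-label argmax predictions — a tested identity).  Classes absent from
a test fold are excluded from macro averages with a warning; AUC/AUPR are
reported as missing (not 0) when the binarized truth is degenerate.
The ablation harness runs all variants against identical folds and seeds
(paired comparison).

## Synthetic data generator

The generator emulates the *shape* of curated DDI resources — a typed,
imbalanced, undirected event network over SMILES-described drugs — with
label recoverability controllable by construction:

- each drug gets a latent cluster and a valid toy SMILES from that
  cluster's structural family (aliphatic, aromatic, halogenated,
  N-heterocyclic, carbonyl, thioether, alicyclic, unsaturated), so Morgan
  fingerprints separate clusters cleanly;
- each cluster draws a latent hazard score; each unordered cluster pair is
  assigned a class by bucketing combined hazard so expected class
  frequencies match the requested proportions, filling classes in rank
  order and guaranteeing every class at least one pair.  The monotone
  (ordinal) table reflects what risk levels are — ordered severities — and
  makes the planted rule exactly representable by an additive pair scorer;
  a `random` table mode (independent class draws per pair) is available
  for non-ordinal regimes;
- a sampled pair takes the table label with probability
  `feature_label_coupling`, else an independent draw from the class
  proportions.  At coupling 1 the Bayes classifier on endpoint clusters is
  perfect; at coupling 0 the best achievable accuracy is the largest class
  share — both ends are tested.

Presets: `ddinter4` (four severity levels, proportions 0.213 / 0.049 /
0.586 / 0.152, mirroring the published four-level resource counts) and
`drugbank65` (65 classes, power-law proportions, 12 clusters).

Study conditions: 300 drugs, edge density 0.03 (~1350 events, mean typed
degree ≈ 9).  The density is chosen so that chemistry, not memorizable
typed topology, carries the planted signal: with only a handful of
incident training edges per node, the typed incidence profile is a noisy
observation of a node's cluster, so the fingerprint-free ablation is held
to a materially lower ceiling while the full model recovers the labels
almost perfectly.  Real curated networks are denser; at matching density
the typed topology alone would nearly determine cluster identity and the
fingerprint ablation would not separate from the full model.

What passing synthetic tests do **not** show: chemical realism (toy SMILES
are small decorated scaffolds, not drug-like molecules), pharmacological
mechanism, annotation noise, or the scale of curated resources (10³ vs
10⁵ events).  Results on synthetic networks validate the machinery —
propagation, decomposition, attention, splitting, metrics — and the
qualitative ablation ordering, not clinical performance.

## Numerical choices

- All training numerics run on a small reverse-mode autodiff engine over
  numpy arrays (broadcast arithmetic, matmul, gather/segment reductions);
  gradients of every layer are verified against central finite differences
  at 1e-6 steps.
- float64 throughout by default (configurable); at desk scale the runtime
  cost over float32 is immaterial and gradient checks are exact.
- Softmax and log-softmax subtract detached row maxima.
- Segment-max ties split their subgradient equally; empty segments yield 0
  and receive no gradient.
- PCA rejects zero-variance input and out-of-range k; eigenvalues are
  clipped at 0 to absorb numerical negatives.

## Known limitations

- Full-graph, full-batch training only; no neighbor sampling, no GPU — by
  design for desk-scale reproducibility, impractical beyond ~10⁴ events.
- The additive edge latent (h_i + h_j) cannot represent arbitrary
  non-ordinal pair tables without help from the typed-topology channel;
  the attention block only partially lifts this.
- The 65-class preset exercises the long-tail code path; with 12 chemistry
  clusters its feature-determined ceiling is far below 1 by construction.
- Cold-start Tasks 2/3 performance rests entirely on fingerprint features;
  with `no_fp` the novel drugs are featureless and predictions collapse to
  the prior, as expected.
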