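# ddirisk

Multi-class prediction of **drug–drug interaction (DDI) risk levels** on a
heterogeneous interaction graph, for computational pharmacology and
drug-combination safety screening.

Most DDI predictors answer only *whether* two drugs interact.  `ddirisk`
classifies each drug pair into an ordinal **risk level** (e.g. Unknown <
Minor < Moderate < Major), which is what actually matters for clinical
decision support: a Major interaction is life-threatening, a Minor one
usually requires no therapy change.

## The model

DDI events are modelled as a heterogeneous information graph *G = (V, E)*:
drugs are nodes, and each interaction event is an undirected edge typed by
its risk level, equivalently a symmetric risk-rating matrix
*Y ∈ {0, …, R−1}^{|V|×|V|}* where a larger coefficient means a higher risk.
Node attributes come from chemistry alone — Morgan (ECFP-style) fingerprints
of each drug's SMILES, reduced by PCA (*Y = (X − mean)·P* with *P* the top-*k*
covariance eigenvectors) — and edge attributes are the concatenation of the
two endpoint features.

The classifier is a two-layer **relational graph convolutional network**
(RGCN) with an attentive edge head:

    x_i' = σ( W₀ x_i + Σ_r Σ_{j∈N_i^r} (1/c_ij) W_r (x_j + E w_ij) )

with one weight matrix *W_r* per risk level, regularized by **basis
decomposition** *W_r = Σ_b a_rb V_b* (or block-diagonal decomposition).
Each query edge is re-embedded from its endpoint states and its own
attribute ("edge propagation"), refined by **multi-head scaled dot-product
attention** `softmax(QKᵀ/√d_k)` with residual connection and layer
normalization, and scored into *R* classes.  Training minimizes multi-class
cross-entropy with AdamW.  GCN, GAT and GraphSAGE encoders are included as
baselines behind the same edge head.

Evaluation covers the warm-start and **cold-start** protocols: drugs are
partitioned into confirmed and novel sets, and the model — trained only on
confirmed–confirmed pairs (Task 1) — is scored on confirmed–novel (Task 2)
and novel–novel (Task 3) pairs, with novel-endpoint edges excluded from the
message-passing graph entirely (leak-free by construction).

A seeded synthetic-network generator produces drug tables (valid toy
SMILES drawn from cluster-specific structural families) and typed event
lists whose labels are a function of endpoint chemistry clusters with
controllable coupling, so recoverability is known by construction.

All numerics run on a small numpy reverse-mode autodiff engine included in
the package; no GPU or deep-learning framework is required.

## Worked example

```python
import ddirisk as dr

# a synthetic 4-level network whose labels are determined by chemistry
cfg = dr.imbalance_preset("ddinter4", n_drugs=120,
                          feature_label_coupling=1.0, seed=3)
drugs, events, truth = dr.generate_network(cfg)

model = dr.DrugInteractionModel(events, drugs,
                                dr.TrainConfig.desk_scale(seed=0))
res = model.fit()
print(res.summary())
```

prints (numbers from this exact run):

```
DDI risk-level classification results
====================================================
encoder                 aergcn
ablation variant        none
event classes (R)       4
drugs / events          120 / 214
training edges          214
feature dim (k)         64
hidden width            64
parameters              82340
epochs                  80
final train loss        0.0086
----------------------------------------------------
train accuracy          1.0000
train macro F1          1.0000
train micro AUC         1.0000
====================================================
```

The summary reports the fitted configuration, capacity and training-set
diagnostics; held-out performance comes from cross-validation:

```python
reports, summary = model.cross_validate(task=1)   # 5-fold, stratified
print(summary["acc"])   # {'mean': 0.7476..., 'std': 0.0578...} at this size
split = model.make_splits()    # cold-start partition
res = model.fit(split)
print(res.evaluate(split.task2_edges).acc)   # 0.6190 on novel-drug pairs
```

(214 events over 120 drugs is a deliberately tiny example; at the study
scale of 300 drugs / ~1350 events the five-fold Task-1 accuracy exceeds
0.95 — see `scripts/acceptance.py`.)

A `ddirisk` command-line interface exposes the same pipeline
(`simulate`, `featurize`, `split`, `train`, `evaluate`, `ablate`).

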