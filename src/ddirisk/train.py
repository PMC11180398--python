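"""Training, cold-start splitting, cross-validation, metrics, ablations.

Training minimizes the multi-class cross-entropy J = -(1/m) sum log p[y]
with AdamW, full-graph and full-batch: every epoch scores all training
edges against the message-passing graph built from training edges only.

Cold-start protocol: drugs are partitioned into *confirmed* and *novel*
sets; events split into Task 1 (both endpoints confirmed), Task 2 (exactly
one novel endpoint) and Task 3 (both novel).  The model is trained on Task 1
edges only — novel-endpoint edges never appear in the training set nor in
the message-passing graph — and evaluated on each task separately.

Metrics: accuracy on argmax predictions, micro-averaged AUPR and AUC over
the one-vs-rest binarized label matrix, and macro-averaged F1 / precision /
recall (plus micro recall, which for single-label argmax predictions equals
accuracy).  Classes absent from the test fold are excluded from macro
averages with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import (average_precision_score, f1_score,
                             multilabel_confusion_matrix, precision_score,
                             recall_score, roc_auc_score)
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split
from sklearn.preprocessing import label_binarize

from .autodiff import AdamW, Tensor
from .baselines import BaselineConfig, BaselineModel
from .featurize import (FingerprintConfig, assemble_edge_features,
                        featurize_nodes)
from .graph import DDIEvent, DrugRecord, HeteroGraph, build_hetero_graph
from .layers import ABLATIONS, AERGCN

EPS_PROB = 1e-12


@dataclass
class TrainConfig:
    epochs: int = 300
    learning_rate: float = 1e-3
    weight_decay: float = 1e-2
    seed: int = 0
    ablation: str = "none"              # none | no_fp | no_at | no_ep
    feature_dim: int = 300              # PCA target dimension k
    hidden: int = 128
    n_heads: int = 4
    num_bases: int | None = None        # default: one basis per risk level
    decomposition: str = "basis"
    value_mode: str = "sum_inputs"
    encoder: str = "aergcn"             # aergcn | gcn | gat | sage
    sage_aggregator: str = "mean"
    gat_heads: int = 1
    attn_batch_size: int = 512
    fingerprint_radius: int = 2
    fingerprint_bits: int = 2048
    novel_fraction: float = 0.2
    validation_fraction: float = 0.0   # >0 enables early stopping
    patience: int = 10
    dtype: type = np.float64

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.ablation not in ABLATIONS:
            raise ValueError(f"unknown ablation {self.ablation!r}")

    @classmethod
    def desk_scale(cls, **overrides) -> "TrainConfig":
        """Configuration for the desk-scale synthetic studies: a few
        hundred drugs, a few thousand events, single CPU.  Smaller widths
        and a shorter, more strongly regularized optimization than the
        generic defaults."""
        base = dict(epochs=80, learning_rate=5e-3, weight_decay=0.05,
                    feature_dim=64, hidden=64, n_heads=4,
                    attn_batch_size=256, validation_fraction=0.15,
                    patience=15)
        base.update(overrides)
        return cls(**base)


@dataclass
class SplitSpec:
    confirmed_drugs: set[str]
    novel_drugs: set[str]
    task1_edges: list[DDIEvent]
    task2_edges: list[DDIEvent]
    task3_edges: list[DDIEvent]
    fold_id: int = 0
    seed: int = 0

    def task_edges(self, task: int) -> list[DDIEvent]:
        return {1: self.task1_edges, 2: self.task2_edges,
                3: self.task3_edges}[task]


@dataclass
class MetricsReport:
    acc: float
    aupr_micro: float | None
    auc_micro: float | None
    f1_macro: float
    precision: float
    recall: float
    recall_micro: float
    n_samples: int
    per_class: pd.DataFrame = field(repr=False, default=None)

    def as_dict(self) -> dict:
        d = asdict(self)
        d.pop("per_class")
        return d


# ------------------------------------------------------------------- loss

def cross_entropy_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """J = -(1/m) sum_i log p[i, y_i] on probability rows.

    Probabilities are clamped below at 1e-12 so a zero probability at the
    true label yields a large finite penalty instead of infinity.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    if labels.min() < 0 or labels.max() >= probs.shape[1]:
        raise ValueError("labels outside [0, R)")
    picked = probs[np.arange(len(labels)), labels]
    return float(-np.mean(np.log(np.maximum(picked, EPS_PROB))))


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Differentiable cross-entropy from logits (stable log-softmax)."""
    m = logits.data.max(axis=1, keepdims=True)
    shifted = logits - Tensor(m)
    logp = shifted - shifted.exp().sum(axis=1, keepdims=True).log()
    onehot = np.zeros(logits.shape, dtype=logits.data.dtype)
    onehot[np.arange(len(labels)), labels] = 1.0
    return -(logp * Tensor(onehot)).sum() * (1.0 / len(labels))


def predict_proba(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ------------------------------------------------------------------ splits

def make_task_splits(events: list[DDIEvent], drug_ids: list[str],
                     novel_fraction: float, seed: int,
                     fold_id: int = 0) -> SplitSpec:
    """Sample novel drugs and partition events into the three task sets."""
    if not 0 < novel_fraction < 1:
        raise ValueError("novel_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    ids = sorted(drug_ids)
    n_novel = math.ceil(novel_fraction * len(ids))
    novel = set(rng.choice(ids, size=n_novel, replace=False).tolist())
    confirmed = set(ids) - novel
    t1, t2, t3 = [], [], []
    for ev in events:
        k = (ev.drug_a in novel) + (ev.drug_b in novel)
        (t1, t2, t3)[k].append(ev)
    if not t1:
        raise ValueError("novel set empties Task 1; use a smaller "
                         "novel_fraction")
    return SplitSpec(confirmed, novel, t1, t2, t3, fold_id=fold_id, seed=seed)


# ----------------------------------------------------------------- metrics

def compute_metrics(y_true: np.ndarray, probs: np.ndarray,
                    n_classes: int | None = None) -> MetricsReport:
    y_true = np.asarray(y_true, dtype=np.int64)
    probs = np.asarray(probs, dtype=np.float64)
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    R = n_classes or probs.shape[1]
    y_pred = probs.argmax(axis=1)
    present = np.unique(y_true)
    if len(present) < R:
        warnings.warn(f"classes {sorted(set(range(R)) - set(present))} absent "
                      "from test labels; excluded from macro averages",
                      stacklevel=2)
    acc = float((y_pred == y_true).mean())
    f1 = float(f1_score(y_true, y_pred, labels=present, average="macro",
                        zero_division=0))
    prec = float(precision_score(y_true, y_pred, labels=present,
                                 average="macro", zero_division=0))
    rec = float(recall_score(y_true, y_pred, labels=present, average="macro",
                             zero_division=0))
    rec_micro = float(recall_score(y_true, y_pred, labels=present,
                                   average="micro", zero_division=0))
    y_bin = label_binarize(y_true, classes=np.arange(R))
    if R == 2 and y_bin.shape[1] == 1:  # sklearn collapses binary
        y_bin = np.hstack([1 - y_bin, y_bin])
    if len(np.unique(y_bin.ravel())) < 2:
        aupr = auc = None  # degenerate truth: curves undefined
    else:
        aupr = float(average_precision_score(y_bin, probs, average="micro"))
        auc = float(roc_auc_score(y_bin.ravel(), probs.ravel()))
    mcm = multilabel_confusion_matrix(y_true, y_pred, labels=np.arange(R))
    per_class = pd.DataFrame(
        {"TN": mcm[:, 0, 0], "FP": mcm[:, 0, 1],
         "FN": mcm[:, 1, 0], "TP": mcm[:, 1, 1]},
        index=pd.Index(np.arange(R), name="class"))
    return MetricsReport(acc=acc, aupr_micro=aupr, auc_micro=auc, f1_macro=f1,
                         precision=prec, recall=rec, recall_micro=rec_micro,
                         n_samples=len(y_true), per_class=per_class)


def summarize(reports: list[MetricsReport]) -> dict:
    """Mean and standard deviation of each scalar metric across folds."""
    keys = ["acc", "aupr_micro", "auc_micro", "f1_macro", "precision",
            "recall", "recall_micro"]
    out = {}
    for k in keys:
        vals = [getattr(r, k) for r in reports if getattr(r, k) is not None]
        if vals:
            out[k] = {"mean": float(np.mean(vals)), "std": float(np.std(vals))}
    return out


# ---------------------------------------------------------------- training

def _events_to_arrays(events: list[DDIEvent], graph: HeteroGraph
                      ) -> tuple[np.ndarray, np.ndarray]:
    pairs = np.array([[graph.index_of(e.drug_a), graph.index_of(e.drug_b)]
                      for e in events], dtype=np.int64).reshape(-1, 2)
    labels = np.array([e.label for e in events], dtype=np.int64)
    return pairs, labels


def _message_graph(pairs: np.ndarray, labels: np.ndarray, n_nodes: int,
                   n_relations: int, features: np.ndarray
                   ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Double-entry arc lists per relation plus per-arc edge features."""
    relations, edge_feats = [], []
    for r in range(n_relations):
        sel = pairs[labels == r]
        arcs = np.concatenate([sel, sel[:, ::-1]], axis=0) if len(sel) \
            else np.zeros((0, 2), dtype=np.int64)
        relations.append(arcs)
        edge_feats.append(assemble_edge_features(features, arcs)
                          if len(arcs) else np.zeros((0, 2 * features.shape[1])))
    return relations, edge_feats


def node_features(drugs: list[DrugRecord], config: TrainConfig) -> np.ndarray:
    """PCA-reduced fingerprints, or one-hot rows under the no_fp ablation
    (topology-only: node identity carries no chemistry)."""
    order = np.argsort([d.drug_id for d in drugs])
    drugs_sorted = [drugs[i] for i in order]
    if config.ablation == "no_fp":
        return np.eye(len(drugs_sorted))
    fp_cfg = FingerprintConfig(config.fingerprint_radius,
                               config.fingerprint_bits)
    feats, _ = featurize_nodes(drugs_sorted, fp_cfg, config.feature_dim)
    return feats


def make_model(config: TrainConfig, n_relations: int, in_dim: int,
               edge_dim: int):
    if config.encoder == "aergcn":
        return AERGCN(n_relations=n_relations, in_dim=in_dim,
                      edge_dim=edge_dim, hidden=config.hidden,
                      n_heads=config.n_heads, num_bases=config.num_bases,
                      decomposition=config.decomposition,
                      value_mode=config.value_mode, ablation=config.ablation,
                      attn_batch_size=config.attn_batch_size,
                      seed=config.seed, dtype=config.dtype)
    bcfg = BaselineConfig(encoder=config.encoder, layers=2,
                          width=config.hidden,
                          sage_aggregator=config.sage_aggregator,
                          gat_heads=config.gat_heads)
    return BaselineModel(bcfg, n_classes=n_relations, in_dim=in_dim,
                         edge_dim=edge_dim, seed=config.seed,
                         dtype=config.dtype)


def fit_edges(graph: HeteroGraph, features: np.ndarray,
              train_events: list[DDIEvent], config: TrainConfig,
              n_relations: int):
    """Train a model on the given edges (message graph = these edges only).

    With ``config.validation_fraction > 0``, training runs in two phases:
    a stratified slice of the training edges is first held out of both the
    loss and the message-passing graph, and training stops once holdout
    accuracy has not improved (or tied its best) for ``config.patience``
    epochs; the epoch of the best holdout accuracy then sets the schedule
    for a fresh fit on all training edges.  Under noisy labels the
    selected schedule is short and the fit collapses to the best simple
    predictor instead of memorizing topology; under clean labels the full
    schedule is retained.

    Returns ``(model, context, history)`` where ``context`` carries the
    message-passing arrays needed for prediction and ``history`` the
    per-epoch training loss of the final fit.
    """
    if not train_events:
        raise ValueError("training edge set is empty")
    all_pairs, all_labels = _events_to_arrays(train_events, graph)
    pairs, labels = all_pairs, all_labels
    val_pairs = val_labels = None
    if config.validation_fraction > 0 and len(train_events) >= 20:
        idx = np.arange(len(train_events))
        strat = labels if np.bincount(labels).min() >= 2 else None
        tr_idx, va_idx = train_test_split(
            idx, test_size=config.validation_fraction,
            random_state=config.seed, stratify=strat)
        tr_idx.sort(), va_idx.sort()
        pairs, val_pairs = all_pairs[tr_idx], all_pairs[va_idx]
        labels, val_labels = all_labels[tr_idx], all_labels[va_idx]
    X = features.astype(config.dtype)
    relations, edge_feats = _message_graph(pairs, labels, graph.n_nodes,
                                           n_relations, X)
    train_ef = assemble_edge_features(X, pairs)
    model = make_model(config, n_relations, X.shape[1], 2 * X.shape[1])
    opt = AdamW(model.parameters(), lr=config.learning_rate,
                weight_decay=config.weight_decay)
    params = model.parameters()
    val_ef = assemble_edge_features(X, val_pairs) \
        if val_pairs is not None else None
    history, val_history = [], []
    best_val, best_epoch, stale = -np.inf, config.epochs, 0
    for epoch in range(config.epochs):
        logits = model.edge_scores(relations, X, edge_feats, pairs, train_ef)
        loss = softmax_cross_entropy(logits, labels)
        val = float(loss.data)
        if not np.isfinite(val):
            raise RuntimeError(
                f"non-finite loss {val} at epoch {epoch}; last finite loss "
                f"{history[-1] if history else 'n/a'}; try a lower "
                "learning rate")
        history.append(val)
        opt.zero_grad()
        loss.backward()
        opt.step()
        if val_pairs is not None:
            vlogits = model.edge_scores(relations, X, edge_feats, val_pairs,
                                        val_ef)
            vacc = float((vlogits.data.argmax(axis=1) == val_labels).mean())
            val_history.append(vacc)
            if vacc >= best_val:
                # ties refresh the selected epoch: holdout accuracy is
                # coarse on a small slice, and continued training on a
                # plateau keeps sharpening the decision boundary
                best_val, stale, best_epoch = vacc, 0, epoch + 1
            else:
                stale += 1
                if stale >= config.patience:
                    break
    if val_pairs is not None:
        # phase 2: refit on all training edges for the selected schedule
        refit_cfg = TrainConfig(**{**asdict_config(config),
                                   "validation_fraction": 0.0,
                                   "epochs": best_epoch})
        model, context, history = fit_edges(graph, features, train_events,
                                            refit_cfg, n_relations)
        context["val_history"] = val_history
        context["selected_epochs"] = best_epoch
        return model, context, history
    context = {"relations": relations, "edge_features": edge_feats,
               "X": X, "n_relations": n_relations,
               "val_history": val_history}
    return model, context, history


def train(graph: HeteroGraph, features: np.ndarray, split: SplitSpec,
          config: TrainConfig):
    """Train on the confirmed-pair (Task 1) edges of a cold-start split."""
    return fit_edges(graph, features, split.task1_edges, config,
                     graph.n_relations)


def predict_events(model, context: dict, graph: HeteroGraph,
                   events: list[DDIEvent]) -> tuple[np.ndarray, np.ndarray]:
    pairs, labels = _events_to_arrays(events, graph)
    ef = assemble_edge_features(context["X"], pairs)
    logits = model.edge_scores(context["relations"], context["X"],
                               context["edge_features"], pairs, ef)
    return predict_proba(logits.data), labels


def evaluate(model, context: dict, graph: HeteroGraph,
             events: list[DDIEvent]) -> MetricsReport:
    probs, labels = predict_events(model, context, graph, events)
    return compute_metrics(labels, probs, context["n_relations"])


# ----------------------------------------------------- cross-validation

def _stratified_folds(labels: np.ndarray, n_folds: int, seed: int):
    counts = np.bincount(labels)
    present = counts[counts > 0]
    if present.min() < n_folds:
        warnings.warn("a class has fewer members than folds; falling back "
                      "to unstratified folds", stacklevel=2)
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        return kf.split(labels)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return skf.split(np.zeros(len(labels)), labels)


def five_fold_cv(events: list[DDIEvent], drugs: list[DrugRecord],
                 config: TrainConfig, task: int = 1, n_folds: int = 5,
                 features: np.ndarray | None = None
                 ) -> tuple[list[MetricsReport], dict]:
    """Cross-validated evaluation.

    Task 1 folds over edges (stratified by class); Tasks 2 and 3 fold over
    the novel-drug sampling seed, training on Task 1 edges each time.
    Returns per-fold reports and a mean/std summary.
    """
    n_relations = max(e.label for e in events) + 1
    graph = build_hetero_graph(events, drugs, n_relations)
    counts = np.bincount([e.label for e in events], minlength=n_relations)
    if (counts > 0).any() and counts[counts > 0].min() < n_folds:
        warnings.warn("fewer than %d events in some class" % n_folds,
                      stacklevel=2)
    if features is None:
        features = node_features(drugs, config)
    reports = []
    if task == 1:
        _, labels = _events_to_arrays(events, graph)
        for fold, (tr, te) in enumerate(
                _stratified_folds(labels, n_folds, config.seed)):
            train_ev = [events[i] for i in tr]
            test_ev = [events[i] for i in te]
            model, ctx, _ = fit_edges(graph, features, train_ev, config,
                                      n_relations)
            reports.append(evaluate(model, ctx, graph, test_ev))
    elif task in (2, 3):
        for fold in range(n_folds):
            split = make_task_splits(events, graph.nodes,
                                     config.novel_fraction,
                                     seed=config.seed + fold, fold_id=fold)
            model, ctx, _ = fit_edges(graph, features, split.task1_edges,
                                      config, n_relations)
            test_ev = split.task_edges(task)
            if not test_ev:
                warnings.warn(f"fold {fold}: empty Task {task} test set",
                              stacklevel=2)
                continue
            reports.append(evaluate(model, ctx, graph, test_ev))
    else:
        raise ValueError("task must be 1, 2 or 3")
    return reports, summarize(reports)


def run_ablation(events: list[DDIEvent], drugs: list[DrugRecord],
                 variants: list[str], config: TrainConfig,
                 tasks: tuple[int, ...] = (1,), n_folds: int = 5
                 ) -> pd.DataFrame:
    """Paired ablation comparison: identical splits and seeds per variant.

    The fingerprint variant (``no_fp``) swaps features, so features are
    computed per variant; fold membership depends only on ``config.seed``
    and is therefore shared.
    """
    unknown = set(variants) - set(ABLATIONS)
    if unknown:
        raise ValueError(f"unknown ablation variants {sorted(unknown)}")
    rows = []
    for task in tasks:
        for variant in variants:
            cfg = TrainConfig(**{**asdict_config(config), "ablation": variant})
            reports, _ = five_fold_cv(events, drugs, cfg, task=task,
                                      n_folds=n_folds)
            for fold, rep in enumerate(reports):
                rows.append({"task": task, "variant": variant, "fold": fold,
                             **rep.as_dict()})
    return pd.DataFrame(rows)


def asdict_config(config: TrainConfig) -> dict:
    d = asdict(config)
    d["dtype"] = config.dtype
    return d
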