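"""Model/Results interface over the DDI risk-level pipeline.

`DrugInteractionModel` bundles a typed event list, the drug table and a
configuration; ``fit()`` runs featurization and training and returns a
`DrugInteractionResults` carrying the trained parameters, the loss history,
training-set diagnostics and a ``summary()`` table.  Cross-validation and
the cold-start protocol hang off the model object.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .graph import (DDINTER_LABEL_MAP, DDIEvent, DrugRecord,
                    build_hetero_graph, read_edge_list, read_smiles_table)
from .train import (MetricsReport, SplitSpec, TrainConfig, asdict_config,
                    compute_metrics, evaluate, fit_edges, five_fold_cv,
                    make_task_splits, node_features, predict_events,
                    run_ablation, summarize)


class DrugInteractionModel:
    """Multi-class DDI risk-level classifier over a heterogeneous graph.

    Parameters
    ----------
    events : list of DDIEvent
        Undirected typed interaction events.
    drugs : list of DrugRecord
        Drug table; every event endpoint must be present.
    config : TrainConfig, optional
        Training and architecture configuration.
    n_relations : int, optional
        Number of event classes; inferred from labels when omitted.
    """

    def __init__(self, events: list[DDIEvent], drugs: list[DrugRecord],
                 config: TrainConfig | None = None,
                 n_relations: int | None = None):
        self.config = config or TrainConfig()
        self.events = list(events)
        self.drugs = list(drugs)
        self.n_relations = n_relations or max(e.label for e in events) + 1
        self.graph = build_hetero_graph(self.events, self.drugs,
                                        self.n_relations)
        self._features: np.ndarray | None = None

    @classmethod
    def from_files(cls, edge_path, smiles_path,
                   label_map: dict[str, int] = DDINTER_LABEL_MAP,
                   config: TrainConfig | None = None,
                   n_relations: int | None = None) -> "DrugInteractionModel":
        events = read_edge_list(edge_path, label_map)
        drugs, report = read_smiles_table(smiles_path)
        if report["n_dropped"]:
            kept = {d.drug_id for d in drugs}
            events = [e for e in events
                      if e.drug_a in kept and e.drug_b in kept]
        return cls(events, drugs, config=config, n_relations=n_relations)

    @property
    def exog_names(self) -> list[str]:
        return self.graph.nodes

    def features(self) -> np.ndarray:
        """Node feature matrix (computed lazily, cached)."""
        if self._features is None:
            self._features = node_features(self.drugs, self.config)
        return self._features

    def make_splits(self, novel_fraction: float | None = None,
                    seed: int | None = None) -> SplitSpec:
        return make_task_splits(
            self.events, self.graph.nodes,
            novel_fraction or self.config.novel_fraction,
            self.config.seed if seed is None else seed)

    def fit(self, split: SplitSpec | None = None) -> "DrugInteractionResults":
        """Train on the Task 1 edges of ``split`` (all events if None)."""
        train_events = split.task1_edges if split is not None else self.events
        net, ctx, history = fit_edges(self.graph, self.features(),
                                      train_events, self.config,
                                      self.n_relations)
        return DrugInteractionResults(self, net, ctx, history, train_events,
                                      split)

    def cross_validate(self, task: int = 1, n_folds: int = 5
                       ) -> tuple[list[MetricsReport], dict]:
        return five_fold_cv(self.events, self.drugs, self.config, task=task,
                            n_folds=n_folds, features=self.features())

    def ablate(self, variants=("none", "no_fp", "no_at", "no_ep"),
               tasks: tuple[int, ...] = (1,), n_folds: int = 5
               ) -> pd.DataFrame:
        return run_ablation(self.events, self.drugs, list(variants),
                            self.config, tasks=tasks, n_folds=n_folds)


class DrugInteractionResults:
    """Fitted-state container: parameters, loss history, diagnostics."""

    def __init__(self, model: DrugInteractionModel, network, context,
                 history: list[float], train_events: list[DDIEvent],
                 split: SplitSpec | None):
        self.model = model
        self.network = network
        self.context = context
        self.history = list(history)
        self.train_events = train_events
        self.split = split

    @property
    def final_loss(self) -> float:
        return self.history[-1]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.network.parameters().values())

    def predict(self, events: list[DDIEvent]) -> np.ndarray:
        """Class probabilities for the given drug pairs."""
        probs, _ = predict_events(self.network, self.context,
                                  self.model.graph, events)
        return probs

    def evaluate(self, events: list[DDIEvent]) -> MetricsReport:
        return evaluate(self.network, self.context, self.model.graph, events)

    def training_metrics(self) -> MetricsReport:
        return self.evaluate(self.train_events)

    def summary(self) -> str:
        cfg = self.model.config
        rep = self.training_metrics()
        lines = [
            "DDI risk-level classification results",
            "=" * 52,
            f"{'encoder':<24}{cfg.encoder}",
            f"{'ablation variant':<24}{cfg.ablation}",
            f"{'event classes (R)':<24}{self.model.n_relations}",
            f"{'drugs / events':<24}{self.model.graph.n_nodes} / "
            f"{len(self.model.events)}",
            f"{'training edges':<24}{len(self.train_events)}",
            f"{'feature dim (k)':<24}{self.context['X'].shape[1]}",
            f"{'hidden width':<24}{cfg.hidden}",
            f"{'parameters':<24}{self.n_parameters()}",
            f"{'epochs':<24}{cfg.epochs}",
            f"{'final train loss':<24}{self.final_loss:.4f}",
            "-" * 52,
            f"{'train accuracy':<24}{rep.acc:.4f}",
            f"{'train macro F1':<24}{rep.f1_macro:.4f}",
        ]
        if rep.auc_micro is not None:
            lines.append(f"{'train micro AUC':<24}{rep.auc_micro:.4f}")
        lines.append("=" * 52)
        return "\n".join(lines)

    # ------------------------------------------------------------- persist
    def save(self, path) -> None:
        """Single-archive checkpoint: parameter arrays + JSON manifest."""
        params = {k: p.data for k, p in self.network.parameters().items()}
        cfg = asdict_config(self.model.config)
        cfg["dtype"] = np.dtype(cfg["dtype"]).name
        manifest = {"config": cfg, "n_relations": self.model.n_relations,
                    "param_names": sorted(params),
                    "history_tail": self.history[-5:]}
        arrays = {f"param::{k}": v for k, v in params.items()}
        arrays["manifest"] = np.frombuffer(
            json.dumps(manifest).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    def load_params(self, path) -> None:
        """Restore parameter arrays from a checkpoint into this network."""
        with np.load(path) as archive:
            params = self.network.parameters()
            for key in archive.files:
                if key.startswith("param::"):
                    params[key[len("param::"):]].data = archive[key]
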