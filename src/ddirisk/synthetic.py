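"""Synthetic multi-relational DDI networks with planted label structure.

The generator emulates the shape of curated DDI datasets — a few thousand
drugs, a typed undirected event network with strong class imbalance — while
making label recoverability controllable by construction:

- every drug is assigned a latent *cluster* and receives a valid toy SMILES
  drawn from that cluster's structural family (aliphatic, aromatic,
  halogenated, N-heterocyclic, ...), so Morgan fingerprints correlate with
  clusters;
- each cluster carries a latent hazard score, and each unordered cluster
  pair is mapped to an event class by bucketing the combined hazard so
  that class frequencies match the requested proportions (risk levels are
  ordinal: a larger coefficient means a higher risk rating, so the planted
  table is monotone in combined hazard; a random surjective table is
  available as ``table_mode="random"``);
- each sampled drug pair takes its label from that table with probability
  ``feature_label_coupling``, and otherwise from the class proportions
  independently of the endpoints.

At coupling 1.0 the Bayes-optimal classifier on endpoint clusters is
perfect; at coupling 0.0 features carry no label information and the best
achievable accuracy is the largest class proportion.

Presets mirror the class-imbalance regimes of public DDI resources: a
four-level severity regime (Unknown/Minor/Moderate/Major with proportions
0.213 / 0.049 / 0.586 / 0.152) and a 65-type long-tailed event regime.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .graph import DDIEvent, DrugRecord

#: Structural families used as cluster signatures.  All strings are valid
#: SMILES (asserted by the test suite via RDKit).
SMILES_FAMILIES: list[list[str]] = [
    # aliphatic chains and alcohols
    ["CCO", "CCCO", "CCCC", "CC(C)O", "CCOC", "CCCCO", "CC(C)CO",
     "CCC(C)O", "CCCCC", "OCCO"],
    # benzenes and phenols
    ["c1ccccc1", "Cc1ccccc1", "CCc1ccccc1", "Oc1ccccc1", "COc1ccccc1",
     "Cc1ccccc1C", "Cc1ccc(C)cc1", "Oc1ccc(C)cc1", "CCc1ccc(O)cc1",
     "COc1ccc(C)cc1"],
    # halogenated small molecules
    ["ClCCCl", "FC(F)F", "CCCCl", "CCCBr", "ClC(Cl)Cl", "FCCF",
     "ClCCBr", "FCCCF", "CC(Cl)C", "BrCCBr"],
    # amines and N-heterocycles
    ["c1ccncc1", "Cc1ccncc1", "Cc1cccnc1", "NCCN", "CCN", "c1cc[nH]c1",
     "CCNCC", "Nc1ccncc1", "CCCN", "NCCCN"],
    # carbonyls and acids
    ["CC(=O)O", "CC(=O)C", "CCC(=O)O", "CC(=O)OC", "CC(=O)N",
     "CC(=O)NC", "O=CC", "CCC(=O)C", "OC(=O)CC(=O)O", "CC(=O)CC"],
    # thioethers and sulfoxides
    ["CCS", "CSC", "CCSC", "SCCS", "CS(=O)C", "CCCS", "CSSC",
     "CCS(=O)C", "SCCCS", "CCCSC"],
    # saturated rings
    ["C1CCCCC1", "C1CCOC1", "C1CCNCC1", "C1CCOCC1", "CC1CCCCC1",
     "C1CCC(O)CC1", "C1CCNC1", "OC1CCCC1", "CC1CCOC1", "C1CCSC1"],
    # nitriles and alkenes
    ["CC#N", "C=CC", "CC=CC", "C=CCO", "N#CCC", "C=CCC", "CC(=C)C",
     "C=CCN", "N#CCO", "C=CCCC"],
]


@dataclass(frozen=True)
class SyntheticConfig:
    n_drugs: int = 300
    n_relations: int = 4
    class_proportions: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    feature_label_coupling: float = 1.0
    n_clusters: int = 4
    edge_density: float = 0.03
    table_mode: str = "ordinal"  # ordinal | random
    seed: int = 0

    def __post_init__(self):
        if self.table_mode not in ("ordinal", "random"):
            raise ValueError(f"unknown table_mode {self.table_mode!r}")
        if len(self.class_proportions) != self.n_relations:
            raise ValueError("class_proportions length must equal n_relations")
        if not math.isclose(sum(self.class_proportions), 1.0, abs_tol=1e-6):
            raise ValueError("class_proportions must sum to 1")
        if not 0.0 <= self.feature_label_coupling <= 1.0:
            raise ValueError("feature_label_coupling must be in [0, 1]")
        if not 0.0 < self.edge_density <= 1.0:
            raise ValueError("edge_density must be in (0, 1]")
        n_pairs = self.n_clusters * (self.n_clusters + 1) // 2
        if n_pairs < self.n_relations:
            raise ValueError(
                f"{self.n_clusters} clusters give only {n_pairs} cluster "
                f"pairs, fewer than {self.n_relations} classes")


def imbalance_preset(name: str, **overrides) -> SyntheticConfig:
    """Named class-imbalance regimes.

    ``ddinter4``: four severity levels with proportions mirroring the
    curated four-level resource (Unknown 0.213, Minor 0.049, Moderate
    0.586, Major 0.152).  ``drugbank65``: 65 event types with a long-tailed
    (power-law) proportion vector.
    """
    if name == "ddinter4":
        counts = np.array([47182.0, 10861.0, 129472.0, 33617.0])
        props = tuple(counts / counts.sum())
        base = dict(n_relations=4, class_proportions=props, n_clusters=4)
    elif name == "drugbank65":
        ranks = np.arange(1, 66, dtype=np.float64)
        w = ranks ** -1.2
        props = tuple(w / w.sum())
        base = dict(n_relations=65, class_proportions=props, n_clusters=12,
                    n_drugs=600, edge_density=0.1)
    else:
        raise ValueError(f"unknown preset {name!r}")
    base.update(overrides)
    return SyntheticConfig(**base)


def _cluster_pair_table(rng: np.random.Generator, n_clusters: int,
                        proportions: np.ndarray,
                        mode: str = "ordinal") -> np.ndarray:
    """Symmetric cluster-pair -> class table; every class reachable.

    ``ordinal`` (default): clusters draw latent hazard scores and the
    combined hazard of a pair is bucketed into classes, filling classes in
    rank order so that expected class frequencies (under a uniform cluster
    assignment) approximate ``proportions``.  ``random``: each pair draws
    its class independently from ``proportions`` (surjectivity forced).
    """
    R = len(proportions)
    table = np.zeros((n_clusters, n_clusters), dtype=np.int64)
    pairs = [(i, j) for i in range(n_clusters) for j in range(i, n_clusters)]
    hazard = None
    if mode == "random":
        labels = rng.choice(R, size=len(pairs), p=proportions)
        missing = [c for c in range(R) if c not in labels]
        if missing:  # force surjectivity onto the class set
            override = rng.choice(len(pairs), size=len(missing), replace=False)
            for c, k in zip(missing, override):
                labels[k] = c
    else:
        hazard = rng.normal(size=n_clusters)
        score = np.array([hazard[i] + hazard[j] for i, j in pairs])
        # weight of each unordered pair under uniform cluster assignment
        weight = np.array([1.0 if i == j else 2.0 for i, j in pairs])
        weight = weight / weight.sum()
        order = np.argsort(score, kind="stable")
        cum_target = np.cumsum(proportions)
        labels = np.zeros(len(pairs), dtype=np.int64)
        acc, cls = 0.0, 0
        remaining = len(order)
        for pos, k in enumerate(order):
            # keep at least one pair per remaining class (surjectivity)
            if remaining <= R - 1 - cls:
                cls += 1
            labels[k] = cls
            acc += weight[k]
            remaining -= 1
            # advance at most one class per assigned pair: keeps the table
            # surjective (there are >= R cluster pairs by construction)
            if cls < R - 1 and acc >= cum_target[cls]:
                cls += 1
    for (i, j), lab in zip(pairs, labels):
        table[i, j] = table[j, i] = lab
    return table, hazard


def generate_network(config: SyntheticConfig
                     ) -> tuple[list[DrugRecord], list[DDIEvent], dict]:
    """Sample a drug table, a typed event list and the ground truth.

    Returns ``(drugs, events, truth)`` where ``truth`` records the cluster
    assignment and the cluster-pair label table for oracle tests.  Output
    is a deterministic function of the config (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_drugs
    width = len(str(n - 1))
    ids = [f"D{idx:0{width}d}" for idx in range(n)]
    clusters = np.tile(np.arange(config.n_clusters),
                       n // config.n_clusters + 1)[:n]
    rng.shuffle(clusters)
    drugs = []
    for idx, did in enumerate(ids):
        family = SMILES_FAMILIES[clusters[idx] % len(SMILES_FAMILIES)]
        drugs.append(DrugRecord(did, family[rng.integers(len(family))]))

    props = np.asarray(config.class_proportions, dtype=np.float64)
    table, hazard = _cluster_pair_table(rng, config.n_clusters, props,
                                        config.table_mode)

    iu, ju = np.triu_indices(n, k=1)
    n_edges = int(round(config.edge_density * len(iu)))
    if n_edges < 1:
        raise ValueError("edge_density too small: no edges to sample")
    chosen = rng.choice(len(iu), size=n_edges, replace=False)
    planted = rng.random(n_edges) < config.feature_label_coupling
    random_labels = rng.choice(config.n_relations, size=n_edges, p=props)
    events = []
    for k, sel in enumerate(chosen):
        i, j = int(iu[sel]), int(ju[sel])
        lab = int(table[clusters[i], clusters[j]]) if planted[k] \
            else int(random_labels[k])
        events.append(DDIEvent(ids[i], ids[j], lab))
    truth = {"clusters": {did: int(c) for did, c in zip(ids, clusters)},
             "label_table": table.tolist(),
             "cluster_hazard": hazard.tolist() if hazard is not None else None,
             "config": {"n_drugs": n, "n_relations": config.n_relations,
                        "feature_label_coupling": config.feature_label_coupling,
                        "seed": config.seed}}
    return drugs, events, truth


# --------------------------------------------------------------- file I/O

FOUR_LEVEL_NAMES = ["Unknown", "Minor", "Moderate", "Major"]


def write_drug_table(drugs: list[DrugRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for d in drugs:
            fh.write(f"{d.drug_id}\t{d.smiles}\n")


def write_edge_list(events: list[DDIEvent], path: str | Path,
                    label_names: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("drug_a\tdrug_b\tlabel\n")
        for ev in events:
            lab = label_names[ev.label] if label_names else str(ev.label)
            fh.write(f"{ev.drug_a}\t{ev.drug_b}\t{lab}\n")


def write_ground_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)
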