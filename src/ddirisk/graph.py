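"""Heterogeneous drug-drug interaction graph: domain types, readers, builders.

A DDI network is modelled as a heterogeneous information graph G = (V, E):
drugs are nodes, and each interaction event is an undirected edge typed by
its risk level (or event class).  The same network can equivalently be viewed
as a symmetric risk-rating matrix Y whose entry y_ij is the risk coefficient
of the pair (i, j), with a sentinel for pairs without a recorded event.

Node order is the lexicographic sort of drug identifiers, so the index space
is a deterministic function of the drug set and never of file row order.
Undirected edges are stored double-entry (both directed arcs) because the
message-passing layers iterate over directed arcs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

#: Default mapping for the four-level severity regime.  Unknown is an
#: ordinary interaction class, ordered lowest so that a larger coefficient
#: means a higher risk rating.
DDINTER_LABEL_MAP = {"Unknown": 0, "Minor": 1, "Moderate": 2, "Major": 3}

#: Sentinel for "no recorded pair" in the risk-rating matrix.
NO_EVENT = -1


@dataclass
class DrugRecord:
    """A drug node: opaque identifier, SMILES, optional fingerprint."""

    drug_id: str
    smiles: str
    fingerprint: np.ndarray | None = None


@dataclass(frozen=True)
class DDIEvent:
    """One undirected typed edge: two distinct drugs and an integer class."""

    drug_a: str
    drug_b: str
    label: int

    def __post_init__(self):
        if self.drug_a == self.drug_b:
            raise ValueError(f"self-interaction {self.drug_a!r} is not allowed")

    @property
    def pair(self) -> frozenset:
        return frozenset((self.drug_a, self.drug_b))


@dataclass
class RiskRatingMatrix:
    """Symmetric integer matrix of risk coefficients with NO_EVENT sentinel."""

    n_drugs: int
    values: np.ndarray

    def __post_init__(self):
        v = self.values
        if v.shape != (self.n_drugs, self.n_drugs):
            raise ValueError("risk matrix shape mismatch")
        if not np.array_equal(v, v.T):
            raise ValueError("risk matrix must be symmetric")


@dataclass
class HeteroGraph:
    """Relation-partitioned adjacency over an ordered drug-node index space.

    ``relations[r]`` holds the directed double-entry arc list of relation
    ``r`` as an (m, 2) integer array; the unordered pair {i, j} appears in
    exactly one relation.
    """

    nodes: list[str]
    relations: list[np.ndarray]
    node_features: np.ndarray | None = None
    edge_features: list[np.ndarray] | None = None
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._index:
            self._index = {d: i for i, d in enumerate(self.nodes)}
        n = len(self.nodes)
        for r, arcs in enumerate(self.relations):
            if arcs.size and arcs.max() >= n:
                raise ValueError(f"relation {r} has an out-of-range endpoint")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_relations(self) -> int:
        return len(self.relations)

    def index_of(self, drug_id: str) -> int:
        return self._index[drug_id]

    def n_events(self) -> int:
        """Number of undirected typed edges (double entries counted once)."""
        return sum(len(a) // 2 for a in self.relations)


# --------------------------------------------------------------------- I/O


def _split_row(line: str) -> list[str]:
    sep = "\t" if "\t" in line else ("," if "," in line else None)
    return [f.strip() for f in line.rstrip("\n").split(sep)]


def read_edge_list(path: str | Path, label_map: dict[str, int]) -> list[DDIEvent]:
    """Read a typed edge list (TSV/CSV: drug_a, drug_b, label).

    A header row is skipped when its third column is not a known label or
    integer.  Row order is preserved.  Unknown labels, self-pairs and
    duplicate unordered pairs raise ``ValueError`` naming the offending row.
    """
    path = Path(path)
    events: list[DDIEvent] = []
    seen: dict[frozenset, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _split_row(line)
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns")
            a, b, lab = fields[0], fields[1], fields[2]
            if lineno == 1 and lab not in label_map and not _is_int(lab):
                continue  # header
            if lab in label_map:
                label = label_map[lab]
            elif _is_int(lab):
                label = int(lab)
            else:
                raise ValueError(f"{path}:{lineno}: unknown label {lab!r}")
            if a == b:
                raise ValueError(f"{path}:{lineno}: self-interaction {a!r}")
            pair = frozenset((a, b))
            if pair in seen:
                raise ValueError(
                    f"{path}:{lineno}: duplicate pair ({a}, {b}); "
                    f"first seen at line {seen[pair]}")
            seen[pair] = lineno
            events.append(DDIEvent(a, b, label))
    return events


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def read_smiles_table(path: str | Path) -> tuple[list[DrugRecord], dict]:
    """Read a two-column drug table (id, SMILES).

    Records whose SMILES does not parse are dropped with a logged warning,
    mirroring the curation step of removing drugs without usable structure
    descriptors.  Returns ``(records, drop_report)`` where the report counts
    and names the dropped identifiers.
    """
    path = Path(path)
    records: list[DrugRecord] = []
    dropped: list[str] = []
    seen: set[str] = set()
    lg = RDLogger.logger()
    lg.setLevel(RDLogger.CRITICAL)  # parse failures are reported by us
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = _split_row(line)
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns")
                drug_id, smiles = fields[0], fields[1]
                if drug_id in seen:
                    raise ValueError(f"{path}:{lineno}: duplicate drug id {drug_id!r}")
                seen.add(drug_id)
                if Chem.MolFromSmiles(smiles) is None:
                    dropped.append(drug_id)
                    logger.warning("dropping %s: unparseable SMILES %r",
                                   drug_id, smiles)
                    continue
                records.append(DrugRecord(drug_id, smiles))
    finally:
        lg.setLevel(RDLogger.ERROR)
    if not records and not dropped:
        raise ValueError(f"{path}: empty drug table")
    return records, {"n_dropped": len(dropped), "dropped_ids": dropped}


# ------------------------------------------------------------- construction


def build_hetero_graph(events: list[DDIEvent], drugs: list[DrugRecord],
                       n_relations: int) -> HeteroGraph:
    """Assemble the heterogeneous graph from events and drug records.

    Nodes are sorted by drug_id; every event is emitted into its label's
    relation as both directed arcs; isolated drugs are kept as nodes.
    """
    nodes = sorted({d.drug_id for d in drugs})
    index = {d: i for i, d in enumerate(nodes)}
    arcs: list[list[tuple[int, int]]] = [[] for _ in range(n_relations)]
    seen: dict[frozenset, int] = {}
    for ev in events:
        if ev.drug_a not in index or ev.drug_b not in index:
            missing = ev.drug_a if ev.drug_a not in index else ev.drug_b
            raise ValueError(f"event references unknown drug {missing!r}")
        if not 0 <= ev.label < n_relations:
            raise ValueError(f"label {ev.label} outside [0, {n_relations})")
        if ev.pair in seen:
            if seen[ev.pair] != ev.label:
                raise ValueError(
                    f"conflicting labels for pair ({ev.drug_a}, {ev.drug_b})")
            raise ValueError(f"duplicate pair ({ev.drug_a}, {ev.drug_b})")
        seen[ev.pair] = ev.label
        i, j = index[ev.drug_a], index[ev.drug_b]
        arcs[ev.label].append((i, j))
        arcs[ev.label].append((j, i))
    relations = [np.array(a, dtype=np.int64).reshape(-1, 2) for a in arcs]
    return HeteroGraph(nodes=nodes, relations=relations)


def risk_matrix(graph: HeteroGraph) -> RiskRatingMatrix:
    """Project the relation-partitioned graph onto the rating matrix Y."""
    n = graph.n_nodes
    values = np.full((n, n), NO_EVENT, dtype=np.int64)
    for r, arcs in enumerate(graph.relations):
        for i, j in arcs:
            values[i, j] = r
    np.fill_diagonal(values, 0)  # zero-diagonal sentinel: no self-interaction
    return RiskRatingMatrix(n_drugs=n, values=values)


def events_from_matrix(matrix: RiskRatingMatrix,
                       nodes: list[str]) -> list[DDIEvent]:
    """Re-extract the undirected labeled pair set from a rating matrix."""
    out = []
    iu, ju = np.triu_indices(matrix.n_drugs, k=1)
    for i, j in zip(iu, ju):
        lab = matrix.values[i, j]
        if lab != NO_EVENT:
            out.append(DDIEvent(nodes[i], nodes[j], int(lab)))
    return out
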