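"""Readers, writers and construction of the analysis-ready weighted interactome.

The interactome is a weighted, undirected protein-protein interaction (PPI)
network: nodes are gene/protein symbols, edge weights are interaction
confidences in (0, 1] (STRING-style combined scores, rescaled if necessary).
Construction keeps only high-confidence edges (weight >= ``high_conf``) and
then *rescues* every study gene (disease gene or drug target) that the
threshold removed, by re-adding its strongest sub-threshold interactions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "WeightedNetwork",
    "GeneSetCollection",
    "DrugTargetTable",
    "DrugTargetRecord",
    "NetworkBuildResult",
    "DRUG_CLASSES",
    "read_edge_list",
    "read_gene_list",
    "read_gmt",
    "read_drug_targets",
    "build_network",
    "load_network",
    "write_edge_list",
    "write_gene_list",
    "write_gmt",
    "write_drug_targets",
]

#: Drug classes recognised in drug->target tables.  The four approved-drug
#: classes are the clinical anti-rheumatic categories; ``herbal_component``
#: marks single ingredients of a multi-component formula.
DRUG_CLASSES = ("NSAID", "DMARD", "glucocorticoid", "biological", "herbal_component")

_CLASS_LOOKUP = {c.lower(): c for c in DRUG_CLASSES}


def _norm_symbol(sym: str) -> str:
    return sym.strip().upper()


class WeightedNetwork:
    """Undirected weighted interaction network with validated invariants.

    Wraps a :class:`networkx.Graph` whose edges carry a ``weight`` attribute
    in (0, 1].  Guarantees: no self-loops, no isolated nodes, symbols stored
    uppercase.  A fixed (sorted) node order is exposed for linear algebra.
    """

    def __init__(self, graph: nx.Graph):
        self._validate(graph)
        self.graph = graph
        self.node_order: tuple[str, ...] = tuple(sorted(graph.nodes))
        self.index: dict[str, int] = {v: i for i, v in enumerate(self.node_order)}

    @staticmethod
    def _validate(graph: nx.Graph) -> None:
        if graph.number_of_edges() == 0:
            raise ValueError("network has no edges")
        for u, v, w in graph.edges(data="weight"):
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            if w is None or not (0.0 < w <= 1.0):
                raise ValueError(f"edge ({u},{v}) weight {w!r} outside (0, 1]")
        isolated = [v for v, d in graph.degree() if d == 0]
        if isolated:
            raise ValueError(f"isolated nodes present: {sorted(isolated)[:5]}")

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, float]]) -> "WeightedNetwork":
        """Build from (a, b, weight) triples.

        Self-loops are dropped; duplicate edges keep the maximum weight
        (confidence scores are upper bounds on evidence).
        """
        g = nx.Graph()
        for a, b, w in edges:
            a, b = _norm_symbol(a), _norm_symbol(b)
            if a == b:
                continue
            if g.has_edge(a, b):
                if w > g[a][b]["weight"]:
                    g[a][b]["weight"] = float(w)
            else:
                g.add_edge(a, b, weight=float(w))
        return cls(g)

    # -- convenience views ------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_node(self, symbol: str) -> bool:
        return self.graph.has_node(symbol)

    def edge_weight(self, a: str, b: str) -> float:
        return self.graph[a][b]["weight"]

    def subgraph(self, members: Iterable[str]) -> nx.Graph:
        """Induced subgraph (plain ``nx.Graph``; may contain isolated nodes)."""
        return nx.Graph(self.graph.subgraph(members))

    def __contains__(self, symbol: str) -> bool:
        return self.graph.has_node(symbol)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"WeightedNetwork({self.number_of_nodes()} nodes, "
            f"{self.number_of_edges()} edges)"
        )


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (pathways) plus their universe.

    ``sets`` maps pathway_id -> (pathway_name, frozenset of member symbols).
    The universe is the union of all members: enrichment statistics are
    computed against the genes covered by the collection, not against the
    whole interactome.
    """

    sets: Mapping[str, tuple[str, frozenset[str]]]

    def __post_init__(self):
        for pid, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {pid!r} is empty")

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for _, members in self.sets.values():
            out.update(members)
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, pathway_id: str) -> frozenset[str]:
        return self.sets[pathway_id][1]

    def name(self, pathway_id: str) -> str:
        return self.sets[pathway_id][0]


@dataclass(frozen=True, order=True)
class DrugTargetRecord:
    drug_id: str
    drug_class: str
    target: str


@dataclass(frozen=True)
class DrugTargetTable:
    """Flat drug -> target association table (one row per link)."""

    records: tuple[DrugTargetRecord, ...]

    def __post_init__(self):
        seen = set()
        for rec in self.records:
            if not rec.drug_id:
                raise ValueError("empty drug_id")
            if rec.drug_class not in DRUG_CLASSES:
                raise ValueError(
                    f"unknown drug class {rec.drug_class!r}; "
                    f"allowed: {', '.join(DRUG_CLASSES)}"
                )
            key = (rec.drug_id, rec.target)
            if key in seen:
                raise ValueError(f"duplicate (drug, target) pair {key}")
            seen.add(key)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str, str]]) -> "DrugTargetTable":
        """Build from (drug_id, drug_class, target) rows, collapsing duplicates.

        Class names are matched case-insensitively against :data:`DRUG_CLASSES`;
        target symbols are uppercased.
        """
        recs: dict[tuple[str, str], DrugTargetRecord] = {}
        for drug_id, drug_class, target in rows:
            drug_id = drug_id.strip()
            cls_norm = _CLASS_LOOKUP.get(drug_class.strip().lower())
            if cls_norm is None:
                raise ValueError(
                    f"unknown drug class {drug_class!r}; "
                    f"allowed: {', '.join(DRUG_CLASSES)}"
                )
            rec = DrugTargetRecord(drug_id, cls_norm, _norm_symbol(target))
            recs.setdefault((rec.drug_id, rec.target), rec)
        return cls(tuple(sorted(recs.values())))

    @property
    def drugs(self) -> dict[str, str]:
        """drug_id -> drug_class."""
        out: dict[str, str] = {}
        for rec in self.records:
            prev = out.setdefault(rec.drug_id, rec.drug_class)
            if prev != rec.drug_class:
                raise ValueError(f"drug {rec.drug_id!r} listed under two classes")
        return out

    def targets_of(self, drug_id: str) -> frozenset[str]:
        return frozenset(r.target for r in self.records if r.drug_id == drug_id)

    def targets_of_class(self, drug_class: str) -> frozenset[str]:
        return frozenset(r.target for r in self.records if r.drug_class == drug_class)

    @property
    def all_targets(self) -> frozenset[str]:
        return frozenset(r.target for r in self.records)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# readers


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_edge_list(path: str | Path, weight_scale: float = 1.0) -> list[tuple[str, str, float]]:
    """Read a STRING-style TSV edge list into (A, B, weight) triples.

    Columns: symbolA, symbolB, score (extra columns ignored).  Fields may be
    separated by tabs or runs of spaces.  A header line is detected by a
    non-numeric third field and skipped.  Scores are divided by
    ``weight_scale`` (1000 for raw STRING combined scores, 1 for
    pre-normalised files); the scaled weight must lie in (0, 1].
    """
    if weight_scale <= 0:
        raise ValueError(f"weight_scale must be > 0, got {weight_scale}")
    path = Path(path)
    edges: list[tuple[str, str, float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >=3 columns, got {len(fields)}"
                )
            if lineno == 1 and not _is_number(fields[2]):
                continue  # header
            if not _is_number(fields[2]):
                raise ValueError(f"{path}:{lineno}: non-numeric score {fields[2]!r}")
            w = float(fields[2]) / weight_scale
            if not (0.0 < w <= 1.0):
                raise ValueError(
                    f"{path}:{lineno}: weight {w!r} out of range (0, 1] "
                    f"after scaling by {weight_scale}"
                )
            edges.append((_norm_symbol(fields[0]), _norm_symbol(fields[1]), w))
    return edges


def load_network(path: str | Path, weight_scale: float = 1.0) -> WeightedNetwork:
    """Read an already-constructed network edge list (no thresholding)."""
    return WeightedNetwork.from_edges(read_edge_list(path, weight_scale))


def read_gene_list(path: str | Path) -> list[str]:
    """One symbol per line; ``#`` starts a comment; symbols uppercased."""
    out: list[str] = []
    seen: set[str] = set()
    with Path(path).open() as fh:
        for line in fh:
            sym = line.split("#", 1)[0].strip()
            if not sym:
                continue
            sym = _norm_symbol(sym)
            if sym not in seen:
                seen.add(sym)
                out.append(sym)
    return out


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets in GMT format (name, description, members...)."""
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">=1 member (got {len(fields)} fields)"
                )
            name, desc = fields[0].strip(), fields[1].strip()
            members = frozenset(
                _norm_symbol(m) for m in fields[2:] if m.strip()
            )
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set id {name!r}")
            sets[name] = (desc, members)
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return GeneSetCollection(sets)


def read_drug_targets(path: str | Path) -> DrugTargetTable:
    """Read a drug->target TSV with columns drug_id, drug_class, target."""
    path = Path(path)
    rows: list[tuple[str, str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            if lineno == 1 and fields[0].strip().lower() == "drug_id":
                continue  # header
            rows.append((fields[0], fields[1], fields[2]))
    if not rows:
        raise ValueError(f"{path}: no drug-target records")
    return DrugTargetTable.from_rows(rows)


# ---------------------------------------------------------------------------
# network construction


@dataclass(frozen=True)
class NetworkBuildResult:
    """Outcome of thresholding + rescue.

    ``rescued`` maps each rescued focus gene to the sub-threshold weight at
    which its edges were re-admitted; ``unmapped`` lists focus genes absent
    from the raw edge list entirely (they cannot be rescued).
    """

    network: WeightedNetwork
    rescued: Mapping[str, float]
    unmapped: tuple[str, ...]


def build_network(
    raw_edges: Sequence[tuple[str, str, float]],
    focus_genes: Iterable[str] = (),
    high_conf: float = 0.9,
) -> NetworkBuildResult:
    """Threshold a raw edge list at ``high_conf`` and rescue missing focus genes.

    All edges with weight >= ``high_conf`` are kept.  A *focus gene* (disease
    gene or drug target) absent from that high-confidence subnetwork but
    present in the raw list is re-admitted via its strongest sub-threshold
    interactions: the maximum incident weight below ``high_conf`` is found and
    every incident edge tied at that weight is added.  Isolated nodes are then
    dropped so the random-walk transition matrix has no zero columns.
    """
    if not (0.0 < high_conf <= 1.0):
        raise ValueError(f"high_conf must be in (0, 1], got {high_conf}")
    focus = {_norm_symbol(g) for g in focus_genes}

    # collapse duplicates (max weight), drop self-loops
    collapsed: dict[frozenset[str], float] = {}
    for a, b, w in raw_edges:
        a, b = _norm_symbol(a), _norm_symbol(b)
        if a == b:
            continue
        key = frozenset((a, b))
        if w > collapsed.get(key, 0.0):
            collapsed[key] = float(w)

    incident: dict[str, list[tuple[frozenset[str], float]]] = {}
    for key, w in collapsed.items():
        for v in key:
            incident.setdefault(v, []).append((key, w))

    kept: dict[frozenset[str], float] = {
        k: w for k, w in collapsed.items() if w >= high_conf
    }
    present = {v for key in kept for v in key}

    rescued: dict[str, float] = {}
    unmapped: list[str] = []
    for g in sorted(focus - present):
        below = [(k, w) for k, w in incident.get(g, []) if w < high_conf]
        if not below:
            unmapped.append(g)
            continue
        wmax = max(w for _, w in below)
        rescued[g] = wmax
        for key, w in below:
            if w == wmax:
                kept[key] = w

    if not kept:
        raise ValueError(f"no edges survive threshold {high_conf}")

    g = nx.Graph()
    for key, w in kept.items():
        a, b = sorted(key)
        g.add_edge(a, b, weight=w)
    # edge-built graphs have no isolated nodes, but guard regardless
    g.remove_nodes_from([v for v, d in dict(g.degree()).items() if d == 0])
    return NetworkBuildResult(WeightedNetwork(g), rescued, tuple(unmapped))


# ---------------------------------------------------------------------------
# writers (used by the simulate subcommand and the pipeline round-trip)


def write_edge_list(network: WeightedNetwork, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for a, b in sorted(tuple(sorted(e)) for e in network.graph.edges):
            fh.write(f"{a}\t{b}\t{network.edge_weight(a, b):.6g}\n")


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for g in sorted(set(genes)):
            fh.write(g + "\n")


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for pid in sorted(collection.sets):
            desc, members = collection.sets[pid]
            fh.write("\t".join([pid, desc, *sorted(members)]) + "\n")


def write_drug_targets(table: DrugTargetTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("drug_id\tdrug_class\ttarget\n")
        for rec in sorted(table.records):
            fh.write(f"{rec.drug_id}\t{rec.drug_class}\t{rec.target}\n")
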