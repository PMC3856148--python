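"""Drug-target bipartite network and formula/drug-class target overlap.

One node set holds drugs, the other their protein targets; a link means
"this drug targets this protein".  Overlap of a multi-component formula's
target set with each approved drug class suggests which clinical drug
categories the formula's action resembles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .netio import DRUG_CLASSES, DrugTargetTable

__all__ = ["BipartiteDrugNet", "SharedTargetReport", "build_bipartite", "shared_targets"]

# internal namespaces guaranteeing drug/protein node-set disjointness even
# when a drug name collides with a gene symbol
_DRUG_NS = "drug:"
_PROT_NS = "prot:"


@dataclass(frozen=True)
class BipartiteDrugNet:
    drug_nodes: Mapping[str, str]  # drug_id -> drug_class
    target_nodes: frozenset[str]
    links: frozenset[tuple[str, str]]  # (drug_id, target)

    def __post_init__(self):
        for d, t in self.links:
            if d not in self.drug_nodes:
                raise ValueError(f"link references unknown drug {d!r}")
            if t not in self.target_nodes:
                raise ValueError(f"link references unknown target {t!r}")

    def targets_of_class(self, drug_class: str) -> frozenset[str]:
        drugs = {d for d, c in self.drug_nodes.items() if c == drug_class}
        return frozenset(t for d, t in self.links if d in drugs)

    def write_tsv(self, edge_path: str | Path, node_path: str | Path) -> None:
        """Edge + node-attribute TSVs for generic graph viewers.

        Node ids are namespaced ("drug:", "prot:") so the two node kinds
        never collide.
        """
        with Path(edge_path).open("w") as fh:
            fh.write("source\ttarget\n")
            for d, t in sorted(self.links):
                fh.write(f"{_DRUG_NS}{d}\t{_PROT_NS}{t}\n")
        with Path(node_path).open("w") as fh:
            fh.write("id\tkind\tclass\n")
            for d in sorted(self.drug_nodes):
                fh.write(f"{_DRUG_NS}{d}\tdrug\t{self.drug_nodes[d]}\n")
            for t in sorted(self.target_nodes):
                fh.write(f"{_PROT_NS}{t}\tprotein\t-\n")


@dataclass(frozen=True)
class SharedTargetReport:
    """Formula targets shared with each approved drug class."""

    by_class: Mapping[str, frozenset[str]]
    overall: frozenset[str]
    n_classes_overlapping: int


def build_bipartite(table: DrugTargetTable) -> BipartiteDrugNet:
    """One drug node per distinct drug_id, one protein node per distinct
    target, one link per association record."""
    if len(table) == 0:
        raise ValueError("empty drug-target table")
    return BipartiteDrugNet(
        drug_nodes=dict(table.drugs),
        target_nodes=table.all_targets,
        links=frozenset((r.drug_id, r.target) for r in table.records),
    )


def shared_targets(
    formula_targets: Iterable[str],
    net: BipartiteDrugNet,
) -> SharedTargetReport:
    """Intersect the formula's targets with each drug class's target union."""
    formula = {t.strip().upper() for t in formula_targets}
    by_class: dict[str, frozenset[str]] = {}
    for cls in DRUG_CLASSES:
        if cls == "herbal_component":
            continue
        by_class[cls] = frozenset(formula & net.targets_of_class(cls))
    overall = frozenset().union(*by_class.values()) if by_class else frozenset()
    n_over = sum(1 for s in by_class.values() if s)
    return SharedTargetReport(by_class, overall, n_over)
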