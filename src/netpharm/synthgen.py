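"""Synthetic interactomes, disease modules, drugs and pathways.

Every downstream stage of the pipeline is exercised on data from this
module, so its generators reproduce the statistical structure the analysis
assumes rather than any particular database snapshot:

* a sparse weighted network with heavy-tailed degrees (preferential
  attachment), standing in for a thresholded interactome;
* a connected planted *disease module* grown around a hub, emulating the
  tendency of disease genes to cluster on the interactome;
* an "effective" drug targeting the module's neighbourhood, a "random"
  drug targeting uniform nodes, and a three-component herbal formula whose
  components all target the effective neighbourhood;
* pathway gene sets, one of which is planted to over-contain drug targets.

The ground truth of every planted feature is returned alongside the data so
recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np

from .netio import DrugTargetTable, GeneSetCollection, WeightedNetwork
from .util import derive_seed

__all__ = [
    "SynthConfig",
    "SynthBundle",
    "generate_network",
    "plant_disease_module",
    "plant_drugs",
    "plant_pathways",
    "generate_bundle",
]

EFFECTIVE_DRUG = "DRUG_EFFECTIVE"
RANDOM_DRUG = "DRUG_RANDOM"
COMPONENTS = ("COMP_A", "COMP_B", "COMP_C")
ENRICHED_PATHWAY = "PW000"


def _symbol(i: int) -> str:
    return f"G{i:05d}"


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic bundle.

    Defaults describe a desk-scale interactome: 200 nodes grown by
    preferential attachment with 3 edges per new node (heavy-tailed degrees,
    mean degree ~6 — the sparse regime of thresholded interactomes), STRING-
    like confidence weights uniform on [0.4, 1.0], a 20-node disease module
    (10% of nodes, mirroring a disease gene set that is small relative to
    the interactome), 5 targets per drug/component, 50 pathways of 10-40
    genes with half of the planted pathway made of formula targets.
    """

    n_nodes: int = 200
    edges_per_node: int = 3
    weight_low: float = 0.4
    weight_high: float = 1.0
    disease_module_size: int = 20
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (10, 40)
    enriched_pathway_size: int = 20
    n_targets_effective: int = 5
    n_targets_random: int = 5
    enriched_fraction: float = 0.5
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 10:
            raise ValueError("n_nodes must be >= 10")
        if self.edges_per_node < 1:
            raise ValueError("edges_per_node must be >= 1")
        if not (0.0 < self.weight_low <= self.weight_high <= 1.0):
            raise ValueError(
                "need 0 < weight_low <= weight_high <= 1, got "
                f"[{self.weight_low}, {self.weight_high}]"
            )
        if not (2 <= self.disease_module_size < self.n_nodes):
            raise ValueError("need 2 <= disease_module_size < n_nodes")
        lo, hi = self.pathway_size_range
        if not (2 <= lo <= hi):
            raise ValueError("pathway sizes must be >= 2 and lo <= hi")
        if self.enriched_pathway_size < 2:
            raise ValueError("enriched_pathway_size must be >= 2")
        if not (0.0 <= self.enriched_fraction <= 1.0):
            raise ValueError("enriched_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SynthBundle:
    network: WeightedNetwork
    disease_genes: frozenset[str]
    drugs: DrugTargetTable
    pathways: GeneSetCollection
    truth: dict

    def __post_init__(self):
        nodes = self.network.nodes
        if not self.disease_genes <= nodes:
            raise ValueError("disease genes not all on network")
        if not self.drugs.all_targets <= nodes:
            raise ValueError("drug targets not all on network")


def generate_network(config: SynthConfig) -> WeightedNetwork:
    """Preferential-attachment network with uniform confidence weights.

    Growth starts from a complete seed graph on max(edges_per_node, 2)
    nodes; each new node attaches to ``edges_per_node`` distinct existing
    nodes chosen with probability proportional to current degree.  The
    result is connected with C(m0,2) + (n - m0) * m edges, deterministic
    given ``rng_seed``.
    """
    m = config.edges_per_node
    m0 = max(m, 2)
    if config.n_nodes <= m0:
        raise ValueError("n_nodes must exceed the seed-graph size")
    rng = np.random.default_rng(config.rng_seed)

    g = nx.Graph()
    # degree-repeated list drives proportional-to-degree sampling
    repeated: list[int] = []
    for i in range(m0):
        for j in range(i + 1, m0):
            g.add_edge(_symbol(i), _symbol(j))
            repeated.extend((i, j))
    for new in range(m0, config.n_nodes):
        chosen: set[int] = set()
        while len(chosen) < m:
            chosen.add(repeated[rng.integers(len(repeated))])
        for tgt in sorted(chosen):
            g.add_edge(_symbol(new), _symbol(tgt))
            repeated.extend((new, tgt))
    for a, b in sorted(g.edges):
        g[a][b]["weight"] = float(
            rng.uniform(config.weight_low, config.weight_high)
        )
    return WeightedNetwork(g)


def plant_disease_module(
    network: WeightedNetwork, size: int, rng_seed: int
) -> frozenset[str]:
    """Connected node set grown breadth-first from a high-degree anchor.

    The anchor is drawn uniformly from the top decile of nodes by degree;
    neighbours are consumed in randomised order, so different seeds give
    different (always connected) modules.
    """
    n = network.number_of_nodes()
    if not (2 <= size < n):
        raise ValueError(f"need 2 <= size < {n}, got {size}")
    rng = np.random.default_rng(rng_seed)
    deg = dict(network.graph.degree())
    ranked = sorted(network.node_order, key=lambda v: (-deg[v], v))
    top = ranked[: max(1, n // 10)]
    anchor = top[rng.integers(len(top))]

    module = [anchor]
    in_mod = {anchor}
    frontier = [anchor]
    while len(module) < size:
        if not frontier:
            raise ValueError(
                f"module of size {size} unreachable from anchor {anchor}"
            )
        nxt: list[str] = []
        for v in frontier:
            nbrs = sorted(u for u in network.graph.neighbors(v) if u not in in_mod)
            rng.shuffle(nbrs)
            for u in nbrs:
                if u in in_mod:
                    continue
                in_mod.add(u)
                module.append(u)
                nxt.append(u)
                if len(module) == size:
                    return frozenset(module)
        frontier = nxt
    return frozenset(module)


def plant_drugs(
    network: WeightedNetwork,
    disease_genes: Iterable[str],
    n_targets_effective: int = 5,
    n_targets_random: int = 5,
    rng_seed: int = 0,
) -> DrugTargetTable:
    """Plant one effective drug, one random drug, and a 3-component formula.

    The effective drug (class DMARD) targets the disease module itself,
    spilling into the module's first-neighbour ring only when more targets
    are requested than the module holds — every target is within graph
    distance 1 of the module, and the drug behaves like a disease-modifying
    agent hitting the disease proteins directly.  The random drug (class
    NSAID) samples uniformly from all nodes.  Each formula component (class
    herbal_component) draws a module/ring mix (roughly 60% module), so
    components overlap the effective drug's territory and possibly one
    another.
    """
    rng = np.random.default_rng(rng_seed)
    module = {g.strip().upper() for g in disease_genes}
    if not module <= network.nodes:
        raise ValueError("disease genes not all on network")
    ring: set[str] = set()
    for v in module:
        ring.update(network.graph.neighbors(v))
    ring -= module
    pool_mod = np.array(sorted(module))
    pool_ring = np.array(sorted(ring))
    pool_all = np.array(sorted(network.nodes))
    if n_targets_effective > len(pool_mod) + len(pool_ring):
        raise ValueError(
            f"{n_targets_effective} effective targets requested but the "
            f"module neighbourhood has only {len(pool_mod) + len(pool_ring)} nodes"
        )
    if n_targets_random > len(pool_all):
        raise ValueError("more random targets requested than network nodes")

    def near_module(n: int, module_share: float) -> list[str]:
        n_mod = min(len(pool_mod), round(module_share * n))
        n_ring = n - n_mod
        if n_ring > len(pool_ring):
            n_ring = len(pool_ring)
            n_mod = n - n_ring
        chosen = rng.choice(pool_mod, n_mod, replace=False).tolist()
        if n_ring:
            chosen += rng.choice(pool_ring, n_ring, replace=False).tolist()
        return [str(t) for t in chosen]

    rows: list[tuple[str, str, str]] = []
    for t in near_module(n_targets_effective, module_share=1.0):
        rows.append((EFFECTIVE_DRUG, "DMARD", t))
    for t in rng.choice(pool_all, n_targets_random, replace=False):
        rows.append((RANDOM_DRUG, "NSAID", str(t)))
    for comp in COMPONENTS:
        for t in near_module(n_targets_effective, module_share=0.6):
            rows.append((comp, "herbal_component", t))
    return DrugTargetTable.from_rows(rows)


def plant_pathways(
    network: WeightedNetwork,
    drug_targets: Iterable[str],
    n_pathways: int = 50,
    size_range: tuple[int, int] = (10, 40),
    enriched_fraction: float = 0.5,
    rng_seed: int = 0,
    enriched_size: int | None = None,
) -> GeneSetCollection:
    """Pathway collection with one planted target-enriched set.

    The planted set (id ``PW000``) draws round(enriched_fraction * size) of
    its members from ``drug_targets`` and the rest from non-target nodes;
    all other sets sample network nodes uniformly.  Sizes are uniform over
    ``size_range``; the planted set's size is ``enriched_size`` when given
    (so the requested target count can be guaranteed to fit small formula
    target sets), otherwise drawn like the rest.
    """
    if n_pathways < 1:
        raise ValueError("n_pathways must be >= 1")
    lo, hi = size_range
    rng = np.random.default_rng(rng_seed)
    targets = np.array(sorted({t.strip().upper() for t in drug_targets}))
    nodes = np.array(sorted(network.nodes))
    non_targets = np.array(sorted(set(nodes) - set(targets)))

    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for p in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        pid = f"PW{p:03d}"
        if p == 0:
            if enriched_size is not None:
                size = enriched_size
            n_in = round(enriched_fraction * size)
            if n_in > len(targets):
                raise ValueError(
                    f"planted pathway needs {n_in} targets but only "
                    f"{len(targets)} exist"
                )
            if size - n_in > len(non_targets):
                raise ValueError("planted pathway cannot fill non-target slots")
            members = set(rng.choice(targets, n_in, replace=False).tolist()) | set(
                rng.choice(non_targets, size - n_in, replace=False).tolist()
            )
        else:
            members = set(rng.choice(nodes, size, replace=False).tolist())
        sets[pid] = (f"synthetic pathway {p}", frozenset(members))
    return GeneSetCollection(sets)


def generate_bundle(config: SynthConfig) -> SynthBundle:
    """One complete synthetic study: network, module, drugs, pathways, truth.

    Stage RNG seeds are derived from ``config.rng_seed`` by stable hashing,
    so each stage is reproducible in isolation.
    """
    network = generate_network(config)
    disease = plant_disease_module(
        network, config.disease_module_size, derive_seed(config.rng_seed, "module")
    )
    drugs = plant_drugs(
        network,
        disease,
        n_targets_effective=config.n_targets_effective,
        n_targets_random=config.n_targets_random,
        rng_seed=derive_seed(config.rng_seed, "drugs"),
    )
    formula_targets = frozenset().union(
        *(drugs.targets_of(c) for c in COMPONENTS)
    )
    pathways = plant_pathways(
        network,
        formula_targets,
        n_pathways=config.n_pathways,
        size_range=config.pathway_size_range,
        enriched_fraction=config.enriched_fraction,
        rng_seed=derive_seed(config.rng_seed, "pathways"),
        enriched_size=config.enriched_pathway_size,
    )
    truth = {
        "effective_drug": EFFECTIVE_DRUG,
        "random_drug": RANDOM_DRUG,
        "components": list(COMPONENTS),
        "enriched_pathway": ENRICHED_PATHWAY,
        "enriched_fraction": config.enriched_fraction,
        "disease_module_size": config.disease_module_size,
        "rng_seed": config.rng_seed,
    }
    return SynthBundle(network, frozenset(disease), drugs, pathways, truth)
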