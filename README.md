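# netpharm

Network pharmacology of multi-component herbal formulas on the protein
interaction network.

Single-target drugs and multi-component formulas act on the same
interactome, but a formula spreads many weak perturbations where a drug
concentrates one strong one. `netpharm` quantifies both on an equal footing
for researchers studying how a candidate therapy relates to a disease at
network level: it builds a weighted protein–protein interaction (PPI)
network, propagates influence from disease genes and from drug targets by
random walk with restart, scores the drug–disease overlap, and tests that
score against a permutation null.

## The model

All influence fields come from the random walk with restart (RWR)

```
x(t+1) = (1 − r) · W · x(t) + r · x0
```

where `W` is the column-normalised weight matrix of the PPI network (from
node *v* the walker moves to neighbour *u* with probability proportional to
the interaction confidence w(u,v)), `r = 0.3` is the restart probability,
and `x0` holds the seed strengths: 1 for disease genes and approved-drug
targets, 0.01 for single herbal-component targets (natural compounds bind
their targets orders of magnitude more weakly than purpose-designed drugs).
A whole formula is seeded on the union of its components' targets at 0.01.
The fixed point `x∞` is the influence field of the seed set.

On top of the walk:

- **Effect score** `E = ⟨x_disease, x_drug⟩` — the inner product of the
  disease and drug fields, large when the drug's influence concentrates
  where the disease's does.
- **Permutation z-score** `z = (E − mean(E_rand)) / sd(E_rand)` over random
  target sets of the same size (default 3000); `|z| > 3` is called
  significant. `z` is invariant under seed-strength rescaling, so drugs and
  components are judged comparably.
- **Pathway enrichment** — upper-tail hypergeometric probability that a
  pathway of *n* genes holds ≥ *k* of the *K* targets in an *N*-gene
  universe, flagged at p < 0.01 (BH q-values reported alongside).
- **Disease subnetwork** — the induced subgraph on the top 3% of nodes by
  disease score, with degree, normalised betweenness and k-core coreness
  per node.

A synthetic-data module (`netpharm.synthgen`) generates complete studies —
preferential-attachment networks, a planted disease module, an effective
and a random drug, a three-component formula, and pathway collections with
one planted enriched set — so every stage is testable without database
downloads.

## Worked example

Simulate a study and run the full pipeline:

```
netpharm simulate --n-nodes 200 --seed 11 --outdir demo
netpharm run --config demo/config.yaml --outdir demo/out
```

with `demo/config.yaml`:

```yaml
network_path: demo/network.tsv
disease_genes_path: demo/disease_genes.txt
drug_targets_path: demo/drug_targets.tsv
pathways_path: demo/pathways.gmt
n_perm: 1000
high_conf: 0.4     # keep the whole synthetic network (no 0.9 thresholding)
rng_seed: 11
```

`demo/out/effect_scores.json` then contains, per drug:

```
DRUG_EFFECTIVE  E=1.636    z=  4.85  significant=True
DRUG_RANDOM     E=0.7068   z= -0.91  significant=False
COMP_A          E=0.01497  z=  3.97  significant=True
FORMULA         E=0.04291  z=  6.07  significant=True
```

The planted module-proximal drug is significant (z = 4.85) while the
uniformly-targeted drug is not (z = −0.91). The whole formula's E (0.043)
exceeds every single component's (COMP_A: 0.015) — the multi-component
union covers more of the disease field than any one ingredient — and its
z-score is the largest of all. `enrichment.tsv` recovers the planted
pathway (PW000, 10 of 20 genes are formula targets, p ≈ 2×10⁻⁸), and
`topology_summary.json` reports the disease subnetwork and how many disease
genes it retains.

For real data, the inputs are a STRING-style weighted edge list (use
`weight_scale: 1000` for raw combined scores and the default `high_conf:
0.9` threshold with rescue of study genes), a disease gene list, a
drug→target TSV with classes (NSAID, DMARD, glucocorticoid, biological,
herbal_component), and pathway sets in GMT format.

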