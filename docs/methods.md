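# Methods

This note records the model, the numerical choices, and what the synthetic
studies do and do not establish.

## Weighted network construction

The interactome is built from a STRING-style edge list of confidence scores
in (0, 1] (`weight_scale` rescales raw 0–1000 combined scores; the source
convention varies, so the scale is a parameter rather than a guess). Edges
at or above `high_conf = 0.9` form the high-confidence core. Study genes —
disease genes and every drug/component target — that the threshold removes
are *rescued*: for each such gene present in the raw list, its maximum
incident weight below the threshold is found and **all** incident edges
tied at that weight are re-admitted (the plural reading of "strongest
interactions"; a single arbitrary tie-break would make the network depend
on input order). Remaining rules: self-loops dropped (the walk and the
centralities are defined on simple graphs), duplicate edges keep the
maximum weight (confidence is an evidence upper bound), symbols compared
case-insensitively and stored uppercase, isolated nodes removed so the
transition matrix has no zero column. Genes absent from the raw list
entirely are reported as unmapped, mirroring how a component whose only
target is off-network drops out of a real analysis.

## Random walk with restart

The transition operator is the **column-normalised** weight matrix: the
move probability from *v* to *u* is w(u,v)/Σ w(·,v). Normalisation is
required — iterating with a raw weighted adjacency matrix of spectral
radius > 1 diverges — and it realises "move probability proportional to
interaction reliability". Because columns sum to 1 and the restart re-injects
`r·x0`, total mass Σx is conserved at Σx0 exactly, which the tests assert
to 1e−8.

Iteration stops when the L1 difference of successive iterates falls below
`tol = 1e−10` (`max_iter = 10 000`); the recurrence contracts with factor
(1 − r) = 0.7, so convergence takes a few dozen iterations and the stopping
error (~`tol`·(1−r)/r) sits far below any reported score. Tests that
compare two runs for exact linearity use `tol = 1e−13`, since the default
stopping error would otherwise dominate the comparison. The restart
probability default r = 0.3 follows the established robust choice for
disease-gene prioritisation walks.

Seed strengths: disease genes and approved-drug targets 1.0; herbal
components 0.01, encoding the ~two-orders-weaker binding of natural
compounds. The whole formula is seeded on the **union** of component
targets at 0.01 — a target shared by several components counts once. The
alternative (summing one strength per targeting component) is available via
`formula_effect(..., additive=True)`, which by linearity equals the sum of
the per-component fields; which convention a published analysis used is
generally not recoverable from its reported totals, so both are exposed and
the union is the default.

Off-network seeds are dropped with a logged warning and recorded on the
`SeedVector`, never silently.

The permutation null propagates all random target sets as columns of one
matrix through a single batched iteration (`rwr_batch`); results agree with
per-set runs to the stopping tolerance, and 1000 permutations on a 200-node
network take well under a second.

## Effect score and permutation null

`E = ⟨x_disease, x_drug⟩`. The null draws `n_perm` (default 3000) target
sets of the same on-network size uniformly from all network nodes —
the literal reading of "random target sets". A degree-matched option
(log2-degree bins) is provided because uniform sampling under-represents
hubs relative to real drug-target sets and the choice changes z; it is off
by default. The z-score uses the sample (n−1) standard deviation —
immaterial at n = 3000 — and `|z| > 3` is the significance convention.
E is linear in seed strength, so z is scale-invariant, which is asserted
exactly in the tests. The null of E is right-skewed (propagation scores are
heavy-tailed), so |z| > 3 exceedance under the null runs near 1%, above the
0.27% a normal tail would give; the calibration test bounds it rather than
assuming normality.

## Enrichment

Universe N is the union of pathway members — enrichment asks about the
pathway collection, not the interactome — and targets outside it are
excluded from K and reported. The upper tail P(X ≥ k) is computed by
scipy's log-space survival function (a stable direct tail sum; the
1 − CDF form loses precision for small P), and the tests verify it against
exhaustive draw-by-draw enumeration for every (N ≤ 20, K, n, k). Raw
p-values with the α = 0.01 cut drive the `significant` flag, matching the
uncorrected convention of the analysis this package operationalises;
Benjamini–Hochberg q-values are emitted alongside for users who want
control of the false discovery rate across pathways.

## Subnetwork and topology

The disease subnetwork is the induced subgraph on the ⌊fraction·N⌋
(default 3%) top nodes by disease score, ties broken by score descending
then symbol lexicographically, so extraction is deterministic. A
`drop_zero_scores` option excludes nodes the walk never reaches before
counting. Centralities are computed on the unweighted simple-graph view —
degree; betweenness over unordered pairs normalised by (n−1)(n−2)/2;
k-core coreness by recursive deletion (computed per connected component,
which the two textbook definitions agree on for connected graphs) — weights
influence the walk, not the shortest-path or peeling definitions. The
target annotation summarises what fraction of on-subnetwork targets exceed
the mean degree and betweenness and sit in the maximum core.

## Synthetic studies

`synthgen` emulates the statistical structure the method assumes:

- **Network**: preferential attachment from a complete seed graph on
  max(m, 2) nodes, m = 3 edges per new node, giving connected, sparse,
  heavy-tailed-degree graphs (hubs and a deep k-core, which the topology
  stage presumes); Erdős–Rényi graphs would make hub/core statements
  vacuous. Weights uniform on [0.4, 1.0] — the analysis requires only
  weights in (0, 1], not a calibrated confidence distribution.
- **Disease module**: breadth-first growth from a random top-decile-degree
  anchor; connected by construction, emulating the clustering of disease
  genes on interactomes. Default 20 of 200 nodes.
- **Drugs**: the effective drug targets the module itself (falling back to
  the first-neighbour ring only when more targets are requested than the
  module holds) — the analogue of a disease-modifying drug hitting disease
  proteins directly; every target is within distance 1 of the module. The
  random drug samples all nodes uniformly. Three formula components draw a
  ~60/40 module/ring mix, overlapping the effective drug's territory and
  each other. Five targets per drug by default.
- **Pathways**: 50 sets of 10–40 genes sampled uniformly; one planted set
  (default size 20) takes `enriched_fraction` (default 0.5) of its members
  from the formula targets. The planted set has its own size parameter so
  its target quota always fits small formula target sets.

All generators are pure functions of their config and seed; stage seeds are
derived from the master seed by hashing stage names, so adding one analysis
never perturbs another's randomness (the same scheme keys per-drug
permutation nulls in the pipeline).

What passing on these bundles does **not** show: real interactomes have
10–100× more nodes, confidence-correlated weights, and disease modules that
are neither perfectly connected nor hub-anchored; real target sets are
degree-biased. The synthetic results establish correctness and calibration
of the machinery, not effect sizes on real data. Problem sizes used
throughout the tests and the acceptance script — 200-node bundles (1000-node
for enrichment calibration), 10 study replicates, 1000 permutations — are
the package's desk-scale defaults; every stage scales to interactome size
through the same sparse/batched code paths.

## Pipeline

The pipeline computes the disease field once and reuses it for every drug
and every permutation. Outputs are plain TSV/JSON with sorted keys and
fixed float formatting; the manifest records all parameters, derived seeds
and input SHA-256 checksums, and two runs with the same config are
byte-identical. Any stage failure aborts with the stage name.

## Known limitations

- No ID mapping: symbols must already agree across inputs (they are only
  case-normalised).
- The hypergeometric test is discrete and therefore conservative at small
  pathway sizes; the attained false-positive rate at p < 0.01 sits below
  0.01 (about 0.5% at the default synthetic conditions).
- The uniform permutation null ignores target degree bias; use the
  degree-matched option when that matters, and expect z to change.
- Betweenness is exact (no sampling), which is fine at subnetwork scale
  (hundreds of nodes) but quadratic-to-cubic beyond it.
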