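# Methods

## The multiscale network

The analysis graph joins three undirected, unweighted layers: a
protein–protein interaction (PPI) layer, protein→biological-function
annotations, and a function–function hierarchy. Node ids are strings; every
node carries one class (`protein`, `function`, `herb`, `compound`,
`disease`) and every edge one class tag. Herb, compound and disease entities
are attached as explicit nodes wired to the protein targets that map into
the network, so a walk can be seeded uniformly at the entity node rather
than spread over its targets; an entity with zero mapped targets is an
error the caller must treat as "excluded from scoring". Gene symbols are
normalized to uppercase ASCII and no alias resolution is attempted — if two
sources spell the same gene differently they stay distinct nodes, a known
limitation.

Herb target sets are the union of the herb's compound targets capped at the
top 50 by *simple path count* (the number of herb→compound→target paths
landing on a target), so targets hit by many constituents are preferred.
Herbs with fewer than 3 target-bearing compounds are excluded before
scoring; the rationale is robustness — with one or two annotated
ingredients the network evidence is too thin to score.

## Biased random walk with restart

At node u the walker steps to neighbor v with probability
`w(class(u,v)) / Σ_v' w(class(u,v'))`; at every step it returns to the seed
with probability α (`restart_prob`). The diffusion profile is the fixed
point `r = α e_seed + (1−α) M r`, computed by power iteration from the seed
indicator with an L1 stopping tolerance. Isolated nodes self-loop so M stays
column-stochastic.

Parameters, defaults and rationale:

| parameter | default | why |
|---|---|---|
| `restart_prob` α | 0.5 | strong localization: the profile decays geometrically with distance from the seed, and the iteration contracts with factor 1−α, converging in ~30 iterations at tol 1e-10 |
| `class_weights` | `protein_function: 2.0`, all others 1.0 | a moderate bias toward biological-function nodes, the qualitative behavior the method calls for; any stronger claim would need a tuning dataset this package deliberately does not ship |
| `tol` | 1e-10 (L1) | with contraction factor 1−α, the distance to the fixed point is at most tol·(1−α)/α, so agreement with the exact solve is well below the 1e-8 oracle bound for any α ≥ 0.1 |
| `max_iter` | 500 | ~5× the worst-case need at α = 0.1; non-convergence is flagged, not fatal |

All are configuration, never hard-coded into results; tests of worked
examples use α = 0.5 with unit weights.

The exact solver (`solve_diffusion_exact`) inverts the dense system and is
guarded at 2000 nodes; it exists as a verification oracle, and the test
suite checks iterative-vs-exact agreement below 1e-8 max-abs on dozens of
random typed graphs.

## Scoring and selection

Correlation between two profiles is computed over the shared
protein/function index only: all entity-class nodes are excluded so an
entity's own seed mass cannot inflate similarity. Pearson on raw
frequencies is the default — the profile magnitudes themselves carry the
signal; Spearman is exposed for rank-only comparisons. A zero-variance
vector raises rather than returning NaN.

The overlap statistic uses the one-sided hypergeometric tail P(X ≥ k)
(scipy's survival function; an exact Fraction-enumeration oracle backs it in
tests) over a background universe N whose default is the network proteins
appearing in at least one compound→target or disease→gene record. The
universe is a parameter: overlap p-values and fold enrichments are only
meaningful relative to a stated background, and different published analyses
imply different ones, so nothing is baked in. Fold enrichment is
(k/n)/(K/N), also exposed directly as `fold_enrichment(k, n,
background_fraction)` so a background rate calibrated from an external
table can be applied to other overlap patterns.

Herb selection applies p < 0.05 and an "active compound" floor (default 5),
where a compound counts as active if it has at least one target in the
disease module or its 1-hop PPI neighborhood — *not* only compounds that
themselves pass p < 0.05, which would contradict observed single-passer
herbs. Survivors are ranked by correlation, ties broken by ascending p then
id, truncated at 10. Compound mode reuses the same scoring per compound with
the p < 0.05 filter. No multiple-testing correction is applied at the
herb/compound level (raw p is reported, BH is available in the enrichment
module); this mirrors how such screens report overlap significance.

## Enrichment

Per term: one-sided hypergeometric p on the 2×2 table against a background
(default: union of library genes), BH adjustment across the library, odds
ratio with Haldane +0.5 when any cell is zero, and a rank-deviation z-score:
the term's p-value rank in the observed query is compared with its rank
distribution over seeded random same-size queries (default 200). The
combined score is |z·ln p|, hence 0 whenever p = 1. Because z depends on the
background-query sample, z and combined scores are comparative, not
portable constants. A whitelist filter retains the nine KEGG signaling
pathways relevant to hyperthyroidism (MAPK, Thyroid hormone, Calcium,
HIF-1, p53, mTOR, PI3K-Akt, Wnt, Parathyroid hormone synthesis/secretion/
action); matching is case-insensitive exact on term names.

## Mechanism subnetworks

For a compound–disease pair the subnetwork contains the top-k (default 20)
protein/function nodes of each profile plus both entity nodes, with all
parent-network edges among them. Connectivity is guaranteed by stitching:
a single breadth-first shortest-path tree is rooted at the disease entity
(among equal-distance parents the one with the higher disease visitation
frequency is chosen, ties lexicographic), and the tree path to every
selected node is added; interior nodes outside both top-k lists are tagged
`connector`. Because the tree is independent of k, node sets are *nested in
k* (growing k only adds nodes) and every stitched path is provably a
shortest path — two properties the test suite sweeps over many generated
worlds. The alternative of stitching disconnected components pairwise was
rejected: the chosen connector paths would then depend on the component
structure at each k, and nodes admitted at small k could vanish at larger
k. Top-k selection breaks frequency ties lexicographically for
reproducibility; a flag can restrict function nodes to an
enrichment-significant whitelist, default off.

## Synthetic worlds

The generator emulates the *structure* the analysis assumes, not any real
database's marginals:

* PPI layer: preferential attachment (Barabási–Albert), 300 proteins, 3
  edges per new node — a connected, heavy-tailed degree layer;
* function layer: a random rooted tree of 60 functions (the walk code is
  tested with an added cross edge, so tree-ness is not assumed), proteins
  annotated to leaf functions at a Poisson rate of 1.5 per protein;
* disease module: a breadth-first ball of 20 proteins around the
  highest-degree node, mimicking the disease-gene clustering that
  propagation methods assume;
* herbs: 10 herbs with 3–8 compounds each, 1–6 targets per compound. Decoy
  herbs draw targets uniformly from non-disease proteins. One planted
  herb draws each target, with probability `planted_herb_proximity` (default
  0.9), from the disease module and its 1-hop neighborhood: a disease gene
  is picked uniformly and kept with probability 1/2, else replaced by one of
  its PPI neighbors. Concentrating on the module itself (rather than
  uniform over the pooled neighborhood, which is mostly 1-hop nodes) gives
  the planted herb a genuinely significant overlap, which is the signal the
  recovery experiments are judged against. The planted herb's compound
  count is floored at 5 so it can pass the active-compound criterion.

Generation is a pure function of config + seed; the emitted TSV/GMT bundle
is byte-identical across reruns. Passing recovery tests on these worlds
shows the pipeline detects a proximity signal of this kind and strength;
it does not certify performance on real interactomes, where annotation
bias, hub effects and incomplete disease-gene lists are harsher.

A separate deterministic micro-fixture (`make_reference_toy`) encodes ten herb
target sets with fixed overlap patterns — (2/50), (5/50), (2/27), (2/26),
(2/38), (1/11), three × (4/50), (3/50) — against a 4227-gene background
containing 10 disease genes, so the background fraction is exactly 1/422.7.
This fixture drives the fold-enrichment cross-consistency checks:
calibrating the background fraction from any row reproduces every other
row's fold enrichment to two decimals.

## Numerical and design notes

* Power iteration error bound: if the L1 step change is below tol, the
  distance to the fixed point is ≤ tol·(1−α)/α.
* Profile invariants (entries ≥ 0, sum = 1 ± 1e-9) are asserted in tests,
  not renormalized away.
* Duplicate records (edge lists, herb–compound, compound–target) collapse
  to one with counts logged; self-loops are dropped at parse time.
* Degenerate inputs: empty layers, zero-target compounds, unmapped
  entities, zero-variance profiles and infeasible generator configs all
  raise typed exceptions rather than propagating NaNs.
* The pipeline's outputs are deterministic for fixed config and inputs; the
  manifest records the config hash and per-file SHA-256 digests.
* Problem sizes in the test suite (worlds of 60–300 proteins, sweeps of
  5–50 graphs/worlds) are chosen so the full suite runs in a few minutes on
  one CPU while still exercising every property at nontrivial scale.

## Known limitations

* No identifier mapping: symbol mismatches silently become distinct nodes.
* The walk treats all layers as static and unweighted beyond class bias; no
  edge confidence scores, no pharmacokinetics, no dosage.
* Enrichment z/combined scores depend on the seeded random-query
  background and are not comparable across backgrounds or libraries.
* The synthetic generator does not reproduce real database marginals
  (target-count distributions, annotation depth), only their broad shape.
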