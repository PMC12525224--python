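# herbwalk

Network-pharmacology prioritization of herbs and their active ingredients by
diffusion on a multiscale interactome.

Multi-component herbal medicines act on many protein targets at once, which
makes single-target screens a poor fit for ranking them against a disease.
`herbwalk` instead embeds herbs, compounds and a disease into a multilayer
network — protein–protein interactions, protein→biological-function
annotations, and a function–function hierarchy — and compares how influence
propagates from each of them. It is a library for computational
pharmacologists and systems biologists who want a tested, reproducible
implementation of this analysis with no external database dependencies: a
synthetic-data generator produces worlds with the same statistical structure
(scale-free PPI layer, rooted function hierarchy, sparse annotations, a
planted disease-proximal herb) so every stage can be exercised end to end.

## The model

Each entity (herb, compound, or disease) is attached as a node wired to its
protein targets. Its **diffusion profile** r is the stationary
visitation-frequency vector of a biased random walk with restart:

    r = α e_seed + (1 − α) M r

where α is the restart probability and M the column-stochastic transition
operator whose step probabilities are reweighted per edge class (raising the
`protein_function` weight biases the walk toward biological-function nodes)
and normalized per node. Profiles are computed by power iteration; a dense
linear solve `r = α (I − (1−α)M)⁻¹ e_seed` serves as an exact oracle in the
tests.

Candidates are then scored two ways:

* **correlation score** — Pearson (or Spearman) correlation between the
  entity's and the disease's diffusion profiles over the shared
  protein/function nodes;
* **overlap significance** — one-sided hypergeometric tail P(X ≥ k) for an
  overlap of k disease targets among the entity's n targets in a background
  of N proteins containing K disease targets, with fold enrichment
  (k/n)/(K/N).

Herbs pass if overlap p < 0.05 and they carry ≥ 5 disease-linked compounds
(herbs with < 3 target-bearing ingredients are excluded up front; target
sets are capped at the top 50 by simple path count). Survivors are ranked by
correlation. The same scoring applied to single compounds nominates putative
active ingredients, and a **mechanism subnetwork** — the top-20 nodes of the
compound and disease profiles, induced and stitched along shortest paths —
proposes how a compound reaches the disease. Target lists can additionally
be run through gene-set enrichment (hypergeometric p, BH adjustment, odds
ratio, rank-deviation z and combined score) against any GMT library.

## Worked example

```python
from herbwalk.diffusion import WalkParams, entity_diffusion_profile
from herbwalk.prioritization import rank_herbs, score_herbs
from herbwalk.synthetic import SyntheticConfig, generate_world

world = generate_world(SyntheticConfig(seed=1))
params = WalkParams()
dprof = entity_diffusion_profile(world.network, world.disease.disease_id,
                                 "disease", world.disease.genes, params)
scores = score_herbs(world.network, world.catalog, dprof, world.disease, params)
print(rank_herbs(scores).to_string(index=False))
```

prints

```
entity  correlation_score  k  n  p_value  enrichment  n_active_compounds
   H06           0.498981  9 23 0.000489    2.993478                   8
```

H06 is the herb the generator planted next to the disease module: its
diffusion profile correlates at 0.499 with the disease profile (decoy herbs
score ≤ 0.057), 9 of its 23 targets are disease genes (hypergeometric
p = 4.9 × 10⁻⁴, 3.0-fold enriched over the background rate), and 8 of its
compounds touch the disease neighborhood — so it alone passes the selection
filters. The scripts in `examples/` walk through each capability (world
generation, diffusion profiles, herb ranking, compound ranking + mechanism
subnetworks, enrichment) with commented output.

A thin CLI mirrors the library for shell use:

```bash
herbwalk generate data/ --seed 1
herbwalk run-all --config config.yaml
```

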