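"""Score every herb against the disease profile and rank the candidates.

Each herb gets a correlation score (similarity of its diffusion profile to
the disease profile) and a hypergeometric overlap statistic for its target
set. Herbs must pass overlap p < 0.05 and carry >= 5 disease-linked
compounds; survivors are ranked by correlation. In a planted world the
planted herb should top the table.
"""

from herbwalk.diffusion import WalkParams, entity_diffusion_profile
from herbwalk.prioritization import rank_herbs, score_herbs
from herbwalk.synthetic import SyntheticConfig, generate_world

world = generate_world(SyntheticConfig(seed=1))
params = WalkParams()

disease_profile = entity_diffusion_profile(
    world.network, world.disease.disease_id, "disease",
    world.disease.genes, params)

scores = score_herbs(world.network, world.catalog, disease_profile,
                     world.disease, params)
print("herb  correlation  overlap             active_compounds")
for s in sorted(scores, key=lambda s: -s.correlation):
    print(f"{s.entity_id:>4}  {s.correlation:>10.4f}  {str(s.overlap):<18}"
          f"  {s.n_active_compounds}")

table = rank_herbs(scores)
print("\nranking after p<0.05 and >=5-active-compound filters:")
print(table.to_string(index=False))
print(f"\nplanted herb was: {world.planted_herb}")
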