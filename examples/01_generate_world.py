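"""Generate a synthetic multiscale world and write its input bundle.

The world has a scale-free protein layer, a function hierarchy, herb/compound
annotation tables and a disease module, with one herb planted close to the
disease. The printed counts describe the world's composition; truth.json
records which herb was planted.
"""

from herbwalk.synthetic import SyntheticConfig, generate_world, write_bundle

config = SyntheticConfig(seed=1)
world = generate_world(config)
paths = write_bundle(world, "scratch/example_world")

net = world.network
print(f"proteins:  {len(net.nodes_of_class('protein'))}")
print(f"functions: {len(net.nodes_of_class('function'))}")
print(f"edges:     {net.n_edges}")
print(f"herbs:     {len(world.catalog.herbs)} (planted: {world.planted_herb})")
print(f"disease genes: {len(world.disease.genes)}")
print("files:", ", ".join(sorted(p.name for p in paths.values())))
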