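"""Self-contained synthetic worlds with the structure the analysis assumes.

A world holds a scale-free PPI layer (preferential attachment), a rooted
function hierarchy (random tree) with proteins annotated to leaf functions,
a connected disease module (breadth-first ball around a high-degree
protein), and a herb catalog in which one *planted* herb's compound targets
are drawn from the disease module and its 1-hop PPI neighborhood while
decoy herbs draw targets uniformly from non-disease proteins. Generation is
a pure function of (config, seed): the same config yields byte-identical
output files.

Proximal draws pick a disease gene uniformly and then keep it or step to
one of its PPI neighbors with equal probability, so roughly half of the
planted targets are disease genes themselves — a deliberately strong, known
signal that planted-recovery experiments are judged against.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .exceptions import ConfigError
from .io import write_gmt
from .network import (
    DiseaseGeneSet,
    HerbCatalog,
    MultiscaleNetwork,
    TypedEdge,
    assemble_network,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults are the package's standard study
    conditions (small enough to run everywhere, large enough for the
    diffusion signal to be nontrivial)."""

    n_proteins: int = 300
    n_functions: int = 60
    ppi_attachment: int = 3          # edges per new protein (preferential attachment)
    annotation_rate: float = 1.5     # mean protein->function edges per protein
    n_herbs: int = 10
    compounds_per_herb: tuple[int, int] = (3, 8)
    targets_per_compound: tuple[int, int] = (1, 6)
    disease_size: int = 20
    planted_herb_proximity: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_functions", "n_herbs", "disease_size"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if self.disease_size > self.n_proteins:
            raise ConfigError("disease_size cannot exceed n_proteins")
        if not 0.0 <= self.planted_herb_proximity <= 1.0:
            raise ConfigError("planted_herb_proximity must be in [0,1]")
        if self.ppi_attachment < 1 or self.ppi_attachment >= self.n_proteins:
            raise ConfigError("ppi_attachment must be in [1, n_proteins)")
        for name in ("compounds_per_herb", "targets_per_compound"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ConfigError(f"{name} must be a nondecreasing positive range")


@dataclass
class SyntheticWorld:
    config: SyntheticConfig
    network: MultiscaleNetwork
    catalog: HerbCatalog
    disease: DiseaseGeneSet
    planted_herb: str
    planted_compounds: tuple[str, ...]


def _protein(i: int) -> str:
    return f"P{i:04d}"


def _function(i: int) -> str:
    return f"F{i:03d}"


def generate_world(config: SyntheticConfig) -> SyntheticWorld:
    """Generate one world deterministically from ``config`` (incl. its seed)."""
    rng = np.random.default_rng(config.seed)

    # protein layer: scale-free via preferential attachment
    ba_seed = int(rng.integers(2**31))
    ba = nx.barabasi_albert_graph(config.n_proteins, config.ppi_attachment,
                                  seed=ba_seed)
    ppi_edges = [TypedEdge(_protein(u + 1), _protein(v + 1), "ppi")
                 for u, v in sorted(ba.edges())]
    proteins = [_protein(i + 1) for i in range(config.n_proteins)]

    # function layer: random rooted tree; children attach to earlier nodes
    fh_edges = []
    children: dict[int, list[int]] = {}
    for i in range(2, config.n_functions + 1):
        parent = int(rng.integers(1, i))
        children.setdefault(parent, []).append(i)
        fh_edges.append(TypedEdge(_function(parent), _function(i),
                                  "function_hierarchy"))
    if not fh_edges:  # single-function degenerate world
        raise ConfigError("n_functions must be at least 2")
    leaves = sorted(_function(i) for i in range(1, config.n_functions + 1)
                    if i not in children)

    # protein -> leaf-function annotations
    pf_edges: list[TypedEdge] = []
    for p in proteins:
        count = min(int(rng.poisson(config.annotation_rate)), len(leaves))
        if count:
            chosen = rng.choice(leaves, size=count, replace=False)
            pf_edges.extend(TypedEdge(p, f, "protein_function")
                            for f in sorted(chosen))
    if not pf_edges:
        pf_edges.append(TypedEdge(proteins[0], leaves[0], "protein_function"))

    network = assemble_network(ppi_edges, pf_edges, fh_edges)

    # disease module: breadth-first ball around the highest-degree protein
    ppi = nx.Graph()
    ppi.add_edges_from((e.u, e.v) for e in ppi_edges)
    start = max(ppi.nodes, key=lambda n: (ppi.degree(n), n))
    module: list[str] = []
    queue = [start]
    seen = {start}
    while queue and len(module) < config.disease_size:
        node = queue.pop(0)
        module.append(node)
        for nb in sorted(ppi[node]):
            if nb not in seen:
                seen.add(nb)
                queue.append(nb)
    disease_genes = sorted(module)
    disease = DiseaseGeneSet("SYNTHETIC_DISEASE", frozenset(disease_genes))

    non_disease = sorted(set(proteins) - set(disease_genes))

    def proximal_target() -> str:
        gene = disease_genes[int(rng.integers(len(disease_genes)))]
        if rng.random() < 0.5:
            return gene
        nbrs = sorted(ppi[gene])
        return nbrs[int(rng.integers(len(nbrs)))]

    def draw_targets(n: int, planted: bool) -> tuple[str, ...]:
        targets: set[str] = set()
        attempts = 0
        while len(targets) < n and attempts < 50 * n:
            attempts += 1
            if planted and rng.random() < config.planted_herb_proximity:
                targets.add(proximal_target())
            elif planted:
                targets.add(proteins[int(rng.integers(len(proteins)))])
            else:
                targets.add(non_disease[int(rng.integers(len(non_disease)))])
        return tuple(sorted(targets))

    planted_idx = int(rng.integers(config.n_herbs))
    herb_compounds: dict[str, tuple[str, ...]] = {}
    compound_targets: dict[str, tuple[str, ...]] = {}
    planted_herb = ""
    planted_compounds: tuple[str, ...] = ()
    c_lo, c_hi = config.compounds_per_herb
    t_lo, t_hi = config.targets_per_compound
    next_compound = 1
    for h in range(config.n_herbs):
        herb = f"H{h + 1:02d}"
        planted = h == planted_idx
        n_comp = int(rng.integers(c_lo, c_hi + 1))
        if planted:
            # the planted herb must survive both the >=3-ingredient filter
            # and the >=5-active-compound selection rule
            n_comp = max(n_comp, 5)
        compounds = []
        for _ in range(n_comp):
            cid = f"C{next_compound:04d}"
            next_compound += 1
            n_t = int(rng.integers(t_lo, t_hi + 1))
            compound_targets[cid] = draw_targets(n_t, planted)
            compounds.append(cid)
        herb_compounds[herb] = tuple(compounds)
        if planted:
            planted_herb = herb
            planted_compounds = tuple(compounds)

    catalog = HerbCatalog(herb_compounds, compound_targets)
    logger.info("generated world seed=%d: %d proteins, %d functions, "
                "%d herbs (planted %s)", config.seed, config.n_proteins,
                config.n_functions, config.n_herbs, planted_herb)
    return SyntheticWorld(config, network, catalog, disease,
                          planted_herb, planted_compounds)


def write_bundle(world: SyntheticWorld, outdir: str | Path) -> dict[str, Path]:
    """Write the standard input bundle (TSV/GMT/JSON) for a world.

    Files: ppi.tsv, protein_function.tsv, function_hierarchy.tsv,
    herb_compound.tsv, compound_target.tsv, disease.gmt, truth.json.
    Output is deterministic (sorted) so reruns are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    by_class: dict[str, list[tuple[str, str]]] = {}
    for u, v, cls in world.network.graph.edges(data="edge_class"):
        a, b = (u, v) if u <= v else (v, u)
        by_class.setdefault(cls, []).append((a, b))
    for cls, fname in (("ppi", "ppi.tsv"),
                       ("protein_function", "protein_function.tsv"),
                       ("function_hierarchy", "function_hierarchy.tsv")):
        path = outdir / fname
        with path.open("w") as fh:
            fh.write(f"# {cls} edges\n")
            for a, b in sorted(by_class.get(cls, [])):
                fh.write(f"{a}\t{b}\n")
        paths[cls] = path

    # protein_function.tsv must list the protein first; restore column order
    pf_path = paths["protein_function"]
    lines = []
    for a, b in sorted(by_class.get("protein_function", [])):
        p, f = (a, b) if a.startswith("P") else (b, a)
        lines.append(f"{p}\t{f}\n")
    with pf_path.open("w") as fh:
        fh.write("# protein_function edges\n")
        fh.writelines(sorted(lines))

    hc_path = outdir / "herb_compound.tsv"
    with hc_path.open("w") as fh:
        fh.write("# herb_id\tcompound_id\n")
        for herb in world.catalog.herbs:
            for c in world.catalog.compounds(herb):
                fh.write(f"{herb}\t{c}\n")
    paths["herb_compound"] = hc_path

    ct_path = outdir / "compound_target.tsv"
    with ct_path.open("w") as fh:
        fh.write("# compound_id\tgene_symbol\n")
        for c in sorted(world.catalog.compound_targets):
            for t in world.catalog.compound_targets[c]:
                fh.write(f"{c}\t{t}\n")
    paths["compound_target"] = ct_path

    gmt_path = outdir / "disease.gmt"
    write_gmt({world.disease.disease_id: set(world.disease.genes)}, gmt_path,
              description="synthetic disease module")
    paths["disease"] = gmt_path

    truth_path = outdir / "truth.json"
    truth = {
        "planted_herb": world.planted_herb,
        "planted_compounds": list(world.planted_compounds),
        "disease_genes": sorted(world.disease.genes),
        "config": asdict(world.config),
    }
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    paths["truth"] = truth_path
    return paths


# ---------------------------------------------------------------------------
# deterministic micro-fixture mirroring the printed herb-overlap table


@dataclass(frozen=True)
class ReferenceToy:
    """Deterministic fixture of ten herb target sets with fixed overlap
    counts against a disease set, over a background chosen so that all
    printed fold-enrichment values share one background fraction.

    ``printed`` maps herb id -> (k, n, printed fold enrichment).
    """

    background: tuple[str, ...]
    disease_genes: frozenset[str]
    herb_targets: dict[str, frozenset[str]] = field(default_factory=dict)
    printed: dict[str, tuple[int, int, float]] = field(default_factory=dict)

    @property
    def background_fraction(self) -> float:
        return len(self.disease_genes) / len(self.background)


#: (k, n, printed enrichment) rows of the reference herb-overlap table.
REFERENCE_OVERLAP_ROWS: tuple[tuple[int, int, float], ...] = (
    (2, 50, 16.91),
    (5, 50, 42.27),
    (2, 27, 31.31),
    (2, 26, 32.52),
    (2, 38, 22.25),
    (1, 11, 38.43),
    (4, 50, 33.82),
    (4, 50, 33.82),
    (4, 50, 33.82),
    (3, 50, 25.36),
)


def make_reference_toy() -> ReferenceToy:
    """Build the micro-fixture: background of 4227 genes, 10 disease genes
    (background fraction exactly 1/422.7) and ten herb target sets with the
    reference (k, n) overlap pattern. Regeneration is idempotent."""
    n_background, n_disease = 4227, 10
    background = tuple(f"G{i:05d}" for i in range(1, n_background + 1))
    disease = frozenset(background[:n_disease])
    disease_sorted = sorted(disease)
    herb_targets: dict[str, frozenset[str]] = {}
    printed: dict[str, tuple[int, int, float]] = {}
    filler_start = n_disease  # index into background of the next free filler
    for i, (k, n, enr) in enumerate(REFERENCE_OVERLAP_ROWS):
        herb = f"H{i + 1:02d}"
        fillers = background[filler_start:filler_start + (n - k)]
        filler_start += n - k
        herb_targets[herb] = frozenset(disease_sorted[:k]) | frozenset(fillers)
        printed[herb] = (k, n, enr)
    return ReferenceToy(background, disease, herb_targets, printed)
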