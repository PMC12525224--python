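"""Typed multiscale network assembly and herb/compound/disease catalogs.

The analysis runs on a multilayer graph joining three undirected, unweighted
layers: protein–protein interactions, protein→biological-function
annotations, and a function–function hierarchy. Herb, compound and disease
entities are attached as explicit nodes wired to their protein targets, so
that diffusion can be seeded uniformly at the entity node.

Node ids are strings; every node carries exactly one class label and every
edge one class tag. Gene symbols are normalized to uppercase ASCII; no alias
resolution is attempted (a documented limitation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import networkx as nx

from .exceptions import (
    ConfigError,
    ConsistencyError,
    EmptyInputError,
    ParseError,
    UnlinkedEntityError,
)
from .io import read_gene_list, read_gmt

logger = logging.getLogger(__name__)

NODE_CLASSES = frozenset({"protein", "function", "herb", "compound", "disease"})
ENTITY_CLASSES = frozenset({"herb", "compound", "disease"})

#: edge class -> (class of first endpoint, class of second endpoint)
EDGE_ENDPOINTS: dict[str, tuple[str, str]] = {
    "ppi": ("protein", "protein"),
    "protein_function": ("protein", "function"),
    "function_hierarchy": ("function", "function"),
    "herb_compound": ("herb", "compound"),
    "herb_target": ("herb", "protein"),
    "compound_target": ("compound", "protein"),
    "disease_gene": ("disease", "protein"),
}
EDGE_CLASSES = frozenset(EDGE_ENDPOINTS)

#: edge class used when an entity of a given class is wired to its targets
ENTITY_EDGE_CLASS = {"herb": "herb_target", "compound": "compound_target",
                     "disease": "disease_gene"}


class TypedEdge(NamedTuple):
    u: str
    v: str
    edge_class: str


def load_edge_list(path: str | Path, edge_class: str) -> list[TypedEdge]:
    """Parse a 2+-column TSV edge list into typed, deduplicated edges.

    Lines starting with ``#`` and blank lines are skipped; columns beyond the
    second are ignored. Edges are undirected: ``A\\tB`` and ``B\\tA`` collapse
    to one edge. Self-loops are dropped with a warning.
    """
    if edge_class not in EDGE_CLASSES:
        raise ConfigError(f"unknown edge class {edge_class!r}")
    path = Path(path)
    edges: list[TypedEdge] = []
    seen: set[tuple[str, str]] = set()
    n_lines = n_self = n_dup = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ParseError(
                    f"{path}:{lineno}: expected at least two tab-separated columns"
                )
            n_lines += 1
            u, v = parts[0], parts[1]
            if u == v:
                n_self += 1
                continue
            key = (u, v) if u <= v else (v, u)
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            edges.append(TypedEdge(u, v, edge_class))
    if not edges:
        raise EmptyInputError(f"{path}: no {edge_class} edges found")
    logger.info("%s: %d data lines -> %d %s edges (%d duplicate, %d self-loop)",
                path, n_lines, len(edges), edge_class, n_dup, n_self)
    return edges


@dataclass
class MultiscaleNetwork:
    """Typed multilayer graph over proteins, functions and attached entities.

    Thin wrapper around an undirected :class:`networkx.Graph` whose nodes
    carry a ``node_class`` attribute and edges an ``edge_class`` attribute.
    """

    graph: nx.Graph

    def node_class(self, node: str) -> str:
        return self.graph.nodes[node]["node_class"]

    def nodes_of_class(self, node_class: str) -> list[str]:
        return sorted(n for n, c in self.graph.nodes(data="node_class")
                      if c == node_class)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def copy(self) -> "MultiscaleNetwork":
        return MultiscaleNetwork(self.graph.copy())

    def isolated_proteins(self) -> list[str]:
        """Proteins with neither a PPI nor a function-annotation edge.

        Such nodes are retained, not dropped; the walk can still reach them
        through entity edges. Reported so callers can flag them.
        """
        out = []
        for n in self.nodes_of_class("protein"):
            classes = {d["edge_class"] for _, _, d in self.graph.edges(n, data=True)}
            if not classes & {"ppi", "protein_function"}:
                out.append(n)
        return out

    def validate(self) -> None:
        """Check edge/endpoint class compatibility for every edge."""
        for u, v, cls in self.graph.edges(data="edge_class"):
            want = frozenset(EDGE_ENDPOINTS[cls])
            got = frozenset({self.node_class(u), self.node_class(v)})
            if got != want:
                raise ConsistencyError(
                    f"edge ({u},{v}) of class {cls} joins classes {sorted(got)}"
                )


def assemble_network(ppi: Sequence[TypedEdge],
                     protein_function: Sequence[TypedEdge],
                     function_hierarchy: Sequence[TypedEdge]) -> MultiscaleNetwork:
    """Assemble the three base layers into one typed network.

    Node classes are inferred from layer membership; for protein→function
    edges the first column is the protein and the second the function. An id
    claimed by two different classes raises :class:`ConsistencyError`.
    """
    for name, layer in (("ppi", ppi), ("protein_function", protein_function),
                        ("function_hierarchy", function_hierarchy)):
        if not layer:
            raise EmptyInputError(f"{name} edge list is empty")

    classes: dict[str, str] = {}

    def assign(node: str, cls: str) -> None:
        prev = classes.setdefault(node, cls)
        if prev != cls:
            raise ConsistencyError(
                f"node {node!r} used as both {prev!r} and {cls!r}"
            )

    for e in ppi:
        assign(e.u, "protein")
        assign(e.v, "protein")
    for e in function_hierarchy:
        assign(e.u, "function")
        assign(e.v, "function")
    for e in protein_function:
        assign(e.u, "protein")
        assign(e.v, "function")

    if not classes:
        raise EmptyInputError("no nodes in any layer")

    g = nx.Graph()
    for node, cls in classes.items():
        g.add_node(node, node_class=cls)
    for e in (*ppi, *protein_function, *function_hierarchy):
        g.add_edge(e.u, e.v, edge_class=e.edge_class)

    net = MultiscaleNetwork(g)
    net.validate()
    iso = net.isolated_proteins()
    if iso:
        logger.warning("%d isolated proteins retained: %s%s", len(iso),
                       ", ".join(iso[:5]), "..." if len(iso) > 5 else "")
    logger.info("assembled network: %d nodes (%d protein, %d function), %d edges",
                net.n_nodes, len(net.nodes_of_class("protein")),
                len(net.nodes_of_class("function")), net.n_edges)
    return net


def attach_entity(net: MultiscaleNetwork, entity_id: str, entity_class: str,
                  targets: Iterable[str]) -> int:
    """Attach one entity node, wired to each target that maps onto a protein.

    Mutates ``net`` in place and returns the number of unmapped symbols.
    Raises :class:`UnlinkedEntityError` when no target maps; callers must
    then exclude the entity from scoring.
    """
    if entity_class not in ENTITY_CLASSES:
        raise ConfigError(f"not an entity class: {entity_class!r}")
    if entity_id in net.graph:
        raise ConsistencyError(f"node id {entity_id!r} already in network")
    symbols = sorted({str(t).upper() for t in targets})
    if not symbols:
        raise EmptyInputError(f"entity {entity_id!r}: empty target set")
    mapped = [s for s in symbols
              if s in net.graph and net.node_class(s) == "protein"]
    if not mapped:
        raise UnlinkedEntityError(
            f"entity {entity_id!r}: none of {len(symbols)} targets map onto "
            "network proteins"
        )
    net.graph.add_node(entity_id, node_class=entity_class)
    cls = ENTITY_EDGE_CLASS[entity_class]
    for s in mapped:
        net.graph.add_edge(entity_id, s, edge_class=cls)
    unmapped = len(symbols) - len(mapped)
    if unmapped:
        logger.info("entity %s: %d/%d targets unmapped", entity_id, unmapped,
                    len(symbols))
    return unmapped


# ---------------------------------------------------------------------------
# herb / compound catalog


@dataclass
class HerbCatalog:
    """Herb→compound and compound→target annotation tables.

    Duplicate compounds within a herb and duplicate targets within a
    compound collapse to one record; target symbols are uppercased.
    Compounds with zero targets are permitted but flagged at load time.
    """

    herb_compounds: dict[str, tuple[str, ...]]
    compound_targets: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        self.herb_compounds = {
            h: tuple(dict.fromkeys(cs)) for h, cs in self.herb_compounds.items()
        }
        self.compound_targets = {
            c: tuple(sorted({str(t).upper() for t in ts}))
            for c, ts in self.compound_targets.items()
        }

    @property
    def herbs(self) -> list[str]:
        return sorted(self.herb_compounds)

    def compounds(self, herb: str) -> tuple[str, ...]:
        if herb not in self.herb_compounds:
            raise KeyError(f"unknown herb {herb!r}")
        return self.herb_compounds[herb]

    def targets_of(self, compound: str) -> tuple[str, ...]:
        return self.compound_targets.get(compound, ())

    def target_bearing_compounds(self, herb: str) -> list[str]:
        """The herb's compounds that have at least one target annotation."""
        return [c for c in self.compounds(herb) if self.targets_of(c)]

    def herb_targets(self, herb: str) -> set[str]:
        """Union of the herb's compound targets."""
        out: set[str] = set()
        for c in self.compounds(herb):
            out.update(self.targets_of(c))
        return out

    def flagged_compounds(self) -> list[str]:
        """Compounds referenced by a herb but carrying zero targets."""
        referenced = {c for cs in self.herb_compounds.values() for c in cs}
        return sorted(c for c in referenced if not self.targets_of(c))

    @classmethod
    def from_tsv(cls, herb_compound_path: str | Path,
                 compound_target_path: str | Path) -> "HerbCatalog":
        """Load from 2-column TSVs (herb_id, compound_id) / (compound_id, symbol)."""
        hc: dict[str, list[str]] = {}
        for e in load_edge_list(herb_compound_path, "herb_compound"):
            hc.setdefault(e.u, []).append(e.v)
        ct: dict[str, list[str]] = {}
        for e in load_edge_list(compound_target_path, "compound_target"):
            ct.setdefault(e.u, []).append(e.v)
        cat = cls({h: tuple(cs) for h, cs in hc.items()},
                  {c: tuple(ts) for c, ts in ct.items()})
        flagged = cat.flagged_compounds()
        if flagged:
            logger.warning("%d compounds have zero target annotations", len(flagged))
        return cat


def filter_herbs_min_ingredients(catalog: HerbCatalog,
                                 min_count: int = 3) -> HerbCatalog:
    """Drop herbs with fewer than ``min_count`` target-bearing compounds.

    Herbs need several target-annotated ingredients before network scoring
    is meaningful; the default floor of 3 matches the study design this
    package implements. Idempotent; the exclusion list is logged.
    """
    kept: dict[str, tuple[str, ...]] = {}
    excluded: list[str] = []
    for herb in catalog.herbs:
        if len(catalog.target_bearing_compounds(herb)) >= min_count:
            kept[herb] = catalog.herb_compounds[herb]
        else:
            excluded.append(herb)
    if excluded:
        logger.info("excluded %d herbs below %d target-bearing compounds: %s",
                    len(excluded), min_count, ", ".join(excluded))
    if not kept:
        logger.warning("no herbs survive the min-ingredient filter")
    return HerbCatalog(kept, dict(catalog.compound_targets))


def simple_path_counts(catalog: HerbCatalog, herb: str) -> dict[str, int]:
    """Count herb→compound→target paths per target.

    A target annotated to several of the herb's compounds counts once per
    compound, so the count measures how many constituents converge on it.
    """
    counts: dict[str, int] = {}
    for compound in catalog.compounds(herb):
        for t in catalog.targets_of(compound):
            counts[t] = counts.get(t, 0) + 1
    return counts


def select_top_targets(path_counts: Mapping[str, int],
                       limit: int = 50) -> list[str]:
    """Targets sorted by descending path count (ties lexicographic), truncated."""
    if not path_counts:
        raise EmptyInputError("empty path-count map")
    ranked = sorted(path_counts, key=lambda t: (-path_counts[t], t))
    return ranked[:limit]


# ---------------------------------------------------------------------------
# disease gene sets


@dataclass(frozen=True)
class DiseaseGeneSet:
    """A disease id with its associated gene symbols (uppercased).

    ``mapped_fraction`` records, after attachment, what share of the symbols
    mapped onto network proteins.
    """

    disease_id: str
    genes: frozenset[str]
    mapped_fraction: float | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise EmptyInputError(f"disease {self.disease_id!r}: empty gene set")
        object.__setattr__(self, "genes",
                           frozenset(str(g).upper() for g in self.genes))

    def with_mapped_fraction(self, frac: float) -> "DiseaseGeneSet":
        return replace(self, mapped_fraction=frac)

    @classmethod
    def from_file(cls, path: str | Path,
                  disease_id: str | None = None) -> "DiseaseGeneSet":
        """Read from GMT (first set) or a one-symbol-per-line list."""
        path = Path(path)
        if path.suffix.lower() == ".gmt":
            sets = read_gmt(path)
            name = disease_id if disease_id in sets else next(iter(sorted(sets)))
            return cls(disease_id or name, frozenset(sets[name]))
        return cls(disease_id or path.stem, frozenset(read_gene_list(path)))


def attach_disease(net: MultiscaleNetwork,
                   disease: DiseaseGeneSet) -> DiseaseGeneSet:
    """Attach the disease entity node; returns the set annotated with the
    fraction of genes that mapped onto network proteins."""
    unmapped = attach_entity(net, disease.disease_id, "disease", disease.genes)
    frac = 1.0 - unmapped / len(disease.genes)
    return disease.with_mapped_fraction(frac)
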