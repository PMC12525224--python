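"""Mechanism subnetwork extraction.

A mechanism subnetwork proposes how a compound reaches a disease: it joins
the top-k protein/function nodes of the compound's diffusion profile with
the top-k nodes of the disease profile, keeps both entity nodes, and induces
all parent-network edges among them. Selected nodes that the induced edges
leave disconnected are stitched in along shortest paths taken from a fixed
breadth-first tree rooted at the disease entity (ties in the tree prefer
parents with higher disease visitation, then lexicographic id). Because the
tree does not depend on k, growing k only ever adds nodes, and every added
path is a shortest path in the parent network. Interior path nodes outside
both top-k lists are tagged ``connector``.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx

from .diffusion import DiffusionProfile, profile_topk
from .exceptions import ConfigError, UnlinkedEntityError
from .network import MultiscaleNetwork

logger = logging.getLogger(__name__)

MECHANISM_CLASSES = frozenset({"protein", "function"})


@dataclass
class MechanismSubnetwork:
    """Induced, stitched subgraph linking a compound to a disease.

    Node attributes: ``node_class``, ``provenance`` (compound_topk,
    disease_topk, both, seed, connector), ``compound_freq``, ``disease_freq``.
    ``connector_paths`` records each stitched root→node path for audit.
    """

    compound_id: str
    disease_id: str
    graph: nx.Graph
    k: int
    connector_paths: dict[str, tuple[str, ...]]

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def nodes_with_provenance(self, tag: str) -> list[str]:
        return sorted(n for n, p in self.graph.nodes(data="provenance")
                      if p == tag)


def _disease_rooted_tree(graph: nx.Graph, root: str,
                         freq: Mapping[str, float]) -> tuple[dict[str, int],
                                                             dict[str, str]]:
    """BFS distances and parents from ``root``.

    Among equal-distance predecessors a node's parent is the one with the
    highest disease visitation frequency (ties: lexicographically smallest
    id), so stitched paths run through nodes the disease walk actually
    visits. Both maps are independent of k.
    """
    dist = {root: 0}
    order = [root]
    queue = deque([root])
    while queue:
        u = queue.popleft()
        for v in sorted(graph[u]):
            if v not in dist:
                dist[v] = dist[u] + 1
                order.append(v)
                queue.append(v)
    parent: dict[str, str] = {}
    for v in order[1:]:
        preds = [u for u in graph[v] if dist.get(u, -1) == dist[v] - 1]
        parent[v] = max(preds, key=lambda u: (freq.get(u, 0.0), u))
    return dist, parent


def extract_mechanism(net: MultiscaleNetwork,
                      compound_profile: DiffusionProfile,
                      disease_profile: DiffusionProfile,
                      k: int = 20,
                      function_whitelist: set[str] | None = None
                      ) -> MechanismSubnetwork:
    """Build the mechanism subnetwork for one compound–disease pair.

    ``net`` must already contain both entity nodes (the profiles' seeds).
    ``function_whitelist``, when given, restricts selected function nodes to
    that set (e.g. enrichment-significant processes); default keeps the raw
    top-k. Raises :class:`UnlinkedEntityError` for a compound with no edge
    into the network.
    """
    if k < 1:
        raise ConfigError("k must be positive")
    compound_id = compound_profile.seed
    disease_id = disease_profile.seed
    g = net.graph
    for node in (compound_id, disease_id):
        if node not in g:
            raise UnlinkedEntityError(f"entity {node!r} not in network")
    if g.degree(compound_id) == 0:
        raise UnlinkedEntityError(
            f"compound {compound_id!r} has no link into the network; excluded")

    def topk(profile: DiffusionProfile) -> list[str]:
        sel = profile_topk(profile, k, MECHANISM_CLASSES)
        sel = [n for n in sel if n not in (compound_id, disease_id)]
        if function_whitelist is not None:
            sel = [n for n in sel
                   if net.node_class(n) != "function" or n in function_whitelist]
        return sel

    top_c = set(topk(compound_profile))
    top_d = set(topk(disease_profile))

    provenance: dict[str, str] = {}
    for n in top_c | top_d:
        if n in top_c and n in top_d:
            provenance[n] = "both"
        elif n in top_c:
            provenance[n] = "compound_topk"
        else:
            provenance[n] = "disease_topk"
    provenance[compound_id] = "seed"
    provenance[disease_id] = "seed"

    dfreq = dict(zip(disease_profile.nodes, disease_profile.values))
    dist, parent = _disease_rooted_tree(g, disease_id, dfreq)

    nodeset = set(provenance)
    connector_paths: dict[str, tuple[str, ...]] = {}
    for target in sorted(top_c | top_d | {compound_id}):
        if target not in dist:
            logger.warning("node %s unreachable from %s; left unstitched",
                           target, disease_id)
            continue
        path = [target]
        while path[-1] != disease_id:
            path.append(parent[path[-1]])
        path.reverse()  # disease_id ... target
        connector_paths[target] = tuple(path)
        for node in path[1:-1]:
            if node not in nodeset:
                nodeset.add(node)
                provenance[node] = "connector"

    sub = g.subgraph(nodeset).copy()
    cfreq = dict(zip(compound_profile.nodes, compound_profile.values))
    for n in sub.nodes:
        sub.nodes[n]["provenance"] = provenance[n]
        sub.nodes[n]["compound_freq"] = float(cfreq.get(n, 0.0))
        sub.nodes[n]["disease_freq"] = float(dfreq.get(n, 0.0))
    logger.info("mechanism %s vs %s: %d nodes (%d connector), %d edges",
                compound_id, disease_id, sub.number_of_nodes(),
                sum(1 for _, p in sub.nodes(data="provenance")
                    if p == "connector"),
                sub.number_of_edges())
    return MechanismSubnetwork(compound_id, disease_id, sub, k, connector_paths)


def export_subnetwork(sub: MechanismSubnetwork, path: str | Path,
                      fmt: str = "graphml") -> Path:
    """Write the subnetwork as GraphML (attributed) or SIF (one edge per line,
    interaction column = edge class)."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(sub.graph, path)
    elif fmt == "sif":
        with path.open("w") as fh:
            for u, v, cls in sorted(sub.graph.edges(data="edge_class")):
                fh.write(f"{u}\t{cls}\t{v}\n")
    else:
        raise ConfigError(f"unsupported export format {fmt!r}")
    return path


def read_subnetwork_graphml(path: str | Path) -> nx.Graph:
    """Round-trip reader for GraphML exports."""
    return nx.read_graphml(Path(path))
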