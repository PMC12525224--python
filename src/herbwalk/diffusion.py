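"""Class-biased random walk with restart and diffusion profiles.

The walker moves on the undirected multiscale network. At a node ``u`` it
steps to neighbor ``v`` with probability proportional to the bias weight of
the edge class joining them, so raising the ``protein_function`` weight
shifts probability mass toward biological-function nodes. At every step the
walker restarts at its seed with probability ``restart_prob``. The diffusion
profile of a seed is the stationary visitation-frequency vector

    r = restart_prob * e_seed + (1 - restart_prob) * M r,

with ``M`` the column-stochastic biased transition operator. Profiles are
computed by power iteration; a dense linear solve is provided as an exact
oracle for small networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import sparse

from .exceptions import ConfigError, SizeLimitError
from .network import MultiscaleNetwork

logger = logging.getLogger(__name__)

#: Default bias weights. The walk is moderately biased toward
#: protein→function steps; every class not listed here defaults to 1.0.
DEFAULT_CLASS_WEIGHTS: dict[str, float] = {
    "ppi": 1.0,
    "protein_function": 2.0,
    "function_hierarchy": 1.0,
    "herb_target": 1.0,
    "herb_compound": 1.0,
    "compound_target": 1.0,
    "disease_gene": 1.0,
}

#: Size guard for the dense exact solver.
EXACT_SOLVE_MAX_NODES = 2000


@dataclass
class WalkParams:
    """Parameters of the biased random walk with restart.

    restart_prob
        Probability of teleporting back to the seed at each step; in (0, 1].
        Higher values localize the profile around the seed.
    class_weights
        Multiplicative bias per edge class (missing classes weigh 1.0).
    tol
        L1 convergence threshold for power iteration.
    max_iter
        Iteration cap; non-convergence is flagged, not fatal.
    """

    restart_prob: float = 0.5
    class_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS))
    tol: float = 1e-10
    max_iter: int = 500

    def __post_init__(self) -> None:
        if not 0.0 < self.restart_prob <= 1.0:
            raise ConfigError(f"restart_prob must be in (0,1], got {self.restart_prob}")
        if self.tol <= 0:
            raise ConfigError("tol must be positive")
        if self.max_iter < 1:
            raise ConfigError("max_iter must be positive")
        for cls, w in self.class_weights.items():
            if not w > 0:
                raise ConfigError(f"class weight {cls}={w} must be positive")

    def weight(self, edge_class: str) -> float:
        return self.class_weights.get(edge_class, 1.0)


@dataclass
class TransitionModel:
    """Column-stochastic transition operator over a fixed node ordering."""

    nodes: tuple[str, ...]
    index: dict[str, int]
    matrix: sparse.csr_matrix  # matrix[v, u] = P(u -> v)
    node_classes: dict[str, str]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass
class DiffusionProfile:
    """Stationary visitation frequencies of one seed entity.

    Entries are nonnegative and sum to 1 (within 1e-9); ``converged`` is
    False only when power iteration hit ``max_iter`` first.
    """

    seed: str
    nodes: tuple[str, ...]
    values: np.ndarray
    node_classes: Mapping[str, str]
    iterations: int
    converged: bool

    def __getitem__(self, node: str) -> float:
        return float(self.values[self.nodes.index(node)])

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.nodes), name=self.seed)

    def to_tsv(self, path: str | Path) -> None:
        """Write as 2-column TSV (node id, visitation frequency)."""
        with Path(path).open("w") as fh:
            fh.write("# node\tfrequency\n")
            for node, val in zip(self.nodes, self.values):
                fh.write(f"{node}\t{val:.12g}\n")


def build_transition_model(net: MultiscaleNetwork,
                           params: WalkParams) -> TransitionModel:
    """Build the biased, column-stochastic transition operator.

    Out of node ``u``, probability to neighbor ``v`` is the edge-class weight
    normalized over all of u's incident edge weights. Isolated nodes get a
    self-loop so the operator stays stochastic.
    """
    if net.n_nodes == 0:
        raise ConfigError("empty network")
    nodes = tuple(sorted(net.graph.nodes))
    index = {n: i for i, n in enumerate(nodes)}
    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    g = net.graph
    for j, u in enumerate(nodes):
        nbrs = sorted(g[u])
        if not nbrs:
            rows.append(j)
            cols.append(j)
            data.append(1.0)
            continue
        weights = np.array([params.weight(g.edges[u, v]["edge_class"])
                            for v in nbrs])
        probs = weights / weights.sum()
        for v, p in zip(nbrs, probs):
            rows.append(index[v])
            cols.append(j)
            data.append(float(p))
    matrix = sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(nodes), len(nodes)))
    classes = {n: net.node_class(n) for n in nodes}
    return TransitionModel(nodes, index, matrix, classes)


def compute_diffusion_profile(model: TransitionModel, seed: str,
                              params: WalkParams) -> DiffusionProfile:
    """Power-iterate the restart equation from the seed indicator vector.

    Stops when the L1 change drops below ``params.tol``; if ``max_iter`` is
    reached first the best iterate is returned with ``converged=False`` and
    a warning is logged.
    """
    if seed not in model.index:
        raise KeyError(f"seed node {seed!r} not in network")
    n = model.n_nodes
    e = np.zeros(n)
    e[model.index[seed]] = 1.0
    r = e.copy()
    c = params.restart_prob
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        r_next = c * e + (1.0 - c) * (model.matrix @ r)
        delta = float(np.abs(r_next - r).sum())
        r = r_next
        if delta < params.tol:
            converged = True
            break
    if not converged:
        logger.warning("diffusion for %s did not converge in %d iterations",
                       seed, params.max_iter)
    return DiffusionProfile(seed, model.nodes, r, model.node_classes,
                            it, converged)


def solve_diffusion_exact(model: TransitionModel, seed: str,
                          restart_prob: float) -> DiffusionProfile:
    """Exact stationary profile via a dense linear solve.

    Solves (I − (1−c) M) r = c e_seed. Verification oracle only; refuses
    networks above the dense-size guard.
    """
    n = model.n_nodes
    if n > EXACT_SOLVE_MAX_NODES:
        raise SizeLimitError(
            f"exact solve limited to {EXACT_SOLVE_MAX_NODES} nodes, got {n}")
    if seed not in model.index:
        raise KeyError(f"seed node {seed!r} not in network")
    if not 0.0 < restart_prob <= 1.0:
        raise ConfigError(f"restart_prob must be in (0,1], got {restart_prob}")
    e = np.zeros(n)
    e[model.index[seed]] = 1.0
    a = np.eye(n) - (1.0 - restart_prob) * model.matrix.toarray()
    r = restart_prob * np.linalg.solve(a, e)
    return DiffusionProfile(seed, model.nodes, r, model.node_classes, 0, True)


def profile_topk(profile: DiffusionProfile, k: int = 20,
                 node_filter: Iterable[str] | None = None) -> list[str]:
    """Top-k nodes by visitation frequency, seed excluded.

    ``node_filter`` restricts to the given node classes (e.g. proteins and
    functions only). Ties break lexicographically on node id; if fewer than
    ``k`` nodes qualify, all are returned.
    """
    allowed = set(node_filter) if node_filter is not None else None
    candidates = [
        (-(float(profile.values[i])), profile.nodes[i])
        for i in range(len(profile.nodes))
        if profile.nodes[i] != profile.seed
        and (allowed is None or profile.node_classes[profile.nodes[i]] in allowed)
    ]
    candidates.sort()
    return [node for _, node in candidates[:k]]


def entity_diffusion_profile(net: MultiscaleNetwork, entity_id: str,
                             entity_class: str, targets: Iterable[str],
                             params: WalkParams) -> DiffusionProfile:
    """Attach one entity to a copy of ``net`` and compute its profile.

    Each entity is scored on the base network plus itself alone, so entities
    never perturb each other's transition probabilities.
    """
    from .network import attach_entity  # local import to avoid cycle at module load

    scratch = net.copy()
    attach_entity(scratch, entity_id, entity_class, targets)
    model = build_transition_model(scratch, params)
    return compute_diffusion_profile(model, entity_id, params)
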