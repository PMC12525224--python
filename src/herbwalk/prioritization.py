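"""Herb and compound prioritization against a disease diffusion profile.

Candidates are scored two ways and must pass both:

* **correlation score** — Pearson (or Spearman) correlation between the
  entity's diffusion profile and the disease profile, taken over the shared
  protein/function nodes (entity-class nodes are excluded so an entity's own
  seed mass cannot inflate similarity);
* **target-overlap significance** — one-sided hypergeometric tail
  probability P(X ≥ k) of drawing k disease targets among the entity's n
  targets from a background universe of N proteins containing K disease
  targets, with fold enrichment (k/n)/(K/N).

Survivors are ranked by correlation score (ties: ascending p, then id).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffusion import DiffusionProfile, WalkParams, entity_diffusion_profile
from .exceptions import (
    ConfigError,
    ConsistencyError,
    EmptyInputError,
    UndefinedCorrelationError,
    UnlinkedEntityError,
)
from .network import (
    ENTITY_CLASSES,
    DiseaseGeneSet,
    HerbCatalog,
    MultiscaleNetwork,
    select_top_targets,
    simple_path_counts,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# statistics


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """One-sided upper tail P(X >= k), X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(n, K) and 0 < n <= N and 0 < K <= N):
        raise ConfigError(f"invalid hypergeometric instance k={k} N={N} K={K} n={n}")
    # survival function is the numerically stable tail sum
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(p, 1.0)


@dataclass(frozen=True)
class OverlapStat:
    """Overlap of an entity target set with the disease target set."""

    k: int  # overlap size
    n: int  # entity target-set size
    K: int  # disease target-set size
    N: int  # background universe size
    p_value: float
    enrichment: float

    def __str__(self) -> str:
        return f"{self.k}/{self.n} (p={self.p_value:.2g}, enr={self.enrichment:.2f})"


def hypergeometric_overlap(entity_targets: set[str], disease_targets: set[str],
                           background: set[str]) -> OverlapStat:
    """Overlap statistic of two gene sets within a background universe."""
    entity_targets, disease_targets = set(entity_targets), set(disease_targets)
    if not entity_targets or not disease_targets:
        raise EmptyInputError("entity and disease target sets must be nonempty")
    if not entity_targets <= background or not disease_targets <= background:
        raise ConsistencyError("target sets must be subsets of the background")
    k = len(entity_targets & disease_targets)
    n = len(entity_targets)
    K = len(disease_targets)
    N = len(background)
    p = hypergeom_tail(k, N, K, n)
    enrichment = (k / n) / (K / N)
    return OverlapStat(k, n, K, N, p, enrichment)


def fold_enrichment(k: int, n: int, background_fraction: float) -> float:
    """Observed overlap rate k/n divided by the background disease-target rate."""
    if n <= 0:
        raise ConfigError("n must be positive")
    if not 0.0 < background_fraction < 1.0:
        raise ConfigError("background_fraction must be in (0,1)")
    return (k / n) / background_fraction


def correlation_score(p: DiffusionProfile, q: DiffusionProfile,
                      method: str = "pearson") -> float:
    """Correlation between two diffusion profiles over shared non-entity nodes."""
    if method not in ("pearson", "spearman"):
        raise ConfigError(f"unknown correlation method {method!r}")
    common = sorted(
        node for node in set(p.nodes) & set(q.nodes)
        if p.node_classes[node] not in ENTITY_CLASSES
        and q.node_classes[node] not in ENTITY_CLASSES
    )
    if len(common) < 2:
        raise EmptyInputError("profiles share fewer than 2 non-entity nodes")
    ps, qs = p.as_series(), q.as_series()
    x = ps.loc[common].to_numpy()
    y = qs.loc[common].to_numpy()
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedCorrelationError(
            "correlation undefined: a profile has zero variance on the "
            "common node index"
        )
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    return float(stats.spearmanr(x, y).statistic)


# ---------------------------------------------------------------------------
# candidate scoring


@dataclass
class CandidateScore:
    """One entity's scores against the disease."""

    entity_id: str
    correlation: float
    overlap: OverlapStat
    n_active_compounds: int | None = None  # herb mode only
    passes_filters: bool = False


def default_background(net: MultiscaleNetwork, catalog: HerbCatalog,
                       disease: DiseaseGeneSet) -> set[str]:
    """Default overlap universe: network proteins appearing in at least one
    compound→target or disease→gene record."""
    recorded = {t for ts in catalog.compound_targets.values() for t in ts}
    recorded |= disease.genes
    return {t for t in recorded
            if t in net.graph and net.node_class(t) == "protein"}


def disease_linked_proteins(net: MultiscaleNetwork,
                            disease: DiseaseGeneSet) -> set[str]:
    """Disease genes mapped onto the network plus their PPI neighbors.

    Used to decide whether a compound counts as "active" (linked to the
    disease neighborhood) for the ≥5-active-compound herb criterion.
    """
    mapped = {g for g in disease.genes
              if g in net.graph and net.node_class(g) == "protein"}
    linked = set(mapped)
    for g in mapped:
        for nb in net.graph[g]:
            if net.node_class(nb) == "protein":
                linked.add(nb)
    return linked


def score_herbs(net: MultiscaleNetwork, catalog: HerbCatalog,
                disease_profile: DiffusionProfile, disease: DiseaseGeneSet,
                params: WalkParams, background: set[str] | None = None,
                top_targets: int = 50,
                method: str = "pearson") -> list[CandidateScore]:
    """Score every herb in the catalog against the disease profile.

    Each herb's target set is the union of its compound targets capped at
    ``top_targets`` by simple path count. Herbs whose targets do not map
    onto the network are excluded with a log entry.
    """
    if background is None:
        background = default_background(net, catalog, disease)
    disease_targets = disease.genes & background
    if not disease_targets:
        raise UnlinkedEntityError("no disease gene maps into the background")
    linked = disease_linked_proteins(net, disease)
    scores: list[CandidateScore] = []
    for herb in catalog.herbs:
        counts = simple_path_counts(catalog, herb)
        if not counts:
            logger.info("herb %s has no targets; excluded", herb)
            continue
        targets = set(select_top_targets(counts, top_targets))
        try:
            profile = entity_diffusion_profile(net, herb, "herb", targets, params)
        except UnlinkedEntityError:
            logger.info("herb %s unlinked from network; excluded", herb)
            continue
        corr = correlation_score(profile, disease_profile, method)
        mapped = {t for t in targets if t in background}
        if not mapped:
            logger.info("herb %s: no target in background; excluded", herb)
            continue
        overlap = hypergeometric_overlap(mapped, disease_targets, background)
        n_active = sum(
            1 for c in catalog.compounds(herb)
            if set(catalog.targets_of(c)) & linked
        )
        scores.append(CandidateScore(herb, corr, overlap, n_active))
    return scores


def _ranking_frame(scores: list[CandidateScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "entity": [s.entity_id for s in scores],
            "correlation_score": [s.correlation for s in scores],
            "k": [s.overlap.k for s in scores],
            "n": [s.overlap.n for s in scores],
            "p_value": [s.overlap.p_value for s in scores],
            "enrichment": [s.overlap.enrichment for s in scores],
            "n_active_compounds": [s.n_active_compounds for s in scores],
        }
    )


def rank_herbs(scores: list[CandidateScore], p_threshold: float = 0.05,
               min_active_compounds: int = 5, top_n: int = 10) -> pd.DataFrame:
    """Filter and rank herb scores.

    Keeps herbs with overlap p below ``p_threshold`` and at least
    ``min_active_compounds`` disease-linked compounds; sorts by descending
    correlation (ties: ascending p, then id) and truncates at ``top_n``.
    Sets ``passes_filters`` on every input score.
    """
    survivors = []
    for s in scores:
        s.passes_filters = (
            s.overlap.p_value < p_threshold
            and (s.n_active_compounds is None
                 or s.n_active_compounds >= min_active_compounds)
        )
        if s.passes_filters:
            survivors.append(s)
    if not survivors:
        logger.warning("no herb passes p<%g with >=%d active compounds",
                       p_threshold, min_active_compounds)
        return _ranking_frame([])
    survivors.sort(key=lambda s: (-s.correlation, s.overlap.p_value, s.entity_id))
    return _ranking_frame(survivors[:top_n]).reset_index(drop=True)


def rank_compounds(herb: str, net: MultiscaleNetwork, catalog: HerbCatalog,
                   disease_profile: DiffusionProfile, disease: DiseaseGeneSet,
                   params: WalkParams, background: set[str] | None = None,
                   p_threshold: float = 0.05,
                   method: str = "pearson") -> pd.DataFrame:
    """Rank one herb's compounds against the disease profile.

    Each compound with at least one mapped target gets its own diffusion
    profile, correlation and overlap statistic; compounds failing p <
    ``p_threshold`` are excluded, survivors sorted as in :func:`rank_herbs`.
    Compounds with zero mapped targets are skipped with a log entry.
    """
    if background is None:
        background = default_background(net, catalog, disease)
    disease_targets = disease.genes & background
    scores: list[CandidateScore] = []
    for compound in sorted(catalog.compounds(herb)):
        targets = set(catalog.targets_of(compound))
        if not targets:
            logger.info("compound %s has no targets; skipped", compound)
            continue
        try:
            profile = entity_diffusion_profile(net, compound, "compound",
                                               targets, params)
        except UnlinkedEntityError:
            logger.info("compound %s unlinked from network; excluded", compound)
            continue
        corr = correlation_score(profile, disease_profile, method)
        mapped = {t for t in targets if t in background}
        if not mapped:
            logger.info("compound %s: no target in background; excluded", compound)
            continue
        overlap = hypergeometric_overlap(mapped, disease_targets, background)
        score = CandidateScore(compound, corr, overlap)
        score.passes_filters = overlap.p_value < p_threshold
        if score.passes_filters:
            scores.append(score)
    if not scores:
        logger.warning("no compound of %s passes p<%g", herb, p_threshold)
    scores.sort(key=lambda s: (-s.correlation, s.overlap.p_value, s.entity_id))
    frame = _ranking_frame(scores).drop(columns=["n_active_compounds"])
    return frame.reset_index(drop=True)
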