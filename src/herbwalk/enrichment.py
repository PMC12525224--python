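"""Over-representation analysis of gene lists against GMT libraries.

For a query gene list and each library term, a 2x2 contingency table over
the background yields a one-sided hypergeometric p-value, a Haldane-corrected
odds ratio, and an Enrichr-style rank-deviation z-score computed against a
seeded population of random same-size queries. The combined score is the
magnitude of z multiplied by the natural log of p, so it is zero whenever
p = 1. Benjamini–Hochberg adjustment is applied across the library.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigError, EmptyInputError
from .prioritization import hypergeom_tail

logger = logging.getLogger(__name__)

#: KEGG signaling pathways treated as the disease-relevant whitelist for
#: hyperthyroidism-focused runs.
DISEASE_PATHWAY_WHITELIST: tuple[str, ...] = (
    "MAPK signaling pathway",
    "Thyroid hormone signaling pathway",
    "Calcium signaling pathway",
    "HIF-1 signaling pathway",
    "p53 signaling pathway",
    "mTOR signaling pathway",
    "PI3K-Akt signaling pathway",
    "Wnt signaling pathway",
    "Parathyroid hormone synthesis, secretion and action",
)


@dataclass
class EnrichmentResult:
    term: str
    overlap_count: int
    term_size: int
    query_size: int
    background_size: int
    p_value: float
    adjusted_p: float
    odds_ratio: float
    z_score: float
    combined_score: float
    genes: tuple[str, ...]


def _odds_ratio(k: int, q: int, m: int, N: int) -> float:
    """Odds ratio of the 2x2 table, Haldane +0.5 when any cell is zero."""
    a, b, c, d = k, q - k, m - k, N - q - m + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def _term_pvalues(query: frozenset[str], terms: Sequence[tuple[str, frozenset[str]]],
                  N: int) -> np.ndarray:
    q = len(query)
    out = np.empty(len(terms))
    for i, (_, members) in enumerate(terms):
        k = len(query & members)
        out[i] = hypergeom_tail(k, N, len(members), q)
    return out


def enrich(query: Iterable[str], library: Mapping[str, set[str]],
           background: Iterable[str] | None = None,
           n_background_queries: int = 200,
           seed: int = 0) -> list[EnrichmentResult]:
    """Enrichment of ``query`` against every term of ``library``.

    ``background`` defaults to the union of all library genes; the query
    must be a subset of it. Terms with no background member are skipped.
    The z-score is the deviation of each term's rank (by p-value) from its
    expected rank over ``n_background_queries`` random same-size queries
    drawn from the background with the given seed; exact z values therefore
    depend on the seed and background and should be read comparatively.
    """
    query = frozenset(query)
    if not query:
        raise EmptyInputError("empty query gene set")
    if not library:
        raise EmptyInputError("empty gene-set library")
    bg = (frozenset().union(*library.values()) if background is None
          else frozenset(background))
    if not query <= bg:
        missing = sorted(query - bg)[:5]
        raise ConfigError(f"query genes outside the background, e.g. {missing}")
    N = len(bg)
    terms: list[tuple[str, frozenset[str]]] = []
    for name in sorted(library):
        members = frozenset(library[name]) & bg
        if not members:
            logger.info("term %r has no background member; skipped", name)
            continue
        terms.append((name, members))
    if not terms:
        raise EmptyInputError("no term overlaps the background")

    pvals = _term_pvalues(query, terms, N)
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    obs_rank = stats.rankdata(pvals, method="average")

    # rank background: random same-size queries, seeded
    rng = np.random.default_rng(seed)
    bg_sorted = sorted(bg)
    ranks = np.empty((n_background_queries, len(terms)))
    for b in range(n_background_queries):
        rand_query = frozenset(
            rng.choice(bg_sorted, size=len(query), replace=False))
        ranks[b] = stats.rankdata(_term_pvalues(rand_query, terms, N),
                                  method="average")
    mean_rank = ranks.mean(axis=0)
    sd_rank = ranks.std(axis=0, ddof=1) if n_background_queries > 1 else None

    results: list[EnrichmentResult] = []
    for i, (name, members) in enumerate(terms):
        k = len(query & members)
        if sd_rank is None or sd_rank[i] == 0.0:
            z = 0.0
        else:
            # positive z = ranked better (smaller p) than random queries
            z = float((mean_rank[i] - obs_rank[i]) / sd_rank[i])
        p = float(pvals[i])
        combined = abs(z * math.log(p)) if p > 0 else float("inf")
        results.append(EnrichmentResult(
            term=name,
            overlap_count=k,
            term_size=len(members),
            query_size=len(query),
            background_size=N,
            p_value=p,
            adjusted_p=float(adj[i]),
            odds_ratio=_odds_ratio(k, len(query), len(members), N),
            z_score=z,
            combined_score=combined,
            genes=tuple(sorted(query & members)),
        ))
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def filter_disease_pathways(
    results: Iterable[EnrichmentResult],
    whitelist: Iterable[str] = DISEASE_PATHWAY_WHITELIST,
) -> list[EnrichmentResult]:
    """Keep only whitelisted term names (case-insensitive exact match)."""
    allowed = {w.casefold() for w in whitelist}
    return [r for r in results if r.term.casefold() in allowed]


def results_to_frame(results: Sequence[EnrichmentResult]):
    """Tabulate results in the conventional report columns."""
    import pandas as pd

    return pd.DataFrame(
        {
            "Term": [r.term for r in results],
            "Overlap": [f"{r.overlap_count}/{r.term_size}" for r in results],
            "P-value": [r.p_value for r in results],
            "Adjusted P-value": [r.adjusted_p for r in results],
            "Odds Ratio": [r.odds_ratio for r in results],
            "Z-score": [r.z_score for r in results],
            "Combined Score": [r.combined_score for r in results],
            "Genes": [";".join(r.genes) for r in results],
        }
    )
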