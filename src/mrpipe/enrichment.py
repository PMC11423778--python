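"""Metabolite pathway over-representation analysis.

Hypergeometric upper-tail test of pathway membership among a query set of
metabolites against a library-wide background universe: with K pathway
members, a query of n compounds and h hits, p = P(X ≥ h) where X is
hypergeometric(N, K, n). The expected hit count is K·n/N, and
``infer_background`` inverts that relation to recover N from a printed
expectation when a library does not publish its background size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import PathwayLibrary

__all__ = ["EnrichmentResult", "ora_hypergeom", "infer_background", "run_enrichment"]


@dataclass
class EnrichmentResult:
    pathway_name: str
    pathway_size: int      # K ("Total")
    query_size: int        # n
    background_size: int   # N
    hits: int              # h
    expected: float        # K·n/N
    pval: float
    significant: bool


def ora_hypergeom(query_size: int, pathway_size: int, background_size: int, hits: int) -> float:
    """Upper-tail hypergeometric probability P(X ≥ hits).

    Computed via the survival function in log-stable form (scipy's
    hypergeometric distribution); h = 0 gives exactly 1.
    """
    n, K, N, h = query_size, pathway_size, background_size, hits
    if not (0 <= h <= min(K, n)):
        raise ValueError("hits must lie in [0, min(K, n)]")
    if K > N or n > N:
        raise ValueError("pathway and query must fit inside the background")
    if h == 0:
        return 1.0
    return float(stats.hypergeom.sf(h - 1, N, K, n))


def infer_background(pathway_size: int, query_size: int, expected: float) -> int:
    """Back out the background size N from the expected hit count K·n/N."""
    if expected <= 0:
        raise ValueError("expected hit count must be positive")
    if expected >= pathway_size:
        raise ValueError("expected >= pathway size implies background <= query")
    return int(round(pathway_size * query_size / expected))


def run_enrichment(
    query: list,
    library: PathwayLibrary,
    hits_by_pathway: dict,
    alpha: float = 0.10,
) -> pd.DataFrame:
    """Per-pathway over-representation for a query metabolite list.

    ``hits_by_pathway`` maps pathway_name → number of query compounds in the
    pathway (membership resolution is the caller's concern; libraries differ
    in identifier conventions). Results are sorted by ascending p with a
    significance mark at ``alpha``.
    """
    uniq = list(dict.fromkeys(query))
    if len(uniq) < len(query):
        import warnings

        warnings.warn(f"{len(query) - len(uniq)} duplicate query entries removed", stacklevel=2)
    n = len(uniq)
    if n == 0:
        raise ValueError("empty query")
    N = library.background_size
    rows = []
    for rec in library.pathways.itertuples():
        K = int(rec.member_count)
        h = int(hits_by_pathway.get(rec.pathway_name, 0))
        p = ora_hypergeom(n, K, N, h)
        rows.append(EnrichmentResult(rec.pathway_name, K, n, N, h, K * n / N, p, p < alpha))
    df = pd.DataFrame([r.__dict__ for r in rows]).sort_values(
        "pval", kind="mergesort", ignore_index=True
    )
    return df
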