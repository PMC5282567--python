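"""Hypergeometric over-representation analysis of gene sets.

For a query set of n genes drawn from a universe of N, and a term with K
members, the enrichment p-value is the hypergeometric upper tail
P(X >= k) with k the observed overlap, computed in log space. Terms are
adjusted with Benjamini-Hochberg within each namespace and ranked; the
"rich factor" k/K (fraction of a term recovered by the query) accompanies
each result for scatterplot-style summaries.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from . import io
from .expression import bh_adjust

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = ["term", "name", "namespace", "N", "K", "n", "k",
                      "p", "q", "rich_factor"]


@dataclass
class GeneSetCollection:
    """Named gene sets (terms) over a gene universe.

    The namespace of a term (GO division or pathway database) is parsed
    from the term-id prefix before the first ':' ("BP:T0001" -> "BP");
    ids without a prefix fall into the "default" namespace.
    """

    terms: dict[str, tuple[str, frozenset[str]]]  # term -> (name, members)
    universe: frozenset[str]

    @classmethod
    def from_gmt(cls, path: str | Path, universe=None) -> "GeneSetCollection":
        raw = io.read_gmt(path)
        terms = {t: (desc, frozenset(members)) for t, (desc, members) in raw.items()}
        if universe is None:
            universe = frozenset().union(*(m for _, m in terms.values())) if terms else frozenset()
        return cls(terms, frozenset(universe))

    def intersected(self, universe: frozenset[str]) -> "GeneSetCollection":
        """Restrict members to a universe, dropping emptied terms."""
        terms = {}
        for term, (name, members) in self.terms.items():
            kept = members & universe
            if kept:
                terms[term] = (name, kept)
        return GeneSetCollection(terms, universe)


def namespace_of(term: str) -> str:
    return term.split(":", 1)[0] if ":" in term else "default"


def _log_hypergeom_pmf(i: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    def logc(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
    return logc(K, i) + logc(N - K, n - i) - logc(N, n)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), in log space.

    p = sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n).
    """
    for name, val in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(val) != val:
            raise ValueError(f"{name} must be an integer")
    N, K, n, k = int(N), int(K), int(n), int(k)
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K, n <= N")
    if not (0 <= k <= min(K, n)):
        raise ValueError("need 0 <= k <= min(K, n)")
    lo = max(k, n - (N - K))
    if k <= max(0, n - (N - K)):
        return 1.0
    i = np.arange(lo, min(K, n) + 1)
    return float(np.exp(logsumexp(_log_hypergeom_pmf(i, N, K, n))))


def enrich(query: set[str], collection: GeneSetCollection,
           min_term_size: int = 3, q_threshold: float = 0.05) -> pd.DataFrame:
    """Over-representation of a query set against every term.

    Query genes outside the universe are dropped (logged); BH adjustment is
    applied within each namespace; rows are ranked by (q, p, -rich_factor).
    """
    universe = collection.universe
    dropped = len(set(query) - universe)
    if dropped:
        logger.info("enrich: dropped %d query genes outside the universe", dropped)
    query = set(query) & universe
    if not query:
        raise ValueError("query is empty after intersection with the universe")
    inter = collection.intersected(frozenset(universe))
    N, n = len(universe), len(query)
    rows = []
    for term, (name, members) in inter.terms.items():
        K = len(members)
        if K < min_term_size:
            continue
        k = len(members & query)
        p = hypergeom_upper_tail(N, K, n, k)
        rows.append((term, name, namespace_of(term), N, K, n, k, p, k / K))
    if not rows:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    df = pd.DataFrame(rows, columns=["term", "name", "namespace", "N", "K",
                                     "n", "k", "p", "rich_factor"])
    df["q"] = np.nan
    for ns, idx in df.groupby("namespace").groups.items():
        df.loc[idx, "q"] = bh_adjust(df.loc[idx, "p"].to_numpy())
    df["significant"] = df["q"] < q_threshold
    df = df.sort_values(["q", "p", "rich_factor"],
                        ascending=[True, True, False],
                        kind="mergesort").reset_index(drop=True)
    return df[ENRICHMENT_COLUMNS + ["significant"]]
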