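"""Over-representation analysis against user-supplied gene sets.

Replaces an external annotation service with an in-house hypergeometric
test: for a query gene list (e.g. a cluster's upregulated markers) and each
term of a GMT collection, the upper tail P[X >= k] of the hypergeometric
distribution gives the probability of seeing at least the observed overlap
by chance.  P-values are Benjamini-Hochberg adjusted across all tested
terms, results are kept when raw p < 0.01 or adjusted p < 0.05, and each
term's enrichment score is -log10 of its adjusted p-value (sign flipped so
larger means more enriched).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_P_FILTER = 0.01
DEFAULT_ADJ_FILTER = 0.05


@dataclass
class GeneSetCollection:
    """Named gene sets (term -> uppercase symbol set)."""

    sets: dict[str, frozenset[str]]
    source_label: str = ""

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for term, genes in self.sets.items():
            genes = frozenset(g.strip().upper() for g in genes if g.strip())
            if not genes:
                raise ValueError(f"gene set {term!r} is empty")
            clean[term] = genes
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (term <tab> description <tab> genes...)."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not line.strip():
                continue
            term, genes = fields[0], fields[2:]
            sets[term] = frozenset(g.strip().upper() for g in genes if g.strip())
    if not sets:
        raise ValueError(f"no gene sets parsed from {path}")
    return GeneSetCollection(sets, source_label=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in collection.sets:
            genes = "\t".join(sorted(collection.sets[term]))
            fh.write(f"{term}\t-\t{genes}\n")


@dataclass(frozen=True)
class EnrichmentRecord:
    term: str
    k: int  # overlap
    K: int  # term size within the universe
    n: int  # query size within the universe
    N: int  # universe size
    p_value: float
    p_adjusted: float
    enrichment_score: float


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P[X >= k] for X ~ Hypergeometric(N, K, n), in log space.

    Summed as logsumexp over the log pmf, so tiny tail probabilities keep
    full relative precision.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K, n <= N; got K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    support = np.arange(k, min(K, n) + 1)
    if support.size == 0:
        return 1.0
    logp = stats.hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def enrich(
    query: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
    p_filter: float = DEFAULT_P_FILTER,
    adj_filter: float = DEFAULT_ADJ_FILTER,
    filtered: bool = True,
) -> list[EnrichmentRecord]:
    """Over-representation of ``query`` in each term, within ``universe``.

    Query genes outside the universe are dropped with a warning; terms are
    intersected with the universe; terms with zero overlap are not reported.
    With ``filtered=True`` (default) only records with raw p < ``p_filter``
    or BH-adjusted p < ``adj_filter`` are returned, sorted by p.
    """
    universe_set = {g.strip().upper() for g in universe}
    query_set = {g.strip().upper() for g in query}
    dropped = query_set - universe_set
    if dropped:
        logger.warning("%d query genes outside the universe dropped", len(dropped))
    query_set &= universe_set
    if not query_set:
        raise ValueError("query is empty after intersecting with the universe")

    N, n = len(universe_set), len(query_set)
    rows: list[tuple[str, int, int]] = []
    for term, genes in sets.sets.items():
        term_genes = genes & universe_set
        k = len(term_genes & query_set)
        if k >= 1:
            rows.append((term, k, len(term_genes)))
    if not rows:
        return []
    p_values = [hypergeometric_tail(k, K, n, N) for _, k, K in rows]
    adjusted = bh_adjust(p_values)
    records = [
        EnrichmentRecord(
            term=term, k=k, K=K, n=n, N=N,
            p_value=p, p_adjusted=float(q),
            enrichment_score=float(-np.log10(q)),
        )
        for (term, k, K), p, q in zip(rows, p_values, adjusted)
    ]
    if filtered:
        records = [
            r for r in records if r.p_value < p_filter or r.p_adjusted < adj_filter
        ]
    records.sort(key=lambda r: (r.p_value, r.term))
    return records


def enrichment_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    cols = ["term", "k", "K", "n", "N", "p_value", "p_adjusted", "enrichment_score"]
    if not records:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([r.__dict__ for r in records])[cols]
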