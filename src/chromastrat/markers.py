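"""Three-criterion upregulated-marker selection and log2 fold-change matrices.

A gene is called an upregulated marker of a cluster when, comparing that
cluster's cells against the pooled cells of all other (non-noise) clusters:

1. the two-sided Wilcoxon rank-sum p-value is below 1e-6,
2. the gene is expressed (count > 0) in at least 20% of in-cluster cells,
3. its mean abundance is at least 2-fold greater in the cluster.

Tests run on normalized expression; rank tests only see the ordering, and
fold changes are computed on linear-scale normalized means (the median-
library-scaled counts, i.e. expm1 of the log1p values) with a 1e-9
pseudocount.  Only upregulation is called, and no multiple-testing
correction is applied at this stage: the selection criterion is a raw-p
threshold by design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import NOISE, ClusterLabels
from .embedding import NormalizedMatrix

logger = logging.getLogger(__name__)

PSEUDOCOUNT = 1e-9
EXACT_LIMIT = 10**7


@dataclass(frozen=True)
class MarkerCriteria:
    """The triple marker threshold (raw p, expressing fraction, fold)."""

    p_threshold: float = 1e-6
    min_fraction: float = 0.20
    min_fold: float = 2.0

    def __post_init__(self) -> None:
        if self.p_threshold <= 0 or self.min_fold <= 0:
            raise ValueError("thresholds must be positive")
        if not 0.0 < self.min_fraction <= 1.0:
            raise ValueError("min_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class MarkerRecord:
    """One gene x cluster test result."""

    gene: str
    cluster: int
    p_value: float
    fraction_in: float
    mean_in: float
    mean_out: float
    fold: float
    log2fc: float


# ---------------------------------------------------------------------------
# rank-sum test


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def _tie_term(pooled: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _normal_p(t: float, n1: int, n2: int, tie_term: float) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    N = n1 + n2
    mu = n1 * (N + 1) / 2.0
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return 1.0
    d = t - mu
    d = max(abs(d) - 0.5, 0.0)
    z = d / np.sqrt(var)
    return min(1.0, 2.0 * float(stats.norm.sf(z)))


def rank_sum_test(
    x: np.ndarray, y: np.ndarray, mode: str = "exact"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of two samples.

    ``exact`` enumerates the permutation null of the rank sum (mid-ranks
    under ties) via a shift-algorithm DP, refusing when C(n1+n2, n1) exceeds
    10^7; ``normal`` uses the tie-corrected normal approximation with
    continuity correction.  Returns ``(rank sum of x, p)``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    t = float(ranks[:n1].sum())

    if mode == "normal":
        return t, _normal_p(t, n1, n2, _tie_term(pooled))
    if mode != "exact":
        raise ValueError(f"unknown mode {mode!r}")
    if comb(n1 + n2, n1) > EXACT_LIMIT:
        raise ValueError(
            f"exact mode refused: C({n1 + n2}, {n1}) > {EXACT_LIMIT}; use normal"
        )

    ranks2 = np.rint(2 * ranks).astype(int)
    N = n1 + n2
    total_sum = int(ranks2.sum())
    count = np.zeros((n1 + 1, total_sum + 1))
    count[0, 0] = 1.0
    for w in ranks2:
        for k in range(n1 - 1, -1, -1):
            row = count[k]
            nz = np.flatnonzero(row)
            if nz.size:
                count[k + 1, nz + w] += row[nz]
    dist = count[n1]
    total = float(comb(N, n1))
    mu2 = n1 * (N + 1)
    dev = np.abs(np.arange(total_sum + 1) - mu2)
    observed_dev = abs(int(np.rint(2 * t)) - mu2)
    extreme = float(dist[dev >= observed_dev].sum())
    return t, min(1.0, extreme / total)


# ---------------------------------------------------------------------------
# vectorized one-vs-rest testing


def _ranksum_p_matrix(values: np.ndarray, in_mask: np.ndarray) -> np.ndarray:
    """Normal-mode rank-sum p for every gene: in_mask cells vs the rest.

    ``values`` is genes x cells (the pooled universe); returns one p per gene.
    """
    n1 = int(in_mask.sum())
    n2 = values.shape[1] - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    N = n1 + n2
    ranks = stats.rankdata(values, method="average", axis=1)
    t = ranks[:, in_mask].sum(axis=1)
    mu = n1 * (N + 1) / 2.0
    # per-gene tie correction
    srt = np.sort(values, axis=1)
    changes = np.diff(srt, axis=1) != 0
    tie_term = np.empty(values.shape[0])
    for g in range(values.shape[0]):
        # run lengths of equal values in the sorted row
        idx = np.flatnonzero(changes[g])
        bounds = np.concatenate([[0], idx + 1, [N]])
        runs = np.diff(bounds).astype(float)
        tie_term[g] = float(np.sum(runs**3 - runs))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    d = np.maximum(np.abs(t - mu) - 0.5, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, d / np.sqrt(var), 0.0)
    p = np.minimum(1.0, 2.0 * stats.norm.sf(z))
    p[var <= 0] = 1.0
    return p


def _cluster_gene_stats(
    linear: np.ndarray, nonzero: np.ndarray, in_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    mean_in = linear[:, in_mask].mean(axis=1)
    mean_out = linear[:, ~in_mask].mean(axis=1)
    frac_in = nonzero[:, in_mask].mean(axis=1)
    fold = (mean_in + PSEUDOCOUNT) / (mean_out + PSEUDOCOUNT)
    return mean_in, mean_out, frac_in, fold, np.log2(fold)


def select_markers(
    normalized: NormalizedMatrix,
    labels: ClusterLabels,
    criteria: MarkerCriteria | None = None,
) -> list[MarkerRecord]:
    """One-vs-rest upregulated marker selection under the triple criterion.

    Each cluster is tested against the pooled cells of all other non-noise
    clusters.  Noise cells never enter any test.  Clusters with fewer than
    3 cells are skipped with a warning.
    """
    criteria = criteria or MarkerCriteria()
    cluster_ids = labels.cluster_ids()
    if len(cluster_ids) < 2:
        raise ValueError("marker selection needs at least 2 non-noise clusters")
    keep = labels.labels != NOISE
    values = normalized.values[:, keep]
    lab = labels.labels[keep]
    linear = np.expm1(values)
    nonzero = values > 0

    records: list[MarkerRecord] = []
    for cid in cluster_ids:
        in_mask = lab == cid
        n_in = int(in_mask.sum())
        if n_in < 3:
            logger.warning("cluster %d has %d cells; skipped", cid, n_in)
            continue
        p = _ranksum_p_matrix(values, in_mask)
        mean_in, mean_out, frac_in, fold, log2fc = _cluster_gene_stats(
            linear, nonzero, in_mask
        )
        selected = (
            (p < criteria.p_threshold)
            & (frac_in >= criteria.min_fraction)
            & (fold >= criteria.min_fold)
        )
        for g in np.flatnonzero(selected):
            records.append(
                MarkerRecord(
                    gene=normalized.gene_symbols[g],
                    cluster=int(cid),
                    p_value=float(p[g]),
                    fraction_in=float(frac_in[g]),
                    mean_in=float(mean_in[g]),
                    mean_out=float(mean_out[g]),
                    fold=float(fold[g]),
                    log2fc=float(log2fc[g]),
                )
            )
    records.sort(key=lambda r: (r.cluster, r.p_value, r.gene))
    return records


def markers_to_frame(records: list[MarkerRecord]) -> pd.DataFrame:
    cols = ["gene", "cluster", "p_value", "fraction_in", "mean_in", "mean_out", "fold", "log2fc"]
    if not records:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([r.__dict__ for r in records])[cols]


def log2fc_matrix(
    normalized: NormalizedMatrix,
    labels: ClusterLabels,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Genes x clusters log2 fold-change matrix (one-vs-rest, shared
    pseudocount and linear-scale means with :func:`select_markers`)."""
    cluster_ids = labels.cluster_ids()
    if not cluster_ids:
        raise ValueError("no non-noise clusters")
    gene_pos = {g: i for i, g in enumerate(normalized.gene_symbols)}
    if genes is None:
        genes = list(normalized.gene_symbols)
    missing = [g for g in genes if g not in gene_pos]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing[:5]}")
    rows = [gene_pos[g] for g in genes]
    keep = labels.labels != NOISE
    linear = np.expm1(normalized.values[np.ix_(rows, np.flatnonzero(keep))])
    lab = labels.labels[keep]
    out = np.zeros((len(genes), len(cluster_ids)))
    for j, cid in enumerate(cluster_ids):
        in_mask = lab == cid
        mean_in = linear[:, in_mask].mean(axis=1)
        mean_out = linear[:, ~in_mask].mean(axis=1)
        out[:, j] = np.log2((mean_in + PSEUDOCOUNT) / (mean_out + PSEUDOCOUNT))
    return pd.DataFrame(out, index=genes, columns=cluster_ids)
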