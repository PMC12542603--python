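"""Per-condition cluster composition and synthetic-truth recovery metrics.

Composition is the pipeline's stratification readout: for each cell type
and subcluster, the percentage of each condition's cells (of that type)
assigned to the subcluster.  Percentages are pooled across donors and
exclude DBSCAN noise cells from the denominators; noise counts are reported
separately.  The disease-enriched subcluster of a type is identified
operationally as the one maximizing (disease% - healthy%).

Recovery metrics score a synthetic run against its planted truth: adjusted
Rand index of the subclustering, exact binomial confidence intervals for
the recovered subpopulation prevalence, and sensitivity/precision of marker
selection on the planted positive-effect genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .clustering import NOISE, ClusterLabels
from .io_formats import CellAnnotation
from .markers import MarkerRecord
from .synthetic_cohort import SyntheticTruth

logger = logging.getLogger(__name__)


@dataclass
class CompositionTable:
    """Counts and percentages per (cell type, subcluster, condition)."""

    table: pd.DataFrame  # cell_type, subcluster, condition, n_cells, percent
    noise: pd.DataFrame  # cell_type, condition, n_noise

    def percent(self, cell_type: str, subcluster: int, condition: str) -> float:
        t = self.table
        row = t[
            (t["cell_type"] == cell_type)
            & (t["subcluster"] == subcluster)
            & (t["condition"] == condition)
        ]
        return float(row["percent"].iloc[0]) if len(row) else 0.0


def composition(
    labels_by_type: dict[str, ClusterLabels], annotation: CellAnnotation
) -> CompositionTable:
    """Per-condition subcluster composition, pooled across donors.

    For each (cell type, condition), a subcluster's percentage is its cell
    count over that condition's non-noise cells of the type, times 100.
    Conditions with zero cells of a type are omitted with a warning.
    """
    ann = annotation.table.set_index("cell_id")
    rows, noise_rows = [], []
    for ctype, labels in labels_by_type.items():
        cond = ann.loc[labels.cell_ids, "condition"].to_numpy()
        if pd.isna(cond).any():
            raise ValueError(f"cells of type {ctype} lack a condition")
        for c in sorted(set(ann["condition"])):
            mask = cond == c
            if not mask.any():
                logger.warning("no %s cells in condition %s; block omitted", ctype, c)
                continue
            lab = labels.labels[mask]
            n_noise = int(np.sum(lab == NOISE))
            noise_rows.append({"cell_type": ctype, "condition": c, "n_noise": n_noise})
            denom = int(np.sum(lab != NOISE))
            for cid in labels.cluster_ids():
                n = int(np.sum(lab == cid))
                rows.append(
                    {
                        "cell_type": ctype,
                        "subcluster": cid,
                        "condition": c,
                        "n_cells": n,
                        "percent": 100.0 * n / denom if denom else float("nan"),
                    }
                )
    return CompositionTable(
        table=pd.DataFrame(rows, columns=["cell_type", "subcluster", "condition", "n_cells", "percent"]),
        noise=pd.DataFrame(noise_rows, columns=["cell_type", "condition", "n_noise"]),
    )


def disease_enriched_subcluster(
    comp: CompositionTable, cell_type: str,
    disease: str = "disease", healthy: str = "healthy",
) -> int:
    """The subcluster of ``cell_type`` maximizing disease% - healthy%."""
    t = comp.table[comp.table["cell_type"] == cell_type]
    if t.empty:
        raise ValueError(f"no composition rows for cell type {cell_type}")
    pivot = t.pivot_table(index="subcluster", columns="condition", values="percent", fill_value=0.0)
    for c in (disease, healthy):
        if c not in pivot.columns:
            pivot[c] = 0.0
    delta = pivot[disease] - pivot[healthy]
    return int(delta.idxmax())


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected Rand agreement; pairs where either label is -1 (noise)
    are excluded before computing the index."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("labelings differ in length")
    keep = (a != NOISE) & (b != NOISE)
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise ValueError("fewer than 2 non-noise items")
    return float(adjusted_rand_score(a, b))


def binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval."""
    if n == 0:
        return (0.0, 1.0)
    res = stats.binomtest(k, n).proportion_ci(confidence_level=level, method="exact")
    return float(res.low), float(res.high)


@dataclass
class RecoveryReport:
    """Truth-based scoring of one synthetic subclustering run."""

    ari: float
    prevalence: dict[str, tuple[float, float, float]]  # condition -> (est, lo, hi)
    marker_sensitivity: float | None
    marker_precision: float | None


def marker_recovery(
    selected: list[MarkerRecord],
    truth: SyntheticTruth,
    cluster: int,
) -> tuple[float | None, float | None]:
    """Sensitivity and precision of marker selection for one subcluster.

    Planted positives are the truth's positive-effect genes (the selection
    calls upregulation only).  Sensitivity is None when nothing was planted;
    precision is None when nothing was selected.
    """
    planted = set(truth.affected_up)
    chosen = {r.gene for r in selected if r.cluster == cluster}
    hit = len(chosen & planted)
    sensitivity = hit / len(planted) if planted else None
    precision = hit / len(chosen) if chosen else None
    return sensitivity, precision


def recovery_report(
    labels: ClusterLabels,
    truth: SyntheticTruth,
    selected: list[MarkerRecord] | None = None,
    cell_type: str = "cardiomyocyte",
) -> RecoveryReport:
    """Score a stage-2 subclustering of one cell type against planted truth."""
    t = truth.cells.set_index("cell_id").loc[labels.cell_ids]
    if not (t["cell_type"] == cell_type).all():
        raise ValueError("labels cover cells outside the requested cell type")
    truth_labels = t["subpop_flag"].astype(int).to_numpy()
    ari = adjusted_rand_index(labels.labels, truth_labels)

    # which subcluster carries the planted subpopulation: majority vote
    prevalence: dict[str, tuple[float, float, float]] = {}
    sub_ids = labels.cluster_ids()
    if sub_ids:
        overlap = {cid: int(np.sum((labels.labels == cid) & (truth_labels == 1))) for cid in sub_ids}
        planted_cluster = max(sorted(overlap), key=lambda c: overlap[c])
        cond = t["condition"].to_numpy()
        for c in sorted(set(cond)):
            mask = (cond == c) & (labels.labels != NOISE)
            n = int(mask.sum())
            k = int(np.sum(labels.labels[mask] == planted_cluster))
            lo, hi = binomial_ci(k, n)
            prevalence[c] = (k / n if n else float("nan"), lo, hi)
    sens = prec = None
    if selected is not None and sub_ids:
        sens, prec = marker_recovery(selected, truth, planted_cluster)
    return RecoveryReport(ari=ari, prevalence=prevalence,
                          marker_sensitivity=sens, marker_precision=prec)
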