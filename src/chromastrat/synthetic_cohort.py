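"""Synthetic two-condition cardiac snRNA-seq cohort generator.

Emulates the study design the pipeline targets: a healthy vs dilated
cardiomyopathy (DCM) cohort of several cardiac cell types, where one
cardiomyocyte subpopulation is present at low prevalence in healthy hearts
(3% of cardiomyocytes by default) and strongly enriched in disease (18%),
and where that subpopulation's transcriptional signature is confined to
genes of the chromatin-structure panel.  Every downstream stage (embedding,
subclustering, marker selection, composition) is testable against the
planted truth without any download.

Generative model
----------------
Counts are drawn gene-independently from a negative binomial with mean
``s_c * mu_g * 2**(sum of log2 effects active in cell c)`` and dispersion
``phi_g`` (variance ``m + m**2/phi``).  ``s_c`` is a log-normal library-size
factor.  Cell types and subpopulation membership are drawn per condition
from the configured proportions.  Lineage-marker elevation and subpopulation
effects compose additively in log2 space.  No dropout layer is added:
sparsity arises from small means, which is the overdispersion structure the
downstream rank tests assume.  Batch effects, ambient RNA and doublets are
deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import CONDITIONS, CellAnnotation, ExpressionMatrix

#: Lineage markers used for cell typing, as listed for the human heart atlas.
DEFAULT_MARKER_MAP: dict[str, tuple[str, ...]] = {
    "cardiomyocyte": ("ACTC1", "MYH7", "TNNT2", "RYR2"),
    "endothelial": ("PECAM1",),
    "smooth_muscle": ("GJC1", "ACTA2"),
    "macrophage": ("CD163",),
    "lymphocyte": ("CD3E", "CD3G", "CD8A"),
    "fibroblast": ("COL1A1", "FN1"),
}

DEFAULT_CELL_TYPE_PROPORTIONS: dict[str, float] = {
    "cardiomyocyte": 0.50,
    "fibroblast": 0.20,
    "endothelial": 0.12,
    "macrophage": 0.08,
    "smooth_muscle": 0.06,
    "lymphocyte": 0.04,
}

#: Fixed stream for the gene universe (baseline means, affected-gene choice),
#: kept separate from the cohort sampling seed so the default gene universe
#: is one fixed object no matter which cohort seed is drawn.
_UNIVERSE_SEED = 20240601


@dataclass(frozen=True)
class SubpopSpec:
    """A planted subpopulation within one parent cell type."""

    parent_cell_type: str = "cardiomyocyte"
    prevalence: dict[str, float] = field(
        default_factory=lambda: {"healthy": 0.03, "disease": 0.18}
    )
    affected_genes: tuple[str, ...] = ()
    log2_effects: tuple[float, ...] = ()

    def validate(self) -> None:
        for cond, p in self.prevalence.items():
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence {p} outside [0, 1]")
        if len(self.affected_genes) != len(self.log2_effects):
            raise ValueError("affected_genes and log2_effects lengths differ")


@dataclass
class CohortConfig:
    """Full parameterization of the synthetic cohort."""

    gene_symbols: tuple[str, ...]
    baseline_mean: np.ndarray
    dispersion: np.ndarray
    n_cells: dict[str, int]
    cell_type_proportions: dict[str, dict[str, float]]
    marker_map: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_MAP)
    )
    marker_fold: float = 8.0
    subpop: SubpopSpec = field(default_factory=SubpopSpec)
    library_meanlog: float = 0.0
    library_sdlog: float = 0.3
    n_donors: dict[str, int] = field(
        default_factory=lambda: {"healthy": 25, "disease": 13}
    )
    seed: int = 0

    def validate(self) -> None:
        n_genes = len(self.gene_symbols)
        if len(set(self.gene_symbols)) != n_genes:
            raise ValueError("duplicate gene symbols in universe")
        for arr, name in ((self.baseline_mean, "baseline_mean"), (self.dispersion, "dispersion")):
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (n_genes,):
                raise ValueError(f"{name} must have one value per gene")
            if not np.all(arr > 0):
                raise ValueError(f"{name} must be strictly positive")
        for cond in CONDITIONS:
            if self.n_cells.get(cond, 0) < 0:
                raise ValueError("n_cells must be non-negative")
            props = self.cell_type_proportions[cond]
            total = float(sum(props.values()))
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{cond} cell-type proportions sum to {total}, not 1")
            if any(p < 0 for p in props.values()):
                raise ValueError("cell-type proportions must be non-negative")
        if sum(self.n_cells.get(c, 0) for c in CONDITIONS) == 0:
            raise ValueError("cohort has zero cells")
        self.subpop.validate()
        index = {g: i for i, g in enumerate(self.gene_symbols)}
        for g in self.subpop.affected_genes:
            if g not in index:
                raise ValueError(f"affected gene {g} not in universe")
        if self.library_sdlog < 0:
            raise ValueError("library_sdlog must be >= 0")

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_symbols)}


@dataclass
class SyntheticTruth:
    """Planted labels and effects for recovery scoring."""

    cells: pd.DataFrame  # cell_id, condition, cell_type, subpop_flag
    genes: pd.DataFrame  # gene, affected, true_log2fc

    @property
    def affected_up(self) -> list[str]:
        g = self.genes
        return list(g.loc[(g["affected"]) & (g["true_log2fc"] > 0), "gene"])

    @property
    def affected_down(self) -> list[str]:
        g = self.genes
        return list(g.loc[(g["affected"]) & (g["true_log2fc"] < 0), "gene"])


def default_config(
    panel_symbols: tuple[str, ...] | None = None,
    n_cells_per_condition: int = 10_000,
    seed: int = 0,
) -> CohortConfig:
    """The documented default cohort.

    Gene universe of 1,000 symbols: the full chromatin panel (892 genes by
    default, from the packaged fixture), the 13 lineage markers, and filler
    genes (``BG####``) to reach 1,000.  Baseline means are log-normal
    (median 0.3, sigma 1) clipped to [0.02, 8]; lineage markers sit at a
    baseline of 2.0 and are elevated 8-fold in their own type.  The planted
    cardiomyocyte subpopulation (3% of healthy, 18% of diseased
    cardiomyocytes) perturbs 40 panel genes with |log2FC| = 1.5, 20 up and
    20 down, drawn among panel genes with baseline mean >= 0.8 so the
    signature is carried by detectably expressed genes.  Dispersion is 2 for
    every gene; library sizes are log-normal(0, 0.3).  10,000 cells per
    condition with a 50% cardiomyocyte share give ~5,000 cardiomyocyte
    nuclei per condition.
    """
    if panel_symbols is None:
        from .gene_panel import packaged_panel

        panel_symbols = packaged_panel().symbols
    markers = [m for ms in DEFAULT_MARKER_MAP.values() for m in ms]
    universe = list(panel_symbols) + [m for m in markers if m not in panel_symbols]
    n_fill = max(0, 1000 - len(universe))
    universe += [f"BG{i:04d}" for i in range(1, n_fill + 1)]

    rng = np.random.default_rng(_UNIVERSE_SEED)
    mu = np.clip(rng.lognormal(mean=np.log(0.3), sigma=1.0, size=len(universe)), 0.02, 8.0)
    gene_pos = {g: i for i, g in enumerate(universe)}
    for m in markers:
        mu[gene_pos[m]] = 2.0
    phi = np.full(len(universe), 2.0)

    panel_set = set(panel_symbols)
    eligible = [g for g in universe if g in panel_set and mu[gene_pos[g]] >= 0.8]
    affected = tuple(sorted(rng.choice(eligible, size=40, replace=False)))
    effects = tuple(1.5 if i < 20 else -1.5 for i in range(40))

    cfg = CohortConfig(
        gene_symbols=tuple(universe),
        baseline_mean=mu,
        dispersion=phi,
        n_cells={c: n_cells_per_condition for c in CONDITIONS},
        cell_type_proportions={c: dict(DEFAULT_CELL_TYPE_PROPORTIONS) for c in CONDITIONS},
        subpop=SubpopSpec(affected_genes=affected, log2_effects=effects),
        seed=seed,
    )
    cfg.validate()
    return cfg


def _sample_group_counts(
    rng: np.random.Generator,
    mean_per_gene: np.ndarray,
    dispersion: np.ndarray,
    lib_factors: np.ndarray,
) -> np.ndarray:
    """NB counts for one homogeneous cell group: genes x cells."""
    m = mean_per_gene[:, None] * lib_factors[None, :]
    phi = dispersion[:, None]
    p = phi / (phi + m)
    return rng.negative_binomial(phi, p)


def generate_cohort(
    config: CohortConfig, seed: int | None = None
) -> tuple[ExpressionMatrix, CellAnnotation, SyntheticTruth]:
    """Sample a cohort; fully reproducible from the seed.

    Returns the counts matrix (genes x cells), the per-cell annotation
    (donor, condition, sex, cell type) and the planted truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    gene_pos = config.gene_index()
    n_genes = len(config.gene_symbols)
    mu = np.asarray(config.baseline_mean, dtype=float)
    phi = np.asarray(config.dispersion, dtype=float)

    cell_rows: list[dict] = []
    for cond in CONDITIONS:
        n = config.n_cells.get(cond, 0)
        props = config.cell_type_proportions[cond]
        types = list(props)
        drawn = rng.choice(len(types), size=n, p=[props[t] for t in types])
        prevalence = config.subpop.prevalence.get(cond, 0.0)
        donors = rng.integers(0, max(1, config.n_donors.get(cond, 1)), size=n)
        for i in range(n):
            ctype = types[drawn[i]]
            is_sub = bool(
                ctype == config.subpop.parent_cell_type and rng.random() < prevalence
            )
            cell_rows.append(
                {
                    "cell_id": f"{cond[0].upper()}{i:05d}",
                    "condition": cond,
                    "donor_id": f"{cond[0].upper()}D{donors[i]:02d}",
                    "cell_type": ctype,
                    "subpop_flag": is_sub,
                }
            )
    cells = pd.DataFrame(cell_rows)
    n_total = len(cells)
    lib = rng.lognormal(config.library_meanlog, config.library_sdlog, size=n_total)

    log2_marker = np.log2(config.marker_fold)
    effect_by_group: dict[tuple[str, bool], np.ndarray] = {}
    for ctype in {r["cell_type"] for r in cell_rows}:
        base = np.zeros(n_genes)
        for m in config.marker_map.get(ctype, ()):  # absent markers are allowed
            if m in gene_pos:
                base[gene_pos[m]] += log2_marker
        effect_by_group[(ctype, False)] = base
        sub = base.copy()
        if ctype == config.subpop.parent_cell_type:
            for g, e in zip(config.subpop.affected_genes, config.subpop.log2_effects):
                sub[gene_pos[g]] += e
        effect_by_group[(ctype, True)] = sub

    counts = np.zeros((n_genes, n_total), dtype=np.int64)
    group_keys = cells[["cell_type", "subpop_flag"]].apply(tuple, axis=1)
    for key in sorted(set(group_keys)):
        idx = np.flatnonzero((group_keys == key).to_numpy())
        mean_g = mu * np.exp2(effect_by_group[key])
        counts[:, idx] = _sample_group_counts(rng, mean_g, phi, lib[idx])

    matrix = ExpressionMatrix(
        sp.csr_matrix(counts), list(config.gene_symbols), list(cells["cell_id"])
    )
    annotation = CellAnnotation(
        cells[["cell_id", "donor_id", "condition", "cell_type"]].copy()
    )
    affected_set = set(config.subpop.affected_genes)
    effect_map = dict(zip(config.subpop.affected_genes, config.subpop.log2_effects))
    genes = pd.DataFrame(
        {
            "gene": list(config.gene_symbols),
            "affected": [g in affected_set for g in config.gene_symbols],
            "true_log2fc": [effect_map.get(g, 0.0) for g in config.gene_symbols],
        }
    )
    truth = SyntheticTruth(
        cells=cells[["cell_id", "condition", "cell_type", "subpop_flag"]].copy(),
        genes=genes,
    )
    return matrix, annotation, truth
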