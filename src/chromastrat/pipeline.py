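"""End-to-end orchestration: simulate, two-stage cluster, mark, enrich, score.

``run_all`` executes the whole stratification pipeline on one cohort:

1. load counts, annotation and the chromatin panel; drop sex-biased genes;
2. stage 1 - filter, normalize, autoencode (10 dims), UMAP, DBSCAN on the
   full gene space, then assign cell types from lineage markers;
3. stage 2 - per cell type, restrict genes to the chromatin panel and re-run
   the embed/project/cluster chain, yielding within-type subclusters;
4. three-criterion marker selection per subcluster, on the full gene set;
5. optional over-representation analysis of each subcluster's markers;
6. per-condition composition, and truth-based recovery when planted truth
   is available.

Every run writes a JSON manifest holding all parameters, seeds and library
versions; rerunning from the manifest reproduces all outputs byte for byte.
One global seed deterministically derives per-stage seeds by stage-name
hashing, so adding a stage never perturbs earlier stages' randomness.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import (
    NOISE,
    StageParams,
    assign_cell_types,
    derive_seed,
    embed_project_cluster,
    subcluster_by_type,
    subcluster_name,
)
from .embedding import filter_rare_genes, normalize
from .enrichment import enrich, enrichment_to_frame, read_gmt
from .evaluation import composition, disease_enriched_subcluster, recovery_report
from .gene_panel import (
    DEFAULT_SEX_EXCLUSION,
    ExclusionList,
    exclude_genes,
    load_panel,
    packaged_panel,
)
from .io_formats import (
    CellAnnotation,
    read_annotation,
    read_dense_tsv,
    read_matrix_market,
    write_annotation,
    write_matrix_market,
    write_table,
)
from .markers import MarkerCriteria, markers_to_frame, select_markers
from .synthetic_cohort import (
    DEFAULT_MARKER_MAP,
    SyntheticTruth,
    default_config,
    generate_cohort,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serializable to YAML/JSON."""

    matrix_path: str
    annotation_path: str
    outdir: str
    panel_path: str | None = None  # None -> packaged synthetic panel
    gmt_path: str | None = None
    truth_cells_path: str | None = None
    truth_genes_path: str | None = None
    stage1: StageParams = field(default_factory=StageParams)
    stage2: StageParams = field(default_factory=StageParams)
    criteria: MarkerCriteria = field(default_factory=MarkerCriteria)
    enrichment_p_filter: float = 0.01
    enrichment_adj_filter: float = 0.05
    exclusion: tuple[str, ...] = DEFAULT_SEX_EXCLUSION
    use_annotation_cell_types: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("matrix_path", "annotation_path", "panel_path", "gmt_path",
                     "truth_cells_path", "truth_genes_path"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name}: {value} does not exist")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exclusion"] = list(self.exclusion)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (("stage1", StageParams), ("stage2", StageParams),
                         ("criteria", MarkerCriteria)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        if "exclusion" in d:
            d["exclusion"] = tuple(d["exclusion"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _load_matrix(path: str):
    p = Path(path)
    if p.is_dir() or p.suffix in (".mtx",) or str(p).endswith(".mtx.gz"):
        return read_matrix_market(p)
    return read_dense_tsv(p)


def _manifest(config: RunConfig) -> dict:
    import sklearn
    import umap as umap_pkg

    return {
        "chromastrat_version": __version__,
        "config": config.to_dict(),
        "derived_seeds": {
            "stage1": derive_seed(config.seed, "stage1"),
            "stage2": derive_seed(config.seed, "stage2"),
        },
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "sklearn": sklearn.__version__,
            "umap": umap_pkg.__version__,
        },
    }


def simulate(outdir: str | Path, n_cells_per_condition: int = 10_000,
             seed: int = 0) -> Path:
    """Generate the default synthetic cohort and write it as pipeline inputs.

    Emits a Matrix-Market triplet directory, the annotation TSV, and the
    planted-truth tables.  Reruns with the same seed are byte-identical.
    """
    if n_cells_per_condition <= 0:
        raise ValueError("n_cells_per_condition must be positive")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = default_config(n_cells_per_condition=n_cells_per_condition, seed=seed)
    matrix, annotation, truth = generate_cohort(cfg)
    write_matrix_market(matrix, outdir / "matrix")
    write_annotation(annotation, outdir / "annotation.tsv")
    truth.cells.to_csv(outdir / "truth_cells.tsv", sep="\t", index=False)
    truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    logger.info("simulated cohort: %d genes x %d cells -> %s",
                matrix.n_genes, matrix.n_cells, outdir)
    return outdir


def run_all(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory.

    Any stage failure aborts with the stage name; a ``FAILED_STAGE`` marker
    file flags partial results.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _manifest(config)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    stage = "load"
    try:
        t0 = time.time()
        matrix = _load_matrix(config.matrix_path)
        annotation = read_annotation(config.annotation_path).aligned_to(matrix.cell_ids)
        panel = load_panel(config.panel_path) if config.panel_path else packaged_panel()
        matrix = exclude_genes(matrix, ExclusionList.from_symbols(config.exclusion))
        logger.info("[load] %.1fs: %d genes x %d cells", time.time() - t0,
                    matrix.n_genes, matrix.n_cells)

        stage = "stage1"
        t0 = time.time()
        if config.use_annotation_cell_types:
            if "cell_type" not in annotation.table.columns:
                raise ValueError("use_annotation_cell_types set but annotation has no cell_type")
            cell_types = annotation.column("cell_type")
        else:
            params1 = StageParams(**{**config.stage1.__dict__,
                                     "seed": derive_seed(config.seed, "stage1")})
            labels1, emb1, proj1, norm1 = embed_project_cluster(matrix, params1)
            assignment = assign_cell_types(norm1, labels1, DEFAULT_MARKER_MAP)
            cell_types = assignment.cell_types(labels1)
            ann2 = annotation.table.copy()
            ann2["cell_type"] = cell_types
            annotation = CellAnnotation(ann2)
            write_table(
                pd.DataFrame({"cell_id": labels1.cell_ids,
                              "cluster": labels1.labels,
                              "cell_type": cell_types}),
                outdir / "stage1_labels.tsv",
            )
        logger.info("[stage1] %.1fs: %d typed cells", time.time() - t0, len(cell_types))

        stage = "stage2"
        t0 = time.time()
        params2 = StageParams(**{**config.stage2.__dict__,
                                 "seed": derive_seed(config.seed, "stage2")})
        results = subcluster_by_type(matrix, annotation, panel, params2)
        sub_rows = []
        for ctype, res in results.items():
            for cid, l in zip(res.labels.cell_ids, res.labels.labels):
                sub_rows.append({"cell_id": cid, "cell_type": ctype,
                                 "subcluster": int(l),
                                 "subcluster_name": subcluster_name(ctype, int(l))})
        write_table(pd.DataFrame(sub_rows).sort_values(["cell_type", "cell_id"]),
                    outdir / "subclusters.tsv")
        logger.info("[stage2] %.1fs: %d cell types subclustered", time.time() - t0, len(results))

        stage = "markers"
        t0 = time.time()
        all_markers = []
        norm_by_type = {}
        type_of = annotation.column("cell_type")
        for ctype, res in results.items():
            idx = np.flatnonzero(type_of == ctype)
            sub_matrix = matrix.subset_cells(idx)
            norm = normalize(sub_matrix)  # full gene set: the rare-gene filter is temporary
            norm_by_type[ctype] = norm
            if res.labels.n_clusters < 2:
                logger.warning("%s: only %d subcluster(s); markers skipped",
                               ctype, res.labels.n_clusters)
                continue
            for rec in select_markers(norm, res.labels, config.criteria):
                row = rec.__dict__.copy()
                row["cell_type"] = ctype
                row["cluster_name"] = subcluster_name(ctype, rec.cluster)
                all_markers.append(row)
        marker_df = pd.DataFrame(
            all_markers,
            columns=["cell_type", "cluster", "cluster_name", "gene", "p_value",
                     "fraction_in", "mean_in", "mean_out", "fold", "log2fc"],
        )
        write_table(marker_df, outdir / "markers.tsv")
        logger.info("[markers] %.1fs: %d marker records", time.time() - t0, len(marker_df))

        stage = "enrichment"
        if config.gmt_path:
            t0 = time.time()
            collection = read_gmt(config.gmt_path)
            universe = filter_rare_genes(matrix, config.stage1.min_gene_fraction).matrix.gene_symbols
            enr_rows = []
            for (ctype, cluster), grp in marker_df.groupby(["cell_type", "cluster"]):
                try:
                    recs = enrich(list(grp["gene"]), collection, universe,
                                  p_filter=config.enrichment_p_filter,
                                  adj_filter=config.enrichment_adj_filter)
                except ValueError:
                    continue
                f = enrichment_to_frame(recs)
                f.insert(0, "cluster_name", subcluster_name(ctype, int(cluster)))
                f.insert(0, "cell_type", ctype)
                enr_rows.append(f)
            enr_df = (pd.concat(enr_rows, ignore_index=True) if enr_rows
                      else pd.DataFrame(columns=["cell_type", "cluster_name"]))
            write_table(enr_df, outdir / "enrichment.tsv")
            logger.info("[enrichment] %.1fs: %d records", time.time() - t0, len(enr_df))

        stage = "composition"
        t0 = time.time()
        labels_by_type = {c: r.labels for c, r in results.items()}
        comp = composition(labels_by_type, annotation)
        write_table(comp.table, outdir / "composition.tsv", kind="composition")
        write_table(comp.noise, outdir / "noise.tsv")
        logger.info("[composition] %.1fs", time.time() - t0)

        stage = "recovery"
        if config.truth_cells_path and config.truth_genes_path:
            truth = SyntheticTruth(
                cells=pd.read_csv(config.truth_cells_path, sep="\t"),
                genes=pd.read_csv(config.truth_genes_path, sep="\t"),
            )
            parent = "cardiomyocyte"
            summary = {}
            if parent in results:
                sel = select_markers(norm_by_type[parent], results[parent].labels,
                                     config.criteria) if results[parent].labels.n_clusters >= 2 else []
                rep = recovery_report(results[parent].labels, truth, sel, cell_type=parent)
                enriched = disease_enriched_subcluster(comp, parent)
                summary = {
                    "cardiomyocyte_ari": rep.ari,
                    "disease_enriched_subcluster": enriched,
                    "disease_percent": comp.percent(parent, enriched, "disease"),
                    "healthy_percent": comp.percent(parent, enriched, "healthy"),
                    "marker_sensitivity": rep.marker_sensitivity,
                    "marker_precision": rep.marker_precision,
                    "prevalence": {c: list(v) for c, v in rep.prevalence.items()},
                }
            (outdir / "recovery.json").write_text(
                json.dumps(summary, indent=2, sort_keys=True) + "\n")
    except Exception:
        (outdir / "FAILED_STAGE").write_text(stage + "\n")
        logger.error("pipeline failed at stage %r", stage)
        raise
    return outdir


def run_from_manifest(manifest_path: str | Path, outdir: str | Path | None = None) -> Path:
    """Re-execute a run from its manifest (bit-for-bit reproduction)."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    config = RunConfig.from_dict(manifest["config"])
    if outdir is not None:
        config.outdir = str(outdir)
    return run_all(config)
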