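import numpy as np
import pytest
import scipy.sparse as sp

from chromastrat.io_formats import ExpressionMatrix
from chromastrat.synthetic_cohort import default_config, generate_cohort


def make_matrix(counts, genes=None, cells=None) -> ExpressionMatrix:
    counts = np.asarray(counts)
    genes = genes or [f"G{i}" for i in range(counts.shape[0])]
    cells = cells or [f"c{i}" for i in range(counts.shape[1])]
    return ExpressionMatrix(sp.csr_matrix(counts), list(genes), list(cells))


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    return make_matrix(
        [[0, 3, 1], [2, 0, 0], [5, 1, 4], [0, 0, 0]],
        genes=["ALPHA", "XIST", "GAMMA", "DELTA"],
        cells=["c1", "c2", "c3"],
    )


@pytest.fixture(scope="session")
def separable_cohort():
    """Cohort whose cell types carry a broader expression program (8 extra
    elevated genes each, on top of the lineage markers), so that stage-1
    clustering can separate even the single-marker rare types — the regime
    real lineages live in, where hundreds of genes differ."""
    cfg = default_config(n_cells_per_condition=600, seed=11)
    gene_pos = cfg.gene_index()
    fillers = [g for g in cfg.gene_symbols if g.startswith("BG")]
    marker_map = dict(cfg.marker_map)
    for i, ctype in enumerate(sorted(marker_map)):
        extra = tuple(fillers[8 * i: 8 * (i + 1)])
        marker_map[ctype] = marker_map[ctype] + extra
        for g in extra:
            cfg.baseline_mean[gene_pos[g]] = 2.0
    cfg.marker_map = marker_map
    cfg.validate()
    matrix, annotation, truth = generate_cohort(cfg)
    return cfg, matrix, annotation, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A scaled-down default cohort (600 cells/condition) shared by the
    slower unit tests; the full-size cohort lives in the acceptance suite."""
    cfg = default_config(n_cells_per_condition=600, seed=7)
    matrix, annotation, truth = generate_cohort(cfg)
    return cfg, matrix, annotation, truth
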