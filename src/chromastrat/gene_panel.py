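"""Curated chromatin-structural gene panel and sex-biased gene exclusion.

The stratification pipeline restricts its second embedding stage to a curated
set of chromatin remodellers and genome-topology regulators, so that
subclusters within a cell type reflect chromatin-regulatory state rather than
global transcriptional differences.  This module houses that panel, validates
it, and applies it (and the routine sex-gene exclusion) to expression
matrices.

The packaged fixture ``data/chromatin_panel_synthetic.tsv`` is a synthetic
stand-in panel of exactly 892 symbols: a curated core of human
chromatin-regulator gene symbols padded with clearly synthetic placeholder
symbols (``SYNCR####``).  Symbol matching is exact string equality after
uppercasing and whitespace stripping; no alias or ortholog resolution is
attempted, so panel and matrix must share a symbol namespace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

#: Sex-biased genes excluded from all analyses by default (nuclei are pooled
#: across donors of both sexes, so these genes track donor sex, not biology).
DEFAULT_SEX_EXCLUSION = ("XIST", "UTY", "KDM5D")

PACKAGED_PANEL = "chromatin_panel_synthetic.tsv"


def _clean_symbol(raw: str) -> str:
    return raw.strip().upper()


@dataclass(frozen=True)
class GenePanel:
    """An ordered, deduplicated set of uppercase gene symbols."""

    symbols: tuple[str, ...]
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("gene panel is empty")
        if any(not s for s in self.symbols):
            raise ValueError("gene panel contains an empty symbol")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("gene panel symbols are not unique")
        if any(s != _clean_symbol(s) for s in self.symbols):
            raise ValueError("gene panel symbols must be uppercase and stripped")

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return _clean_symbol(symbol) in set(self.symbols)

    @classmethod
    def from_symbols(cls, symbols: Iterable[str], source_label: str = "") -> "GenePanel":
        seen: dict[str, None] = {}
        for s in symbols:
            c = _clean_symbol(s)
            if c:
                seen.setdefault(c, None)
        return cls(symbols=tuple(seen), source_label=source_label)


@dataclass(frozen=True)
class ExclusionList:
    """A set of gene symbols removed from matrices before analysis.

    Application is idempotent: excluding twice equals excluding once.
    """

    symbols: frozenset[str] = field(
        default_factory=lambda: frozenset(DEFAULT_SEX_EXCLUSION)
    )

    @classmethod
    def from_symbols(cls, symbols: Iterable[str]) -> "ExclusionList":
        return cls(frozenset(_clean_symbol(s) for s in symbols if _clean_symbol(s)))


def load_panel(path: str | Path, source_label: str | None = None) -> GenePanel:
    """Load a gene panel from a one-symbol-per-row TSV/CSV.

    Only the first column is read; a header row is skipped when its first
    field is a common column name (``gene``, ``symbol``, ...) — single gene
    symbols never collide with these.  Duplicate rows (after uppercasing)
    are deduplicated with a warning.

    Raises
    ------
    ValueError
        If the file contains no valid symbol.
    """
    path = Path(path)
    header_names = {"GENE", "GENES", "SYMBOL", "SYMBOLS", "GENE_SYMBOL", "NAME"}
    rows: list[str] = []
    with open(path) as fh:
        for line in fh:
            first = line.split("\t")[0].split(",")[0]
            sym = _clean_symbol(first)
            if sym:
                rows.append(sym)
    if rows and rows[0] in header_names:
        rows = rows[1:]
    if not rows:
        raise ValueError(f"no valid gene symbols found in {path}")
    n_dup = len(rows) - len(set(rows))
    if n_dup:
        logger.warning("panel %s: %d duplicate symbols collapsed", path.name, n_dup)
    panel = GenePanel.from_symbols(rows, source_label=source_label or str(path))
    logger.info("loaded panel %s: %d symbols", path.name, len(panel))
    return panel


def packaged_panel() -> GenePanel:
    """The synthetic 892-symbol chromatin-structure panel shipped with the package."""
    ref = resources.files("chromastrat").joinpath("data", PACKAGED_PANEL)
    with resources.as_file(ref) as p:
        return load_panel(p, source_label="packaged synthetic chromatin panel")


def restrict_to_panel(matrix: ExpressionMatrix, panel: GenePanel) -> ExpressionMatrix:
    """Keep only matrix genes that appear in the panel (matrix row order).

    Matching uppercases matrix symbols; retained per-cell counts are
    untouched.  Raises ``ValueError`` when the overlap is empty, which almost
    always means the panel and matrix use different symbol namespaces.
    """
    panel_set = set(panel.symbols)
    keep = [i for i, g in enumerate(matrix.gene_symbols) if _clean_symbol(g) in panel_set]
    if not keep:
        raise ValueError(
            "no overlap between panel and matrix gene symbols "
            f"(panel n={len(panel)}, matrix n={matrix.n_genes})"
        )
    n_absent = len(panel) - len(keep)
    if n_absent:
        logger.info("%d panel genes absent from matrix", n_absent)
    return matrix.subset_genes(keep)


def exclude_genes(matrix: ExpressionMatrix, excl: ExclusionList) -> ExpressionMatrix:
    """Drop rows named in the exclusion list; absent symbols are ignored."""
    drop = {s for s in excl.symbols}
    keep = [i for i, g in enumerate(matrix.gene_symbols) if _clean_symbol(g) not in drop]
    n_dropped = matrix.n_genes - len(keep)
    if n_dropped:
        logger.info("excluded %d genes (%s)", n_dropped, ", ".join(sorted(drop)))
    else:
        logger.debug("exclusion list disjoint from matrix; nothing removed")
    if len(keep) == matrix.n_genes:
        return matrix
    return matrix.subset_genes(keep)
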