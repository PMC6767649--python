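"""Single-cell co-expression statistics for a gene family of interest.

Works on a raw cell-by-gene count matrix with a presence threshold
(default: at least one read) rather than any normalisation.  For a
designated gene subset (here: trypsins) it reports how many cells express
at least one member, the distribution of members expressed per cell, and,
per gene, the relationship between expression ubiquity (cells expressing
the gene) and co-expression (cells where it is on together with at least
one other member).  Rows may be cells or metacells — the module is
agnostic; callers record which in their provenance log.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread
from scipy.stats import pearsonr, spearmanr


@dataclass
class CellCounts:
    """Non-negative integer cell-by-gene counts with a tagged gene subset."""

    cells: list[str]
    genes: list[str]
    counts: sp.csr_matrix
    trypsin_set: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.cells), len(self.genes)):
            raise ValueError("counts shape does not match cell/gene labels")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        unknown = set(self.trypsin_set) - set(self.genes)
        if unknown:
            raise ValueError(f"trypsin_set contains unknown genes: {sorted(unknown)[:5]}")
        self.trypsin_set = frozenset(self.trypsin_set)

    @classmethod
    def from_tsv(
        cls, path: str | Path, trypsin_set: Iterable[str] = ()
    ) -> "CellCounts":
        """Read a dense cells-by-genes TSV (first column = cell identifiers)."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            cells=[str(c) for c in df.index],
            genes=[str(g) for g in df.columns],
            counts=sp.csr_matrix(df.to_numpy(dtype=np.int64)),
            trypsin_set=frozenset(trypsin_set),
        )

    @classmethod
    def from_mtx(
        cls,
        mtx_path: str | Path,
        cells_path: str | Path,
        genes_path: str | Path,
        trypsin_set: Iterable[str] = (),
    ) -> "CellCounts":
        """Read MatrixMarket counts plus one-per-line row/column label files."""
        mat = sp.csr_matrix(mmread(str(mtx_path)))
        cells = Path(cells_path).read_text().split()
        genes = Path(genes_path).read_text().split()
        return cls(cells=cells, genes=genes, counts=mat, trypsin_set=frozenset(trypsin_set))


@dataclass
class CoexpressionSummary:
    n_expressing_cells: int
    histogram: dict[int, int]
    per_gene: pd.DataFrame  # columns: ubiquity, co_cells; index: gene
    pearson: tuple[float, float] | None
    spearman: tuple[float, float] | None

    @property
    def correlation(self) -> tuple[float, float] | None:
        """Default-reported flavour (Pearson)."""
        return self.pearson


def expression_mask(cc: CellCounts, min_reads: int = 1) -> sp.csr_matrix:
    """Boolean cell-by-gene presence matrix: count >= min_reads."""
    mask = cc.counts >= min_reads
    return sp.csr_matrix(mask, dtype=bool)


def _trypsin_submask(cc: CellCounts, min_reads: int) -> tuple[sp.csr_matrix, list[str]]:
    if not cc.trypsin_set:
        raise ValueError("trypsin_set is empty")
    genes = [g for g in cc.genes if g in cc.trypsin_set]
    idx = [cc.genes.index(g) for g in genes]
    mask = expression_mask(cc, min_reads)[:, idx]
    return sp.csr_matrix(mask), genes


def coexpression_summary(cc: CellCounts, min_reads: int = 1) -> CoexpressionSummary:
    """Expressing-cell count, members-per-cell histogram and ubiquity relation.

    All quantities are computed over the tagged gene subset only.  The
    per-gene table pairs ubiquity (cells expressing the gene) with co_cells
    (cells where the gene is on together with >= 1 other subset member);
    Pearson and Spearman correlations over those pairs are attached
    (``None`` and flagged when undefined, e.g. zero expressing cells).
    """
    mask, genes = _trypsin_submask(cc, min_reads)
    per_cell = np.asarray(mask.sum(axis=1)).ravel()

    expressing = per_cell >= 1
    n_expressing = int(expressing.sum())
    ks, cnts = np.unique(per_cell[expressing], return_counts=True)
    histogram = {int(k): int(c) for k, c in zip(ks, cnts)}

    multi = per_cell >= 2
    ubiquity = np.asarray(mask.sum(axis=0)).ravel()
    co_cells = np.asarray(mask[multi].sum(axis=0)).ravel()
    per_gene = pd.DataFrame({"ubiquity": ubiquity, "co_cells": co_cells}, index=genes)

    pear = spear = None
    x, y = per_gene["ubiquity"], per_gene["co_cells"]
    if n_expressing > 0 and len(genes) > 1 and x.std() > 0 and y.std() > 0:
        r, p = pearsonr(x, y)
        pear = (float(r), float(p))
        r, p = spearmanr(x, y)
        spear = (float(r), float(p))
    return CoexpressionSummary(
        n_expressing_cells=n_expressing,
        histogram=histogram,
        per_gene=per_gene,
        pearson=pear,
        spearman=spear,
    )


def coexpression_partners(
    cc: CellCounts, gene: str, min_reads: int = 1
) -> list[tuple[str, int]]:
    """Subset members co-expressed with ``gene``, with shared-cell counts.

    Sorted by descending shared cells, ties broken by gene identifier.
    Partners sharing zero cells are omitted.
    """
    if gene not in cc.trypsin_set:
        raise KeyError(f"{gene!r} is not in the tagged gene subset")
    mask, genes = _trypsin_submask(cc, min_reads)
    dense = np.asarray(mask.todense())
    g_idx = genes.index(gene)
    on = dense[:, g_idx]
    shared = dense[on].sum(axis=0)
    pairs = [
        (other, int(shared[i]))
        for i, other in enumerate(genes)
        if other != gene and shared[i] > 0
    ]
    return sorted(pairs, key=lambda t: (-t[1], t[0]))


def write_summary(summary: CoexpressionSummary, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hist = pd.DataFrame(
        sorted(summary.histogram.items()), columns=["n_trypsins", "n_cells"]
    )
    hist.to_csv(out / "histogram.tsv", sep="\t", index=False)
    summary.per_gene.to_csv(out / "per_gene.tsv", sep="\t", index_label="gene")
    with open(out / "summary.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"n_expressing_cells\t{summary.n_expressing_cells}\n")
        if summary.pearson:
            fh.write(f"pearson_r\t{summary.pearson[0]:.6g}\n")
            fh.write(f"pearson_p\t{summary.pearson[1]:.6g}\n")
        if summary.spearman:
            fh.write(f"spearman_r\t{summary.spearman[0]:.6g}\n")
            fh.write(f"spearman_p\t{summary.spearman[1]:.6g}\n")
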