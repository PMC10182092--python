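"""Validation metrics: barnyard statistics, region fractions, gene-body
coverage, biotype tallies, saturation by downsampling, matrix filtering and
pseudobulk correlation.

These are the quality-control readouts of the chemistry: the two-species
mixing experiment quantifies doublets and per-barcode species specificity;
exon/intron fractions show how intron-rich the random-primed libraries are;
the 100-bin gene-body profile diagnoses 5'/3' capture bias; saturation curves
show detection as a function of depth; and the filter implements the standard
preprocessing cuts (nuclei with <200 detected genes out, genes detected in <3
nuclei out, mitochondrial/ribosomal genes removed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import pearsonr

from .quantify import (AnnotationIndex, CountMatrix, assign_frame,
                       count_matrix, parse_blocks)
from .simulate import ToyAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "BarnyardReport", "CoverageProfile", "SaturationCurve", "FilterConfig",
    "barnyard", "region_fractions", "genebody_coverage", "biotype_counts",
    "saturation", "filter_matrix", "pseudobulk_correlation",
]


# ---------------------------------------------------------------------------
# Barnyard
# ---------------------------------------------------------------------------

@dataclass
class BarnyardReport:
    per_cell: pd.DataFrame        # umis_A, umis_B, specificity, is_doublet
    doublet_rate: Optional[float]
    median_specificity: Dict[str, float]
    t_minor: float


def barnyard(matrix: CountMatrix, t_minor: float = 0.1) -> BarnyardReport:
    """Species-mixing statistics per barcode.

    specificity s_c = max(umis_A, umis_B) / (umis_A + umis_B) ∈ [0.5, 1];
    a barcode is a doublet when its minor-species UMI fraction is >= t_minor.
    The summary doublet rate is taken over barcodes with at least one UMI.
    A single-species matrix yields doublet_rate None with a warning.
    """
    species = matrix.gene_meta["species"].to_numpy()
    total = matrix.total
    umis_a = np.asarray(total[:, species == "A"].sum(axis=1)).ravel()
    umis_b = np.asarray(total[:, species == "B"].sum(axis=1)).ravel()
    tot = umis_a + umis_b
    with np.errstate(invalid="ignore", divide="ignore"):
        spec = np.where(tot > 0, np.maximum(umis_a, umis_b) / np.maximum(tot, 1), np.nan)
        minor = np.where(tot > 0, np.minimum(umis_a, umis_b) / np.maximum(tot, 1), np.nan)
    per_cell = pd.DataFrame({
        "cell_id": matrix.cells, "umis_A": umis_a, "umis_B": umis_b,
        "specificity": spec, "is_doublet": minor >= t_minor,
    }).set_index("cell_id")

    present = set(species)
    if present < {"A", "B"}:
        logger.warning("single-species matrix: doublet rate undefined")
        rate = None
    else:
        informative = per_cell[tot > 0]
        rate = float(informative["is_doublet"].mean()) if len(informative) else None
    majority = np.where(umis_a >= umis_b, "A", "B")
    med = {}
    for sp_name in ("A", "B"):
        mask = (majority == sp_name) & (tot > 0)
        if mask.any():
            med[sp_name] = float(np.nanmedian(spec[mask]))
    return BarnyardReport(per_cell=per_cell, doublet_rate=rate,
                          median_specificity=med, t_minor=t_minor)


# ---------------------------------------------------------------------------
# Region fractions
# ---------------------------------------------------------------------------

def region_fractions(source: Union[dict, pd.DataFrame]) -> Dict[str, float]:
    """Percentages of assigned reads in exon/intron/intergenic (sums to 100).

    Accepts the assignment report dict from :func:`~snrandom.quantify.
    assign_frame` or a frame with a ``region`` column.
    """
    if isinstance(source, pd.DataFrame):
        counts = source["region"].value_counts().to_dict()
    else:
        counts = source
    n = sum(counts.get(k, 0) for k in ("exon", "intron", "intergenic"))
    if n == 0:
        raise ValueError("no assigned reads: region fractions undefined")
    return {k: 100.0 * counts.get(k, 0) / n
            for k in ("exon", "intron", "intergenic")}


# ---------------------------------------------------------------------------
# Gene-body coverage
# ---------------------------------------------------------------------------

@dataclass
class CoverageProfile:
    bins: np.ndarray              # length B, sums to 1, 5'->3'
    n_transcripts: int
    n_reads: int

    def __post_init__(self):
        assert abs(float(self.bins.sum()) - 1.0) < 1e-9
        assert (self.bins >= 0).all()


def genebody_coverage(
    records: pd.DataFrame,
    annotation: ToyAnnotation,
    B: int = 100,
    min_len: int = 500,
) -> CoverageProfile:
    """Normalised read coverage along the scaled gene body, 5'->3'.

    For every transcript with spliced length >= ``min_len``, exon-contained
    alignment blocks are projected onto spliced-transcript coordinates,
    rescaled to ``B`` bins and accumulated per base; minus-strand transcripts
    have their bin vector reversed so bin 0 is always the 5' end.  ``records``
    needs chrom, start, end and optionally blocks columns.
    """
    qualifying = [g for g in annotation.genes if g.spliced_len >= min_len]
    if not qualifying:
        raise ValueError(f"no transcript with spliced length >= {min_len}")
    by_gene = {g.gene_id: g for g in qualifying}
    index = AnnotationIndex(annotation)

    total = np.zeros(B, dtype=float)
    n_used = 0
    has_blocks = "blocks" in records.columns
    # per-gene exon offsets in genomic (left) order
    offsets = {}
    for g in qualifying:
        offs, acc = [], 0
        for es, ee in g.exons:
            offs.append((es, ee, acc))
            acc += ee - es
        offsets[g.gene_id] = offs

    per_gene_bins: Dict[str, np.ndarray] = {gid: np.zeros(B) for gid in by_gene}
    for row in records.itertuples(index=False):
        blocks = parse_blocks(row.blocks) if has_blocks else [(row.start, row.end)]
        genes = index.overlapping_genes(row.chrom, blocks)
        if len(genes) != 1 or genes[0].gene_id not in by_gene:
            continue
        g = genes[0]
        if index.region_of(g, blocks) != "exon":
            continue
        T = g.spliced_len
        hit = False
        for a, b in blocks:
            for es, ee, off in offsets[g.gene_id]:
                lo, hi = max(a, es), min(b, ee)
                if lo < hi:
                    tpos = np.arange(off + lo - es, off + hi - es)
                    np.add.at(per_gene_bins[g.gene_id], tpos * B // T, 1.0)
                    hit = True
        n_used += hit

    for gid, v in per_gene_bins.items():
        if by_gene[gid].strand == "-":
            v = v[::-1]
        total += v
    s = total.sum()
    if s == 0:
        raise ValueError("no exon-contained reads on qualifying transcripts")
    return CoverageProfile(bins=total / s, n_transcripts=len(qualifying),
                           n_reads=int(n_used))


# ---------------------------------------------------------------------------
# Biotype tallies
# ---------------------------------------------------------------------------

KNOWN_BIOTYPES = ("protein_coding", "lncRNA", "snoRNA", "snRNA", "miRNA",
                  "miscRNA", "mito", "ribo")


def biotype_counts(matrix: CountMatrix) -> pd.DataFrame:
    """Detected genes (total count > 0) and UMIs per RNA biotype; unknown
    biotype labels are pooled under 'other'."""
    bt = matrix.gene_meta["biotype"].to_numpy()
    bt = np.where(np.isin(bt, KNOWN_BIOTYPES), bt, "other")
    total = matrix.total
    detected = np.asarray((total > 0).sum(axis=0)).ravel() > 0
    umis = np.asarray(total.sum(axis=0)).ravel()
    df = pd.DataFrame({"biotype": bt, "detected": detected, "umis": umis})
    out = df.groupby("biotype").agg(genes_detected=("detected", "sum"),
                                    umis=("umis", "sum"))
    return out.astype({"genes_detected": int, "umis": int})


# ---------------------------------------------------------------------------
# Saturation
# ---------------------------------------------------------------------------

@dataclass
class SaturationCurve:
    fractions: np.ndarray
    median_genes: np.ndarray
    median_umis: np.ndarray
    seed: int


def _medians(cm: CountMatrix, cells: Sequence[str]):
    idx = [i for i, c in enumerate(cm.cells) if c in set(cells)]
    if not idx:
        return 0.0, 0.0
    sub = cm.subset(cell_idx=idx)
    return (float(np.median(sub.genes_detected_per_cell())),
            float(np.median(sub.cell_totals())))


def saturation(
    assigned: pd.DataFrame,
    annotation: ToyAnnotation,
    fractions: Sequence[float],
    seed: int = 0,
    cells: Optional[Sequence[str]] = None,
    dedup_mode: str = "directional",
) -> SaturationCurve:
    """Median genes/UMIs per cell as a function of read downsampling.

    Reads (rows of ``assigned``) are subsampled without replacement at each
    fraction and the dedup+count pipeline is re-run from scratch; f = 1 keeps
    every row in original order, so it is bit-identical to the direct run.
    ``cells`` fixes the cell set over which medians are taken (defaults to
    the cells of the full, undownsampled matrix).
    """
    fractions = sorted(float(f) for f in fractions)
    if not fractions or fractions[0] <= 0 or fractions[-1] > 1:
        raise ValueError("fractions must be sorted within (0, 1]")
    if len(assigned) == 0:
        raise ValueError("no reads to downsample")
    rng = np.random.default_rng(seed)
    full = count_matrix(assigned, annotation, dedup_mode=dedup_mode)
    if cells is None:
        cells = list(full.cells)
    genes_med, umis_med = [], []
    for f in fractions:
        if f == 1.0:
            cm = full
        else:
            k = int(round(f * len(assigned)))
            take = np.sort(rng.choice(len(assigned), size=k, replace=False))
            cm = count_matrix(assigned.iloc[take], annotation,
                              dedup_mode=dedup_mode)
        g, u = _medians(cm, cells)
        genes_med.append(g)
        umis_med.append(u)
    return SaturationCurve(fractions=np.array(fractions),
                           median_genes=np.array(genes_med),
                           median_umis=np.array(umis_med), seed=seed)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterConfig:
    """Preprocessing cuts: exclusion lists first, then nuclei with fewer than
    ``min_genes_per_nucleus`` detected genes, then genes detected in fewer
    than ``min_nuclei_per_gene`` nuclei (one pass, in that order)."""

    min_genes_per_nucleus: int = 200
    min_nuclei_per_gene: int = 3
    exclude_genes: tuple = ()      # e.g. mitochondrial + ribosomal gene ids

    def __post_init__(self):
        if self.min_genes_per_nucleus < 0 or self.min_nuclei_per_gene < 0:
            raise ValueError("filter thresholds must be >= 0")


def filter_matrix(matrix: CountMatrix, config: FilterConfig):
    """Apply the preprocessing cuts; returns (filtered matrix, report dict).

    An input that filters to nothing returns an empty matrix with an explicit
    report rather than raising.
    """
    excluded = set(config.exclude_genes)
    keep_genes = np.array([g not in excluded for g in matrix.genes])
    cm = matrix.subset(gene_idx=np.flatnonzero(keep_genes))
    n_excluded = int((~keep_genes).sum())

    genes_per_cell = cm.genes_detected_per_cell()
    keep_cells = genes_per_cell >= config.min_genes_per_nucleus
    cm = cm.subset(cell_idx=np.flatnonzero(keep_cells))
    n_cells_removed = int((~keep_cells).sum())

    cells_per_gene = cm.cells_detected_per_gene()
    keep_g2 = cells_per_gene >= config.min_nuclei_per_gene
    cm = cm.subset(gene_idx=np.flatnonzero(keep_g2))
    n_genes_removed = int((~keep_g2).sum())

    report = {
        "genes_excluded_by_list": n_excluded,
        "cells_removed_min_genes": n_cells_removed,
        "genes_removed_min_nuclei": n_genes_removed,
        "cells_kept": len(cm.cells),
        "genes_kept": len(cm.genes),
    }
    return cm, report


# ---------------------------------------------------------------------------
# Pseudobulk correlation
# ---------------------------------------------------------------------------

def _pseudobulk(matrix: CountMatrix) -> pd.Series:
    total = matrix.total.astype(float).toarray()
    depth = total.sum(axis=1, keepdims=True)
    keep = depth.ravel() > 0
    cp10k = total[keep] / depth[keep] * 1e4
    return pd.Series(np.log1p(cp10k.mean(axis=0)), index=matrix.genes)


def pseudobulk_correlation(matrix_a: CountMatrix, matrix_b: CountMatrix):
    """Pearson r between pseudobulk expression of two libraries.

    Per library: depth-normalise each cell to counts-per-10k, average over
    cells per gene, then ln(x + 1).  r is computed over the intersection of
    the two gene universes; fewer than 10 shared genes is an error.  Returns
    (r, paired gene table).
    """
    a = _pseudobulk(matrix_a)
    b = _pseudobulk(matrix_b)
    shared = a.index.intersection(b.index)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared genes (< 10)")
    table = pd.DataFrame({"a": a.loc[shared], "b": b.loc[shared]})
    r = float(pearsonr(table["a"], table["b"])[0])
    return r, table
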