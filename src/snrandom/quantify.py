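"""Feature assignment, UMI deduplication and the cell x gene count matrix.

Reads are assigned to whole gene bodies (not exons only): random-primed
nuclear libraries are intron-dominated, so an exon-only counter would discard
most of the signal.  A read overlapping exactly one gene body is kept; its
region is ``exon`` when the alignment is fully contained in exonic sequence,
``intron`` when it overlaps any intronic sequence, ``intergenic`` otherwise
(e.g. an overhang past the gene end).  Reads overlapping two or more gene
bodies are discarded as ambiguous and counted.

Molecules are UMI clusters per (cell, gene) under directional single-linkage
collapse at Hamming distance 1 (a cluster absorbs a neighbour when its read
count is at least twice-minus-one the neighbour's), the established default
for short UMIs.  A molecule is ``spliced`` when every read is exonic and
``unspliced`` when any read shows intronic sequence; multi-read molecules
with neither property (mixed exon/overhang evidence) land in ``ambiguous``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam
import scipy.io
import scipy.sparse as sp
from intervaltree import IntervalTree

from .simulate import Gene, ToyAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationIndex", "CountMatrix", "assign_feature", "assign_frame",
    "collapse_umis", "dedup_umis", "count_matrix", "write_matrix",
    "read_matrix", "parse_blocks", "load_truth_alignments", "load_sam_alignments",
    "matrix_from_profiles",
]

LAYERS = ("spliced", "unspliced", "ambiguous")


def parse_blocks(s: str) -> List[Tuple[int, int]]:
    """Parse 'a-b,c-d' block strings (single interval if no comma)."""
    return [tuple(map(int, part.split("-"))) for part in str(s).split(",")]


class AnnotationIndex:
    """Interval index over gene bodies plus per-gene exon/intron geometry."""

    def __init__(self, annotation: ToyAnnotation):
        self.annotation = annotation
        self.trees: Dict[str, IntervalTree] = {}
        for g in annotation.genes:
            self.trees.setdefault(g.chrom, IntervalTree())[g.start:g.end] = g

    def overlapping_genes(self, chrom: str, blocks) -> List[Gene]:
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        hits = set()
        for a, b in blocks:
            for iv in tree.overlap(a, b):
                hits.add(iv.data.gene_id)
        return [self.annotation.genes_by_id[gid] for gid in sorted(hits)]

    @staticmethod
    def region_of(gene: Gene, blocks) -> str:
        exonic = all(
            any(es <= a and b <= ee for es, ee in gene.exons) for a, b in blocks
        )
        if exonic:
            return "exon"
        for a, b in blocks:
            for isv, iev in gene.introns:
                if a < iev and isv < b:
                    return "intron"
        return "intergenic"


def assign_feature(index: AnnotationIndex, chrom: str, blocks) -> Tuple[str, str]:
    """Assign one alignment; returns (gene_id | 'intergenic' | 'ambiguous', region)."""
    genes = index.overlapping_genes(chrom, blocks)
    if not genes:
        return "intergenic", "intergenic"
    if len(genes) > 1:
        return "ambiguous", "ambiguous"
    g = genes[0]
    return g.gene_id, index.region_of(g, blocks)


def assign_frame(records: pd.DataFrame, annotation: ToyAnnotation,
                 index: Optional[AnnotationIndex] = None):
    """Vectorised-ish assignment over an AlignmentRecord frame.

    ``records`` needs columns chrom, start, end (0-based half-open) and
    optionally ``blocks`` ('a-b,c-d'); returns (frame with gene_id/region
    columns added, assignment report dict).
    """
    index = index or AnnotationIndex(annotation)
    missing_chrom = 0
    genes_out, regions_out = [], []
    has_blocks = "blocks" in records.columns
    for row in records.itertuples(index=False):
        blocks = parse_blocks(row.blocks) if has_blocks else [(row.start, row.end)]
        if row.chrom not in index.trees:
            missing_chrom += 1
            genes_out.append("intergenic")
            regions_out.append("intergenic")
            continue
        gid, region = assign_feature(index, row.chrom, blocks)
        genes_out.append(gid)
        regions_out.append(region)
    out = records.copy()
    out["gene_id"] = genes_out
    out["region"] = regions_out
    report = {
        "reads": len(out),
        "exon": int((out["region"] == "exon").sum()),
        "intron": int((out["region"] == "intron").sum()),
        "intergenic": int((out["region"] == "intergenic").sum()),
        "ambiguous": int((out["gene_id"] == "ambiguous").sum()),
        "missing_chrom": missing_chrom,
    }
    if missing_chrom:
        logger.warning("%d reads on chromosomes absent from the annotation",
                       missing_chrom)
    return out, report


# ---------------------------------------------------------------------------
# UMI deduplication
# ---------------------------------------------------------------------------

def _hamming1(a: str, b: str) -> bool:
    seen = False
    for x, y in zip(a, b):
        if x != y:
            if seen:
                return False
            seen = True
    return seen


def collapse_umis(counts: Mapping[str, int]) -> Dict[str, str]:
    """Directional single-link collapse; maps each UMI to its representative.

    Nodes are visited in order of decreasing read count (ties broken
    lexicographically); an unassigned node starts a cluster and a breadth-
    first search follows edges u->v where Hamming(u, v) == 1 and
    count(u) >= 2*count(v) - 1, absorbing unassigned nodes.  Deterministic.
    """
    order = sorted(counts, key=lambda u: (-counts[u], u))
    rep: Dict[str, str] = {}
    for seed in order:
        if seed in rep:
            continue
        rep[seed] = seed
        frontier = [seed]
        while frontier:
            nxt = []
            for u in frontier:
                cu = counts[u]
                for v in order:
                    if v in rep or not _hamming1(u, v):
                        continue
                    if cu >= 2 * counts[v] - 1:
                        rep[v] = seed
                        nxt.append(v)
            frontier = nxt
    return rep


def dedup_umis(umis: Iterable[str], mode: str = "directional") -> int:
    """Number of molecules in one (cell, gene) group of raw UMIs."""
    counts: Dict[str, int] = {}
    for u in umis:
        counts[u] = counts.get(u, 0) + 1
    if not counts:
        return 0
    if mode == "exact":
        return len(counts)
    if mode != "directional":
        raise ValueError(f"unknown dedup mode {mode!r}")
    return len(set(collapse_umis(counts).values()))


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """cell x gene UMI counts with spliced/unspliced/ambiguous layers."""

    cells: list
    genes: list
    gene_meta: pd.DataFrame            # index gene_id; columns species, biotype
    layers: Dict[str, sp.csr_matrix]   # spliced, unspliced, ambiguous

    def __post_init__(self):
        for name in LAYERS:
            if name not in self.layers:
                raise ValueError(f"missing layer {name}")
            m = self.layers[name]
            if m.shape != (len(self.cells), len(self.genes)):
                raise ValueError(f"layer {name} shape {m.shape} inconsistent")
            if m.nnz and m.data.min() < 0:
                raise ValueError("negative counts")

    @property
    def total(self) -> sp.csr_matrix:
        return (self.layers["spliced"] + self.layers["unspliced"]
                + self.layers["ambiguous"]).tocsr()

    @property
    def shape(self):
        return (len(self.cells), len(self.genes))

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.total.sum(axis=1)).ravel()

    def genes_detected_per_cell(self) -> np.ndarray:
        return np.asarray((self.total > 0).sum(axis=1)).ravel()

    def cells_detected_per_gene(self) -> np.ndarray:
        return np.asarray((self.total > 0).sum(axis=0)).ravel()

    def subset(self, cell_idx=None, gene_idx=None) -> "CountMatrix":
        ci = np.arange(len(self.cells)) if cell_idx is None else np.asarray(cell_idx)
        gi = np.arange(len(self.genes)) if gene_idx is None else np.asarray(gene_idx)
        genes = [self.genes[i] for i in gi]
        return CountMatrix(
            cells=[self.cells[i] for i in ci],
            genes=genes,
            gene_meta=self.gene_meta.loc[genes],
            layers={k: v[ci][:, gi].tocsr() for k, v in self.layers.items()},
        )

    def to_frame(self, layer: str = "total") -> pd.DataFrame:
        m = self.total if layer == "total" else self.layers[layer]
        return pd.DataFrame(m.toarray(), index=self.cells, columns=self.genes)


def _molecule_layer(all_exon: bool, any_intron: bool, n_reads: int) -> str:
    if all_exon:
        return "spliced"
    if any_intron or n_reads == 1:
        # single-read molecules are never 'ambiguous'; non-exonic evidence on
        # a lone read is treated as unspliced (pre-mRNA/readthrough sequence)
        return "unspliced"
    return "ambiguous"


def count_matrix(
    assigned: pd.DataFrame,
    annotation: ToyAnnotation,
    called_cells: Optional[Sequence[str]] = None,
    dedup_mode: str = "directional",
) -> CountMatrix:
    """Build the count matrix from assigned, tagged alignment records.

    ``assigned`` needs columns cell_id, umi, gene_id, region (from
    :func:`assign_frame`); rows with gene_id in {intergenic, ambiguous} are
    ignored.  When ``called_cells`` is given the matrix is restricted to (and
    ordered by) those cells.
    """
    meta = annotation.gene_meta()
    if meta.index.duplicated().any():
        raise ValueError("duplicate gene ids in annotation")
    genes = list(meta.index)
    gene_pos = {g: i for i, g in enumerate(genes)}

    df = assigned[~assigned["gene_id"].isin(["intergenic", "ambiguous"])]
    if called_cells is not None:
        called = list(called_cells)
        df = df[df["cell_id"].isin(set(called))]
        cells = called
    else:
        cells = sorted(df["cell_id"].unique())
    cell_pos = {c: i for i, c in enumerate(cells)}

    triplets: Dict[str, list] = {name: [] for name in LAYERS}
    for (cell, gene), grp in df.groupby(["cell_id", "gene_id"], sort=True):
        counts: Dict[str, int] = grp["umi"].value_counts().to_dict()
        if dedup_mode == "exact":
            rep = {u: u for u in counts}
        else:
            rep = collapse_umis(counts)
        by_mol: Dict[str, list] = {}
        for u, region in zip(grp["umi"], grp["region"]):
            by_mol.setdefault(rep[u], []).append(region)
        tallies = {name: 0 for name in LAYERS}
        for regions in by_mol.values():
            layer = _molecule_layer(
                all_exon=all(r == "exon" for r in regions),
                any_intron=any(r == "intron" for r in regions),
                n_reads=len(regions),
            )
            tallies[layer] += 1
        for name, v in tallies.items():
            if v:
                triplets[name].append((cell_pos[cell], gene_pos[gene], v))

    layers = {}
    shape = (len(cells), len(genes))
    for name, trips in triplets.items():
        if trips:
            r, c, v = zip(*trips)
            layers[name] = sp.coo_matrix((v, (r, c)), shape=shape,
                                         dtype=np.int64).tocsr()
        else:
            layers[name] = sp.csr_matrix(shape, dtype=np.int64)
    return CountMatrix(cells=cells, genes=genes, gene_meta=meta, layers=layers)


def matrix_from_profiles(profiles, annotation: ToyAnnotation) -> CountMatrix:
    """CountMatrix directly from simulated expression profiles (one nucleus =
    one cell; every molecule captured).  Useful for matrix-level QC tests."""
    spl = sp.csr_matrix(profiles.spliced)
    uns = sp.csr_matrix(profiles.unspliced)
    shape = spl.shape
    return CountMatrix(
        cells=list(profiles.nucleus_ids),
        genes=list(profiles.gene_ids),
        gene_meta=annotation.gene_meta(),
        layers={"spliced": spl, "unspliced": uns,
                "ambiguous": sp.csr_matrix(shape, dtype=np.int64)},
    )


# ---------------------------------------------------------------------------
# Matrix I/O (MatrixMarket + sidecars)
# ---------------------------------------------------------------------------

def write_matrix(cm: CountMatrix, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), cm.total.T.tocoo())
    for name in LAYERS:
        scipy.io.mmwrite(str(outdir / f"{name}.mtx"), cm.layers[name].T.tocoo())
    with open(outdir / "barcodes.tsv", "w") as fh:
        fh.writelines(c + "\n" for c in cm.cells)
    feat = cm.gene_meta.reset_index()[["gene_id", "biotype", "species"]]
    feat.to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)


def read_matrix(indir) -> CountMatrix:
    indir = Path(indir)
    with open(indir / "barcodes.tsv") as fh:
        cells = [line.strip() for line in fh if line.strip()]
    feat = pd.read_csv(indir / "features.tsv", sep="\t", header=None,
                       names=["gene_id", "biotype", "species"])
    meta = feat.set_index("gene_id")[["species", "biotype"]]
    layers = {}
    for name in LAYERS:
        m = scipy.io.mmread(str(indir / f"{name}.mtx")).T.tocsr().astype(np.int64)
        if m.shape != (len(cells), len(meta)):
            raise ValueError(
                f"{name}.mtx shape {m.shape} does not match sidecars "
                f"({len(cells)} cells, {len(meta)} genes)")
        layers[name] = m
    return CountMatrix(cells=cells, genes=list(meta.index), gene_meta=meta,
                       layers=layers)


# ---------------------------------------------------------------------------
# Alignment-record loaders
# ---------------------------------------------------------------------------

def load_truth_alignments(alignments: pd.DataFrame,
                          tagged: pd.DataFrame) -> pd.DataFrame:
    """Join simulator truth-mode coordinates with demultiplexed tags by
    read_id; reads rejected by demux drop out."""
    cols = ["read_id", "cell_id", "umi"]
    return alignments.merge(tagged[cols], on="read_id", how="inner")


def load_sam_alignments(path, cell_tag: str = "CB", umi_tag: str = "UB") -> pd.DataFrame:
    """AlignmentRecords from a SAM/BAM with cell/UMI tags (aligned blocks from
    the CIGAR, so spliced alignments keep their exon structure)."""
    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or not aln.has_tag(cell_tag) or not aln.has_tag(umi_tag):
                continue
            blocks = aln.get_blocks() or [(aln.reference_start, aln.reference_end)]
            rows.append({
                "read_id": aln.query_name,
                "chrom": aln.reference_name,
                "start": blocks[0][0],
                "end": blocks[-1][1],
                "strand": "-" if aln.is_reverse else "+",
                "blocks": ",".join(f"{a}-{b}" for a, b in blocks),
                "cell_id": aln.get_tag(cell_tag),
                "umi": aln.get_tag(umi_tag),
            })
    return pd.DataFrame(rows)
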