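"""Generative model of snRandom-seq libraries with full ground truth.

The simulator emulates the experiment end to end: a two-species ("barnyard")
nucleus mixture, random-primed reverse transcription in K pre-indexed tubes,
dA tailing, droplet encapsulation with Poisson co-occupancy and one barcoded
bead per droplet, and paired-end sequencing with substitution errors and an
ambient-read background.  Every emitted read is recorded in a
:class:`TruthTable` (origin nucleus, droplet, gene, genomic footprint, region,
UMI), so the demultiplexer, quantifier, nucleus caller and QC metrics can be
validated against known truth.

Scales are deliberately small (tens of kilobase chromosomes, hundreds of
nuclei, a few hundred reads per nucleus): the point is to reproduce the
statistical structure of the chemistry — intron-rich random priming, a 3'
bias from the oligo(dT) fraction, 1/K doublet thinning — not sequencing-scale
data volumes.

Key modelling choices
---------------------
* A molecule is one cDNA: it receives a single UMI and a single fragment
  placement; repeated reads of a molecule are duplicates (same coordinates,
  independent sequencing errors), as PCR duplicates are.
* Random priming places the fragment window uniformly over the transcript
  *allowing overhang at both ends* (the window is clipped), which makes the
  expected per-base coverage exactly uniform; oligo(dT) priming anchors the
  window at the transcript 3' end.
* Within one (nucleus, gene) group, UMIs are drawn so that no two are within
  Hamming distance 1 of each other.  Such collisions are unresolvable in
  principle by any UMI deduplicator, so excluding them keeps the simulator's
  molecule counts a well-defined ground truth; real libraries incur a small
  collision undercount that this generator does not model.
"""

from __future__ import annotations

import gzip as gzip_mod
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .chemistry import BarcodeWhitelist, ReadStructure

__all__ = [
    "Gene",
    "ToyAnnotation",
    "LibraryConfig",
    "ExpressionProfiles",
    "DropletMap",
    "TruthTable",
    "Library",
    "simulate_annotation",
    "simulate_expression",
    "simulate_droplets",
    "simulate_reads",
    "simulate_library",
    "collision_rate",
    "lambda_for_collision_rate",
    "random_dna",
]

BIOTYPES = ("protein_coding", "lncRNA", "snoRNA", "snRNA", "miRNA",
            "miscRNA", "mito", "ribo")

DEFAULT_BIOTYPE_WEIGHTS = {
    "protein_coding": 0.70, "lncRNA": 0.12, "snoRNA": 0.03, "snRNA": 0.03,
    "miRNA": 0.03, "miscRNA": 0.03, "mito": 0.03, "ribo": 0.03,
}

# relative expression of each biotype class (multiplies the per-gene Gamma
# propensity): short non-coding and structural RNAs are detectable but carry
# far fewer molecules than protein-coding transcripts in nuclei
BIOTYPE_EXPRESSION_FACTOR = {
    "protein_coding": 1.0, "lncRNA": 1.0, "snoRNA": 0.3, "snRNA": 0.3,
    "miRNA": 0.3, "miscRNA": 0.3, "mito": 0.5, "ribo": 0.5,
}

_COMP = str.maketrans("ACGT", "TGCA")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

@dataclass
class Gene:
    """One gene: a contiguous genomic body tiled by alternating exons/introns.

    Coordinates are 0-based half-open genomic positions.  ``exons`` are sorted
    by genomic start; introns are the gaps between consecutive exons.
    """

    gene_id: str
    species: str            # 'A' or 'B'
    biotype: str
    chrom: str
    start: int
    end: int
    strand: str             # '+' or '-'
    exons: list = field(default_factory=list)

    def __post_init__(self):
        assert self.start < self.end
        assert self.strand in "+-"
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            assert a < b <= c < d, "exons must be disjoint and ordered"
        assert self.exons[0][0] == self.start and self.exons[-1][1] == self.end

    @property
    def introns(self) -> list:
        return [(b, c) for (_, b), (c, _) in zip(self.exons, self.exons[1:])]

    @property
    def spliced_len(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def unspliced_len(self) -> int:
        return self.end - self.start

    # -- coordinate maps ----------------------------------------------------
    # "left" spliced coordinates run along the concatenated exons in genomic
    # order regardless of strand; transcript-sense position t maps to left
    # position t (+) or spliced_len-1-t (-).

    def spliced_window_to_blocks(self, a: int, b: int) -> list:
        """Map left-based spliced interval [a, b) to genomic exon blocks."""
        blocks = []
        offset = 0
        for es, ee in self.exons:
            elen = ee - es
            lo, hi = max(a, offset), min(b, offset + elen)
            if lo < hi:
                blocks.append((es + lo - offset, es + hi - offset))
            offset += elen
        return blocks

    def sense_spliced_to_left(self, a: int, b: int) -> tuple:
        """Transcript-sense spliced interval [a, b) -> left-based interval."""
        if self.strand == "+":
            return a, b
        t = self.spliced_len
        return t - b, t - a

    def sense_body_to_genomic(self, a: int, b: int) -> tuple:
        """Transcript-sense gene-body interval [a, b) -> genomic interval."""
        if self.strand == "+":
            return self.start + a, self.start + b
        return self.end - b, self.end - a


@dataclass
class ToyAnnotation:
    """A miniature two-species annotation plus its chromosome sequences."""

    genes: list
    chrom_seqs: dict

    def __post_init__(self):
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids in annotation")
        self.genes_by_id = {g.gene_id: g for g in self.genes}

    @property
    def gene_ids(self) -> list:
        return [g.gene_id for g in self.genes]

    def gene_meta(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": [g.gene_id for g in self.genes],
             "species": [g.species for g in self.genes],
             "biotype": [g.biotype for g in self.genes]}
        ).set_index("gene_id")

    def genes_of_biotype(self, *biotypes: str) -> list:
        return [g.gene_id for g in self.genes if g.biotype in biotypes]

    @property
    def mito_genes(self) -> list:
        return self.genes_of_biotype("mito")

    @property
    def ribo_genes(self) -> list:
        return self.genes_of_biotype("ribo")

    # -- I/O ----------------------------------------------------------------

    def write_gtf(self, path) -> None:
        with open(path, "w") as fh:
            for g in self.genes:
                attrs = (f'gene_id "{g.gene_id}"; species "{g.species}"; '
                         f'biotype "{g.biotype}";')
                fh.write(f"{g.chrom}\tsnrandom\tgene\t{g.start + 1}\t{g.end}\t."
                         f"\t{g.strand}\t.\t{attrs}\n")
                for es, ee in g.exons:
                    fh.write(f"{g.chrom}\tsnrandom\texon\t{es + 1}\t{ee}\t."
                             f"\t{g.strand}\t.\t{attrs}\n")

    def write_fasta(self, path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.chrom_seqs.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @classmethod
    def read_gtf(cls, gtf_path, fasta_path=None) -> "ToyAnnotation":
        import re

        genes: dict = {}
        exons: dict = {}
        with open(gtf_path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                chrom, _, feat, start, end, _, strand, _, attrs = \
                    line.rstrip("\n").split("\t")
                a = dict(re.findall(r'(\w+) "([^"]*)"', attrs))
                gid = a["gene_id"]
                iv = (int(start) - 1, int(end))
                if feat == "gene":
                    genes[gid] = (chrom, iv, strand,
                                  a.get("species", "A"),
                                  a.get("biotype", "protein_coding"))
                elif feat == "exon":
                    exons.setdefault(gid, []).append(iv)
        chrom_seqs = {}
        if fasta_path:
            from Bio import SeqIO

            chrom_seqs = {rec.id: str(rec.seq).upper()
                          for rec in SeqIO.parse(str(fasta_path), "fasta")}
        out = []
        for gid, (chrom, (s, e), strand, sp, bt) in genes.items():
            out.append(Gene(gid, sp, bt, chrom, s, e, strand,
                            exons=sorted(exons.get(gid, [(s, e)]))))
        return cls(genes=out, chrom_seqs=chrom_seqs)


def _allocate_biotypes(n: int, weights: dict) -> list:
    """Largest-remainder allocation: deterministic, every biotype with
    n*weight >= 0.5 is guaranteed to appear."""
    items = sorted(weights.items())
    total = sum(w for _, w in items)
    raw = [(bt, n * w / total) for bt, w in items]
    counts = {bt: int(x) for bt, x in raw}
    short = n - sum(counts.values())
    for bt, _ in sorted(raw, key=lambda t: -(t[1] - int(t[1])))[:short]:
        counts[bt] += 1
    out = []
    for bt, c in counts.items():
        out.extend([bt] * c)
    return out


def simulate_annotation(
    n_genes_per_species: int = 60,
    seed: int = 0,
    biotype_weights: Optional[dict] = None,
    genes_per_chrom: int = 30,
) -> ToyAnnotation:
    """Generate a reproducible two-species toy annotation and genome.

    Protein-coding and lncRNA genes are multi-exon with introns roughly four
    times the exonic length (so random-primed, intron-inclusive libraries are
    intron-dominated); short non-coding biotypes are single-exon.
    """
    if n_genes_per_species < 1:
        raise ValueError("need at least one gene per species")
    weights = dict(biotype_weights or DEFAULT_BIOTYPE_WEIGHTS)
    rng = np.random.default_rng(seed)
    genes: list = []
    chrom_seqs: dict = {}
    for species in ("A", "B"):
        biotypes = _allocate_biotypes(n_genes_per_species, weights)
        rng.shuffle(biotypes)
        n_chroms = max(1, math.ceil(n_genes_per_species / genes_per_chrom))
        per_chrom = np.array_split(np.arange(n_genes_per_species), n_chroms)
        gi = 0
        for ci, idxs in enumerate(per_chrom):
            chrom = f"chr{species}{ci + 1}"
            pos = int(rng.integers(500, 2000))
            for _ in idxs:
                bt = biotypes[gi]
                gid = f"g{species}{gi + 1:04d}"
                gi += 1
                if bt in ("protein_coding", "lncRNA"):
                    n_exons = 2 + int(rng.poisson(2.0))
                    exon_lens = np.maximum(
                        80, rng.lognormal(math.log(220), 0.5, n_exons)
                    ).astype(int)
                    intron_lens = np.maximum(
                        400, rng.lognormal(math.log(2000), 0.55, n_exons - 1)
                    ).astype(int)
                elif bt in ("mito", "ribo"):
                    n_exons = 1
                    exon_lens = np.array([int(rng.integers(800, 2000))])
                    intron_lens = np.array([], dtype=int)
                else:  # short non-coding
                    n_exons = 1
                    exon_lens = np.array([int(rng.integers(80, 300))])
                    intron_lens = np.array([], dtype=int)
                exons = []
                p = pos
                for i in range(n_exons):
                    exons.append((p, p + int(exon_lens[i])))
                    p += int(exon_lens[i])
                    if i < n_exons - 1:
                        p += int(intron_lens[i])
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(Gene(gid, species, bt, chrom, pos, p, strand, exons))
                pos = p + int(rng.integers(500, 2000))
            chrom_seqs[chrom] = random_dna(rng, pos + 500)
    return ToyAnnotation(genes=genes, chrom_seqs=chrom_seqs)


# ---------------------------------------------------------------------------
# Library configuration
# ---------------------------------------------------------------------------

@dataclass
class LibraryConfig:
    """Knobs of the generative model; defaults define the study conditions.

    ``mean_nuclei_per_droplet`` is the Poisson loading rate lambda;
    ``k_tubes`` the number of pre-indexed RT tubes; ``unspliced_fraction``
    the probability a molecule is nascent (intron-bearing pre-mRNA), set so
    that with the default annotation intronic reads outnumber exonic roughly
    3:1; ``oligodt_fraction`` the share of molecules primed by the extra
    oligo(dT) primer (3'-anchored) rather than random hexamer-like primers.
    """

    n_nuclei_a: int = 250
    n_nuclei_b: int = 250
    k_tubes: int = 10
    mean_nuclei_per_droplet: float = 0.06
    reads_per_nucleus: float = 400.0
    mean_molecules_per_nucleus: float = 200.0
    unspliced_fraction: float = 0.88
    oligodt_fraction: float = 0.15
    fragment_len_meanlog: float = math.log(450.0)   # mode ~400 bp, in 300-800
    fragment_len_sdlog: float = 0.35
    fragment_len_min: int = 60
    da_tail_mean: float = 12.0
    da_tail_min: int = 8
    substitution_error_rate: float = 0.005
    ambient_read_fraction: float = 0.05
    read1_len: int = 150
    read2_len: int = 150
    seed: int = 0

    def __post_init__(self):
        for name in ("unspliced_fraction", "oligodt_fraction",
                     "substitution_error_rate", "ambient_read_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.mean_nuclei_per_droplet <= 0:
            raise ValueError("mean_nuclei_per_droplet must be > 0")
        if self.n_nuclei_a < 0 or self.n_nuclei_b < 0 or \
                self.n_nuclei_a + self.n_nuclei_b == 0:
            raise ValueError("need at least one nucleus")
        if self.k_tubes < 1:
            raise ValueError("k_tubes must be >= 1")

    @property
    def n_nuclei(self) -> int:
        return self.n_nuclei_a + self.n_nuclei_b

    def to_yaml(self, path) -> None:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "LibraryConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def collision_rate(lam: float) -> float:
    """P(>=2 nuclei | >=1 nucleus) for Poisson(lam) droplet occupancy."""
    if lam <= 0:
        return 0.0
    p0 = math.exp(-lam)
    p1 = lam * p0
    return (1.0 - p0 - p1) / (1.0 - p0)


def lambda_for_collision_rate(target: float) -> float:
    """Poisson loading rate whose physical-collision fraction equals target."""
    from scipy.optimize import brentq

    if not 0 < target < 1:
        raise ValueError("target collision rate must be in (0, 1)")
    return float(brentq(lambda l: collision_rate(l) - target, 1e-9, 50.0))


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionProfiles:
    """Per-nucleus molecule counts (Gamma-Poisson), species-exclusive."""

    nucleus_ids: list
    species: np.ndarray          # '<U1' per nucleus
    gene_ids: list
    spliced: np.ndarray          # (n_nuclei, n_genes) int
    unspliced: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.spliced + self.unspliced


def simulate_expression(
    annotation: ToyAnnotation,
    config: LibraryConfig,
    rng: Optional[np.random.Generator] = None,
    gene_weights: Optional[np.ndarray] = None,
) -> ExpressionProfiles:
    """Draw molecule counts for every nucleus.

    Gene propensities are Gamma(0.8) draws normalised within each species
    (``gene_weights`` lets two libraries share one propensity vector, e.g.
    for technical-replicate simulations); per-nucleus totals get a log-normal
    size factor; counts are Poisson; each molecule is independently nascent
    (unspliced) with probability ``unspliced_fraction``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    gene_ids = annotation.gene_ids
    species_of_gene = np.array([g.species for g in annotation.genes])
    n_genes = len(gene_ids)

    if gene_weights is None:
        factors = np.array([BIOTYPE_EXPRESSION_FACTOR.get(g.biotype, 1.0)
                            for g in annotation.genes])
        gene_weights = rng.gamma(0.8, 1.0, n_genes) * factors
    gene_weights = np.asarray(gene_weights, dtype=float)
    w = gene_weights.copy()
    for sp in ("A", "B"):
        mask = species_of_gene == sp
        if mask.any() and w[mask].sum() > 0:
            w[mask] /= w[mask].sum()

    nucleus_ids, species = [], []
    for sp, n in (("A", config.n_nuclei_a), ("B", config.n_nuclei_b)):
        nucleus_ids += [f"n{sp}{i + 1:05d}" for i in range(n)]
        species += [sp] * n
    species = np.array(species)

    size = rng.lognormal(0.0, 0.35, len(nucleus_ids))
    lam = (config.mean_molecules_per_nucleus * size)[:, None] * w[None, :]
    lam *= (species[:, None] == species_of_gene[None, :])
    counts = rng.poisson(lam)
    unspliced = rng.binomial(counts, config.unspliced_fraction)
    return ExpressionProfiles(nucleus_ids, species, gene_ids,
                              (counts - unspliced).astype(np.int64),
                              unspliced.astype(np.int64))


# ---------------------------------------------------------------------------
# Droplets
# ---------------------------------------------------------------------------

@dataclass
class DropletMap:
    """Assignment of nuclei to pre-index tubes, droplets and bead barcodes."""

    per_nucleus: pd.DataFrame    # nucleus_id, species, tube, preindex, droplet_id, barcode, cell_id
    per_droplet: pd.DataFrame    # droplet_id, barcode, n_nuclei, n_tubes, physical_doublet, observed_doublet

    @property
    def physical_collision_rate(self) -> float:
        return float(self.per_droplet["physical_doublet"].mean())

    @property
    def observed_doublet_rate(self) -> float:
        return float(self.per_droplet["observed_doublet"].mean())


def _truncated_poisson_sizes(rng, lam: float, n_items: int) -> np.ndarray:
    """Droplet occupancy counts ~ Poisson(lam) conditioned on >=1, drawn until
    they cover n_items (the last droplet keeps the remainder)."""
    sizes = []
    covered = 0
    while covered < n_items:
        draw = rng.poisson(lam, size=max(64, int(2 * n_items / max(lam, 0.05))))
        for s in draw[draw > 0]:
            s = int(min(s, n_items - covered))
            sizes.append(s)
            covered += s
            if covered >= n_items:
                break
    return np.array(sizes, dtype=int)


def simulate_droplets(
    profiles: ExpressionProfiles,
    whitelist: BarcodeWhitelist,
    config: LibraryConfig,
    rng: Optional[np.random.Generator] = None,
) -> DropletMap:
    """Split nuclei over K pre-index tubes, co-encapsulate them in droplets
    with truncated-Poisson occupancy, and give each droplet a unique bead
    barcode.  A droplet is a *physical* collision when it holds >=2 nuclei and
    an *observed* doublet only when >=2 of its nuclei also share a tube
    (identical pre-index) — the mechanism by which pre-indexing thins the
    doublet rate by ~1/K."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = len(profiles.nucleus_ids)
    K = config.k_tubes
    if K > 1:
        if len(whitelist.preindexes) < K:
            raise ValueError(
                f"whitelist has {len(whitelist.preindexes)} pre-indexes, "
                f"config asks for {K} tubes")
        preindexes = whitelist.preindexes[:K]
    else:
        preindexes = whitelist.preindexes[:1] or [""]

    tube = rng.integers(0, K, n)
    order = rng.permutation(n)
    sizes = _truncated_poisson_sizes(rng, config.mean_nuclei_per_droplet, n)
    n_droplets = len(sizes)
    if n_droplets > len(whitelist.accepted):
        raise ValueError(
            f"whitelist capacity {len(whitelist.accepted)} < {n_droplets} droplets")
    bc_idx = rng.choice(len(whitelist.accepted), n_droplets, replace=False)
    barcodes = [whitelist.accepted[i] for i in bc_idx]

    droplet_of = np.empty(n, dtype=int)
    pos = 0
    for d, s in enumerate(sizes):
        droplet_of[order[pos : pos + s]] = d
        pos += s

    per_nucleus = pd.DataFrame({
        "nucleus_id": profiles.nucleus_ids,
        "species": profiles.species,
        "tube": tube,
        "preindex": [preindexes[t] for t in tube],
        "droplet_id": droplet_of,
        "barcode": [barcodes[d] for d in droplet_of],
    })
    per_nucleus["cell_id"] = per_nucleus["preindex"] + per_nucleus["barcode"]

    grp = per_nucleus.groupby("droplet_id")["tube"]
    n_nuclei = grp.size()
    n_tubes = grp.nunique()
    per_droplet = pd.DataFrame({
        "droplet_id": n_nuclei.index,
        "barcode": [barcodes[d] for d in n_nuclei.index],
        "n_nuclei": n_nuclei.values,
        "n_tubes": n_tubes.values,
    })
    per_droplet["physical_doublet"] = per_droplet["n_nuclei"] >= 2
    per_droplet["observed_doublet"] = per_droplet["n_nuclei"] > per_droplet["n_tubes"]
    return DropletMap(per_nucleus=per_nucleus, per_droplet=per_droplet)


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

@dataclass
class TruthTable:
    """Ground truth: one row per emitted read, plus droplet and nucleus layers."""

    reads: pd.DataFrame
    droplets: pd.DataFrame
    nuclei: pd.DataFrame

    def write_tsv(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.reads.to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
        self.droplets.to_csv(outdir / "truth_droplets.tsv", sep="\t", index=False)
        self.nuclei.to_csv(outdir / "truth_nuclei.tsv", sep="\t", index=False)

    def molecule_counts(self) -> pd.DataFrame:
        """Captured molecules per (cell_id, gene): distinct truth UMIs."""
        df = self.reads[self.reads["gene_id"] != "intergenic"]
        return (df.groupby(["cell_id", "gene_id"])["umi"]
                  .nunique().rename("molecules").reset_index())


@dataclass
class Library:
    """An in-memory simulated paired-end library."""

    r1: list                  # (read_id, sequence)
    r2: list
    truth: TruthTable
    config: LibraryConfig
    structure: ReadStructure

    def write_fastq(self, r1_path, r2_path, quality_char: str = "F") -> None:
        for path, records in ((r1_path, self.r1), (r2_path, self.r2)):
            opener = gzip_mod.open if str(path).endswith(".gz") else open
            with opener(path, "wt") as fh:
                for rid, seq in records:
                    fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")

    def truth_alignments(self) -> pd.DataFrame:
        """Truth-mode alignment records (what a perfect aligner would report)."""
        cols = ["read_id", "chrom", "start", "end", "strand", "blocks"]
        return self.truth.reads[cols].copy()


def _blocks_str(blocks) -> str:
    return ",".join(f"{a}-{b}" for a, b in blocks)


def _draw_umi(rng, existing: list) -> str:
    """UMI resolvable (Hamming >= 2) against UMIs already in its group."""
    while True:
        umi = random_dna(rng, 8)
        ok = True
        for other in existing:
            d = sum(a != b for a, b in zip(umi, other))
            if d <= 1:
                ok = False
                break
        if ok:
            return umi


def _place_fragment(rng, gene: Gene, spliced: bool, is_dt: bool,
                    config: LibraryConfig):
    """Choose the fragment window; return (blocks, region, insert-sense seq
    coordinates as (chrom, gstart, gend, blocks))."""
    T = gene.spliced_len if spliced else gene.unspliced_len
    L = int(np.clip(round(rng.lognormal(config.fragment_len_meanlog,
                                        config.fragment_len_sdlog)),
                    config.fragment_len_min, None))
    L = min(L, T) if T < config.fragment_len_min else L
    if is_dt:
        a, b = max(0, T - L), T
    else:
        s = int(rng.integers(-(L - 1), T)) if L > 1 else int(rng.integers(0, T))
        a, b = max(0, s), min(T, s + L)
        if a >= b:                       # fully-overhanging corner case
            a, b = 0, min(L, T)
    if spliced:
        la, lb = gene.sense_spliced_to_left(a, b)
        blocks = gene.spliced_window_to_blocks(la, lb)
        region = "exon"
    else:
        ga, gb = gene.sense_body_to_genomic(a, b)
        blocks = [(ga, gb)]
        region = "exon"
        for isv, iev in gene.introns:
            if ga < iev and isv < gb:
                region = "intron"
                break
    return blocks, region


def _insert_seq(annotation: ToyAnnotation, gene: Gene, blocks) -> str:
    seq = "".join(annotation.chrom_seqs[gene.chrom][a:b] for a, b in blocks)
    return revcomp(seq) if gene.strand == "-" else seq


def simulate_reads(
    annotation: ToyAnnotation,
    profiles: ExpressionProfiles,
    droplets: DropletMap,
    structure: ReadStructure,
    config: LibraryConfig,
    whitelist: BarcodeWhitelist,
    rng: Optional[np.random.Generator] = None,
) -> Library:
    """Emit the paired-end library.

    Per nucleus, Poisson(reads_per_nucleus) reads sample that nucleus's
    molecules with replacement; only sampled ("captured") molecules receive a
    UMI and a fragment placement.  Read1 = barcode + UMI + poly(T) dA-tail
    junction + insert-proximal bases; Read2 = pre-index + insert.  Ambient
    reads (fraction ``ambient_read_fraction`` of the library) carry a valid
    bead barcode drawn uniformly from the whitelist and a random gene from
    either species.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    genes = annotation.genes
    min_r2 = structure.preindex_len + 1
    if config.read2_len < min_r2 or config.read1_len < structure.r1_min_len + 1:
        raise ValueError("configured read lengths shorter than the structural minimum")

    pn = droplets.per_nucleus.set_index("nucleus_id")
    rows = []          # truth rows (dict) in emission order
    r1_parts, r2_parts = [], []

    def emit(cell_pre, cell_bc, umi, gene: Gene, blocks, region, spliced,
             droplet_id, nucleus_id):
        insert = _insert_seq(annotation, gene, blocks)
        tail = config.da_tail_min + int(rng.geometric(
            1.0 / max(1.0, config.da_tail_mean - config.da_tail_min + 1.0))) - 1
        r1 = (cell_bc + umi + structure.r1_junction_base * tail +
              revcomp(insert))[: config.read1_len]
        r2 = (cell_pre + insert +
              structure.r2_tail_trim_base * tail)[: config.read2_len]
        r1_parts.append(r1)
        r2_parts.append(r2)
        rows.append({
            "droplet_id": droplet_id, "nucleus_id": nucleus_id,
            "cell_id": cell_pre + cell_bc, "gene_id": gene.gene_id,
            "region": region, "spliced": bool(spliced), "umi": umi,
            "chrom": gene.chrom, "start": blocks[0][0], "end": blocks[-1][1],
            "strand": gene.strand, "blocks": _blocks_str(blocks),
        })

    gene_idx_by_col = {i: genes[i] for i in range(len(genes))}
    spl, uns = profiles.spliced, profiles.unspliced
    for ni, nucleus_id in enumerate(profiles.nucleus_ids):
        total_row = spl[ni] + uns[ni]
        M = int(total_row.sum())
        if M == 0:
            continue
        n_reads = int(rng.poisson(config.reads_per_nucleus))
        if n_reads == 0:
            continue
        gene_of_mol = np.repeat(np.arange(len(genes)), total_row)
        spliced_of_mol = np.zeros(M, dtype=bool)
        off = 0
        for gi in np.flatnonzero(total_row):
            spliced_of_mol[off : off + spl[ni, gi]] = True
            off += total_row[gi]
        picks = rng.integers(0, M, n_reads)
        uniq, counts = np.unique(picks, return_counts=True)

        info = pn.loc[nucleus_id]
        umis_per_gene: dict = {}
        for mol, n_dup in zip(uniq, counts):
            gene = gene_idx_by_col[int(gene_of_mol[mol])]
            is_spliced = bool(spliced_of_mol[mol])
            group = umis_per_gene.setdefault(gene.gene_id, [])
            umi = _draw_umi(rng, group)
            group.append(umi)
            is_dt = rng.random() < config.oligodt_fraction
            blocks, region = _place_fragment(rng, gene, is_spliced, is_dt, config)
            for _ in range(int(n_dup)):
                emit(info["preindex"], info["barcode"], umi, gene, blocks,
                     region, is_spliced, int(info["droplet_id"]), nucleus_id)

    # ambient background
    n_nuc_reads = len(rows)
    a = config.ambient_read_fraction
    n_amb = int(round(n_nuc_reads * a / (1.0 - a))) if a > 0 else 0
    preindex_pool = (whitelist.preindexes[: config.k_tubes]
                     if whitelist.preindexes else [""])
    for _ in range(n_amb):
        gene = genes[int(rng.integers(0, len(genes)))]
        is_spliced = rng.random() >= config.unspliced_fraction
        is_dt = rng.random() < config.oligodt_fraction
        blocks, region = _place_fragment(rng, gene, is_spliced, is_dt, config)
        umi = random_dna(rng, structure.umi_len)
        bc = whitelist.accepted[int(rng.integers(0, len(whitelist.accepted)))]
        pre = preindex_pool[int(rng.integers(0, len(preindex_pool)))]
        emit(pre, bc, umi, gene, blocks, region, is_spliced, -1, "ambient")

    # shuffle, name, inject sequencing errors
    n_total = len(rows)
    order = rng.permutation(n_total)
    reads_df = pd.DataFrame([rows[i] for i in order])
    reads_df.insert(0, "read_id", [f"r{i + 1:08d}" for i in range(n_total)])
    r1_seqs = [r1_parts[i] for i in order]
    r2_seqs = [r2_parts[i] for i in order]

    e = config.substitution_error_rate
    if e > 0:
        for seqs in (r1_seqs, r2_seqs):
            lens = np.fromiter((len(s) for s in seqs), dtype=int, count=n_total)
            n_err = rng.binomial(lens, e)
            for i in np.flatnonzero(n_err):
                s = list(seqs[i])
                for p in rng.choice(len(s), size=n_err[i], replace=False):
                    alt = "ACGT".replace(s[p], "")
                    s[p] = alt[int(rng.integers(0, 3))]
                seqs[i] = "".join(s)

    rids = reads_df["read_id"].tolist()
    truth = TruthTable(
        reads=reads_df,
        droplets=droplets.per_droplet.copy(),
        nuclei=droplets.per_nucleus.copy(),
    )
    return Library(r1=list(zip(rids, r1_seqs)), r2=list(zip(rids, r2_seqs)),
                   truth=truth, config=config, structure=structure)


def simulate_library(
    annotation: ToyAnnotation,
    whitelist: BarcodeWhitelist,
    config: LibraryConfig,
    structure: Optional[ReadStructure] = None,
    gene_weights: Optional[np.ndarray] = None,
) -> Library:
    """Convenience front-end: expression -> droplets -> reads from one seed."""
    structure = structure or ReadStructure(preindex_len=whitelist.preindex_len)
    rng = np.random.default_rng(config.seed)
    profiles = simulate_expression(annotation, config, rng, gene_weights)
    droplets = simulate_droplets(profiles, whitelist, config, rng)
    return simulate_reads(annotation, profiles, droplets, structure, config,
                          whitelist, rng)
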