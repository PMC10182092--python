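# snrandom

Simulation and computational validation of **pre-indexed, random-primed
droplet single-nucleus RNA-seq** (snRandom-seq-style) libraries.

In this chemistry, total nuclear RNA — including non-polyadenylated and
intronic sequence — is captured by random-primer reverse transcription inside
nuclei that were first split across *K* pre-indexed RT tubes, then pooled.
First-strand cDNAs receive a poly(dA) tail; inside droplets, barcoded
poly(dT) bead primers anneal to that tail and append a 30-nt split-pool cell
barcode and an 8-nt UMI. Because co-encapsulated nuclei usually come from
different tubes, pre-indexing thins the observed doublet rate roughly by
1/K relative to the physical collision rate.

`snrandom` provides both sides of the computational problem:

* a **generative simulator** of such libraries with complete ground truth
  (two-species barnyard mixtures, Poisson droplet co-occupancy, dA-tail
  junctions, random vs. oligo(dT) priming, substitution errors, ambient
  background), and
* the **processing pipeline**: demultiplexing with Hamming-bounded
  unique-assignment barcode correction, gene-body read assignment,
  directional UMI deduplication into spliced/unspliced count matrices,
  barcode-rank knee calling, and the standard QC metrics (barnyard doublet
  statistics, exon/intron fractions, gene-body coverage, saturation,
  filtering, pseudobulk correlation).

It is aimed at method developers and pipeline engineers who need a testable,
truth-annotated model of this chemistry.

## The model in brief

**Read anatomy.** Read1 = `barcode(30 nt) + UMI(8 nt) + poly(T) run + cDNA`;
Read2 = `pre-index(p nt) + cDNA (+ dA-tail read-through)`. The 30-nt barcode
is the concatenation of three split-pool rounds; the accepted set *W* is the
product of the round sets.

**Barcode correction.** An observed barcode *b* is merged into *w ∈ W* iff
*w* is the *unique* accepted barcode with Hamming distance d(b, w) ≤ d_max
(default 2); two or more candidates within d_max ⇒ rejected as ambiguous.
If the whitelist separation satisfies min-pairwise-distance ≥ 2·d_max + 1,
no observation with ≤ d_max errors is ever miscorrected.

**Doublet thinning.** With droplet occupancy ~ Poisson(λ) conditioned on ≥ 1
nucleus, the physical collision rate is
P(k ≥ 2 | k ≥ 1) = (1 − e^(−λ) − λe^(−λ)) / (1 − e^(−λ)); an observed
(barnyard-visible) doublet additionally requires two co-encapsulated nuclei
to share a pre-index, which happens with probability 1/K per pair.

**Counting.** Reads are assigned to whole gene bodies (exon *and* intron —
random priming makes nuclear libraries intron-dominated); molecules are UMI
clusters per (cell, gene) under directional collapse (merge neighbours at
Hamming 1 when counts satisfy n₁ ≥ 2·n₂ − 1); a molecule is *spliced* when
all its reads are exonic and *unspliced* when any read overlaps an intron.

## Worked example

```python
import numpy as np
from snrandom import (LibraryConfig, build_whitelist, simulate_annotation,
                      simulate_library)
from snrandom.demux import demux_to_frame
from snrandom.quantify import assign_frame, count_matrix, load_truth_alignments
from snrandom.cellcall import call_knee, rank_barcodes
from snrandom.qc import barnyard, region_fractions

# 3 split-pool rounds x 12 segments -> 1,728 accepted barcodes; 10 pre-index tubes
wl = build_whitelist([round1, round2, round3], preindexes)   # segment lists

ann = simulate_annotation(n_genes_per_species=60, seed=1)
lib = simulate_library(ann, wl, LibraryConfig(n_nuclei_a=100, n_nuclei_b=100, seed=1))
lib.write_fastq("scratch/R1.fastq", "scratch/R2.fastq")

frame, report = demux_to_frame("scratch/R1.fastq", "scratch/R2.fastq",
                               lib.structure, wl)
records = load_truth_alignments(lib.truth_alignments(), frame)
assigned, assign_report = assign_frame(records, ann)
cm = count_matrix(assigned, ann)
call = call_knee(rank_barcodes(cm, metric="genes"))
```

Output (printed by the snippet above with the bundled defaults):

```
reads=84505  valid=84443 (99.93%)  corrected=13766
exon=29.2%  intron=70.8%  intron:exon=2.42
barcodes=3917  nuclei called=200 (method=knee)
median genes/nucleus=41  median UMIs/nucleus=174
doublet rate=0.00%  specificity medians={'A': 1.0, 'B': 1.0}
```

Reading: 99.93 % of read pairs carried a barcode assignable within Hamming
distance 2 (13,766 needed correction); intronic reads dominate ~2.4:1, as
expected for random-primed nuclear RNA at this configuration; the knee
caller separated the 200 true nuclei from ~3,700 ambient barcodes; and with
100 + 100 nuclei of two species at λ = 0.06 and K = 10 tubes, no barnyard
doublet survives pre-indexing in a library this small.

The same flow is available from the shell:

```bash
snrandom sim library --n-genes 60 --seed 1 --out lib/
snrandom demux --r1 lib/R1.fastq --r2 lib/R2.fastq \
    --rounds lib/whitelist_round1.txt --rounds lib/whitelist_round2.txt \
    --rounds lib/whitelist_round3.txt --preindex lib/preindexes.txt \
    --out tagged.tsv --report demux.json
snrandom quant --tagged tagged.tsv --alignments lib/alignments.tsv \
    --gtf lib/annotation.gtf --out matrix/
snrandom cells --matrix matrix/ --out called.txt
snrandom qc barnyard --matrix matrix/
```

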