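# Methods

This note documents the generative model behind `snrandom.simulate`, the
processing algorithms built on top of it, the parameter defaults and the
reasoning behind the genuinely open design choices. Nothing here asserts an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. The chemistry being modelled

A pre-indexed, random-primed droplet snRNA-seq library is built in four
conceptual steps, each mirrored by a simulator stage:

1. **Pre-indexed reverse transcription.** Nuclei are split uniformly across
   *K* RT tubes; the random primers in tube *k* carry a tube-specific
   pre-index that ends up at position 0 of Read2. Random priming samples the
   whole transcript — including introns of nascent (unspliced) transcripts —
   without 3′ bias; an extra oligo(dT) primer fraction anneals at the 3′
   end.
2. **dA tailing.** First-strand cDNAs receive a poly(dA) tail; on Read1 this
   appears as a poly(T) run between the UMI and the insert, and on Read2 as
   a possible poly(A) read-through at the 3′ end.
3. **Droplet barcoding.** Pooled nuclei are encapsulated with barcoded
   hydrogel beads. Droplet occupancy is Poisson(λ) conditioned on at least
   one nucleus; each occupied droplet carries exactly one bead whose 30-nt
   barcode is the concatenation of three split-pool ligation rounds. Every
   cDNA in a droplet gets the bead barcode plus its own 8-nt UMI.
4. **Sequencing.** Paired-end reads with uniform substitution errors;
   base qualities are a constant placeholder (Q37) because no downstream
   step uses them.

The *cell identifier* is the pair (pre-index, bead barcode). Two nuclei in
one droplet are indistinguishable — an *observed doublet* — only when they
also share a pre-index; for small λ this thins the doublet rate by ≈ 1/K
(triple occupancy adds a positive correction of order λ/3, which is why the
1/K law is only asserted in the ~3 %-collision regime).

## 2. Generative model, stage by stage

**Annotation** (`simulate_annotation`). Two species (A, B) on disjoint
chromosomes; default 60 genes per species. Biotypes are allocated
deterministically by largest remainder from configurable weights (default
70 % protein-coding, 12 % lncRNA, the remainder split over snoRNA, snRNA,
miRNA, misc RNA, mitochondrial and ribosomal classes), so every biotype with
n·w ≥ 0.5 is guaranteed to appear. Protein-coding/lncRNA genes have 2 +
Poisson(2) exons (exon lengths ≈ lognormal, median ~220 nt, min 80) and
introns ≈ lognormal, median ~2,000 nt (min 400): introns are roughly four
times the exonic length, which is what makes a random-primed nuclear
library intron-dominated. Short non-coding genes are single-exon (80–300
nt); mito/ribo genes single-exon 800–2,000 nt. Chromosome sequences are
i.i.d. random DNA. Coordinates are 0-based half-open throughout;
transcript-sense positions respect strand.

**Expression** (`simulate_expression`). Gamma–Poisson: per-gene propensities
~ Gamma(shape 0.8) multiplied by a biotype expression factor (1.0 for
protein-coding/lncRNA, 0.5 mito/ribo, 0.3 short non-coding), normalised
within species; per-nucleus lognormal size factor (σ = 0.35) times
`mean_molecules_per_nucleus`; Poisson counts. A molecule is nascent
(unspliced) independently with probability *u*. Nuclei express only their
own species' genes — the barnyard construction.

**Droplets** (`simulate_droplets`). Occupancy sizes are drawn from the
zero-truncated Poisson until all nuclei are placed; each droplet draws a
distinct bead barcode (error if the whitelist is smaller than the droplet
count). Truth flags: `physical_doublet` (≥ 2 nuclei) and `observed_doublet`
(≥ 2 nuclei sharing a tube).

**Reads** (`simulate_reads`). One molecule = one cDNA: it receives exactly
one UMI and one fragment placement; Poisson(`reads_per_nucleus`) reads per
nucleus sample molecules with replacement, so repeated reads of a molecule
are PCR-style duplicates (identical coordinates, independent sequencing
errors) and only *captured* (sampled) molecules exist in the truth table.
Fragment length is lognormal (mode ≈ 400 bp, within the 300–800 bp library
peak). Random priming places the fragment window uniformly over the
transcript *allowing overhang at both ends* (clipped); this makes expected
per-base coverage exactly uniform, with terminal fragments shorter — the
behaviour a flat gene-body profile diagnoses. The oligo(dT) fraction *q*
anchors the window at the 3′ end. Unspliced molecules use gene-body
coordinates (intron-inclusive); spliced molecules use spliced-transcript
coordinates and map back to exon blocks. Ambient reads (fraction *a* of the
library) each carry a valid bead barcode drawn uniformly from the whole
whitelist, a uniform random gene from either species and a free UMI — they
produce the low shoulder of the barcode-rank curve.

**UMI resolvability.** Within one (nucleus, gene) group, molecule UMIs are
rejection-sampled to pairwise Hamming distance ≥ 2. Hamming-1 collisions
between molecules of the same cell and gene are unresolvable *in principle*
by any deduplicator, so excluding them keeps "molecules captured" a
well-defined ground truth that the pipeline can be required to recover
exactly; the cost is that the simulator does not reproduce the small
(sub-percent at these group sizes) collision undercount of real libraries.

## 3. Processing algorithms

**Homopolymer runs** (Read1 junction, Read2 tail trim). A run extends
greedily, tolerating isolated mismatches up to 1 per started 10 nt, but two
*consecutive* mismatches end it — without this, a tolerant run creeps into
genuine insert sequence that merely starts with one matching base. The run
must end on a matching base. Read1 requires ≥ 6 nt; Read2 trims a trailing
run of ≥ 4 nt. Note the inherent ambiguity: genuine terminal A's of a
transcript adjacent to the dA tail are trimmed with it.

**Barcode correction.** Unique assignment: exact membership wins; otherwise
the observation is accepted only if exactly one whitelist barcode lies
within d_max = 2 (pre-index: d_pre = 1). Two candidates within the radius ⇒
ambiguous, even when one is strictly nearer; a `nearest` mode relaxes this
behind a flag. Length-mismatched observations are counted as malformed, not
raised. The implementation (set lookup, then a vectorised distance scan) is
required by tests to agree exactly with an exhaustive per-read Hamming
scan. `min_pairwise_dist` of a product whitelist equals the minimum over
rounds of each round's internal minimum pairwise distance (differing in one
round achieves it; differing in more only adds distance), so the large-
whitelist shortcut is exact, not a bound.

**Demultiplexing.** Pairing is positional with id verification; any
mismatch is a hard error. Each pair yields exactly one tagged read or one
counted rejection (malformed / ambiguous / no-match), so
valid + ambiguous + no_match + malformed = total on every run. A read is
valid only if *both* barcode and pre-index resolve. Rejected reads are
dropped with counters.

**Assignment and counting.** Reads are assigned to whole gene bodies
("GeneFull"-style): exon-only counting would discard the intron-dominated
majority of the signal. Region: `exon` iff all alignment blocks fall in
exonic sequence; `intron` iff any block overlaps an intron; `intergenic`
otherwise (e.g. an overhang past the gene end). Reads overlapping ≥ 2 gene
bodies are discarded and counted; strand is ignored (random-primed second-
strand chemistry leaves the strand of origin ambiguous). UMI deduplication
is directional single-linkage at Hamming 1 (merge u→v when
count(u) ≥ 2·count(v) − 1), nodes visited by decreasing count with
lexicographic tie-break — fully deterministic; an exact-match mode exists
behind a flag. Molecule layers: all-exonic → `spliced`; any intronic →
`unspliced`; multi-read molecules with mixed exon/overhang evidence →
`ambiguous`; a single-read molecule is never ambiguous (a lone non-exonic
read is treated as unspliced evidence). Layers always sum to the total.

**Nucleus calling** (`call_knee`). The rank curve (default metric: genes
detected; ties broken lexicographically) is resampled onto a 512-point
uniform log₁₀(rank) grid — the raw curve is piecewise constant, so slopes
are meaningless without this — and smoothed with a 15-point running median.
The knee is the point of maximum perpendicular distance to the chord
joining the endpoints; it must be unique and have relative prominence
≥ 0.05, else the caller falls back to an expected-cell-count quantile rule
(99th percentile of the top-N values / 10) or raises `NoKneeError`
(likewise for curves spanning < 1 decade). The *calling threshold* is not
the value at the knee rank: on realistic (lognormal) populations that rank
sits partway down the upper population's tail and would drop a quarter of
the true nuclei. Instead the threshold is the geometric mean of the
smoothed values half a window above and below the steepest grid point after
the knee (the cliff; the last 5 % of the grid is excluded because rank
compression makes the integer-valued deep tail artificially steep). The
whole construction is scale-invariant, so uniform rescaling of the metric
leaves the called set unchanged; ties at the threshold are included.
Measured on 20-seed two-population curves across five separation regimes,
recall ≥ 0.9996 with ambient contamination ≤ 0.04 %.

**QC.** Barnyard specificity s_c = max(A, B)/(A + B) ∈ [0.5, 1]; a barcode
is a doublet when its minor-species fraction ≥ t_minor = 0.1 — the
threshold is an explicit stand-in (the chemistry's reported specificities
put singlets far from this boundary) and is configurable. Gene-body
coverage projects exon-contained blocks of reads on transcripts with
spliced length ≥ 500 nt onto 100 bins; per-gene bin vectors are computed in
genomic orientation and *flipped* for minus-strand genes (flipping the
vector, rather than reversing positions, makes strand reversal reverse the
profile exactly despite integer bin boundaries). Saturation subsamples
reads without replacement per fraction and re-runs the full dedup+count
pipeline; f = 1 keeps all rows in order and is bit-identical to the direct
run. Filtering applies, in one pass: exclusion lists (mito/ribo gene ids
supplied as inputs, no name-pattern magic), then nuclei with < 200 detected
genes, then genes detected in < 3 nuclei. The single pass is not a fixpoint
in adversarial cases (removing rare genes could in principle push a nucleus
below threshold), but is idempotent on realistic matrices and matches the
stated order. Pseudobulk correlation: per-cell counts-per-10k, mean over
cells per gene, ln(x + 1), Pearson r over the gene-universe intersection
(< 10 shared genes is an error).

## 4. Parameter defaults (the packaged study conditions)

| parameter | default | unit | rationale |
|---|---|---|---|
| barcode_len / segments | 30 = 3×10 | nt | three split-pool rounds; segment split configurable (only the 30-nt total is fixed by the chemistry) |
| umi_len | 8 | nt | chemistry constant |
| preindex_len / d_pre | 6 / 1 | nt | not fixed by the chemistry description; configurable |
| d_max | 2 | nt | the unique-assignment merge radius |
| junction min run / tolerance | 6 / 1 per 10 | nt | tolerant of the ~0.5 % substitution regime |
| k_tubes (K) | 10 | — | ~10-fold doublet thinning |
| λ (mean nuclei/droplet) | 0.06 | — | physical collisions ≈ 3 %, observed ≈ 0.3 % at K = 10 |
| reads_per_nucleus | 400 | reads | toy scale; ~2 reads per captured molecule leaves detection unsaturated |
| mean_molecules_per_nucleus | 200 | molecules | toy scale |
| unspliced_fraction u | 0.88 | — | nuclear RNA is mostly nascent; with the default annotation this lands the intron:exon read ratio near 3:1 |
| oligodt_fraction q | 0.15 | — | a minor oligo(dT) component ⇒ slight 3′ bias |
| fragment length | lognormal(ln 450, 0.35) | bp | mode ≈ 400, inside the 300–800 bp library peak |
| dA tail | 8 + geometric, mean 12 | nt | enough to satisfy the junction detector |
| substitution_error_rate e | 0.005 | /base | Illumina-like |
| ambient_read_fraction a | 0.05 | — | produces a visible rank-plot shoulder |

Simulated problem sizes in the tests and the acceptance script (500 nuclei
× 400 reads; 4,000-nucleus droplet runs; 80-nucleus coverage libraries) are
the package's chosen toy scale: large enough for 3σ statistical bands,
small enough to run on one CPU in about a minute each.

## 5. What passing tests do and do not show

The simulator reproduces the *statistical structure* the pipeline must
handle: split-pool barcode space, Hamming-distributed errors, Poisson
collisions thinned by pre-indexing, intron-rich random priming vs
3′-anchored priming, duplicate reads per molecule, an ambient shoulder. It
deliberately does **not** model: indels (correction is Hamming-based),
position- or quality-dependent error profiles, PCR chimeras or
amplification bias, FFPE-specific degradation beyond the fragment-length
and error-rate knobs, genome/DNA contamination, sub-Poisson bead loading,
bead barcode synthesis errors, or UMI collisions within a gene (see §2).
Green tests therefore certify algorithmic correctness under the stated
model, not performance on any particular real library; quantities that are
properties of real tissue (capture rates, per-nucleus medians, doublet
percentages) are reported by the acceptance script as functions of the
configured conditions.

## 6. Numerical and degenerate-input conventions

Determinism everywhere: one `numpy` Generator seeded from the config drives
every draw; FASTQ output is byte-identical across runs. Rank-curve zeros
are clamped to 0.5 before log transform. Coverage profiles normalise to
sum 1 (±1e-9). Empty UMI groups count 0 molecules; an empty filter result
returns an empty matrix with an explicit report, not an exception; a
single-species barnyard matrix reports a null doublet rate with a warning;
a flat rank curve raises rather than calling nonsense.
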