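"""QC metrics: barnyard, regions, coverage, biotypes, saturation, filtering,
pseudobulk correlation."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from snrandom.qc import (FilterConfig, barnyard, biotype_counts, filter_matrix,
                         genebody_coverage, pseudobulk_correlation,
                         region_fractions, saturation)
from snrandom.quantify import (CountMatrix, assign_frame, count_matrix,
                               load_truth_alignments, matrix_from_profiles)
from snrandom.simulate import (Gene, LibraryConfig, ToyAnnotation,
                               simulate_expression, simulate_library)
from conftest import make_whitelist


def make_matrix(counts, species=None, biotype=None):
    """CountMatrix from a dense cell x gene array (all counts spliced)."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    genes = [f"g{i:03d}" for i in range(n_genes)]
    meta = pd.DataFrame({
        "gene_id": genes,
        "species": species or ["A"] * n_genes,
        "biotype": biotype or ["protein_coding"] * n_genes,
    }).set_index("gene_id")
    zero = sp.csr_matrix(counts.shape, dtype=np.int64)
    return CountMatrix(cells=[f"c{i:03d}" for i in range(n_cells)],
                       genes=genes, gene_meta=meta,
                       layers={"spliced": sp.csr_matrix(counts),
                               "unspliced": zero, "ambiguous": zero.copy()})


class TestBarnyard:
    def test_pure_cell_is_specific_singlet(self):
        cm = make_matrix([[10, 0], [0, 8]], species=["A", "B"])
        rep = barnyard(cm)
        assert rep.per_cell["specificity"].tolist() == [1.0, 1.0]
        assert not rep.per_cell["is_doublet"].any()
        assert rep.doublet_rate == 0.0

    def test_balanced_cell_is_doublet(self):
        cm = make_matrix([[5, 5]], species=["A", "B"])
        rep = barnyard(cm)
        assert rep.per_cell["specificity"].iloc[0] == 0.5
        assert rep.per_cell["is_doublet"].iloc[0]

    def test_doublet_rate_invariant_to_species_swap(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 20, (50, 6))
        cm_ab = make_matrix(counts, species=["A", "B", "A", "B", "A", "B"])
        cm_ba = make_matrix(counts, species=["B", "A", "B", "A", "B", "A"])
        assert barnyard(cm_ab).doublet_rate == barnyard(cm_ba).doublet_rate

    def test_specificity_bounded(self):
        rng = np.random.default_rng(6)
        cm = make_matrix(rng.integers(0, 30, (80, 4)),
                         species=["A", "A", "B", "B"])
        s = barnyard(cm).per_cell["specificity"].dropna()
        assert ((s >= 0.5) & (s <= 1.0)).all()

    def test_single_species_matrix_has_undefined_rate(self):
        cm = make_matrix([[3, 1]], species=["A", "A"])
        assert barnyard(cm).doublet_rate is None

    def test_preindex_thinning_visible_in_barnyard(self, annotation):
        """K=10 cuts the barnyard doublet rate ~10-fold vs K=1 at equal
        loading (truth-level check through the droplet layer)."""
        from snrandom.simulate import lambda_for_collision_rate, simulate_droplets

        wl = make_whitelist(round_size=24, seed=9)
        lam = lambda_for_collision_rate(0.03)   # small-lambda regime
        rates = {}
        for k in (1, 10):
            obs = phys = 0
            for seed in range(4):
                cfg = LibraryConfig(n_nuclei_a=2000, n_nuclei_b=2000,
                                    seed=100 + seed, k_tubes=k,
                                    mean_nuclei_per_droplet=lam)
                prof = simulate_expression(annotation, cfg)
                drops = simulate_droplets(prof, wl, cfg)
                obs += drops.per_droplet["observed_doublet"].sum()
                phys += drops.per_droplet["physical_doublet"].sum()
            rates[k] = obs / phys
        assert rates[1] == 1.0
        se = np.sqrt(0.1 * 0.9 / phys)
        assert abs(rates[10] - 0.1) <= 3 * se


class TestRegionFractions:
    def test_all_exonic(self):
        assert region_fractions({"exon": 10}) == \
            {"exon": 100.0, "intron": 0.0, "intergenic": 0.0}

    def test_partition_to_100(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            counts = {k: int(v) for k, v in
                      zip(("exon", "intron", "intergenic"),
                          rng.integers(1, 100, 3))}
            assert sum(region_fractions(counts).values()) == pytest.approx(100.0)

    def test_zero_reads_is_error(self):
        with pytest.raises(ValueError):
            region_fractions({"exon": 0})

    def test_frame_input(self):
        df = pd.DataFrame({"region": ["exon", "intron", "intron"]})
        out = region_fractions(df)
        assert out["intron"] == pytest.approx(200 / 3)


class TestGenebodyCoverage:
    def test_single_read_covers_its_bins_exactly(self):
        g = Gene("g1", "A", "protein_coding", "chr1", 0, 1000, "+",
                 exons=[(0, 1000)])
        ann = ToyAnnotation(genes=[g], chrom_seqs={})
        rec = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        prof = genebody_coverage(rec, ann, B=100, min_len=500)
        expected = np.zeros(100)
        expected[10:20] = 0.1
        assert np.allclose(prof.bins, expected)

    def test_profile_sums_to_one(self, clean_library, annotation):
        prof = genebody_coverage(clean_library.truth_alignments(), annotation)
        assert prof.bins.sum() == pytest.approx(1.0)

    def test_strand_reversal_reverses_profile(self):
        g = Gene("g1", "A", "protein_coding", "chr1", 0, 1000, "+",
                 exons=[(0, 1000)])
        g_rev = Gene("g1", "A", "protein_coding", "chr1", 0, 1000, "-",
                     exons=[(0, 1000)])
        rec = pd.DataFrame({"chrom": ["chr1"] * 3,
                            "start": [0, 450, 900], "end": [50, 500, 1000]})
        fwd = genebody_coverage(rec, ToyAnnotation(genes=[g], chrom_seqs={}))
        rev = genebody_coverage(rec, ToyAnnotation(genes=[g_rev], chrom_seqs={}))
        assert np.allclose(fwd.bins, rev.bins[::-1])

    def test_random_priming_gives_flat_profile(self, annotation, whitelist):
        cfg = LibraryConfig(n_nuclei_a=40, n_nuclei_b=40, seed=41,
                            reads_per_nucleus=500,
                            mean_molecules_per_nucleus=250,
                            oligodt_fraction=0.0, unspliced_fraction=0.0,
                            ambient_read_fraction=0.0,
                            substitution_error_rate=0.0)
        lib = simulate_library(annotation, whitelist, cfg)
        prof = genebody_coverage(lib.truth_alignments(), annotation)
        central = prof.bins[5:95]
        assert central.max() / central.min() <= 2.0

    def test_oligodt_priming_gives_3prime_enrichment(self, annotation,
                                                     whitelist):
        cfg = LibraryConfig(n_nuclei_a=30, n_nuclei_b=30, seed=42,
                            reads_per_nucleus=300,
                            oligodt_fraction=1.0, unspliced_fraction=0.0,
                            ambient_read_fraction=0.0,
                            substitution_error_rate=0.0)
        lib = simulate_library(annotation, whitelist, cfg)
        prof = genebody_coverage(lib.truth_alignments(), annotation)
        assert prof.bins[-10:].mean() > 3.0 * max(prof.bins[:10].mean(), 1e-12)

    def test_no_qualifying_transcripts_is_error(self):
        g = Gene("g1", "A", "miRNA", "chr1", 0, 100, "+", exons=[(0, 100)])
        ann = ToyAnnotation(genes=[g], chrom_seqs={})
        rec = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [50]})
        with pytest.raises(ValueError):
            genebody_coverage(rec, ann, min_len=500)


class TestBiotypeCounts:
    def test_only_lncRNA_counts_land_there(self):
        cm = make_matrix([[3, 0], [2, 0]], biotype=["lncRNA", "snoRNA"])
        out = biotype_counts(cm)
        assert out.loc["lncRNA", "genes_detected"] == 1
        assert out.loc["lncRNA", "umis"] == 5
        assert out.loc["snoRNA", "genes_detected"] == 0

    def test_zero_matrix_all_zero(self):
        cm = make_matrix(np.zeros((3, 4), dtype=int))
        out = biotype_counts(cm)
        assert out["genes_detected"].sum() == 0 and out["umis"].sum() == 0

    def test_totals_match_matrix_wide_detections(self):
        rng = np.random.default_rng(3)
        cm = make_matrix(rng.integers(0, 3, (10, 8)),
                         biotype=list(np.random.default_rng(1).choice(
                             ["protein_coding", "mito", "weird_label"], 8)))
        out = biotype_counts(cm)
        assert out["genes_detected"].sum() == \
            int(((cm.total > 0).sum(axis=0) > 0).sum())
        assert "other" in out.index


@pytest.fixture(scope="module")
def assigned(clean_library, clean_tagged, annotation):
    frame, _ = clean_tagged
    records = load_truth_alignments(clean_library.truth_alignments(), frame)
    out, _ = assign_frame(records, annotation)
    return out


class TestSaturation:
    def test_full_fraction_identical_to_direct_run(self, assigned, annotation):
        curve = saturation(assigned, annotation, fractions=[1.0], seed=3)
        cm = count_matrix(assigned, annotation)
        assert curve.median_genes[0] == float(np.median(cm.genes_detected_per_cell()))
        assert curve.median_umis[0] == float(np.median(cm.cell_totals()))

    def test_heavy_downsampling_strictly_reduces_detection(self, assigned,
                                                           annotation):
        curve = saturation(assigned, annotation, fractions=[0.02, 1.0], seed=4)
        assert curve.median_genes[0] < curve.median_genes[1]
        assert curve.median_umis[0] < curve.median_umis[1]

    def test_expected_medians_non_decreasing(self, assigned, annotation):
        fractions = [0.1, 0.3, 0.6, 1.0]
        genes = np.zeros(len(fractions))
        for seed in range(5):
            curve = saturation(assigned, annotation, fractions, seed=seed)
            genes += curve.median_genes
        assert np.all(np.diff(genes) >= 0)

    def test_bad_inputs_rejected(self, assigned, annotation):
        with pytest.raises(ValueError):
            saturation(assigned, annotation, fractions=[0.5, 1.5], seed=0)
        with pytest.raises(ValueError):
            saturation(assigned.iloc[:0], annotation, fractions=[1.0], seed=0)


class TestFilterMatrix:
    def test_min_genes_boundary_199_removed_200_kept(self):
        counts = np.zeros((2, 250), dtype=int)
        counts[0, :199] = 1
        counts[1, :200] = 1
        cm = make_matrix(counts)
        out, report = filter_matrix(cm, FilterConfig(min_nuclei_per_gene=0))
        assert out.cells == ["c001"]
        assert report["cells_removed_min_genes"] == 1

    def test_min_nuclei_boundary_2_removed_3_kept(self):
        counts = np.zeros((3, 2), dtype=int)
        counts[:2, 0] = 1          # gene 0 in 2 nuclei
        counts[:, 1] = 1           # gene 1 in 3 nuclei
        cm = make_matrix(counts)
        out, report = filter_matrix(cm, FilterConfig(min_genes_per_nucleus=0))
        assert out.genes == ["g001"]
        assert report["genes_removed_min_nuclei"] == 1

    def test_zero_thresholds_identity(self):
        rng = np.random.default_rng(9)
        cm = make_matrix(rng.integers(0, 4, (6, 5)))
        out, _ = filter_matrix(cm, FilterConfig(min_genes_per_nucleus=0,
                                                min_nuclei_per_gene=0))
        assert out.cells == cm.cells and out.genes == cm.genes
        assert (out.total != cm.total).nnz == 0

    def test_exclusion_lists_applied_first(self):
        counts = np.ones((4, 3), dtype=int)
        cm = make_matrix(counts)
        cfg = FilterConfig(min_genes_per_nucleus=3, min_nuclei_per_gene=0,
                           exclude_genes=("g000",))
        out, report = filter_matrix(cm, cfg)
        # after exclusion only 2 genes remain -> every cell drops below 3
        assert report["genes_excluded_by_list"] == 1
        assert out.cells == []

    def test_everything_filtered_returns_empty_with_report(self):
        cm = make_matrix(np.ones((2, 2), dtype=int))
        out, report = filter_matrix(cm, FilterConfig())
        assert out.shape == (0, 0) or out.total.sum() == 0
        assert report["cells_kept"] == 0

    def test_idempotent_on_simulated_matrix(self, annotation):
        cfg_lib = LibraryConfig(n_nuclei_a=100, n_nuclei_b=100, seed=6,
                                mean_molecules_per_nucleus=150)
        cm = matrix_from_profiles(simulate_expression(annotation, cfg_lib),
                                  annotation)
        cfg = FilterConfig(min_genes_per_nucleus=15, min_nuclei_per_gene=3,
                           exclude_genes=tuple(annotation.mito_genes
                                               + annotation.ribo_genes))
        once, _ = filter_matrix(cm, cfg)
        twice, rep2 = filter_matrix(once, cfg)
        assert twice.cells == once.cells and twice.genes == once.genes


class TestPseudobulkCorrelation:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(4)
        cm = make_matrix(rng.integers(0, 10, (20, 15)))
        r, _ = pseudobulk_correlation(cm, cm)
        assert r == pytest.approx(1.0)

    def test_replicates_from_shared_profile_correlate(self, annotation):
        rng = np.random.default_rng(8)
        weights = rng.gamma(0.8, 1.0, len(annotation.genes))
        mats = []
        for seed in (101, 202):
            cfg = LibraryConfig(n_nuclei_a=260, n_nuclei_b=260, seed=seed,
                                mean_molecules_per_nucleus=150)
            prof = simulate_expression(annotation, cfg, gene_weights=weights)
            mats.append(matrix_from_profiles(prof, annotation))
        r, table = pseudobulk_correlation(*mats)
        assert r >= 0.9
        assert len(table) == len(annotation.genes)

    def test_too_few_shared_genes_is_error(self):
        a = make_matrix([[1, 2]])
        b = make_matrix([[3, 4]])
        b.genes = ["x1", "x2"]
        b.gene_meta.index = ["x1", "x2"]
        with pytest.raises(ValueError, match="shared genes"):
            pseudobulk_correlation(a, b)
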