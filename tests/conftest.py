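"""Shared fixtures: small deterministic whitelists, annotations and libraries.

Everything is generated programmatically at test time; nothing is read from
disk except files the tests themselves write into tmp_path.
"""

import numpy as np
import pytest

from snrandom import chemistry, simulate
from snrandom.chemistry import ReadStructure, build_whitelist
from snrandom.simulate import LibraryConfig, simulate_annotation, simulate_library


def make_segments(rng, n, length, min_dist=3):
    """n random DNA segments with pairwise Hamming distance >= min_dist."""
    segs = []
    while len(segs) < n:
        s = simulate.random_dna(rng, length)
        if all(chemistry.hamming(s, t) >= min_dist for t in segs):
            segs.append(s)
    return segs


def make_whitelist(round_size=12, n_preindex=10, seed=0, min_dist=3):
    rng = np.random.default_rng(seed)
    rounds = [make_segments(rng, round_size, 10, min_dist) for _ in range(3)]
    pre = make_segments(rng, n_preindex, 6, min_dist)
    return build_whitelist(rounds, pre)


@pytest.fixture(scope="session")
def whitelist():
    """12^3 = 1728 accepted barcodes, 10 pre-indexes."""
    return make_whitelist()


@pytest.fixture(scope="session")
def structure():
    return ReadStructure()


@pytest.fixture(scope="session")
def annotation():
    return simulate_annotation(n_genes_per_species=30, seed=7)


@pytest.fixture(scope="session")
def clean_library(annotation, whitelist):
    """Error-free, ambient-free library: the lossless reference dataset."""
    config = LibraryConfig(n_nuclei_a=30, n_nuclei_b=30, seed=11,
                           reads_per_nucleus=150,
                           mean_molecules_per_nucleus=80,
                           substitution_error_rate=0.0,
                           ambient_read_fraction=0.0)
    return simulate_library(annotation, whitelist, config)


@pytest.fixture(scope="session")
def clean_fastq(clean_library, tmp_path_factory):
    d = tmp_path_factory.mktemp("clean_fastq")
    r1, r2 = d / "R1.fastq", d / "R2.fastq"
    clean_library.write_fastq(r1, r2)
    return r1, r2


@pytest.fixture(scope="session")
def clean_tagged(clean_library, clean_fastq, whitelist):
    from snrandom.demux import demux_to_frame

    frame, report = demux_to_frame(*clean_fastq, clean_library.structure,
                                   whitelist)
    return frame, report
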