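"""Read architecture, split-pool whitelists, and Hamming-bounded barcode correction.

The snRandom-seq library has a fixed read anatomy.  Read1 carries the cell
identity: a 30-nt cell barcode assembled from three rounds of split-and-pool
ligation on hydrogel beads, followed by an 8-nt UMI and the poly(dT) stretch
that the bead primer annealed to on the dA-tailed cDNA; everything after that
T-run is cDNA sequence.  Read2 begins with the pre-index (the tube-specific
tag carried by the random RT primer) and continues into cDNA, possibly running
through the dA tail at its far end.

This module declares that layout (:class:`ReadStructure`), builds and
validates the combinatorial whitelist of accepted barcodes
(:class:`BarcodeWhitelist`), and implements unique-assignment barcode
correction: an observed barcode is merged into an accepted one when it can be
assigned to exactly one whitelist member within a Hamming-distance bound
(default 2), and rejected as ambiguous when two or more accepted barcodes are
that close.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml

DNA = frozenset("ACGT")

__all__ = [
    "ReadStructure",
    "BarcodeWhitelist",
    "CorrectionResult",
    "Read1Parse",
    "build_whitelist",
    "correct_barcode",
    "match_preindex",
    "parse_read1",
    "homopolymer_run",
    "hamming",
    "read_segment_file",
    "WhitelistError",
]


class WhitelistError(ValueError):
    """Raised for malformed whitelist inputs (non-DNA characters, duplicates...)."""


def _check_dna(s: str, context: str) -> None:
    bad = set(s) - DNA
    if bad:
        raise WhitelistError(f"non-ACGT character(s) {sorted(bad)} in {context}: {s!r}")


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def _encode(strings: Sequence[str]) -> np.ndarray:
    """Pack equal-length DNA strings into a (n, L) uint8 matrix."""
    if not strings:
        return np.empty((0, 0), dtype=np.uint8)
    joined = "".join(strings).encode("ascii")
    return np.frombuffer(joined, dtype=np.uint8).reshape(len(strings), len(strings[0]))


def _encode_one(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


# ---------------------------------------------------------------------------
# Read layout
# ---------------------------------------------------------------------------

@dataclass
class ReadStructure:
    """Declarative layout of Read1/Read2.

    Parameters
    ----------
    barcode_len
        Total cell-barcode length on Read1, nucleotides.
    barcode_segment_lens
        Length of the segment contributed by each split-pool round; must sum
        to ``barcode_len``.
    linker_seqs
        Optional fixed sequences between consecutive barcode segments (one
        fewer than the number of segments, or empty for none).
    umi_len
        UMI length, immediately after the barcode (and last linker).
    r1_junction_base, r1_junction_min_run, r1_mismatch_per_10
        The homopolymer junction expected after the UMI on Read1 (the read
        through the dA tail appears as a T-run on this strand): minimum run
        length to accept, and how many mismatched bases are tolerated per
        10 nt of run.
    preindex_len
        Length of the RT pre-index at position 0 of Read2; 0 disables
        pre-indexing.
    r2_tail_trim_base
        Homopolymer base trimmed from the 3' end of Read2 (read-through into
        the dA tail).
    """

    barcode_len: int = 30
    barcode_segment_lens: tuple[int, ...] = (10, 10, 10)
    linker_seqs: tuple[str, ...] = ()
    umi_len: int = 8
    r1_junction_base: str = "T"
    r1_junction_min_run: int = 6
    r1_mismatch_per_10: int = 1
    preindex_len: int = 6
    r2_tail_trim_base: str = "A"

    def __post_init__(self) -> None:
        self.barcode_segment_lens = tuple(self.barcode_segment_lens)
        self.linker_seqs = tuple(self.linker_seqs)
        if any(l <= 0 for l in self.barcode_segment_lens):
            raise ValueError("barcode segment lengths must be positive")
        if sum(self.barcode_segment_lens) != self.barcode_len:
            raise ValueError(
                f"segment lengths {self.barcode_segment_lens} do not sum to "
                f"barcode_len={self.barcode_len}"
            )
        if self.linker_seqs and len(self.linker_seqs) != len(self.barcode_segment_lens) - 1:
            raise ValueError("need one linker fewer than segments (or none)")
        for seq in self.linker_seqs:
            _check_dna(seq, "linker")
        if self.umi_len <= 0:
            raise ValueError("umi_len must be positive")
        if self.preindex_len < 0:
            raise ValueError("preindex_len must be >= 0")
        if self.r1_junction_base not in DNA or self.r2_tail_trim_base not in DNA:
            raise ValueError("junction/tail bases must be single DNA bases")

    @property
    def linker_total(self) -> int:
        return sum(len(s) for s in self.linker_seqs)

    @property
    def r1_min_len(self) -> int:
        """Shortest Read1 that still contains barcode, linkers and UMI."""
        return self.barcode_len + self.linker_total + self.umi_len

    def to_dict(self) -> dict:
        return {
            "barcode_len": self.barcode_len,
            "barcode_segment_lens": list(self.barcode_segment_lens),
            "linker_seqs": list(self.linker_seqs),
            "umi_len": self.umi_len,
            "r1_junction_base": self.r1_junction_base,
            "r1_junction_min_run": self.r1_junction_min_run,
            "r1_mismatch_per_10": self.r1_mismatch_per_10,
            "preindex_len": self.preindex_len,
            "r2_tail_trim_base": self.r2_tail_trim_base,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ReadStructure":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Whitelist
# ---------------------------------------------------------------------------

def read_segment_file(path) -> list[str]:
    """Read one whitelist segment per line; '#' starts a comment."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip().upper()
            if line:
                out.append(line)
    return out


def _pairwise_min_hamming(strings: Sequence[str], chunk: int = 256) -> Optional[int]:
    """Exact minimum pairwise Hamming distance by chunked all-pairs scan."""
    n = len(strings)
    if n < 2:
        return None
    mat = _encode(strings)
    best = mat.shape[1]
    for i0 in range(0, n, chunk):
        block = mat[i0 : i0 + chunk]
        # distances of this block against every later row (upper triangle)
        d = (block[:, None, :] != mat[None, i0:, :]).sum(axis=2)
        rows = np.arange(block.shape[0])[:, None]
        cols = np.arange(d.shape[1])[None, :]
        d[cols <= rows] = mat.shape[1] + 1  # mask self and lower triangle
        if d.size:
            best = min(best, int(d.min()))
    return best


@dataclass
class BarcodeWhitelist:
    """Accepted cell barcodes (product of split-pool rounds) and pre-indexes."""

    rounds: Optional[list[list[str]]]
    accepted: list[str]
    preindexes: list[str] = field(default_factory=list)
    min_pairwise_dist: Optional[int] = None

    # lazy caches
    _accepted_set: Optional[frozenset] = field(default=None, repr=False, compare=False)
    _matrix: Optional[np.ndarray] = field(default=None, repr=False, compare=False)
    _pre_set: Optional[frozenset] = field(default=None, repr=False, compare=False)
    _pre_matrix: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    @property
    def barcode_len(self) -> int:
        return len(self.accepted[0]) if self.accepted else 0

    @property
    def preindex_len(self) -> int:
        return len(self.preindexes[0]) if self.preindexes else 0

    @property
    def accepted_set(self) -> frozenset:
        if self._accepted_set is None:
            self._accepted_set = frozenset(self.accepted)
        return self._accepted_set

    @property
    def matrix(self) -> np.ndarray:
        if self._matrix is None:
            self._matrix = _encode(self.accepted)
        return self._matrix

    @property
    def preindex_set(self) -> frozenset:
        if self._pre_set is None:
            self._pre_set = frozenset(self.preindexes)
        return self._pre_set

    @property
    def preindex_matrix(self) -> np.ndarray:
        if self._pre_matrix is None:
            self._pre_matrix = _encode(self.preindexes)
        return self._pre_matrix

    @classmethod
    def from_files(cls, round_paths: Sequence, preindex_path=None) -> "BarcodeWhitelist":
        rounds = [read_segment_file(p) for p in round_paths]
        pre = read_segment_file(preindex_path) if preindex_path else []
        return build_whitelist(rounds, pre)

    @classmethod
    def from_combined(cls, path, preindex_path=None) -> "BarcodeWhitelist":
        """Load a flat list of full-length accepted barcodes (rounds unknown)."""
        accepted = read_segment_file(path)
        if not accepted:
            raise WhitelistError(f"empty whitelist file {path}")
        length = len(accepted[0])
        for bc in accepted:
            _check_dna(bc, "barcode")
            if len(bc) != length:
                raise WhitelistError("barcodes of unequal length in combined whitelist")
        if len(set(accepted)) != len(accepted):
            raise WhitelistError("duplicate barcodes in combined whitelist")
        pre = read_segment_file(preindex_path) if preindex_path else []
        mpd = _pairwise_min_hamming(accepted) if len(accepted) <= 10_000 else None
        return cls(rounds=None, accepted=sorted(accepted), preindexes=sorted(pre),
                   min_pairwise_dist=mpd)


def build_whitelist(
    round_sets: Sequence[Iterable[str]],
    preindexes: Iterable[str] = (),
    brute_force_limit: int = 10_000,
) -> BarcodeWhitelist:
    """Assemble the accepted-barcode set from per-round segment sets.

    The accepted set is the concatenation product round1 x round2 x ... .
    ``min_pairwise_dist`` is computed by brute force when the product is small
    (<= ``brute_force_limit``); for larger products the minimum over rounds of
    each round's internal minimum is used — two accepted barcodes differing in
    a single round realise exactly that round's minimum, and differing in more
    rounds only increases the distance, so the shortcut is exact.
    """
    rounds: list[list[str]] = []
    for i, rset in enumerate(round_sets):
        segs = sorted(set(rset))
        raw = list(rset)
        if not raw:
            raise WhitelistError(f"round {i + 1} is empty")
        if len(segs) != len(raw):
            raise WhitelistError(f"duplicate segment within round {i + 1}")
        length = len(segs[0])
        for s in segs:
            _check_dna(s, f"round {i + 1} segment")
            if len(s) != length:
                raise WhitelistError(f"unequal segment lengths within round {i + 1}")
        rounds.append(segs)

    pre = sorted(set(preindexes))
    for p in pre:
        _check_dna(p, "preindex")
    if pre and len(set(map(len, pre))) != 1:
        raise WhitelistError("preindexes of unequal length")

    n_accept = math.prod(len(r) for r in rounds)
    accepted = ["".join(parts) for parts in itertools.product(*rounds)]
    assert len(accepted) == n_accept

    if n_accept <= brute_force_limit:
        mpd = _pairwise_min_hamming(accepted)
    else:
        per_round = [_pairwise_min_hamming(r) for r in rounds]
        mins = [m for m in per_round if m is not None]
        mpd = min(mins) if mins else None

    return BarcodeWhitelist(rounds=rounds, accepted=sorted(accepted),
                            preindexes=pre, min_pairwise_dist=mpd)


# ---------------------------------------------------------------------------
# Correction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrectionResult:
    """Outcome of unique-assignment correction of one observed barcode."""

    status: str  # exact | corrected | ambiguous | no_match
    barcode: Optional[str] = None
    distance: Optional[int] = None
    malformed: bool = False

    def __post_init__(self):
        if self.status == "exact":
            assert self.distance == 0
        if self.status == "corrected":
            assert self.distance is not None and self.distance >= 1


def _unique_assign(
    observed: str,
    members: Sequence[str],
    member_set: frozenset,
    matrix: np.ndarray,
    d_max: int,
    mode: str,
) -> CorrectionResult:
    if observed in member_set:
        return CorrectionResult("exact", observed, 0)
    dists = (matrix != _encode_one(observed)).sum(axis=1)
    within = np.flatnonzero(dists <= d_max)
    if within.size == 0:
        return CorrectionResult("no_match")
    if within.size == 1:
        i = int(within[0])
        return CorrectionResult("corrected", members[i], int(dists[i]))
    if mode == "nearest":
        dmin = int(dists[within].min())
        nearest = within[dists[within] == dmin]
        if nearest.size == 1:
            i = int(nearest[0])
            return CorrectionResult("corrected", members[i], dmin)
        return CorrectionResult("ambiguous", None, dmin)
    # unique-assignment reading: any second candidate within d_max is fatal
    return CorrectionResult("ambiguous", None, int(dists[within].min()))


def correct_barcode(
    observed: str,
    whitelist: BarcodeWhitelist,
    d_max: int = 2,
    mode: str = "unique",
) -> CorrectionResult:
    """Merge an observed barcode into the accepted set.

    ``mode='unique'`` (default) rejects as ambiguous whenever two or more
    accepted barcodes lie within ``d_max``, even if one is strictly nearer;
    ``mode='nearest'`` accepts a unique nearest neighbour.  A length-mismatched
    observation is returned as ``no_match`` with ``malformed=True`` rather
    than raising, so streaming callers can count it.
    """
    if mode not in ("unique", "nearest"):
        raise ValueError(f"unknown correction mode {mode!r}")
    if len(observed) != whitelist.barcode_len or not set(observed) <= DNA:
        return CorrectionResult("no_match", malformed=True)
    return _unique_assign(observed, whitelist.accepted, whitelist.accepted_set,
                          whitelist.matrix, d_max, mode)


def match_preindex(
    observed: str,
    whitelist: BarcodeWhitelist,
    d_pre: int = 1,
    mode: str = "unique",
) -> CorrectionResult:
    """Unique-assignment correction of the RT pre-index (same semantics as
    :func:`correct_barcode`).  With pre-indexing disabled (no pre-indexes in
    the whitelist) every observation maps to the empty pre-index."""
    if not whitelist.preindexes:
        return CorrectionResult("exact", "", 0)
    if len(observed) != whitelist.preindex_len or not set(observed) <= DNA:
        return CorrectionResult("no_match", malformed=True)
    return _unique_assign(observed, whitelist.preindexes, whitelist.preindex_set,
                          whitelist.preindex_matrix, d_pre, mode)


# ---------------------------------------------------------------------------
# Read1 parsing
# ---------------------------------------------------------------------------

def homopolymer_run(seq: str, base: str, tol_per_10: int = 1) -> int:
    """Length of the leading homopolymer run of ``base`` in ``seq``.

    The run extends greedily; isolated non-``base`` characters are tolerated
    up to ``tol_per_10 * ceil(L/10)`` for the running length L, but two
    consecutive mismatches end the run (otherwise a tolerant run would creep
    into genuine insert sequence that merely starts with a few ``base``
    characters).  The reported run ends on the last matching base.
    """
    best = 0
    mismatches = 0
    prev_mismatch = False
    for i, ch in enumerate(seq):
        if ch != base:
            if prev_mismatch:
                break
            mismatches += 1
            if mismatches > tol_per_10 * math.ceil((i + 1) / 10):
                break
            prev_mismatch = True
        else:
            prev_mismatch = False
            best = i + 1
    return best


@dataclass(frozen=True)
class Read1Parse:
    """Result of slicing one Read1 by the declared layout."""

    ok: bool
    reason: Optional[str] = None
    barcode: Optional[str] = None
    umi: Optional[str] = None
    junction_ok: bool = False
    insert: str = ""


def parse_read1(seq: str, structure: ReadStructure) -> Read1Parse:
    """Extract barcode and UMI from Read1 and locate the poly(dT) junction.

    The barcode is the concatenation of the declared segments (linkers, if
    any, are verified with at most one mismatch each and excluded from the
    barcode).  ``junction_ok`` is true when a T-run of at least
    ``r1_junction_min_run`` (with the per-10-nt mismatch tolerance) follows
    the UMI; the insert is whatever follows that run.
    """
    seq = seq.upper()
    if len(seq) < structure.r1_min_len:
        return Read1Parse(ok=False, reason="too_short")
    pos = 0
    segments = []
    for i, seg_len in enumerate(structure.barcode_segment_lens):
        segments.append(seq[pos : pos + seg_len])
        pos += seg_len
        if structure.linker_seqs and i < len(structure.barcode_segment_lens) - 1:
            linker = structure.linker_seqs[i]
            observed = seq[pos : pos + len(linker)]
            if hamming(observed, linker) > 1:
                return Read1Parse(ok=False, reason="linker_mismatch")
            pos += len(linker)
    barcode = "".join(segments)
    umi = seq[pos : pos + structure.umi_len]
    pos += structure.umi_len
    tail = seq[pos:]
    run = homopolymer_run(tail, structure.r1_junction_base, structure.r1_mismatch_per_10)
    junction_ok = run >= structure.r1_junction_min_run
    insert = tail[run:] if junction_ok else tail
    return Read1Parse(ok=True, barcode=barcode, umi=umi,
                      junction_ok=junction_ok, insert=insert)
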