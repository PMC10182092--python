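"""Streaming demultiplexer: FASTQ pairs -> cell/UMI-tagged reads + run report.

For each read pair, Read1 is sliced into cell barcode + UMI and checked for
the poly(dT) junction left by dA tailing; Read2 yields the RT pre-index and
the cDNA insert (with any read-through into the dA tail trimmed from its 3'
end).  The barcode is merged into the whitelist by unique assignment within
Hamming distance ``d_max`` (default 2); the pre-index likewise within
``d_pre``.  A pair produces exactly one :class:`TaggedRead` or exactly one
counted rejection, so the report categories always partition the input.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Iterator, Optional, Tuple

import pandas as pd
import pysam

from .chemistry import (BarcodeWhitelist, CorrectionResult, ReadStructure,
                        correct_barcode, homopolymer_run, match_preindex,
                        parse_read1)

logger = logging.getLogger(__name__)

__all__ = ["TaggedRead", "DemuxReport", "trim_read2", "demux_pair_stream",
           "demux_to_frame", "write_tagged_tsv", "PairingError"]


class PairingError(RuntimeError):
    """Read1/Read2 ids disagree or a record is truncated: corrupt pairing."""


@dataclass(frozen=True)
class TaggedRead:
    """One demultiplexed read: cell id = pre-index + accepted barcode."""

    read_id: str
    cell_id: str
    umi: str
    insert2: str
    insert1: str = ""
    barcode_status: str = "exact"       # exact | corrected
    preindex_status: str = "exact"      # exact | corrected | disabled
    junction_ok: bool = True


@dataclass
class DemuxReport:
    """Category counters; valid + ambiguous + no_match + malformed == total.

    ``reads_corrected`` counts the subset of valid reads whose barcode (or
    pre-index) needed correction, so it is informational, not a partition
    member.
    """

    reads_total: int = 0
    reads_valid_barcode: int = 0
    reads_corrected: int = 0
    reads_ambiguous: int = 0
    reads_no_match: int = 0
    reads_malformed: int = 0

    @property
    def valid_barcode_rate(self) -> float:
        return self.reads_valid_barcode / self.reads_total if self.reads_total else 0.0

    def check_partition(self) -> None:
        parts = (self.reads_valid_barcode + self.reads_ambiguous +
                 self.reads_no_match + self.reads_malformed)
        if parts != self.reads_total:
            raise AssertionError(
                f"report categories ({parts}) do not partition total "
                f"({self.reads_total})")

    def to_json(self, path=None) -> str:
        d = asdict(self)
        d["valid_barcode_rate"] = self.valid_barcode_rate
        s = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def trim_read2(seq: str, structure: ReadStructure) -> Optional[Tuple[str, str]]:
    """Split Read2 into (observed pre-index, insert).

    The first ``preindex_len`` bases are the pre-index; a trailing homopolymer
    run of >= 4 ``r2_tail_trim_base`` characters (dA-tail read-through, with
    the same per-10-nt mismatch tolerance as the Read1 junction) is trimmed
    from the 3' end.  Returns None for reads shorter than the pre-index
    (malformed; the caller counts them).
    """
    seq = seq.upper()
    p = structure.preindex_len
    if len(seq) < p:
        return None
    preindex, rest = seq[:p], seq[p:]
    run = homopolymer_run(rest[::-1], structure.r2_tail_trim_base,
                          structure.r1_mismatch_per_10)
    if run >= 4:
        rest = rest[: len(rest) - run]
    return preindex, rest


def _fastq_pairs(fastq_r1, fastq_r2) -> Iterator[Tuple[str, str, str]]:
    """Yield (id, seq1, seq2); verifies positional pairing by id prefix."""
    with pysam.FastxFile(str(fastq_r1)) as f1, pysam.FastxFile(str(fastq_r2)) as f2:
        it2 = iter(f2)
        for rec1 in f1:
            try:
                rec2 = next(it2)
            except StopIteration:
                raise PairingError("Read2 file ended before Read1 file") from None
            id1 = rec1.name.split("/", 1)[0]
            id2 = rec2.name.split("/", 1)[0]
            if id1 != id2:
                raise PairingError(f"read id mismatch: {id1!r} vs {id2!r}")
            yield id1, rec1.sequence, rec2.sequence
        try:
            next(it2)
        except StopIteration:
            pass
        else:
            raise PairingError("Read1 file ended before Read2 file")


def demux_pair_stream(
    fastq_r1,
    fastq_r2,
    structure: ReadStructure,
    whitelist: BarcodeWhitelist,
    d_max: int = 2,
    d_pre: int = 1,
    report: Optional[DemuxReport] = None,
    correction_mode: str = "unique",
) -> Iterator[TaggedRead]:
    """Stream TaggedReads from a FASTQ pair, filling ``report`` as a side
    effect (pass one in to inspect it; it is complete once the stream is
    exhausted)."""
    report = report if report is not None else DemuxReport()
    # exact-membership fast path: most reads are error-free
    accepted = whitelist.accepted_set
    pre_set = whitelist.preindex_set
    preindex_enabled = structure.preindex_len > 0 and bool(whitelist.preindexes)

    for read_id, seq1, seq2 in _fastq_pairs(fastq_r1, fastq_r2):
        report.reads_total += 1
        parsed = parse_read1(seq1, structure)
        if not parsed.ok:
            report.reads_malformed += 1
            continue
        trimmed = trim_read2(seq2, structure)
        if trimmed is None:
            report.reads_malformed += 1
            continue
        pre_obs, insert2 = trimmed

        if parsed.barcode in accepted:
            bc_res = CorrectionResult("exact", parsed.barcode, 0)
        else:
            bc_res = correct_barcode(parsed.barcode, whitelist, d_max,
                                     mode=correction_mode)
        if bc_res.status == "ambiguous":
            report.reads_ambiguous += 1
            continue
        if bc_res.status == "no_match":
            if bc_res.malformed:
                report.reads_malformed += 1
            else:
                report.reads_no_match += 1
            continue

        if not preindex_enabled:
            pre_res = CorrectionResult("exact", "", 0)
            pre_status = "disabled"
        else:
            if pre_obs in pre_set:
                pre_res = CorrectionResult("exact", pre_obs, 0)
            else:
                pre_res = match_preindex(pre_obs, whitelist, d_pre,
                                         mode=correction_mode)
            pre_status = pre_res.status
            if pre_res.status == "ambiguous":
                report.reads_ambiguous += 1
                continue
            if pre_res.status == "no_match":
                if pre_res.malformed:
                    report.reads_malformed += 1
                else:
                    report.reads_no_match += 1
                continue

        report.reads_valid_barcode += 1
        if bc_res.status == "corrected" or pre_status == "corrected":
            report.reads_corrected += 1
        yield TaggedRead(
            read_id=read_id,
            cell_id=pre_res.barcode + bc_res.barcode,
            umi=parsed.umi,
            insert2=insert2,
            insert1=parsed.insert,
            barcode_status=bc_res.status,
            preindex_status=pre_status,
            junction_ok=parsed.junction_ok,
        )


def demux_to_frame(fastq_r1, fastq_r2, structure, whitelist, d_max: int = 2,
                   d_pre: int = 1, correction_mode: str = "unique"):
    """Materialise the stream into a DataFrame; returns (frame, report)."""
    report = DemuxReport()
    rows = list(demux_pair_stream(fastq_r1, fastq_r2, structure, whitelist,
                                  d_max=d_max, d_pre=d_pre, report=report,
                                  correction_mode=correction_mode))
    report.check_partition()
    frame = pd.DataFrame([asdict(t) for t in rows],
                         columns=[f.name for f in
                                  TaggedRead.__dataclass_fields__.values()])
    return frame, report


def write_tagged_tsv(frame: pd.DataFrame, path) -> None:
    """Headered TSV of tagged reads (read_id, cell_id, umi, insert2, ...)."""
    frame.to_csv(path, sep="\t", index=False)
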