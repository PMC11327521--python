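"""Alignment ingestion: SAM/BAM records normalised to per-read segment models.

Built on pysam. Each mapped record (primary or supplementary) becomes one
:class:`SegmentAlignment` with its query interval re-expressed in the original
read orientation, so chimeric (split) reads can be reasoned about as ordered
segment chains. Per-read 5mC CpG calls are decoded from SAM MM/ML
base-modification tags and projected through the CIGAR onto plus-strand CpG
C coordinates.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentAlignment",
    "ReadAlignmentSet",
    "read_alignments",
    "write_alignments",
    "group_by_read",
    "read_meth_tags",
]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")


@dataclass
class SegmentAlignment:
    """One aligned segment of a read.

    ``query_start/query_end`` are 0-based half-open in the *original read
    orientation* (i.e. on the molecule as sequenced, not on SEQ as stored).
    """

    read_id: str
    query_start: int
    query_end: int
    chrom: str
    ref_start: int
    ref_end: int
    strand: str
    cigar: str
    mapq: int
    is_primary: bool

    @property
    def query_length(self) -> int:
        return self.query_end - self.query_start

    @property
    def ref_length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class ReadAlignmentSet:
    """All segments of one read, ordered by query start."""

    read_id: str
    segments: List[SegmentAlignment]
    read_length: int


def _cigar_lengths(cigar: str) -> Tuple[int, int, int, int]:
    """(leading clip, aligned query length, trailing clip, reference length)."""
    ops = _CIGAR_RE.findall(cigar)
    if not ops or "".join(f"{n}{o}" for n, o in ops) != cigar:
        raise ValueError(f"malformed CIGAR: {cigar!r}")
    lead = 0
    i = 0
    while i < len(ops) and ops[i][1] in "SH":
        lead += int(ops[i][0])
        i += 1
    trail = 0
    j = len(ops) - 1
    while j >= i and ops[j][1] in "SH":
        trail += int(ops[j][0])
        j -= 1
    qlen = sum(int(n) for n, o in ops[i : j + 1] if o in _QUERY_OPS)
    rlen = sum(int(n) for n, o in ops[i : j + 1] if o in _REF_OPS)
    if any(o in "SH" for n, o in ops[i : j + 1]):
        raise ValueError(f"internal clip in CIGAR: {cigar!r}")
    return lead, qlen, trail, rlen


def record_to_segment(rec: pysam.AlignedSegment) -> SegmentAlignment:
    """Normalise one mapped SAM record into a SegmentAlignment."""
    cigar = rec.cigarstring
    lead, qlen, trail, rlen = _cigar_lengths(cigar)
    total = lead + qlen + trail
    if rec.is_reverse:
        qs, qe = total - (lead + qlen), total - lead
    else:
        qs, qe = lead, lead + qlen
    return SegmentAlignment(
        read_id=rec.query_name,
        query_start=qs,
        query_end=qe,
        chrom=rec.reference_name,
        ref_start=rec.reference_start,
        ref_end=rec.reference_start + rlen,
        strand="-" if rec.is_reverse else "+",
        cigar=cigar,
        mapq=rec.mapping_quality,
        is_primary=not (rec.is_supplementary or rec.is_secondary),
    )


def read_alignments(path: str) -> List[SegmentAlignment]:
    """Parse SAM/BAM into segments; unmapped and secondary records are skipped.

    Accepts unsorted input. A malformed CIGAR raises with the offending read
    named.
    """
    out: List[SegmentAlignment] = []
    n_unmapped = 0
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                n_unmapped += 1
                continue
            if rec.is_secondary:
                continue
            try:
                out.append(record_to_segment(rec))
            except ValueError as exc:
                raise ValueError(f"read {rec.query_name}: {exc}") from exc
    if n_unmapped:
        logger.info("skipped %d unmapped records in %s", n_unmapped, path)
    return out


def write_alignments(
    segments: Sequence[SegmentAlignment],
    contigs: Dict[str, int],
    path: str,
) -> None:
    """Emit segments back to SAM (sequence-less records, modeled fields only)."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": n} for c, n in contigs.items()],
        }
    )
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for s in segments:
            a = pysam.AlignedSegment(header)
            a.query_name = s.read_id
            a.flag = (16 if s.strand == "-" else 0) | (0 if s.is_primary else 2048)
            a.reference_id = header.get_tid(s.chrom)
            a.reference_start = s.ref_start
            a.mapping_quality = s.mapq
            a.cigarstring = s.cigar
            out.write(a)


def group_by_read(alignments: Iterable[SegmentAlignment]) -> List[ReadAlignmentSet]:
    """Group segments by read id, ordered by query start within each read.

    Ties break by (chrom, ref_start); read sets come out sorted by read id so
    the result is independent of input order.
    """
    by_read: Dict[str, List[SegmentAlignment]] = {}
    for seg in alignments:
        by_read.setdefault(seg.read_id, []).append(seg)
    out = []
    for read_id in sorted(by_read):
        segs = sorted(
            by_read[read_id], key=lambda s: (s.query_start, s.chrom, s.ref_start)
        )
        lead, qlen, trail, _ = _cigar_lengths(segs[0].cigar)
        out.append(ReadAlignmentSet(read_id, segs, lead + qlen + trail))
    return out


def read_meth_tags(
    path: str, threshold: float = 0.5
) -> Dict[str, Dict[int, int]]:
    """Per-read binary 5mC CpG calls from MM/ML tags.

    Calls are projected through the CIGAR onto reference coordinates and onto
    the plus-strand C of the CpG (a call on the opposite strand maps to
    ``ref_pos - 1``, the symmetric-CpG convention). The modification
    probability is thresholded at ``threshold``; ties count as methylated.
    Reads whose tags cannot be reconciled with the CIGAR are skipped with a
    warning counter.
    """
    calls: Dict[str, Dict[int, int]] = {}
    n_bad = 0
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                continue
            try:
                mods = rec.modified_bases
            except Exception:
                n_bad += 1
                continue
            if not mods:
                continue
            pair_map = dict(rec.get_aligned_pairs(matches_only=True))
            read_calls = calls.setdefault(rec.query_name, {})
            for (base, strand, mod), entries in mods.items():
                if base != "C" or mod != "m":
                    continue
                for qpos, ml in entries:
                    rpos = pair_map.get(qpos)
                    if rpos is None:
                        continue
                    site = rpos - 1 if strand == 1 else rpos
                    prob = ml / 255.0
                    read_calls.setdefault(site, int(prob >= threshold))
    if n_bad:
        logger.warning("skipped %d records with unparseable MM/ML tags", n_bad)
    return {k: v for k, v in calls.items() if v}
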