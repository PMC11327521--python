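"""On-target enrichment QC for Cas9-targeted reads.

Quantifies how well reads concentrate on the regions of interest and whether
their ends carry the Cas9 cleavage signature: per-ROI read counts (full
containment and overlap), per-base coverage tracks, read-start offsets from
each guide's expected blunt-cut boundary, and NGG PAM checks.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .alignment_io import ReadAlignmentSet, SegmentAlignment
from .synthetic_data import CrRNASpec, Feature, ToyGenome, revcomp

__all__ = [
    "CutSiteHit",
    "RoiReport",
    "count_on_target",
    "coverage_track",
    "cut_site_profile",
    "pam_check",
]


@dataclass
class CutSiteHit:
    """One read end matched to a guide's expected cut boundary."""

    crrna: str
    read_id: str
    observed: int  # reference boundary coordinate of the read's starting end
    offset: int  # observed - expected_cut, signed bp
    pam_motif_ok: bool


@dataclass
class RoiReport:
    name: str
    chrom: str
    start: int
    end: int
    n_reads_overlapping: int
    n_reads_fully_covering: int
    mean_depth: float
    depth: np.ndarray

    def __post_init__(self) -> None:
        assert self.n_reads_fully_covering <= self.n_reads_overlapping
        assert len(self.depth) == self.end - self.start


def _merge_intervals(ivals: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    out: List[Tuple[int, int]] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def count_on_target(
    read_sets: Sequence[ReadAlignmentSet],
    rois: Sequence[Feature],
) -> List[RoiReport]:
    """Per-ROI read counts and depth.

    A read *fully covers* an ROI when the union of its segments on that
    chromosome contains the ROI interval; it *overlaps* when the intersection
    is non-empty. Both are reported because 'reads covering a region' is used
    loosely in practice.
    """
    reports = []
    for roi in rois:
        if roi.end <= roi.start:
            raise ValueError(f"ROI {roi.name}: empty interval")
        n_over = 0
        n_full = 0
        segs: List[SegmentAlignment] = []
        for rs in read_sets:
            ivals = [
                (s.ref_start, s.ref_end) for s in rs.segments if s.chrom == roi.chrom
            ]
            if not ivals:
                continue
            merged = _merge_intervals(ivals)
            if any(s < roi.end and roi.start < e for s, e in merged):
                n_over += 1
            if any(s <= roi.start and roi.end <= e for s, e in merged):
                n_full += 1
            segs.extend(s for s in rs.segments if s.chrom == roi.chrom)
        depth = coverage_track(segs, roi.chrom, roi.start, roi.end)
        reports.append(
            RoiReport(
                name=roi.name,
                chrom=roi.chrom,
                start=roi.start,
                end=roi.end,
                n_reads_overlapping=n_over,
                n_reads_fully_covering=n_full,
                mean_depth=float(depth.mean()) if len(depth) else 0.0,
                depth=depth,
            )
        )
    return reports


def coverage_track(
    alignments: Iterable[SegmentAlignment],
    chrom: str,
    start: int,
    end: int,
) -> np.ndarray:
    """Per-base depth over [start, end): number of segment reference spans
    containing each position (deletions inside a segment still count)."""
    n = end - start
    diff = np.zeros(n + 1, dtype=np.int64)
    for seg in alignments:
        if seg.chrom != chrom:
            continue
        lo, hi = max(seg.ref_start, start), min(seg.ref_end, end)
        if lo < hi:
            diff[lo - start] += 1
            diff[hi - start] -= 1
    return np.cumsum(diff[:-1])


def pam_check(genome: ToyGenome, crrna: CrRNASpec) -> Tuple[bool, str]:
    """NGG test at the guide's PAM interval, on the spacer strand."""
    s, e = crrna.pam_interval
    if s < 0 or e > len(genome.chromosomes[crrna.chrom]):
        raise ValueError(f"{crrna.name}: PAM interval outside chromosome")
    observed = crrna.pam_seq(genome)
    return observed[1] == "G" and observed[2] == "G", observed


def cut_site_profile(
    read_sets: Sequence[ReadAlignmentSet],
    crrnas: Sequence[CrRNASpec],
    genome: ToyGenome,
    window: int = 20,
) -> Tuple[List[CutSiteHit], int, Dict[str, Counter]]:
    """Match each read's starting end to the nearest expected cut boundary.

    The starting end is the reference boundary where the molecule begins: the
    segment's ref start for a forward read, its (half-open) ref end for a
    reverse read, taken from the query-5' segment. Reads with no cut within
    ±window are tallied as off-signature. Returns (hits, n_off_signature,
    per-guide offset histograms).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    pam_ok = {c.name: pam_check(genome, c)[0] for c in crrnas}
    hits: List[CutSiteHit] = []
    histograms: Dict[str, Counter] = {c.name: Counter() for c in crrnas}
    n_off = 0
    for rs in read_sets:
        first = rs.segments[0]
        observed = first.ref_start if first.strand == "+" else first.ref_end
        best: Optional[Tuple[int, CrRNASpec]] = None
        for cr in crrnas:
            if cr.chrom != first.chrom:
                continue
            off = observed - cr.expected_cut
            if abs(off) <= window and (best is None or abs(off) < abs(best[0])):
                best = (off, cr)
        if best is None:
            n_off += 1
            continue
        off, cr = best
        hits.append(
            CutSiteHit(
                crrna=cr.name,
                read_id=rs.read_id,
                observed=observed,
                offset=off,
                pam_motif_ok=pam_ok[cr.name],
            )
        )
        histograms[cr.name][off] += 1
    return hits, n_off, histograms
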