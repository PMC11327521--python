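"""Split-read fusion breakpoint detection.

Chimeric long reads — single molecules whose consecutive parts align to
different loci — are mined for inter-locus junctions; junction observations
are clustered (single linkage within a bp tolerance) into consensus calls
whose coordinates are per-coordinate medians; calls are classified into
transcript labels (b2a2/b3a2 style) by the annotated introns containing each
breakpoint, and emitted as BEDPE and VCF 4.2 BND mate pairs.

Junction coordinate convention: the last aligned base of the query-5' partner
(posA) and the first aligned base of the query-3' partner (posB), 0-based
internally, 1-based in emitted VCF and human-readable output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .alignment_io import ReadAlignmentSet
from .synthetic_data import Feature

__all__ = [
    "JunctionObservation",
    "FusionCall",
    "find_chimeric_junctions",
    "cluster_junctions",
    "classify_fusion",
    "report_fusions",
    "read_bedpe",
    "DEFAULT_TRANSCRIPT_TABLE",
]

DEFAULT_TRANSCRIPT_TABLE: Dict[Tuple[str, str], str] = {
    # (intron containing the 5' breakpoint, intron containing the 3' breakpoint)
    ("BCR_intron13", "ABL1_intron1"): "b2a2",
    ("BCR_intron14", "ABL1_intron1"): "b3a2",
}


@dataclass(frozen=True)
class JunctionObservation:
    """One read's evidence for an inter-locus junction."""

    read_id: str
    chromA: str
    posA: int  # last aligned base of the query-5' segment
    chromB: str
    posB: int  # first aligned base of the query-3' segment
    strandA: str
    strandB: str
    query_gap: int

    @property
    def orientation(self) -> Tuple[str, str]:
        return (self.strandA, self.strandB)


@dataclass
class FusionCall:
    chromA: str
    posA: int
    chromB: str
    posB: int
    strandA: str
    strandB: str
    n_supporting_reads: int
    read_ids: List[str]
    mad: float  # median absolute deviation of member junction coordinates
    label: str = "unclassified"

    def __post_init__(self) -> None:
        assert self.n_supporting_reads == len(self.read_ids)


def find_chimeric_junctions(
    read_sets: Sequence[ReadAlignmentSet],
    min_segment: int = 200,
    max_query_gap: int = 100,
    min_intra_distance: int = 10_000,
    overlap_tolerance: int = 50,
) -> List[JunctionObservation]:
    """Junction observations from query-adjacent segment pairs.

    A pair qualifies when both segments align at least ``min_segment`` query
    bases, the gap between them on the read is at most ``max_query_gap`` (and
    at least -``overlap_tolerance``), and they map to different chromosomes or
    to loci at least ``min_intra_distance`` apart. posA/posB are the
    junction-facing aligned bases, strand-aware: for a '+' segment the
    junction-facing end going 5'->3' on the query is its reference end (A
    side) or start (B side); for a '-' segment the reverse.
    """
    out: List[JunctionObservation] = []
    for rs in read_sets:
        for a, b in zip(rs.segments, rs.segments[1:]):
            if a.query_length < min_segment or b.query_length < min_segment:
                continue
            gap = b.query_start - a.query_end
            if gap > max_query_gap or gap < -overlap_tolerance:
                continue
            posA = a.ref_end - 1 if a.strand == "+" else a.ref_start
            posB = b.ref_start if b.strand == "+" else b.ref_end - 1
            if a.chrom == b.chrom and abs(posA - posB) <= min_intra_distance:
                continue
            out.append(
                JunctionObservation(
                    read_id=rs.read_id,
                    chromA=a.chrom,
                    posA=posA,
                    chromB=b.chrom,
                    posB=posB,
                    strandA=a.strand,
                    strandB=b.strand,
                    query_gap=gap,
                )
            )
    return out


def _lower_median(values: Sequence[int]) -> int:
    """Median with the lower of the two middles for even n (deterministic)."""
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def cluster_junctions(
    observations: Sequence[JunctionObservation],
    tolerance: int = 50,
    min_support: int = 3,
) -> List[FusionCall]:
    """Single-linkage clustering of junctions into consensus fusion calls.

    Observations sharing (chromA, chromB, orientation) are linked when both
    coordinates differ by at most ``tolerance``; connected components become
    calls with per-coordinate (lower) median consensus. Components with fewer
    than ``min_support`` members are dropped.
    """
    if tolerance < 0 or min_support < 1:
        raise ValueError("tolerance >= 0 and min_support >= 1 required")
    groups: Dict[Tuple[str, str, str, str], List[JunctionObservation]] = {}
    for obs in observations:
        groups.setdefault((obs.chromA, obs.chromB, obs.strandA, obs.strandB), []).append(obs)

    calls: List[FusionCall] = []
    for (chromA, chromB, sA, sB), members in sorted(groups.items()):
        # union-find over members within tolerance on both coordinates
        members = sorted(members, key=lambda o: (o.posA, o.posB, o.read_id))
        parent = list(range(len(members)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if members[j].posA - members[i].posA > tolerance:
                    break
                if abs(members[i].posB - members[j].posB) <= tolerance:
                    parent[find(i)] = find(j)
        comps: Dict[int, List[JunctionObservation]] = {}
        for i, obs in enumerate(members):
            comps.setdefault(find(i), []).append(obs)
        for comp in comps.values():
            if len(comp) < min_support:
                continue
            posA = _lower_median([o.posA for o in comp])
            posB = _lower_median([o.posB for o in comp])
            devs = [abs(o.posA - posA) for o in comp] + [abs(o.posB - posB) for o in comp]
            calls.append(
                FusionCall(
                    chromA=chromA,
                    posA=posA,
                    chromB=chromB,
                    posB=posB,
                    strandA=sA,
                    strandB=sB,
                    n_supporting_reads=len(comp),
                    read_ids=sorted(o.read_id for o in comp),
                    mad=float(np.median(devs)),
                )
            )
    calls.sort(key=lambda c: (c.chromA, c.posA, c.chromB, c.posB))
    return calls


def classify_fusion(
    call: FusionCall,
    annotation: Sequence[Feature],
    table: Optional[Dict[Tuple[str, str], str]] = None,
) -> str:
    """Transcript label from the annotated introns containing each breakpoint.

    The default table maps (breakpoint-cluster intron 13, partner intron 1) to
    b2a2 and (intron 14, intron 1) to b3a2; anything outside annotated introns
    is 'unclassified'.
    """
    introns = [f for f in annotation if f.role == "intron"]
    if not introns:
        raise ValueError("annotation contains no introns")
    if table is None:
        table = DEFAULT_TRANSCRIPT_TABLE

    def containing(chrom: str, pos: int) -> Optional[str]:
        for f in introns:
            if f.chrom == chrom and f.start <= pos < f.end:
                return f.name
        return None

    ia = containing(call.chromA, call.posA)
    ib = containing(call.chromB, call.posB)
    if ia is None or ib is None:
        return "unclassified"
    return table.get((ia, ib), "unclassified")


# ---------------------------------------------------------------------------
# reporting: BEDPE + VCF BND
# ---------------------------------------------------------------------------

def _bnd_alts(call: FusionCall, ref: str = "N") -> Tuple[str, str]:
    """Bracketed BND ALT pair for the call's joined sides.

    Side A is the right flank of posA when strandA is '+', else the left; side
    B mirrors with '+' meaning left flank.
    """
    pa, pb = call.posA + 1, call.posB + 1
    right_a = call.strandA == "+"
    left_b = call.strandB == "+"
    if right_a and left_b:
        return f"{ref}[{call.chromB}:{pb}[", f"]{call.chromA}:{pa}]{ref}"
    if right_a and not left_b:
        return f"{ref}]{call.chromB}:{pb}]", f"{ref}]{call.chromA}:{pa}]"
    if not right_a and left_b:
        return f"]{call.chromB}:{pb}]{ref}", f"{ref}[{call.chromA}:{pa}["
    return f"[{call.chromB}:{pb}[{ref}", f"[{call.chromA}:{pa}[{ref}"


def report_fusions(
    calls: Sequence[FusionCall],
    bedpe_path: str,
    vcf_path: str,
    contigs: Optional[Dict[str, int]] = None,
) -> None:
    """Write consensus calls as BEDPE (0-based half-open single-base intervals)
    and as VCF 4.2 breakend mate pairs (1-based, cross-referenced by ID)."""
    with open(bedpe_path, "w") as fh:
        fh.write(
            "#chromA\tstartA\tendA\tchromB\tstartB\tendB\tname\tsupport\tstrandA\tstrandB\tmad\tlabel\n"
        )
        for i, c in enumerate(calls):
            fh.write(
                f"{c.chromA}\t{c.posA}\t{c.posA + 1}\t{c.chromB}\t{c.posB}\t{c.posB + 1}"
                f"\tfusion{i}\t{c.n_supporting_reads}\t{c.strandA}\t{c.strandB}"
                f"\t{c.mad}\t{c.label}\n"
            )
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for cname, clen in (contigs or {}).items():
            fh.write(f"##contig=<ID={cname},length={clen}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend">\n')
        fh.write('##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting reads">\n')
        fh.write('##INFO=<ID=LABEL,Number=1,Type=String,Description="Transcript label">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, c in enumerate(calls):
            alt_a, alt_b = _bnd_alts(c)
            ida, idb = f"bnd_{i}_A", f"bnd_{i}_B"
            info = f"SVTYPE=BND;SUPPORT={c.n_supporting_reads};LABEL={c.label}"
            fh.write(
                f"{c.chromA}\t{c.posA + 1}\t{ida}\tN\t{alt_a}\t.\tPASS\t{info};MATEID={idb}\n"
            )
            fh.write(
                f"{c.chromB}\t{c.posB + 1}\t{idb}\tN\t{alt_b}\t.\tPASS\t{info};MATEID={ida}\n"
            )


def read_bedpe(path: str) -> List[FusionCall]:
    """Reparse a BEDPE written by :func:`report_fusions`."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            support = int(f[7])
            out.append(
                FusionCall(
                    chromA=f[0],
                    posA=int(f[1]),
                    chromB=f[3],
                    posB=int(f[4]),
                    strandA=f[8],
                    strandB=f[9],
                    n_supporting_reads=support,
                    read_ids=[""] * support,  # member ids are not serialised in BEDPE
                    mad=float(f[10]),
                    label=f[11],
                )
            )
    return out
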