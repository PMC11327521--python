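"""Pileup SNV calling and multi-caller concordance analytics.

The caller is a transparent pileup genotyper: per column, genotype likelihoods
for RR/RA/AA follow Binomial(depth, f) on the alt-allele count with
f = e, 0.5, 1-e (e = column error rate from mean base quality, floored at
1e-3), a flat prior, and QUAL = -10 log10 P(RR | data). The concordance
analytics (UpSet-style intersection cells, depth effects, QUAL-depth
correlation) are caller-agnostic set operations that also accept external
VCFs, so real caller outputs can be compared the same way.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .synthetic_data import ToyGenome

logger = logging.getLogger(__name__)

__all__ = [
    "PileupColumn",
    "Pileup",
    "SNVCall",
    "CallerSetComparison",
    "build_pileup",
    "call_snvs",
    "intersect_callsets",
    "depth_effect",
    "qual_depth_correlation",
    "write_vcf",
    "read_vcf",
    "kd_region_span_bp",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

# Published K562 coordinates (hg38, 1-based) for the BCR-ABL1 assay: the ABL1
# breakpoint and the ABL1 kinase-domain guide target delimit the region in
# which kinase-domain SNVs are evaluated.
HG38_ABL1_BREAKPOINT = 130_731_760
HG38_ABL1_KD_CRRNA_SITE = 130_888_808
HG38_BCR_BREAKPOINT = 23_290_555


def kd_region_span_bp() -> int:
    """Length in bp of the kinase-domain evaluation region on chromosome 9:
    the span between the ABL1 breakpoint and the ABL1 guide target site."""
    return abs(HG38_ABL1_KD_CRRNA_SITE - HG38_ABL1_BREAKPOINT)


@dataclass
class PileupColumn:
    chrom: str
    pos: int
    ref: str
    counts: np.ndarray  # A, C, G, T
    n_del: int
    qual_sum: float  # summed base qualities of counted bases

    @property
    def depth(self) -> int:
        return int(self.counts.sum()) + self.n_del

    @property
    def mean_qual(self) -> float:
        n = int(self.counts.sum())
        return self.qual_sum / n if n else 0.0


@dataclass
class SNVCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str  # "het" | "hom_alt"
    depth: int
    allele_fraction: float
    qual: float
    posterior: Tuple[float, float, float] = (0.0, 0.0, 0.0)  # P(RR), P(RA), P(AA)
    multiallelic: bool = False

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


class Pileup(List[PileupColumn]):
    """List of pileup columns plus a side tally of insertion events keyed by
    anchor position."""

    def __init__(self, columns: Iterable[PileupColumn], insertions: Dict[int, int]):
        super().__init__(columns)
        self.insertions = insertions


def build_pileup(
    sam_path: str,
    genome: ToyGenome,
    region: Tuple[str, int, int],
    min_base_quality: int = 7,
) -> Pileup:
    """CIGAR-aware pileup over [start, end), 0-based half-open.

    Bases below the quality floor are masked (not counted); deletions are
    tallied per column; insertions are tallied against their anchor column in
    a side count (``insertions`` attribute on the returned list).
    """
    chrom, start, end = region
    if chrom not in genome.chromosomes:
        raise ValueError(f"region chromosome {chrom} not in genome")
    n = end - start
    counts = np.zeros((4, n), dtype=np.int64)
    dels = np.zeros(n, dtype=np.int64)
    qsum = np.zeros(n, dtype=np.float64)
    ins_tally: Dict[int, int] = {}

    with pysam.AlignmentFile(sam_path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                continue
            if rec.reference_name != chrom:
                continue
            if rec.reference_end <= start or rec.reference_start >= end:
                continue
            seq = rec.query_sequence
            quals = rec.query_qualities
            qpos, rpos = 0, rec.reference_start
            for op, length in rec.cigartuples:
                if op in (0, 7, 8):  # M, =, X
                    lo = max(rpos, start)
                    hi = min(rpos + length, end)
                    if lo < hi:
                        q0 = qpos + (lo - rpos)
                        codes = np.frombuffer(
                            seq[q0 : q0 + (hi - lo)].encode(), dtype=np.uint8
                        )
                        qv = np.asarray(quals[q0 : q0 + (hi - lo)], dtype=np.float64)
                        cols = np.arange(lo - start, hi - start)
                        ok = qv >= min_base_quality
                        for bi, base in enumerate(_BASES):
                            mask = ok & (codes == ord(base))
                            np.add.at(counts[bi], cols[mask], 1)
                            qsum[cols[mask]] += qv[mask]
                    qpos += length
                    rpos += length
                elif op == 1:  # I: anchor on preceding column
                    if start <= rpos - 1 < end:
                        ins_tally[rpos - 1] = ins_tally.get(rpos - 1, 0) + 1
                    qpos += length
                elif op in (2, 3):  # D, N
                    lo = max(rpos, start)
                    hi = min(rpos + length, end)
                    if lo < hi and op == 2:
                        dels[lo - start : hi - start] += 1
                    rpos += length
                elif op == 4:  # S
                    qpos += length
                # H, P consume nothing

    refseq = genome.chromosomes[chrom][start:end]
    columns = [
        PileupColumn(
            chrom=chrom,
            pos=start + i,
            ref=refseq[i],
            counts=counts[:, i].copy(),
            n_del=int(dels[i]),
            qual_sum=float(qsum[i]),
        )
        for i in range(n)
    ]
    return Pileup(columns, dict(sorted(ins_tally.items())))


def genotype_posteriors(
    depth: int, alt_count: int, error_rate: float
) -> Tuple[float, float, float]:
    """Flat-prior posteriors of RR/RA/AA from Binomial(depth, f) likelihoods
    on the alt count, with f = e, 0.5, 1-e."""
    e = max(error_rate, 1e-3)
    fs = np.array([e, 0.5, 1.0 - e])
    logl = stats.binom.logpmf(alt_count, depth, fs)
    w = np.exp(logl - logl.max())
    post = w / w.sum()
    return float(post[0]), float(post[1]), float(post[2])


def call_snvs(
    pileup: Sequence[PileupColumn],
    min_depth: int = 10,
    min_alt_count: int = 4,
    min_alt_fraction: float = 0.2,
    min_qual: float = 20.0,
    error_rate: Optional[float] = None,
) -> List[SNVCall]:
    """Genotype each column and emit non-reference calls passing thresholds.

    QUAL is the phred-scaled posterior probability that the site is reference
    (-10 log10 P(RR | data), capped at 5000). The alt allele is the
    highest-count non-reference base; other non-reference bases present at or
    above ``min_alt_count`` flag the call multi-allelic.
    """
    calls: List[SNVCall] = []
    for col in pileup:
        if col.ref not in _BASE_INDEX:
            continue
        depth = col.depth
        if depth < min_depth:
            continue
        ref_i = _BASE_INDEX[col.ref]
        alt_counts = col.counts.copy()
        alt_counts[ref_i] = -1
        alt_i = int(alt_counts.argmax())
        n_alt = int(col.counts[alt_i])
        if n_alt < min_alt_count:
            continue
        frac = n_alt / depth
        if frac < min_alt_fraction:
            continue
        e = error_rate if error_rate is not None else 10 ** (-col.mean_qual / 10)
        p_rr, p_ra, p_aa = genotype_posteriors(depth, n_alt, e)
        qual = 5000.0 if p_rr == 0 else min(-10.0 * np.log10(p_rr), 5000.0)
        if qual < min_qual:
            continue
        others = [
            int(c)
            for i, c in enumerate(col.counts)
            if i not in (ref_i, alt_i) and c >= min_alt_count
        ]
        calls.append(
            SNVCall(
                chrom=col.chrom,
                pos=col.pos,
                ref=col.ref,
                alt=_BASES[alt_i],
                genotype="het" if p_ra >= p_aa else "hom_alt",
                depth=depth,
                allele_fraction=frac,
                qual=float(qual),
                posterior=(p_rr, p_ra, p_aa),
                multiallelic=bool(others),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# caller concordance analytics
# ---------------------------------------------------------------------------

VariantKey = Tuple[str, int, str, str]


@dataclass
class CallerSetComparison:
    """UpSet-style exact disjoint intersection cells over named callsets."""

    callers: List[str]
    sets: Dict[str, FrozenSet[VariantKey]]
    cells: Dict[FrozenSet[str], int]
    cell_members: Dict[FrozenSet[str], List[VariantKey]]

    @property
    def union_size(self) -> int:
        return len(frozenset().union(*self.sets.values())) if self.sets else 0


def intersect_callsets(
    callsets: Mapping[str, Iterable[VariantKey]]
) -> CallerSetComparison:
    """Exact disjoint-cell counts for every non-empty caller combination.

    Cells partition the union: each variant is counted once, in the cell of
    exactly the callers that detected it.
    """
    if len(callsets) < 2:
        raise ValueError("need at least two callsets")
    sets = {name: frozenset(keys) for name, keys in callsets.items()}
    callers = sorted(sets)
    cells: Dict[FrozenSet[str], int] = {}
    members: Dict[FrozenSet[str], List[VariantKey]] = {}
    for r in range(1, len(callers) + 1):
        for combo in itertools.combinations(callers, r):
            cells[frozenset(combo)] = 0
            members[frozenset(combo)] = []
    for key in sorted(frozenset().union(*sets.values())):
        combo = frozenset(name for name in callers if key in sets[name])
        cells[combo] += 1
        members[combo].append(key)
    return CallerSetComparison(callers, sets, cells, members)


def depth_effect(
    comparison: CallerSetComparison,
    depths: Mapping[VariantKey, float],
) -> pd.DataFrame:
    """Per-cell depth summaries plus a depth ~ detected-by-all correlation.

    Returns a DataFrame (one row per non-empty combination cell) with n,
    median depth and IQR, and stores the point-biserial correlation between
    depth and the all-caller indicator in ``df.attrs['point_biserial']``
    (0 when either variable has zero variance). Variants without a depth are
    excluded from the summaries and correlation (tracked in ``n_with_depth``).
    """
    rows = []
    all_combo = frozenset(comparison.callers)
    depths_vec: List[float] = []
    indicator: List[int] = []
    for combo, keys in sorted(
        comparison.cell_members.items(), key=lambda kv: sorted(kv[0])
    ):
        d = [depths[k] for k in keys if k in depths]
        rows.append(
            {
                "combination": "&".join(sorted(combo)),
                "n": len(keys),
                "n_with_depth": len(d),
                "median_depth": float(np.median(d)) if d else float("nan"),
                "iqr_depth": float(np.subtract(*np.percentile(d, [75, 25]))) if d else float("nan"),
            }
        )
        depths_vec.extend(d)
        indicator.extend([int(combo == all_combo)] * len(d))
    df = pd.DataFrame(rows)
    dv, iv = np.asarray(depths_vec, float), np.asarray(indicator, float)
    if len(dv) >= 2 and dv.std() > 0 and iv.std() > 0:
        r = float(stats.pointbiserialr(iv, dv).statistic)
    else:
        r = 0.0
    df.attrs["point_biserial"] = r
    return df


def qual_depth_correlation(
    calls: Sequence[SNVCall],
) -> Tuple[Optional[float], int, Optional[str]]:
    """Pearson r between QUAL and depth over a callset.

    Returns (r, n, reason); r is None with a reason when n < 3 or either
    variable has zero variance.
    """
    q = np.array([c.qual for c in calls], dtype=float)
    d = np.array([c.depth for c in calls], dtype=float)
    n = len(calls)
    if n < 3:
        return None, n, "fewer than 3 calls"
    if q.std() == 0 or d.std() == 0:
        return None, n, "zero variance"
    r = float(stats.pearsonr(q, d).statistic)
    return r, n, None


# ---------------------------------------------------------------------------
# VCF emission / parsing
# ---------------------------------------------------------------------------

def write_vcf(
    calls: Sequence[SNVCall], genome: ToyGenome, path: str
) -> None:
    """VCF 4.2 with 1-based POS; INFO carries DP and AF; GT in the sample column."""
    ordered = sorted(calls, key=lambda c: (c.chrom, c.pos))
    if list(ordered) != list(calls):
        logger.info("calls were unsorted; sorted on write")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, s in genome.chromosomes.items():
            fh.write(f"##contig=<ID={c},length={len(s)}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Alt allele fraction">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for v in ordered:
            gt = "0/1" if v.genotype == "het" else "1/1"
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t{v.qual:.6g}\tPASS"
                f"\tDP={v.depth};AF={v.allele_fraction:.6g}\tGT\t{gt}\n"
            )


def read_vcf(path: str) -> List[SNVCall]:
    """Parse a VCF of SNVs (ours or an external caller's) into SNVCall records.

    Only single-base REF/ALT records are returned; DP/AF default to 0 when the
    INFO field lacks them.
    """
    out: List[SNVCall] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            chrom, pos, _, ref, alt, qual = f[0], int(f[1]) - 1, f[2], f[3], f[4], f[5]
            if len(ref) != 1 or len(alt) != 1 or alt == ".":
                continue
            info = dict(
                kv.split("=", 1) if "=" in kv else (kv, "1")
                for kv in f[7].split(";")
                if kv
            )
            gt = "het"
            if len(f) > 9 and f[9].split(":")[0] in ("1/1", "1|1"):
                gt = "hom_alt"
            out.append(
                SNVCall(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    genotype=gt,
                    depth=int(float(info.get("DP", 0))),
                    allele_fraction=float(info.get("AF", 0.0)),
                    qual=0.0 if qual == "." else float(qual),
                )
            )
    return out
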