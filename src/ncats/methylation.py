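"""CpG 5mC aggregation, pattern segmentation, and bisulfite concordance.

Per-read binary CpG calls (from MM/ML tags via :mod:`ncats.alignment_io`, or
any per-read call table) are pooled on the plus-strand C coordinate into
per-site methylation frequencies; sites are segmented into
hypo/intermediate/hyper runs to characterise promoter/CpG-island patterns;
and long-read frequencies are compared to bisulfite-amplicon (BSAS) counts by
inner join, Pearson correlation and mean absolute difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .synthetic_data import BSASRecord

logger = logging.getLogger(__name__)

__all__ = [
    "MethSiteRecord",
    "MethRegionSummary",
    "aggregate_sites",
    "segment_pattern",
    "region_means",
    "bsas_call",
    "concordance",
    "write_bedmethyl",
]


@dataclass
class MethSiteRecord:
    chrom: str
    pos: int  # plus-strand C of the CpG
    n_meth: int
    n_total: int
    low_confidence: bool = False

    @property
    def freq(self) -> float:
        return self.n_meth / self.n_total

    def __post_init__(self) -> None:
        assert 0 <= self.n_meth <= self.n_total


@dataclass
class MethRegionSummary:
    region_id: str
    chrom: str
    start: int
    end: int  # half-open; for site runs, end = last site + 1
    n_sites: int
    mean_freq: Optional[float]
    label: str  # hypo | hyper | intermediate | (n_sites==0 -> "empty")


def aggregate_sites(
    read_calls: Mapping[str, Mapping[int, int]],
    chrom: str,
    min_depth: int = 5,
) -> List[MethSiteRecord]:
    """Pool per-read binary calls into per-site frequencies.

    Sites seen in fewer than ``min_depth`` reads are retained but flagged
    low-confidence. Sites with no informative reads simply do not appear.
    """
    n_meth: Dict[int, int] = {}
    n_total: Dict[int, int] = {}
    for calls in read_calls.values():
        for pos, state in calls.items():
            n_total[pos] = n_total.get(pos, 0) + 1
            n_meth[pos] = n_meth.get(pos, 0) + int(state)
    return [
        MethSiteRecord(
            chrom=chrom,
            pos=pos,
            n_meth=n_meth[pos],
            n_total=n_total[pos],
            low_confidence=n_total[pos] < min_depth,
        )
        for pos in sorted(n_total)
    ]


def segment_pattern(
    records: Sequence[MethSiteRecord],
    hypo_threshold: float = 0.3,
    hyper_threshold: float = 0.7,
    min_run: int = 3,
) -> List[MethRegionSummary]:
    """Segment sites into maximal hypo/intermediate/hyper runs.

    Each site is labeled by its frequency against the two thresholds; maximal
    runs of at least ``min_run`` same-label sites become regions, and shorter
    runs are merged into the flanking run whose mean frequency is nearer.
    """
    if not hypo_threshold < hyper_threshold:
        raise ValueError("hypo_threshold must be < hyper_threshold")
    if not records:
        return []
    ordered = sorted(records, key=lambda r: r.pos)

    def site_label(f: float) -> str:
        if f < hypo_threshold:
            return "hypo"
        if f > hyper_threshold:
            return "hyper"
        return "intermediate"

    # runs as [label, [records...]]
    runs: List[List] = []
    for rec in ordered:
        lab = site_label(rec.freq)
        if runs and runs[-1][0] == lab:
            runs[-1][1].append(rec)
        else:
            runs.append([lab, [rec]])

    def run_mean(run) -> float:
        return float(np.mean([r.freq for r in run[1]]))

    # merge short runs into the nearer-mean flank, shortest first
    while len(runs) > 1:
        short = [i for i, run in enumerate(runs) if len(run[1]) < min_run]
        if not short:
            break
        i = min(short, key=lambda i: len(runs[i][1]))
        candidates = [j for j in (i - 1, i + 1) if 0 <= j < len(runs)]
        j = min(
            candidates,
            key=lambda j: abs(run_mean(runs[j]) - run_mean(runs[i])),
        )
        lo, hi = min(i, j), max(i, j)
        merged_records = runs[lo][1] + runs[hi][1]
        runs[lo] = [runs[j][0], merged_records]
        del runs[hi]
        # adjacent runs may now share a label; coalesce
        k = 0
        while k + 1 < len(runs):
            if runs[k][0] == runs[k + 1][0]:
                runs[k] = [runs[k][0], runs[k][1] + runs[k + 1][1]]
                del runs[k + 1]
            else:
                k += 1

    return [
        MethRegionSummary(
            region_id=f"run{idx}",
            chrom=run[1][0].chrom,
            start=run[1][0].pos,
            end=run[1][-1].pos + 1,
            n_sites=len(run[1]),
            mean_freq=run_mean(run),
            label=run[0],
        )
        for idx, run in enumerate(runs)
    ]


def region_means(
    records: Sequence[MethSiteRecord],
    regions: Sequence[Tuple[str, str, int, int]],
    hypo_threshold: float = 0.3,
    hyper_threshold: float = 0.7,
) -> List[MethRegionSummary]:
    """Unweighted mean site frequency per fixed region (amplicon-style)."""
    if not regions:
        raise ValueError("no regions given")
    out = []
    for region_id, chrom, start, end in regions:
        freqs = [r.freq for r in records if r.chrom == chrom and start <= r.pos < end]
        if not freqs:
            out.append(
                MethRegionSummary(region_id, chrom, start, end, 0, None, "empty")
            )
            continue
        m = float(np.mean(freqs))
        label = "hypo" if m < hypo_threshold else "hyper" if m > hyper_threshold else "intermediate"
        out.append(
            MethRegionSummary(region_id, chrom, start, end, len(freqs), m, label)
        )
    return out


def bsas_call(
    records: Sequence[BSASRecord],
    conversion_efficiency: float = 1.0,
) -> List[MethSiteRecord]:
    """Per-site methylation frequency from bisulfite-amplicon counts.

    With imperfect conversion c < 1, the raw retained fraction is corrected as
    clamp((raw - (1-c)) / c, 0, 1); counts are rescaled so the record still
    carries its depth. Zero-total records are dropped with a warning.
    """
    if not 0 < conversion_efficiency <= 1:
        raise ValueError("conversion efficiency must be in (0, 1]")
    c = conversion_efficiency
    out = []
    n_dropped = 0
    for r in records:
        total = r.n_retained + r.n_converted
        if total == 0:
            n_dropped += 1
            continue
        raw = r.n_retained / total
        corrected = min(max((raw - (1 - c)) / c, 0.0), 1.0)
        out.append(
            MethSiteRecord(
                chrom=r.chrom,
                pos=r.pos,
                n_meth=int(round(corrected * total)),
                n_total=total,
            )
        )
    if n_dropped:
        logger.warning("dropped %d BSAS records with zero total count", n_dropped)
    return out


def concordance(
    ncats_records: Sequence[MethSiteRecord],
    bsas_records: Sequence[MethSiteRecord],
    min_depth: int = 5,
) -> dict:
    """Site-matched concordance between long-read and bisulfite frequencies.

    Inner join on (chrom, pos) with both depths >= min_depth; reports Pearson
    r, mean absolute difference, and the matched pairs. r is absent (with a
    reason) below 3 pairs or at zero variance.
    """
    a = {
        (r.chrom, r.pos): r.freq
        for r in ncats_records
        if r.n_total >= min_depth
    }
    b = {
        (r.chrom, r.pos): r.freq
        for r in bsas_records
        if r.n_total >= min_depth
    }
    keys = sorted(set(a) & set(b))
    xs = np.array([a[k] for k in keys])
    ys = np.array([b[k] for k in keys])
    result = {
        "n_pairs": len(keys),
        "pairs": [
            {"chrom": k[0], "pos": k[1], "ncats": float(x), "bsas": float(y)}
            for k, x, y in zip(keys, xs, ys)
        ],
        "pearson_r": None,
        "mean_abs_diff": float(np.mean(np.abs(xs - ys))) if keys else None,
        "reason": None,
    }
    if len(keys) < 3:
        result["reason"] = "fewer than 3 matched sites"
    elif xs.std() == 0 or ys.std() == 0:
        result["reason"] = "zero variance in matched frequencies"
    else:
        result["pearson_r"] = float(stats.pearsonr(xs, ys).statistic)
    return result


def write_bedmethyl(records: Sequence[MethSiteRecord], path: str) -> None:
    """bedMethyl-style TSV: chrom, start, end, freq, n_meth, n_total."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tfreq\tn_meth\tn_total\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{r.freq:.6g}\t{r.n_meth}\t{r.n_total}\n"
            )
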