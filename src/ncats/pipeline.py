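"""Stage orchestration: composable pipeline stages over file interfaces.

Stages communicate only through files in standard formats (FASTA/BED/SAM/
VCF/BEDPE/TSV/JSON), so any stage can be replaced by an external tool's
output — e.g. a real caller's VCF can feed ``compare-callers``. Each stage
writes only under its own subdirectory of the run directory and leaves a
manifest (inputs, parameters, derived seed, output hashes); deterministic
stages reproduce byte-identical outputs for identical config and seed.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import os
import zlib
from typing import Dict, List, Optional, Tuple

from . import alignment_io, enrichment_qc, fusion_detection, methylation, snv
from . import synthetic_data as sd

logger = logging.getLogger(__name__)

__all__ = [
    "STAGES",
    "ConfigError",
    "default_config",
    "load_config",
    "validate_config",
    "stage_seed",
    "run_stage",
    "make_report",
]

STAGES = ["simulate", "qc", "fusion", "snv", "compare-callers", "meth", "report"]

REPORT_SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Invalid pipeline configuration (unknown key or bad value)."""


def default_config() -> dict:
    return {
        "seed": 0,
        "out_dir": "ncats_run",
        "paths": {
            "genome_fasta": None,
            "features_bed": None,
            "crrna_tsv": None,
            "alignments": None,
            "bsas_tsv": None,
            "callsets": {},  # caller name -> VCF path (compare-callers)
        },
        "simulate": {
            "n_reads_per_cut": 500,
            "sub_rate": 0.01,
            "ins_rate": 0.0025,
            "del_rate": 0.0025,
            "jitter": 2,
            "read_length_mean": 8000,
            "read_length_sd": 800,
            "fusion_fraction": 0.5,
            "fusion_bp": [15200, 10000],
            "n_snvs": 10,
            "snv_vaf": 0.5,
            "p_high": 0.9,
            "p_low": 0.1,
            "bsas_depth": 100,
            "conversion_efficiency": 1.0,
        },
        "qc": {"window": 20},
        "fusion": {
            "min_segment": 200,
            "max_query_gap": 100,
            "tolerance": 50,
            "min_support": 3,
        },
        "snv": {
            "min_depth": 10,
            "min_alt_count": 4,
            "min_alt_fraction": 0.2,
            "min_qual": 20.0,
            "min_base_quality": 7,
            "region": None,  # "chrom:start-end" (1-based inclusive); default: ABL1_KD ROI
        },
        "meth": {
            "min_depth": 5,
            "hypo_threshold": 0.3,
            "hyper_threshold": 0.7,
            "min_run": 3,
            "threshold": 0.5,
            "conversion_efficiency": 1.0,
        },
    }


def validate_config(config: dict) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys."""
    defaults = default_config()

    def merge(base: dict, user: dict, path: str) -> dict:
        out = copy.deepcopy(base)
        for key, value in user.items():
            if key not in base:
                raise ConfigError(f"unknown config key: {path}{key}")
            if isinstance(base[key], dict) and key != "callsets":
                if not isinstance(value, dict):
                    raise ConfigError(f"{path}{key} must be a mapping")
                out[key] = merge(base[key], value, f"{path}{key}.")
            else:
                out[key] = value
        return out

    return merge(defaults, config or {}, "")


def load_config(path: Optional[str]) -> dict:
    if path is None:
        return default_config()
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return validate_config(raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: (seed + crc32(stage)) mod 2^31."""
    return (int(global_seed) + zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(stage_dir: str, stage: str, seed: int, params: dict, inputs: dict) -> None:
    outputs = {
        name: _sha256(os.path.join(stage_dir, name))
        for name in sorted(os.listdir(stage_dir))
        if name != "manifest.json"
    }
    with open(os.path.join(stage_dir, "manifest.json"), "w") as fh:
        json.dump(
            {"stage": stage, "seed": seed, "parameters": params, "inputs": inputs, "outputs": outputs},
            fh,
            indent=1,
            sort_keys=True,
        )


def _require(path: Optional[str], what: str) -> str:
    if path is None or not os.path.exists(path):
        raise FileNotFoundError(f"missing input for {what}: {path}")
    return path


def _resolve(config: dict, key: str, default_rel: str) -> str:
    explicit = config["paths"].get(key)
    if explicit:
        return _require(explicit, key)
    return _require(os.path.join(config["out_dir"], "simulate", default_rel), key)


def _load_genome(config: dict) -> sd.ToyGenome:
    fasta = _resolve(config, "genome_fasta", "genome.fasta")
    bed = _resolve(config, "features_bed", "features.bed")
    return sd.ToyGenome.from_files(fasta, bed)


def _parse_region(text: str) -> Tuple[str, int, int]:
    chrom, span = text.rsplit(":", 1)
    lo, hi = span.replace(",", "").split("-")
    return chrom, int(lo) - 1, int(hi)  # 1-based inclusive -> 0-based half-open


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: dict, stage_dir: str, seed: int) -> dict:
    p = config["simulate"]
    bundle = sd.simulate_run(
        seed=seed,
        fusion_bp=tuple(p["fusion_bp"]) if p["fusion_bp"] else None,
        n_snvs=p["n_snvs"],
        snv_vaf=p["snv_vaf"],
        p_high=p["p_high"],
        p_low=p["p_low"],
        bsas_depth=p["bsas_depth"],
        conversion_efficiency=p["conversion_efficiency"],
        jitter=p["jitter"],
        n_reads_per_cut=p["n_reads_per_cut"],
        sub_rate=p["sub_rate"],
        ins_rate=p["ins_rate"],
        del_rate=p["del_rate"],
        read_length_mean=p["read_length_mean"],
        read_length_sd=p["read_length_sd"],
        fusion_fraction=p["fusion_fraction"],
    )
    bundle.genome.write_fasta(os.path.join(stage_dir, "genome.fasta"))
    bundle.genome.write_bed(os.path.join(stage_dir, "features.bed"))
    sd.write_crrna_tsv(bundle.crrnas, os.path.join(stage_dir, "crrnas.tsv"))
    sd.write_fastq(bundle.reads, os.path.join(stage_dir, "reads.fastq"))
    sd.write_truth_sam(bundle.reads, bundle.genome, os.path.join(stage_dir, "truth.sam"))
    sd.write_truth_vcf(bundle.truth.snvs, bundle.genome, os.path.join(stage_dir, "truth_snvs.vcf"))
    sd.write_bsas_tsv(bundle.bsas, os.path.join(stage_dir, "bsas.tsv"))
    bundle.truth.to_json(os.path.join(stage_dir, "truthset.json"))
    return {
        "n_reads": len(bundle.reads),
        "n_snvs": len(bundle.truth.snvs),
        "n_cpg_sites": len(bundle.truth.meth_profile),
    }


def _stage_qc(config: dict, stage_dir: str, seed: int) -> dict:
    genome = _load_genome(config)
    crrnas = sd.read_crrna_tsv(_resolve(config, "crrna_tsv", "crrnas.tsv"))
    aln = alignment_io.read_alignments(_resolve(config, "alignments", "truth.sam"))
    read_sets = alignment_io.group_by_read(aln)
    rois = genome.features_by_role("ROI")
    reports = enrichment_qc.count_on_target(read_sets, rois)
    hits, n_off, hists = enrichment_qc.cut_site_profile(
        read_sets, crrnas, genome, window=config["qc"]["window"]
    )
    with open(os.path.join(stage_dir, "roi_report.tsv"), "w") as fh:
        fh.write("roi\tchrom\tstart\tend\tn_overlapping\tn_fully_covering\tmean_depth\n")
        for r in reports:
            fh.write(
                f"{r.name}\t{r.chrom}\t{r.start}\t{r.end}\t{r.n_reads_overlapping}"
                f"\t{r.n_reads_fully_covering}\t{r.mean_depth:.2f}\n"
            )
    with open(os.path.join(stage_dir, "cut_sites.tsv"), "w") as fh:
        fh.write("crrna\tread_id\tobserved\toffset\tpam_ok\n")
        for h in hits:
            fh.write(f"{h.crrna}\t{h.read_id}\t{h.observed}\t{h.offset}\t{int(h.pam_motif_ok)}\n")
    with open(os.path.join(stage_dir, "depth.bedgraph"), "w") as fh:
        for r in reports:
            prev = None
            run_start = r.start
            for i, d in enumerate(list(r.depth) + [None]):
                if d != prev and prev is not None:
                    fh.write(f"{r.chrom}\t{run_start}\t{r.start + i}\t{prev}\n")
                    run_start = r.start + i
                elif prev is None:
                    run_start = r.start + i
                prev = d
    summary = {
        "rois": {
            r.name: {
                "n_overlapping": r.n_reads_overlapping,
                "n_fully_covering": r.n_reads_fully_covering,
                "mean_depth": r.mean_depth,
            }
            for r in reports
        },
        "n_cut_site_hits": len(hits),
        "n_off_signature": n_off,
        "pam_ok_fraction": (
            sum(h.pam_motif_ok for h in hits) / len(hits) if hits else None
        ),
        "offset_histograms": {name: dict(sorted(h.items())) for name, h in hists.items()},
    }
    with open(os.path.join(stage_dir, "qc_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary


def _stage_fusion(config: dict, stage_dir: str, seed: int) -> dict:
    genome = _load_genome(config)
    p = config["fusion"]
    aln = alignment_io.read_alignments(_resolve(config, "alignments", "truth.sam"))
    read_sets = alignment_io.group_by_read(aln)
    obs = fusion_detection.find_chimeric_junctions(
        read_sets, min_segment=p["min_segment"], max_query_gap=p["max_query_gap"]
    )
    calls = fusion_detection.cluster_junctions(
        obs, tolerance=p["tolerance"], min_support=p["min_support"]
    )
    for c in calls:
        c.label = fusion_detection.classify_fusion(c, genome.features)
    contigs = {c: len(s) for c, s in genome.chromosomes.items()}
    fusion_detection.report_fusions(
        calls,
        os.path.join(stage_dir, "fusions.bedpe"),
        os.path.join(stage_dir, "fusions.vcf"),
        contigs,
    )
    summary = {
        "n_observations": len(obs),
        "calls": [
            {
                "chromA": c.chromA,
                "posA": c.posA,
                "chromB": c.chromB,
                "posB": c.posB,
                "orientation": c.strandA + c.strandB,
                "support": c.n_supporting_reads,
                "mad": c.mad,
                "label": c.label,
            }
            for c in calls
        ],
    }
    with open(os.path.join(stage_dir, "fusion_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary


def _stage_snv(config: dict, stage_dir: str, seed: int) -> dict:
    genome = _load_genome(config)
    p = config["snv"]
    if p["region"]:
        region = _parse_region(p["region"])
    else:
        kd = genome.feature("ABL1_KD")
        region = (kd.chrom, kd.start, kd.end)
    pileup = snv.build_pileup(
        _resolve(config, "alignments", "truth.sam"),
        genome,
        region,
        min_base_quality=p["min_base_quality"],
    )
    calls = snv.call_snvs(
        pileup,
        min_depth=p["min_depth"],
        min_alt_count=p["min_alt_count"],
        min_alt_fraction=p["min_alt_fraction"],
        min_qual=p["min_qual"],
    )
    snv.write_vcf(calls, genome, os.path.join(stage_dir, "snv_calls.vcf"))
    summary = {
        "region": {"chrom": region[0], "start": region[1], "end": region[2]},
        "n_calls": len(calls),
        "calls": [
            {
                "chrom": c.chrom,
                "pos": c.pos,
                "ref": c.ref,
                "alt": c.alt,
                "genotype": c.genotype,
                "depth": c.depth,
                "allele_fraction": round(c.allele_fraction, 4),
                "qual": round(c.qual, 2),
            }
            for c in calls
        ],
    }
    with open(os.path.join(stage_dir, "snv_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary


def _stage_compare_callers(config: dict, stage_dir: str, seed: int) -> dict:
    callset_paths: Dict[str, str] = dict(config["paths"]["callsets"] or {})
    if not callset_paths:
        # default: compare our calls against the simulator truth VCF
        callset_paths = {
            "pileup": _require(
                os.path.join(config["out_dir"], "snv", "snv_calls.vcf"), "pileup VCF"
            ),
            "truth": _require(
                os.path.join(config["out_dir"], "simulate", "truth_snvs.vcf"),
                "truth VCF",
            ),
        }
    callsets = {}
    depths = {}
    quals = {}
    for name, path in callset_paths.items():
        calls = snv.read_vcf(_require(path, f"callset {name}"))
        callsets[name] = [c.key for c in calls]
        quals[name] = calls
        for c in calls:
            if c.depth:
                depths[c.key] = c.depth
    comparison = snv.intersect_callsets(callsets)
    cells_rows = [
        {"combination": "&".join(sorted(combo)), "n": n}
        for combo, n in sorted(comparison.cells.items(), key=lambda kv: sorted(kv[0]))
    ]
    with open(os.path.join(stage_dir, "intersection_cells.tsv"), "w") as fh:
        fh.write("combination\tn\n")
        for row in cells_rows:
            fh.write(f"{row['combination']}\t{row['n']}\n")
    depth_df = snv.depth_effect(comparison, depths) if depths else None
    if depth_df is not None:
        depth_df.to_csv(os.path.join(stage_dir, "depth_effect.tsv"), sep="\t", index=False)
    corr_rows = []
    for name, calls in quals.items():
        r, n, reason = snv.qual_depth_correlation(calls)
        corr_rows.append({"caller": name, "pearson_r": r, "n": n, "reason": reason})
    with open(os.path.join(stage_dir, "qual_depth.tsv"), "w") as fh:
        fh.write("caller\tpearson_r\tn\treason\n")
        for row in corr_rows:
            r_text = "" if row["pearson_r"] is None else f"{row['pearson_r']:.4f}"
            fh.write(f"{row['caller']}\t{r_text}\t{row['n']}\t{row['reason'] or ''}\n")
    summary = {
        "cells": cells_rows,
        "union_size": comparison.union_size,
        "point_biserial_depth_vs_all_callers": (
            None if depth_df is None else depth_df.attrs["point_biserial"]
        ),
        "qual_depth": corr_rows,
    }
    with open(os.path.join(stage_dir, "compare_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary


def _stage_meth(config: dict, stage_dir: str, seed: int) -> dict:
    genome = _load_genome(config)
    p = config["meth"]
    island = genome.features_by_role("CpG_island")[0]
    calls = alignment_io.read_meth_tags(
        _resolve(config, "alignments", "truth.sam"), threshold=p["threshold"]
    )
    sites = methylation.aggregate_sites(calls, island.chrom, min_depth=p["min_depth"])
    methylation.write_bedmethyl(sites, os.path.join(stage_dir, "meth_sites.tsv"))
    regions = methylation.segment_pattern(
        sites,
        hypo_threshold=p["hypo_threshold"],
        hyper_threshold=p["hyper_threshold"],
        min_run=p["min_run"],
    )
    with open(os.path.join(stage_dir, "meth_regions.tsv"), "w") as fh:
        fh.write("region_id\tchrom\tstart\tend\tn_sites\tmean_freq\tlabel\n")
        for r in regions:
            mean = "" if r.mean_freq is None else f"{r.mean_freq:.4f}"
            fh.write(
                f"{r.region_id}\t{r.chrom}\t{r.start}\t{r.end}\t{r.n_sites}\t{mean}\t{r.label}\n"
            )
    summary: dict = {
        "n_sites": len(sites),
        "regions": [
            {
                "region_id": r.region_id,
                "start": r.start,
                "end": r.end,
                "n_sites": r.n_sites,
                "mean_freq": r.mean_freq,
                "label": r.label,
            }
            for r in regions
        ],
        "concordance": None,
    }
    bsas_path = config["paths"].get("bsas_tsv") or os.path.join(
        config["out_dir"], "simulate", "bsas.tsv"
    )
    if os.path.exists(bsas_path):
        bsas = methylation.bsas_call(
            sd.read_bsas_tsv(bsas_path),
            conversion_efficiency=p["conversion_efficiency"],
        )
        conc = methylation.concordance(sites, bsas, min_depth=p["min_depth"])
        with open(os.path.join(stage_dir, "concordance.json"), "w") as fh:
            json.dump(conc, fh, indent=1)
        summary["concordance"] = {
            "n_pairs": conc["n_pairs"],
            "pearson_r": conc["pearson_r"],
            "mean_abs_diff": conc["mean_abs_diff"],
        }
    with open(os.path.join(stage_dir, "meth_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary


def make_report(out_dir: str, stage_dir: str) -> dict:
    """Aggregate per-stage summaries into one schema-versioned report."""
    sections = {
        "qc": ("qc", "qc_summary.json"),
        "fusion": ("fusion", "fusion_summary.json"),
        "snv": ("snv", "snv_summary.json"),
        "compare_callers": ("compare-callers", "compare_summary.json"),
        "methylation": ("meth", "meth_summary.json"),
    }
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION}
    n_present = 0
    for key, (stage, fname) in sections.items():
        path = os.path.join(out_dir, stage, fname)
        if os.path.exists(path):
            with open(path) as fh:
                report[key] = json.load(fh)
            n_present += 1
        else:
            report[key] = None
    if n_present == 0:
        raise FileNotFoundError(f"no stage outputs found under {out_dir}")
    with open(os.path.join(stage_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1)
    with open(os.path.join(stage_dir, "report.tsv"), "w") as fh:
        fh.write("section\tpresent\n")
        for key in sections:
            fh.write(f"{key}\t{int(report[key] is not None)}\n")
    return report


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "fusion": _stage_fusion,
    "snv": _stage_snv,
    "compare-callers": _stage_compare_callers,
    "meth": _stage_meth,
}


def run_stage(name: str, config: dict, seed: Optional[int] = None) -> dict:
    """Run one pipeline stage; outputs go under <out_dir>/<stage>/.

    The stage seed is derived from the global seed and the stage name; a
    manifest with parameters, inputs and output hashes accompanies every run.
    """
    if name not in STAGES:
        raise ConfigError(f"unknown stage: {name}")
    global_seed = config["seed"] if seed is None else seed
    sseed = stage_seed(global_seed, name)
    stage_dir = os.path.join(config["out_dir"], name)
    os.makedirs(stage_dir, exist_ok=True)
    if name == "report":
        return make_report(config["out_dir"], stage_dir)
    summary = _STAGE_FUNCS[name](config, stage_dir, sseed)
    params = config.get(name.replace("-", "_"), config.get(name, {}))
    inputs = {k: v for k, v in config["paths"].items() if v}
    _write_manifest(stage_dir, name, sseed, params if isinstance(params, dict) else {}, inputs)
    return summary
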