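"""Seeded simulator for Cas9-targeted nanopore sequencing (nCATS) experiments.

Generates a two-chromosome toy genome that mimics the geometry of a
BCR-ABL1-style assay: a promoter + CpG island locus, a major-breakpoint-cluster
region with annotated introns, a kinase-domain region of interest on the
partner chromosome, and SpCas9 guide (crRNA) sites with NGG PAMs. From the
genome it derives a fusion allele, planted heterozygous SNVs, a
high-low-high CpG methylation profile, Cas9-cut-anchored long reads with
configurable error rates and truth alignments (SAM with MM/ML 5mC tags), and
matched bisulfite-amplicon (BSAS) count tables.

All coordinates are 0-based half-open; 1-based coordinates appear only in
emitted SAM/VCF. Every generator is deterministic given its seed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigurationError",
    "Feature",
    "ToyGenome",
    "CrRNASpec",
    "SNV",
    "TruthSet",
    "Allele",
    "SimSegment",
    "SimulatedRead",
    "BSASRecord",
    "SimulationBundle",
    "default_genome_config",
    "make_toy_genome",
    "make_fusion_allele",
    "wild_type_alleles",
    "plant_snvs",
    "methylation_profile",
    "simulate_reads",
    "simulate_bsas",
    "simulate_run",
    "write_fastq",
    "write_truth_sam",
    "write_truth_vcf",
    "write_bsas_tsv",
    "write_crrna_tsv",
    "read_crrna_tsv",
    "revcomp",
]


class ConfigurationError(ValueError):
    """A simulation/layout configuration that cannot be realised."""


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
_RC_TABLE = str.maketrans("ACGT", "TGCA")


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A=0, C=1, G=2, T=3)."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.max(initial=0) > 3:
        raise ValueError("sequence contains characters outside A/C/G/T")
    return arr


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

FEATURE_ROLES = {"ROI", "CpG_island", "promoter", "intron", "exon"}


@dataclass(frozen=True)
class Feature:
    name: str
    chrom: str
    start: int
    end: int
    role: str


@dataclass
class ToyGenome:
    """Synthetic reference: chromosome name -> uppercase DNA, plus features."""

    chromosomes: Dict[str, str]
    features: List[Feature] = field(default_factory=list)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.chromosomes[chrom][start:end]

    def feature(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def features_by_role(self, role: str) -> List[Feature]:
        return [f for f in self.features if f.role == role]

    def validate(self) -> None:
        for chrom, seq in self.chromosomes.items():
            if set(seq) - set("ACGT"):
                raise ConfigurationError(f"{chrom}: non-ACGT characters")
        for f in self.features:
            if f.chrom not in self.chromosomes:
                raise ConfigurationError(f"feature {f.name}: unknown chromosome {f.chrom}")
            n = len(self.chromosomes[f.chrom])
            if not (0 <= f.start < f.end <= n):
                raise ConfigurationError(
                    f"feature {f.name} [{f.start},{f.end}) outside {f.chrom} (length {n})"
                )
            if f.role not in FEATURE_ROLES:
                raise ConfigurationError(f"feature {f.name}: unknown role {f.role}")
        for f in self.features_by_role("CpG_island"):
            if self.fetch(f.chrom, f.start, f.end).count("CG") < 20:
                raise ConfigurationError(f"CpG island {f.name} has <20 CpG dinucleotides")

    def write_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.chromosomes.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    def write_bed(self, path: str) -> None:
        """Features as BED4 + role column (chrom, start, end, name, role)."""
        with open(path, "w") as fh:
            for f in self.features:
                fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.name}\t{f.role}\n")

    @classmethod
    def from_files(cls, fasta: str, bed: Optional[str] = None) -> "ToyGenome":
        chroms: Dict[str, str] = {}
        name = None
        parts: List[str] = []
        with open(fasta) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if name is not None:
                        chroms[name] = "".join(parts)
                    name = line[1:].split()[0]
                    parts = []
                elif line:
                    parts.append(line.upper())
        if name is not None:
            chroms[name] = "".join(parts)
        features: List[Feature] = []
        if bed:
            with open(bed) as fh:
                for line in fh:
                    if not line.strip() or line.startswith(("#", "track")):
                        continue
                    c, s, e, n, role = line.rstrip("\n").split("\t")[:5]
                    features.append(Feature(n, c, int(s), int(e), role))
        return cls(chroms, features)


@dataclass(frozen=True)
class CrRNASpec:
    """An SpCas9 guide: 20 nt protospacer, NGG PAM, blunt cut 3 nt 5' of the PAM.

    ``strand`` is the protospacer strand on the reference. ``pam_start`` is the
    reference start of the 3 nt PAM interval; ``expected_cut`` is the 0-based
    inter-base boundary of the blunt cut. Reads initiate at the cut and extend
    away from the PAM side (the PAM-distal fragment is the one whose fresh end
    receives the sequencing adaptor).
    """

    name: str
    chrom: str
    spacer_seq: str
    strand: str
    pam_start: int
    expected_cut: int

    @property
    def pam_interval(self) -> Tuple[int, int]:
        return (self.pam_start, self.pam_start + 3)

    @property
    def read_direction(self) -> int:
        """+1 when reads extend toward higher coordinates, else -1."""
        return -1 if self.strand == "+" else 1

    def pam_seq(self, genome: ToyGenome) -> str:
        """The PAM 3-mer read 5'->3' on the protospacer strand."""
        raw = genome.fetch(self.chrom, *self.pam_interval)
        return raw if self.strand == "+" else revcomp(raw)


@dataclass(frozen=True)
class SNV:
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float


@dataclass
class TruthSet:
    """Ground truth of one simulated experiment."""

    fusion: Optional[Tuple[str, int, str, int]]  # (chromA, bpA, chromB, bpB)
    snvs: List[SNV]
    meth_profile: Dict[int, float]
    meth_chrom: Optional[str]
    jitter: int
    seed: int

    def to_json(self, path: str) -> None:
        payload = {
            "fusion": list(self.fusion) if self.fusion else None,
            "snvs": [asdict(s) for s in self.snvs],
            "meth_chrom": self.meth_chrom,
            "meth_profile": {str(k): v for k, v in self.meth_profile.items()},
            "jitter": self.jitter,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "TruthSet":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            fusion=tuple(p["fusion"]) if p["fusion"] else None,
            snvs=[SNV(**s) for s in p["snvs"]],
            meth_profile={int(k): v for k, v in p["meth_profile"].items()},
            meth_chrom=p.get("meth_chrom"),
            jitter=p["jitter"],
            seed=p["seed"],
        )


@dataclass
class Allele:
    """A haplotype assembled from reference pieces laid end to end."""

    name: str
    seq: str
    pieces: List[Tuple[str, int, int]]  # (chrom, ref_start, ref_end), '+' orientation

    def __post_init__(self) -> None:
        assert len(self.seq) == sum(e - s for _, s, e in self.pieces)

    def locate(self, chrom: str, start: int, end: int) -> Optional[int]:
        """Allele coordinate of reference position `start` if [start,end) is
        fully contained in a single piece, else None."""
        off = 0
        for c, s, e in self.pieces:
            if c == chrom and s <= start and end <= e:
                return off + (start - s)
            off += e - s
        return None

    def ref_segments(self, a0: int, a1: int) -> List[Tuple[str, int, int]]:
        """Reference intervals covered by allele interval [a0, a1), in allele order."""
        out = []
        off = 0
        for c, s, e in self.pieces:
            lo, hi = max(a0, off), min(a1, off + (e - s))
            if lo < hi:
                out.append((c, s + (lo - off), s + (hi - off)))
            off += e - s
        return out


@dataclass
class SimSegment:
    """One contiguous piece of a read's truth alignment.

    ``query_start/query_end`` are in molecule (original read) orientation;
    ``cigar`` is a list of (op, length) with op in 'MID', in molecule order.
    """

    chrom: str
    ref_start: int
    ref_end: int
    strand: str
    query_start: int
    query_end: int
    cigar: List[Tuple[str, int]]


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str  # molecule orientation, errors applied
    qual: str
    strand: str
    segments: List[SimSegment]  # in query (molecule) order
    cpg_states: Dict[int, int]  # plus-strand CpG C position -> 0/1 truth state
    meth_entries: List[Tuple[int, int]]  # surviving (molecule C index, state)
    crrna: str
    allele: str


@dataclass
class BSASRecord:
    """Per-CpG-site bisulfite-amplicon counts (plus-strand C convention)."""

    region_id: str
    chrom: str
    pos: int
    n_retained: int
    n_converted: int

    @property
    def freq(self) -> float:
        total = self.n_retained + self.n_converted
        return self.n_retained / total if total else float("nan")


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def default_genome_config() -> dict:
    """Two ~34 kb toy chromosomes emulating the assay geometry.

    toy22 carries a promoter + CpG island (methylation locus) and the
    breakpoint-cluster introns 13/14; toy9 carries an intron-1 analog (fusion
    acceptor) and a kinase-domain ROI. Three '-' spacer guides produce
    rightward reads (CpG island / fusion junction downstream of their cuts);
    the '+' spacer guide produces leftward reads covering the kinase domain.
    """
    return {
        "chromosomes": {"toy22": 34_000, "toy9": 34_000},
        "features": [
            ("BCR_promoter", "toy22", 4000, 5000, "promoter"),
            ("BCR_CpG_island", "toy22", 5000, 7000, "CpG_island"),
            ("BCR_intron13", "toy22", 12_000, 14_000, "intron"),
            ("BCR_exon14", "toy22", 14_000, 14_200, "exon"),
            ("BCR_intron14", "toy22", 14_200, 16_200, "intron"),
            ("ROI_promoter_island", "toy22", 4000, 7000, "ROI"),
            ("ROI_mbcr", "toy22", 12_000, 16_200, "ROI"),
            ("ABL1_intron1", "toy9", 8000, 12_000, "intron"),
            ("ABL1_KD", "toy9", 19_500, 25_000, "ROI"),
        ],
        # (name, chrom, protospacer start, spacer strand)
        "crrnas": [
            ("BCR-3600 crRNA-", "toy22", 3600, "-"),
            ("BCR-11000 crRNA-", "toy22", 11_000, "-"),
            ("BCR-11560 crRNA-", "toy22", 11_560, "-"),
            ("ABL1-25650 crRNA+", "toy9", 25_650, "+"),
        ],
        "cpg_spacing": 24,  # planted CpG spacing inside CpG islands
    }


def make_toy_genome(
    config: Optional[dict] = None, seed: int = 0
) -> Tuple[ToyGenome, List[CrRNASpec]]:
    """Generate a seeded toy genome with guides planted as exact NGG sites.

    Returns the genome together with the planted guide specs (both are
    products of the same draw). Deterministic given (config, seed).
    """
    cfg = dict(default_genome_config() if config is None else config)
    rng = np.random.default_rng(seed)

    codes: Dict[str, np.ndarray] = {}
    for chrom, size in cfg["chromosomes"].items():
        if size < 10_000:
            raise ConfigurationError(f"{chrom}: chromosome size must be >= 10 kb")
        codes[chrom] = rng.integers(0, 4, size=size, dtype=np.uint8)

    features = [Feature(*f) for f in cfg["features"]]
    spacing = int(cfg.get("cpg_spacing", 24))
    for f in features:
        if f.role == "CpG_island":
            for p in range(f.start + 10, f.end - 1, spacing):
                codes[f.chrom][p] = 1  # C
                codes[f.chrom][p + 1] = 2  # G

    crrnas: List[CrRNASpec] = []
    C, G = 1, 2
    for name, chrom, s, strand in cfg["crrnas"]:
        arr = codes[chrom]
        spacer = rng.integers(0, 4, size=20, dtype=np.uint8)
        if strand == "+":
            if s < 0 or s + 23 > len(arr):
                raise ConfigurationError(f"{name}: guide outside {chrom}")
            arr[s : s + 20] = spacer
            arr[s + 20] = rng.integers(0, 4)
            arr[s + 21] = G
            arr[s + 22] = G
            pam_start, cut = s + 20, s + 17
        elif strand == "-":
            if s - 3 < 0 or s + 20 > len(arr):
                raise ConfigurationError(f"{name}: guide outside {chrom}")
            arr[s : s + 20] = _revcomp_codes(spacer)
            arr[s - 3] = C
            arr[s - 2] = C
            arr[s - 1] = rng.integers(0, 4)
            pam_start, cut = s - 3, s + 3
        else:
            raise ConfigurationError(f"{name}: strand must be '+' or '-'")
        crrnas.append(
            CrRNASpec(name, chrom, decode(spacer), strand, pam_start, cut)
        )

    genome = ToyGenome({c: decode(a) for c, a in codes.items()}, features)
    genome.validate()
    for cr in crrnas:
        pam = cr.pam_seq(genome)
        if not (pam[1] == "G" and pam[2] == "G"):
            raise ConfigurationError(f"{cr.name}: PAM {pam} is not NGG")
    return genome, crrnas


def wild_type_alleles(genome: ToyGenome) -> List[Allele]:
    return [
        Allele(f"wt_{c}", seq, [(c, 0, len(seq))])
        for c, seq in genome.chromosomes.items()
    ]


def make_fusion_allele(
    genome: ToyGenome,
    bpA: int,
    bpB: int,
    chromA: str = "toy22",
    chromB: str = "toy9",
    name: str = "fusion",
) -> Allele:
    """Join chromA[0:bpA] to chromB[bpB:end] at blunt boundaries.

    ``bpA``/``bpB`` are 0-based inter-base boundaries: the last donor base is
    bpA-1 and the first acceptor base is bpB.
    """
    seqA, seqB = genome.chromosomes[chromA], genome.chromosomes[chromB]
    if not (0 <= bpA <= len(seqA)) or not (0 <= bpB <= len(seqB)):
        raise ConfigurationError("fusion boundary outside chromosome")
    pieces = []
    if bpA > 0:
        pieces.append((chromA, 0, bpA))
    if bpB < len(seqB):
        pieces.append((chromB, bpB, len(seqB)))
    return Allele(name, seqA[:bpA] + seqB[bpB:], pieces)


# ---------------------------------------------------------------------------
# truth planting
# ---------------------------------------------------------------------------

def plant_snvs(
    genome: ToyGenome,
    region: Tuple[str, int, int],
    n: int,
    vaf: float = 0.5,
    seed: int = 0,
) -> List[SNV]:
    """Plant n distinct SNVs (alt != ref) in region at the given allele fraction."""
    chrom, start, end = region
    if not 0 < vaf <= 1:
        raise ConfigurationError("vaf must be in (0, 1]")
    if n > end - start:
        raise ConfigurationError("more SNVs requested than positions in region")
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(np.arange(start, end), size=n, replace=False))
    out = []
    for pos in positions:
        ref = genome.chromosomes[chrom][pos]
        alt = decode(np.array([(encode(ref)[0] + rng.integers(1, 4)) % 4], dtype=np.uint8))
        out.append(SNV(chrom, int(pos), ref, alt, vaf))
    return out


def methylation_profile(
    genome: ToyGenome,
    island: Tuple[str, int, int],
    p_high: float = 0.9,
    p_low: float = 0.1,
    boundaries: Optional[Tuple[int, int]] = None,
) -> Dict[int, float]:
    """Per-CpG Bernoulli methylation probabilities in a high-low-high layout.

    Every CpG C position in ``island`` is assigned p_high, p_low, or p_high
    according to which of the three runs (delimited by ``boundaries``, default
    thirds of the island) it falls in.
    """
    chrom, start, end = island
    if not (0 <= p_low <= p_high <= 1):
        raise ConfigurationError("require 0 <= p_low <= p_high <= 1")
    if boundaries is None:
        third = (end - start) // 3
        boundaries = (start + third, start + 2 * third)
    b1, b2 = boundaries
    if not (start <= b1 <= b2 <= end):
        raise ConfigurationError("run boundaries outside island")
    seq = genome.chromosomes[chrom]
    profile: Dict[int, float] = {}
    i = seq.find("CG", start)
    while 0 <= i < end - 1:
        profile[i] = p_low if b1 <= i < b2 else p_high
        i = seq.find("CG", i + 1)
    return profile


# ---------------------------------------------------------------------------
# error injection
# ---------------------------------------------------------------------------

def _inject_errors(
    seg: np.ndarray,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, List[Tuple[str, int]], np.ndarray, np.ndarray]:
    """Apply per-base substitution/insertion/deletion errors to one segment.

    Returns (new_codes, cigar ops in molecule order, new_index_of_old,
    unchanged_mask). ``new_index_of_old[i]`` is the output index of input base
    i (valid only where the base was kept); ``unchanged_mask[i]`` is True when
    base i was kept with its original identity.
    """
    n = len(seg)
    keep = rng.random(n) >= del_rate
    sub = keep & (rng.random(n) < sub_rate)
    ins = keep & (rng.random(n) < ins_rate)  # one inserted base after the kept base

    out = seg.copy()
    n_sub = int(sub.sum())
    if n_sub:
        out[sub] = (seg[sub] + rng.integers(1, 4, size=n_sub, dtype=np.uint8)) % 4

    contrib = keep.astype(np.int64) + ins
    new_index_of_old = np.cumsum(contrib) - contrib

    kept_codes = out[keep]
    ins_ref_idx = np.flatnonzero(ins)
    if len(ins_ref_idx):
        ins_bases = rng.integers(0, 4, size=len(ins_ref_idx), dtype=np.uint8)
        kept_rank = np.cumsum(keep)  # count of kept bases up to and including i
        new_codes = np.insert(kept_codes, kept_rank[ins_ref_idx], ins_bases)
    else:
        new_codes = kept_codes

    # cigar: one op per reference base (M or D), I ops spliced in after their anchor
    ops_ref = np.where(keep, 0, 2).astype(np.uint8)  # 0=M, 2=D
    ops = np.insert(ops_ref, ins_ref_idx + 1, 1) if len(ins_ref_idx) else ops_ref
    cigar: List[Tuple[str, int]] = []
    if len(ops):
        change = np.flatnonzero(np.diff(ops)) + 1
        bounds = np.concatenate(([0], change, [len(ops)]))
        letters = "MID"
        cigar = [
            (letters[ops[bounds[k]]], int(bounds[k + 1] - bounds[k]))
            for k in range(len(bounds) - 1)
        ]
    return new_codes, cigar, new_index_of_old, keep & ~sub


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    genome: ToyGenome,
    crrnas: Sequence[CrRNASpec],
    truth: TruthSet,
    *,
    n_reads_per_cut: int = 500,
    sub_rate: float = 0.01,
    ins_rate: float = 0.0025,
    del_rate: float = 0.0025,
    jitter: Optional[int] = None,
    read_length_mean: float = 8000.0,
    read_length_sd: float = 800.0,
    min_read_length: int = 500,
    fusion_fraction: float = 0.5,
    opposite_side_prob: float = 0.0,
    base_quality: int = 20,
    seed: int = 0,
) -> List[SimulatedRead]:
    """Simulate Cas9-cut-anchored long reads from wild-type and fusion alleles.

    Each read starts within ±jitter of a guide's expected cut and extends away
    from the PAM (flipped with ``opposite_side_prob``). Fusion-allele reads
    crossing the junction carry two truth segments. Heterozygous SNVs are
    applied per read by a haplotype coin at the SNV's allele fraction; per-read
    CpG methylation states are drawn Bernoulli(profile) before error
    injection. Deterministic given seed.
    """
    for rate in (sub_rate, ins_rate, del_rate):
        if not 0 <= rate < 1:
            raise ConfigurationError("error rates must be in [0, 1)")
    if n_reads_per_cut < 0:
        raise ConfigurationError("n_reads_per_cut must be >= 0")
    if jitter is None:
        jitter = truth.jitter
    rng = np.random.default_rng(seed)

    alleles = wild_type_alleles(genome)
    if truth.fusion is not None:
        chromA, bpA, chromB, bpB = truth.fusion
        alleles.append(make_fusion_allele(genome, bpA, bpB, chromA, chromB))
    allele_codes = {a.name: encode(a.seq) for a in alleles}

    site_arr = np.array(sorted(truth.meth_profile), dtype=np.int64)
    site_p = np.array([truth.meth_profile[s] for s in site_arr])
    qual_char = chr(33 + base_quality)

    reads: List[SimulatedRead] = []
    serial = 0
    for cr in crrnas:
        # locus (protospacer + PAM) must be intact on the allele
        lo = min(cr.pam_start, cr.expected_cut - 20)
        hi = max(cr.pam_start + 3, cr.expected_cut + 20)
        candidates: List[Tuple[Allele, int]] = []
        for al in alleles:
            pos = al.locate(cr.chrom, lo, hi)
            if pos is not None:
                candidates.append((al, pos + (cr.expected_cut - lo)))
        if not candidates:
            warnings.warn(f"{cr.name}: no allele carries this guide; no reads emitted")
            continue
        weights = np.array(
            [fusion_fraction if al.name == "fusion" else 1.0 for al, _ in candidates]
        )
        if any(al.name == "fusion" for al, _ in candidates):
            wt = [i for i, (al, _) in enumerate(candidates) if al.name != "fusion"]
            if wt:
                weights[wt] = (1.0 - fusion_fraction) / len(wt)
        weights = weights / weights.sum()

        for _ in range(n_reads_per_cut):
            ai = rng.choice(len(candidates), p=weights)
            allele, allele_cut = candidates[ai]
            codes = allele_codes[allele.name]
            direction = cr.read_direction
            if opposite_side_prob and rng.random() < opposite_side_prob:
                direction = -direction
            offset = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
            length = max(min_read_length, int(round(rng.normal(read_length_mean, read_length_sd))))
            boundary = int(np.clip(allele_cut + offset, 0, len(codes)))
            if direction > 0:
                a0, a1 = boundary, min(boundary + length, len(codes))
                strand = "+"
            else:
                a0, a1 = max(0, boundary - length), boundary
                strand = "-"
            if a1 - a0 < 50:
                continue

            molecule = codes[a0:a1].copy()
            if strand == "-":
                molecule = _revcomp_codes(molecule)

            ref_pieces = allele.ref_segments(a0, a1)
            if strand == "-":
                ref_pieces = ref_pieces[::-1]
            # molecule-order query offsets of each piece
            qoffs = np.concatenate(
                ([0], np.cumsum([e - s for _, s, e in ref_pieces]))
            )

            def mol_index(chrom: str, pos: int) -> Optional[int]:
                for k, (c, s, e) in enumerate(ref_pieces):
                    if c == chrom and s <= pos < e:
                        if strand == "+":
                            return int(qoffs[k] + (pos - s))
                        return int(qoffs[k] + (e - 1 - pos))
                return None

            # haplotype coin: SNV applied when u < vaf (one draw per read)
            u = rng.random()
            for snv in truth.snvs:
                if u < snv.vaf:
                    mi = mol_index(snv.chrom, snv.pos)
                    if mi is not None:
                        alt_code = encode(snv.alt)[0]
                        molecule[mi] = alt_code if strand == "+" else 3 - alt_code

            # per-read CpG truth states (site and its G both inside one piece)
            cpg_states: Dict[int, int] = {}
            meth_mol: List[Tuple[int, int]] = []
            if len(site_arr) and truth.meth_chrom is not None:
                for k, (c, s, e) in enumerate(ref_pieces):
                    if c != truth.meth_chrom:
                        continue
                    ilo, ihi = np.searchsorted(site_arr, [s, e - 1])
                    for j in range(ilo, ihi):
                        p = int(site_arr[j])
                        state = int(rng.random() < site_p[j])
                        cpg_states[p] = state
                        if strand == "+":
                            meth_mol.append((int(qoffs[k] + (p - s)), state))
                        else:
                            meth_mol.append((int(qoffs[k] + (e - 1 - (p + 1))), state))
            meth_mol.sort()

            # error injection, per piece, tracking index remaps
            segments: List[SimSegment] = []
            new_parts: List[np.ndarray] = []
            remaps = []
            out_off = 0
            for k, (c, s, e) in enumerate(ref_pieces):
                part = molecule[qoffs[k] : qoffs[k + 1]]
                if sub_rate or ins_rate or del_rate:
                    new_part, cigar, idx_map, unchanged = _inject_errors(
                        part, sub_rate, ins_rate, del_rate, rng
                    )
                else:
                    new_part = part
                    cigar = [("M", len(part))]
                    idx_map = np.arange(len(part))
                    unchanged = np.ones(len(part), dtype=bool)
                segments.append(
                    SimSegment(
                        chrom=c,
                        ref_start=s,
                        ref_end=e,
                        strand=strand,
                        query_start=out_off,
                        query_end=out_off + len(new_part),
                        cigar=cigar,
                    )
                )
                remaps.append((int(qoffs[k]), out_off, idx_map, unchanged))
                new_parts.append(new_part)
                out_off += len(new_part)
            final = np.concatenate(new_parts) if new_parts else np.empty(0, np.uint8)

            surviving: List[Tuple[int, int]] = []
            for mi, state in meth_mol:
                for old_off, new_off, idx_map, unchanged in remaps:
                    local = mi - old_off
                    if 0 <= local < len(idx_map):
                        if unchanged[local]:
                            surviving.append((new_off + int(idx_map[local]), state))
                        break

            read_id = f"r{serial:06d}"
            serial += 1
            reads.append(
                SimulatedRead(
                    read_id=read_id,
                    sequence=decode(final),
                    qual=qual_char * len(final),
                    strand=strand,
                    segments=segments,
                    cpg_states=cpg_states,
                    meth_entries=sorted(surviving),
                    crrna=cr.name,
                    allele=allele.name,
                )
            )
    return reads


# ---------------------------------------------------------------------------
# BSAS simulation
# ---------------------------------------------------------------------------

def simulate_bsas(
    profile: Dict[int, float],
    regions: Sequence[Tuple[str, str, int, int]],
    depth: int = 100,
    conversion_efficiency: float = 1.0,
    seed: int = 0,
    chrom: str = "toy22",
) -> List[BSASRecord]:
    """Binomial bisulfite-amplicon counts for CpG sites inside each region.

    A methylated C is retained; an unmethylated C converts with probability
    ``conversion_efficiency`` c, so the retention probability at a site with
    methylation level p is p + (1-c)(1-p).
    """
    if depth < 1:
        raise ConfigurationError("depth must be >= 1")
    if not 0 < conversion_efficiency <= 1:
        raise ConfigurationError("conversion efficiency must be in (0, 1]")
    rng = np.random.default_rng(seed)
    c = conversion_efficiency
    out: List[BSASRecord] = []
    for region_id, rchrom, start, end in regions:
        sites = [p for p in sorted(profile) if rchrom == chrom and start <= p < end]
        if not sites:
            warnings.warn(f"BSAS region {region_id} contains no CpG sites")
            continue
        for p in sites:
            p_retain = profile[p] + (1 - c) * (1 - profile[p])
            n_ret = int(rng.binomial(depth, p_retain))
            out.append(BSASRecord(region_id, rchrom, p, n_ret, depth - n_ret))
    return out


# ---------------------------------------------------------------------------
# emission: FASTQ / truth SAM / truth VCF / TSVs
# ---------------------------------------------------------------------------

def write_fastq(reads: Sequence[SimulatedRead], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.qual}\n")


def _mm_ml_tags(read: SimulatedRead) -> Optional[Tuple[str, List[int]]]:
    """SAM MM/ML base-modification tags (5mC at CpG, '?' skip mode).

    Every surviving profile-site C of the molecule is listed; ML encodes the
    binary truth state as a high (230/255) or low (25/255) probability so that
    downstream thresholding at 0.5 recovers the state.
    """
    if not read.meth_entries:
        return None
    mol = np.frombuffer(read.sequence.encode(), dtype=np.uint8)
    c_pos = np.flatnonzero(mol == ord("C"))
    deltas, mls = [], []
    prev_rank = -1
    for mi, state in read.meth_entries:
        rank = int(np.searchsorted(c_pos, mi))
        if rank >= len(c_pos) or c_pos[rank] != mi:
            continue  # base no longer a C (should not happen for survivors)
        deltas.append(rank - prev_rank - 1)
        mls.append(230 if state else 25)
        prev_rank = rank
    if not deltas:
        return None
    mm = "C+m?," + ",".join(map(str, deltas)) + ";"
    return mm, mls


def _cigar_str(ops: List[Tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in ops)


def write_truth_sam(reads: Sequence[SimulatedRead], genome: ToyGenome, path: str) -> None:
    """Truth alignments: one primary plus supplementary records per read.

    Records carry MM/ML 5mC tags, the originating guide (``XC``) and allele
    (``XO``). Soft clips represent the other segments of chimeric reads.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": c, "LN": len(s)} for c, s in genome.chromosomes.items()
            ],
        }
    )
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in reads:
            L = len(r.sequence)
            seq_fwd = r.sequence if r.strand == "+" else revcomp(r.sequence)
            tags = _mm_ml_tags(r)
            primary = max(
                range(len(r.segments)),
                key=lambda i: r.segments[i].query_end - r.segments[i].query_start,
            )
            for i, seg in enumerate(r.segments):
                a = pysam.AlignedSegment(header)
                a.query_name = r.read_id
                flag = 0
                if r.strand == "-":
                    flag |= 16
                if i != primary:
                    flag |= 2048
                a.flag = flag
                a.reference_id = header.get_tid(seg.chrom)
                a.reference_start = seg.ref_start
                a.mapping_quality = 60
                # SEQ-orientation clip bounds
                if r.strand == "+":
                    qs, qe = seg.query_start, seg.query_end
                    cig = seg.cigar
                else:
                    qs, qe = L - seg.query_end, L - seg.query_start
                    cig = seg.cigar[::-1]
                parts = []
                if qs:
                    parts.append(("S", qs))
                parts.extend(cig)
                if L - qe:
                    parts.append(("S", L - qe))
                a.cigarstring = _cigar_str(parts)
                a.query_sequence = seq_fwd
                a.query_qualities = pysam.qualitystring_to_array(
                    r.qual if r.strand == "+" else r.qual[::-1]
                )
                if tags is not None:
                    a.set_tag("MM", tags[0])
                    a.set_tag("ML", tags[1])
                a.set_tag("XC", r.crrna)
                a.set_tag("XO", r.allele)
                out.write(a)


def write_truth_vcf(snvs: Sequence[SNV], genome: ToyGenome, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, s in genome.chromosomes.items():
            fh.write(f"##contig=<ID={c},length={len(s)}>\n")
        fh.write('##INFO=<ID=VAF,Number=1,Type=Float,Description="Planted allele fraction">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(snvs, key=lambda s: (s.chrom, s.pos)):
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\tVAF={v.vaf}\n"
            )


def write_bsas_tsv(records: Sequence[BSASRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("region_id\tchrom\tpos\tn_retained\tn_converted\n")
        for r in records:
            fh.write(
                f"{r.region_id}\t{r.chrom}\t{r.pos}\t{r.n_retained}\t{r.n_converted}\n"
            )


def read_bsas_tsv(path: str) -> List[BSASRecord]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("region_id")
        for line in fh:
            rid, chrom, pos, nr, nc = line.rstrip("\n").split("\t")
            out.append(BSASRecord(rid, chrom, int(pos), int(nr), int(nc)))
    return out


def write_crrna_tsv(crrnas: Sequence[CrRNASpec], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("name\tchrom\tspacer\tstrand\tpam_start\texpected_cut\n")
        for c in crrnas:
            fh.write(
                f"{c.name}\t{c.chrom}\t{c.spacer_seq}\t{c.strand}\t{c.pam_start}\t{c.expected_cut}\n"
            )


def read_crrna_tsv(path: str) -> List[CrRNASpec]:
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            name, chrom, spacer, strand, pam_start, cut = line.rstrip("\n").split("\t")
            out.append(CrRNASpec(name, chrom, spacer, strand, int(pam_start), int(cut)))
    return out


# ---------------------------------------------------------------------------
# one-call orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimulationBundle:
    genome: ToyGenome
    crrnas: List[CrRNASpec]
    truth: TruthSet
    reads: List[SimulatedRead]
    bsas: List[BSASRecord]
    bsas_regions: List[Tuple[str, str, int, int]]


def default_bsas_regions() -> List[Tuple[str, str, int, int]]:
    """Three ~200 bp amplicons hitting the high, low, and high methylation runs."""
    return [
        ("BSP1", "toy22", 5100, 5300),
        ("BSP2", "toy22", 5800, 6000),
        ("BSP3", "toy22", 6500, 6700),
    ]


def simulate_run(
    seed: int = 0,
    genome_config: Optional[dict] = None,
    *,
    fusion_bp: Optional[Tuple[int, int]] = (15_200, 10_000),
    n_snvs: int = 10,
    snv_vaf: float = 0.5,
    snv_region_feature: str = "ABL1_KD",
    p_high: float = 0.9,
    p_low: float = 0.1,
    bsas_regions: Optional[List[Tuple[str, str, int, int]]] = None,
    bsas_depth: int = 100,
    conversion_efficiency: float = 1.0,
    jitter: int = 2,
    **read_kwargs,
) -> SimulationBundle:
    """Generate a complete seeded experiment: genome, truth, reads, BSAS.

    Sub-seeds for each generator stage are derived from ``seed`` so the stages
    are individually reproducible.
    """
    genome, crrnas = make_toy_genome(genome_config, seed=seed)
    kd = genome.feature(snv_region_feature)
    snvs = plant_snvs(genome, (kd.chrom, kd.start, kd.end), n_snvs, snv_vaf, seed=seed + 1)
    island = genome.features_by_role("CpG_island")[0]
    profile = methylation_profile(genome, (island.chrom, island.start, island.end), p_high, p_low)
    truth = TruthSet(
        fusion=("toy22", fusion_bp[0], "toy9", fusion_bp[1]) if fusion_bp else None,
        snvs=snvs,
        meth_profile=profile,
        meth_chrom=island.chrom,
        jitter=jitter,
        seed=seed,
    )
    reads = simulate_reads(genome, crrnas, truth, jitter=jitter, seed=seed + 2, **read_kwargs)
    regions = bsas_regions if bsas_regions is not None else default_bsas_regions()
    bsas = simulate_bsas(
        profile, regions, depth=bsas_depth,
        conversion_efficiency=conversion_efficiency, seed=seed + 3, chrom=island.chrom,
    )
    return SimulationBundle(genome, crrnas, truth, reads, bsas, list(regions))
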