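# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the simulator does and does not emulate, and the numerical
conventions that make results reproducible.

## Coordinates and conventions

All internal coordinates are 0-based half-open; 1-based coordinates appear
only where a format requires them (SAM/VCF POS) or in human-readable output.
A fusion boundary `bp` is an inter-base position: the donor contributes
`[0, bpA)` and the acceptor `[bpB, end)`. A junction is reported as the last
aligned donor base (`bpA - 1` internally, `bpA` 1-based) and the first
aligned acceptor base (`bpB` internally, `bpB + 1` 1-based). Which side of
the junction a single published coordinate indexes varies between tools;
when comparing against external calls, allow ±1.

## The simulator

### Genome and guides

`make_toy_genome` builds two ~34 kb chromosomes from uniform random bases:

- **toy22** — promoter [4000, 5000), CpG island [5000, 7000) with a CpG
  planted every 24 bp (plus incidental CpGs from the random background,
  ~190 sites in total), breakpoint-cluster introns 13 [12000, 14000) and
  14 [14200, 16200) separated by a 200 bp exon;
- **toy9** — an intron-1 analog [8000, 12000) (fusion acceptor) and a
  5.5 kb kinase-domain ROI [19500, 25000).

Four SpCas9 guides are planted as exact sequence: a 20 nt protospacer, an
NGG PAM adjacent to it on the protospacer strand, and a blunt cut 3 nt
5' of the PAM (standard SpCas9 geometry). Reads initiate at the cut and
extend away from the PAM — the PAM-distal fragment is the one whose fresh
end receives the adaptor — so a '+'-spacer guide yields leftward
(reverse-strand) reads and a '−'-spacer guide rightward (forward-strand)
reads. The layout places each target on the PAM-distal side of its guide:
the CpG island downstream of its guide's cut, the fusion junction downstream
of the two flanking guides, and the kinase domain upstream of its guide.
This mirrors the geometry of the real assay this package emulates, where one
guide covers the promoter/CpG island, two flank the breakpoint cluster, and
one covers the kinase domain from the far side.

### Reads

Each guide contributes `n_reads_per_cut` reads (default 500, the on-target
yield per ROI reported for the real assay). Per read:

- the start is the expected cut plus a uniform integer jitter on
  [-j, +j] (default j = 2; the end-offset distribution of real Cas9 cuts is
  not standardised, so the simplest symmetric bounded model is used);
- length ~ Normal(8000, 800) truncated at 500 bp — a realistic nCATS
  fragment scale for this toy layout, long enough that fusion-guide reads
  span the junction and kinase-domain reads cover the ROI;
- the source allele is drawn between wild type and (when configured) the
  fusion allele with `fusion_fraction` (default 0.5);
- heterozygous SNVs are applied by one haplotype coin per read at the
  planted allele fraction (default 0.5), i.e. planted variants are phased;
- per-read CpG states are drawn Bernoulli(profile) *before* error
  injection, so sequencing errors can erase but never invent evidence;
- substitution/insertion/deletion errors are injected per base (defaults
  1% / 0.25% / 0.25%).

Truth alignments are written as SAM: one primary record plus supplementary
records for the other segments of chimeric reads, soft-clip encoded, with
5mC-at-CpG MM/ML tags (listing every surviving profile-site C with
probability 230/255 for methylated and 25/255 for unmethylated, so
thresholding at 0.5 recovers the drawn state), the originating guide in
`XC`, and the source allele in `XO`. Base qualities are constant Q20 per
read (errors are injected independently of quality); Q20 corresponds to the
default 1% substitution rate, so the caller's quality-derived error rate is
consistent with the simulation.

### What the simulator does not emulate

- **Alignment noise.** The truth SAM is an exact alignment of the erroneous
  read. A real long-read aligner wanders at junction edges and soft-clips
  low-quality ends, so on real data junction observations scatter around
  the breakpoint, which is exactly what the clustering tolerance (50 bp)
  and median consensus absorb. On simulations the consensus is exact even
  at 8% read error; the ±5 bp acceptance bound is the margin a real aligner
  would need.
- **Nanopore error structure.** Errors are i.i.d. per base; real nanopore
  data has homopolymer-biased indels and correlated error bursts.
- **Raw signal.** No FAST5/POD5 or basecaller emulation; per-read 5mC calls
  are taken as given (tags), not re-derived from signal.

Passing tests therefore demonstrate the correctness of the analysis logic
under its stated model, not robustness to aligner- or chemistry-specific
artefacts.

### Bisulfite amplicons

`simulate_bsas` draws, per CpG site in each of three ~200 bp regions placed
in the high, low, and high methylation runs, retained counts
`Binomial(depth, p + (1-c)(1-p))` at depth 100, where `c` is the bisulfite
conversion efficiency (default 1.0, i.e. no correction — matching the
default of `bsas_call`, which only corrects when told `c < 1`).

## Analysis stages

### Enrichment QC

A read's *starting end* is the reference boundary where the molecule begins
(segment ref start for forward reads, half-open ref end for reverse reads),
taken from the query-5' segment. It is matched to the nearest expected cut
within ±20 bp; 20 bp separates genuine cut ends from fragmented or
off-target ends while staying far below inter-guide distances. "Covering"
an ROI is reported both as full containment of the interval by the read's
segment union (the strict sense) and as non-empty overlap, since usage
varies. Depth uses the alignment-span convention (deletions count), like
standard depth tools.

### Fusion detection

Junction observations require both segments >= 200 bp aligned (robust
against spurious micro-alignments), query gap <= 100 bp (nanopore junction
slop), and different chromosomes or >= 10 kb separation. Single-linkage
clustering within 50 bp on both coordinates; consensus is the per-coordinate
median with the *lower* middle for even n — deterministic and robust to
outlier split points. Calls need >= 3 supporting reads by default.
Classification looks up the annotated introns containing the two consensus
coordinates in a configurable table (intron 13 → b2a2, intron 14 → b3a2
against the acceptor's intron 1); breakpoints outside annotated introns are
"unclassified". BND bracket orientation follows the VCF 4.2 rules for the
four strand combinations; mates cross-reference by ID.

### SNV calling

The pileup walks CIGAR operations directly (no sorted/indexed BAM needed),
masks bases below Q7, tallies deletions per column and insertions against
their anchor column. Genotype likelihoods are binomial on the alt count
with alt fractions (e, 0.5, 1−e) for RR/RA/AA; e comes from the column's
mean base quality, floored at 1e-3 so a handful of inflated quality values
cannot zero the error model. The prior is flat: with only three genotypes
and desk-scale data a population prior adds tuning surface without changing
any decision at the default thresholds. QUAL = −10·log10 P(RR|data), capped
at 5000 (the posterior underflows to exactly 0 at high depth). Thresholds
(depth >= 10, alt >= 4, fraction >= 0.2, QUAL >= 20) are conventional
long-read pileup settings. Multi-allelic columns emit the top alt only,
flagged. Variant identity for set comparisons is exact (chrom, pos, ref,
alt); indels and MNVs are out of scope. QUAL scales of different callers
are not comparable, so QUAL-depth correlations are computed per caller,
never pooled.

### Methylation

CpG evidence from both strands is projected to the plus-strand C (a call on
the opposite strand maps to `ref_pos − 1`) and pooled — the symmetric-CpG
assumption. Per-read calls are binarised at modification probability 0.5,
ties methylated; binary calls match the frequency-table outputs of common
modified-base pipelines and keep aggregation transparent. Sites with fewer
than 5 informative reads are kept but flagged low-confidence. Segmentation
labels sites hypo (< 0.3) / hyper (> 0.7) / intermediate, takes maximal
same-label runs of >= 3 sites, and merges shorter runs into the flanking
run with the nearer mean (shortest run first; coalescing equal-label
neighbours after each merge). Concordance with BSAS is an inner join on
(chrom, pos) with both depths >= 5, reporting Pearson r, mean absolute
difference, and n; r is reported absent (with the reason) below 3 pairs or
at zero variance rather than as a misleading number.

### Pipeline

Stages exchange only files, under per-stage subdirectories, each with a
manifest (parameters, inputs, derived seed, sha256 of outputs). The stage
seed is `(global_seed + crc32(stage_name)) mod 2^31`, so stages are
individually reproducible and uncorrelated. Unknown config keys are
rejected before anything is written (exit 2 from the CLI); missing inputs
name the path (exit 1).

## Problem sizes

The test suite and `scripts/acceptance.py` run the stated study conditions
at desk scale: 20 fusion-spanning reads for breakpoint recovery (low error
1%/0.5%, high error 8% total), 500 reads per cut (≈500x) for SNV recovery
of 10 planted heterozygous SNVs, 200 reads per cut (≈200x) with 100x BSAS
for methylation recovery, and 50 noiseless reads per cut for cut-site QC.
The shared test fixture uses 50 reads per cut. The full suite runs in well
under a minute.

## Real-data validation

On real K562 nCATS data aligned to hg38 the fusion stage should recover the
known BCR-ABL1 breakpoints (chr22:23,290,555 and chr9:130,731,760, ±1 bp
for the junction-side convention) and classify the fusion b3a2 once BCR
introns 13/14 and ABL1 intron 1 are supplied as the annotation; the
kinase-domain evaluation region between the ABL1 breakpoint and the ABL1
guide target spans 157,048 bp (`ncats.snv.kd_region_span_bp`). These checks
require the deposited reads, hg38, and an external aligner (minimap2), so
they are not part of the test suite.

## Known limitations

- No indel or MNV calling; no haplotype assembly or phasing of calls.
- No off-target site discovery; the on/off-target summary is count-based.
- BSAS conversion-efficiency correction is a linear rescaling; it does not
  model strand-specific or context-specific conversion failure.
- `read_bedpe` does not recover member read ids (BEDPE carries only the
  support count).
- The simulator's alleles are balanced or configurably skewed, but copy
  number (e.g. amplified fusion alleles) is not modeled beyond
  `fusion_fraction`.
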