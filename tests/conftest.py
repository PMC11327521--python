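"""Shared fixtures: seeded simulations and hand-built SAM helpers."""

import pysam
import pytest

import ncats
from ncats.alignment_io import group_by_read, read_alignments
from ncats.synthetic_data import write_truth_sam


@pytest.fixture(scope="session")
def bundle():
    """Default-condition simulation, scaled to 50 reads per cut for speed."""
    return ncats.simulate_run(seed=7, n_reads_per_cut=50)


@pytest.fixture(scope="session")
def sam_path(bundle, tmp_path_factory):
    path = tmp_path_factory.mktemp("sim") / "truth.sam"
    write_truth_sam(bundle.reads, bundle.genome, str(path))
    return str(path)


@pytest.fixture(scope="session")
def read_sets(sam_path):
    return group_by_read(read_alignments(sam_path))


@pytest.fixture(scope="session")
def clean_bundle():
    """Noiseless simulation: no errors, no cut-site jitter."""
    return ncats.simulate_run(
        seed=11, n_reads_per_cut=20, sub_rate=0.0, ins_rate=0.0, del_rate=0.0, jitter=0
    )


@pytest.fixture(scope="session")
def clean_sam_path(clean_bundle, tmp_path_factory):
    path = tmp_path_factory.mktemp("clean") / "truth.sam"
    write_truth_sam(clean_bundle.reads, clean_bundle.genome, str(path))
    return str(path)


def make_sam(path, contigs, records):
    """Write a SAM from record dicts (name, flag, chrom, pos, cigar, seq, tags)."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6"},
            "SQ": [{"SN": c, "LN": n} for c, n in contigs.items()],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in records:
            a = pysam.AlignedSegment(header)
            a.query_name = r["name"]
            a.flag = r.get("flag", 0)
            a.reference_id = header.get_tid(r["chrom"])
            a.reference_start = r["pos"]
            a.mapping_quality = r.get("mapq", 60)
            a.cigarstring = r["cigar"]
            if "seq" in r:
                a.query_sequence = r["seq"]
                a.query_qualities = pysam.qualitystring_to_array(
                    r.get("qual", "I" * len(r["seq"]))
                )
            for tag, value in r.get("tags", []):
                a.set_tag(tag, value)
            out.write(a)
    return str(path)
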