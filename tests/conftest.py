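import pysam
import pytest

from asequant.simulate import SimConfig, simulate_fixture


@pytest.fixture(scope="session")
def toy_header() -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_references(
        ["chr1", "chr2", "chrM"], [100_000, 100_000, 16_000]
    )


@pytest.fixture(scope="session")
def make_record(toy_header):
    """Factory for aligned segments with sensible defaults."""

    def build(
        name="read1",
        contig="chr1",
        start=100,  # 0-based
        seq="ACGT" * 25,
        cigar=None,
        mapq=50,
        is_read2=False,
        is_reverse=False,
        unmapped=False,
        mate_unmapped=False,
        mate_start=400,
        duplicate=False,
        secondary=False,
        tags=(),
    ):
        rec = pysam.AlignedSegment(header=toy_header)
        rec.query_name = name
        rec.query_sequence = seq
        rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
        rec.is_paired = True
        rec.is_read2 = is_read2
        rec.is_read1 = not is_read2
        rec.reference_name = contig
        rec.reference_start = start
        rec.is_reverse = is_reverse
        rec.is_duplicate = duplicate
        rec.is_secondary = secondary
        if unmapped:
            rec.is_unmapped = True
            rec.mapping_quality = 0
        else:
            rec.cigarstring = cigar or f"{len(seq)}M"
            rec.mapping_quality = mapq
        if mate_unmapped:
            rec.mate_is_unmapped = True
        else:
            rec.next_reference_name = contig
            rec.next_reference_start = mate_start
        for tag, value in tags:
            rec.set_tag(tag, value)
        return rec

    return build


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A small simulated diploid library with one strongly imbalanced gene."""
    out = tmp_path_factory.mktemp("fixture")
    config = SimConfig(
        genome_length=20_000,
        n_contigs=1,
        n_genes=2,
        snp_rate=0.003,
        indel_count=4,
        fragment_depth=30,
        allelic_ratio_map={"G01": 0.9},
        seed=11,
    )
    truth = simulate_fixture(config, out)
    return config, truth, out
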