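"""Alignment-confounder annotation, the removal rules and the binned
ASE-proportion diagnostics."""

import math

import pytest

from asequant.ase import AseCall
from asequant.genemodel import Gene, Transcript
from asequant.qc import (
    AlignabilityTrack,
    annotate_feature,
    annotate_proximity,
    apply_filters,
    binned_ase_proportion,
    lookup_alignability,
)
from asequant.variants import HetSite, PhasedVariant


def h(pos, ref_hap="A"):
    return HetSite(contig="chr1", position=pos, ref="A", alt="G", ref_haplotype=ref_hap)


def unphased_snp(pos, contig="chr1"):
    return PhasedVariant(
        contig=contig, position=pos, ref_allele="A", alt_allele="T",
        zygosity="het", source="de_novo", phased=False,
    )


def unphased_del(pos, length=3, contig="chr1"):
    return PhasedVariant(
        contig=contig, position=pos, ref_allele="A" * (length + 1), alt_allele="A",
        zygosity="het", source="de_novo", variant_class="indel", phased=False,
    )


class TestProximity:
    def test_nearest_snp_distance_and_window_count(self):
        sites = [h(1000)]
        snvs = [unphased_snp(800), unphased_snp(950), unphased_snp(1090),
                unphased_snp(1250)]
        [ann] = annotate_proximity(sites, snvs)
        assert ann.snp_distance == 50
        assert ann.proximal_snp_count == 2  # 950 and 1090 within 100 bp

    def test_indel_distance_to_interval_edge_not_anchor(self):
        # deletion anchored at 900 removes bases 901-903; site at 1000 is
        # 97 bp from the nearest deleted base
        [ann] = annotate_proximity([h(1000)], [unphased_del(900, length=3)])
        assert ann.indel_distance == 97

    def test_no_indel_on_contig(self):
        [ann] = annotate_proximity([h(1000)], [unphased_snp(1200)])
        assert ann.indel_distance is None
        assert ann.snp_distance == 200

    def test_phased_neighbors_counted_only_on_request(self):
        sites = [h(1000), h(1050)]
        anns = annotate_proximity(sites, [], phased_sites=sites)
        assert [a.proximal_snp_count for a in anns] == [0, 0]
        anns = annotate_proximity(sites, [], phased_sites=sites, include_phased=True)
        # each counts the other, never itself
        assert [a.proximal_snp_count for a in anns] == [1, 1]


class TestAlignability:
    def test_lookup_values_and_uncovered_default(self):
        track = AlignabilityTrack({"chr1": [(0, 1000, 1.0), (1000, 2000, 0.5)]})
        assert lookup_alignability(h(1000), track) == 1.0  # 1-based 1000 = last base
        assert lookup_alignability(h(1001), track) == 0.5
        assert lookup_alignability(h(5000), track) == 0.0
        assert track.lookup("chrX", 10) == 0.0

    def test_conflicting_overlaps_rejected(self):
        with pytest.raises(ValueError, match="conflicting"):
            AlignabilityTrack({"chr1": [(0, 1000, 1.0), (500, 1500, 0.5)]})

    def test_bed_and_bedgraph_parsing(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t0\t100\t1.0\nchr1\t100\t200\tname\t0.5\n")
        track = AlignabilityTrack.from_bed(bed)
        assert track.lookup("chr1", 50) == 1.0
        assert track.lookup("chr1", 150) == 0.5


class TestFeatureAnnotation:
    @pytest.fixture()
    def gene(self):
        t1 = Transcript(
            "T1", "G1", "chr1", "+",
            exons=[(1001, 1400), (1701, 2100)],
            cds=[(1101, 1400), (1701, 2000)],
            utr5=[(1001, 1100)],
            utr3=[(2001, 2100)],
        )
        # second isoform whose 3'UTR covers part of T1's CDS
        t2 = Transcript(
            "T2", "G1", "chr1", "+",
            exons=[(1001, 1400)],
            cds=[(1101, 1300)],
            utr5=[(1001, 1100)],
            utr3=[(1301, 1400)],
        )
        return Gene("G1", "chr1", 1001, 2100, transcripts=[t1, t2])

    def test_unambiguous_labels(self, gene):
        assert annotate_feature(h(1200), [gene]) == "coding_exonic"
        assert annotate_feature(h(1050), [gene]) == "utr5"
        assert annotate_feature(h(2050), [gene]) == "multiple"  # utr3 in T1, intronic in T2-less span
        assert annotate_feature(h(500), [gene]) == "intergenic"

    def test_conflicting_transcripts_give_multiple(self, gene):
        # 1350: CDS in T1 but 3'UTR in T2
        assert annotate_feature(h(1350), [gene]) == "multiple"

    def test_intronic_within_single_transcript_gene(self):
        t = Transcript("T1", "G1", "chr1", "+", exons=[(1001, 1200), (1501, 1700)],
                       cds=[(1001, 1200), (1501, 1700)])
        gene = Gene("G1", "chr1", 1001, 1700, transcripts=[t])
        assert annotate_feature(h(1300), [gene]) == "intronic"


class TestFilters:
    def _verdicts(self, sites, snvs, track=None):
        from asequant.qc import annotate_all

        anns = annotate_all(sites, snvs, alignability=track)
        return anns, apply_filters(anns)

    def test_hand_placed_truth_set(self):
        """Indels at 5/99/101 bp, SNP clusters of 3 vs 4, alignability 0.5
        vs 1.0: survivors must match the hand-computed list exactly."""
        sites = [h(p) for p in (1000, 3000, 5000, 7000, 9000, 11000)]
        snvs = [
            unphased_del(1004, length=2),   # bases 1005-1006 -> distance 5
            unphased_del(3098, length=2),   # bases 3099-3100 -> distance 99
            unphased_del(5100, length=2),   # bases 5101-5102 -> distance 101
        ]
        # 4-cluster around 7000; 3-cluster around 9000
        snvs += [unphased_snp(p) for p in (6950, 6970, 7030, 7090)]
        snvs += [unphased_snp(p) for p in (8950, 9030, 9090)]
        track = AlignabilityTrack(
            {"chr1": [(0, 10_500, 1.0), (10_500, 12_000, 0.5)]}
        )
        anns, verdicts = self._verdicts(sites, snvs, track)
        by_pos = {a.site.position: v for a, v in zip(anns, verdicts)}
        assert by_pos[1000].reasons == ("indel_within_100bp",)
        assert by_pos[3000].reasons == ("indel_within_100bp",)  # 99 <= 100
        assert by_pos[5000].passed                              # 101 > 100
        assert by_pos[7000].reasons == ("four_plus_snps_within_100bp",)
        assert by_pos[9000].passed                              # only 3 in window
        assert by_pos[11000].reasons == ("imperfect_alignability",)
        survivors = sorted(p for p, v in by_pos.items() if v.passed)
        assert survivors == [5000, 9000]

    def test_multiple_reasons_recorded_together(self):
        sites = [h(1000)]
        snvs = [unphased_del(1004)] + [unphased_snp(p) for p in (960, 970, 1030, 1040)]
        track = AlignabilityTrack({"chr1": [(0, 2000, 0.5)]})
        _, [verdict] = self._verdicts(sites, snvs, track)
        assert set(verdict.reasons) == {
            "indel_within_100bp",
            "four_plus_snps_within_100bp",
            "imperfect_alignability",
        }


def call(pos, is_ase, depth=20):
    k = 19 if is_ase else 10
    return AseCall(
        site=h(pos), ref_count=k, alt_count=depth - k, other_count=0,
        expected=0.5, observed=k / depth, delta=abs(k / depth - 0.5),
        p_value=0.01 if is_ase else 1.0,
        classification="ASE" if is_ase else "not_ASE",
        direction="toward_hapA" if is_ase else "balanced",
    )


class TestBinnedProportions:
    def test_printed_percentage_for_a_bin(self):
        calls = [call(i, i < 31) for i in range(95)]
        table = binned_ase_proportion(calls, [5.0] * 95, edges=(0, 10, 100))
        row = table[table["bin"] == "[0,10)"].iloc[0]
        assert row["n"] == 95 and row["n_ASE"] == 31
        assert row["proportion"] == pytest.approx(32.63, abs=0.005)

    def test_all_negative_calls_give_zero_proportions(self):
        calls = [call(i, False) for i in range(40)]
        table = binned_ase_proportion(
            calls, [1.0] * 20 + [50.0] * 20, edges=(0, 10, 100)
        )
        assert (table["proportion"] == 0).all()
        assert table["p_value"].isna().all()  # degenerate global proportion

    def test_single_bin_self_comparison_is_null(self):
        calls = [call(i, i % 10 == 0) for i in range(50)]
        table = binned_ase_proportion(calls, [5.0] * 50, edges=(0, 10))
        assert len(table) == 1
        assert table.iloc[0]["p_value"] > 0.5

    def test_row_counts_conserved_and_none_excluded(self):
        calls = [call(i, False) for i in range(10)]
        keys = [1.0] * 4 + [None] * 2 + [20.0] * 4
        table = binned_ase_proportion(calls, keys, edges=(0, 10, 100))
        assert table["n"].sum() == 8
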