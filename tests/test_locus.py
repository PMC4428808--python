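"""Gene-level aggregation, phase concordance, replicate comparison and
SNP-to-isoform assignment."""

import pytest

from asequant.ase import AseCall, binomial_two_sided
from asequant.genemodel import Gene, Transcript
from asequant.locus import (
    aggregate_gene_ase,
    compare_replicates,
    flag_gene_criteria,
    map_snps_to_isoforms,
    phase_concordance,
)
from asequant.variants import HetSite


def call(pos, ref_n, alt_n, ref_hap="A", classification=None, p=None,
         replicate="rep1", contig="chr1"):
    n = ref_n + alt_n
    rf = ref_n / n if n else float("nan")
    hap_a = ref_n if ref_hap == "A" else alt_n
    hap_b = n - hap_a
    if classification is None:
        classification = "ASE" if abs(rf - 0.5) > 0.15 and n >= 10 else "not_ASE"
    direction = (
        "toward_hapA" if hap_a > hap_b else "toward_hapB" if hap_b > hap_a else "balanced"
    )
    return AseCall(
        site=HetSite(contig=contig, position=pos, ref="A", alt="G", ref_haplotype=ref_hap),
        ref_count=ref_n, alt_count=alt_n, other_count=0,
        expected=0.5, observed=rf, delta=abs(rf - 0.5),
        p_value=p if p is not None else binomial_two_sided(ref_n, n, 0.5),
        classification=classification, direction=direction, replicate=replicate,
    )


def gene(gid="G1", start=1, end=10_000, contig="chr1", transcripts=()):
    return Gene(gene_id=gid, contig=contig, start=start, end=end,
                transcripts=list(transcripts))


class TestAggregation:
    def test_haplotype_sums_and_pvalue(self):
        calls = [call(100, 30, 10), call(200, 25, 15)]
        [res] = aggregate_gene_ase(calls, [gene()])
        assert (res.hap_a_sum, res.hap_b_sum) == (55, 25)
        assert res.p_value == pytest.approx(binomial_two_sided(25, 80, 0.5))
        assert res.n_testable_snps == 2

    def test_balanced_sums_give_p_one(self):
        calls = [call(100, 40, 40)]
        [res] = aggregate_gene_ase(calls, [gene()])
        assert res.p_value == 1.0

    def test_single_snp_gene_reduces_to_snp_test(self):
        calls = [call(100, 18, 2)]
        [res] = aggregate_gene_ase(calls, [gene()])
        assert res.p_value == pytest.approx(binomial_two_sided(18, 20, 0.5))

    def test_phase_swap_moves_counts_between_haplotypes(self):
        flipped = [call(100, 30, 10, ref_hap="B"), call(200, 25, 15, ref_hap="B")]
        [res] = aggregate_gene_ase(flipped, [gene()])
        assert (res.hap_a_sum, res.hap_b_sum) == (25, 55)

    def test_sum_conservation_over_members(self):
        calls = [call(p, 12 + p % 5, 9) for p in (100, 200, 300)]
        [res] = aggregate_gene_ase(calls, [gene()])
        assert res.hap_a_sum == sum(c.hap_a_count for c in calls)
        assert res.hap_b_sum == sum(c.hap_b_count for c in calls)

    def test_genes_without_members_omitted_and_ranked_by_p(self):
        calls = [call(100, 30, 10), call(15_000, 20, 20)]
        genes = [gene("G1", 1, 10_000), gene("G2", 14_000, 16_000),
                 gene("G3", 20_000, 21_000)]
        results = aggregate_gene_ase(calls, genes)
        assert [r.gene_id for r in results] == ["G1", "G2"]
        assert [r.rank for r in results] == [1, 2]

    def test_monotone_p_in_imbalance_at_fixed_depth(self):
        pvals = []
        for a in range(40, 81, 10):
            [res] = aggregate_gene_ase([call(100, a, 80 - a)], [gene()])
            pvals.append(res.p_value)
        assert pvals == sorted(pvals, reverse=True)


class TestPhaseConcordance:
    def test_uniform_direction(self):
        assert phase_concordance([call(1, 18, 2), call(2, 15, 5)])

    def test_mixed_directions(self):
        assert not phase_concordance([call(1, 18, 2), call(2, 2, 18)])

    def test_single_member_vacuously_concordant(self):
        assert phase_concordance([call(1, 18, 2)])

    def test_balanced_members_are_neutral(self):
        assert phase_concordance([call(1, 18, 2), call(2, 10, 10)])

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            phase_concordance([])


class TestReplicateFlags:
    def test_replicated_ase_snp_detection(self):
        rep1 = [call(100, 18, 2, replicate="rep1"), call(200, 11, 9, replicate="rep1")]
        rep2 = [call(100, 17, 3, replicate="rep2"), call(200, 10, 10, replicate="rep2")]
        frame = flag_gene_criteria({"rep1": rep1, "rep2": rep2}, [gene()],
                                   exonic_positions={("chr1", 100), ("chr1", 200)})
        row = frame.iloc[0]
        assert row["has_replicated_ase_snp"]
        assert row["two_testable_exonic_snps_in_both"]
        assert not row["partial"]

    def test_one_exonic_snp_fails_two_snp_criterion(self):
        rep1 = [call(100, 18, 2), call(200, 11, 9)]
        rep2 = [call(100, 17, 3)]
        frame = flag_gene_criteria({"rep1": rep1, "rep2": rep2}, [gene()],
                                   exonic_positions={("chr1", 100), ("chr1", 200)})
        assert not frame.iloc[0]["two_testable_exonic_snps_in_both"]

    def test_no_ase_anywhere(self):
        rep1 = [call(100, 11, 9), call(200, 10, 10)]
        rep2 = [call(100, 9, 11), call(200, 12, 8)]
        frame = flag_gene_criteria({"rep1": rep1, "rep2": rep2}, [gene()],
                                   exonic_positions={("chr1", 100), ("chr1", 200)})
        assert not frame.iloc[0]["has_replicated_ase_snp"]

    def test_single_replicate_marked_partial(self):
        frame = flag_gene_criteria({"rep1": [call(100, 18, 2)]}, [gene()],
                                   exonic_positions=set())
        assert frame.iloc[0]["partial"]


class TestCompareReplicates:
    def _callset(self, spec, replicate):
        # spec: pos -> (is_ase, depth)
        return [
            call(pos, int(round(depth * (0.9 if is_ase else 0.5))),
                 depth - int(round(depth * (0.9 if is_ase else 0.5))),
                 classification="ASE" if is_ase else "not_ASE",
                 replicate=replicate)
            for pos, (is_ase, depth) in spec.items()
        ]

    def test_contingency_partition(self):
        rep1 = self._callset({1: (True, 20), 2: (True, 20), 3: (False, 20),
                              4: (False, 20)}, "rep1")
        rep2 = self._callset({1: (False, 20), 2: (True, 20), 3: (True, 20),
                              4: (False, 20)}, "rep2")
        [comp] = compare_replicates(rep1, rep2, [10])
        assert (comp.n_ase_both, comp.n_ase_rep1_only, comp.n_ase_rep2_only,
                comp.n_not_ase_both) == (1, 1, 1, 1)
        assert comp.n_testable_both == 4
        assert comp.overlap_proportion == pytest.approx(1 / 3)

    def test_identical_callsets_have_no_exclusive_ase(self):
        rep = self._callset({i: (i % 2 == 0, 30) for i in range(1, 7)}, "rep1")
        [comp] = compare_replicates(rep, rep, [10])
        assert comp.n_ase_rep1_only == comp.n_ase_rep2_only == 0

    def test_threshold_above_all_depths_empties_comparison(self):
        rep = self._callset({1: (True, 20)}, "rep1")
        [comp] = compare_replicates(rep, rep, [500])
        assert comp.n_testable_both == 0

    def test_low_threshold_warns(self):
        rep = self._callset({1: (True, 20)}, "rep1")
        with pytest.warns(UserWarning, match="below"):
            compare_replicates(rep, rep, [5])


class TestIsoformAssignment:
    @pytest.fixture()
    def two_isoform_gene(self):
        t1 = Transcript("T1", "G1", "chr1", "+",
                        exons=[(1000, 1400), (2000, 2400), (3000, 3400)])
        t2 = Transcript("T2", "G1", "chr1", "+",
                        exons=[(1000, 1400), (3000, 3400)])
        return gene("G1", 1000, 3400, transcripts=[t1, t2])

    def test_exon_membership_drives_assignment(self, two_isoform_gene):
        shared = call(1200, 18, 2)
        t1_only = call(2200, 2, 18)
        intronic = call(2600, 15, 5)
        mapping = map_snps_to_isoforms([shared, t1_only, intronic], [two_isoform_gene])
        assert {c.site.position for c in mapping["T1"]["calls"]} == {1200, 2200}
        assert {c.site.position for c in mapping["T2"]["calls"]} == {1200}

    def test_direction_summary_reveals_isoform_discordance(self, two_isoform_gene):
        mapping = map_snps_to_isoforms(
            [call(1200, 18, 2), call(2200, 2, 18)], [two_isoform_gene]
        )
        assert mapping["T1"]["n_toward_hapA"] == 1
        assert mapping["T1"]["n_toward_hapB"] == 1
        assert mapping["T2"]["n_toward_hapB"] == 0

    def test_transcripts_without_testable_exonic_snps_excluded(self, two_isoform_gene):
        mapping = map_snps_to_isoforms([call(2200, 18, 2)], [two_isoform_gene])
        assert "T2" not in mapping
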