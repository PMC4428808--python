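"""Best-alignment selection: the pairwise optimality rules, origin tagging
and post-merge filtering."""

import itertools

import pytest

from asequant.merge import (
    AlignmentCandidate,
    AlignmentCandidateTriple,
    choose_alignment,
    filter_alignments,
    merge_alignment_sets,
    read_name_grouped,
    write_merged,
)


def cand(origin, nm1=0, nm2=0, m1=True, m2=True, **kw):
    return AlignmentCandidate(
        origin=origin,
        mate1_mapped=m1,
        mate2_mapped=m2,
        nm1=nm1 if m1 else None,
        nm2=nm2 if m2 else None,
        **kw,
    )


def triple(maternal=None, paternal=None, universal=None):
    return AlignmentCandidateTriple(
        read_id="r1", maternal=maternal, paternal=paternal, universal=universal
    )


class TestChooseAlignment:
    def test_smallest_nm_sum_wins(self):
        d = choose_alignment(
            triple(cand("maternal", 1, 0), cand("paternal", 2, 1), cand("universal", 1, 1))
        )
        assert (d.chosen, d.reason) == ("maternal", "fewest_mismatches")

    def test_three_way_tie_selects_universal(self):
        d = choose_alignment(
            triple(cand("maternal", 1, 1), cand("paternal", 2, 0), cand("universal", 0, 2))
        )
        assert (d.chosen, d.reason) == ("universal", "tie_universal")

    def test_mapped_pair_beats_lower_nm_with_unmapped_mate(self):
        d = choose_alignment(
            triple(
                maternal=cand("maternal", nm1=0, m2=False),
                universal=cand("universal", 2, 2),
            )
        )
        assert (d.chosen, d.reason) == ("universal", "mapped_pair_preferred")

    def test_maternal_paternal_tie_is_deterministically_maternal(self):
        d = choose_alignment(triple(cand("maternal", 1, 0), cand("paternal", 0, 1)))
        assert d.chosen == "maternal"

    def test_sole_candidate(self):
        d = choose_alignment(triple(universal=cand("universal", 3, 3)))
        assert (d.chosen, d.reason) == ("universal", "only_candidate")

    def test_nothing_mapped_anywhere_prefers_universal(self):
        t = triple(
            cand("maternal", m1=False, m2=False),
            cand("paternal", m1=False, m2=False),
            cand("universal", m1=False, m2=False),
        )
        d = choose_alignment(t)
        assert (d.chosen, d.reason) == ("universal", "only_candidate")

    def test_empty_triple_rejected(self):
        with pytest.raises(ValueError):
            choose_alignment(triple())


def _oracle(candidates):
    """Independent statement of the selection rules, written as a literal
    scan: maximize mapped mates; then minimize NM sum; break ties in the
    fixed order universal, maternal, paternal."""
    best = None
    preference = {"universal": 0, "maternal": 1, "paternal": 2}
    if all(c.n_mapped == 0 for c in candidates):
        names = {c.origin for c in candidates}
        if "universal" in names:
            return "universal"
        return candidates[0].origin
    for c in candidates:
        if best is None:
            best = c
            continue
        if c.n_mapped != best.n_mapped:
            if c.n_mapped > best.n_mapped:
                best = c
        elif c.nm_sum != best.nm_sum:
            if c.nm_sum < best.nm_sum:
                best = c
        elif preference[c.origin] < preference[best.origin]:
            best = c
    return best.origin


def test_exhaustive_rule_table_equivalence():
    """choose_alignment agrees with the hand-written rule scan over every
    combination of presence, mapped flags and NM sums 0-3."""
    mate_states = [(True, True), (True, False), (False, False)]
    nm_values = range(4)

    def candidates_for(origin):
        yield None
        for (m1, m2) in mate_states:
            if m1 and m2:
                for a, b in itertools.product(nm_values, repeat=2):
                    yield cand(origin, a, b)
            elif m1:
                for a in nm_values:
                    yield cand(origin, nm1=a, m2=False)
            else:
                yield cand(origin, m1=False, m2=False)

    n_checked = 0
    for m, p, u in itertools.product(
        candidates_for("maternal"), candidates_for("paternal"), candidates_for("universal")
    ):
        present = [c for c in (m, p, u) if c is not None]
        if not present:
            continue
        t = AlignmentCandidateTriple(read_id="x", maternal=m, paternal=p, universal=u)
        assert choose_alignment(t).chosen == _oracle(present)
        n_checked += 1
    assert n_checked > 5_000


class TestStreamMerge:
    def _pair(self, make_record, name, nm=(0, 0), start=1000, mapq=50,
              contig="chr1", unmapped2=False, secondary_extra=False):
        r1 = make_record(
            name=name, contig=contig, start=start, mate_start=start + 160,
            mapq=mapq, tags=[("NM", nm[0])],
        )
        r2 = make_record(
            name=name, contig=contig, start=start + 160, mate_start=start,
            is_read2=True, is_reverse=True, mapq=mapq,
            unmapped=unmapped2, tags=[] if unmapped2 else [("NM", nm[1])],
        )
        records = [r1, r2]
        if secondary_extra:
            records.append(
                make_record(
                    name=name, contig=contig, start=start + 5000, mapq=0,
                    secondary=True, tags=[("NM", nm[0] + 1)],
                )
            )
        return records

    def test_merged_records_carry_origin_tag(self, make_record, tmp_path):
        mat = {"r1": self._pair(make_record, "r1", nm=(0, 0))}
        pat = {"r1": self._pair(make_record, "r1", nm=(2, 1))}
        uni = {"r1": self._pair(make_record, "r1", nm=(1, 1))}
        merged = merge_alignment_sets(mat, pat, uni)
        assert len(merged) == 1
        rid, decision, chosen = merged[0]
        assert decision.chosen == "maternal"
        sam_in = tmp_path / "template.sam"
        write_merged_template = list(uni.values())[0]
        import pysam

        with pysam.AlignmentFile(
            sam_in, "wh", header=write_merged_template[0].header
        ) as fh:
            for rec in write_merged_template:
                fh.write(rec)
        out = tmp_path / "merged.sam"
        write_merged(merged, sam_in, out)
        with pysam.AlignmentFile(out) as fh:
            tags = {rec.get_tag("ZR") for rec in fh}
        assert tags == {"maternal"}

    def test_read_present_only_in_universal(self, make_record):
        uni = {"solo": self._pair(make_record, "solo")}
        merged = merge_alignment_sets({}, {}, uni)
        assert [(rid, d.chosen, d.reason) for rid, d, _ in merged] == [
            ("solo", "universal", "only_candidate")
        ]

    def test_empty_streams_give_empty_output(self):
        assert merge_alignment_sets({}, {}, {}) == []

    def test_each_read_id_appears_once(self, make_record):
        mat = {f"r{i}": self._pair(make_record, f"r{i}") for i in range(5)}
        uni = {f"r{i}": self._pair(make_record, f"r{i}", nm=(1, 1)) for i in range(3, 8)}
        merged = merge_alignment_sets(mat, {}, uni)
        ids = [rid for rid, _, _ in merged]
        assert len(ids) == len(set(ids)) == 8


class TestFilter:
    def _entry(self, make_record, name, start=1000, mapq=50, contig="chr1",
               multimapped=False, mate_start=None):
        from asequant.merge import MergeDecision, candidate_from_records

        mate_start = start + 160 if mate_start is None else mate_start
        records = [
            make_record(name=name, contig=contig, start=start,
                        mate_start=mate_start, mapq=mapq, tags=[("NM", 0)]),
            make_record(name=name, contig=contig, start=mate_start,
                        mate_start=start, is_read2=True, is_reverse=True,
                        mapq=mapq, tags=[("NM", 0)]),
        ]
        cand_obj = candidate_from_records(records, "universal")
        cand_obj.is_multimapped = multimapped
        return (name, MergeDecision("universal", "only_candidate"), cand_obj)

    def test_mapq_boundary(self, make_record):
        entries = [
            self._entry(make_record, "keep", start=100, mapq=9),
            self._entry(make_record, "drop", start=900, mapq=8),
        ]
        kept, tally = filter_alignments(entries)
        assert [rid for rid, _, _ in kept] == ["keep"]
        assert tally["low_mapq"] == 1

    def test_duplicate_pairs_collapse_to_one(self, make_record):
        entries = [
            self._entry(make_record, "a", start=500),
            self._entry(make_record, "b", start=500),
            self._entry(make_record, "c", start=500, mate_start=900),
        ]
        kept, tally = filter_alignments(entries)
        assert tally["duplicate"] == 1
        assert {rid for rid, _, _ in kept} == {"a", "c"}

    def test_mitochondrial_reads_removed(self, make_record):
        entries = [
            self._entry(make_record, "nuclear", contig="chr1"),
            self._entry(make_record, "mito", contig="chrM"),
        ]
        kept, tally = filter_alignments(entries)
        assert [rid for rid, _, _ in kept] == ["nuclear"]
        assert tally["mitochondrial"] == 1

    def test_multimapped_removed(self, make_record):
        entries = [self._entry(make_record, "multi", multimapped=True)]
        kept, tally = filter_alignments(entries)
        assert kept == [] and tally["multimapped"] == 1

    def test_unknown_mito_name_warns(self, make_record):
        entries = [self._entry(make_record, "a")]
        with pytest.warns(UserWarning, match="mitochondrial"):
            filter_alignments(entries, known_contigs=["chr1", "chr2"])
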