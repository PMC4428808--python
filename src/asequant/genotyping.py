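"""Heuristic WGS heterozygosity verification for SNPs and indels.

SNP heterozygosity follows depth-stratified alternate-allele-count rules
applied to WGS pileups built from filter-passing reads: at total depth ≤ 12
the alternate allele must be seen on more than 3 reads; at depth 13–30 on
more than 4; at depth ≥ 31 on at least 25% of reads. Read-level filters
require an aligned (CIGAR M) length ≥ 34, ≤ 4 mismatches in the MD tag, an
SM (mapping-quality of the single-end mode) tag > 10 and non-duplicate
status. Indel calls are heterozygous when supporting/informative reads fall
in [0.2, 0.7] (bounds inclusive); calls adjacent to or inside a homopolymer
of ≥ 7 bases, overlapping annotated simple repeats, or ≥ 200 bp long are
removed outright.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pysam

from asequant.variants import PhasedVariant

logger = logging.getLogger(__name__)

_MD_MISMATCH = re.compile(r"\^[A-Z]+|([A-Z])")

BASES = ("A", "C", "G", "T")


@dataclass
class PileupSummary:
    """Filtered-read base counts at one genomic position (1-based)."""

    contig: str
    position: int
    ref_base: str
    counts: dict[str, int] = field(default_factory=lambda: {b: 0 for b in BASES})

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    def count(self, base: str) -> int:
        return self.counts.get(base.upper(), 0)


@dataclass
class GenotypeVerdict:
    call: str  # "het" | "not_het"
    rule_applied: str  # depth_le12 | depth_13_30 | depth_ge31
    dna_reference_fraction: float


@dataclass
class IndelCall:
    contig: str
    position: int
    type: str  # "ins" | "del"
    length: int
    supporting_reads: int
    informative_reads: int
    homopolymer7plus: bool = False
    repeat_overlap: bool = False

    def __post_init__(self) -> None:
        if self.supporting_reads > self.informative_reads:
            raise ValueError("supporting reads cannot exceed informative reads")


def md_mismatches(md: str) -> int:
    """Number of substitution mismatches recorded in an MD tag.

    Deletion runs (``^ACGT``) are skipped; remaining letters each mark one
    mismatching reference base.
    """
    return sum(1 for m in _MD_MISMATCH.finditer(md) if m.group(1))


def aligned_length(record: pysam.AlignedSegment) -> int:
    """Total aligned length (CIGAR M/=/X operations)."""
    return sum(n for op, n in (record.cigartuples or ()) if op in (0, 7, 8))


def passes_read_filters(
    record: pysam.AlignedSegment,
    min_aligned: int = 34,
    max_md_mismatches: int = 4,
    min_sm: int = 10,
    sm_missing: str = "fail",
) -> bool:
    """Read-level inclusion filter for WGS pileups.

    Pass requires aligned length ≥ ``min_aligned``, MD mismatches ≤
    ``max_md_mismatches``, SM tag strictly greater than ``min_sm`` and
    non-duplicate status. The SM tag is aligner-specific; ``sm_missing``
    selects the policy when it is absent ("fail" or "ignore").
    """
    if record.is_unmapped or record.is_duplicate:
        return False
    if aligned_length(record) < min_aligned:
        return False
    if record.has_tag("MD") and md_mismatches(str(record.get_tag("MD"))) > max_md_mismatches:
        return False
    if record.has_tag("SM"):
        if int(record.get_tag("SM")) <= min_sm:
            return False
    elif sm_missing == "fail":
        logger.debug("record %s lacks SM tag; failing read filter", record.query_name)
        return False
    return True


def call_het_snp(ref_count: int, alt_count: int) -> GenotypeVerdict:
    """Depth-stratified heterozygosity heuristic on called-allele counts.

    Depth is ref+alt of high-quality bases (third alleles excluded).
    """
    if ref_count < 0 or alt_count < 0:
        raise ValueError("counts must be non-negative")
    depth = ref_count + alt_count
    if depth < 1:
        raise ValueError("total depth must be at least 1")
    if depth <= 12:
        rule = "depth_le12"
        het = alt_count > 3
    elif depth <= 30:
        rule = "depth_13_30"
        het = alt_count > 4
    else:
        rule = "depth_ge31"
        het = alt_count >= 0.25 * depth
    return GenotypeVerdict(
        call="het" if het else "not_het",
        rule_applied=rule,
        dna_reference_fraction=ref_count / depth,
    )


def call_het_indel(
    indel: IndelCall,
    ratio_low: float = 0.2,
    ratio_high: float = 0.7,
    max_length: int = 200,
) -> str:
    """Classify an indel call as "het", "not_het" or "removed".

    Context filters (homopolymer ≥ 7, repeat overlap, length ≥ 200 bp) remove
    the call before the supporting/informative ratio is considered; the ratio
    bounds are inclusive.
    """
    if indel.informative_reads < 1:
        raise ValueError(
            f"indel at {indel.contig}:{indel.position} has no informative reads; "
            "heterozygosity ratio undefined"
        )
    if indel.homopolymer7plus or indel.repeat_overlap or indel.length >= max_length:
        return "removed"
    ratio = indel.supporting_reads / indel.informative_reads
    return "het" if ratio_low <= ratio <= ratio_high else "not_het"


def homopolymer_adjacent(
    reference: str, start: int, end: int, min_run: int = 7
) -> bool:
    """True if [start, end] (1-based inclusive) touches a homopolymer run.

    A run of ``min_run`` identical reference bases counts when it overlaps
    the interval or is immediately contiguous with either edge.
    """
    lo = max(0, start - 1 - min_run)
    hi = min(len(reference), end + min_run)
    window = reference[lo:hi].upper()
    run_base, run_len, run_start = "", 0, 0
    for i, base in enumerate(window):
        if base == run_base:
            run_len += 1
        else:
            run_base, run_len, run_start = base, 1, i
        if run_len >= min_run:
            run_lo = lo + run_start + 1  # 1-based
            run_hi = lo + i + 1
            if run_hi >= start - 1 and run_lo <= end + 1:
                return True
    return False


def build_pileups(
    records: Iterable[pysam.AlignedSegment],
    sites: Sequence[tuple[str, int, str]],
    read_filter=passes_read_filters,
) -> dict[tuple[str, int], PileupSummary]:
    """Base counts at (contig, 1-based position, ref base) sites over
    filter-passing reads."""
    wanted: dict[str, dict[int, PileupSummary]] = {}
    for contig, pos, ref_base in sites:
        wanted.setdefault(contig, {})[pos] = PileupSummary(contig, pos, ref_base)
    for rec in records:
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        if read_filter is not None and not read_filter(rec):
            continue
        by_pos = wanted.get(rec.reference_name)
        if not by_pos:
            continue
        seq = rec.query_sequence
        for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
            summary = by_pos.get(rpos + 1)
            if summary is not None:
                base = seq[qpos].upper()
                if base in summary.counts:
                    summary.counts[base] += 1
    return {(s.contig, s.position): s for by_pos in wanted.values() for s in by_pos.values()}


def verify_imputed_genotypes(
    variants: Sequence[PhasedVariant],
    pileups: Mapping[tuple[str, int], PileupSummary],
    min_depth: int = 8,
) -> dict[str, list[PhasedVariant]]:
    """Partition imputed heterozygous SNPs by WGS support.

    Returns a dict with keys ``verified`` (WGS heuristics call het),
    ``failed`` (confident non-het WGS evidence) and ``untestable``
    (no pileup or called-allele depth below ``min_depth``). The three lists
    partition the input; verified variants get ``wgs_verified=True``.
    """
    out: dict[str, list[PhasedVariant]] = {"verified": [], "failed": [], "untestable": []}
    for v in variants:
        if not v.is_het:
            raise ValueError("verification operates on heterozygous variants only")
        summary = pileups.get((v.contig, v.position))
        if summary is None:
            out["untestable"].append(v)
            continue
        ref_n = summary.count(v.ref_allele)
        alt_n = summary.count(v.alt_allele)
        if ref_n + alt_n < min_depth:
            out["untestable"].append(v)
            continue
        verdict = call_het_snp(ref_n, alt_n)
        if verdict.call == "het":
            v.wgs_verified = True
            out["verified"].append(v)
        else:
            out["failed"].append(v)
    return out
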