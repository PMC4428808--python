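"""Best-alignment selection across maternal/paternal/universal alignment sets.

Each read pair is aligned three times: to the two personalized haplotype
references and to the universal reference. Because haplotype genomes are
SNP-substituted only, coordinates are interchangeable, and the three
candidate alignments can be compared directly:

1. a candidate producing a fully mapped read pair beats any candidate with
   one or more unmapped mates;
2. among equally-mapped candidates the smallest summed edit distance
   (SAM ``NM``) wins;
3. ties go to the universal alignment, then maternal before paternal.

The chosen record set is tagged with its origin in the custom SAM tag
``ZR:Z:<origin>``. Post-merge filtering removes PCR duplicates, multi-mapped
reads, low mapping quality (MAPQ < 9) and mitochondrial alignments.
"""

from __future__ import annotations

import logging
import warnings
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pysam

logger = logging.getLogger(__name__)

ORIGINS = ("maternal", "paternal", "universal")
DEFAULT_MIN_MAPQ = 9
DEFAULT_MITO_NAMES = ("chrM", "MT", "chrMT", "M")


@dataclass
class AlignmentCandidate:
    """One origin's candidate alignment for a read pair."""

    origin: str
    mate1_mapped: bool
    mate2_mapped: bool
    nm1: Optional[int] = None
    nm2: Optional[int] = None
    mapping_quality: int = 0
    is_multimapped: bool = False
    contig: Optional[str] = None
    position: Optional[int] = None
    cigar: Optional[str] = None
    strand: Optional[str] = None
    records: tuple = ()  # underlying pysam records, when stream-derived

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.mate1_mapped and self.nm1 is None:
            raise ValueError("mapped mate1 requires an edit distance")
        if self.mate2_mapped and self.nm2 is None:
            raise ValueError("mapped mate2 requires an edit distance")

    @property
    def n_mapped(self) -> int:
        return int(self.mate1_mapped) + int(self.mate2_mapped)

    @property
    def nm_sum(self) -> int:
        """Summed edit distance over mapped mates."""
        total = 0
        if self.mate1_mapped:
            total += int(self.nm1)
        if self.mate2_mapped:
            total += int(self.nm2)
        return total


@dataclass
class AlignmentCandidateTriple:
    read_id: str
    maternal: Optional[AlignmentCandidate] = None
    paternal: Optional[AlignmentCandidate] = None
    universal: Optional[AlignmentCandidate] = None

    def candidates(self) -> list[AlignmentCandidate]:
        return [c for c in (self.maternal, self.paternal, self.universal) if c is not None]

    def get(self, origin: str) -> Optional[AlignmentCandidate]:
        return getattr(self, origin)


@dataclass
class MergeDecision:
    chosen: str
    reason: str  # fewest_mismatches | tie_universal | tie_maternal |
    #              mapped_pair_preferred | only_candidate


def choose_alignment(triple: AlignmentCandidateTriple) -> MergeDecision:
    """Select the optimal origin for one read pair.

    Precedence: fully mapped pair > fewer unmapped mates; then smallest NM
    sum; ties resolved to universal, then maternal before paternal. A triple
    with no mapped mate anywhere resolves to universal when supplied, else
    the first supplied origin.
    """
    cands = triple.candidates()
    if not cands:
        raise ValueError(f"empty candidate triple for read {triple.read_id!r}")
    if len(cands) == 1:
        return MergeDecision(cands[0].origin, "only_candidate")
    best_mapped = max(c.n_mapped for c in cands)
    if best_mapped == 0:
        if triple.universal is not None:
            return MergeDecision("universal", "only_candidate")
        return MergeDecision(cands[0].origin, "only_candidate")
    tier = [c for c in cands if c.n_mapped == best_mapped]
    if len(tier) == 1:
        return MergeDecision(tier[0].origin, "mapped_pair_preferred")
    best_nm = min(c.nm_sum for c in tier)
    winners = {c.origin for c in tier if c.nm_sum == best_nm}
    if len(winners) == 1:
        return MergeDecision(winners.pop(), "fewest_mismatches")
    if "universal" in winners:
        return MergeDecision("universal", "tie_universal")
    # maternal vs paternal tie: maternal wins, deterministically
    return MergeDecision("maternal", "tie_maternal")


# ---------------------------------------------------------------------------
# Stream-level merging
# ---------------------------------------------------------------------------


def _primary_pair(records: Sequence[pysam.AlignedSegment]):
    """Split records into (mate1, mate2) primaries, ignoring secondaries."""
    r1 = r2 = None
    for rec in records:
        if rec.is_secondary or rec.is_supplementary:
            continue
        if rec.is_read2:
            r2 = rec
        else:
            r1 = rec
    return r1, r2


def _nm(rec: Optional[pysam.AlignedSegment]) -> Optional[int]:
    if rec is None or rec.is_unmapped:
        return None
    try:
        return int(rec.get_tag("NM"))
    except KeyError:
        return None
    except (TypeError, ValueError):
        logger.warning("malformed NM tag on %s; treating mate as unmapped", rec.query_name)
        return None


def candidate_from_records(
    records: Sequence[pysam.AlignedSegment], origin: str
) -> Optional[AlignmentCandidate]:
    """Build a candidate from one origin's records for a read pair.

    Multi-mapped reads contribute the record set with the smallest edit
    distance (secondary alignments are compared on NM); the candidate is
    flagged multi-mapped for downstream removal.
    """
    if not records:
        return None
    primaries = [r for r in records if not (r.is_secondary or r.is_supplementary)]
    secondaries = [r for r in records if r.is_secondary]
    r1, r2 = _primary_pair(records)
    if r1 is None and r2 is None:
        return None
    multimapped = bool(secondaries)
    for rec in primaries:
        try:
            if int(rec.get_tag("NH")) > 1:
                multimapped = True
        except KeyError:
            pass
    # among multi-mapped alternatives keep the smallest-NM placement
    if secondaries and r1 is not None and not r1.is_unmapped:
        alts = [r for r in secondaries if not r.is_read2]
        best = min([r1] + alts, key=lambda r: _nm(r) if _nm(r) is not None else 1 << 30)
        r1 = best
    nm1, nm2 = _nm(r1), _nm(r2)
    m1 = r1 is not None and not r1.is_unmapped and nm1 is not None
    m2 = r2 is not None and not r2.is_unmapped and nm2 is not None
    anchor = r1 if m1 else (r2 if m2 else (r1 or r2))
    return AlignmentCandidate(
        origin=origin,
        mate1_mapped=m1,
        mate2_mapped=m2,
        nm1=nm1 if m1 else None,
        nm2=nm2 if m2 else None,
        mapping_quality=min(
            [r.mapping_quality for r in (r1, r2) if r is not None and not r.is_unmapped]
            or [0]
        ),
        is_multimapped=multimapped,
        contig=anchor.reference_name if anchor is not None and not anchor.is_unmapped else None,
        position=anchor.reference_start if anchor is not None and not anchor.is_unmapped else None,
        cigar=anchor.cigarstring if anchor is not None else None,
        strand=("-" if anchor.is_reverse else "+") if anchor is not None else None,
        records=tuple(r for r in (r1, r2) if r is not None),
    )


def read_name_grouped(path: str | Path) -> "OrderedDict[str, list[pysam.AlignedSegment]]":
    """Load a SAM/BAM into an insertion-ordered name→records mapping."""
    grouped: OrderedDict[str, list[pysam.AlignedSegment]] = OrderedDict()
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            grouped.setdefault(rec.query_name, []).append(rec)
    return grouped


def merge_alignment_sets(
    maternal: Mapping[str, Sequence[pysam.AlignedSegment]],
    paternal: Mapping[str, Sequence[pysam.AlignedSegment]],
    universal: Mapping[str, Sequence[pysam.AlignedSegment]],
) -> list[tuple[str, MergeDecision, AlignmentCandidate]]:
    """Resolve each read pair to its optimal origin.

    Returns (read_id, decision, winning candidate) in a stable order. Reads
    absent from every stream cannot occur by construction; reads present in
    only some streams are resolved among the supplied candidates.
    """
    streams = {"maternal": maternal, "paternal": paternal, "universal": universal}
    read_ids: "OrderedDict[str, None]" = OrderedDict()
    for stream in streams.values():
        for rid in stream:
            read_ids.setdefault(rid)
    merged = []
    for rid in read_ids:
        triple = AlignmentCandidateTriple(read_id=rid)
        for origin, stream in streams.items():
            cand = candidate_from_records(stream.get(rid, ()), origin)
            setattr(triple, origin, cand)
        if not triple.candidates():
            warnings.warn(f"read {rid!r} has no usable records in any stream; skipped")
            continue
        decision = choose_alignment(triple)
        merged.append((rid, decision, triple.get(decision.chosen)))
    return merged


def write_merged(
    merged: Iterable[tuple[str, MergeDecision, AlignmentCandidate]],
    template_path: str | Path,
    out_path: str | Path,
) -> None:
    """Write chosen records as coordinate-sorted SAM with ZR origin tags."""
    with pysam.AlignmentFile(str(template_path), check_sq=False) as template:
        header = template.header.to_dict()
    records = []
    for _, decision, cand in merged:
        for rec in cand.records:
            rec = rec.__copy__()
            rec.set_tag("ZR", decision.chosen, value_type="Z")
            records.append(rec)
    records.sort(key=lambda r: (r.is_unmapped, r.reference_id, r.reference_start))
    with pysam.AlignmentFile(str(out_path), "wh", header=header) as out:
        for rec in records:
            out.write(rec)


# ---------------------------------------------------------------------------
# Post-merge filtering
# ---------------------------------------------------------------------------


def _unclipped_start(rec: pysam.AlignedSegment) -> int:
    """Leftmost position after undoing soft clips (duplicate-marking key)."""
    start = rec.reference_start
    cig = rec.cigartuples or ()
    if cig and cig[0][0] == 4:  # leading soft clip
        start -= cig[0][1]
    return start


def filter_alignments(
    merged: Sequence[tuple[str, MergeDecision, AlignmentCandidate]],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    mito_names: Sequence[str] = DEFAULT_MITO_NAMES,
    known_contigs: Optional[Sequence[str]] = None,
) -> tuple[list[tuple[str, MergeDecision, AlignmentCandidate]], dict[str, int]]:
    """Remove PCR duplicates, multi-mapped, low-MAPQ and mitochondrial pairs.

    Duplicates share (contig, unclipped start, strand, mate unclipped start);
    the highest-MAPQ pair is retained, ties going to the first encountered.
    The tally reports removals per category.
    """
    if known_contigs is not None and not set(mito_names) & set(known_contigs):
        warnings.warn(
            "no mitochondrial contig matching %r found in the input; "
            "mitochondrial filtering will be a no-op" % (tuple(mito_names),)
        )
    tally = {"duplicate": 0, "multimapped": 0, "low_mapq": 0, "mitochondrial": 0, "kept": 0}
    best_by_key: "OrderedDict[tuple, tuple[int, int]]" = OrderedDict()
    entries = list(merged)
    for idx, (rid, decision, cand) in enumerate(entries):
        mapped = [r for r in cand.records if not r.is_unmapped]
        if not mapped:
            continue
        first = mapped[0]
        mate = mapped[1] if len(mapped) > 1 else None
        key = (
            first.reference_name,
            _unclipped_start(first),
            first.is_reverse,
            _unclipped_start(mate) if mate is not None else None,
        )
        if key not in best_by_key or cand.mapping_quality > best_by_key[key][0]:
            best_by_key[key] = (cand.mapping_quality, idx)
    keep_idx = {idx for _, idx in best_by_key.values()}
    kept = []
    for idx, (rid, decision, cand) in enumerate(entries):
        mapped = [r for r in cand.records if not r.is_unmapped]
        if not mapped:
            tally["multimapped"] += 0  # unmapped pairs simply drop out
            continue
        if idx not in keep_idx:
            tally["duplicate"] += 1
            continue
        if cand.is_multimapped:
            tally["multimapped"] += 1
            continue
        if cand.mapping_quality < min_mapq:
            tally["low_mapq"] += 1
            continue
        if cand.contig in mito_names:
            tally["mitochondrial"] += 1
            continue
        kept.append((rid, decision, cand))
        tally["kept"] += 1
    return kept, tally
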