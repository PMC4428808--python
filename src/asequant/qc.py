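"""Alignment-confounder annotation and QC filtering of testable SNPs.

Variants absent from the personalized references — un-phased SNPs and all
indels — still distort alignments around them, inflating apparent allelic
imbalance; regions of imperfect alignability do the same. Each testable SNP
is therefore annotated with the distance to its nearest un-phased indel and
SNP, the number of proximal un-phased SNPs within a read length, the
alignability of its position, its transcript feature class, and the
imputation R². The removal rule drops SNPs with an indel within 100 bp,
four or more un-phased SNPs within 100 bp, or alignability below 1.

Binned ASE-proportion diagnostics compare each bin's ASE rate against the
global rate with an exact two-sided binomial test.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from asequant.ase import AseCall, binomial_two_sided
from asequant.genemodel import Gene
from asequant.variants import HetSite, PhasedVariant

DEFAULT_WINDOW = 100
DEFAULT_MAX_PROXIMAL_SNPS = 3  # fail at >= 4
FEATURES = ("coding_exonic", "intronic", "utr3", "utr5", "intergenic")
DEFAULT_DISTANCE_EDGES = (0, 10, 100, 1_000, 10_000, float("inf"))


@dataclass
class ProximityAnnotation:
    site: HetSite
    indel_distance: Optional[int] = None
    snp_distance: Optional[int] = None
    proximal_snp_count: int = 0
    alignability: float = 1.0
    feature: str = "intergenic"

    @property
    def r_squared(self) -> Optional[float]:
        return self.site.r_squared


@dataclass
class FilterVerdict:
    passed: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        assert self.passed == (len(self.reasons) == 0)


def _interval_distance(pos: int, start: int, end: int) -> int:
    """Distance from a position to a 1-based inclusive interval (0 if inside)."""
    if start <= pos <= end:
        return 0
    return start - pos if pos < start else pos - end


def annotate_proximity(
    sites: Sequence[HetSite],
    unphased_variants: Sequence[PhasedVariant],
    phased_sites: Optional[Sequence[HetSite]] = None,
    window: int = DEFAULT_WINDOW,
    include_phased: bool = False,
) -> list[ProximityAnnotation]:
    """Nearest-SNV distances and proximal-SNP counts per testable site.

    Indel distance is measured to the nearest edge of the indel's
    reference-affected interval (not the VCF anchor base). The proximal-SNP
    count covers heterozygous un-phased SNPs within ±``window`` bp
    (excluding the site itself); set ``include_phased`` to also count phased
    het SNPs, as for the proximal-heterozygous-SNP diagnostic.
    """
    snp_pos: dict[str, np.ndarray] = {}
    indel_ivals: dict[str, list[tuple[int, int]]] = {}
    for v in unphased_variants:
        if not v.is_het:
            continue
        if v.variant_class == "snp":
            snp_pos.setdefault(v.contig, []).append(v.position)  # type: ignore[arg-type]
        else:
            indel_ivals.setdefault(v.contig, []).append(v.affected_interval())
    if include_phased and phased_sites:
        for s in phased_sites:
            snp_pos.setdefault(s.contig, []).append(s.position)  # type: ignore[arg-type]
    snp_pos = {c: np.unique(np.asarray(p, dtype=int)) for c, p in snp_pos.items()}
    indel_ivals = {c: sorted(iv) for c, iv in indel_ivals.items()}

    out = []
    for site in sites:
        positions = snp_pos.get(site.contig)
        snp_distance = None
        proximal = 0
        if positions is not None and positions.size:
            others = positions[positions != site.position]
            if others.size:
                dists = np.abs(others - site.position)
                snp_distance = int(dists.min())
                proximal = int((dists <= window).sum())
        indel_distance = None
        for start, end in indel_ivals.get(site.contig, ()):
            d = _interval_distance(site.position, start, end)
            if indel_distance is None or d < indel_distance:
                indel_distance = d
        out.append(
            ProximityAnnotation(
                site=site,
                indel_distance=indel_distance,
                snp_distance=snp_distance,
                proximal_snp_count=proximal,
            )
        )
    return out


class AlignabilityTrack:
    """Per-position alignability values from BED/bedGraph intervals.

    Intervals are half-open 0-based (BED convention) with values in [0, 1].
    Positions outside every interval score 0 (unalignable by default).
    Overlapping intervals with conflicting values are an input error.
    """

    def __init__(self, intervals: Mapping[str, Sequence[tuple[int, int, float]]]):
        self._trees: dict[str, IntervalTree] = {}
        for contig, ivals in intervals.items():
            tree = IntervalTree()
            for start, end, value in ivals:
                if not 0.0 <= value <= 1.0:
                    raise ValueError(f"alignability value {value} outside [0, 1]")
                for hit in tree.overlap(start, end):
                    if hit.data != value:
                        raise ValueError(
                            f"conflicting alignability at {contig}:{start}-{end}"
                        )
                tree.addi(start, end, value)
            self._trees[contig] = tree

    @classmethod
    def from_bed(cls, path: str | Path) -> "AlignabilityTrack":
        intervals: dict[str, list[tuple[int, int, float]]] = {}
        for line in Path(path).read_text().splitlines():
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            contig, start, end = fields[0], int(fields[1]), int(fields[2])
            # bedGraph puts the value in column 4; BED in column 5 (score)
            value = float(fields[3]) if len(fields) == 4 else float(fields[4])
            intervals.setdefault(contig, []).append((start, end, value))
        return cls(intervals)

    def lookup(self, contig: str, position: int) -> float:
        """Alignability at a 1-based position; uncovered positions → 0."""
        tree = self._trees.get(contig)
        if tree is None:
            return 0.0
        hits = tree.at(position - 1)
        if not hits:
            return 0.0
        return float(next(iter(hits)).data)


def lookup_alignability(site: HetSite, track: AlignabilityTrack) -> float:
    return track.lookup(site.contig, site.position)


def annotate_feature(site: HetSite, genes: Sequence[Gene]) -> str:
    """Transcript-feature label for a site: one of coding_exonic, intronic,
    utr3, utr5, intergenic — or "multiple" when overlapping transcripts imply
    more than one label."""
    labels: set[str] = set()
    in_gene = False
    for gene in genes:
        if gene.contig != site.contig or not gene.contains(site.position):
            continue
        in_gene = True
        for t in gene.transcripts:
            s, e = t.span
            if not s <= site.position <= e:
                labels.add("intronic")  # within gene span, outside this transcript
                continue
            if any(a <= site.position <= b for a, b in t.cds):
                labels.add("coding_exonic")
            elif any(a <= site.position <= b for a, b in t.utr5):
                labels.add("utr5")
            elif any(a <= site.position <= b for a, b in t.utr3):
                labels.add("utr3")
            elif t.contains_exonic(site.position):
                labels.add("coding_exonic")  # exon of a transcript without CDS rows
            else:
                labels.add("intronic")
        if not gene.transcripts:
            labels.add("intronic")
    if not in_gene:
        return "intergenic"
    if len(labels) > 1:
        return "multiple"
    return labels.pop()


def annotate_all(
    sites: Sequence[HetSite],
    unphased_variants: Sequence[PhasedVariant],
    alignability: Optional[AlignabilityTrack] = None,
    genes: Sequence[Gene] = (),
    **proximity_kwargs,
) -> list[ProximityAnnotation]:
    anns = annotate_proximity(sites, unphased_variants, **proximity_kwargs)
    for ann in anns:
        if alignability is not None:
            ann.alignability = lookup_alignability(ann.site, alignability)
        if genes:
            ann.feature = annotate_feature(ann.site, genes)
    return anns


def apply_filters(
    annotations: Sequence[ProximityAnnotation],
    window: int = DEFAULT_WINDOW,
    max_proximal_snps: int = DEFAULT_MAX_PROXIMAL_SNPS,
    min_alignability: float = 1.0,
) -> list[FilterVerdict]:
    """Removal rule per site; "within 100 bp" is inclusive (distance ≤ 100)."""
    verdicts = []
    for ann in annotations:
        reasons = []
        if ann.indel_distance is not None and ann.indel_distance <= window:
            reasons.append("indel_within_100bp")
        if ann.proximal_snp_count > max_proximal_snps:
            reasons.append("four_plus_snps_within_100bp")
        if ann.alignability < min_alignability:
            reasons.append("imperfect_alignability")
        verdicts.append(FilterVerdict(passed=not reasons, reasons=tuple(reasons)))
    return verdicts


def binned_ase_proportion(
    calls: Sequence[AseCall],
    key_values: Sequence[Optional[float | str]],
    edges: Sequence[float] = DEFAULT_DISTANCE_EDGES,
    categorical: bool = False,
) -> pd.DataFrame:
    """ASE proportion per bin of a confounder key, with per-bin enrichment test.

    ``key_values`` aligns with ``calls`` (None → excluded, e.g. no indel on
    the contig). Numeric keys are binned by half-open ``edges`` intervals;
    categorical keys (transcript features, say) bin by value. Each bin's ASE
    count is tested two-sided against the global ASE proportion; degenerate
    global proportions (0 or 1) give no test.
    """
    kept = [
        (call, key)
        for call, key in zip(calls, key_values)
        if key is not None and call.classification != "untestable"
    ]
    if not kept:
        return pd.DataFrame(columns=["bin", "n", "n_ASE", "proportion", "p_value"])
    n_total = len(kept)
    n_ase_total = sum(call.is_ase for call, _ in kept)
    global_prop = n_ase_total / n_total

    def bin_label(key) -> str:
        if categorical:
            return str(key)
        for lo, hi in zip(edges[:-1], edges[1:]):
            if lo <= key < hi:
                return f"[{lo:g},{hi:g})"
        return f"[{edges[-2]:g},inf)"

    grouped: dict[str, list[AseCall]] = {}
    for call, key in kept:
        grouped.setdefault(bin_label(key), []).append(call)
    rows = []
    for label, members in grouped.items():
        n = len(members)
        n_ase = sum(c.is_ase for c in members)
        if n and 0.0 < global_prop < 1.0:
            p = binomial_two_sided(n_ase, n, global_prop)
        else:
            p = float("nan")
        rows.append(
            {
                "bin": label,
                "n": n,
                "n_ASE": n_ase,
                "proportion": 100.0 * n_ase / n if n else float("nan"),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
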