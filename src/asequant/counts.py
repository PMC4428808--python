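"""Allele-resolved read counting at phased heterozygous SNPs, and RPKM.

Counting mirrors a permissive pileup (base quality threshold 0, no
realignment-based base-quality adjustment, anomalous pairs included): every
unique, de-duplicated, non-multimapped read contributes the base it carries
over each covered site. Overlapping mates are each counted. The reference
fraction uses ref/(ref+alt); bases matching neither allele are tallied
separately and count toward depth for the ≥ 10-read testability threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pysam

from asequant.genemodel import Gene
from asequant.variants import HetSite


@dataclass
class SiteCounts:
    """Per-site allele counts for one library/replicate."""

    site: HetSite
    ref_count: int
    alt_count: int
    other_count: int = 0
    library: str = "lib1"
    replicate: str = "rep1"

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count + self.other_count

    @property
    def allelic_depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def reference_fraction(self) -> float:
        if self.allelic_depth == 0:
            return float("nan")
        return self.ref_count / self.allelic_depth

    @property
    def hap_a_count(self) -> int:
        return self.ref_count if self.site.ref_haplotype == "A" else self.alt_count

    @property
    def hap_b_count(self) -> int:
        return self.alt_count if self.site.ref_haplotype == "A" else self.ref_count

    @property
    def ordered_genotype(self) -> tuple[str, str]:
        return (self.site.ref, self.site.alt)

    def testable(self, min_depth: int = 10) -> bool:
        return self.depth >= min_depth


def haplotype_counts(counts: SiteCounts) -> tuple[int, int]:
    """Map ref/alt counts onto haplotypes A/B via the site's phase."""
    if counts.site.ref_haplotype not in ("A", "B"):
        raise ValueError(f"site {counts.site.key} has no haplotype phase")
    return counts.hap_a_count, counts.hap_b_count


def _usable(rec: pysam.AlignedSegment) -> bool:
    return not (
        rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.is_duplicate
    )


def pileup_counts(
    records: Iterable[pysam.AlignedSegment],
    sites: Sequence[HetSite],
    library: str = "lib1",
    replicate: str = "rep1",
    min_base_quality: int = 0,
) -> list[SiteCounts]:
    """Count allele-informative reads at each het site.

    ``records`` is any iterable of aligned segments (e.g. a pysam
    AlignmentFile over the merged, filtered alignments). Sites on contigs
    absent from the alignment header are a coordinate error when the header
    declares references.
    """
    by_pos: dict[str, dict[int, list[int]]] = {}
    acc: list[list[int]] = []
    for i, site in enumerate(sites):
        by_pos.setdefault(site.contig, {})[site.position] = [i]
        acc.append([0, 0, 0])  # ref, alt, other
    for rec in records:
        if not _usable(rec):
            continue
        contig_sites = by_pos.get(rec.reference_name)
        if not contig_sites:
            continue
        seq = rec.query_sequence
        quals = rec.query_qualities
        for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
            hit = contig_sites.get(rpos + 1)
            if hit is None:
                continue
            if quals is not None and quals[qpos] < min_base_quality:
                continue
            for i in hit:
                base = seq[qpos].upper()
                site = sites[i]
                if base == site.ref.upper():
                    acc[i][0] += 1
                elif base == site.alt.upper():
                    acc[i][1] += 1
                else:
                    acc[i][2] += 1
    return [
        SiteCounts(
            site=site,
            ref_count=a[0],
            alt_count=a[1],
            other_count=a[2],
            library=library,
            replicate=replicate,
        )
        for site, a in zip(sites, acc)
    ]


def pileup_counts_from_path(
    path: str,
    sites: Sequence[HetSite],
    require_contigs: bool = True,
    **kwargs,
) -> list[SiteCounts]:
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        if require_contigs and fh.references:
            known = set(fh.references)
            for site in sites:
                if site.contig not in known:
                    raise ValueError(
                        f"site contig {site.contig!r} not present in alignment header"
                    )
        return pileup_counts(fh, sites, **kwargs)


def rpkm_value(fragments: int, gene_length_bp: int, total_mapped_r1: int) -> float:
    """RPKM = fragments / (gene length in kb × mapped R1 reads in millions)."""
    if total_mapped_r1 <= 0:
        raise ValueError("no mapped R1 reads; RPKM undefined")
    return fragments / ((gene_length_bp / 1e3) * (total_mapped_r1 / 1e6))


def compute_rpkm(
    records: Iterable[pysam.AlignedSegment],
    genes: Sequence[Gene],
) -> dict[str, float]:
    """Gene RPKM from R1 fragment start positions within genic boundaries.

    RPKM = fragments / (gene length in kb × mapped R1 reads in millions);
    gene length is the genomic span of the gene boundary. Raises when no
    mapped R1 reads exist (the normalization is undefined).
    """
    by_contig: dict[str, list[Gene]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)
    frags = {g.gene_id: 0 for g in genes}
    total_r1 = 0
    for rec in records:
        if not _usable(rec) or rec.is_read2:
            continue
        total_r1 += 1
        pos = rec.reference_start + 1
        for g in by_contig.get(rec.reference_name, ()):
            if g.contains(pos):
                frags[g.gene_id] += 1
    return {
        gid: rpkm_value(n, g.length, total_r1)
        for (gid, n), g in zip(frags.items(), genes)
    }


def counts_to_frame(counts: Sequence[SiteCounts], min_depth: int = 10):
    """Tabulate counts as the per-site TSV schema."""
    import pandas as pd

    rows = []
    for c in counts:
        rows.append(
            {
                "contig": c.site.contig,
                "pos": c.site.position,
                "ref": c.site.ref,
                "alt": c.site.alt,
                "refHap": c.site.ref_haplotype,
                "refCount": c.ref_count,
                "altCount": c.alt_count,
                "otherCount": c.other_count,
                "depth": c.depth,
                "refFraction": c.reference_fraction,
                "hapA": c.hap_a_count,
                "hapB": c.hap_b_count,
                "testable": c.testable(min_depth),
                "library": c.library,
                "replicate": c.replicate,
            }
        )
    return pd.DataFrame(rows)


def frame_to_counts(frame) -> list[SiteCounts]:
    """Rebuild :class:`SiteCounts` from the per-site TSV schema."""
    out = []
    for row in frame.itertuples(index=False):
        site = HetSite(
            contig=str(row.contig),
            position=int(row.pos),
            ref=row.ref,
            alt=row.alt,
            ref_haplotype=row.refHap,
        )
        out.append(
            SiteCounts(
                site=site,
                ref_count=int(row.refCount),
                alt_count=int(row.altCount),
                other_count=int(row.otherCount),
                library=str(row.library),
                replicate=str(row.replicate),
            )
        )
    return out
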