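"""Gene- and isoform-level ASE aggregation and replicate analytics.

Individual SNPs are noisy at moderate depth; summing haplotype-resolved
counts over all QC-passing testable SNPs inside a gene's annotated boundary
gives a far better powered test. Haplotype A and B counts are summed
independently and tested with a two-sided binomial against an expected
proportion of 0.5 (haplotype sums mix ordered genotypes and diploid
alignment removes reference bias, so no per-genotype baseline applies).
Genes are ranked from most to least imbalanced; per-gene flags record phase
concordance of member-SNP imbalance directions and the presence of
replicated ASE SNPs across technical replicates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from asequant.ase import AseCall, binomial_two_sided
from asequant.genemodel import Gene, Transcript


@dataclass
class GeneAseResult:
    gene_id: str
    hap_a_sum: int
    hap_b_sum: int
    p_value: float
    n_testable_snps: int
    member_positions: tuple[int, ...] = ()
    phase_concordant: bool = True
    has_replicated_ase_snp: bool = False
    rank: Optional[int] = None
    replicate: str = "rep1"

    @property
    def total(self) -> int:
        return self.hap_a_sum + self.hap_b_sum

    @property
    def hap_a_fraction(self) -> float:
        return self.hap_a_sum / self.total if self.total else float("nan")

    @property
    def imbalance(self) -> int:
        return abs(self.hap_a_sum - self.hap_b_sum)


@dataclass
class ReplicateComparison:
    depth_threshold: int
    n_testable_both: int
    n_ase_both: int
    n_ase_rep1_only: int
    n_ase_rep2_only: int
    n_not_ase_both: int
    reference_fraction_correlation: float = float("nan")

    @property
    def ase_either(self) -> int:
        return self.n_ase_both + self.n_ase_rep1_only + self.n_ase_rep2_only

    @property
    def overlap_proportion(self) -> float:
        """ASE-in-both among ASE-in-either (replication rate)."""
        return self.n_ase_both / self.ase_either if self.ase_either else float("nan")


def phase_concordance(calls: Sequence[AseCall]) -> bool:
    """True iff every non-balanced member SNP leans toward the same haplotype.

    Balanced SNPs (equal haplotype counts) are neutral and never break
    concordance.
    """
    if not calls:
        raise ValueError("phase concordance requires at least one member call")
    directions = {c.direction for c in calls if c.direction != "balanced"}
    return len(directions) <= 1


def aggregate_gene_ase(
    calls: Sequence[AseCall],
    genes: Sequence[Gene],
    expected: float = 0.5,
    min_depth: int = 10,
    replicate: str = "rep1",
) -> list[GeneAseResult]:
    """Haplotype-summed binomial ASE per gene, ranked by imbalance p-value.

    Membership is SNP position within the gene's annotated genomic span.
    Only testable calls contribute. Genes without member SNPs are omitted.
    Ranking ties break by |hap imbalance| (larger first) then gene id.
    """
    results = []
    for gene in genes:
        members = [
            c
            for c in calls
            if c.site.contig == gene.contig
            and gene.contains(c.site.position)
            and c.classification != "untestable"
        ]
        if not members:
            continue
        hap_a = sum(c.hap_a_count for c in members)
        hap_b = sum(c.hap_b_count for c in members)
        total = hap_a + hap_b
        if total == 0:
            continue
        p = binomial_two_sided(hap_a, total, expected)
        results.append(
            GeneAseResult(
                gene_id=gene.gene_id,
                hap_a_sum=hap_a,
                hap_b_sum=hap_b,
                p_value=p,
                n_testable_snps=len(members),
                member_positions=tuple(sorted(c.site.position for c in members)),
                phase_concordant=phase_concordance(members),
                replicate=replicate,
            )
        )
    results.sort(key=lambda r: (r.p_value, -r.imbalance, r.gene_id))
    for i, r in enumerate(results, start=1):
        r.rank = i
    return results


def flag_gene_criteria(
    calls_by_replicate: Mapping[str, Sequence[AseCall]],
    genes: Sequence[Gene],
    exonic_positions: Optional[set[tuple[str, int]]] = None,
) -> "pd.DataFrame":
    """Per-gene replication flags across technical replicates.

    Computes, per gene: whether each replicate holds ≥ 2 testable exonic
    SNPs; whether any member SNP is classified ASE in every replicate (a
    "replicated ASE SNP"); and per-replicate phase concordance. With a single
    replicate supplied the cross-replicate flags are computed on available
    data and marked partial. ``exonic_positions`` defaults to positions
    exonic in any transcript of the annotation.
    """
    import pandas as pd

    if exonic_positions is None:
        exonic_positions = set()
        for g in genes:
            for t in g.transcripts:
                for c in _all_calls(calls_by_replicate):
                    if c.site.contig == g.contig and t.contains_exonic(c.site.position):
                        exonic_positions.add(c.site.key)
    reps = list(calls_by_replicate)
    partial = len(reps) < 2
    rows = []
    for gene in genes:
        per_rep_members: dict[str, list[AseCall]] = {}
        for rep, calls in calls_by_replicate.items():
            per_rep_members[rep] = [
                c
                for c in calls
                if c.site.contig == gene.contig
                and gene.contains(c.site.position)
                and c.classification != "untestable"
            ]
        if not any(per_rep_members.values()):
            continue
        two_exonic_each = all(
            sum(1 for c in members if c.site.key in exonic_positions) >= 2
            for members in per_rep_members.values()
        )
        ase_keys_per_rep = [
            {c.site.key for c in members if c.is_ase}
            for members in per_rep_members.values()
        ]
        replicated = bool(set.intersection(*ase_keys_per_rep)) if ase_keys_per_rep else False
        row = {
            "gene_id": gene.gene_id,
            "two_testable_exonic_snps_in_both": two_exonic_each,
            "has_replicated_ase_snp": replicated,
            "partial": partial,
        }
        for rep, members in per_rep_members.items():
            row[f"in_phase_{rep}"] = phase_concordance(members) if members else None
            row[f"n_testable_{rep}"] = len(members)
        rows.append(row)
    return pd.DataFrame(rows)


def _all_calls(calls_by_replicate: Mapping[str, Sequence[AseCall]]):
    for calls in calls_by_replicate.values():
        yield from calls


def compare_replicates(
    calls1: Sequence[AseCall],
    calls2: Sequence[AseCall],
    depth_thresholds: Sequence[int] = (10, 50, 100),
) -> list[ReplicateComparison]:
    """2×2 ASE classification contingency over sites testable in both
    replicates, per minimum-depth threshold, with reference-fraction
    correlation."""
    by_key1 = {c.site.key: c for c in calls1}
    by_key2 = {c.site.key: c for c in calls2}
    shared = sorted(set(by_key1) & set(by_key2))
    out = []
    for threshold in depth_thresholds:
        if threshold < 10:
            warnings.warn(
                f"depth threshold {threshold} is below the 10-read testability floor"
            )
        pairs = [
            (by_key1[k], by_key2[k])
            for k in shared
            if by_key1[k].depth >= threshold
            and by_key2[k].depth >= threshold
            and by_key1[k].classification != "untestable"
            and by_key2[k].classification != "untestable"
        ]
        both = sum(1 for a, b in pairs if a.is_ase and b.is_ase)
        only1 = sum(1 for a, b in pairs if a.is_ase and not b.is_ase)
        only2 = sum(1 for a, b in pairs if not a.is_ase and b.is_ase)
        neither = len(pairs) - both - only1 - only2
        if len(pairs) >= 2:
            rf1 = np.array([a.observed for a, _ in pairs])
            rf2 = np.array([b.observed for _, b in pairs])
            with np.errstate(invalid="ignore"):
                corr = float(np.corrcoef(rf1, rf2)[0, 1])
        else:
            corr = float("nan")
        out.append(
            ReplicateComparison(
                depth_threshold=threshold,
                n_testable_both=len(pairs),
                n_ase_both=both,
                n_ase_rep1_only=only1,
                n_ase_rep2_only=only2,
                n_not_ase_both=neither,
                reference_fraction_correlation=corr,
            )
        )
    return out


def map_snps_to_isoforms(
    calls: Sequence[AseCall],
    genes: Sequence[Gene],
) -> dict[str, dict]:
    """Assign testable SNPs to transcripts whose exons contain them.

    Transcripts with zero testable exonic SNPs are excluded. The summary per
    transcript reports member calls and the tally of imbalance directions,
    enabling isoform-discordance diagnosis (SNPs specific to different
    isoforms leaning toward different haplotypes).
    """
    out: dict[str, dict] = {}
    for gene in genes:
        for t in gene.transcripts:
            members = [
                c
                for c in calls
                if c.site.contig == gene.contig
                and c.classification != "untestable"
                and t.contains_exonic(c.site.position)
            ]
            if not members:
                continue
            out[t.transcript_id] = {
                "gene_id": gene.gene_id,
                "calls": members,
                "n_toward_hapA": sum(c.direction == "toward_hapA" for c in members),
                "n_toward_hapB": sum(c.direction == "toward_hapB" for c in members),
                "n_ase": sum(c.is_ase for c in members),
            }
    return out
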