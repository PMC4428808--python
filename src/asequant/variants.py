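"""Phased and un-phased small-variant records and VCF input/output.

A :class:`PhasedVariant` carries the haplotype assignment of a heterozygous
SNP (which allele sits on haplotype A vs B), its provenance (array genotyped,
imputed, or de novo called from WGS), the imputation quality R² when the
variant was imputed, and whether WGS verification confirmed the genotype.
Haplotype A/B labels are arbitrary; A is conventionally written "maternal"
and B "paternal" in alignment-set names.

VCF files are read and written through :mod:`pysam`. Heterozygous phased
genotypes are encoded ``a|b`` with the first allele on haplotype A;
un-phased records use ``/`` separators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pysam

_SOURCES = ("array", "imputed", "de_novo")


@dataclass
class PhasedVariant:
    """A small variant with optional haplotype assignment.

    ``position`` is 1-based. For heterozygous SNPs exactly one of
    ``hap_a_allele``/``hap_b_allele`` equals ``ref_allele``; for homozygous
    alternate sites both equal ``alt_allele``.
    """

    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    zygosity: str  # "het" or "hom_alt"
    hap_a_allele: Optional[str] = None
    hap_b_allele: Optional[str] = None
    r_squared: Optional[float] = None
    source: str = "imputed"
    wgs_verified: bool = False
    variant_class: str = "snp"  # "snp" or "indel"
    phased: bool = True

    def __post_init__(self) -> None:
        if self.zygosity not in ("het", "hom_alt"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.source not in _SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.variant_class == "snp" and (
            len(self.ref_allele) != 1 or len(self.alt_allele) != 1
        ):
            raise ValueError("SNP alleles must be single bases")
        if self.phased and self.zygosity == "het" and self.variant_class == "snp":
            alleles = {self.hap_a_allele, self.hap_b_allele}
            if alleles != {self.ref_allele, self.alt_allele}:
                raise ValueError(
                    f"het SNP at {self.contig}:{self.position} must place ref on "
                    "exactly one haplotype"
                )
        if self.zygosity == "hom_alt" and self.phased:
            self.hap_a_allele = self.alt_allele
            self.hap_b_allele = self.alt_allele

    @property
    def is_het(self) -> bool:
        return self.zygosity == "het"

    @property
    def ref_haplotype(self) -> Optional[str]:
        """'A' or 'B': the haplotype carrying the reference allele (het only)."""
        if not (self.phased and self.is_het):
            return None
        return "A" if self.hap_a_allele == self.ref_allele else "B"

    def affected_interval(self) -> tuple[int, int]:
        """1-based inclusive reference interval altered by this variant.

        For SNPs this is the single base. For VCF-anchored deletions it is the
        deleted bases (anchor excluded); for insertions, the two flanking
        anchor bases.
        """
        if self.variant_class == "snp":
            return (self.position, self.position)
        if len(self.ref_allele) > len(self.alt_allele):  # deletion
            return (self.position + 1, self.position + len(self.ref_allele) - 1)
        # insertion between anchor and next base
        return (self.position, self.position + 1)


@dataclass
class HetSite:
    """A phased heterozygous SNP eligible for ASE testing."""

    contig: str
    position: int  # 1-based
    ref: str
    alt: str
    ref_haplotype: str  # "A" or "B"
    genes: tuple[str, ...] = ()
    r_squared: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("het sites must be single-base SNPs")
        if self.ref_haplotype not in ("A", "B"):
            raise ValueError("ref_haplotype must be 'A' or 'B'")

    @property
    def key(self) -> tuple[str, int]:
        return (self.contig, self.position)


def _vcf_header(contigs: Mapping[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("R2", 1, "Float", "Imputation quality (estimated r-squared)")
    header.info.add("SRC", 1, "String", "Variant provenance: array, imputed or de_novo")
    header.info.add("WGSV", 0, "Flag", "Genotype verified against WGS data")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample("SAMPLE")
    return header


def write_vcf(
    path: str | Path,
    variants: Iterable[PhasedVariant],
    contigs: Mapping[str, int],
) -> None:
    """Write variants as VCF 4.2; het phase encoded in the GT separator."""
    header = _vcf_header(contigs)
    ordered = sorted(variants, key=lambda v: (v.contig, v.position))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in ordered:
            rec = out.new_record(
                contig=v.contig,
                start=v.position - 1,
                alleles=(v.ref_allele, v.alt_allele),
            )
            rec.info["SRC"] = v.source
            if v.r_squared is not None:
                rec.info["R2"] = float(v.r_squared)
            if v.wgs_verified:
                rec.info["WGSV"] = True
            if v.zygosity == "hom_alt":
                gt = (1, 1)
            elif v.phased:
                gt = (0, 1) if v.hap_a_allele == v.ref_allele else (1, 0)
            else:
                gt = (0, 1)
            rec.samples["SAMPLE"]["GT"] = gt
            rec.samples["SAMPLE"].phased = v.phased
            out.write(rec)


def read_vcf(path: str | Path) -> list[PhasedVariant]:
    """Read a VCF written by :func:`write_vcf` (or any single-sample VCF)."""
    out: list[PhasedVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample = list(vcf.header.samples)[0]
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                raise ValueError(
                    f"multi-allelic record at {rec.contig}:{rec.pos} not supported"
                )
            ref, alt = rec.ref, rec.alts[0]
            call = rec.samples[sample]
            gt = call["GT"]
            phased = bool(call.phased)
            if gt == (1, 1):
                zygosity = "hom_alt"
                hap_a = hap_b = alt
            else:
                zygosity = "het"
                alleles = [(ref, alt)[i] for i in gt]
                hap_a, hap_b = alleles if phased else (None, None)
            variant_class = "snp" if len(ref) == 1 and len(alt) == 1 else "indel"
            out.append(
                PhasedVariant(
                    contig=rec.contig,
                    position=rec.pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    zygosity=zygosity,
                    hap_a_allele=hap_a,
                    hap_b_allele=hap_b,
                    r_squared=(
                        float(rec.info["R2"]) if "R2" in rec.info else None
                    ),
                    source=rec.info.get("SRC", "imputed"),
                    wgs_verified=bool(rec.info.get("WGSV", False)),
                    variant_class=variant_class,
                    phased=phased,
                )
            )
    return out


def het_sites_from_variants(
    variants: Sequence[PhasedVariant],
    require_verified: bool = False,
) -> list[HetSite]:
    """Extract phased heterozygous SNPs as ASE-testable sites."""
    sites = []
    for v in variants:
        if v.variant_class != "snp" or not v.is_het or not v.phased:
            continue
        if require_verified and not v.wgs_verified:
            continue
        sites.append(
            HetSite(
                contig=v.contig,
                position=v.position,
                ref=v.ref_allele,
                alt=v.alt_allele,
                ref_haplotype=v.ref_haplotype,
                r_squared=v.r_squared,
            )
        )
    return sites
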