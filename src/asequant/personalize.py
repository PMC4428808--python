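"""Personalized per-haplotype reference construction.

Haplotype genomes are built by substituting phased SNP alleles into the
universal reference: heterozygous SNPs contribute their haplotype-specific
allele, homozygous-alternate SNPs are substituted into both haplotypes.
Only SNPs are accepted, so each haplotype contig stays coordinate-identical
to the universal reference — downstream alignment coordinates remain directly
comparable across the three alignment spaces.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from asequant.variants import PhasedVariant


class ReferenceMismatchError(ValueError):
    """A variant's stated reference allele disagrees with the reference base."""


@dataclass
class HaplotypeGenome:
    haplotype: str  # "A" or "B"
    sequences: dict[str, str]
    substitutions: int

    @property
    def label(self) -> str:
        """Conventional parental label: A=maternal, B=paternal (arbitrary)."""
        return "maternal" if self.haplotype == "A" else "paternal"


def build_haplotype_sequence(
    reference: Mapping[str, str],
    variants: Sequence[PhasedVariant],
    haplotype: str,
) -> HaplotypeGenome:
    """Substitute phased SNP alleles into the reference for one haplotype.

    Parameters
    ----------
    reference
        Contig name to uppercase sequence.
    variants
        Phased SNPs (het or hom_alt). Indels, multi-allelic or overlapping
        records are rejected.
    haplotype
        "A" or "B".
    """
    if haplotype not in ("A", "B"):
        raise ValueError("haplotype must be 'A' or 'B'")
    seqs = {name: bytearray(seq.upper(), "ascii") for name, seq in reference.items()}
    seen: set[tuple[str, int]] = set()
    n_sub = 0
    for v in variants:
        if v.variant_class != "snp":
            raise ValueError(
                f"indel at {v.contig}:{v.position} cannot enter haplotype "
                "construction; personalized genomes are SNP-only"
            )
        if not v.phased:
            raise ValueError(f"un-phased variant at {v.contig}:{v.position}")
        if v.contig not in seqs:
            raise KeyError(f"variant contig {v.contig!r} absent from reference")
        key = (v.contig, v.position)
        if key in seen:
            raise ValueError(f"overlapping variants at {v.contig}:{v.position}")
        seen.add(key)
        seq = seqs[v.contig]
        if not 1 <= v.position <= len(seq):
            raise IndexError(f"position {v.position} outside contig {v.contig}")
        ref_base = chr(seq[v.position - 1])
        if ref_base != v.ref_allele.upper():
            raise ReferenceMismatchError(
                f"{v.contig}:{v.position} reference has {ref_base}, "
                f"variant claims {v.ref_allele}"
            )
        allele = v.hap_a_allele if haplotype == "A" else v.hap_b_allele
        if allele is None:
            raise ValueError(f"variant at {v.contig}:{v.position} lacks haplotype alleles")
        if allele.upper() != ref_base:
            seq[v.position - 1] = ord(allele.upper())
            n_sub += 1
    return HaplotypeGenome(
        haplotype=haplotype,
        sequences={name: bytes(seq).decode("ascii") for name, seq in seqs.items()},
        substitutions=n_sub,
    )


def write_fasta(path: str | Path, sequences: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a contig→sequence dict (uppercased)."""
    import pyfaidx

    with pyfaidx.Fasta(str(path), rebuild=True, build_index=True) as fa:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}


def personalize(
    reference: Mapping[str, str],
    variants: Sequence[PhasedVariant],
) -> tuple[HaplotypeGenome, HaplotypeGenome]:
    """Build both haplotype genomes from WGS-verified phased SNPs."""
    usable = [v for v in variants if v.variant_class == "snp" and v.phased]
    hap_a = build_haplotype_sequence(reference, usable, "A")
    hap_b = build_haplotype_sequence(reference, usable, "B")
    return hap_a, hap_b
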