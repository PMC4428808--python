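"""Synthetic diploid data with known truth for every pipeline stage.

The generator emulates the data regime the pipeline consumes: a toy diploid
genome with phased heterozygous/homozygous-alternate SNPs, a withheld
un-phased SNP set, intronic/intergenic indels, stranded paired reads drawn
from the two haplotypes with configurable per-gene allelic ratios and
substitution sequencing error, and three pre-computed alignment sets
(maternal, paternal, universal) with exact edit distances.

Alignment emulation: reads are ungapped within exons, and a read is mapped
in a given alignment space iff its true mismatch count against that
reference does not exceed ``aligner_max_mismatches``. Because un-phased SNP
alleles are carried by reads but absent from every reference, and variant
alleles at phased SNPs are absent from the universal reference, this bounded
tolerance reproduces reference bias: variant-carrying reads near other
variation fail to map in universal space but map cleanly to their own
haplotype. Indels are planted only outside exons so haplotype references
stay coordinate-identical to the universal reference.

All randomness flows from a single integer seed; identical configurations
produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pysam

from asequant.genemodel import Gene, Transcript, write_gtf
from asequant.genotyping import PileupSummary
from asequant.counts import SiteCounts
from asequant.personalize import personalize, write_fasta
from asequant.variants import HetSite, PhasedVariant, write_vcf

BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SizingError(ValueError):
    """The configured genome cannot host the requested gene models."""


class PositionCollisionError(ValueError):
    """Requested variant density forces colliding variant positions."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic diploid experiment.

    Defaults describe a small but realistic regime: ~0.1% heterozygous SNP
    density, 100 bp paired reads, moderate per-SNP coverage and a low
    substitution error rate typical of short-read sequencers.
    """

    genome_length: int = 100_000
    n_contigs: int = 1
    n_genes: int = 8
    exons_per_gene: int = 3
    snp_rate: float = 0.002
    indel_count: int = 5
    het_fraction: float = 0.8
    read_length: int = 100
    fragment_depth: int = 30  # mean read pairs per exonic het SNP
    base_error_rate: float = 0.002
    allelic_ratio_map: dict[str, float] = field(default_factory=dict)
    unphased_fraction: float = 0.1
    seed: int = 1
    aligner_max_mismatches: int = 1
    mapq: int = 50

    # fixed toy geometry (bases)
    exon_length: int = 400
    intron_length: int = 300
    gene_gap: int = 500
    flank: int = 200
    fragment_length: int = 260

    def validate(self) -> None:
        for name in ("snp_rate", "het_fraction", "base_error_rate", "unphased_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for ratio in self.allelic_ratio_map.values():
            if not 0.0 <= ratio <= 1.0:
                raise ValueError("allelic ratios must be in [0, 1]")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.exon_length < self.read_length:
            raise SizingError("exons must be at least one read length long")


@dataclass
class TruthSet:
    """Ground truth for the planted variants and expression ratios."""

    reference: dict[str, str]
    genes: list[Gene]
    phased: list[PhasedVariant]
    unphased_snps: list[PhasedVariant]
    indels: list[PhasedVariant]
    hidden_ref_haplotype: dict[tuple[str, int], str]  # incl. un-phased het SNPs
    gene_ratio: dict[str, float]
    snp_ref_fraction: dict[tuple[str, int], float]

    @property
    def all_het_snps(self) -> list[PhasedVariant]:
        return [v for v in self.phased if v.is_het] + self.unphased_snps


@dataclass
class SimReads:
    """Simulated read pairs and their three alignment record sets."""

    read_names: list[str]
    fastq_r1: list[tuple[str, str]]  # (name, sequence)
    fastq_r2: list[tuple[str, str]]
    sam_sets: dict[str, list[pysam.AlignedSegment]]  # origin -> records
    true_haplotype: dict[str, str]  # read name -> "A" | "B"
    header: pysam.AlignmentHeader


# ---------------------------------------------------------------------------
# Reference and annotation
# ---------------------------------------------------------------------------


def _gene_span(config: SimConfig) -> int:
    return (
        config.exons_per_gene * config.exon_length
        + (config.exons_per_gene - 1) * config.intron_length
    )


def generate_toy_reference(config: SimConfig) -> tuple[dict[str, str], list[Gene]]:
    """Random contigs plus non-overlapping gene models with CDS/UTR structure.

    Each gene gets one full-length transcript (5'UTR, CDS, 3'UTR across its
    exons); genes with ≥ 3 exons get a second, exon-skipping isoform so
    isoform-level assignment is exercised.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    contig_len = config.genome_length // config.n_contigs
    reference = {
        f"chr{i + 1}": "".join(rng.choice(BASES, size=contig_len))
        for i in range(config.n_contigs)
    }
    genes: list[Gene] = []
    span = _gene_span(config)
    per_contig = -(-config.n_genes // config.n_contigs) if config.n_genes else 0
    needed = config.flank + per_contig * (span + config.gene_gap)
    if config.n_genes and needed > contig_len:
        raise SizingError(
            f"contigs of {contig_len} bp cannot host {per_contig} genes of "
            f"{span} bp each (need {needed} bp)"
        )
    for g in range(config.n_genes):
        contig = f"chr{g % config.n_contigs + 1}"
        slot = g // config.n_contigs
        start = config.flank + slot * (span + config.gene_gap) + 1  # 1-based
        gene_id = f"G{g + 1:02d}"
        exons = []
        pos = start
        for _ in range(config.exons_per_gene):
            exons.append((pos, pos + config.exon_length - 1))
            pos += config.exon_length + config.intron_length
        end = exons[-1][1]
        utr = min(100, config.exon_length // 4)
        t1 = _make_transcript(f"{gene_id}T1", gene_id, contig, exons, utr)
        transcripts = [t1]
        if config.exons_per_gene >= 3:
            skipped = exons[: len(exons) // 2] + exons[len(exons) // 2 + 1 :]
            transcripts.append(
                _make_transcript(f"{gene_id}T2", gene_id, contig, skipped, utr)
            )
        genes.append(
            Gene(
                gene_id=gene_id,
                contig=contig,
                start=start,
                end=end,
                strand="+",
                name=gene_id,
                transcripts=transcripts,
            )
        )
    return reference, genes


def _make_transcript(
    tid: str, gene_id: str, contig: str, exons: list[tuple[int, int]], utr: int
) -> Transcript:
    first_s, first_e = exons[0]
    last_s, last_e = exons[-1]
    utr5 = [(first_s, first_s + utr - 1)]
    utr3 = [(last_e - utr + 1, last_e)]
    cds = []
    for i, (s, e) in enumerate(exons):
        cs, ce = s, e
        if i == 0:
            cs = first_s + utr
        if i == len(exons) - 1:
            ce = last_e - utr
        if cs <= ce:
            cds.append((cs, ce))
    return Transcript(
        transcript_id=tid,
        gene_id=gene_id,
        contig=contig,
        strand="+",
        exons=list(exons),
        cds=cds,
        utr5=utr5,
        utr3=utr3,
    )


# ---------------------------------------------------------------------------
# Variant planting
# ---------------------------------------------------------------------------


def plant_phased_variants(
    reference: Mapping[str, str],
    genes: Sequence[Gene],
    config: SimConfig,
) -> TruthSet:
    """Plant SNPs and indels; withhold a fraction of het SNPs from phasing.

    Every het SNP gets a hidden haplotype assignment used for read
    simulation; withheld SNPs are emitted un-phased (they never enter the
    personalized references). Indels are un-phased and land only outside
    exons, keeping haplotype references coordinate-identical.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    exon_mask: dict[str, np.ndarray] = {
        contig: np.zeros(len(seq), dtype=bool) for contig, seq in reference.items()
    }
    gene_of_pos: dict[str, list[Gene]] = {}
    for g in genes:
        gene_of_pos.setdefault(g.contig, []).append(g)
        for t in g.transcripts:
            for s, e in t.exons:
                exon_mask[g.contig][s - 1 : e] = True

    phased: list[PhasedVariant] = []
    unphased_snps: list[PhasedVariant] = []
    hidden: dict[tuple[str, int], str] = {}
    taken: dict[str, set[int]] = {c: set() for c in reference}

    for contig, seq in reference.items():
        length = len(seq)
        n_snps = rng.binomial(length, config.snp_rate)
        if n_snps > length:
            raise PositionCollisionError("snp_rate too high for contig length")
        positions = np.sort(rng.choice(length, size=n_snps, replace=False)) + 1
        for pos in positions:
            ref_base = seq[pos - 1]
            alt_base = str(rng.choice(BASES[BASES != ref_base]))
            is_het = rng.random() < config.het_fraction
            if is_het:
                ref_hap = "A" if rng.random() < 0.5 else "B"
                hidden[(contig, int(pos))] = ref_hap
                withheld = rng.random() < config.unphased_fraction
                variant = PhasedVariant(
                    contig=contig,
                    position=int(pos),
                    ref_allele=ref_base,
                    alt_allele=alt_base,
                    zygosity="het",
                    hap_a_allele=ref_base if ref_hap == "A" else alt_base,
                    hap_b_allele=alt_base if ref_hap == "A" else ref_base,
                    r_squared=round(float(1.0 - rng.random() * 0.3), 3),
                    source="imputed",
                    phased=not withheld,
                )
                if withheld:
                    variant.phased = False
                    variant.source = "de_novo"
                    variant.hap_a_allele = variant.hap_b_allele = None
                    unphased_snps.append(variant)
                else:
                    phased.append(variant)
            else:
                phased.append(
                    PhasedVariant(
                        contig=contig,
                        position=int(pos),
                        ref_allele=ref_base,
                        alt_allele=alt_base,
                        zygosity="hom_alt",
                        r_squared=round(float(1.0 - rng.random() * 0.3), 3),
                        source="imputed",
                    )
                )
            taken[contig].add(int(pos))

    indels = _plant_indels(reference, exon_mask, taken, config, rng)

    gene_ratio = {
        g.gene_id: float(config.allelic_ratio_map.get(g.gene_id, 0.5)) for g in genes
    }
    snp_rf: dict[tuple[str, int], float] = {}
    for (contig, pos), ref_hap in hidden.items():
        ratio = 0.5
        for g in gene_of_pos.get(contig, ()):
            if g.contains(pos):
                ratio = gene_ratio[g.gene_id]
                break
        snp_rf[(contig, pos)] = ratio if ref_hap == "A" else 1.0 - ratio
    return TruthSet(
        reference=dict(reference),
        genes=list(genes),
        phased=phased,
        unphased_snps=unphased_snps,
        indels=indels,
        hidden_ref_haplotype=hidden,
        gene_ratio=gene_ratio,
        snp_ref_fraction=snp_rf,
    )


def _plant_indels(reference, exon_mask, taken, config: SimConfig, rng) -> list[PhasedVariant]:
    indels: list[PhasedVariant] = []
    contigs = list(reference)
    attempts = 0
    while len(indels) < config.indel_count:
        attempts += 1
        if attempts > 200 * max(1, config.indel_count):
            raise PositionCollisionError(
                "could not place the requested indels outside exons without collisions"
            )
        contig = contigs[int(rng.integers(len(contigs)))]
        seq = reference[contig]
        length = int(rng.integers(1, 6))
        pos = int(rng.integers(1, len(seq) - length - 1))
        interval = range(pos, pos + length + 1)
        if any(exon_mask[contig][p - 1] for p in interval):
            continue
        if any(p in taken[contig] for p in interval):
            continue
        if rng.random() < 0.5:  # deletion
            ref_allele = seq[pos - 1 : pos + length]
            alt_allele = seq[pos - 1]
        else:  # insertion
            ref_allele = seq[pos - 1]
            alt_allele = seq[pos - 1] + "".join(rng.choice(BASES, size=length))
        for p in interval:
            taken[contig].add(p)
        indels.append(
            PhasedVariant(
                contig=contig,
                position=pos,
                ref_allele=ref_allele,
                alt_allele=alt_allele,
                zygosity="het",
                source="de_novo",
                variant_class="indel",
                phased=False,
            )
        )
    indels.sort(key=lambda v: (v.contig, v.position))
    return indels


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _truth_haplotype_sequences(truth: TruthSet) -> dict[str, dict[str, str]]:
    """Per-haplotype transcribed sequence including un-phased SNP alleles."""
    seqs = {"A": {}, "B": {}}
    for contig, seq in truth.reference.items():
        a, b = bytearray(seq, "ascii"), bytearray(seq, "ascii")
        for v in truth.phased:
            if v.contig != contig or v.variant_class != "snp":
                continue
            a[v.position - 1] = ord(v.hap_a_allele)
            b[v.position - 1] = ord(v.hap_b_allele)
        for v in truth.unphased_snps:
            if v.contig != contig:
                continue
            ref_hap = truth.hidden_ref_haplotype[(contig, v.position)]
            if ref_hap == "A":
                b[v.position - 1] = ord(v.alt_allele)
            else:
                a[v.position - 1] = ord(v.alt_allele)
        seqs["A"][contig] = bytes(a).decode()
        seqs["B"][contig] = bytes(b).decode()
    return seqs


def _alignment_references(truth: TruthSet) -> dict[str, dict[str, str]]:
    """The three alignment spaces: phased-SNP haplotypes plus universal."""
    hap_a, hap_b = personalize(truth.reference, truth.phased)
    return {
        "maternal": hap_a.sequences,
        "paternal": hap_b.sequences,
        "universal": dict(truth.reference),
    }


def _mismatches(read: str, ref: str, start0: int) -> int:
    segment = ref[start0 : start0 + len(read)]
    return sum(1 for a, b in zip(read, segment) if a != b)


def simulate_allelic_reads(truth: TruthSet, config: SimConfig) -> SimReads:
    """Draw read pairs over exonic het SNPs and build the alignment triples.

    Each pair is drawn from haplotype A with probability equal to its gene's
    allelic ratio; ``fragment_depth`` pairs target each exonic het SNP (R1
    covers the SNP; R2 sits downstream in the same exon on the reverse
    strand). NM tags carry true mismatch counts against each alignment
    space, and a mate is mapped in a space iff that count is within the
    aligner tolerance.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    hap_seqs = _truth_haplotype_sequences(truth)
    align_refs = _alignment_references(truth)
    header = pysam.AlignmentHeader.from_references(
        list(truth.reference), [len(s) for s in truth.reference.values()]
    )
    rl = config.read_length
    reads = SimReads(
        read_names=[],
        fastq_r1=[],
        fastq_r2=[],
        sam_sets={o: [] for o in align_refs},
        true_haplotype={},
        header=header,
    )
    serial = 0
    for gene in truth.genes:
        ratio = truth.gene_ratio[gene.gene_id]
        exons = sorted({iv for t in gene.transcripts for iv in t.exons})
        targets = [
            (v.contig, v.position, next((s, e) for s, e in exons if s <= v.position <= e))
            for v in truth.all_het_snps
            if v.contig == gene.contig
            and any(s <= v.position <= e for s, e in exons)
        ]
        for contig, snp_pos, (ex_s, ex_e) in sorted(targets, key=lambda t: t[1]):
            for _ in range(config.fragment_depth):
                hap = "A" if rng.random() < ratio else "B"
                lo = max(ex_s, snp_pos - rl + 1)
                hi = min(snp_pos, ex_e - rl + 1)
                if hi < lo:
                    continue  # exon too short to place a covering read
                r1_start = int(rng.integers(lo, hi + 1))  # 1-based
                # jitter the fragment length so mate coordinates vary and
                # exact-coordinate duplicate marking only removes true clones
                flen = int(rng.integers(config.fragment_length - 60, config.fragment_length + 61))
                r2_start = min(r1_start + flen - rl, ex_e - rl + 1)
                r2_start = max(r2_start, ex_s)
                serial += 1
                name = f"r{serial:06d}_{gene.gene_id}_{snp_pos}_{hap}"
                pair = []
                for start, is_r2 in ((r1_start, False), (r2_start, True)):
                    seq = hap_seqs[hap][contig][start - 1 : start - 1 + rl]
                    seq = _apply_errors(seq, rng, config.base_error_rate)
                    pair.append((start, seq, is_r2))
                _emit_pair(reads, config, align_refs, contig, name, pair)
                reads.read_names.append(name)
                reads.true_haplotype[name] = hap
                (s1, q1, _), (s2, q2, _) = pair
                reads.fastq_r1.append((name, q1))
                reads.fastq_r2.append((name, _revcomp(q2)))
    return reads


def _apply_errors(seq: str, rng, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        arr[i] = str(rng.choice(BASES[BASES != arr[i]]))
    return "".join(arr)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _emit_pair(reads: SimReads, config: SimConfig, align_refs, contig, name, pair) -> None:
    rl = config.read_length
    for origin, ref_seqs in align_refs.items():
        ref = ref_seqs[contig]
        mapped_flags = []
        nms = []
        for start, seq, _ in pair:
            nm = _mismatches(seq, ref, start - 1)
            nms.append(nm)
            mapped_flags.append(nm <= config.aligner_max_mismatches)
        recs = []
        for idx, (start, seq, is_r2) in enumerate(pair):
            other = 1 - idx
            rec = pysam.AlignedSegment(header=reads.header)
            rec.query_name = name
            rec.query_sequence = seq
            rec.query_qualities = pysam.qualitystring_to_array("I" * rl)
            rec.is_paired = True
            rec.is_read2 = is_r2
            rec.is_read1 = not is_r2
            rec.reference_name = contig
            rec.reference_start = start - 1
            rec.is_reverse = is_r2
            rec.mate_is_reverse = not is_r2
            if mapped_flags[idx]:
                rec.cigarstring = f"{rl}M"
                rec.mapping_quality = config.mapq
                rec.set_tag("NM", nms[idx])
                rec.set_tag("MD", _md_tag(seq, ref, start - 1))
            else:
                rec.is_unmapped = True
                rec.mapping_quality = 0
            if mapped_flags[other]:
                rec.next_reference_name = contig
                rec.next_reference_start = pair[other][0] - 1
            else:
                rec.mate_is_unmapped = True
                rec.next_reference_name = contig
                rec.next_reference_start = start - 1
            rec.is_proper_pair = all(mapped_flags)
            recs.append(rec)
        reads.sam_sets[origin].extend(recs)


def _md_tag(seq: str, ref: str, start0: int) -> str:
    out = []
    run = 0
    for i, base in enumerate(seq):
        if ref[start0 + i] == base:
            run += 1
        else:
            out.append(str(run))
            out.append(ref[start0 + i])
            run = 0
    out.append(str(run))
    return "".join(out)


# ---------------------------------------------------------------------------
# Direct count draws
# ---------------------------------------------------------------------------


def simulate_site_counts(
    true_rf: float,
    depth: int,
    n_sites: int,
    seed: int,
    library: str = "lib1",
    replicate: str = "rep1",
) -> list[SiteCounts]:
    """Binomial reference-count draws at synthetic het sites.

    Bypasses read simulation for sampling-behaviour studies: each site's
    reference count is Binomial(depth, true_rf) with the reference allele on
    haplotype A.
    """
    if not 0.0 <= true_rf <= 1.0:
        raise ValueError("true_rf must be in [0, 1]")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    ref_counts = rng.binomial(depth, true_rf, size=n_sites)
    out = []
    for i, ref_n in enumerate(ref_counts):
        site = HetSite(
            contig="sim",
            position=i + 1,
            ref="A",
            alt="G",
            ref_haplotype="A",
        )
        out.append(
            SiteCounts(
                site=site,
                ref_count=int(ref_n),
                alt_count=depth - int(ref_n),
                library=library,
                replicate=replicate,
            )
        )
    return out


def simulate_wgs_pileups(
    truth: TruthSet, mean_depth: int = 30, seed: int = 0
) -> dict[tuple[str, int], PileupSummary]:
    """Synthetic WGS base counts at all planted SNPs (het ≈ 50/50, hom alt)."""
    rng = np.random.default_rng(seed)
    out: dict[tuple[str, int], PileupSummary] = {}
    for v in truth.phased + truth.unphased_snps:
        if v.variant_class != "snp":
            continue
        depth = max(1, int(rng.poisson(mean_depth)))
        summary = PileupSummary(v.contig, v.position, v.ref_allele)
        if v.is_het:
            ref_n = int(rng.binomial(depth, 0.5))
        else:
            ref_n = 0
        summary.counts[v.ref_allele] += ref_n
        summary.counts[v.alt_allele] += depth - ref_n
        out[(v.contig, v.position)] = summary
    return out


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------


def write_sam(path: str | Path, records: Sequence[pysam.AlignedSegment], header) -> None:
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in records:
            out.write(rec)


def _write_fastq(path: Path, entries: Sequence[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_pileups_tsv(path: Path, pileups: Mapping[tuple[str, int], PileupSummary]) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tpos\tref\tA\tC\tG\tT\n")
        for (contig, pos), s in sorted(pileups.items()):
            fh.write(
                f"{contig}\t{pos}\t{s.ref_base}\t"
                f"{s.counts['A']}\t{s.counts['C']}\t{s.counts['G']}\t{s.counts['T']}\n"
            )


def read_pileups_tsv(path: str | Path) -> dict[tuple[str, int], PileupSummary]:
    out: dict[tuple[str, int], PileupSummary] = {}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        contig, pos, ref, a, c, g, t = line.split("\t")
        summary = PileupSummary(contig, int(pos), ref)
        summary.counts.update({"A": int(a), "C": int(c), "G": int(g), "T": int(t)})
        out[(contig, int(pos))] = summary
    return out


def simulate_fixture(config: SimConfig, out_dir: str | Path) -> TruthSet:
    """Generate and write the complete fixture set for one library.

    Writes reference FASTA, GTF annotation, phased and un-phased VCFs,
    a WGS pileup table, paired FASTQ, the three SAM alignment sets, a
    full-coverage alignability BED and a truth JSON under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reference, genes = generate_toy_reference(config)
    truth = plant_phased_variants(reference, genes, config)
    reads = simulate_allelic_reads(truth, config)
    contig_lengths = {c: len(s) for c, s in reference.items()}

    write_fasta(out_dir / "reference.fa", reference)
    write_gtf(out_dir / "annotation.gtf", genes)
    write_vcf(out_dir / "phased.vcf", truth.phased, contig_lengths)
    write_vcf(
        out_dir / "unphased.vcf", truth.unphased_snps + truth.indels, contig_lengths
    )
    pileups = simulate_wgs_pileups(truth, seed=config.seed + 3)
    write_pileups_tsv(out_dir / "wgs_pileups.tsv", pileups)
    _write_fastq(out_dir / "reads_R1.fastq", reads.fastq_r1)
    _write_fastq(out_dir / "reads_R2.fastq", reads.fastq_r2)
    for origin, records in reads.sam_sets.items():
        write_sam(out_dir / f"aln_{origin}.sam", records, reads.header)
    with open(out_dir / "alignability.bed", "w") as fh:
        for contig, length in contig_lengths.items():
            fh.write(f"{contig}\t0\t{length}\t1.0\n")
    truth_json = {
        "gene_ratio": truth.gene_ratio,
        "snp_ref_fraction": {
            f"{c}:{p}": rf for (c, p), rf in sorted(truth.snp_ref_fraction.items())
        },
        "hidden_ref_haplotype": {
            f"{c}:{p}": h for (c, p), h in sorted(truth.hidden_ref_haplotype.items())
        },
        "n_phased": len(truth.phased),
        "n_unphased_snps": len(truth.unphased_snps),
        "n_indels": len(truth.indels),
    }
    (out_dir / "truth.json").write_text(json.dumps(truth_json, indent=2))
    return truth
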