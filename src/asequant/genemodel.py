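"""Gene and transcript models with GTF (Ensembl dialect) input/output.

Coordinates are 1-based inclusive throughout, matching GTF. A gene's span is
its annotated genomic boundary (used for genic SNP grouping and RPKM); exon,
CDS and UTR intervals live on transcripts and drive transcript-feature
annotation and SNP-to-isoform assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

Interval = tuple[int, int]


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    @property
    def span(self) -> Interval:
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))

    def contains_exonic(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.exons)


@dataclass
class Gene:
    gene_id: str
    contig: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


def _attrs(**kv: str) -> str:
    return " ".join(f'{k} "{v}";' for k, v in kv.items())


def write_gtf(path: str | Path, genes: Sequence[Gene], source: str = "asequant") -> None:
    """Write gene models as Ensembl-style GTF (gene/transcript/exon/CDS/UTR rows)."""
    lines: list[str] = []

    def row(contig: str, feature: str, start: int, end: int, strand: str, attrs: str) -> None:
        lines.append(
            "\t".join(
                [contig, source, feature, str(start), str(end), ".", strand, ".", attrs]
            )
        )

    for g in sorted(genes, key=lambda g: (g.contig, g.start)):
        gattrs = _attrs(gene_id=g.gene_id, gene_name=g.name or g.gene_id)
        row(g.contig, "gene", g.start, g.end, g.strand, gattrs)
        for t in g.transcripts:
            tattrs = _attrs(
                gene_id=g.gene_id,
                transcript_id=t.transcript_id,
                gene_name=g.name or g.gene_id,
            )
            s, e = t.span
            row(g.contig, "transcript", s, e, t.strand, tattrs)
            for s, e in sorted(t.exons):
                row(g.contig, "exon", s, e, t.strand, tattrs)
            for s, e in sorted(t.cds):
                row(g.contig, "CDS", s, e, t.strand, tattrs)
            for s, e in sorted(t.utr5):
                row(g.contig, "five_prime_utr", s, e, t.strand, tattrs)
            for s, e in sorted(t.utr3):
                row(g.contig, "three_prime_utr", s, e, t.strand, tattrs)
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str | Path) -> list[Gene]:
    """Parse an Ensembl-dialect GTF into :class:`Gene` objects.

    Gene rows are optional: gene spans default to the union of transcript
    exons when absent. UTR rows may be spelled ``five_prime_utr``/``UTR``.
    """
    genes: dict[str, Gene] = {}
    transcripts: dict[str, Transcript] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"malformed GTF row: {line[:80]!r}")
        contig, _, feature, start_s, end_s, _, strand, _, attr_text = fields
        start, end = int(start_s), int(end_s)
        attrs = _parse_attributes(attr_text)
        gene_id = attrs.get("gene_id", "")
        if feature == "gene":
            genes[gene_id] = Gene(
                gene_id=gene_id,
                contig=contig,
                start=start,
                end=end,
                strand=strand,
                name=attrs.get("gene_name", gene_id),
            )
            continue
        tid = attrs.get("transcript_id")
        if tid is None:
            continue
        if tid not in transcripts:
            transcripts[tid] = Transcript(
                transcript_id=tid, gene_id=gene_id, contig=contig, strand=strand
            )
        t = transcripts[tid]
        if feature == "exon":
            t.exons.append((start, end))
        elif feature == "CDS":
            t.cds.append((start, end))
        elif feature in ("five_prime_utr", "5UTR"):
            t.utr5.append((start, end))
        elif feature in ("three_prime_utr", "3UTR"):
            t.utr3.append((start, end))
    for t in transcripts.values():
        if t.gene_id not in genes:
            s, e = t.span
            genes[t.gene_id] = Gene(
                gene_id=t.gene_id, contig=t.contig, start=s, end=e, strand=t.strand
            )
        g = genes[t.gene_id]
        g.transcripts.append(t)
        s, e = t.span
        g.start, g.end = min(g.start, s), max(g.end, e)
    return sorted(genes.values(), key=lambda g: (g.contig, g.start))
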