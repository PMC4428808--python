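"""End-to-end orchestration of the recommended ASE workflow.

Stages run in order: personalize → merge → filter → verify → count →
classify → qc → gene-ase. Every stage writes its table under the output
directory, a manifest records every threshold that affects results, and the
log keeps per-stage record tallies. A stage failure aborts the run with the
failing stage named; outputs of completed stages are retained.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from asequant import ase, counts as counts_mod, locus, merge as merge_mod, qc as qc_mod
from asequant.genemodel import read_gtf
from asequant.personalize import personalize, read_fasta, write_fasta
from asequant.genotyping import verify_imputed_genotypes
from asequant.simulate import read_pileups_tsv
from asequant.variants import het_sites_from_variants, read_vcf

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Input paths and thresholds for one library run."""

    reference: str = ""
    phased_vcf: str = ""
    unphased_vcf: str = ""
    wgs_pileups: str = ""
    maternal_bam: str = ""
    paternal_bam: str = ""
    universal_bam: str = ""
    gtf: str = ""
    alignability_bed: str = ""
    out_dir: str = "asequant_out"
    library: str = "lib1"
    replicate: str = "rep1"

    min_depth: int = 10
    delta_threshold: float = 0.15
    alpha: float = 0.05
    proximity_window: int = 100
    max_proximal_snps: int = 3
    min_mapq: int = 9
    mito_name: str = "chrM"
    min_wgs_depth: int = 8
    two_sided_method: str = "minlike"
    fdr_column: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for name in ("min_depth", "proximity_window", "min_mapq"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "reference",
            "phased_vcf",
            "maternal_bam",
            "paternal_bam",
            "universal_bam",
        ):
            path = getattr(self, name)
            if not path or not Path(path).exists():
                raise FileNotFoundError(f"{name} path {path!r} does not exist")


@dataclass
class PipelineResult:
    out_dir: Path
    tallies: dict = field(default_factory=dict)
    calls: list = field(default_factory=list)
    qc_pass_calls: list = field(default_factory=list)
    gene_results: list = field(default_factory=list)
    rpkm: dict = field(default_factory=dict)


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - surfaced with stage name
                raise PipelineError(name, str(exc)) from exc

        return run

    return wrap


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow for one library and write all outputs."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(out_dir=out_dir)
    log_lines: list[str] = []

    def log(stage: str, message: str) -> None:
        line = f"[{stage}] {message}"
        logger.info(line)
        log_lines.append(line)

    # --- personalize -----------------------------------------------------
    @_stage("personalize")
    def stage_personalize():
        reference = read_fasta(config.reference)
        variants = read_vcf(config.phased_vcf)
        snps = [v for v in variants if v.variant_class == "snp" and v.phased]
        hap_a, hap_b = personalize(reference, snps)
        write_fasta(out_dir / "reference_hapA.fa", hap_a.sequences)
        write_fasta(out_dir / "reference_hapB.fa", hap_b.sequences)
        log(
            "personalize",
            f"substituted {hap_a.substitutions} (hapA) / "
            f"{hap_b.substitutions} (hapB) SNP alleles",
        )
        return reference, variants

    reference, phased_variants = stage_personalize()

    # --- merge ------------------------------------------------------------
    @_stage("merge")
    def stage_merge():
        streams = {
            name: merge_mod.read_name_grouped(path)
            for name, path in (
                ("maternal", config.maternal_bam),
                ("paternal", config.paternal_bam),
                ("universal", config.universal_bam),
            )
        }
        merged = merge_mod.merge_alignment_sets(
            streams["maternal"], streams["paternal"], streams["universal"]
        )
        merge_mod.write_merged(merged, config.universal_bam, out_dir / "merged.sam")
        origins = {}
        for _, decision, _cand in merged:
            origins[decision.chosen] = origins.get(decision.chosen, 0) + 1
        log("merge", f"resolved {len(merged)} read pairs; origins {origins}")
        return merged

    merged = stage_merge()

    # --- filter -----------------------------------------------------------
    @_stage("filter")
    def stage_filter():
        kept, tally = merge_mod.filter_alignments(
            merged,
            min_mapq=config.min_mapq,
            mito_names=(config.mito_name,),
            known_contigs=list(read_fasta(config.reference)),
        )
        result.tallies["filter"] = tally
        log("filter", f"tally {tally}")
        records = [r for _, _, cand in kept for r in cand.records if not r.is_unmapped]
        return kept, records

    kept_pairs, filtered_records = stage_filter()

    # --- verify -----------------------------------------------------------
    @_stage("verify")
    def stage_verify():
        het = [v for v in phased_variants if v.is_het and v.variant_class == "snp"]
        if config.wgs_pileups and Path(config.wgs_pileups).exists():
            pileups = read_pileups_tsv(config.wgs_pileups)
            partition = verify_imputed_genotypes(het, pileups, config.min_wgs_depth)
            log(
                "verify",
                "verified=%d failed=%d untestable=%d"
                % tuple(len(partition[k]) for k in ("verified", "failed", "untestable")),
            )
            return partition["verified"]
        log("verify", "no WGS pileups supplied; all phased het SNPs pass unverified")
        return het

    verified_het = stage_verify()
    sites = het_sites_from_variants(verified_het)

    # --- count ------------------------------------------------------------
    @_stage("count")
    def stage_count():
        site_counts = counts_mod.pileup_counts(
            filtered_records, sites, library=config.library, replicate=config.replicate
        )
        frame = counts_mod.counts_to_frame(site_counts, config.min_depth)
        frame.to_csv(out_dir / "counts.tsv", sep="\t", index=False)
        rpkm = {}
        if config.gtf and Path(config.gtf).exists():
            genes = read_gtf(config.gtf)
            rpkm = counts_mod.compute_rpkm(filtered_records, genes)
            with open(out_dir / "rpkm.tsv", "w") as fh:
                fh.write("gene_id\trpkm\n")
                for gid, value in rpkm.items():
                    fh.write(f"{gid}\t{value:.4f}\n")
        n_testable = sum(c.testable(config.min_depth) for c in site_counts)
        log("count", f"{len(site_counts)} sites, {n_testable} testable")
        return site_counts, rpkm

    site_counts, result.rpkm = stage_count()

    # --- classify ---------------------------------------------------------
    @_stage("classify")
    def stage_classify():
        medians = ase.compute_bin_medians(site_counts, config.min_depth)
        calls = ase.classify_all(
            site_counts,
            medians,
            delta_threshold=config.delta_threshold,
            alpha=config.alpha,
            min_depth=config.min_depth,
            method=config.two_sided_method,
        )
        frame = ase.calls_to_frame(calls)
        if config.fdr_column:
            frame = ase.add_bh_fdr(frame)
        frame.to_csv(out_dir / "calls.tsv", sep="\t", index=False)
        n_ase = sum(c.is_ase for c in calls)
        log("classify", f"{n_ase} ASE of {len(calls)} sites")
        return calls

    result.calls = stage_classify()

    # --- qc ---------------------------------------------------------------
    @_stage("qc")
    def stage_qc():
        unphased = (
            read_vcf(config.unphased_vcf)
            if config.unphased_vcf and Path(config.unphased_vcf).exists()
            else []
        )
        track = (
            qc_mod.AlignabilityTrack.from_bed(config.alignability_bed)
            if config.alignability_bed and Path(config.alignability_bed).exists()
            else None
        )
        genes = read_gtf(config.gtf) if config.gtf and Path(config.gtf).exists() else []
        anns = qc_mod.annotate_all(
            [c.site for c in result.calls],
            unphased,
            alignability=track,
            genes=genes,
            window=config.proximity_window,
        )
        verdicts = qc_mod.apply_filters(
            anns,
            window=config.proximity_window,
            max_proximal_snps=config.max_proximal_snps,
        )
        import pandas as pd

        qc_frame = pd.DataFrame(
            {
                "contig": [a.site.contig for a in anns],
                "pos": [a.site.position for a in anns],
                "indel_distance": [a.indel_distance for a in anns],
                "snp_distance": [a.snp_distance for a in anns],
                "proximal_snp_count": [a.proximal_snp_count for a in anns],
                "alignability": [a.alignability for a in anns],
                "feature": [a.feature for a in anns],
                "pass": [v.passed for v in verdicts],
                "reasons": [";".join(v.reasons) for v in verdicts],
            }
        )
        qc_frame.to_csv(out_dir / "qc.tsv", sep="\t", index=False)
        removed: dict[str, int] = {}
        for v in verdicts:
            for reason in v.reasons:
                removed[reason] = removed.get(reason, 0) + 1
        result.tallies["qc"] = removed
        passing = [
            call
            for call, verdict in zip(result.calls, verdicts)
            if verdict.passed and call.classification != "untestable"
        ]
        n_removed = sum(1 for v in verdicts if not v.passed)
        log("qc", f"removed {n_removed} sites ({removed}); {len(passing)} retained")
        return passing

    result.qc_pass_calls = stage_qc()

    # --- gene-ase ---------------------------------------------------------
    @_stage("gene-ase")
    def stage_gene_ase():
        if not config.gtf or not Path(config.gtf).exists():
            raise FileNotFoundError(
                f"gene-level aggregation requires the GTF annotation; {config.gtf!r} missing"
            )
        genes = read_gtf(config.gtf)
        gene_results = locus.aggregate_gene_ase(
            result.qc_pass_calls, genes, min_depth=config.min_depth,
            replicate=config.replicate,
        )
        with open(out_dir / "genes.tsv", "w") as fh:
            fh.write(
                "rank\tgene_id\thapA\thapB\thapA_fraction\tpvalue\t"
                "n_testable_snps\tphase_concordant\n"
            )
            for r in gene_results:
                fh.write(
                    f"{r.rank}\t{r.gene_id}\t{r.hap_a_sum}\t{r.hap_b_sum}\t"
                    f"{r.hap_a_fraction:.6g}\t{r.p_value:.6g}\t"
                    f"{r.n_testable_snps}\t{r.phase_concordant}\n"
                )
        log("gene-ase", f"{len(gene_results)} genes aggregated")
        return gene_results

    result.gene_results = stage_gene_ase()

    manifest = {
        "parameters": {
            k: v
            for k, v in asdict(config).items()
            if k
            in (
                "min_depth",
                "delta_threshold",
                "alpha",
                "proximity_window",
                "max_proximal_snps",
                "min_mapq",
                "mito_name",
                "min_wgs_depth",
                "two_sided_method",
                "library",
                "replicate",
            )
        },
        "tallies": result.tallies,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return result


def config_for_fixture(fixture_dir: str | Path, out_dir: str | Path, **overrides) -> PipelineConfig:
    """PipelineConfig wired to a directory written by
    :func:`asequant.simulate.simulate_fixture`."""
    fixture_dir = Path(fixture_dir)
    cfg = PipelineConfig(
        reference=str(fixture_dir / "reference.fa"),
        phased_vcf=str(fixture_dir / "phased.vcf"),
        unphased_vcf=str(fixture_dir / "unphased.vcf"),
        wgs_pileups=str(fixture_dir / "wgs_pileups.tsv"),
        maternal_bam=str(fixture_dir / "aln_maternal.sam"),
        paternal_bam=str(fixture_dir / "aln_paternal.sam"),
        universal_bam=str(fixture_dir / "aln_universal.sam"),
        gtf=str(fixture_dir / "annotation.gtf"),
        alignability_bed=str(fixture_dir / "alignability.bed"),
        out_dir=str(out_dir),
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg
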