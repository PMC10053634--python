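"""End-to-end driver: count reads, call the genotype, profile each allele.

``run_sample`` is the in-memory pipeline for one sample; ``run_pipeline``
wraps it with file IO, per-sample error isolation and stage logging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .consensus import (
    ConsensusTract,
    InterruptionCall,
    PurityReport,
    build_consensus,
    detect_interruptions,
    purity_metrics,
    select_window_reads,
)
from .design import AmpliconDesign
from .genotype import CallerParams, GenotypeCall, call_genotype
from .io import read_fastq, write_calls_tsv, write_consensus_fasta, write_genotypes_tsv
from .repeatcall import AnchorParams, RepeatCall, collect_distribution, count_repeats
from .simulate import ReadRecord

log = logging.getLogger("gaatract")


@dataclass
class PipelineConfig:
    design: AmpliconDesign
    fastq_by_sample: dict[str, str | Path]
    anchor: AnchorParams = field(default_factory=AnchorParams)
    caller: CallerParams = field(default_factory=CallerParams)
    window: int = 20
    interruption_tolerance: int = 5
    out_dir: str | Path | None = None


@dataclass
class AlleleProfile:
    allele: int
    allele_count: int
    tracts: dict[str, ConsensusTract | None]  # strand -> consensus (None if absent)
    purity: dict[str, PurityReport]  # strand -> purity of that consensus
    interruptions: list[InterruptionCall]  # cross-strand validated + candidates


@dataclass
class SampleReport:
    sample_id: str
    n_reads_total: int
    n_reads_passing: int
    genotype: GenotypeCall | None
    profiles: list[AlleleProfile] = field(default_factory=list)
    error: str | None = None

    @property
    def validated_interruptions(self) -> list[tuple[int, InterruptionCall]]:
        return [
            (p.allele, itr)
            for p in self.profiles
            for itr in p.interruptions
            if itr.validated
        ]


def run_sample(
    sample_id: str,
    reads: list[ReadRecord],
    design: AmpliconDesign,
    anchor: AnchorParams = AnchorParams(),
    caller: CallerParams = CallerParams(),
    window: int = 20,
    interruption_tolerance: int = 5,
) -> tuple[SampleReport, list[RepeatCall]]:
    """Count, genotype and profile one sample's reads in memory."""
    by_id = {r.id: r for r in reads}
    calls = [count_repeats(r.id, r.sequence, design, anchor) for r in reads]
    dist = collect_distribution(calls, sample_id)
    log.info(
        "%s: %d reads, %d passing anchors", sample_id, len(reads), dist.size
    )
    genotype = call_genotype(dist, caller)
    log.info(
        "%s: genotype %d/%d (%s)",
        sample_id,
        genotype.allele1_count,
        genotype.allele2_count,
        genotype.zygosity,
    )

    alleles = [(1, genotype.allele1_count)]
    if genotype.zygosity == "biallelic":
        alleles.append((2, genotype.allele2_count))

    profiles = []
    for allele, count in alleles:
        by_strand = select_window_reads(calls, count, window)
        tracts: dict[str, ConsensusTract | None] = {}
        purity: dict[str, PurityReport] = {}
        for strand in ("+", "-"):
            pairs = [(c, by_id[c.read_id]) for c in by_strand[strand]]
            tract = build_consensus(pairs, design, strand, count, sample_id, allele)
            tracts[strand] = tract
            if tract is not None and tract.consensus_sequence:
                purity[strand] = purity_metrics(tract, design)
        interruptions = detect_interruptions(
            tracts["+"], tracts["-"], design, interruption_tolerance
        )
        profiles.append(AlleleProfile(allele, count, tracts, purity, interruptions))
        log.info(
            "%s allele %d: +%d/-%d window reads, %d validated interruption(s)",
            sample_id,
            allele,
            len(by_strand["+"]),
            len(by_strand["-"]),
            sum(i.validated for i in interruptions),
        )

    report = SampleReport(
        sample_id=sample_id,
        n_reads_total=len(reads),
        n_reads_passing=dist.size,
        genotype=genotype,
        profiles=profiles,
    )
    return report, calls


def run_pipeline(config: PipelineConfig) -> list[SampleReport]:
    """Run the full pipeline over every configured sample.

    All referenced files must exist before any stage runs; a failure inside
    one sample is recorded on its report and does not abort the others.
    """
    missing = [str(p) for p in config.fastq_by_sample.values() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input FASTQ file(s): {', '.join(missing)}")

    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    reports = []
    for sample_id, fastq in config.fastq_by_sample.items():
        try:
            reads = read_fastq(fastq)
            report, calls = run_sample(
                sample_id,
                reads,
                config.design,
                config.anchor,
                config.caller,
                config.window,
                config.interruption_tolerance,
            )
        except Exception as exc:  # noqa: BLE001 - per-sample isolation
            log.error("%s: pipeline failed: %s", sample_id, exc)
            reports.append(SampleReport(sample_id, 0, 0, None, error=str(exc)))
            continue
        reports.append(report)
        if out_dir:
            write_calls_tsv(calls, out_dir / f"{sample_id}.calls.tsv")
            write_genotypes_tsv([report.genotype], out_dir / f"{sample_id}.genotype.tsv")
            tracts = [
                t for p in report.profiles for t in p.tracts.values() if t is not None
            ]
            write_consensus_fasta(tracts, out_dir / f"{sample_id}.consensus.fasta")
            _write_profile_tsv(report, out_dir / f"{sample_id}.profile.tsv")
    return reports


def _write_profile_tsv(report: SampleReport, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "sample\tallele\tstrand\tn_reads\tcopy_number\tpercent_matches\t"
            "percent_indels\tvalidated_interruptions\n"
        )
        for profile in report.profiles:
            validated = ";".join(
                f"{i.unit_offset}:{i.motif}" for i in profile.interruptions if i.validated
            )
            for strand in ("+", "-"):
                tract = profile.tracts[strand]
                if tract is None:
                    continue
                pur = profile.purity.get(strand)
                fh.write(
                    f"{report.sample_id}\t{profile.allele}\t{strand}\t{tract.n_reads}\t"
                    f"{pur.copy_number:.1f}\t{pur.percent_matches}\t{pur.percent_indels}\t"
                    f"{validated}\n"
                )
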