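"""Seeded simulator of diploid repeat-amplicon reads with known truth.

Emulates the substrate the pipeline consumes: full-length amplicon reads
from two repeat alleles, with per-read repeat-count jitter (somatic
mosaicism), substitution/insertion/deletion errors, both strands, and
optional interruption motifs spliced into the tract.  Every read is paired
with a truth record so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .design import AmpliconDesign, revcomp, round_half_up

_BASES = "ACGT"
#: substitution targets per base, in a fixed order so draws are replayable
_SUB_CHOICES = {b: [c for c in _BASES if c != b] for b in _BASES}


@dataclass(frozen=True)
class Interruption:
    """A motif spliced between repeat units at ``unit_offset``."""

    allele: int  # 1 or 2
    unit_offset: int
    motif: str


@dataclass
class SimConfig:
    """Study conditions for one simulated diploid sample.

    ``jitter_sd`` is the standard deviation, in repeat units, of the
    per-read Gaussian mosaicism jitter; error rates are per-base and
    mutually exclusive per position.  ``plus_strand_fraction`` is the
    probability a read is emitted in sense orientation.
    """

    allele1_count: int
    allele2_count: int
    reads_per_allele: int = 100
    jitter_sd: float = 0.0
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    plus_strand_fraction: float = 0.5
    interruptions: Sequence[Interruption] = field(default_factory=tuple)
    seed: int = 0
    quality_char: str = "-"  # Phred+33 Q12; qualities are never used downstream

    def validate(self) -> None:
        if self.allele1_count < 0 or self.allele2_count < 0:
            raise ValueError("allele counts must be >= 0")
        if self.reads_per_allele < 1:
            raise ValueError("reads_per_allele must be >= 1")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        for name in ("sub_rate", "ins_rate", "del_rate"):
            r = getattr(self, name)
            if not 0 <= r < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.sub_rate + self.ins_rate + self.del_rate >= 1:
            raise ValueError("sub_rate + ins_rate + del_rate must be < 1")
        if not 0 <= self.plus_strand_fraction <= 1:
            raise ValueError("plus_strand_fraction must be in [0, 1]")
        for itr in self.interruptions:
            if itr.allele not in (1, 2):
                raise ValueError("interruption allele selector must be 1 or 2")
            count = self.allele1_count if itr.allele == 1 else self.allele2_count
            if not 0 <= itr.unit_offset <= count:
                raise ValueError(
                    f"interruption unit_offset {itr.unit_offset} exceeds allele "
                    f"{itr.allele} count {count}"
                )


@dataclass(frozen=True)
class ReadRecord:
    """One read: id, sequence, and a (downstream-unused) quality string."""

    id: str
    sequence: str
    quality: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id}: empty sequence")


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    allele: int
    true_count: int
    strand: str
    interruptions: tuple[tuple[int, str], ...] = ()


@dataclass
class SimTruth:
    """Per-read ground truth emitted alongside the simulated FASTQ."""

    records: list[TruthRecord]

    def by_read(self) -> dict[str, TruthRecord]:
        return {r.read_id: r for r in self.records}

    def counts(self, allele: int | None = None) -> list[int]:
        return [r.true_count for r in self.records if allele is None or r.allele == allele]


def mutate_sequence(
    seq: str,
    rates: tuple[float, float, float],
    rng: np.random.Generator,
    with_log: bool = False,
):
    """Apply per-base substitution/insertion/deletion errors in one pass.

    For each template position a single uniform draw selects, in this order,
    deletion, substitution, or insertion of a uniform random base after the
    position; otherwise the base is copied.  Events are mutually exclusive
    per position, so ``sub + ins + del`` must stay below 1.  With
    ``with_log=True`` also returns the event list ``(position, kind, base)``
    so tests can replay the exact edit history.
    """
    sub, ins, dele = rates
    out: list[str] = []
    log: list[tuple[int, str, str]] = []
    if sub + ins + dele > 0:
        draws = rng.random(len(seq))
    else:
        draws = None
    for i, base in enumerate(seq):
        u = draws[i] if draws is not None else 1.0
        if u < dele:
            log.append((i, "del", base))
            continue
        if u < dele + sub:
            new = _SUB_CHOICES[base][rng.integers(3)]
            out.append(new)
            log.append((i, "sub", new))
            continue
        out.append(base)
        if u < dele + sub + ins:
            inserted = _BASES[rng.integers(4)]
            out.append(inserted)
            log.append((i, "ins", inserted))
    mutated = "".join(out)
    return (mutated, log) if with_log else mutated


def simulate_sample(
    design: AmpliconDesign,
    config: SimConfig,
    sample_id: str = "sim",
) -> tuple[list[ReadRecord], SimTruth]:
    """Generate reads for a diploid sample plus the matching truth table.

    One RNG stream seeded from ``config.seed`` drives jitter, errors and
    strand choice, consumed in read-id order (all allele-1 reads, then all
    allele-2 reads), so identical inputs reproduce byte-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    reads: list[ReadRecord] = []
    truth: list[TruthRecord] = []
    rates = (config.sub_rate, config.ins_rate, config.del_rate)

    for allele, nominal in ((1, config.allele1_count), (2, config.allele2_count)):
        motifs = [
            (i.unit_offset, i.motif) for i in config.interruptions if i.allele == allele
        ]
        for i in range(config.reads_per_allele):
            read_id = f"{sample_id}_a{allele}_{i:05d}"
            if config.jitter_sd > 0:
                k = max(0, nominal + round(float(rng.normal(0.0, config.jitter_sd))))
            else:
                k = nominal
            placed = [(min(off, k), motif) for off, motif in motifs]
            template = design.template(k, placed)
            seq = mutate_sequence(template, rates, rng)
            strand = "+" if rng.random() < config.plus_strand_fraction else "-"
            if strand == "-":
                seq = revcomp(seq)
            if not seq:  # total deletion of a zero-repeat template
                seq = "N"
            reads.append(ReadRecord(read_id, seq, config.quality_char * len(seq)))
            truth.append(TruthRecord(read_id, allele, k, strand, tuple(placed)))
    return reads, SimTruth(truth)


def truth_to_tsv(truth: SimTruth) -> str:
    lines = ["read_id\tallele\ttrue_count\tstrand\tinterruptions"]
    for r in truth.records:
        itr = ";".join(f"{off}:{motif}" for off, motif in r.interruptions)
        lines.append(f"{r.read_id}\t{r.allele}\t{r.true_count}\t{r.strand}\t{itr}")
    return "\n".join(lines) + "\n"


def truth_from_tsv(text: str) -> SimTruth:
    records = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for ln in lines[1:]:
        read_id, allele, count, strand, itr = ln.split("\t")
        interruptions = tuple(
            (int(part.split(":")[0]), part.split(":")[1])
            for part in itr.split(";")
            if part
        )
        records.append(TruthRecord(read_id, int(allele), int(count), strand, interruptions))
    return SimTruth(records)
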