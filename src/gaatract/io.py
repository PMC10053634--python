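"""File formats: FASTQ, TSV tables, design YAML, packaged fixtures.

All tables are tab-separated with a header row and ``na`` as the missing
token.  FASTQ is Sanger-encoded (Phred+33) and read through Biopython.
"""

from __future__ import annotations

import importlib.resources as resources
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import AmpliconDesign
from .simulate import ReadRecord
from .stats import MethodTable


class ParseError(ValueError):
    pass


def read_fastq(path) -> list[ReadRecord]:
    """Load a Sanger FASTQ file into read records.

    Malformed records raise :class:`ParseError` carrying the approximate
    line number of the offending record.
    """
    records: list[ReadRecord] = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            records.append(ReadRecord(rec.id, str(rec.seq).upper(), qual))
    except ValueError as exc:
        raise ParseError(f"{path}: malformed FASTQ near line {4 * len(records) + 1}: {exc}") from exc
    return records


def write_fastq(reads, path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in r.quality]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def load_design(path) -> AmpliconDesign:
    """Read an amplicon design from a YAML mapping."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        return AmpliconDesign(
            upstream_flank=doc["upstream_flank"].upper(),
            downstream_flank=doc["downstream_flank"].upper(),
            repeat_unit=doc.get("repeat_unit", "GAA").upper(),
            flank_total_bp=int(doc.get("flank_total_bp", -1)),
        )
    except (KeyError, AttributeError, TypeError) as exc:
        raise ParseError(f"{path}: invalid design file: {exc}") from exc


def write_design(design: AmpliconDesign, path) -> None:
    doc = {
        "upstream_flank": design.upstream_flank,
        "downstream_flank": design.downstream_flank,
        "repeat_unit": design.repeat_unit,
        "flank_total_bp": design.flank_total_bp,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _read_tsv(path, required: set[str], numeric: list[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str, na_values=["na"], keep_default_na=False)
    if frame.empty:
        raise ParseError(f"{path}: table has no rows")
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    for col in numeric:
        try:
            frame[col] = pd.to_numeric(frame[col])
        except (ValueError, TypeError) as exc:
            bad = frame[pd.to_numeric(frame[col], errors="coerce").isna() & frame[col].notna()]
            row = bad.index[0] + 2 if len(bad) else "?"
            raise ParseError(f"{path}: non-numeric value in column {col!r}, line {row}") from exc
    return frame


def load_method_table(path) -> MethodTable:
    """Read a (sample, method, allele1, allele2) TSV; ``na`` marks missing."""
    frame = _read_tsv(path, {"sample", "method", "allele1", "allele2"}, ["allele1", "allele2"])
    return MethodTable(frame)


def load_phenotype_table(path) -> pd.DataFrame:
    """Read a (sample, age_at_onset) TSV; ages must be non-negative."""
    frame = _read_tsv(path, {"sample", "age_at_onset"}, ["age_at_onset"])
    if (frame["age_at_onset"] < 0).any():
        raise ParseError(f"{path}: negative age_at_onset")
    return frame


def _fixture(name: str):
    return resources.files("gaatract.data") / name


def load_table1() -> MethodTable:
    """Packaged study table: per-sample lengths by nanopore signal counting
    (STRique) and long-range PCR sizing (RP-PCR), 11 patients."""
    return load_method_table(_fixture("table1.tsv"))


def load_table2() -> MethodTable:
    """Packaged study table: per-sample lengths from strand-separated manual
    consensus counts (Alfred-plus/Alfred-minus), signal counting (STRique)
    and alignment-based counting (Tandem-genotypes), 11 patients + 1
    healthy control."""
    return load_method_table(_fixture("table2.tsv"))


def load_phenotype() -> pd.DataFrame:
    """Packaged ages at onset for the 11 patients."""
    return load_phenotype_table(_fixture("phenotype.tsv"))


def write_calls_tsv(calls, path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tstrand\tstart\tend\tcount\tanchor_identity\n")
        for c in calls:
            start, end = c.tract_span if c.tract_span else ("na", "na")
            count = c.repeat_count if c.repeat_count is not None else "na"
            fh.write(
                f"{c.read_id}\t{c.strand}\t{start}\t{end}\t{count}\t{c.anchor_identity:.4f}\n"
            )


def read_calls_tsv(path):
    from .repeatcall import RepeatCall

    calls = []
    frame = pd.read_csv(path, sep="\t", dtype=str, na_values=["na"], keep_default_na=False)
    for _, row in frame.iterrows():
        if row["strand"] == "fail" or pd.isna(row["count"]):
            calls.append(RepeatCall(row["read_id"], "fail"))
        else:
            calls.append(
                RepeatCall(
                    row["read_id"],
                    row["strand"],
                    tract_span=(int(row["start"]), int(row["end"])),
                    repeat_count=int(row["count"]),
                    anchor_identity=float(row["anchor_identity"]),
                )
            )
    return calls


def write_genotypes_tsv(genotypes, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "sample\tallele1\tallele2\tsupport1\tsupport2\tzygosity\tclass1\tclass2\n"
        )
        for g in genotypes:
            fh.write(
                f"{g.sample_id}\t{g.allele1_count}\t{g.allele2_count}\t{g.support1}\t"
                f"{g.support2}\t{g.zygosity}\t{g.class1}\t{g.class2}\n"
            )


def write_consensus_fasta(tracts, path) -> None:
    records = [
        SeqRecord(
            Seq(t.consensus_sequence),
            id=f"{t.sample_id}_allele{t.allele}_{'plus' if t.strand == '+' else 'minus'}",
            description=f"n_reads={t.n_reads}",
        )
        for t in tracts
        if t is not None
    ]
    SeqIO.write(records, str(path), "fasta")
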