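"""Per-allele, per-strand consensus tracts, purity metrics and interruptions.

Reads within a +/-20-repeat window of the called allele are pooled per
strand; each read's repeat tract is globally aligned to a backbone read
and a per-column majority vote yields the consensus tract, always reported
in sense (GAA) orientation.  Purity is measured by aligning the consensus
against a perfect repeat of matched length (copy number, percent matches,
percent indels).  Interruption motifs — non-canonical segments such as
GGAGAA inside an otherwise pure tract — are called per strand and only
reported as validated when both strand consensuses agree on the motif at
a compatible unit offset.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import edlib

from .design import AmpliconDesign, round_half_up
from .repeatcall import RepeatCall, oriented_sequence
from .simulate import ReadRecord


@dataclass(frozen=True)
class ConsensusTract:
    sample_id: str
    allele: int
    strand: str
    consensus_sequence: str
    n_reads: int


@dataclass(frozen=True)
class InterruptionCall:
    """A candidate or validated interruption at ``unit_offset`` repeat units.

    ``phase_break`` is True when the disrupting segment cannot be read as
    part of the repeat in any phase (e.g. ``GGA`` inside a GAA tract).
    Phase-compatible disruptions (pure gaps or runs of repeat bases such as
    ``AA``) are indistinguishable from sequencing indel noise and are never
    cross-validated as motif interruptions, only counted as indels.
    """

    unit_offset: int
    motif: str
    validated: bool = False
    strands: tuple[str, ...] = ()
    phase_break: bool = True


@dataclass(frozen=True)
class PurityReport:
    copy_number: float
    percent_matches: int
    percent_indels: int
    interruptions: tuple[InterruptionCall, ...] = ()


def select_window_reads(
    calls: list[RepeatCall],
    allele_count: int,
    window: int = 20,
) -> dict[str, list[RepeatCall]]:
    """Passing reads within ``window`` repeats (inclusive) of the allele call,
    partitioned by strand."""
    if window < 0:
        raise ValueError("window must be >= 0")
    selected: dict[str, list[RepeatCall]] = {"+": [], "-": []}
    for call in calls:
        if call.passed and abs(call.repeat_count - allele_count) <= window:
            selected[call.strand].append(call)
    return selected


def extract_tract(call: RepeatCall, read: ReadRecord) -> str:
    """The repeat tract of one read, sense-oriented."""
    oriented = oriented_sequence(read.sequence, call.strand)
    start, end = call.tract_span
    return oriented[start:end]


def _pick_backbone(pairs, allele_estimate: int):
    """Backbone read: count closest to the allele estimate, then highest
    anchor identity, then lexicographically smallest read id."""
    return min(
        pairs,
        key=lambda p: (
            abs(p[0].repeat_count - allele_estimate),
            -p[0].anchor_identity,
            p[0].read_id,
        ),
    )


def build_consensus(
    pairs: list[tuple[RepeatCall, ReadRecord]],
    design: AmpliconDesign,
    strand: str,
    allele_estimate: int,
    sample_id: str = "sample",
    allele: int = 1,
) -> ConsensusTract | None:
    """Majority-vote consensus of the repeat tracts of one strand's reads.

    Every tract is globally aligned to the backbone tract; per backbone
    column the most frequent base wins (deletions compete as a symbol),
    ties keep the backbone base; an insertion between backbone columns is
    emitted when more than half the reads carry one there, spelled as the
    most frequent inserted string.  Returns None when no reads are given.
    """
    pairs = [p for p in pairs if p[0].passed and p[0].strand == strand]
    if not pairs:
        return None
    backbone_call, backbone_read = _pick_backbone(pairs, allele_estimate)
    backbone = extract_tract(backbone_call, backbone_read)
    n = len(pairs)
    if n == 1 or not backbone:
        return ConsensusTract(sample_id, allele, strand, backbone, n)

    base_votes: list[Counter] = [Counter() for _ in range(len(backbone))]
    ins_votes: dict[int, Counter] = defaultdict(Counter)

    for call, read in pairs:
        tract = extract_tract(call, read)
        if not tract:
            for col in base_votes:
                col["-"] += 1
            continue
        res = edlib.align(tract, backbone, mode="NW", task="path")
        nice = edlib.getNiceAlignment(res, tract, backbone)
        q, t = nice["query_aligned"], nice["target_aligned"]
        bp = 0
        pending = []
        for qc, tc in zip(q, t):
            if tc == "-":
                pending.append(qc)
                continue
            if pending:
                ins_votes[bp][("".join(pending))] += 1
                pending = []
            base_votes[bp][qc] += 1
            bp += 1
        if pending:
            ins_votes[bp]["".join(pending)] += 1

    out: list[str] = []
    for bp in range(len(backbone) + 1):
        ins = ins_votes.get(bp)
        if ins and sum(ins.values()) * 2 > n:
            best = max(ins.items(), key=lambda kv: (kv[1], kv[0]))
            # most frequent insertion; ties resolved lexicographically last
            # for determinism (any fixed rule works; insertions at the same
            # point in near-identical reads rarely disagree)
            out.append(best[0])
        if bp < len(backbone):
            votes = base_votes[bp]
            top = max(votes.values())
            winners = [b for b, c in votes.items() if c == top]
            base = backbone[bp] if backbone[bp] in winners else sorted(winners)[0]
            if base != "-":
                out.append(base)
    return ConsensusTract(sample_id, allele, strand, "".join(out), n)


def find_interruption_candidates(tract_seq: str, unit: str) -> list[InterruptionCall]:
    """Single-tract interruption candidates.

    The tract is decomposed into maximal runs of the exact unit; every
    internal segment between two runs is a candidate.  The candidate motif
    spans from the start of the disrupting segment through the end of the
    first complete unit after it, so splicing ``GGAGAA`` into a pure GAA
    tract is reported back verbatim as ``GGAGAA``.  Offsets are in repeat
    units from the tract start.
    """
    runs = [m.span() for m in re.finditer(f"(?:{unit})+", tract_seq)]
    candidates = []
    for (_, prev_end), (next_start, _) in zip(runs, runs[1:]):
        gap = tract_seq[prev_end:next_start]
        motif = gap + tract_seq[next_start : next_start + len(unit)]
        offset = round_half_up(prev_end / len(unit))
        candidates.append(
            InterruptionCall(
                offset, motif, validated=False, phase_break=_breaks_phase(gap, unit)
            )
        )
    return candidates


def _breaks_phase(gap: str, unit: str) -> bool:
    """Whether a disrupting segment is incompatible with the repeat phase.

    A segment that occurs somewhere inside the endlessly repeated unit only
    changes the tract length (it is an in-phase insertion/deletion remnant);
    a segment that occurs nowhere in the repeat, like ``GGA`` in a GAA
    tract, is a genuine sequence interruption.
    """
    if not gap:
        return False
    context = unit * (len(gap) // len(unit) + 2)
    return gap not in context


def detect_interruptions(
    plus: ConsensusTract | None,
    minus: ConsensusTract | None,
    design: AmpliconDesign,
    offset_tolerance: int = 5,
) -> list[InterruptionCall]:
    """Cross-validate interruption candidates between strand consensuses.

    A candidate is validated only when the other strand's (sense-oriented)
    consensus shows the identical motif within ``offset_tolerance`` repeat
    units; the validated offset is the half-up mean of the two strand
    offsets, making the result symmetric under strand exchange.  With only
    one strand available all candidates are reported unvalidated.  Only
    phase-breaking candidates take part: in-phase length remnants are
    consensus indel noise, not motif interruptions.
    """
    unit = design.repeat_unit
    plus_cands = [
        c
        for c in (find_interruption_candidates(plus.consensus_sequence, unit) if plus else [])
        if c.phase_break
    ]
    minus_cands = [
        c
        for c in (find_interruption_candidates(minus.consensus_sequence, unit) if minus else [])
        if c.phase_break
    ]

    results: list[InterruptionCall] = []
    unmatched_minus = list(minus_cands)
    for p in plus_cands:
        match = None
        for m in unmatched_minus:
            if m.motif == p.motif and abs(m.unit_offset - p.unit_offset) <= offset_tolerance:
                if match is None or abs(m.unit_offset - p.unit_offset) < abs(
                    match.unit_offset - p.unit_offset
                ):
                    match = m
        if match is not None and plus is not None and minus is not None:
            unmatched_minus.remove(match)
            offset = round_half_up((p.unit_offset + match.unit_offset) / 2.0)
            results.append(InterruptionCall(offset, p.motif, validated=True, strands=("+", "-")))
        else:
            results.append(InterruptionCall(p.unit_offset, p.motif, validated=False, strands=("+",)))
    for m in unmatched_minus:
        results.append(InterruptionCall(m.unit_offset, m.motif, validated=False, strands=("-",)))
    return sorted(results, key=lambda c: (c.unit_offset, c.motif))


def purity_metrics(tract: ConsensusTract, design: AmpliconDesign) -> PurityReport:
    """Purity of a consensus tract against a perfect repeat of matched length.

    The consensus is globally aligned to ``unit ^ round(len/unit_len)``;
    percent matches and percent indels are per alignment column, rounded
    half-up to integers; copy number is the consensus length in units.
    Single-tract interruption candidates are attached unvalidated.
    """
    seq = tract.consensus_sequence
    if not seq:
        raise ValueError("cannot profile an empty consensus")
    unit_len = design.unit_length
    reference = design.repeat_unit * round_half_up(len(seq) / unit_len)
    res = edlib.align(seq, reference, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, seq, reference)
    columns = len(nice["matched_aligned"])
    matches = nice["matched_aligned"].count("|")
    indels = nice["query_aligned"].count("-") + nice["target_aligned"].count("-")
    return PurityReport(
        copy_number=len(seq) / unit_len,
        percent_matches=round_half_up(100.0 * matches / columns),
        percent_indels=round_half_up(100.0 * indels / columns),
        interruptions=tuple(find_interruption_candidates(seq, design.repeat_unit)),
    )
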