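"""Per-read repeat counting from flank anchors.

Each read is oriented by locally aligning short anchors — the flank bases
immediately adjacent to the repeat — against both the read and its reverse
complement.  The repeat tract is the interval between the inner ends of the
two located anchors, and the repeat count is the tract length divided by
the unit length, rounded half-up.  Counting from the tract span rather
than walking unit motifs keeps the count robust to substitutions inside
the tract.  A length-based sizer (the long-range-PCR gel emulation) is
provided for method comparisons.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib

from .design import AmpliconDesign, revcomp, round_half_up


@dataclass(frozen=True)
class AnchorParams:
    """Anchoring knobs: anchor length and minimum mean anchor identity."""

    anchor_length: int = 30
    min_identity: float = 0.80


@dataclass(frozen=True)
class RepeatCall:
    """One read's orientation, repeat-tract span and integer repeat count.

    ``tract_span`` is 0-based half-open on the read *as oriented to the
    sense strand*; ``strand`` is ``fail`` when the anchors could not be
    located confidently, in which case no count is reported.
    """

    read_id: str
    strand: str  # "+", "-", or "fail"
    tract_span: tuple[int, int] | None = None
    repeat_count: int | None = None
    anchor_identity: float = 0.0

    @property
    def passed(self) -> bool:
        return self.strand in ("+", "-")


@dataclass
class CountDistribution:
    """Multiset of (repeat_count, strand) over a sample's passing reads."""

    sample_id: str
    counts: Counter = field(default_factory=Counter)  # (count, strand) -> n

    def add(self, call: RepeatCall) -> None:
        if call.passed:
            self.counts[(call.repeat_count, call.strand)] += 1

    @property
    def size(self) -> int:
        return sum(self.counts.values())

    def histogram(self) -> Counter:
        """Strand-pooled integer histogram count -> reads."""
        hist: Counter = Counter()
        for (count, _strand), n in self.counts.items():
            hist[count] += n
        return hist


def _anchors(design: AmpliconDesign, k: int) -> tuple[str, str]:
    """The k flank bases adjacent to the repeat on each side (sense strand)."""
    up = design.upstream_flank[-k:] if design.upstream_flank else ""
    down = design.downstream_flank[:k] if design.downstream_flank else ""
    return up, down


def _best_hit(anchor: str, seq: str):
    """Best infix placement of ``anchor`` in ``seq``: (identity, start, end)."""
    res = edlib.align(anchor, seq, mode="HW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return 0.0, None, None
    identity = max(0.0, 1.0 - res["editDistance"] / len(anchor))
    start, end = res["locations"][0]
    return identity, start, end + 1  # edlib ends are inclusive


def detect_orientation(read_seq: str, design: AmpliconDesign, params: AnchorParams = AnchorParams()):
    """Resolve a read's strand by anchor search in both orientations.

    Returns ``(strand, hits)`` where hits maps ``"up"``/``"down"`` to the
    ``(identity, start, end)`` placement on the winning orientation of the
    read.  Reads shorter than one anchor, or whose best mean anchor
    identity falls below ``params.min_identity``, are flagged ``fail``.
    """
    up, down = _anchors(design, params.anchor_length)
    if len(read_seq) < min(len(up), len(down)) or not up or not down:
        return "fail", {}
    best = None
    for strand, seq in (("+", read_seq), ("-", revcomp(read_seq))):
        up_hit = _best_hit(up, seq)
        down_hit = _best_hit(down, seq)
        score = up_hit[0] + down_hit[0]
        if best is None or score > best[0]:
            best = (score, strand, {"up": up_hit, "down": down_hit})
    score, strand, hits = best
    if score / 2.0 < params.min_identity:
        return "fail", {}
    return strand, hits


def count_repeats(
    read_id: str,
    read_seq: str,
    design: AmpliconDesign,
    params: AnchorParams = AnchorParams(),
) -> RepeatCall:
    """Count repeat units in one read from its anchor placements.

    The tract is the interval between the inner end of the upstream anchor
    and the inner start of the downstream anchor on the sense-oriented
    read; the count is the tract length over the unit length, half-up.
    Fail-flagged reads yield a call with ``strand="fail"`` and no count.
    """
    strand, hits = detect_orientation(read_seq, design, params)
    if strand == "fail":
        return RepeatCall(read_id, "fail")
    up_identity, _, up_end = hits["up"]
    down_identity, down_start, _ = hits["down"]
    start, end = up_end, max(down_start, up_end)
    count = round_half_up((end - start) / design.unit_length)
    return RepeatCall(
        read_id,
        strand,
        tract_span=(start, end),
        repeat_count=count,
        anchor_identity=(up_identity + down_identity) / 2.0,
    )


def count_from_length(read_length_bp: int, design: AmpliconDesign) -> int:
    """Repeat count implied by total amplicon length (gel-sizing emulator)."""
    if read_length_bp < design.flank_total_bp:
        raise ValueError(
            f"read length {read_length_bp} bp is shorter than the non-repeat "
            f"amplicon length {design.flank_total_bp} bp"
        )
    return round_half_up((read_length_bp - design.flank_total_bp) / design.unit_length)


def collect_distribution(calls, sample_id: str) -> CountDistribution:
    """Pool passing calls into the per-sample count distribution."""
    dist = CountDistribution(sample_id)
    for call in calls:
        dist.add(call)
    return dist


def oriented_sequence(read_seq: str, strand: str) -> str:
    """The read as seen on the sense strand."""
    if strand == "-":
        return revcomp(read_seq)
    return read_seq
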