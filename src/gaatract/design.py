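"""Amplicon design: the coordinate frame for repeat sizing.

A targeted repeat amplicon is ``upstream_flank + (repeat_unit x k) +
downstream_flank`` on the sense strand.  Every downstream stage (per-read
counting, length-based sizing, consensus extraction) is expressed relative
to this frame, so the design object is passed everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

_DNA = set("ACGT")


def round_half_up(x: float) -> int:
    """Round to the nearest integer with exact halves going up.

    Python's built-in ``round`` is banker's rounding; repeat counts and
    percent metrics are reported half-up throughout.
    """
    return math.floor(x + 0.5)


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass(frozen=True)
class AmpliconDesign:
    """Flanks, repeat unit and the non-repeat length budget of the amplicon.

    Parameters
    ----------
    upstream_flank, downstream_flank:
        Non-repeat sequence 5' and 3' of the tract, sense strand, A/C/G/T.
    repeat_unit:
        The tandem unit, default ``GAA`` (the frataxin intron-1 repeat).
    flank_total_bp:
        Combined non-repeat amplicon length used for length-based sizing
        (the gel/electrophoresis emulation).  Defaults to the sum of the two
        flank lengths and must equal it when both flanks are given.
    """

    upstream_flank: str
    downstream_flank: str
    repeat_unit: str = "GAA"
    flank_total_bp: int = field(default=-1)

    def __post_init__(self) -> None:
        for name in ("upstream_flank", "downstream_flank", "repeat_unit"):
            seq = getattr(self, name)
            if name == "repeat_unit" and len(seq) < 1:
                raise ValueError("repeat_unit must be at least 1 bp")
            if set(seq) - _DNA:
                raise ValueError(f"{name} contains non-ACGT characters")
        implied = len(self.upstream_flank) + len(self.downstream_flank)
        if self.flank_total_bp == -1:
            object.__setattr__(self, "flank_total_bp", implied)
        elif self.upstream_flank and self.downstream_flank and self.flank_total_bp != implied:
            raise ValueError(
                f"flank_total_bp={self.flank_total_bp} but flanks sum to {implied}"
            )
        if self.flank_total_bp < 0:
            raise ValueError("flank_total_bp must be >= 0")

    @property
    def unit_length(self) -> int:
        return len(self.repeat_unit)

    def template(self, n_units: int, interruptions: list[tuple[int, str]] | None = None) -> str:
        """Sense-strand amplicon carrying ``n_units`` repeats.

        ``interruptions`` is a list of ``(unit_offset, motif)`` pairs; each
        motif is spliced between units at its offset (offsets refer to the
        uninterrupted unit grid and are clamped to the tract).
        """
        tract = self.repeat_unit * n_units
        if interruptions:
            for offset, motif in sorted(interruptions, reverse=True):
                cut = min(max(offset, 0), n_units) * self.unit_length
                tract = tract[:cut] + motif + tract[cut:]
        return self.upstream_flank + tract + self.downstream_flank


def random_design(
    flank_length: int = 800,
    repeat_unit: str = "GAA",
    seed: int = 20230329,
) -> AmpliconDesign:
    """Synthetic amplicon design with uniform-random flanks.

    The real assay's primer-anchored flanks are not distributed with the
    package; random flanks of the same length budget stand in for them.
    The default 800 bp per flank gives ``flank_total_bp = 1600``, which
    reproduces the assay's sizing arithmetic (a 2.2 kb amplicon carries
    about 200 GAA units).  The seed fixes the flank sequences themselves
    and is independent of read-simulation seeds.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    up = "".join(rng.choice(bases, size=flank_length))
    down = "".join(rng.choice(bases, size=flank_length))
    return AmpliconDesign(up, down, repeat_unit=repeat_unit)
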