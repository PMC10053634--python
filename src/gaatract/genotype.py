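"""Mode-based biallelic genotyping from a repeat-count distribution.

Each allele is called as the repeat length supported by the most reads
(the mode of the count histogram) in its region of the distribution.  At
expanded lengths the raw integer histogram is sparse because of somatic
mosaicism, so mode-finding runs on a centred moving sum; the reported
allele value is the raw-histogram mode within the winning smoothed bin,
which leaves clean data untouched.  After the first allele is called, all
counts within ``min_separation`` units of it are masked and the second
allele is taken from the remainder; insufficient remaining support yields
a homozygous call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .repeatcall import CountDistribution

#: FRDA classification bounds on GAA repeat count: healthy alleles carry
#: 5-33 units; alleles above 66 units are full-length pathogenic expansions.
NORMAL_MAX = 33
INTERMEDIATE_MAX = 66


@dataclass(frozen=True)
class CallerParams:
    smooth_window: int = 5
    min_separation: int = 50
    min_reads: int = 3

    def __post_init__(self) -> None:
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be an odd integer >= 1")


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    allele1_count: int
    allele2_count: int
    support1: int
    support2: int
    zygosity: str  # "homozygous" | "biallelic"
    class1: str
    class2: str


def classify_allele(count: int) -> str:
    """FRDA class of one allele: normal (<=33), intermediate (34-66), expanded (>66)."""
    if count < 0:
        raise ValueError("repeat count must be >= 0")
    if count <= NORMAL_MAX:
        return "normal"
    if count <= INTERMEDIATE_MAX:
        return "intermediate"
    return "expanded"


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving sum; edges padded with zeros."""
    if window == 1:
        return values.astype(float)
    kernel = np.ones(window)
    return np.convolve(values, kernel, mode="same")


def _peak(raw: np.ndarray, smoothed: np.ndarray, offset: int, window: int):
    """Locate one allele: smoothed argmax, then the raw mode inside its bin.

    Ties break toward the smaller count.  Returns (reported count,
    smoothed support at the peak) or None if there is no support left.
    """
    if smoothed.max() <= 0:
        return None
    peak = int(np.argmax(smoothed))  # argmax returns the first (smallest) index on ties
    half = window // 2
    lo, hi = max(0, peak - half), min(len(raw), peak + half + 1)
    segment = raw[lo:hi]
    reported = lo + int(np.argmax(segment))
    return offset + reported, float(smoothed[peak])


def call_genotype(dist: CountDistribution, params: CallerParams = CallerParams()) -> GenotypeCall:
    """Call a biallelic repeat genotype by the two-pass mode rule."""
    hist = dist.histogram()
    if not hist:
        raise ValueError(f"sample {dist.sample_id}: empty count distribution")

    lo, hi = min(hist), max(hist)
    raw = np.zeros(hi - lo + 1, dtype=float)
    for count, n in hist.items():
        raw[count - lo] = n

    smoothed = _smooth(raw, params.smooth_window)
    first = _peak(raw, smoothed, lo, params.smooth_window)
    allele_a, support_a = first

    masked = raw.copy()
    span = np.arange(lo, hi + 1)
    masked[np.abs(span - allele_a) <= params.min_separation] = 0.0
    second = None
    if masked.max() > 0:
        resmoothed = _smooth(masked, params.smooth_window)
        cand = _peak(masked, resmoothed, lo, params.smooth_window)
        # the second allele must clear min_reads of raw read support
        if cand is not None and raw[cand[0] - lo] >= params.min_reads:
            second = cand

    if second is None:
        a1 = a2 = allele_a
        s1 = s2 = int(support_a)
        zygosity = "homozygous"
    else:
        allele_b, support_b = second
        (a1, s1), (a2, s2) = sorted(
            [(allele_a, int(support_a)), (allele_b, int(support_b))]
        )
        zygosity = "biallelic"

    return GenotypeCall(
        sample_id=dist.sample_id,
        allele1_count=a1,
        allele2_count=a2,
        support1=s1,
        support2=s2,
        zygosity=zygosity,
        class1=classify_allele(a1),
        class2=classify_allele(a2),
    )
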