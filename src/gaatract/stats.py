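"""Method-concordance and genotype-phenotype statistics.

Pearson correlation between sizing methods (combined alleles or per
allele), ordinary least-squares regression of age at onset on allele
length with R-squared, and mean signed between-method offsets.  Missing
entries are handled pairwise-complete: each statistic uses every sample
where both quantities are present, and the n actually used is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class MethodTable:
    """Sample x method table of (allele1, allele2) repeat lengths.

    Backed by a long-format DataFrame with columns ``sample``, ``method``,
    ``allele1``, ``allele2``; missing entries are NaN.  Allele ordering
    (allele1 <= allele2) is enforced on construction.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"sample", "method", "allele1", "allele2"}
        if not required.issubset(frame.columns):
            raise ValueError(f"method table needs columns {sorted(required)}")
        if frame.empty:
            raise ValueError("method table is empty")
        frame = frame.copy()
        frame["allele1"] = pd.to_numeric(frame["allele1"])
        frame["allele2"] = pd.to_numeric(frame["allele2"])
        bad = frame.dropna(subset=["allele1", "allele2"])
        bad = bad[bad["allele1"] > bad["allele2"]]
        if len(bad):
            rows = ", ".join(bad["sample"].astype(str))
            raise ValueError(f"allele1 > allele2 for sample(s): {rows}")
        self.frame = frame

    @property
    def methods(self) -> list[str]:
        return list(dict.fromkeys(self.frame["method"]))

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.frame["sample"]))

    def subset(self, samples) -> "MethodTable":
        return MethodTable(self.frame[self.frame["sample"].isin(samples)])

    def values(self, method: str, scope: str = "combined") -> pd.Series:
        """Allele lengths for one method, indexed so that values from
        different methods align sample-by-sample (and allele-by-allele for
        the combined scope)."""
        sub = self.frame[self.frame["method"] == method].set_index("sample")
        if scope == "allele1":
            return sub["allele1"]
        if scope == "allele2":
            return sub["allele2"]
        if scope == "combined":
            a1 = sub["allele1"].rename(index=lambda s: f"{s}/a1")
            a2 = sub["allele2"].rename(index=lambda s: f"{s}/a2")
            return pd.concat([a1, a2])
        raise ValueError(f"unknown scope {scope!r} (combined|allele1|allele2)")


@dataclass(frozen=True)
class CorrelationResult:
    scope: str
    matrix: pd.DataFrame  # method x method Pearson r, NaN where undefined
    n_used: pd.DataFrame  # pairwise-complete n per method pair


def pearson(x, y) -> float:
    """Product-moment correlation on pairwise-complete observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"need >= 3 complete pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(sps.pearsonr(x, y).statistic)


def correlation_matrix(table: MethodTable, scope: str = "combined") -> CorrelationResult:
    """Pairwise Pearson r between all methods at the requested scope."""
    methods = table.methods
    if len(methods) < 2:
        raise ValueError("need at least 2 methods")
    series = {m: table.values(m, scope) for m in methods}
    r = pd.DataFrame(np.nan, index=methods, columns=methods)
    n = pd.DataFrame(0, index=methods, columns=methods)
    for i, a in enumerate(methods):
        for b in methods[i:]:
            va, vb = series[a].align(series[b], join="inner")
            keep = ~(va.isna() | vb.isna())
            n.loc[a, b] = n.loc[b, a] = int(keep.sum())
            if a == b:
                if keep.sum() >= 2 and np.ptp(va[keep].to_numpy()) > 0:
                    r.loc[a, a] = 1.0
                continue
            try:
                r.loc[a, b] = r.loc[b, a] = pearson(va.to_numpy(), vb.to_numpy())
            except ValueError:
                pass  # undefined pair stays NaN, n still recorded
    return CorrelationResult(scope, r, n)


def regress_onset(lengths, age_at_onset) -> tuple[float, float, float]:
    """OLS of age at onset on allele length: (slope, intercept, r_squared)."""
    x = np.asarray(lengths, dtype=float)
    y = np.asarray(age_at_onset, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"need >= 3 complete pairs, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("regression undefined for a constant predictor")
    fit = sps.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def mean_method_difference(table: MethodTable, method_a: str, method_b: str) -> float:
    """Mean signed difference (A - B) over all alleles present in both methods."""
    va = table.values(method_a, scope="combined")
    vb = table.values(method_b, scope="combined")
    va, vb = va.align(vb, join="inner")
    diff = (va - vb).dropna()
    if diff.empty:
        raise ValueError(f"no samples shared between {method_a} and {method_b}")
    return float(diff.mean())
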