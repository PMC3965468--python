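"""Statistical contrasts for nearest-neighbour and intraspecific distances.

Implements the toolkit a barcode-library audit uses to relate divergence to
species traits: Mood's median test (k-sample, ties counted at-or-below the
pooled median, Pearson chi-square without continuity correction), one-way
ANOVA with the full sum-of-squares decomposition, the unequal-variance
(Welch) t-test with Satterthwaite degrees of freedom, Spearman rank
correlation, balanced subsampling without replacement, and per-group
count/sum/mean summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

GroupedValues = Mapping[str, Sequence[float]]


@dataclass
class MedianTestResult:
    chi_square: float
    df: int
    p: float
    pooled_median: float
    n: int
    contingency: dict[str, tuple[int, int]]  # group -> (n_above, n_at_or_below)


@dataclass
class AnovaTable:
    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    ms_between: float
    ms_within: float
    F: float
    p: float
    degenerate: bool = False

    @property
    def ss_total(self) -> float:
        return self.ss_between + self.ss_within


def _as_arrays(groups: GroupedValues) -> dict[str, np.ndarray]:
    out = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in out.items():
        if v.ndim != 1:
            raise ValidationError(f"group {k!r} is not one-dimensional")
    return out


def chi_square_from_contingency(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on a k×2 count table."""
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValidationError(
            "contingency table has an empty margin; an exact test is advised"
        )
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def moods_median_test(groups: GroupedValues) -> MedianTestResult:
    """Mood's median test across k groups.

    Values equal to the pooled median count in the at-or-below cell; the
    chi-square is Pearson's on the k×2 table, df = k−1.
    """
    arrays = _as_arrays(groups)
    if len(arrays) < 2:
        raise ValidationError("need at least two groups")
    for k, v in arrays.items():
        if len(v) == 0:
            raise ValidationError(f"group {k!r} is empty")
    pooled = np.concatenate(list(arrays.values()))
    if len(pooled) < 2:
        raise ValidationError("pooled sample must hold at least two values")
    median = float(np.median(pooled))
    contingency = {
        k: (int((v > median).sum()), int((v <= median).sum()))
        for k, v in arrays.items()
    }
    table = np.array(list(contingency.values()), dtype=float)
    if (table.sum(axis=0) == 0).any():
        raise ValidationError(
            "all values fall on one side of the pooled median; "
            "an exact test is advised"
        )
    chi2, df, p = chi_square_from_contingency(table)
    return MedianTestResult(
        chi_square=chi2,
        df=df,
        p=p,
        pooled_median=median,
        n=int(len(pooled)),
        contingency=contingency,
    )


def one_way_anova(groups: GroupedValues) -> AnovaTable:
    """One-way fixed-effects ANOVA with the explicit SS decomposition."""
    arrays = _as_arrays(groups)
    if len(arrays) < 2:
        raise ValidationError("need at least two groups")
    values = list(arrays.values())
    pooled = np.concatenate(values)
    if len(pooled) - len(values) < 1:
        raise ValidationError("within-group degrees of freedom must be >= 1")
    grand = pooled.mean()
    ss_between = float(sum(len(v) * (v.mean() - grand) ** 2 for v in values))
    ss_within = float(sum(((v - v.mean()) ** 2).sum() for v in values))
    df_between = len(values) - 1
    df_within = len(pooled) - len(values)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        return AnovaTable(
            ss_between, ss_within, df_between, df_within,
            ms_between, ms_within, F=0.0, p=float("nan"), degenerate=True,
        )
    F = ms_between / ms_within
    p = float(sps.f.sf(F, df_between, df_within))
    return AnovaTable(
        ss_between, ss_within, df_between, df_within, ms_between, ms_within, F, p
    )


def anova_from_sums(
    ss_between: float, df_between: int, ss_within: float, df_within: int
) -> AnovaTable:
    """Reconstruct an ANOVA table (MS, F, p) from printed SS and df."""
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    F = ms_between / ms_within
    p = float(sps.f.sf(F, df_between, df_within))
    return AnovaTable(
        ss_between, ss_within, df_between, df_within, ms_between, ms_within, F, p
    )


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, Satterthwaite df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least two values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise ValidationError("both groups have zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with mid-rank ties; (nan, nan) if a vector
    is constant (correlation undefined)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need equal-length vectors with at least 3 values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def balanced_resample(
    groups: GroupedValues, n: int, seed: int
) -> dict[str, np.ndarray]:
    """Draw n values per group without replacement (deterministic per seed)."""
    arrays = _as_arrays(groups)
    rng = np.random.default_rng(seed)
    out = {}
    for k in arrays:  # dict order: reproducible for a given input ordering
        v = arrays[k]
        if len(v) < n:
            raise ValidationError(f"group {k!r} has {len(v)} < n={n} values")
        out[k] = rng.choice(v, size=n, replace=False)
    return out


def group_means(groups: GroupedValues) -> list[tuple[str, int, float, float]]:
    """Per group: (label, count, sum, mean); mean is nan for empty groups."""
    arrays = _as_arrays(groups)
    return [
        (k, len(v), float(v.sum()), float(v.mean()) if len(v) else float("nan"))
        for k, v in arrays.items()
    ]
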