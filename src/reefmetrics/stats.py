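"""Group comparison of structural metrics across benthic classes.

The comparison stage mirrors standard practice for per-colony metrics: an
optional natural-log transform when the pooled residuals are strongly skewed,
a two-response MANOVA (Wilks' lambda with Rao's F approximation) to screen
for collinear responses, then one-way ANOVA per metric with Tukey's HSD post
hoc pairwise tests at alpha = 0.01.

Sums of squares and the test statistics are computed directly from their
definitions; p-values come from the scipy F and studentized-range
distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupedSample",
    "AnovaResult",
    "TukeyResult",
    "ManovaResult",
    "screen_and_transform",
    "one_way_anova",
    "tukey_hsd",
    "wilks_manova",
]


@dataclass
class GroupedSample:
    """One metric observed on features grouped by benthic class."""

    data: dict[str, np.ndarray]
    transform_applied: str = "none"

    def __post_init__(self) -> None:
        clean = {}
        for label, vals in self.data.items():
            arr = np.asarray(vals, dtype=float)
            if arr.size == 0:
                raise ValueError(f"group {label!r} is empty")
            if not np.isfinite(arr).all():
                raise ValueError(f"group {label!r} contains non-finite values")
            clean[label] = arr
        self.data = clean

    @property
    def k(self) -> int:
        return len(self.data)

    @property
    def n_total(self) -> int:
        return sum(v.size for v in self.data.values())

    def pooled_residuals(self) -> np.ndarray:
        return np.concatenate([v - v.mean() for v in self.data.values()])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, value_col: str, group_col: str = "class_label"):
        sub = df[[group_col, value_col]].dropna()
        return cls(data={g: v[value_col].to_numpy() for g, v in sub.groupby(group_col)})


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: Mapping[str, float]


@dataclass(frozen=True)
class TukeyResult:
    """All pairwise comparisons at a declared alpha; ``pairs`` is a DataFrame
    with columns (group_a, group_b, mean_diff, q, p_adj, significant)."""

    pairs: pd.DataFrame
    alpha: float

    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.pairs[self.pairs["significant"]]
        return list(zip(sig["group_a"], sig["group_b"]))


@dataclass(frozen=True)
class ManovaResult:
    wilks_lambda: float
    F: float
    df_num: float
    df_den: float
    p: float


def screen_and_transform(
    sample: GroupedSample,
    skew_threshold: float = 1.0,
    force: bool | None = None,
) -> GroupedSample:
    """Apply a natural-log transform when pooled-residual skewness demands it.

    The screen fires when |skewness| of the pooled within-group residuals
    exceeds ``skew_threshold`` (default 1).  ``force=True``/``False``
    overrides the screen.  Log on non-positive values is an error naming the
    offending group and value.
    """
    if force is None:
        skew = float(sps.skew(sample.pooled_residuals()))
        apply_log = abs(skew) > skew_threshold
    else:
        apply_log = bool(force)
    if not apply_log:
        return GroupedSample(data=dict(sample.data), transform_applied="none")
    for label, vals in sample.data.items():
        if (vals <= 0).any():
            bad = float(vals[vals <= 0][0])
            raise ValueError(
                f"log transform requires positive values; group {label!r} has {bad}"
            )
    return GroupedSample(
        data={k: np.log(v) for k, v in sample.data.items()}, transform_applied="log"
    )


def _sums_of_squares(sample: GroupedSample) -> tuple[float, float, float]:
    allv = np.concatenate(list(sample.data.values()))
    grand = allv.mean()
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in sample.data.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in sample.data.values())
    return float(ssb), float(ssw), float(grand)


def one_way_anova(sample: GroupedSample) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA across the groups."""
    k, N = sample.k, sample.n_total
    if k < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if N <= k:
        raise ValueError("ANOVA needs total N > number of groups")
    ssb, ssw, _ = _sums_of_squares(sample)
    if ssb == 0 and ssw == 0:
        raise ValueError("degenerate sample: no variation within or between groups")
    df_b, df_w = k - 1, N - k
    msb, msw = ssb / df_b, ssw / df_w
    if msw == 0:
        F = np.inf
        p = 0.0
    else:
        F = msb / msw
        p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(
        F=float(F),
        df_between=df_b,
        df_within=df_w,
        p=p,
        group_means={g: float(v.mean()) for g, v in sample.data.items()},
    )


def tukey_hsd(sample: GroupedSample, alpha: float = 0.01) -> TukeyResult:
    """Tukey's HSD over all group pairs.

    q = |m_i - m_j| / sqrt(MS_within / 2 * (1/n_i + 1/n_j)) (Tukey-Kramer for
    unequal n); adjusted p from the studentized-range distribution with k
    groups and the ANOVA within-group df.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if sample.k < 2:
        raise ValueError("Tukey's HSD needs at least 2 groups")
    _, ssw, _ = _sums_of_squares(sample)
    df_w = sample.n_total - sample.k
    if df_w <= 0:
        raise ValueError("no within-group degrees of freedom")
    msw = ssw / df_w
    rows = []
    for a, b in combinations(sample.data, 2):
        va, vb = sample.data[a], sample.data[b]
        diff = float(va.mean() - vb.mean())
        se = np.sqrt(msw / 2 * (1 / va.size + 1 / vb.size))
        q = abs(diff) / se if se > 0 else np.inf
        p_adj = float(sps.studentized_range.sf(q, sample.k, df_w)) if np.isfinite(q) else 0.0
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "mean_diff": diff,
                "q": float(q),
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return TukeyResult(pairs=pd.DataFrame(rows), alpha=alpha)


def wilks_manova(samples: Sequence[GroupedSample]) -> ManovaResult:
    """MANOVA over >= 1 responses observed on identical grouped features.

    All samples must share group labels and per-group sizes, aligned
    observation-by-observation.  Wilks' lambda = det(W) / det(W + B) with W,
    B the within/between cross-product matrices; the F approximation is
    Rao's, which is exact for p <= 2 responses or k <= 3 groups.  With a
    single response it reduces to the one-way ANOVA F.
    """
    samples = list(samples)
    p = len(samples)
    if p < 1:
        raise ValueError("need at least one response")
    labels = list(samples[0].data)
    for s in samples[1:]:
        if list(s.data) != labels or any(
            s.data[g].size != samples[0].data[g].size for g in labels
        ):
            raise ValueError("responses must be observed on identical feature lists")
    k = len(labels)
    N = samples[0].n_total
    if k < 2:
        raise ValueError("MANOVA needs at least 2 groups")
    if N <= k + p - 1:
        raise ValueError("too few observations for the requested responses")

    # response matrix per group: (n_g, p)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    grand = np.array([np.concatenate(list(s.data.values())).mean() for s in samples])
    for g in labels:
        X = np.column_stack([s.data[g] for s in samples])
        m = X.mean(axis=0)
        R = X - m
        W += R.T @ R
        d = m - grand
        B += X.shape[0] * np.outer(d, d)

    detW = np.linalg.det(W)
    if detW <= 0 or not np.isfinite(detW):
        raise ValueError("deficient within-group variation: singular W matrix")
    lam = float(detW / np.linalg.det(W + B))

    # Rao's F approximation
    q = k - 1
    if p**2 + q**2 - 5 > 0:
        t = np.sqrt((p**2 * q**2 - 4) / (p**2 + q**2 - 5))
    else:
        t = 1.0
    df1 = p * q
    ms = (N - 1) - (p + k) / 2
    df2 = ms * t - (p * q - 2) / 2
    lam_t = lam ** (1 / t)
    F = (1 - lam_t) / lam_t * df2 / df1
    pval = float(sps.f.sf(F, df1, df2))
    return ManovaResult(wilks_lambda=lam, F=float(F), df_num=float(df1), df_den=float(df2), p=pval)
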