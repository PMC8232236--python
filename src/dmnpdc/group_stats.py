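"""Group-level statistics: normality screening, one-way ANOVA with effect
size, Tukey HSD, Bonferroni correction, group summaries and Pearson
correlation of connectivity with SIAS scores.

Two units of analysis are supported for the band-wise ANOVA:

* ``connection`` level: for each group, the 8x8 = 64 directed pairs
  (including the zeroed diagonal) averaged across the group's subjects, so
  four groups give 256 observations and df = (3, 252) — the layout implied
  by the degrees of freedom reported in such studies;
* ``subject`` level: one mean off-diagonal value per subject, df = (3, 84)
  at 22 subjects per group — the statistically defensible layout, since
  subjects (not connections) are the independent sampling units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "CorrResult",
    "ks_normality",
    "oneway_anova",
    "tukey_hsd",
    "bonferroni",
    "pearson_corr",
    "group_summary",
    "connection_level_values",
    "subject_level_values",
]


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    eta2: float

    def __str__(self) -> str:  # Table-3-style rendering
        return (
            f"F({self.df_between}, {self.df_within}) = {self.F:.3f}, "
            f"p = {self.p:.3g}, eta2 = {self.eta2:.3f}"
        )


@dataclass
class CorrResult:
    r: float
    n: int
    p: float


def ks_normality(values) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against a normal distribution
    with the sample's own mean and SD.

    Estimating the parameters from the sample makes the test conservative
    (the Lilliefors caveat); it is used as an advisory screen, never as a
    gate.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate (zero-variance) sample")
    stat, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    return float(stat), float(p)


def oneway_anova(groups: list) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA with eta-squared effect size
    (SS_between / SS_total)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ss_total = ss_between + ss_within
    df_b = len(arrays) - 1
    df_w = all_vals.size - len(arrays)
    if ss_within == 0:
        F = np.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        F = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(F, df_b, df_w))
    eta2 = float(ss_between / ss_total) if ss_total > 0 else 0.0
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w, p=p, eta2=eta2)


def tukey_hsd(groups: list, labels: list[str] | None = None, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey honestly-significant-difference pairwise comparisons.

    Returns one row per unordered pair with the mean difference, adjusted
    p-value (studentized range) and the rejection decision at ``alpha``.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    res = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "diff": float(arrays[i].mean() - arrays[j].mean()),
                    "p_adj": float(res.pvalue[i, j]),
                    "reject": bool(res.pvalue[i, j] < alpha),
                }
            )
    return pd.DataFrame(rows)


def bonferroni(pvals, alpha: float = 0.05) -> np.ndarray:
    """Bonferroni decisions: reject iff p <= alpha / m."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return p <= alpha / p.size


def pearson_corr(x, y) -> CorrResult:
    """Sample Pearson correlation with two-sided p from the t distribution
    on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input")
    r, p = stats.pearsonr(x, y)
    return CorrResult(r=float(r), n=int(x.size), p=float(p))


def subject_level_values(tensors_by_group: dict, band: str) -> dict:
    """Per-group lists of each subject's mean off-diagonal band PDC."""
    return {
        g: [t.mean_offdiag(band) for t in tensors]
        for g, tensors in tensors_by_group.items()
    }


def connection_level_values(tensors_by_group: dict, band: str) -> dict:
    """Per-group flattened 8x8 group-mean matrices (64 values per group,
    diagonal zeros included), the layout giving df (3, 252) as reported in connection-level severity studies."""
    out = {}
    for g, tensors in tensors_by_group.items():
        mats = np.stack([t.band(band) for t in tensors])
        out[g] = mats.mean(axis=0).ravel().tolist()
    return out


def group_summary(tensors_by_group: dict, band: str) -> pd.DataFrame:
    """Mean +- SD over subjects of each subject's mean off-diagonal band
    PDC, one row per group. SD is NaN-flagged for single-subject groups."""
    rows = []
    for g, tensors in tensors_by_group.items():
        if not tensors:
            raise ValueError(f"empty group: {g}")
        vals = np.array([t.mean_offdiag(band) for t in tensors])
        rows.append(
            {
                "group": g,
                "n": vals.size,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
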