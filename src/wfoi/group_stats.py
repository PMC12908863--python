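"""Comparison statistics for trial-wise response metrics.

Behavioural-state and correction-method comparisons use: Welch's
unequal-variance t test (with Welch-Satterthwaite degrees of freedom),
pooled-SD Cohen's d, Levene's variance-equality test, the Kruskal-Wallis
rank test, and Bonferroni-corrected pairwise Mann-Whitney tests.  Each
accepts either raw samples or (mean, sd, n) group summaries where the
statistic is summary-computable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InvalidArgumentError

__all__ = [
    "GroupSummary",
    "welch_t",
    "cohens_d_pooled",
    "levene",
    "kruskal_wallis",
    "mann_whitney_bonferroni",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics of one group: mean, SD (ddof=1) and n."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise InvalidArgumentError("group summary requires n >= 2")
        if self.sd < 0:
            raise InvalidArgumentError("sd must be >= 0")

    @classmethod
    def from_samples(cls, x) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        if x.size < 2:
            raise InvalidArgumentError("need >= 2 samples per group")
        return cls(float(x.mean()), float(x.std(ddof=1)), int(x.size))


def _as_summary(g) -> GroupSummary:
    return g if isinstance(g, GroupSummary) else GroupSummary.from_samples(g)


def welch_t(a, b) -> tuple[float, float]:
    """Welch's unequal-variance t statistic and its degrees of freedom.

    ``t = (mean_a - mean_b) / sqrt(sd_a^2/n_a + sd_b^2/n_b)`` with the
    Welch-Satterthwaite df.  Accepts :class:`GroupSummary` objects or raw
    sample arrays.
    """
    a, b = _as_summary(a), _as_summary(b)
    va, vb = a.sd ** 2 / a.n, b.sd ** 2 / b.n
    if va + vb == 0:
        raise InvalidArgumentError("both group variances are zero")
    t = (a.mean - b.mean) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    return float(t), float(df)


def welch_t_p(a, b) -> tuple[float, float, float]:
    """Welch's t with its two-sided p-value: (t, df, p)."""
    t, df = welch_t(a, b)
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, float(p)


def cohens_d_pooled(a, b) -> float:
    """Cohen's d with the pooled standard deviation.

    ``d = (mean_a - mean_b) / s_p`` where
    ``s_p^2 = ((n_a-1) sd_a^2 + (n_b-1) sd_b^2) / (n_a + n_b - 2)``.
    """
    a, b = _as_summary(a), _as_summary(b)
    if a.n + b.n <= 2:
        raise InvalidArgumentError("need n_a + n_b > 2")
    sp2 = ((a.n - 1) * a.sd ** 2 + (b.n - 1) * b.sd ** 2) / (a.n + b.n - 2)
    if sp2 == 0:
        raise InvalidArgumentError("pooled variance is zero")
    return float((a.mean - b.mean) / np.sqrt(sp2))


def levene(a, b, center: str = "mean") -> tuple[float, float]:
    """Levene's test of variance equality on two raw samples.

    The classical form uses absolute deviations from the group mean
    (``center='mean'``); the Brown-Forsythe variant uses the median.
    Returns (F, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidArgumentError("need >= 2 samples per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise InvalidArgumentError(
            "both groups are constant; Levene's F is undefined")
    f, p = stats.levene(a, b, center=center)
    return float(f), float(p)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis rank test across >= 2 groups, with tie correction.

    If every observation is tied (all groups one constant) the statistic
    degenerates; by convention (0, 1) is returned.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise InvalidArgumentError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def mann_whitney_bonferroni(groups: dict,
                            alternative: str = "two-sided") -> dict:
    """Pairwise Mann-Whitney U tests with Bonferroni correction.

    ``groups`` maps name -> samples.  Each raw p-value is multiplied by
    the number of pairs and capped at 1.  Returns
    ``{(name_a, name_b): {'u', 'p_raw', 'p_corrected'}}``.
    """
    names = list(groups)
    if len(names) < 2 or any(len(np.atleast_1d(groups[n])) == 0 for n in names):
        raise InvalidArgumentError("need >= 2 non-empty groups")
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    out = {}
    for a, b in pairs:
        u, p = stats.mannwhitneyu(groups[a], groups[b], alternative=alternative)
        out[(a, b)] = {"u": float(u), "p_raw": float(p),
                       "p_corrected": min(1.0, float(p) * len(pairs))}
    return out
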