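"""Paired group statistics with Holm step-down correction.

The three procedures that gate the pipeline's pairwise claims — the
two-tailed paired t test, the Wilcoxon signed-rank test (exact null
distribution up to n = 25, normal approximation with tie and continuity
corrections beyond), and the Holm–Bonferroni step-down adjustment — are
implemented here directly. Reference CDFs come from scipy.stats;
auxiliary omnibus checks (Kruskal–Wallis, Levene, Shapiro–Wilk, one-way
ANOVA) are thin delegations to scipy.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.stats import rankdata

from .errors import DegenerateDifferences, InvalidP

__all__ = ["ComparisonResult", "paired_t", "wilcoxon_signed_rank",
           "holm_adjust", "kruskal_wallis", "levene", "shapiro",
           "one_way_anova"]


@dataclass
class ComparisonResult:
    """One pairwise or omnibus comparison."""

    label: str
    method: str
    statistic: float
    p: float
    df: float | None = None
    n: int | None = None
    effect: float | None = None        #: mean or median difference
    dispersion: float | None = None    #: SD (t) or IQR (rank-based)
    p_adjusted: float | None = None

    def as_dict(self) -> dict:
        return {"label": self.label, "method": self.method,
                "statistic": self.statistic, "df": self.df, "n": self.n,
                "effect": self.effect, "dispersion": self.dispersion,
                "p": self.p, "p_adjusted": self.p_adjusted}


def paired_t(x, y, label: str = "") -> ComparisonResult:
    """Two-tailed paired t test.

    t = mean(d) / (sd(d)/√n) on the paired differences d = x − y, with
    df = n − 1. Raises :class:`DegenerateDifferences` when the
    differences have zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need equal-length paired samples with n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise DegenerateDifferences("paired differences have zero variance")
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return ComparisonResult(label=label, method="paired_t",
                            statistic=float(t), p=p, df=float(n - 1), n=n,
                            effect=float(d.mean()), dispersion=float(sd))


def _signed_rank_exact_cdf(ranks2: np.ndarray) -> np.ndarray:
    """Counts of subsets of ``ranks2`` (doubled mid-ranks, ints) per sum.

    Dynamic programme over the 2ⁿ sign assignments: entry s holds the
    number of sign patterns whose positive-rank sum (doubled) equals s.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(x, y=None, label: str = "",
                         exact_max_n: int = 25) -> ComparisonResult:
    """Two-tailed Wilcoxon signed-rank test on paired data.

    Zero differences are dropped, ties receive mid-ranks. The statistic
    reported is W+ (sum of ranks of positive differences). For
    n ≤ ``exact_max_n`` the p-value is exact over all 2ⁿ sign patterns;
    otherwise a normal approximation with tie correction and a 0.5
    continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0.0]
    if d.size == 0:
        raise DegenerateDifferences("all paired differences are zero")
    n = d.size
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0

    if n <= exact_max_n:
        ranks2 = np.rint(2 * ranks).astype(int)
        counts = _signed_rank_exact_cdf(ranks2)
        total = 2.0 ** n
        w2 = int(round(2 * w_plus))
        p_le = counts[:w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 \
            - (tie_counts ** 3 - tie_counts).sum() / 48.0
        z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / np.sqrt(var)
        p = 2.0 * float(sps.norm.sf(abs(z)))
    q25, q75 = np.percentile(d, [25, 75])
    return ComparisonResult(label=label, method="wilcoxon_signed_rank",
                            statistic=w_plus, p=min(p, 1.0), n=n,
                            effect=float(np.median(d)),
                            dispersion=float(q75 - q25))


def holm_adjust(pvals) -> np.ndarray:
    """Holm–Bonferroni step-down adjusted p-values, in input order.

    Sort ascending; adj_(i) = max_{j ≤ i} (m − j + 1)·p_(j), capped at 1.
    Uniformly more powerful than Bonferroni while controlling the
    family-wise error rate.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or
                   not np.all(np.isfinite(p))):
        raise InvalidP("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    stepped = (m - np.arange(m)) * p[order]
    adj_sorted = np.minimum(np.maximum.accumulate(stepped), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


# --- delegated omnibus / assumption checks --------------------------------

def kruskal_wallis(groups: list, label: str = "") -> ComparisonResult:
    """Kruskal–Wallis rank-sum test across independent groups."""
    h, p = sps.kruskal(*groups)
    return ComparisonResult(label=label, method="kruskal_wallis",
                            statistic=float(h), p=float(p),
                            df=float(len(groups) - 1),
                            n=int(sum(len(g) for g in groups)))


def levene(groups: list, label: str = "") -> ComparisonResult:
    w, p = sps.levene(*groups)
    return ComparisonResult(label=label, method="levene",
                            statistic=float(w), p=float(p))


def shapiro(x, label: str = "") -> ComparisonResult:
    w, p = sps.shapiro(np.asarray(x, dtype=float))
    return ComparisonResult(label=label, method="shapiro",
                            statistic=float(w), p=float(p))


def one_way_anova(groups: list, label: str = "") -> ComparisonResult:
    f, p = sps.f_oneway(*groups)
    k = len(groups)
    n = sum(len(g) for g in groups)
    return ComparisonResult(label=label, method="one_way_anova",
                            statistic=float(f), p=float(p),
                            df=float(k - 1), n=int(n))
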