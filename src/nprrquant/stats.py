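"""Nonparametric and one-sample comparisons used for release quantification.

Two tests cover the study designs here: the Mann-Whitney U test for
independent two-group comparisons (exact small-sample p by full enumeration
when both groups have at most EXACT_CUTOFF observations and there are no
ties; normal approximation with midranks, tie correction and continuity
correction otherwise), and the one-sample t test against a reference value
(normalized frequency responses compared to zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "mann_whitney_u",
    "one_sample_t",
    "significance_stars",
    "EXACT_CUTOFF",
]

EXACT_CUTOFF = 8  # exact enumeration when n_a, n_b <= this and no ties


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    p_value: float
    method: str  # mann_whitney_exact | mann_whitney_normal | one_sample_t
    n: tuple[int, ...]
    sided: str  # two | greater | less
    df: float | None = None

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "method": self.method,
            "n": list(self.n),
            "sided": self.sided,
            "df": self.df,
            "stars": self.stars,
        }


def significance_stars(p: float) -> str:
    """Star convention: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p < cut:
            return stars
    return "n.s."


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a from midrank sums: U_a = R_a - n_a(n_a+1)/2."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks for ties
    ra = ranks[: len(a)].sum()
    return float(ra - len(a) * (len(a) + 1) / 2)


@lru_cache(maxsize=64)
def _exact_u_distribution(n_a: int, n_b: int) -> np.ndarray:
    """Counts of arrangements by integer U value for tie-free samples:
    full enumeration of the C(n_a+n_b, n_a) rank assignments."""
    n = n_a + n_b
    counts = np.zeros(n_a * n_b + 1, dtype=np.int64)
    base = n_a * (n_a + 1) // 2
    for comb in combinations(range(1, n + 1), n_a):
        counts[sum(comb) - base] += 1
    return counts


def mann_whitney_u(
    a, b, sided: str = "two", exact_cutoff: int = EXACT_CUTOFF
) -> ComparisonResult:
    """Mann-Whitney U test of two independent samples.

    Exact p (full enumeration over all rank arrangements) when both samples
    have at most ``exact_cutoff`` observations and the pooled sample is
    tie-free; otherwise the normal approximation with tie correction and a
    0.5 continuity correction.  ``sided='greater'`` tests whether ``a``
    tends to exceed ``b``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if sided not in ("two", "greater", "less"):
        raise ValueError("sided must be 'two', 'greater' or 'less'")
    n_a, n_b = a.size, b.size
    u = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size

    if n_a <= exact_cutoff and n_b <= exact_cutoff and not has_ties:
        counts = _exact_u_distribution(n_a, n_b)
        total = counts.sum()
        ui = int(round(u))
        p_ge = counts[ui:].sum() / total
        p_le = counts[: ui + 1].sum() / total
        if sided == "greater":
            p = p_ge
        elif sided == "less":
            p = p_le
        else:
            # symmetric null distribution (no ties): two-sided tail mass
            mean = n_a * n_b / 2
            lo = int(round(min(ui, 2 * mean - ui)))
            hi = int(round(max(ui, 2 * mean - ui)))
            p = (counts[: lo + 1].sum() + counts[hi:].sum()) / total
            p = min(1.0, float(p))
        return ComparisonResult(u, float(min(p, 1.0)), "mann_whitney_exact",
                                (n_a, n_b), sided)

    # normal approximation with tie correction and continuity correction
    mean = n_a * n_b / 2
    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n_a * n_b / 12 * (n + 1 - tie_term)
    if var <= 0:
        # all observations identical: no evidence either way
        return ComparisonResult(u, 1.0, "mann_whitney_normal", (n_a, n_b), sided)
    sd = np.sqrt(var)
    if sided == "greater":
        z = (u - mean - 0.5) / sd
        p = sps.norm.sf(z)
    elif sided == "less":
        z = (u - mean + 0.5) / sd
        p = sps.norm.cdf(z)
    else:
        z = (abs(u - mean) - 0.5) / sd
        p = 2 * sps.norm.sf(max(z, 0.0))
    return ComparisonResult(u, float(min(p, 1.0)), "mann_whitney_normal",
                            (n_a, n_b), sided)


def one_sample_t(x, mu0: float = 0.0, sided: str = "two") -> ComparisonResult:
    """One-sample t test of the mean against ``mu0`` (default 0)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if sided not in ("two", "greater", "less"):
        raise ValueError("sided must be 'two', 'greater' or 'less'")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance sample: t statistic undefined")
    n = x.size
    t = (x.mean() - mu0) / (sd / np.sqrt(n))
    df = n - 1
    if sided == "greater":
        p = sps.t.sf(t, df)
    elif sided == "less":
        p = sps.t.cdf(t, df)
    else:
        p = 2 * sps.t.sf(abs(t), df)
    return ComparisonResult(float(t), float(p), "one_sample_t", (n,), sided,
                            df=float(df))
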