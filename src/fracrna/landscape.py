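"""Ranked enrichment landscapes and class-distribution statistics.

A landscape ranks every detected gene by its fraction/extract enrichment
ratio and assigns percentile ranks; the class composition of the landscape
is then summarised as a moving-average quota curve (the share of genes in
a sliding percentile window belonging to a class), tail-overrepresentation
tests (hypergeometric upper tail over the top or bottom 30%, say, with
Benjamini-Hochberg correction across the tests of a run), and rank-based
two-sample comparisons of class enrichment distributions (Mann-Whitney and
Kolmogorov-Smirnov).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import EnrichmentTable

logger = logging.getLogger(__name__)


@dataclass
class TailEnrichmentResult:
    """Hypergeometric tail-overrepresentation of a class in a landscape tail."""

    loc_class: str
    side: str
    tail_fraction: float
    n_total: int      # N: genes in the landscape
    n_tail: int       # K: genes in the tail
    class_size: int   # n: class members in the landscape
    class_in_tail: int  # k
    p_value: float
    q_value: float | None = None


@dataclass
class RankTestResult:
    test: str
    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str


def percentile_rank(enrichment: EnrichmentTable | pd.Series,
                    classes: pd.Series | None = None) -> pd.DataFrame:
    """Rank genes by enrichment ratio, ascending, with percentile ranks.

    Percentile of the gene at (1-based) rank r of N is 100*(r - 0.5)/N.
    Ties are broken by gene id, so the ranking is stable and reproducible.
    Returns a DataFrame (gene id index, columns ratio, rank, percentile
    and, when ``classes`` is given, loc_class), sorted ascending.
    """
    ratios = enrichment.ratios if isinstance(enrichment, EnrichmentTable) else enrichment
    if len(ratios) < 2:
        raise ValueError("a landscape needs at least 2 genes")
    frame = ratios.rename("ratio").to_frame()
    frame = frame.sort_index(kind="stable")
    frame = frame.sort_values("ratio", kind="stable")  # id order preserved in ties
    n = len(frame)
    frame["rank"] = np.arange(1, n + 1)
    frame["percentile"] = 100.0 * (frame["rank"] - 0.5) / n
    if classes is not None:
        frame["loc_class"] = classes.reindex(frame.index)
    return frame


def quota_curve(landscape: pd.DataFrame, classes: pd.Series,
                window_width: float = 10.0, step: float = 1.0) -> pd.DataFrame:
    """Moving-average class quota along the landscape.

    For window centers spaced ``step`` percentiles apart, the quota of a
    class is (class members in the window) / (genes in the window), the
    window being [center - width/2, center + width/2] truncated at the
    landscape edges. Returns a tidy frame (center, loc_class, quota,
    genes_in_window).
    """
    if not 0 < window_width <= 100:
        raise ValueError("window width must be in (0, 100]")
    cls = classes.reindex(landscape.index)
    pct = landscape["percentile"].to_numpy()
    centers = np.arange(0.0, 100.0 + step / 2, step)
    rows = []
    for c in centers:
        lo, hi = max(c - window_width / 2, 0.0), min(c + window_width / 2, 100.0)
        in_win = (pct >= lo) & (pct <= hi)
        total = int(in_win.sum())
        if total == 0:
            continue
        counts = cls[in_win].value_counts()
        for name in cls.dropna().unique():
            rows.append((c, name, counts.get(name, 0) / total, total))
    return pd.DataFrame(rows, columns=["center", "loc_class", "quota",
                                       "genes_in_window"])


def hypergeom_upper_tail(N: int, n: int, K: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, n, K), by exact summation.

    N genes, n of them in the class, K drawn into the tail; the summation
    is carried out in exact integer arithmetic before the final division.
    """
    if not (0 <= k <= min(n, K)):
        if k > min(n, K):
            return 0.0
        raise ValueError("k must be >= 0")
    numer = sum(math.comb(n, i) * math.comb(N - n, K - i)
                for i in range(k, min(n, K) + 1))
    return numer / math.comb(N, K)


def tail_overrepresentation(landscape: pd.DataFrame, loc_class: str,
                            tail_fraction: float = 0.30,
                            side: str = "top") -> TailEnrichmentResult:
    """Is a class overrepresented in the extreme ``tail_fraction`` of ranks?

    The tail holds K = round(tail_fraction * N) genes taken from the top
    (most enriched) or bottom of the ranked landscape; boundary genes are
    included by rank order. Overrepresentation is the hypergeometric upper
    tail P(X >= k).
    """
    if not 0 < tail_fraction < 1:
        raise ValueError("tail_fraction must be in (0, 1)")
    if side not in ("top", "bottom"):
        raise ValueError("side must be 'top' or 'bottom'")
    cls = landscape["loc_class"]
    if loc_class not in set(cls.dropna()):
        raise ValueError(f"class {loc_class!r} not present in landscape")
    N = len(landscape)
    K = int(round(tail_fraction * N))
    tail = landscape.nlargest(K, "rank") if side == "top" else landscape.nsmallest(K, "rank")
    n = int((cls == loc_class).sum())
    k = int((tail["loc_class"] == loc_class).sum())
    p = hypergeom_upper_tail(N, n, K, k)
    return TailEnrichmentResult(loc_class, side, tail_fraction, N, K, n, k, p)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(list(pvalues), float)
    if len(p) == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_tail_tests(results: Sequence[TailEnrichmentResult]
                      ) -> list[TailEnrichmentResult]:
    """Attach BH q-values across the tail tests performed in one run."""
    qs = bh_fdr([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
    return list(results)


def mann_whitney_test(a: Sequence[float], b: Sequence[float],
                      alternative: str = "two-sided") -> RankTestResult:
    """Mann-Whitney U comparison of two enrichment-ratio samples.

    Midranks for ties; the exact null distribution when n1*n2 <= 400 and
    the data are tie-free, otherwise the normal approximation with tie
    correction (and continuity correction).
    """
    a, b = np.asarray(list(a), float), np.asarray(list(b), float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) * len(b) <= 400 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return RankTestResult("mann-whitney", float(res.statistic),
                          float(res.pvalue), len(a), len(b), method)


def ks_test(a: Sequence[float], b: Sequence[float]) -> RankTestResult:
    """Two-sample Kolmogorov-Smirnov comparison of enrichment distributions.

    D = sup |ECDF_a - ECDF_b|; exact small-sample p when n1*n2 <= 100,
    else the asymptotic two-sample formula.
    """
    a, b = np.asarray(list(a), float), np.asarray(list(b), float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if len(a) * len(b) <= 100 else "asymp"
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return RankTestResult("kolmogorov-smirnov", float(res.statistic),
                          float(res.pvalue), len(a), len(b), method)


def class_summary(landscape: pd.DataFrame,
                  classes: pd.Series | None = None) -> pd.DataFrame:
    """Per-class median/mean enrichment and % change vs the all-gene mean.

    The percent change of a class is 100 * (class mean - all-gene mean) /
    all-gene mean, the all-gene mean being taken over every detected gene
    in the landscape.
    """
    cls = classes.reindex(landscape.index) if classes is not None \
        else landscape["loc_class"]
    overall = landscape["ratio"].mean()
    rows = []
    for name, group in landscape.groupby(cls, sort=False):
        m = group["ratio"].mean()
        rows.append((name, len(group), group["ratio"].median(), m,
                     100.0 * (m - overall) / overall))
    return pd.DataFrame(rows, columns=["loc_class", "n", "median_ratio",
                                       "mean_ratio", "pct_change_vs_all"]
                        ).set_index("loc_class")


def select_binder_groups(binding: EnrichmentTable | pd.Series,
                         classes: pd.Series, loc_class: str = "MPR",
                         weak_fraction: float = 0.30,
                         overlap_sets: Sequence[Sequence[str]] = (),
                         ) -> tuple[list[str], list[str]]:
    """Weak- and strong-binder gene groups from a binding landscape.

    Weak binders are the class members found among the ``weak_fraction``
    least-bound genes of the full binding landscape (pull-down elution vs
    input); strong binders are an equal-sized group of class members taken
    from the top of the binding-sorted list. Both groups are then
    intersected with every gene set in ``overlap_sets`` (e.g. genes
    detected in all fractions of all strains).
    """
    ratios = binding.ratios if isinstance(binding, EnrichmentTable) else binding
    ranked = percentile_rank(ratios, classes)
    members = ranked[ranked["loc_class"] == loc_class]
    if len(members) == 0:
        raise ValueError(f"no {loc_class} genes in the binding landscape")
    cutoff = int(round(weak_fraction * len(ranked)))
    bottom_ids = set(ranked.head(cutoff).index)
    weak = [g for g in members.index if g in bottom_ids]
    n_weak = len(weak)
    strong = list(members.index[::-1][:n_weak])
    for s in overlap_sets:
        s = set(s)
        weak = [g for g in weak if g in s]
        strong = [g for g in strong if g in s]
    logger.info("binder groups: %d weak, %d strong %s genes",
                len(weak), len(strong), loc_class)
    return weak, strong
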