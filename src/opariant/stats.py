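"""Rank-based inference and resampling intervals.

The analysis convention: a Kruskal–Wallis omnibus across groups, pairwise
two-sided Wilcoxon rank-sum follow-ups (exact for small tie-free groups,
otherwise normal approximation with continuity and tie correction,
Holm-adjusted by default), percentile bootstrap confidence intervals around
group medians (10 000 with-replacement resamples), and a two-group label
permutation test on the median difference.  Significance tiers:
``*`` p<0.05, ``**`` p<0.01, ``***`` p<0.001, ``****`` p<0.0001.

The "permutation" interval language in this field conflates two procedures;
both are provided and explicitly labelled: :func:`median_resampling_ci`
(with-replacement percentile interval, used for the ± bands) and
:func:`two_group_permutation_test` (label permutation, used for p-values).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def significance_stars(p: float) -> str:
    """Significance tier label for a p-value."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


@dataclass(frozen=True)
class GroupComparison:
    groups: Tuple[str, str]
    statistic_name: str
    statistic: float
    p_raw: float
    p_adjusted: float
    medians: Tuple[float, float]
    cis: Tuple[Tuple[float, float], Tuple[float, float]]
    n: Tuple[int, int]
    n_resamples: int
    seed: Optional[int]

    @property
    def stars(self) -> str:
        return significance_stars(self.p_adjusted)

    def to_dict(self) -> dict:
        return {
            "groups": list(self.groups),
            "statistic": self.statistic_name,
            "value": self.statistic,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "stars": self.stars,
            "medians": list(self.medians),
            "ci_low": [ci[0] for ci in self.cis],
            "ci_high": [ci[1] for ci in self.cis],
            "n": list(self.n),
            "n_resamples": self.n_resamples,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    slope: float
    intercept: float
    p: float
    n: int

    @property
    def stars(self) -> str:
        return significance_stars(self.p)

    def to_dict(self) -> dict:
        return {"r": self.r, "slope": self.slope, "intercept": self.intercept,
                "p": self.p, "n": self.n, "stars": self.stars}


def _clean_groups(samples: Sequence[Sequence[float]]) -> List[np.ndarray]:
    cleaned = []
    for i, s in enumerate(samples):
        arr = np.asarray(s, dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {i} is empty")
        finite = arr[np.isfinite(arr)]
        if finite.size == 0:
            raise ValueError(f"group {i} has no finite values")
        cleaned.append(finite)
    return cleaned


def _kw_statistic(pooled_ranks: np.ndarray, sizes: Sequence[int],
                  tie_correction: float) -> float:
    n = len(pooled_ranks)
    h = 0.0
    offset = 0
    for ni in sizes:
        ri = pooled_ranks[offset:offset + ni].mean()
        h += ni * (ri - (n + 1) / 2) ** 2
        offset += ni
    h *= 12.0 / (n * (n + 1))
    return h / tie_correction if tie_correction > 0 else 0.0


def kruskal_wallis(samples: Sequence[Sequence[float]],
                   exact_max_n: int = 10) -> dict:
    """Kruskal–Wallis H with midranks and tie correction.

    Returns ``{"H", "p", "df", "p_exact"}``; the chi-square p always, and for
    total n ≤ ``exact_max_n`` additionally the exact permutation p over all
    assignments of the pooled values to groups.
    """
    groups = _clean_groups(samples)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    h, p = sps.kruskal(*groups)
    out = {"H": float(h), "p": float(p), "df": len(groups) - 1,
           "p_exact": None}

    total = sum(len(g) for g in groups)
    if total <= exact_max_n:
        pooled = np.concatenate(groups)
        ranks = sps.rankdata(pooled)
        ties = np.unique(pooled, return_counts=True)[1]
        correction = 1.0 - (ties ** 3 - ties).sum() / (total ** 3 - total)
        sizes = [len(g) for g in groups]
        observed = _kw_statistic(ranks, sizes, correction)
        count = hits = 0
        for assignment in _group_assignments(total, sizes):
            count += 1
            if _kw_statistic(ranks[assignment], sizes,
                             correction) >= observed - 1e-12:
                hits += 1
        out["p_exact"] = hits / count
    return out


def _group_assignments(n: int, sizes: Sequence[int]):
    """All index orderings that split range(n) into consecutive groups."""
    def rec(remaining: tuple, sizes_left):
        if not sizes_left:
            yield ()
            return
        k = sizes_left[0]
        for chosen in combinations(remaining, k):
            rest = tuple(x for x in remaining if x not in chosen)
            for tail in rec(rest, sizes_left[1:]):
                yield chosen + tail
    for perm in rec(tuple(range(n)), list(sizes)):
        yield np.array(perm)


def rank_sum_test(a, b) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact when both groups have ≤ 8 observations and the pooled data are
    tie-free; otherwise the normal approximation with continuity correction
    and tie-corrected variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and tie_free) \
        else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def pairwise_wilcoxon(samples: Sequence[Sequence[float]],
                      labels: Optional[Sequence[str]] = None,
                      adjust: str = "holm",
                      n_resamples: int = 10000,
                      seed: Optional[int] = None) -> List[GroupComparison]:
    """All pairwise rank-sum tests with multiplicity adjustment.

    ``adjust`` is ``"holm"`` (default) or ``"none"``.  Each comparison
    carries group medians with bootstrap CIs.
    """
    groups = _clean_groups(samples)
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    if adjust not in ("holm", "none"):
        raise ValueError("adjust must be 'holm' or 'none'")

    pairs = list(combinations(range(len(groups)), 2))
    stats_p = [rank_sum_test(groups[i], groups[j]) for i, j in pairs]
    raw = [p for _, p in stats_p]
    if adjust == "holm":
        adjusted = multipletests(raw, method="holm")[1]
    else:
        adjusted = raw

    cis = {}
    for i, g in enumerate(groups):
        sub_seed = None if seed is None else seed + i
        if len(g) >= 2:
            lo, med, hi = median_resampling_ci(g, n_resamples=n_resamples,
                                               seed=sub_seed)
        else:
            lo = med = hi = float(np.median(g))
        cis[i] = (lo, med, hi)

    out = []
    for (i, j), (stat, p_raw), p_adj in zip(pairs, stats_p, adjusted):
        out.append(GroupComparison(
            groups=(labels[i], labels[j]),
            statistic_name="rank-sum U", statistic=stat,
            p_raw=float(p_raw), p_adjusted=float(p_adj),
            medians=(cis[i][1], cis[j][1]),
            cis=((cis[i][0], cis[i][2]), (cis[j][0], cis[j][2])),
            n=(len(groups[i]), len(groups[j])),
            n_resamples=n_resamples, seed=seed))
    return out


def median_resampling_ci(sample, n_resamples: int = 10000,
                         level: float = 0.95,
                         seed: Optional[int] = None,
                         ) -> Tuple[float, float, float]:
    """Percentile interval of the median over with-replacement resamples.

    Returns ``(low, median, high)``.  Deterministic given ``seed``.
    """
    arr = np.asarray(sample, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise ValueError("sample size must be >= 2")
    if n_resamples < 100:
        import warnings
        warnings.warn("n_resamples < 100: interval unstable", stacklevel=2)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(n_resamples, arr.size))
    meds = np.median(arr[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(meds, [alpha, 1.0 - alpha])
    return float(lo), float(np.median(arr)), float(hi)


def _median_diff(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.median(a) - np.median(b))


def two_group_permutation_test(a, b, n_perm: int = 10000,
                               seed: Optional[int] = None,
                               exact_max_n: int = 12) -> float:
    """Two-sided label-permutation p for the group median difference.

    Exact enumeration of all splits when total n ≤ ``exact_max_n``;
    otherwise Monte Carlo with the plus-one correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    na, n = a.size, pooled.size
    observed = abs(_median_diff(a, b))

    if n <= exact_max_n:
        hits = count = 0
        for chosen in combinations(range(n), na):
            mask = np.zeros(n, dtype=bool)
            mask[list(chosen)] = True
            if abs(_median_diff(pooled[mask], pooled[~mask])) \
                    >= observed - 1e-12:
                hits += 1
            count += 1
        return hits / count

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if abs(_median_diff(pooled[perm[:na]], pooled[perm[na:]])) \
                >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def correlation_with_slope(x, y) -> CorrelationResult:
    """Pearson r and least-squares slope with the zero-slope t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 finite (x, y) pairs")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    res = sps.linregress(x, y)
    return CorrelationResult(r=float(res.rvalue), slope=float(res.slope),
                             intercept=float(res.intercept),
                             p=float(res.pvalue), n=int(x.size))
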