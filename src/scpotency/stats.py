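"""Statistical primitives used throughout the analysis.

Two-group differential expression uses the Wilcoxon rank-sum test on
log2(CPM + 1) values; group-level comparisons use Kruskal-Wallis with Dunn's
post hoc z-tests; multiplicity is controlled with Benjamini-Hochberg; gene-set
over-representation uses the upper-tail hypergeometric distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

EXACT_LIMIT = 10  # pooled size at or below which the rank-sum test is enumerated


@dataclass
class TestResult:
    statistic: float
    p_raw: float
    group_sizes: tuple[int, ...]
    p_adj: float | None = None


def signed_fold_change(mean_a: float, mean_b: float, offset: float = 0.01) -> float:
    """Signed fold change of ``mean_a`` relative to ``mean_b``.

    Both means are shifted by ``offset`` (CPM) to guard division by zero.
    Returns a'/b' when a' >= b', else -b'/a'; the magnitude is always >= 1
    and equal means give +1.
    """
    if mean_a < 0 or mean_b < 0:
        raise ValueError("means must be non-negative")
    a = mean_a + offset
    b = mean_b + offset
    if a == b:
        return 1.0
    if a > b:
        return a / b
    return -b / a


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact rank-sum p by enumeration of all group assignments.

    Mid-ranks are used for ties, so the enumeration is over which pooled
    mid-ranks land in the first group.  Returns (U of x, p).
    """
    pooled = np.concatenate([x, y])
    ranks = st.rankdata(pooled)
    nx = len(x)
    rx = ranks[:nx].sum()
    u_obs = rx - nx * (nx + 1) / 2
    mu = nx * len(y) / 2
    dev_obs = abs(u_obs - mu)
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), nx):
        u = ranks[list(idx)].sum() - nx * (nx + 1) / 2
        if abs(u - mu) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return float(u_obs), count / total


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration (mid-ranks for ties) when the pooled size is at most
    10; otherwise the normal approximation with tie-corrected variance and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if len(x) + len(y) <= EXACT_LIMIT:
        u, p = _exact_rank_sum_p(x, y)
        return TestResult(u, p, (len(x), len(y)))
    res = st.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult(float(res.statistic), float(res.pvalue), (len(x), len(y)))


def rank_sum_genes(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorised two-sided rank-sum p-values, one per row (gene).

    ``a`` and ``b`` are (n_genes, n_cells) arrays for the two groups; uses the
    normal approximation with tie correction and continuity correction, i.e.
    the same asymptotic path as :func:`wilcoxon_rank_sum`.  Constant rows
    (zero rank variance) get p = 1.
    """
    na, nb = a.shape[1], b.shape[1]
    n = na + nb
    pooled = np.concatenate([a, b], axis=1)
    ranks = st.rankdata(pooled, axis=1)
    u = ranks[:, :na].sum(axis=1) - na * (na + 1) / 2.0
    mu = na * nb / 2.0
    # tie correction: sum over tie groups of (t^3 - t), per row
    srt = np.sort(pooled, axis=1)
    tie_term = np.empty(pooled.shape[0])
    for i in range(pooled.shape[0]):
        _, counts = np.unique(srt[i], return_counts=True)
        tie_term[i] = np.sum(counts.astype(float) ** 3 - counts)
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    dev = u - mu
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (dev - 0.5 * np.sign(dev)) / np.sqrt(var)
    p = 2.0 * st.norm.sf(np.abs(z))
    p = np.where(var <= 0, 1.0, np.minimum(p, 1.0))
    return p


def kruskal_wallis(groups: list[np.ndarray]) -> TestResult:
    """Kruskal-Wallis H with tie correction; p from chi-square (k-1 df).

    All values identical across groups yields H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    sizes = tuple(len(g) for g in groups)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        # fully tied data: H is 0 by definition (scipy yields 0/0 here)
        return TestResult(0.0, 1.0, sizes)
    h, p = st.kruskal(*groups)
    return TestResult(float(h), float(p), sizes)


def dunn_posthoc(groups: list[np.ndarray], labels: list[str] | None = None) -> pd.DataFrame:
    """Dunn's post hoc pairwise z-tests on pooled ranks, BH-adjusted.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with T the tie term sum(t^3 - t); two-sided normal p-values are BH
    corrected across the reported pairs.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    k = len(groups)
    labels = labels or [str(i) for i in range(k)]
    pooled = np.concatenate(groups)
    n_tot = len(pooled)
    ranks = st.rankdata(pooled)
    mean_ranks = []
    pos = 0
    for g in groups:
        mean_ranks.append(ranks[pos : pos + len(g)].mean())
        pos += len(g)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts.astype(float) ** 3 - counts)
    base_var = n_tot * (n_tot + 1) / 12.0 - tie_term / (12.0 * (n_tot - 1))
    rows = []
    for i, j in combinations(range(k), 2):
        se = np.sqrt(base_var * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * st.norm.sf(abs(z))
        rows.append({"group_a": labels[i], "group_b": labels[j], "z": z, "p_raw": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["p_adj"] = benjamini_hochberg(out["p_raw"].to_numpy())
    return out


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values; order-preserving, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_overrep(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail over-representation p-value P(X >= k), X ~ Hypergeom(N, K, n).

    ``k`` observed overlap, ``K`` gene-set size, ``n`` query size, ``N``
    background size; evaluated in log space for numerical stability.
    """
    if not (0 <= k <= min(K, n)) or K > N or n > N:
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    support = np.arange(k, min(K, n) + 1)
    if support.size == 0:
        return 0.0
    logp = st.hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))
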