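"""Shared nonparametric and empirical-Bayes statistical primitives.

The exact branches of the signed-rank and rank-sum tests are computed by
generating-function dynamic programming over integer (doubled-midrank)
supports, so tied absolute values are handled exactly; the large-sample
branches use the normal approximation with tie and continuity corrections.
scipy's implementations of the same tests are used only as independent
cross-checks in the test suite, never here.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import special
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# one-sample Wilcoxon signed-rank test on paired differences
# ---------------------------------------------------------------------------

def paired_signed_rank(deltas, exact_max_n: int = 25) -> float:
    """Two-sided p-value for the median of paired differences being zero.

    Zero differences are discarded before ranking (Wilcoxon's original
    handling); tied absolute differences share midranks.  The exact null
    distribution of W+ is enumerated (as a sign-flip generating function over
    doubled midranks) when the number of nonzero differences is at most
    ``exact_max_n``; otherwise the normal approximation with tie and
    continuity corrections is used.

    Returns 1.0 with a warning when every difference is zero.
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size == 0:
        raise ValueError("no paired differences supplied")
    nonzero = deltas[deltas != 0]
    if nonzero.size == 0:
        warnings.warn("all paired differences are zero; p set to 1", stacklevel=2)
        return 1.0
    n = nonzero.size
    ranks = rankdata(np.abs(nonzero))
    w_plus = float(ranks[nonzero > 0].sum())
    if n <= exact_max_n:
        return _signed_rank_exact(ranks, w_plus)
    return _signed_rank_normal(ranks, w_plus, n)


def _signed_rank_exact(ranks: np.ndarray, w_plus: float) -> float:
    # doubled midranks are integers; W2+ distribution via polynomial product
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[:-r].copy()
    w2 = int(round(2 * w_plus))
    n_assign = counts.sum()  # == 2**n, exact in double for n <= 25
    cdf = counts[: w2 + 1].sum() / n_assign
    sf = counts[w2:].sum() / n_assign
    return float(min(1.0, 2.0 * min(cdf, sf)))


def _signed_rank_normal(ranks: np.ndarray, w_plus: float, n: int) -> float:
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return 1.0
    d = w_plus - mean
    # continuity correction toward the mean
    d = np.sign(d) * max(abs(d) - 0.5, 0.0)
    z = d / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# two-sample Wilcoxon rank-sum test on rank partitions
# ---------------------------------------------------------------------------

#: exact enumeration is used when the smaller group has at most this many
#: members; beyond EXACT_MAX_TOTAL ranked items the DP cost is prohibitive
#: and the normal approximation takes over regardless.
RANKSUM_EXACT_MAX_GROUP = 12
RANKSUM_EXACT_MAX_TOTAL = 2000


def ranksum_p(fore_ranks, back_ranks) -> float:
    """Two-sided Wilcoxon rank-sum p comparing two groups of rank values.

    Exact when the smaller group has ≤ ``RANKSUM_EXACT_MAX_GROUP`` members
    (and the total is small enough for the subset-sum DP); otherwise normal
    approximation with tie and continuity corrections.  Rank values may be
    midranks (ties allowed); the exact branch requires untied integer ranks
    and falls back to the approximation when ties are present.
    """
    fore = np.asarray(fore_ranks, dtype=float)
    back = np.asarray(back_ranks, dtype=float)
    if fore.size == 0 or back.size == 0:
        raise ValueError("both rank groups must be non-empty")
    n1, n2 = fore.size, back.size
    n = n1 + n2
    all_ranks = np.concatenate([fore, back])
    untied = np.array_equal(np.sort(all_ranks), np.arange(1, n + 1))
    if (
        min(n1, n2) <= RANKSUM_EXACT_MAX_GROUP
        and n <= RANKSUM_EXACT_MAX_TOTAL
        and untied
    ):
        return _ranksum_exact(fore, n1, n2)
    return _ranksum_normal(fore, all_ranks, n1, n2)


def _ranksum_exact(fore: np.ndarray, n1: int, n2: int) -> float:
    # work with the smaller group's Mann-Whitney U statistic
    if n1 <= n2:
        k, other = n1, n2
        w = fore.sum()
    else:
        k, other = n2, n1
        n = n1 + n2
        w = n * (n + 1) / 2 - fore.sum()
    u = int(round(w - k * (k + 1) / 2))
    counts = mannwhitney_counts(k, other)
    total = counts.sum()
    cdf = counts[: u + 1].sum() / total
    sf = counts[u:].sum() / total
    return float(min(1.0, 2.0 * min(cdf, sf)))


def mannwhitney_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution of the Mann-Whitney U statistic as subset counts.

    ``counts[u]`` is the number of ways to choose ``n1`` foreground ranks out
    of ``n1 + n2`` untied ranks such that exactly ``u`` (foreground,
    background) pairs have the foreground rank larger.  Recurrence on the
    largest pooled rank: f(k, j, u) = f(k, j-1, u) + f(k-1, j, u-j).  Counts
    are exact in double precision for the sizes the exact branch allows.
    """
    umax = n1 * n2
    # counts[k, u] = f(k, j, u); j advances in the outer loop
    counts = np.zeros((n1 + 1, umax + 1))
    counts[:, 0] = 1.0  # f(k, 0, 0) = 1: all-foreground pools have U = 0
    for j in range(1, n2 + 1):
        new = np.zeros_like(counts)
        new[0, 0] = 1.0
        for k in range(1, n1 + 1):
            new[k] = counts[k]  # largest rank is background
            new[k, j:] += new[k - 1, : umax + 1 - j]  # largest is foreground
        counts = new
    return counts[n1]


def _ranksum_normal(
    fore: np.ndarray, all_ranks: np.ndarray, n1: int, n2: int
) -> float:
    n = n1 + n2
    w = fore.sum()
    mean = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(all_ranks, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / ((n) * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    d = w - mean
    d = np.sign(d) * max(abs(d) - 0.5, 0.0)
    z = d / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation (moderated t hyperparameters)
# ---------------------------------------------------------------------------

def fit_moderation(sample_variances, dfs) -> tuple[float, float]:
    """Moment-match the scaled-F prior for gene-wise variances.

    Given per-gene sample variances s² with residual degrees of freedom df,
    fits the prior s² ~ s0²·(d0/χ²_{d0}) by matching the mean and variance of
    log s², returning ``(d0, s0_sq)``.  ``d0 = inf`` (complete shrinkage to a
    common value) is returned when the empirical spread of log-variances does
    not exceed the sampling floor.
    """
    s2 = np.asarray(sample_variances, dtype=float)
    df = np.broadcast_to(np.asarray(dfs, dtype=float), s2.shape).astype(float)
    keep = (s2 > 0) & (df > 0)
    if keep.sum() < 2:
        raise ValueError("need at least two positive variances to fit the prior")
    s2, df = s2[keep], df[keep]
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1)
    if evar <= 1e-15 * (1.0 + emean**2):
        # literally constant sample variances: degenerate prior at that value
        return float("inf"), float(s2[0])
    evar_adj = evar - np.mean(special.polygamma(1, df / 2.0))
    if evar_adj <= 0:
        return float("inf"), float(np.exp(emean))
    half_d0 = _trigamma_inverse(evar_adj)
    d0 = 2.0 * half_d0
    s0_sq = np.exp(emean + special.digamma(half_d0) - np.log(half_d0))
    return float(d0), float(s0_sq)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def moderated_t_from_stats(
    effects, s2, dfs, stderr_scale, d0: float, s0_sq: float
):
    """Moderated t statistics and two-sided p-values from summary statistics.

    Parameters
    ----------
    effects
        Per-gene effect estimates (e.g. mean group difference).
    s2, dfs
        Per-gene sample variances and their residual degrees of freedom.
    stderr_scale
        Multiplier c such that SE(effect) = sqrt(c · s̃²) (e.g. 1/n1 + 1/n2
        for a two-sample comparison, 1/n for paired differences).
    d0, s0_sq
        Prior degrees of freedom and prior variance; ``d0=0`` gives the
        ordinary t, ``d0=inf`` fully pooled prior variance.
    """
    from scipy.stats import t as t_dist

    effects = np.asarray(effects, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(dfs, dtype=float), s2.shape).astype(float)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(s2, np.inf)
    elif d0 == 0:
        s2_post = s2
        df_total = df
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effects / np.sqrt(stderr_scale * s2_post)
    p = np.where(
        np.isinf(df_total),
        2.0 * norm.sf(np.abs(t)),
        2.0 * t_dist.sf(np.abs(t), np.where(np.isinf(df_total), 1.0, df_total)),
    )
    return t, np.clip(p, 0.0, 1.0)
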