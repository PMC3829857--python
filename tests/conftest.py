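"""Shared fixtures and oracle helpers for the test suite."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from psormod.datatypes import IUPAC_CODES, MotifModel, iupac_complement


def motif_from_consensus(consensus: str, motif_id: str | None = None) -> MotifModel:
    """Uniform-PPM motif realizing an IUPAC consensus."""
    ppm = np.zeros((4, len(consensus)))
    for j, code in enumerate(consensus):
        bases = sorted(IUPAC_CODES[code])
        for b in bases:
            ppm["ACGT".index(b), j] = 1.0 / len(bases)
    return MotifModel(motif_id=motif_id or consensus, ppm=ppm,
                      consensus=consensus)


def naive_scan_count(seq: str, consensus: str) -> int:
    """Position-by-position two-strand scan oracle (O(L·m))."""

    def matches(window: str, cons: str) -> bool:
        return all(
            ch != "N" and ch in IUPAC_CODES[cc] for ch, cc in zip(window, cons)
        )

    rc = iupac_complement(consensus)
    m = len(consensus)
    return sum(
        1
        for i in range(len(seq) - m + 1)
        if matches(seq[i : i + m], consensus) or matches(seq[i : i + m], rc)
    )


def enumerate_ranksum_p(fore_ranks, n_total: int) -> float:
    """Two-sided rank-sum p by full enumeration of all rank configurations."""
    fore = sorted(int(r) for r in fore_ranks)
    k = len(fore)
    w_obs = sum(fore)
    sums = [sum(c) for c in itertools.combinations(range(1, n_total + 1), k)]
    total = len(sums)
    cdf = sum(1 for s in sums if s <= w_obs) / total
    sf = sum(1 for s in sums if s >= w_obs) / total
    return min(1.0, 2.0 * min(cdf, sf))


def subset_sum_ranksum_p(fore_ranks, n_total: int) -> float:
    """Two-sided rank-sum p via an item-by-item subset-sum DP.

    Structured differently from the package's U-space recurrence: counts
    k-subsets of {1..N} by rank sum directly.
    """
    fore = np.asarray(fore_ranks, dtype=float)
    k = len(fore)
    w_obs = int(round(fore.sum()))
    smax = sum(range(n_total - k + 1, n_total + 1))
    dp = np.zeros((k + 1, smax + 1))
    dp[0, 0] = 1.0
    for item in range(1, n_total + 1):
        for kk in range(min(k, item), 0, -1):
            dp[kk, item:] += dp[kk - 1, : smax + 1 - item]
    dist = dp[k]
    total = dist.sum()
    cdf = dist[: w_obs + 1].sum() / total
    sf = dist[w_obs:].sum() / total
    return min(1.0, 2.0 * min(cdf, sf))


def normal_ranksum_p(fore_ranks, n_total: int) -> float:
    """Normal-approximation rank-sum p (continuity corrected), via erfc."""
    fore = np.asarray(fore_ranks, dtype=float)
    n1 = len(fore)
    n2 = n_total - n1
    w = fore.sum()
    mean = n1 * (n_total + 1) / 2.0
    var = n1 * n2 * (n_total + 1) / 12.0
    d = w - mean
    d = math.copysign(max(abs(d) - 0.5, 0.0), d)
    z = abs(d) / math.sqrt(var)
    return min(1.0, 2.0 * 0.5 * math.erfc(z / math.sqrt(2.0)))


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
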