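"""Motif dictionary handling, sequence masking, scanning, and GAM enrichment.

Motif occurrences are exact IUPAC-consensus matches counted on both strands
with overlaps allowed; windows containing masked ('N') bases never match.
Masking covers interval masks (coding sequence, assembly gaps, repeats; BED
0-based half-open) and an optional conservation mask: bases scoring below
the median PhastCons score of the still-unmasked sequence are masked, with
the threshold capped at 0.70 when the median exceeds it.

Association between module membership and motif frequency is tested with a
semiparametric generalized additive logistic model: membership ~ s(x₁) + β·x₂
with x₁ = log scanned length entering as a penalized cubic P-spline smooth
(4 effective degrees of freedom by default) and x₂ = log(1 + occurrence
count) as a parametric term.  The reported statistic is Z = β̂/SE(β̂); the
smooth absorbs any dependence of membership on sequence length, which would
otherwise confound count-based enrichment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.stats import norm

from psormod.datatypes import IUPAC_CODES, MotifModel, iupac_complement
from psormod.stats import bh_adjust

logger = logging.getLogger(__name__)

MIN_MOTIF_LENGTH = 4
PPM_REDUNDANCY_EPS = 0.02
PHASTCONS_CAP = 0.70
SMOOTH_DF = 4.0
REPORTABLE_Q = 0.10
REPORTABLE_FRAC = 0.05


# ---------------------------------------------------------------------------
# dictionary
# ---------------------------------------------------------------------------

def dedupe_dictionary(motifs: list[MotifModel]) -> list[MotifModel]:
    """Drop short and redundant motifs, keeping first occurrences.

    Motifs shorter than 4 bp are removed first.  A motif is redundant with a
    retained motif when both have the same consensus and the mean absolute
    difference between corresponding PPM entries is below 0.02.
    """
    retained: list[MotifModel] = []
    for motif in motifs:
        if motif.length < MIN_MOTIF_LENGTH:
            logger.info("motif %s dropped: length %d < %d",
                        motif.motif_id, motif.length, MIN_MOTIF_LENGTH)
            continue
        redundant = False
        for kept in retained:
            if kept.consensus == motif.consensus and kept.length == motif.length:
                if np.abs(kept.ppm - motif.ppm).mean() < PPM_REDUNDANCY_EPS:
                    redundant = True
                    break
        if redundant:
            logger.info("motif %s dropped: redundant", motif.motif_id)
        else:
            retained.append(motif)
    return retained


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------

@dataclass
class MaskedSequence:
    """A gene-adjacent sequence with masked positions set to 'N'."""

    gene_id: str
    bases: str
    region_kind: str = "intergenic"

    @property
    def length(self) -> int:
        return len(self.bases)

    @property
    def scanned_length(self) -> int:
        return self.length - self.bases.count("N")


def apply_masks(
    seq: str | MaskedSequence,
    mask_intervals: list[tuple[int, int]],
    gene_id: str = "",
    region_kind: str = "intergenic",
) -> MaskedSequence:
    """Mask 0-based half-open intervals to 'N'.

    Intervals extending beyond the sequence are clipped with a warning.
    """
    if isinstance(seq, MaskedSequence):
        gene_id = gene_id or seq.gene_id
        region_kind = seq.region_kind
        seq = seq.bases
    arr = np.frombuffer(seq.upper().encode(), dtype="S1").copy()
    n = len(arr)
    for start, end in mask_intervals:
        if start < 0 or end > n:
            warnings.warn(
                f"interval ({start}, {end}) clipped to sequence bounds [0, {n})",
                stacklevel=2,
            )
        arr[max(start, 0) : min(end, n)] = b"N"
    return MaskedSequence(gene_id=gene_id, bases=arr.tobytes().decode(),
                          region_kind=region_kind)


def conservation_mask(
    seq: MaskedSequence, scores: np.ndarray, cap: float = PHASTCONS_CAP
) -> MaskedSequence:
    """Mask weakly conserved bases by the median-or-0.70 rule.

    The threshold is the median PhastCons score over the still-unmasked
    bases, capped at ``cap``; bases scoring strictly below the threshold are
    masked.  Runs after interval masking.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size != seq.length:
        raise ValueError(
            f"scores length {scores.size} != sequence length {seq.length}"
        )
    arr = np.frombuffer(seq.bases.encode(), dtype="S1").copy()
    unmasked = arr != b"N"
    if not unmasked.any():
        return seq
    threshold = min(float(np.median(scores[unmasked])), cap)
    arr[unmasked & (scores < threshold)] = b"N"
    return MaskedSequence(gene_id=seq.gene_id, bases=arr.tobytes().decode(),
                          region_kind=seq.region_kind)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

_CODE_OF = {b: i for i, b in enumerate("ACGTN")}


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE_OF.get(c, 4) for c in seq], dtype=np.int8)


def _match_table(consensus: str) -> np.ndarray:
    """(L, 5) boolean table: does sequence code c match consensus position j.

    The masked code 'N' (column 4) never matches, even a motif 'N'.
    """
    table = np.zeros((len(consensus), 5), dtype=bool)
    for j, code in enumerate(consensus):
        for base in IUPAC_CODES[code]:
            table[j, _CODE_OF[base]] = True
    return table


def occurrence_positions(
    seq: str | MaskedSequence, motif: MotifModel
) -> np.ndarray:
    """Start positions where the motif matches on either strand.

    Overlapping matches count; a position matching on both strands counts
    once.  Matching is exact against the IUPAC consensus; any masked base in
    the window disqualifies it.
    """
    bases = seq.bases if isinstance(seq, MaskedSequence) else seq.upper()
    m = motif.length
    L = len(bases)
    if L < m:
        return np.array([], dtype=int)
    codes = _encode(bases)
    n_win = L - m + 1
    hit = np.zeros(n_win, dtype=bool)
    for consensus in {motif.consensus, iupac_complement(motif.consensus)}:
        table = _match_table(consensus)
        acc = np.ones(n_win, dtype=bool)
        for j in range(m):
            acc &= table[j][codes[j : j + n_win]]
        hit |= acc
    return np.flatnonzero(hit)


def count_occurrences(seq: str | MaskedSequence, motif: MotifModel) -> int:
    """Number of motif occurrences on either strand (overlaps counted)."""
    return int(occurrence_positions(seq, motif).size)


# ---------------------------------------------------------------------------
# semiparametric GAM logistic enrichment test
# ---------------------------------------------------------------------------

@dataclass
class GamResult:
    """Enrichment of one motif near module genes."""

    motif_id: str
    z: float
    p: float
    beta: float
    frac_with_site: float
    converged: bool
    q: float | None = None
    reportable: bool | None = None


def _pspline_basis(x: np.ndarray, n_basis: int = 10, degree: int = 3):
    """Cubic B-spline design matrix with quantile knots + 2nd-order penalty."""
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        return None, None
    n_interior = n_basis - degree - 1
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.unique(np.quantile(x, qs))
        interior = interior[(interior > lo) & (interior < hi)]
    else:
        interior = np.array([])
    t = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    B = BSpline.design_matrix(x, t, degree, extrapolate=True).toarray()
    k = B.shape[1]
    D = np.diff(np.eye(k), n=2, axis=0)
    return B, D.T @ D


def gam_motif_test(
    membership: np.ndarray,
    x1: np.ndarray,
    x2: np.ndarray,
    motif_id: str = "",
    smooth_df: float = SMOOTH_DF,
    n_basis: int = 10,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> GamResult:
    """Logistic GAM test of motif-count association with module membership.

    Fits logit P(member) = α + β·x₂ + f(x₁) by penalized IRLS, where f is a
    cubic P-spline with the penalty tuned so the smooth has ``smooth_df``
    effective degrees of freedom.  Z = β̂/SE(β̂) with a two-sided normal p.
    A constant x₂ yields Z = 0, p = 1; complete separation is flagged with
    NaN statistics.
    """
    y = np.asarray(membership, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if not (y.size == x1.size == x2.size):
        raise ValueError("membership, x1, x2 must have equal length")
    n_member = int(y.sum())
    if n_member < 2 or y.size - n_member < 2:
        raise ValueError("need >=2 members and >=2 non-members")
    frac = float(np.mean(x2[y == 1] > 0))
    if np.ptp(x2) == 0:
        return GamResult(motif_id=motif_id, z=0.0, p=1.0, beta=0.0,
                         frac_with_site=frac, converged=True)

    B, S_raw = _pspline_basis(x1, n_basis=n_basis)
    if B is None:
        # degenerate x1: ordinary logistic on x2 alone
        X = np.column_stack([np.ones_like(y), x2])
        S = np.zeros((2, 2))
        beta_idx = 1
    else:
        # the basis satisfies sum_j B_ij = 1, so a constant shift of the
        # spline coefficients is an intercept shift; project that direction
        # out to keep [intercept, x2, smooth] full rank
        k = B.shape[1]
        Q = _null_of_ones(k)
        B2 = (B - B.mean(axis=0, keepdims=True)) @ Q
        S2 = Q.T @ S_raw @ Q
        X = np.column_stack([np.ones_like(y), x2, B2])
        lam = _lambda_for_df(X, S2, smooth_df, n_para=2)
        S = np.zeros((X.shape[1], X.shape[1]))
        S[2:, 2:] = lam * S2
        beta_idx = 1

    beta_hat, info_pen, converged = _pirls(y, X, S, max_iter=max_iter, tol=tol)
    if not converged or abs(beta_hat[beta_idx]) > 15.0:
        return GamResult(motif_id=motif_id, z=float("nan"), p=float("nan"),
                         beta=float(beta_hat[beta_idx]), frac_with_site=frac,
                         converged=False)
    cov = np.linalg.inv(info_pen)
    se = float(np.sqrt(cov[beta_idx, beta_idx]))
    z = float(beta_hat[beta_idx] / se)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return GamResult(motif_id=motif_id, z=z, p=p,
                     beta=float(beta_hat[beta_idx]), frac_with_site=frac,
                     converged=True)


def _null_of_ones(k: int) -> np.ndarray:
    """Orthonormal basis of the complement of the all-ones vector in R^k."""
    from scipy.linalg import null_space

    return null_space(np.ones((1, k)))


def _lambda_for_df(X, S_raw, target_df, n_para, w0: float = 0.25):
    """Penalty weight giving the smooth ``target_df`` effective df.

    Effective df = trace of the smoother restricted to the spline block,
    evaluated at the null-model IRLS weights (p = 0.5); bisection on log λ.
    """
    XtWX = w0 * X.T @ X
    k = X.shape[1]

    def smooth_edf(log_lam):
        S = np.zeros((k, k))
        S[n_para:, n_para:] = 10.0**log_lam * S_raw
        F = np.linalg.solve(XtWX + S, XtWX)
        return np.trace(F[n_para:, n_para:])

    lo, hi = -8.0, 12.0
    if smooth_edf(lo) < target_df:
        return 10.0**lo
    if smooth_edf(hi) > target_df:
        return 10.0**hi
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if smooth_edf(mid) > target_df:
            lo = mid
        else:
            hi = mid
    return 10.0 ** ((lo + hi) / 2.0)


def _pirls(y, X, S, max_iter=100, tol=1e-8):
    """Penalized IRLS for the logistic additive model."""
    beta = np.zeros(X.shape[1])
    beta[0] = np.log((y.mean() + 1e-6) / (1 - y.mean() + 1e-6))
    dev_old = np.inf
    info_pen = None
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = X.T * w
        info_pen = XtW @ X + S
        try:
            beta_new = np.linalg.solve(info_pen, XtW @ z)
        except np.linalg.LinAlgError:
            return beta, info_pen, False
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = -2.0 * np.sum(
                y * np.log(np.clip(mu, 1e-12, None))
                + (1 - y) * np.log(np.clip(1 - mu, 1e-12, None))
            )
        if not np.isfinite(dev):
            return beta, info_pen, False
        beta = beta_new
        if abs(dev_old - dev) < tol * (abs(dev) + 0.1):
            return beta, info_pen, True
        dev_old = dev
    return beta, info_pen, False


def naive_logistic_z(membership, x2) -> float:
    """Z for x₂ from a plain logistic fit *without* the length smooth.

    The contrast partner of the GAM in confounding analyses: when counts
    scale with sequence length and membership is length-correlated, this Z
    inflates while the GAM Z stays calibrated.
    """
    y = np.asarray(membership, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if np.ptp(x2) == 0:
        return 0.0
    X = np.column_stack([np.ones_like(y), x2])
    beta, info, converged = _pirls(y, X, np.zeros((2, 2)))
    if not converged:
        return float("nan")
    cov = np.linalg.inv(info)
    return float(beta[1] / np.sqrt(cov[1, 1]))


# ---------------------------------------------------------------------------
# module screens and hotspot scan
# ---------------------------------------------------------------------------

def screen_module(
    members: set[str],
    dictionary: list[MotifModel],
    sequences: dict[str, MaskedSequence],
    smooth_df: float = SMOOTH_DF,
) -> list[GamResult]:
    """GAM-screen a motif dictionary against one module.

    The analysis universe is every gene with a sequence of positive scanned
    length; membership is intersected with it.  BH across motifs; results
    are sorted by p.  A result is ``reportable`` when q < 0.10 and at least
    5% of module genes carry ≥ 1 occurrence.
    """
    genes = [g for g, s in sequences.items() if s.scanned_length > 0]
    dropped = len(sequences) - len(genes)
    if dropped:
        logger.warning("%d sequences fully masked; excluded from screen", dropped)
    y = np.array([g in members for g in genes], dtype=float)
    x1 = np.log(np.array([sequences[g].scanned_length for g in genes], float))
    results: list[GamResult] = []
    for motif in dictionary:
        counts = np.array([count_occurrences(sequences[g], motif) for g in genes])
        x2 = np.log1p(counts)
        results.append(
            gam_motif_test(y, x1, x2, motif_id=motif.motif_id,
                           smooth_df=smooth_df)
        )
    pvals = np.array([1.0 if np.isnan(r.p) else r.p for r in results])
    qvals = bh_adjust(pvals)
    for r, q in zip(results, qvals):
        r.q = float(q)
        r.reportable = bool(
            not np.isnan(r.p)
            and r.q < REPORTABLE_Q
            and r.frac_with_site >= REPORTABLE_FRAC
        )
    return sorted(results, key=lambda r: (np.isnan(r.p), r.p))


def hotspot_scan(
    seq: MaskedSequence,
    enriched_motifs: list[MotifModel],
    window_sizes: tuple[int, ...] = (400, 200, 100, 50),
) -> dict[int, tuple[int, int, int]]:
    """Best window per size by total enriched-motif site count.

    Sites are localized by match start (either strand, all motifs pooled);
    per window size the left-most window maximizing the number of site
    starts inside it wins.  Window sizes longer than the sequence are
    skipped with a warning.
    """
    starts: set[int] = set()
    for motif in enriched_motifs:
        starts.update(int(i) for i in occurrence_positions(seq, motif))
    site = np.zeros(seq.length, dtype=int)
    for i in starts:
        site[i] = 1
    csum = np.concatenate([[0], np.cumsum(site)])
    best: dict[int, tuple[int, int, int]] = {}
    for w in window_sizes:
        if w > seq.length:
            warnings.warn(
                f"window {w} exceeds sequence length {seq.length}; skipped",
                stacklevel=2,
            )
            continue
        counts = csum[w:] - csum[:-w]
        start = int(np.argmax(counts))  # argmax takes the left-most maximum
        best[w] = (start, start + w, int(counts[start]))
    return best
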