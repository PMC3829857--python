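"""Rank-based gene-set enrichment and differentially-expressed-module calls.

Genes are ranked by the signed score I × −log10(p) from a differential test
(I = +1 for increased, −1 for decreased expression).  Enrichment of a
foreground set is measured by the area between its cumulative detection-rate
curve and the diagonal; the p-value of that area is the two-sided Wilcoxon
rank-sum p comparing foreground and background rank values — the two views
are equivalent because the normalized area is a linear function of the
foreground rank sum.

A module is a DEM (differentially expressed module) when GSEA FDR < 0.05
together with a median-of-medians fold-change score > 1.25 or < 0.80, or
when its overlap with the DEG sets is significant by Fisher's exact test at
FDR < 0.05 (proportion route).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom
from scipy.stats.contingency import odds_ratio as _odds_ratio

from psormod.datatypes import GeneModule
from psormod.stats import bh_adjust, ranksum_p

# DEM gates
DEM_GSEA_Q = 0.05
DEM_FC_UP = 1.25
DEM_FC_DOWN = 0.80
DEM_FISHER_Q = 0.05

#: cap on −log10(p) when a differential test reports p == 0
LOGP_CAP = 300.0


@dataclass
class RankedGeneList:
    """Genes in decreasing order of the signed score I × −log10(p)."""

    genes: list[str]
    score: dict[str, float]

    tie_policy = "equal scores ordered by gene id (stable)"

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranking")

    @property
    def n(self) -> int:
        return len(self.genes)

    def ranks_of(self, foreground: set[str]) -> np.ndarray:
        """1-based rank positions of the foreground genes."""
        idx = [i + 1 for i, g in enumerate(self.genes) if g in foreground]
        return np.asarray(idx, dtype=float)


def rank_by_signed_logp(stats: pd.DataFrame) -> RankedGeneList:
    """Build a ranking from per-gene columns ``p`` and ``direction``.

    Scores are direction × −log10(p), sorted descending; p = 0 is clamped to
    a score magnitude of ``LOGP_CAP`` with a warning.  Score ties are broken
    by gene id, so the ordering is deterministic.
    """
    p = stats["p"].to_numpy(dtype=float)
    direction = stats["direction"].to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not np.all(np.isin(direction, [-1.0, 1.0])):
        raise ValueError("direction must be -1 or +1")
    zero = p == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero p-values clamped to -log10 p = {LOGP_CAP}",
            stacklevel=2,
        )
    with np.errstate(divide="ignore"):
        logp = np.where(zero, LOGP_CAP, -np.log10(np.where(zero, 1.0, p)))
    score = direction * logp
    order = sorted(
        range(len(score)), key=lambda i: (-score[i], str(stats.index[i]))
    )
    genes = [str(stats.index[i]) for i in order]
    return RankedGeneList(genes=genes, score={g: float(s) for g, s in
                                              zip(genes, score[order])})


@dataclass
class GseaResult:
    """Detection-rate-curve enrichment of one foreground set."""

    area: float
    p: float
    direction: str  # "increased" | "decreased"
    n_fore: int
    n_back: int
    q: float | None = None


def drc_area(ranking: RankedGeneList, foreground: set[str]) -> GseaResult:
    """Area between the foreground detection-rate curve and the diagonal.

    The curve tracks the cumulative fraction of foreground genes recovered
    while walking the ranking from the top; both axes are normalized to
    [0, 1], so the signed area lies in (−1, 1) and is positive when the
    foreground concentrates at low ranks (increased expression).  The
    p-value is the two-sided rank-sum p on foreground vs background rank
    values (exact for small foregrounds, normal approximation otherwise).
    """
    fore_in = foreground & set(ranking.genes)
    if not fore_in:
        raise ValueError("foreground has no genes in the ranking")
    if len(fore_in) == ranking.n:
        raise ValueError("foreground equals the ranking; background is empty")
    n = ranking.n
    fore_ranks = ranking.ranks_of(fore_in)
    back_ranks = np.setdiff1d(np.arange(1, n + 1, dtype=float), fore_ranks)

    is_fore = np.zeros(n, dtype=bool)
    is_fore[fore_ranks.astype(int) - 1] = True
    curve = np.cumsum(is_fore) / len(fore_ranks)
    diagonal = np.arange(1, n + 1) / n
    area = float(np.mean(curve - diagonal))

    p = ranksum_p(fore_ranks, back_ranks)
    return GseaResult(
        area=area,
        p=p,
        direction="increased" if area >= 0 else "decreased",
        n_fore=len(fore_ranks),
        n_back=n - len(fore_ranks),
    )


def plot_drc(ranking: RankedGeneList, foreground: set[str], ax=None,
             label: str | None = None):
    """Plot the foreground detection-rate curve against the diagonal.

    Returns the matplotlib axes; the shaded region is the signed area the
    statistic measures.
    """
    import matplotlib.pyplot as plt

    res = drc_area(ranking, foreground)
    n = ranking.n
    fore_ranks = ranking.ranks_of(foreground & set(ranking.genes))
    is_fore = np.zeros(n, dtype=bool)
    is_fore[fore_ranks.astype(int) - 1] = True
    x = np.arange(1, n + 1) / n
    curve = np.cumsum(is_fore) / len(fore_ranks)
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.plot(x, curve, lw=1.5,
            label=label or f"area={res.area:.3f}, p={res.p:.2g}")
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=1)
    ax.fill_between(x, curve, x, alpha=0.2)
    ax.set_xlabel("rank fraction")
    ax.set_ylabel("foreground detection rate")
    ax.legend(frameon=False)
    return ax


def fisher_overlap(
    foreground: set[str], annotation: set[str], universe: set[str]
) -> tuple[float, float]:
    """Two-sided Fisher exact test of overlap within a gene universe.

    Returns ``(odds_ratio, p)``; the odds ratio is the conditional maximum
    likelihood estimate from the 2×2 table.
    """
    if not universe:
        raise ValueError("empty universe")
    fore = foreground & universe
    anno = annotation & universe
    a = len(fore & anno)
    b = len(fore - anno)
    c = len(anno - fore)
    d = len(universe) - a - b - c
    table = [[a, b], [c, d]]
    p = float(fisher_exact(table, alternative="two-sided")[1])
    oddsr = float(_odds_ratio(table, kind="conditional").statistic)
    return oddsr, p


@dataclass
class DemCall:
    """DEM decision for one module with the route that fired."""

    module_id: str
    is_dem: bool
    route: str | None  # "gsea_fc" | "fisher_proportion" | None
    direction: str | None
    gsea_p: float
    gsea_q: float
    fc_score: float
    fisher_q: float


def call_dems(
    modules: list[GeneModule],
    gsea: dict[str, GseaResult],
    deg_up: set[str],
    deg_down: set[str],
    universe: set[str],
    gsea_q_max: float = DEM_GSEA_Q,
    fc_up: float = DEM_FC_UP,
    fc_down: float = DEM_FC_DOWN,
    fisher_q_max: float = DEM_FISHER_Q,
) -> list[DemCall]:
    """Call DEMs under the dual GSEA+FC / Fisher-proportion gates.

    GSEA q-values are BH-adjusted across all modules supplied (one family);
    the Fisher route adjusts, per module, the smaller of the up/down overlap
    p-values across the same family.  ``fc_score`` must be present on every
    module.  When both routes fire, the GSEA route is recorded.
    """
    ids = [m.module_id for m in modules]
    missing = [i for i in ids if i not in gsea]
    if missing:
        raise ValueError(f"no GSEA result for modules: {missing[:5]}")
    if any(m.fc_score is None for m in modules):
        raise ValueError("every module needs an fc_score before DEM calling")

    gsea_q = bh_adjust([gsea[i].p for i in ids])
    for i, q in zip(ids, gsea_q):
        gsea[i].q = float(q)

    fisher_p, fisher_dir = [], []
    for m in modules:
        members = set(m.members)
        _, p_up = fisher_overlap(members, deg_up, universe)
        _, p_down = fisher_overlap(members, deg_down, universe)
        if p_up <= p_down:
            fisher_p.append(p_up)
            fisher_dir.append("increased")
        else:
            fisher_p.append(p_down)
            fisher_dir.append("decreased")
    fisher_q = bh_adjust(fisher_p)

    calls = []
    for k, m in enumerate(modules):
        res = gsea[m.module_id]
        fc = float(m.fc_score)
        gsea_fires = bool(res.q < gsea_q_max and (fc > fc_up or fc < fc_down))
        fisher_fires = bool(fisher_q[k] < fisher_q_max)
        if gsea_fires:
            route = "gsea_fc"
            direction = "increased" if fc > 1.0 else "decreased"
        elif fisher_fires:
            route = "fisher_proportion"
            direction = fisher_dir[k]
        else:
            route, direction = None, None
        calls.append(
            DemCall(
                module_id=m.module_id,
                is_dem=gsea_fires or fisher_fires,
                route=route,
                direction=direction,
                gsea_p=res.p,
                gsea_q=res.q,
                fc_score=fc,
                fisher_q=float(fisher_q[k]),
            )
        )
    return calls


def annotation_enrichment(
    members: set[str],
    term_map: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of annotation terms.

    For each term, tests whether term genes are over-represented among
    ``members`` relative to the universe; BH across terms.  Returns a
    DataFrame indexed by term with columns ``overlap``, ``term_size``,
    ``p``, ``q``.
    """
    members = members & universe
    n_universe = len(universe)
    n_members = len(members)
    rows = []
    for term, genes in term_map.items():
        term_genes = genes & universe
        k = len(members & term_genes)
        # P(X >= k) for X ~ Hypergeom(N, |term|, |members|)
        p = float(hypergeom.sf(k - 1, n_universe, len(term_genes), n_members))
        rows.append({"term": term, "overlap": k, "term_size": len(term_genes),
                     "p": min(p, 1.0)})
    df = pd.DataFrame(rows).set_index("term")
    df["q"] = bh_adjust(df["p"]) if len(df) else []
    return df


def trait_overlap(
    deg_set: set[str],
    trait_map: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Fisher overlap of a DEG set with each trait's gene list.

    The trait map should already be filtered to the expressed-gene universe;
    any residual out-of-universe genes are dropped.  BH across traits.
    Returns a DataFrame indexed by trait with columns ``overlap_genes``,
    ``n_overlap``, ``odds_ratio``, ``p``, ``q``.
    """
    rows = []
    for trait, genes in trait_map.items():
        trait_genes = genes & universe
        overlap = sorted(deg_set & trait_genes)
        oddsr, p = fisher_overlap(deg_set, trait_genes, universe)
        rows.append(
            {
                "trait": trait,
                "overlap_genes": ",".join(overlap),
                "n_overlap": len(overlap),
                "odds_ratio": oddsr,
                "p": p,
            }
        )
    df = pd.DataFrame(rows).set_index("trait")
    df["q"] = bh_adjust(df["p"]) if len(df) else []
    return df.sort_values("p")
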