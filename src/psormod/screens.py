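"""Screens built on small two-group experiments and paired methylation data.

Genes are ranked from cytokine/therapy/RNAi experiments with an
empirical-Bayes moderated t-statistic (gene-wise variances shrunk toward a
moment-matched scaled-F prior), picking the best feature per gene (lowest
p).  A module is called a cytokine hub edge only when both the rank-based
enrichment p and the Fisher overlap p clear 10⁻³ with agreeing direction;
edge tiers (10⁻³ / 10⁻⁶ / 10⁻⁹) come from the weaker of the two p-values.
Methylation bias uses paired PP−PN M-value differences through the same
moderated-t → best-site-per-gene → signed-ranking → enrichment chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from psormod.datatypes import Condition, ExpressionMatrix, GeneModule
from psormod.enrichment import (
    GseaResult,
    RankedGeneList,
    drc_area,
    fisher_overlap,
    rank_by_signed_logp,
)
from psormod.stats import fit_moderation, moderated_t_from_stats

logger = logging.getLogger(__name__)

HUB_P_MAX = 1e-3
TIER_CUTOFFS = (("p9", 1e-9), ("p6", 1e-6), ("p3", 1e-3))


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------

def moderated_t_two_group(
    expr: ExpressionMatrix,
    treated: str = Condition.TREATED.value,
    control: str = Condition.CONTROL.value,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> pd.DataFrame:
    """Two-sample moderated t per gene (treated minus control).

    Hyperparameters are fitted by moment matching on the observed gene-wise
    variances unless supplied.  Returns a DataFrame with columns ``effect``
    (log2 difference of means), ``t``, ``p``, ``direction``.
    """
    cond = expr.samples["condition"]
    g1 = expr.values.loc[:, (cond == treated).to_numpy()].to_numpy()
    g2 = expr.values.loc[:, (cond == control).to_numpy()].to_numpy()
    n1, n2 = g1.shape[1], g2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >=2 samples per group, got {n1} vs {n2}")
    effect = g1.mean(axis=1) - g2.mean(axis=1)
    df = n1 + n2 - 2
    s2 = (g1.var(axis=1, ddof=1) * (n1 - 1) + g2.var(axis=1, ddof=1) * (n2 - 1)) / df
    if d0 is None or s0_sq is None:
        d0, s0_sq = fit_moderation(s2, df)
    t, p = moderated_t_from_stats(effect, s2, df, 1.0 / n1 + 1.0 / n2, d0, s0_sq)
    return _stats_frame(expr.genes, effect, t, p)


def moderated_t_paired(
    diffs: pd.DataFrame,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> pd.DataFrame:
    """One-sample moderated t on per-pair differences (features × pairs)."""
    X = diffs.to_numpy()
    n = X.shape[1]
    if n < 2:
        raise ValueError("paired moderated t needs at least 2 pairs")
    effect = X.mean(axis=1)
    s2 = X.var(axis=1, ddof=1)
    df = n - 1
    if d0 is None or s0_sq is None:
        d0, s0_sq = fit_moderation(s2, df)
    t, p = moderated_t_from_stats(effect, s2, df, 1.0 / n, d0, s0_sq)
    return _stats_frame(list(diffs.index), effect, t, p)


def _stats_frame(index, effect, t, p) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "effect": effect,
            "t": t,
            "p": p,
            "direction": np.where(effect >= 0, 1, -1),
        },
        index=index,
    )


def best_feature_per_gene(
    results: pd.DataFrame, gene_of: pd.Series
) -> pd.DataFrame:
    """Collapse per-feature statistics to one row per gene.

    Keeps, per gene, the feature with the lowest p; p ties prefer larger
    |effect|, then the lexicographically first feature id.  ``gene_of`` maps
    feature id → gene id and must cover every feature in ``results``.
    """
    missing = results.index.difference(gene_of.index)
    if len(missing):
        raise ValueError(f"features without gene mapping: {list(missing[:5])}")
    tbl = results.copy()
    tbl["gene"] = gene_of.loc[tbl.index].to_numpy()
    tbl["feature"] = tbl.index
    tbl["_abs_effect"] = tbl["effect"].abs()
    tbl = tbl.sort_values(
        ["gene", "p", "_abs_effect", "feature"],
        ascending=[True, True, False, True],
    )
    best = tbl.drop_duplicates("gene", keep="first").set_index("gene")
    return best.drop(columns=["_abs_effect"])


# ---------------------------------------------------------------------------
# cytokine hub edges
# ---------------------------------------------------------------------------

@dataclass
class HubEdge:
    """One cytokine → module edge of the hub diagram."""

    cytokine: str
    module_id: str
    sign: str  # "induced" | "repressed"
    tier: str  # "p3" | "p6" | "p9"
    gsea_p: float
    fisher_p: float


def edge_tier(gsea_p: float, fisher_p: float) -> str | None:
    """Evidence tier from the weaker (larger) of the two p-values.

    ``p9`` below 10⁻⁹, ``p6`` below 10⁻⁶, ``p3`` below 10⁻³, else no edge.
    """
    worst = max(gsea_p, fisher_p)
    if worst >= 1e-3:
        return None
    if worst < 1e-9:
        return "p9"
    if worst < 1e-6:
        return "p6"
    return "p3"


def call_hub_edges(
    module: GeneModule,
    experiment_rankings: dict[str, RankedGeneList],
    responsive_sets: dict[str, tuple[set[str], set[str]]],
    universe: set[str],
    p_max: float = HUB_P_MAX,
) -> list[HubEdge]:
    """Dual-gate cytokine edges for one module.

    For each experiment, the module is enriched by the detection-rate-curve
    statistic on the experiment's signed ranking and, independently, by
    Fisher overlap with the experiment's induced / repressed responsive
    sets.  An edge exists only when both p-values are below ``p_max`` and
    the directions agree.  Experiments present in only one of the two maps
    are skipped with a warning.
    """
    edges: list[HubEdge] = []
    members = set(module.members) & universe
    for cytokine, ranking in experiment_rankings.items():
        if cytokine not in responsive_sets:
            logger.warning("no responsive sets for %s; skipped", cytokine)
            continue
        induced, repressed = responsive_sets[cytokine]
        gsea = drc_area(ranking, members)
        gsea_dir = "induced" if gsea.direction == "increased" else "repressed"
        overlap_set = induced if gsea_dir == "induced" else repressed
        _, fisher_p = fisher_overlap(members, overlap_set & universe, universe)
        if gsea.p < p_max and fisher_p < p_max:
            tier = edge_tier(gsea.p, fisher_p)
            edges.append(
                HubEdge(
                    cytokine=cytokine,
                    module_id=module.module_id,
                    sign=gsea_dir,
                    tier=tier,
                    gsea_p=gsea.p,
                    fisher_p=fisher_p,
                )
            )
    return edges


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def compute_mvalues(
    meth: pd.DataFrame, unmeth: pd.DataFrame, floor: float = 1.0
) -> pd.DataFrame:
    """M = log2((methylated + floor) / (unmethylated + floor)).

    The intensity floor keeps M finite at zero signal; intensities must be
    non-negative and the two matrices must share shape and labels.
    """
    if meth.shape != unmeth.shape:
        raise ValueError(f"shape mismatch: {meth.shape} vs {unmeth.shape}")
    if (meth.to_numpy() < 0).any() or (unmeth.to_numpy() < 0).any():
        raise ValueError("intensities must be non-negative")
    unmeth = unmeth.loc[meth.index, meth.columns]
    return np.log2((meth + floor) / (unmeth + floor))


def methylation_bias(
    modules: list[GeneModule],
    m_pp: pd.DataFrame,
    m_pn: pd.DataFrame,
    gene_of: pd.Series,
) -> dict[str, GseaResult]:
    """Per-module enrichment for hyper-/hypo-methylated genes.

    Per-site paired moderated t on PP−PN M-value differences, best site per
    gene, signed −log10 p ranking (hyper-methylated at low ranks), then the
    detection-rate-curve statistic per module.  Modules with no measured
    member genes are reported as untestable (skipped with a warning).
    """
    if m_pp.shape != m_pn.shape:
        raise ValueError("PP and PN M-value matrices must share shape")
    diffs = m_pp - m_pn.loc[m_pp.index, m_pp.columns]
    site_stats = moderated_t_paired(diffs)
    gene_stats = best_feature_per_gene(site_stats, gene_of)
    ranking = rank_by_signed_logp(gene_stats)
    measured = set(ranking.genes)
    results: dict[str, GseaResult] = {}
    for module in modules:
        members = set(module.members) & measured
        if not members or len(members) == len(measured):
            logger.warning("module %s untestable for methylation bias",
                           module.module_id)
            continue
        results[module.module_id] = drc_area(ranking, members)
    return results
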