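"""Paired differential-expression meta-analysis.

Representative probe-set selection, the above-background expression filter,
a per-gene paired signed-rank test on within-patient PP−PN log2 differences,
Benjamini-Hochberg control, and DEG calling with fold-change gates and
per-study consistency.  Fold change is 2^(median paired log2 difference), so
"median FC" is exchangeable with the median of per-patient ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from psormod.datatypes import ExpressionMatrix
from psormod.stats import bh_adjust, paired_signed_rank

logger = logging.getLogger(__name__)

# DEG calling gates: FDR < 0.05 with median FC > 1.50 (up) or < 0.67 (down),
# and per-study median FC on the same side of 1 in every study.
Q_MAX = 0.05
FC_UP = 1.50
FC_DOWN = 0.67


class SuffixClass(str, Enum):
    """Hybridization-specificity class of an Affymetrix probe-set id."""

    SPECIFIC = "specific"
    S_SUFFIX = "s_suffix"
    X_SUFFIX = "x_suffix"

    @classmethod
    def of(cls, probe_id: str) -> "SuffixClass":
        if "_s_at" in probe_id:
            return cls.S_SUFFIX
        if "_x_at" in probe_id:
            return cls.X_SUFFIX
        return cls.SPECIFIC


def select_representative_probesets(
    candidates: dict[str, list[tuple[str, float]]],
    suffix_of: dict[str, SuffixClass] | None = None,
) -> pd.DataFrame:
    """Choose one representative probe set per gene.

    Probe sets with ``_s``/``_x`` suffixes (cross-hybridizing) are excluded
    whenever a gene-specific probe set exists; among the remaining candidates
    the most highly expressed on average wins.  Ties on mean expression break
    lexicographically by probe id.

    Parameters
    ----------
    candidates
        gene → list of (probe_id, mean_expr) pairs.
    suffix_of
        probe_id → :class:`SuffixClass`; inferred from the id when omitted.

    Returns
    -------
    DataFrame indexed by gene with columns ``probe_id``, ``suffix_class``,
    ``mean_expr``.
    """
    rows = []
    for gene, probes in candidates.items():
        if not probes:
            raise ValueError(f"gene {gene!r} has no candidate probe sets")
        classed = [
            (
                pid,
                (suffix_of or {}).get(pid, SuffixClass.of(pid)),
                float(mean_expr),
            )
            for pid, mean_expr in probes
        ]
        specific = [c for c in classed if c[1] == SuffixClass.SPECIFIC]
        pool = specific if specific else classed
        pid, suffix, mean_expr = max(pool, key=lambda c: (c[2], _neg_lex(c[0])))
        rows.append(
            {
                "gene": gene,
                "probe_id": pid,
                "suffix_class": suffix.value,
                "mean_expr": mean_expr,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def _neg_lex(s: str):
    # max() tie-break helper: prefer lexicographically smaller id
    return tuple(-ord(c) for c in s)


def filter_expressed(expr: ExpressionMatrix, min_fraction: float = 0.10) -> list[str]:
    """Genes flagged above background in ≥ ``min_fraction`` of samples.

    The boundary is inclusive: a gene flagged in exactly 10% of samples is
    kept at the default threshold.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError(f"min_fraction must be in [0, 1], got {min_fraction}")
    frac = expr.above_background.mean(axis=1)
    return list(frac.index[frac >= min_fraction])


@dataclass
class PairedDeResult:
    """Per-gene paired differential-expression table plus FC matrices.

    ``table`` columns: median_fc, p, q, direction (±1), n_pairs, and one
    ``fc_<study>`` column per study.  ``fc_matrix`` holds per-patient
    fold-change ratios (genes × patients); ``log2_diffs`` the paired log2
    differences.
    """

    table: pd.DataFrame
    fc_matrix: pd.DataFrame
    log2_diffs: pd.DataFrame


def paired_differential_expression(
    expr: ExpressionMatrix, genes: list[str] | None = None
) -> PairedDeResult:
    """Run the paired PP-vs-PN analysis for every (or the given) genes.

    For each gene the per-patient difference PP − PN of log2 expression is
    tested against a zero median with the paired signed-rank test; p-values
    are BH-adjusted across genes.  Direction is +1 iff median FC > 1, with a
    median FC of exactly 1 resolved by the sign of the mean paired log2
    difference (ties broken toward +1, logged).
    """
    pairs = expr.paired_pp_pn()
    if len(pairs) < 2:
        raise ValueError("paired analysis needs at least two PP/PN pairs")
    values = expr.values if genes is None else expr.values.loc[list(genes)]
    pp = values[pairs["pp_sample"]].to_numpy()
    pn = values[pairs["pn_sample"]].to_numpy()
    diffs = pp - pn  # genes × patients, log2 units
    studies = pairs["study_id"].to_numpy()

    pvals = np.array([paired_signed_rank(row) for row in diffs])
    qvals = bh_adjust(pvals)
    median_diff = np.median(diffs, axis=1)
    median_fc = 2.0**median_diff

    direction = np.where(median_fc > 1.0, 1, -1)
    at_one = median_fc == 1.0
    if at_one.any():
        mean_diff = diffs[at_one].mean(axis=1)
        fallback = np.where(mean_diff >= 0.0, 1, -1)
        direction[at_one] = fallback
        logger.info(
            "%d genes with median FC exactly 1; direction from mean log2 "
            "difference (ties toward +1)", int(at_one.sum()),
        )

    table = pd.DataFrame(
        {
            "median_fc": median_fc,
            "p": pvals,
            "q": qvals,
            "direction": direction,
            "n_pairs": diffs.shape[1],
        },
        index=values.index,
    )
    for study in pd.unique(studies):
        cols = studies == study
        table[f"fc_{study}"] = 2.0 ** np.median(diffs[:, cols], axis=1)

    fc_matrix = pd.DataFrame(
        2.0**diffs, index=values.index, columns=pairs.index
    )
    log2_diffs = pd.DataFrame(diffs, index=values.index, columns=pairs.index)
    return PairedDeResult(table=table, fc_matrix=fc_matrix, log2_diffs=log2_diffs)


def call_degs(
    table: pd.DataFrame,
    q_max: float = Q_MAX,
    fc_up: float = FC_UP,
    fc_down: float = FC_DOWN,
) -> tuple[set[str], set[str]]:
    """Call PP-increased / PP-decreased DEGs from a differential table.

    A gene is PP-increased iff q < ``q_max``, median FC > ``fc_up``, and its
    median FC exceeds 1 in every study individually; PP-decreased mirrors
    with FC < ``fc_down`` and every per-study FC below 1.  All inequalities
    strict.
    """
    study_cols = [c for c in table.columns if c.startswith("fc_")]
    if not study_cols:
        raise ValueError("table has no per-study fold-change columns (fc_*)")
    study_fcs = table[study_cols]
    sig = table["q"] < q_max
    up = sig & (table["median_fc"] > fc_up) & (study_fcs > 1.0).all(axis=1)
    down = sig & (table["median_fc"] < fc_down) & (study_fcs < 1.0).all(axis=1)
    return set(table.index[up]), set(table.index[down])


def universal_direction_count(fc_matrix: pd.DataFrame) -> dict[str, set[str]]:
    """Genes whose per-patient FC is on the same side of 1 in every patient.

    Returns ``{"up": ..., "down": ...}``; an FC of exactly 1 in any patient
    disqualifies the gene from both sets.
    """
    if fc_matrix.isna().any().any():
        raise ValueError("fc_matrix contains missing values")
    arr = fc_matrix.to_numpy()
    up = (arr > 1.0).all(axis=1)
    down = (arr < 1.0).all(axis=1)
    return {
        "up": set(fc_matrix.index[up]),
        "down": set(fc_matrix.index[down]),
    }
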