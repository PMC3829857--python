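"""Epidermal co-expression module detection and the module landscape.

The reference matrix is standardized in two steps (per-gene centering, then
per-array z-scoring), clustered with average-linkage hierarchical clustering
on Euclidean distances, and cut with a top-down dynamic dendrogram cut: the
tree is recursively sub-divided while both branches meet the minimum module
size (25 genes by default) and the merge height of the split stands out from
the within-branch merge heights; genes falling in undersized side branches of
a significant split remain unassigned.  Modules are named after their
best-annotated member gene (most GO biological-process terms) plus the member
count, e.g. ``CDK1-38``.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import ClusterNode, linkage, to_tree
from scipy.spatial.distance import pdist, squareform

from psormod.datatypes import ExpressionMatrix, GeneModule

logger = logging.getLogger(__name__)

MIN_MODULE_SIZE = 25

#: a sub-division is significant when the merge height of the node stands
#: above the median merge height within its subtree by at least this factor.
#: Unstructured (pure-noise) data have near-uniform merge heights (ratio ≈ 1)
#: and never split; latent-factor structure produces large ratios at module
#: boundaries.
MIN_HEIGHT_RATIO = 1.4


def standardize_profiles(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Center each gene, then z-score each array across genes.

    Step 1 subtracts the per-gene mean so positive values mark above-average
    expression for that gene.  Step 2 rescales every sample (array) to mean 0
    and variance 1 across genes, equalizing per-array scale.
    """
    if expr.n_genes < 2 or expr.n_samples < 2:
        raise ValueError("need at least 2 genes and 2 samples to standardize")
    centered = expr.values.sub(expr.values.mean(axis=1), axis=0)
    sd = centered.std(axis=0, ddof=0)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(
            f"zero variance after centering in sample(s): {list(zero.index)}"
        )
    standardized = centered.sub(centered.mean(axis=0), axis=1).div(sd, axis=1)
    return ExpressionMatrix(
        values=standardized,
        samples=expr.samples,
        above_background=expr.above_background,
    )


def detect_modules(
    std_expr: ExpressionMatrix,
    min_size: int = MIN_MODULE_SIZE,
    min_height_ratio: float = MIN_HEIGHT_RATIO,
) -> tuple[list[GeneModule], list[str]]:
    """Detect co-expression modules by top-down dynamic dendrogram cutting.

    Starting from the dendrogram root, each node is sub-divided while the
    split is significant (node merge height ≥ ``min_height_ratio`` × the
    median merge height within its subtree) and at least one branch meets
    ``min_size``; genes in undersized branches of significant splits stay
    unassigned rather than being forced into a neighboring module.

    Returns ``(modules, unassigned_genes)``.  Module ids are ``M1``, ``M2``,
    ... in dendrogram order; every module has at least ``min_size`` members.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    genes = std_expr.genes
    if len(genes) < min_size:
        warnings.warn(
            f"only {len(genes)} genes (< min_size={min_size}); no modules",
            stacklevel=2,
        )
        return [], list(genes)
    X = std_expr.values.to_numpy()
    Z = linkage(X, method="average", metric="euclidean")
    root = to_tree(Z)

    clusters: list[list[int]] = []
    unassigned: list[int] = []

    def subtree_heights(node: ClusterNode, acc: list[float]) -> list[float]:
        if not node.is_leaf():
            acc.append(node.dist)
            subtree_heights(node.left, acc)
            subtree_heights(node.right, acc)
        return acc

    def descend(node: ClusterNode) -> None:
        if node.count < min_size:
            unassigned.extend(_leaves(node))
            return
        left, right = node.left, node.right
        median_height = float(np.median(subtree_heights(node, [])))
        significant = (
            median_height > 0 and node.dist / median_height >= min_height_ratio
        )
        if significant and left.count >= min_size and right.count >= min_size:
            descend(left)
            descend(right)
        elif significant and max(left.count, right.count) >= min_size:
            big, small = (
                (left, right) if left.count >= right.count else (right, left)
            )
            unassigned.extend(_leaves(small))
            descend(big)
        else:
            clusters.append(_leaves(node))

    descend(root)

    modules = [
        GeneModule(module_id=f"M{k}", members=[genes[i] for i in idx])
        for k, idx in enumerate(clusters, start=1)
    ]
    return modules, [genes[i] for i in sorted(unassigned)]


def _leaves(node: ClusterNode) -> list[int]:
    return node.pre_order(lambda leaf: leaf.id)


def name_module(members: list[str], go_term_counts: dict[str, int]) -> str:
    """``GENE-N`` label: best-annotated member (most GO BP terms) + size.

    Genes without a recorded count score 0; count ties break
    lexicographically by gene id.
    """
    if not members:
        raise ValueError("cannot name an empty module")
    best = min(members, key=lambda g: (-go_term_counts.get(g, 0), g))
    return f"{best}-{len(members)}"


def module_medoid(
    members: list[str], std_expr: ExpressionMatrix
) -> tuple[str, np.ndarray]:
    """Member gene minimizing summed Euclidean distance to all other members.

    Returns ``(gene_id, profile)``; distance-sum ties resolve to the
    lexicographically smallest gene id.
    """
    missing = [g for g in members if g not in std_expr.values.index]
    if missing:
        raise ValueError(f"module members absent from matrix: {missing[:5]}")
    members_sorted = sorted(members)
    profiles = std_expr.values.loc[members_sorted].to_numpy()
    dist = squareform(pdist(profiles, metric="euclidean"))
    sums = dist.sum(axis=1)
    idx = int(np.argmin(sums))  # argmin takes the first (lexicographic) tie
    return members_sorted[idx], profiles[idx].copy()


def module_fc_score(members: list[str], fc_matrix: pd.DataFrame) -> float:
    """Median-of-medians fold-change score of a module.

    Per-gene median FC across patients, then the median across member genes;
    even-length medians are midpoint means.
    """
    if not members:
        raise ValueError("empty member set")
    missing = [g for g in members if g not in fc_matrix.index]
    if missing:
        raise ValueError(f"members absent from FC matrix: {missing[:5]}")
    per_gene = fc_matrix.loc[list(members)].median(axis=1)
    return float(per_gene.median())


def annotate_modules(
    modules: list[GeneModule],
    std_expr: ExpressionMatrix,
    fc_matrix: pd.DataFrame | None = None,
    go_term_counts: dict[str, int] | None = None,
) -> list[GeneModule]:
    """Fill labels, medoids, and FC scores of detected modules in place."""
    for module in modules:
        module.label = name_module(module.members, go_term_counts or {})
        module.medoid_gene, module.medoid = module_medoid(
            module.members, std_expr
        )
        if fc_matrix is not None:
            module.fc_score = module_fc_score(module.members, fc_matrix)
    return modules


class ModuleLandscape:
    """Module-level summary of the reference landscape.

    Holds the module × module Euclidean medoid distance matrix, an
    average-linkage dendrogram over medoids (Newick export), and per-module
    (PC1, PC2) coordinates: the median of member-gene scores on the first two
    principal components of the standardized matrix.
    """

    def __init__(
        self,
        modules: list[GeneModule],
        medoid_distance: pd.DataFrame,
        pc_coords: pd.DataFrame,
        linkage_matrix: np.ndarray,
    ):
        self.modules = modules
        self.medoid_distance = medoid_distance
        self.pc_coords = pc_coords
        self.linkage_matrix = linkage_matrix

    def to_newick(self) -> str:
        names = list(self.medoid_distance.index)
        tree = to_tree(self.linkage_matrix)

        def render(node: ClusterNode, parent_dist: float) -> str:
            length = max(parent_dist - node.dist, 0.0)
            if node.is_leaf():
                return f"{names[node.id]}:{length:g}"
            return (
                f"({render(node.left, node.dist)},{render(node.right, node.dist)})"
                f":{length:g}"
            )

        return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


def build_landscape(
    modules: list[GeneModule], std_expr: ExpressionMatrix
) -> ModuleLandscape:
    """Ordinate annotated modules: medoid distances, dendrogram, PC medians."""
    if len(modules) < 2:
        raise ValueError("landscape needs at least 2 modules")
    for module in modules:
        if module.medoid is None:
            module.medoid_gene, module.medoid = module_medoid(
                module.members, std_expr
            )
    names = [m.module_id for m in modules]
    medoids = np.vstack([m.medoid for m in modules])
    dist = squareform(pdist(medoids, metric="euclidean"))
    medoid_distance = pd.DataFrame(dist, index=names, columns=names)
    Z = linkage(medoids, method="average", metric="euclidean")

    X = std_expr.values.to_numpy()
    Xc = X - X.mean(axis=0, keepdims=True)
    # gene scores on the first two PCs of the standardized matrix
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    scores = Xc @ vt[:2].T
    score_df = pd.DataFrame(scores, index=std_expr.genes, columns=["PC1", "PC2"])
    pc_coords = pd.DataFrame(
        [score_df.loc[m.members].median(axis=0) for m in modules], index=names
    )
    return ModuleLandscape(modules, medoid_distance, pc_coords, Z)
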