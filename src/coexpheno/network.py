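"""Weighted gene co-expression network: soft-threshold selection, adjacency,
topological overlap, module detection and module eigengenes.

The workflow mirrors the standard weighted co-expression recipe: raise
absolute (or signed-rescaled) Pearson correlations to a soft-threshold power
chosen for approximate scale-free topology, convert the adjacency to a
topological-overlap dissimilarity, cluster genes by average linkage, cut the
tree into modules, and summarize each module by its first principal component
(the module eigengene).

The tree cut here is a deliberately simplified variant of the dynamic
hybrid cut: a static cut near the top of the dendrogram followed by recursive
splitting of branches whenever the split is supported by a merge-height gap
and yields at least one sub-branch of viable size; undersized branches are
pruned to label 0.  Over-split fragments of a single true module are fused
back by the eigengene-correlation merge step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .expression import ExpressionMatrix


@dataclass
class NetworkParams:
    power: int = 6
    network_type: str = "unsigned"  # or "signed"
    min_module_size: int = 30
    merge_height: float = 0.15  # merge modules with eigengene cor > 1 - merge_height
    scale_free_r2_target: float = 0.8
    cut_height_fraction: float = 0.99  # static cut at this fraction of max merge height
    split_gap: float = 0.01  # minimum merge-height gap supporting a branch split
    # a branch is only labeled if its mean internal dissimilarity is below
    # qlo + factor * (cut height - qlo), qlo being the 5th percentile of merge
    # heights; 0.94 is the hybrid tree cut's conventional core-scatter factor
    max_core_scatter_factor: float = 0.94

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ValueError("power must be >= 1")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if not 0 <= self.merge_height <= 1:
            raise ValueError("merge_height must be in [0, 1]")


@dataclass
class ModulePartition:
    """Gene -> module labels; 0 marks pruned/unassigned genes.

    Labels are contiguous 1..M ordered by decreasing module size.
    """

    labels: np.ndarray
    gene_ids: list[str]

    @property
    def n_modules(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def module_sizes(self) -> dict[int, int]:
        uniq, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return {int(u): int(c) for u, c in zip(uniq, counts)}

    def module_genes(self, label: int) -> list[str]:
        return [g for g, l in zip(self.gene_ids, self.labels) if l == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.gene_ids, "module": self.labels})


@dataclass
class ModuleEigengenes:
    """Samples x modules eigengene scores (columns ME1..MEM, unit variance)."""

    values: np.ndarray
    sample_ids: list[str]
    module_labels: list[int]
    var_explained: list[float] = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        return [f"ME{m}" for m in self.module_labels]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.names)


# ---------------------------------------------------------------------------
# adjacency and TOM


def _pearson_matrix(values: np.ndarray) -> np.ndarray:
    sd = values.std(axis=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(f"constant genes (zero variance) at rows {constant[:10].tolist()}")
    cor = np.corrcoef(values)
    if np.isnan(cor).any():
        raise ValueError("NaN correlations in expression matrix")
    return np.clip(cor, -1.0, 1.0)


def adjacency(x: ExpressionMatrix, params: NetworkParams) -> np.ndarray:
    """Soft-threshold adjacency: |cor|^power (unsigned) or ((1+cor)/2)^power."""
    cor = _pearson_matrix(x.values)
    if params.network_type == "unsigned":
        a = np.abs(cor) ** params.power
    elif params.network_type == "signed":
        a = ((1.0 + cor) / 2.0) ** params.power
    else:
        raise ValueError(f"unknown network_type {params.network_type!r}")
    np.fill_diagonal(a, 1.0)
    return a


def connectivity(a: np.ndarray) -> np.ndarray:
    """Whole-network connectivity k_i = sum_{j != i} a_ij."""
    return a.sum(axis=1) - np.diag(a)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """R^2 and slope of log10 p(k) on log10 mean-k over connectivity bins."""
    k = np.asarray(k, dtype=float)
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        mean_k = k[mask].mean()
        frac = mask.mean()
        if mean_k <= 0 or frac <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(frac))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    fitted = slope * np.asarray(xs) + intercept
    ss_res = float(np.sum((np.asarray(ys) - fitted) ** 2))
    ss_tot = float(np.sum((np.asarray(ys) - np.mean(ys)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(r2), float(slope)


def pick_soft_threshold(
    x: ExpressionMatrix,
    candidate_powers: list[int] = (1, 2, 3, 4, 5, 6, 8, 10, 12, 14, 16, 18, 20),
    params: NetworkParams | None = None,
) -> tuple[int, pd.DataFrame]:
    """Choose the smallest power reaching the scale-free R^2 target.

    Falls back to the argmax-R^2 power when no candidate reaches the target.
    Returns the chosen power and the per-power fit table.
    """
    base = params or NetworkParams()
    cor = _pearson_matrix(x.values)
    rows = []
    for power in candidate_powers:
        if base.network_type == "unsigned":
            a = np.abs(cor) ** power
        else:
            a = ((1.0 + cor) / 2.0) ** power
        np.fill_diagonal(a, 1.0)
        k = connectivity(a)
        r2, slope = scale_free_fit(k)
        rows.append((power, r2, slope, float(k.mean()), float(k.max())))
    table = pd.DataFrame(rows, columns=["power", "r2", "slope", "mean_k", "max_k"])
    ok = table[table.r2 >= base.scale_free_r2_target]
    chosen = int(ok.power.iloc[0]) if len(ok) else int(table.loc[table.r2.idxmax(), "power"])
    return chosen, table


def tom_similarity(a: np.ndarray) -> np.ndarray:
    """Topological overlap: (sum_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    The shared-neighbor sum excludes u in {i, j}; connectivity k excludes the
    self-edge; the diagonal is 1.
    """
    a = np.asarray(a, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if a.min() < 0 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    d = np.diag(a).copy()
    if not np.allclose(d, 1.0):
        raise ValueError("adjacency must have unit diagonal")
    k = a.sum(axis=1) - d
    # (A @ A)_ij includes u = i and u = j terms: a_ii a_ij + a_ij a_jj = 2 a_ij
    shared = a @ a - 2.0 * a
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def tom_dissimilarity(a: np.ndarray) -> np.ndarray:
    return 1.0 - tom_similarity(a)


# ---------------------------------------------------------------------------
# module detection


def _split_recursive(
    node: sch.ClusterNode, min_size: int, gap: float, out: list[list[int]]
) -> None:
    """Recursively split a branch while the split is supported.

    A split is accepted when the merge-height gap between the branch root and
    its taller child is at least ``gap`` and at least one child is of viable
    size; otherwise the branch is kept whole.
    """
    if node.is_leaf() or node.get_count() <= min_size:
        out.append(node.pre_order())
        return
    left, right = node.get_left(), node.get_right()
    child_h = max(left.dist, right.dist)
    viable = max(left.get_count(), right.get_count()) >= min_size
    if viable and (node.dist - child_h) >= gap:
        _split_recursive(left, min_size, gap, out)
        _split_recursive(right, min_size, gap, out)
    else:
        out.append(node.pre_order())


def _eigengene_of(values: np.ndarray) -> tuple[np.ndarray, float]:
    """First-PC sample scores (unit variance, sign-aligned to the module mean)
    and the proportion of variance explained."""
    sd = values.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    me = vt[0]
    if np.corrcoef(me, z.mean(axis=0))[0, 1] < 0:
        me = -me
    var_expl = float(s[0] ** 2 / np.sum(s**2))
    me_sd = me.std(ddof=0)
    return me / me_sd if me_sd > 0 else me, var_expl


def detect_modules(
    dissim: np.ndarray,
    params: NetworkParams,
    expression: ExpressionMatrix | None = None,
    gene_ids: list[str] | None = None,
) -> ModulePartition:
    """Cluster the TOM dissimilarity into modules.

    Average-linkage hierarchical clustering, static cut at
    ``cut_height_fraction`` of the maximum merge height, recursive gap-based
    branch splitting, pruning of undersized branches to label 0, and (when
    ``expression`` is given) merging of modules whose eigengenes correlate
    above ``1 - merge_height``.  Labels are relabeled 1..M by decreasing size.
    """
    dissim = np.asarray(dissim, dtype=float)
    n = dissim.shape[0]
    if gene_ids is None:
        gene_ids = (
            list(expression.gene_ids) if expression is not None else [f"g{i}" for i in range(n)]
        )
    if n < params.min_module_size:
        import warnings

        warnings.warn("fewer genes than min_module_size; all genes unassigned", stacklevel=2)
        return ModulePartition(np.zeros(n, dtype=int), gene_ids)

    condensed = squareform((dissim + dissim.T) / 2.0, checks=False)
    linkage = sch.linkage(condensed, method="average")
    cut_h = params.cut_height_fraction * linkage[:, 2].max()
    flat = sch.fcluster(linkage, t=cut_h, criterion="distance")

    # recursive descent inside every static-cut cluster
    tree = sch.to_tree(linkage)
    clusters: list[list[int]] = []

    def collect(node: sch.ClusterNode) -> None:
        if node.dist <= cut_h or node.is_leaf():
            _split_recursive(node, params.min_module_size, params.split_gap, clusters)
        else:
            collect(node.get_left())
            collect(node.get_right())

    collect(tree)
    del flat

    # core-scatter criterion: reject loose branches (noise agglomerations
    # that complete merging just under the cut height)
    qlo = float(np.quantile(linkage[:, 2], 0.05))
    max_scatter = qlo + params.max_core_scatter_factor * (cut_h - qlo)

    labels = np.zeros(n, dtype=int)
    next_label = 1
    for members in clusters:
        if len(members) < params.min_module_size:
            continue
        sub = dissim[np.ix_(members, members)]
        m = len(members)
        mean_dissim = (sub.sum() - np.trace(sub)) / (m * (m - 1))
        if mean_dissim > max_scatter:
            continue
        labels[members] = next_label
        next_label += 1

    if expression is not None and next_label > 2:
        labels = _merge_by_eigengene(expression, labels, params)

    return ModulePartition(_relabel_by_size(labels), gene_ids)


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    uniq, counts = np.unique(labels[labels > 0], return_counts=True)
    # decreasing size; ties by original label for determinism
    order = sorted(range(len(uniq)), key=lambda i: (-counts[i], uniq[i]))
    mapping = {int(uniq[i]): rank + 1 for rank, i in enumerate(order)}
    out = np.zeros_like(labels)
    for old, new in mapping.items():
        out[labels == old] = new
    return out


def _merge_by_eigengene(
    x: ExpressionMatrix, labels: np.ndarray, params: NetworkParams
) -> np.ndarray:
    """Iteratively merge the most correlated eigengene pair above threshold."""
    threshold = 1.0 - params.merge_height
    labels = labels.copy()
    while True:
        uniq = [int(u) for u in np.unique(labels) if u > 0]
        if len(uniq) < 2:
            return labels
        mes = []
        for u in uniq:
            me, _ = _eigengene_of(x.values[labels == u])
            mes.append(me)
        cor = np.corrcoef(np.asarray(mes))
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if cor[i, j] <= threshold:
            return labels
        keep, absorb = sorted((uniq[i], uniq[j]))
        labels[labels == absorb] = keep


def module_eigengenes(x: ExpressionMatrix, partition: ModulePartition) -> ModuleEigengenes:
    """First-PC eigengene per module, unit variance, sign-aligned with the
    module's mean standardized expression."""
    values, labels_out, var_expl = [], [], []
    for label in sorted(partition.module_sizes):
        mask = partition.labels == label
        sub = x.values[mask]
        if np.any(sub.std(axis=1) == 0):
            raise ValueError(f"module {label} contains constant genes")
        if mask.sum() < 2:
            raise ValueError(f"module {label} has fewer than 2 genes")
        me, ve = _eigengene_of(sub)
        values.append(me)
        labels_out.append(label)
        var_expl.append(ve)
    mat = np.asarray(values).T if values else np.zeros((x.n_samples, 0))
    return ModuleEigengenes(mat, list(x.sample_ids), labels_out, var_expl)
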