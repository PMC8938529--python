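"""Consensus weighted co-expression networks (WGCNA-style).

Builds signed soft-thresholded Pearson adjacencies per dataset, converts
them to topological overlap matrices (TOM), calibrates and combines the two
TOMs into a consensus by element-wise minimum, clusters genes by average
linkage on 1 - TOM with a recursive top-down tree cut followed by kME
reassignment, residual re-seeding and eigengene merging, and summarizes
each module by its eigengene (first principal component) and per-gene
module membership kME.

Signed networks are used throughout so that up/down concordance between the
two stress models is preserved in module assignment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "GeneNetwork",
    "ModulePartition",
    "SoftPowerResult",
    "adjacency",
    "pick_soft_power",
    "tom",
    "consensus_tom",
    "cut_modules",
    "refine_kme",
    "detect_modules",
    "module_coherence",
    "null_coherence_floor",
    "prune_incoherent",
    "merge_close_modules",
    "eigengenes",
    "kme",
]


@dataclass
class GeneNetwork:
    """Symmetric gene x gene matrix in [0, 1] (adjacency or TOM)."""

    matrix: np.ndarray
    genes: list[str]
    kind: str  # "adjacency" | "tom"
    beta: float
    signed: bool

    def connectivity(self) -> np.ndarray:
        """k_i = sum_{j != i} a_ij (self-adjacency excluded)."""
        return self.matrix.sum(axis=1) - np.diag(self.matrix)


@dataclass
class ModulePartition:
    """Gene -> module labels with per-dataset eigengenes and kME.

    Label 0 marks unassigned/background genes; module labels 1..K are
    ordered by decreasing module size.
    """

    labels: pd.Series  # index = genes, int labels
    linkage: np.ndarray | None = None
    eigengene_per_dataset: dict[str, pd.DataFrame] = field(default_factory=dict)
    kme_per_dataset: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.labels) - {0})

    def members(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def consensus_kme(self) -> pd.DataFrame:
        """Mean kME across datasets (the combination used for hub ranking)."""
        if not self.kme_per_dataset:
            raise ValueError("kME has not been computed")
        mats = list(self.kme_per_dataset.values())
        return sum(mats[1:], start=mats[0].copy()) / len(mats)


@dataclass
class SoftPowerResult:
    beta: int
    r_squared: float
    table: pd.DataFrame  # candidate beta, signed scale-free R^2, mean k
    warning: bool  # True when no candidate met the target


def _check_expr(expr: pd.DataFrame) -> None:
    sd = expr.std(axis=1)
    bad = sd.index[sd == 0].tolist()
    if bad:
        raise ValueError(f"zero-variance gene(s): {bad[:10]}")


def adjacency(expr: pd.DataFrame, beta: float = 6, signed: bool = True) -> GeneNetwork:
    """Soft-thresholded Pearson adjacency of a genes x samples matrix.

    signed: a_ij = ((1 + cor_ij) / 2) ** beta; unsigned: |cor_ij| ** beta.
    """
    if expr.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    if beta < 1:
        raise ValueError("beta must be >= 1")
    _check_expr(expr)
    cor = np.corrcoef(expr.to_numpy(dtype=float))
    cor = np.clip(cor, -1.0, 1.0)
    a = ((1.0 + cor) / 2.0) ** beta if signed else np.abs(cor) ** beta
    return GeneNetwork(a, list(expr.index), "adjacency", float(beta), signed)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit R^2 of a connectivity vector.

    Bins connectivity, regresses log10 frequency on log10 mean connectivity
    per occupied bin, and returns R^2 signed by minus the slope sign (a
    positive slope yields a negative fit, enforcing the expected decay).
    """
    k = np.asarray(k, dtype=float)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        mean_k = k[sel].mean()
        if mean_k <= 0:
            continue
        xs.append(math.log10(mean_k))
        ys.append(math.log10(sel.sum() / len(k)))
    if len(xs) < 2:
        raise ValueError("fewer than 2 occupied connectivity bins")
    slope, _ = np.polyfit(xs, ys, 1)
    r = np.corrcoef(xs, ys)[0, 1]
    return float(-np.sign(slope) * r**2)


def pick_soft_power(
    expr: pd.DataFrame,
    candidates=tuple(range(1, 21)),
    r2_target: float = 0.8,
    signed: bool = True,
) -> SoftPowerResult:
    """Smallest candidate power reaching the scale-free fit target.

    Falls back to the candidate with maximal fit (warning flagged) if none
    reaches the target.
    """
    if not len(candidates):
        raise ValueError("no candidate powers")
    rows = []
    for b in candidates:
        net = adjacency(expr, beta=b, signed=signed)
        k = net.connectivity()
        fit = scale_free_fit(k)
        rows.append((b, fit, float(k.mean())))
        if fit >= r2_target:
            table = pd.DataFrame(rows, columns=["beta", "r_squared", "mean_k"])
            return SoftPowerResult(int(b), fit, table, warning=False)
    table = pd.DataFrame(rows, columns=["beta", "r_squared", "mean_k"])
    best = table.loc[table["r_squared"].idxmax()]
    warnings.warn(
        f"no candidate power reached scale-free R^2 {r2_target}; "
        f"using beta={int(best['beta'])} (R^2={best['r_squared']:.3f})"
    )
    return SoftPowerResult(int(best["beta"]), float(best["r_squared"]), table, True)


def tom(net: GeneNetwork) -> GeneNetwork:
    """Topological overlap matrix of an adjacency.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    with unit diagonal.
    """
    if net.kind != "adjacency":
        raise ValueError("tom() expects an adjacency network")
    a = net.matrix
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency is not symmetric")
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    shared = a0 @ a0  # (i,j) entry = sum_u a_iu a_uj over u != i and u != j
    k = a0.sum(axis=1)
    num = shared + a0
    den = np.minimum.outer(k, k) + 1.0 - a0
    t = num / den
    np.fill_diagonal(t, 1.0)
    t = np.clip(t, 0.0, 1.0)
    return GeneNetwork(t, net.genes, "tom", net.beta, net.signed)


def consensus_tom(
    tom_a: GeneNetwork, tom_b: GeneNetwork, calib_quantile: float = 0.95
) -> GeneNetwork:
    """Consensus TOM: element-wise minimum after quantile calibration.

    The second TOM is multiplicatively rescaled so its off-diagonal
    ``calib_quantile`` matches the first's, then clipped to [0, 1]; the
    consensus is the element-wise minimum, so a gene pair is only strongly
    connected in the consensus if it is in both datasets.
    """
    if tom_a.genes != tom_b.genes:
        raise ValueError("gene sets differ between the two TOMs")
    n = len(tom_a.genes)
    off = ~np.eye(n, dtype=bool)
    q_a = np.quantile(tom_a.matrix[off], calib_quantile)
    q_b = np.quantile(tom_b.matrix[off], calib_quantile)
    scale = q_a / q_b if q_b > 0 else 1.0
    b_cal = np.clip(tom_b.matrix * scale, 0.0, 1.0)
    np.fill_diagonal(b_cal, 1.0)
    cons = np.minimum(tom_a.matrix, b_cal)
    return GeneNetwork(cons, tom_a.genes, "tom", tom_a.beta, tom_a.signed)


def _topdown_cut(Z: np.ndarray, min_size: int, height: float) -> np.ndarray:
    """Top-down tree cut: descend from the root, splitting every branch that
    joins at or above ``height``; a branch joined strictly below it becomes a
    module, and branches that can no longer yield a min_size module fall to
    background."""
    n = Z.shape[0] + 1
    root, _ = hierarchy.to_tree(Z, rd=True)
    labels = np.zeros(n, dtype=int)
    next_label = 1
    stack = [root]
    while stack:
        node = stack.pop()
        if node.count < min_size:
            continue
        if not node.is_leaf() and node.dist >= height:
            stack.append(node.left)
            stack.append(node.right)
        else:
            labels[node.pre_order()] = next_label
            next_label += 1
    return labels


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    sizes = {m: int((labels == m).sum()) for m in set(labels) - {0}}
    order = sorted(sizes, key=lambda m: (-sizes[m], m))
    mapping = {m: i + 1 for i, m in enumerate(order)}
    mapping[0] = 0
    return np.array([mapping[m] for m in labels])


def cut_modules(
    dissim: np.ndarray,
    genes: list[str],
    min_size: int = 30,
    cut_height: float = 0.995,
) -> ModulePartition:
    """Average-linkage clustering of a TOM dissimilarity into modules.

    ``cut_height`` is a fraction of the dendrogram height range: the cut
    sits at ``h_min + cut_height * (h_max - h_min)``.  The tree is then cut
    top-down: every branch joining at or above the cut is split, a branch
    joining strictly below it becomes a module, and branches that cannot
    yield a module of ``min_size`` genes fall to background label 0.
    Labels are ordered by decreasing module size.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    d = np.asarray(dissim, dtype=float)
    if not np.allclose(d, d.T, atol=1e-10) or not np.allclose(np.diag(d), 0):
        raise ValueError("dissimilarity must be symmetric with zero diagonal")
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    heights = Z[:, 2]
    h = heights.min() + cut_height * (heights.max() - heights.min())
    raw = _topdown_cut(Z, min_size, h)
    labels = _relabel_by_size(raw)
    return ModulePartition(
        labels=pd.Series(labels, index=pd.Index(genes, name="gene")), linkage=Z
    )


def refine_kme(
    partition: ModulePartition,
    exprs: dict[str, pd.DataFrame],
    kme_min: float = 0.4,
    min_size: int = 30,
    n_iter: int = 3,
) -> ModulePartition:
    """Reassign genes to their best-matching module by consensus kME.

    A tree cut leaves some module genes stranded on background branches and
    lets weakly attached genes ride along with a module; this pass (the
    analogue of the PAM stage of dynamic tree cutting) recomputes module
    eigengenes, moves every gene to the module with its highest mean-over-
    datasets kME when that exceeds ``kme_min``, drops the rest to
    background, removes modules that fall under ``min_size``, and repeats
    up to ``n_iter`` times or until stable.
    """
    labels = partition.labels.copy()
    for _ in range(n_iter):
        part = ModulePartition(labels=labels)
        mods = part.module_ids
        if not mods:
            break
        kmes = []
        for expr in exprs.values():
            e = eigengenes(expr, part)
            kmes.append(kme(expr, e))
        kc = sum(kmes[1:], start=kmes[0].copy()) / len(kmes)
        best = kc.idxmax(axis=1)
        best_val = kc.max(axis=1)
        new = pd.Series(
            np.where(best_val >= kme_min, best, 0), index=labels.index, dtype=int
        )
        sizes = new.value_counts()
        small = sizes.index[(sizes < min_size) & (sizes.index != 0)]
        new[new.isin(small)] = 0
        if new.equals(labels):
            break
        labels = new
    return ModulePartition(
        labels=pd.Series(_relabel_by_size(labels.to_numpy()), index=labels.index),
        linkage=partition.linkage,
    )


def detect_modules(
    dissim: np.ndarray,
    genes: list[str],
    exprs: dict[str, pd.DataFrame],
    min_size: int = 20,
    cut_height: float = 0.995,
    kme_min: float = 0.35,
    refine_iter: int = 5,
    merge_height: float = 0.25,
    reseed_rounds: int = 2,
    final_min_size: int | None = 30,
) -> ModulePartition:
    """Full module detection: tree cut, kME refinement, residual re-seeding,
    eigengene merge, final size filter.

    The initial top-down cut seeds candidate modules; kME reassignment
    cleans and completes them; up to ``reseed_rounds`` extra cut passes on
    the remaining background genes recover modules the first dendrogram
    failed to isolate (weakly attached branches are easily lost in a single
    cut of a noisy consensus TOM); near-duplicate modules are merged on
    consensus eigengene similarity.  Modules below ``final_min_size`` are
    then dropped to background: seeding tolerates smaller fragments
    (``min_size``) so that true modules are not lost, but small clusters
    that failed to grow during refinement are mostly correlation-noise
    artifacts and would dilute downstream enrichment statistics.
    """
    part = cut_modules(dissim, genes, min_size, cut_height)
    part = refine_kme(part, exprs, kme_min, min_size, refine_iter)
    pos = {g: i for i, g in enumerate(genes)}
    for _ in range(reseed_rounds):
        bg = list(part.labels.index[part.labels == 0])
        if len(bg) < 3 * min_size:
            break
        idx = [pos[g] for g in bg]
        residual = cut_modules(dissim[np.ix_(idx, idx)], bg, min_size, cut_height)
        if not residual.module_ids:
            break
        labels = part.labels.copy()
        offset = int(labels.max())
        new = residual.labels[residual.labels > 0] + offset
        labels.loc[new.index] = new
        part = refine_kme(
            ModulePartition(labels=labels), exprs, kme_min, min_size, refine_iter
        )
    part = merge_close_modules(part, exprs, merge_height)
    if final_min_size is not None and part.module_ids:
        labels = part.labels.copy()
        sizes = labels[labels > 0].value_counts()
        labels[labels.isin(sizes.index[sizes < final_min_size])] = 0
        part = merge_close_modules(
            ModulePartition(
                labels=pd.Series(
                    _relabel_by_size(labels.to_numpy()), index=labels.index
                ),
                linkage=part.linkage,
            ),
            exprs,
            0.0,  # labels final; recompute eigengenes and kME only
        )
    return part


def module_coherence(
    exprs: dict[str, pd.DataFrame], partition: ModulePartition
) -> pd.Series:
    """Per-module coherence: min over datasets of the mean within-module
    pairwise Pearson correlation.

    A consensus module driven by a real shared factor is coherent in every
    dataset; gene sets assembled from correlation noise by an aggressive
    search are not reproducibly so.
    """
    out = {}
    for mod in partition.module_ids:
        members = partition.members(mod)
        vals = []
        for expr in exprs.values():
            c = np.corrcoef(expr.loc[members].to_numpy(dtype=float))
            vals.append(float(c[np.triu_indices(len(members), 1)].mean()))
        out[mod] = min(vals)
    s = pd.Series(out, dtype=float)
    s.index.name = "module"
    return s


def null_coherence_floor(
    exprs: dict[str, pd.DataFrame],
    beta: float,
    rng: np.random.Generator,
    signed: bool = True,
    calib_quantile: float = 0.95,
    **detect_kwargs,
) -> float:
    """Coherence ceiling of modules the detector finds in decorrelated data.

    Each gene's samples are permuted independently (within dataset),
    destroying all gene-gene correlation while preserving marginals; the
    full detection pipeline is re-run on the permuted consensus TOM, and
    the largest coherence among the modules it fabricates is returned (0.0
    when it finds none).  Modules from the real data whose coherence does
    not exceed this floor are indistinguishable from selection artifacts.
    """
    permuted = {}
    for name, expr in exprs.items():
        x = expr.to_numpy(dtype=float).copy()
        for i in range(x.shape[0]):
            rng.shuffle(x[i])
        permuted[name] = pd.DataFrame(x, index=expr.index, columns=expr.columns)
    toms = [
        tom(adjacency(e, beta=beta, signed=signed)) for e in permuted.values()
    ]
    cons = toms[0]
    for other in toms[1:]:
        cons = consensus_tom(cons, other, calib_quantile)
    dissim = 1.0 - cons.matrix
    np.fill_diagonal(dissim, 0.0)
    part = detect_modules(dissim, cons.genes, permuted, **detect_kwargs)
    if not part.module_ids:
        return 0.0
    return float(module_coherence(permuted, part).max())


def prune_incoherent(
    partition: ModulePartition,
    exprs: dict[str, pd.DataFrame],
    floor: float,
    merge_height: float = 0.25,
) -> tuple[ModulePartition, pd.Series]:
    """Drop modules whose coherence does not exceed the permutation floor.

    Returns the pruned partition (eigengenes and kME recomputed) together
    with the coherence values of the input modules.
    """
    coh = module_coherence(exprs, partition)
    drop = coh.index[coh <= floor]
    labels = partition.labels.copy()
    labels[labels.isin(drop)] = 0
    pruned = ModulePartition(
        labels=pd.Series(_relabel_by_size(labels.to_numpy()), index=labels.index),
        linkage=partition.linkage,
    )
    return merge_close_modules(pruned, exprs, merge_height), coh


def eigengenes(expr: pd.DataFrame, partition: ModulePartition) -> pd.DataFrame:
    """First-PC module eigengenes, samples x modules, unit norm.

    Each module's genes are standardized across samples; the eigengene is
    the leading right singular vector, sign-oriented to correlate positively
    with the module's mean standardized profile.
    """
    cols = {}
    for mod in partition.module_ids:
        members = partition.members(mod)
        if len(members) < 2:
            raise ValueError(f"module {mod} has fewer than 2 genes")
        x = expr.loc[members].to_numpy(dtype=float)
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True, ddof=1)
        if np.any(sd == 0):
            raise ValueError(f"zero-variance gene in module {mod}")
        z = (x - mu) / sd
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        e = vt[0]
        mean_profile = z.mean(axis=0)
        if np.dot(e, mean_profile) < 0:
            e = -e
        cols[mod] = e / np.linalg.norm(e)
    return pd.DataFrame(cols, index=expr.columns)


def kme(expr: pd.DataFrame, eig: pd.DataFrame) -> pd.DataFrame:
    """Module membership: Pearson correlation of each gene with each eigengene."""
    x = expr.to_numpy(dtype=float)
    xz = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    e = eig.to_numpy(dtype=float)
    ez = (e - e.mean(axis=0, keepdims=True)) / e.std(axis=0, keepdims=True)
    r = xz @ ez / x.shape[1]
    return pd.DataFrame(
        np.clip(r, -1.0, 1.0), index=expr.index, columns=eig.columns
    )


def _eigengene_dissim(
    partition: ModulePartition, exprs: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Consensus eigengene dissimilarity: max over datasets of 1 - cor."""
    mods = partition.module_ids
    diss = pd.DataFrame(0.0, index=mods, columns=mods)
    for expr in exprs.values():
        e = eigengenes(expr, partition)
        c = np.corrcoef(e.to_numpy().T)
        d = pd.DataFrame(1.0 - c, index=e.columns, columns=e.columns)
        diss = np.maximum(diss, d.loc[mods, mods])
    return diss


def merge_close_modules(
    partition: ModulePartition,
    exprs: dict[str, pd.DataFrame],
    merge_height: float = 0.25,
) -> ModulePartition:
    """Iteratively merge modules whose consensus eigengenes nearly coincide.

    The dissimilarity between two modules is the maximum over datasets of
    1 - cor(eigengene_1, eigengene_2); the closest pair below
    ``merge_height`` is merged and the loop repeats until stable.  Final
    labels are reordered by size and eigengenes/kME recomputed per dataset.
    """
    labels = partition.labels.copy()
    while True:
        part = ModulePartition(labels=labels)
        mods = part.module_ids
        if len(mods) < 2 or merge_height <= 0:
            break
        diss = _eigengene_dissim(part, exprs).to_numpy()
        np.fill_diagonal(diss, np.inf)
        a, b = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[a, b] >= merge_height:
            break
        keep, drop = sorted((mods[a], mods[b]))
        labels = labels.replace(drop, keep)
    final = ModulePartition(
        labels=pd.Series(
            _relabel_by_size(labels.to_numpy()), index=labels.index
        ),
        linkage=partition.linkage,
    )
    for name, expr in exprs.items():
        e = eigengenes(expr, final)
        final.eigengene_per_dataset[name] = e
        final.kme_per_dataset[name] = kme(expr, e)
    return final
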