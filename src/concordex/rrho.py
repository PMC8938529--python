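"""Stratified rank-rank hypergeometric overlap (RRHO).

Two gene lists ranked by signed significance (-log10 p times the sign of the
fold change) are compared over a grid of rank thresholds; each grid cell
scores the overlap of the two top (or bottom) slices with an upper-tail
hypergeometric test over the common background.  The stratified variant
evaluates the four direction quadrants separately: UU (up in both lists,
from the tops), DD (down in both, from the bottoms), and the discordant UD /
DU quadrants mixing a top with a bottom.  Genes with signed score exactly 0
fall in the down stratum (a score of 0 arises only from p = 1).

Per-quadrant "peaks" — the cell with the largest -log10 p, ties resolved
toward the smallest thresholds — summarize each quadrant, and the genes
overlapping at the peak form the quadrant's concordant (or discordant) set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RankedList",
    "RRHOMap",
    "QuadrantPeak",
    "hypergeom_overlap_p",
    "rrho_map",
    "quadrant_peaks",
    "intersect_peak_sets",
]

QUADRANTS = ("UU", "DD", "UD", "DU")


@dataclass
class RankedList:
    """Genes ordered by signed score, descending (most up first)."""

    genes: list[str]
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids in ranked list")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def n_pos(self) -> int:
        """Number of genes in the up stratum (signed score strictly > 0)."""
        return int(np.sum(self.scores > 0))

    def up_genes(self) -> list[str]:
        return self.genes[: self.n_pos]

    def down_genes(self) -> list[str]:
        """Down-stratum genes ordered from most down-regulated."""
        return self.genes[self.n_pos :][::-1]


def hypergeom_overlap_p(k: int, i: int, j: int, N: int) -> float:
    """Upper-tail P(X >= k) for the overlap of an i-set and a j-set from N."""
    if not (0 <= k <= min(i, j) <= max(i, j) <= N):
        raise ValueError(f"invalid overlap bounds k={k}, i={i}, j={j}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, i, j))


@dataclass
class QuadrantPeak:
    quadrant: str
    i: int
    j: int
    neglog_p: float
    genes: set[str] = field(default_factory=set)
    present: bool = True


@dataclass
class RRHOMap:
    """Quadrant-stratified grid of -log10 hypergeometric overlap p-values.

    ``grids[q]`` is a (len(i_thresholds[q]), len(j_thresholds[q])) array;
    thresholds count genes taken from the top (UU/UD rows, UU/DU columns) or
    bottom (DD/DU rows, DD/UD columns) of the respective stratum.
    """

    background: list[str]
    step: int
    n1_pos: int
    n2_pos: int
    strata1: dict[str, list[str]]  # "up"/"down" ordered slices of list 1
    strata2: dict[str, list[str]]
    i_thresholds: dict[str, np.ndarray]
    j_thresholds: dict[str, np.ndarray]
    grids: dict[str, np.ndarray]
    corrected_grids: dict[str, np.ndarray] | None = None

    @property
    def N(self) -> int:
        return len(self.background)

    def cell_genes(self, quadrant: str, i: int, j: int) -> set[str]:
        """Overlap gene set at thresholds (i, j) of the given quadrant."""
        side1 = "up" if quadrant[0] == "U" else "down"
        side2 = "up" if quadrant[1] == "U" else "down"
        return set(self.strata1[side1][:i]) & set(self.strata2[side2][:j])


def _thresholds(n: int, step: int) -> np.ndarray:
    if n <= 0:
        return np.array([], dtype=int)
    t = list(range(step, n + 1, step))
    if not t or t[-1] != n:
        t.append(n)
    return np.array(t, dtype=int)


def _overlap_grid(
    genes1: Sequence[str], genes2: Sequence[str], ti: np.ndarray, tj: np.ndarray
) -> np.ndarray:
    """k(i, j) = |top-i of genes1 ∩ top-j of genes2| on the threshold grid."""
    pos2 = {g: r for r, g in enumerate(genes2, start=1)}
    r1, r2 = [], []
    for r, g in enumerate(genes1, start=1):
        if g in pos2:
            r1.append(r)
            r2.append(pos2[g])
    if not r1:
        return np.zeros((len(ti), len(tj)), dtype=int)
    r1 = np.asarray(r1)
    r2 = np.asarray(r2)
    # cumulative 2-d count of shared genes with rank1 <= i and rank2 <= j
    k = np.zeros((len(ti), len(tj)), dtype=int)
    for a, i in enumerate(ti):
        sel = r2[r1 <= i]
        sel.sort()
        k[a, :] = np.searchsorted(sel, tj, side="right")
    return k


def rrho_map(
    list1: RankedList,
    list2: RankedList,
    step: int | None = None,
    correction: str | None = None,
) -> RRHOMap:
    """Compute the stratified RRHO grid between two ranked lists.

    Both lists must rank the same background.  ``step`` defaults to
    ceil(sqrt(N)), keeping the grid near 150x150 cells even at transcriptome
    scale.  ``correction`` ("bh" or "by") additionally stores a grid of
    -log10 FDR-adjusted p-values over all cells of all quadrants jointly;
    the primary grid always holds raw p-values.
    """
    bg1, bg2 = set(list1.genes), set(list2.genes)
    if bg1 != bg2:
        missing = sorted(bg1 ^ bg2)
        raise ValueError(f"backgrounds differ; symmetric difference: {missing[:10]}")
    N = len(list1)
    if step is None:
        step = max(1, math.ceil(math.sqrt(N)))
    if step < 1:
        raise ValueError("step must be >= 1")

    strata1 = {"up": list1.up_genes(), "down": list1.down_genes()}
    strata2 = {"up": list2.up_genes(), "down": list2.down_genes()}
    sizes1 = {"up": list1.n_pos, "down": N - list1.n_pos}
    sizes2 = {"up": list2.n_pos, "down": N - list2.n_pos}

    i_thr: dict[str, np.ndarray] = {}
    j_thr: dict[str, np.ndarray] = {}
    grids: dict[str, np.ndarray] = {}
    for q in QUADRANTS:
        s1 = "up" if q[0] == "U" else "down"
        s2 = "up" if q[1] == "U" else "down"
        ti = _thresholds(sizes1[s1], step)
        tj = _thresholds(sizes2[s2], step)
        i_thr[q], j_thr[q] = ti, tj
        if len(ti) == 0 or len(tj) == 0:
            grids[q] = np.zeros((len(ti), len(tj)))
            continue
        k = _overlap_grid(strata1[s1], strata2[s2], ti, tj)
        p = stats.hypergeom.sf(k - 1, N, ti[:, None], tj[None, :])
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        grids[q] = -np.log10(p)

    out = RRHOMap(
        background=list(list1.genes),
        step=step,
        n1_pos=list1.n_pos,
        n2_pos=list2.n_pos,
        strata1=strata1,
        strata2=strata2,
        i_thresholds=i_thr,
        j_thresholds=j_thr,
        grids=grids,
    )
    if correction is not None:
        method = {"bh": "fdr_bh", "by": "fdr_by"}.get(correction)
        if method is None:
            raise ValueError("correction must be 'bh', 'by' or None")
        from statsmodels.stats.multitest import multipletests

        flat = np.concatenate(
            [10.0 ** (-grids[q].ravel()) for q in QUADRANTS if grids[q].size]
        )
        if flat.size:
            adj = multipletests(flat, method=method)[1]
            adj = np.clip(adj, np.finfo(float).tiny, 1.0)
            corrected = {}
            pos = 0
            for q in QUADRANTS:
                size = grids[q].size
                corrected[q] = -np.log10(adj[pos : pos + size]).reshape(grids[q].shape)
                pos += size
            out.corrected_grids = corrected
    return out


def quadrant_peaks(rmap: RRHOMap) -> dict[str, QuadrantPeak]:
    """Locate each quadrant's most significant cell and its overlap genes.

    Ties break toward the smallest row threshold, then the smallest column
    threshold.  An empty quadrant (no genes in a stratum) yields a record
    flagged ``present=False`` rather than an error.
    """
    peaks: dict[str, QuadrantPeak] = {}
    for q in QUADRANTS:
        grid = rmap.grids[q]
        if grid.size == 0:
            peaks[q] = QuadrantPeak(q, 0, 0, 0.0, set(), present=False)
            continue
        a, b = np.unravel_index(np.argmax(grid), grid.shape)  # C-order: first max
        i = int(rmap.i_thresholds[q][a])
        j = int(rmap.j_thresholds[q][b])
        peaks[q] = QuadrantPeak(q, i, j, float(grid[a, b]), rmap.cell_genes(q, i, j))
    return peaks


def intersect_peak_sets(
    named_sets: Mapping[str, Iterable[str]]
) -> dict[frozenset, set[str]]:
    """Exact Venn decomposition of several named gene sets.

    Returns one entry per non-empty membership pattern: the key is the
    frozenset of set names a region belongs to, the value the genes falling
    exactly in that region (inside every named set of the key, outside all
    others).
    """
    sets = {k: set(v) for k, v in named_sets.items()}
    regions: dict[frozenset, set[str]] = {}
    for g in set().union(*sets.values()) if sets else set():
        key = frozenset(k for k, s in sets.items() if g in s)
        regions.setdefault(key, set()).add(g)
    return regions
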