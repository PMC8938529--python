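"""Module-level statistics: DEG enrichment, relevance, key modules, hubs.

Each module is tested for enrichment of each directional DEG set with a
one-sided Fisher exact test over the network background, adjusted jointly
by Benjamini-Hochberg across all module x set tests.  A module's relevance
score is the mean -log10 adjusted p across the eight directional sets (the
circos bar height); a module is "key" when it is significantly enriched in
at least one DEG set from each of the two experiments.  Hubs are module
members whose consensus kME exceeds the module mean by more than one sample
standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import ModulePartition

__all__ = [
    "EnrichmentResult",
    "HubSet",
    "fisher_enrichment",
    "bh_adjust",
    "relevance_score",
    "key_modules",
    "select_hubs",
    "module_edges",
]

log = logging.getLogger(__name__)

_P_FLOOR = 1e-300


@dataclass
class EnrichmentResult:
    """Module x DEG-set Fisher table with joint BH adjustment."""

    table: pd.DataFrame  # module, set, k, module_size, set_size, background, odds_ratio, p, p_adj
    background_size: int
    dropped_genes: dict[str, int] = field(default_factory=dict)  # set -> n dropped

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_adj"] < alpha]


@dataclass
class HubSet:
    """Per-module hub genes by the mu + sigma rule on kME."""

    module: int
    ranking: pd.DataFrame  # gene, kme (descending), is_hub, deg_sets
    threshold: float

    @property
    def hubs(self) -> list[str]:
        return list(self.ranking.index[self.ranking["is_hub"]])


def bh_adjust(p: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrichment(
    partition: ModulePartition,
    degsets: Mapping[str, Iterable[str]],
    background: Iterable[str],
) -> EnrichmentResult:
    """One-sided Fisher enrichment of every module in every DEG set.

    The 2x2 table per (module, set) is [in-module & DEG, in-module not DEG;
    DEG not module, neither]; the one-sided p is the upper hypergeometric
    tail P(X >= k).  DEG genes absent from the background are dropped with a
    logged count.  BH adjustment is applied jointly across all tests.
    """
    bg = list(dict.fromkeys(background))
    bg_set = set(bg)
    N = len(bg)
    dropped: dict[str, int] = {}
    clean: dict[str, set[str]] = {}
    for name, genes in degsets.items():
        s = set(genes)
        out = s - bg_set
        if out:
            log.warning("%d DEG genes of set %r absent from background", len(out), name)
            dropped[name] = len(out)
        clean[name] = s & bg_set

    rows = []
    for mod in partition.module_ids:
        members = set(partition.members(mod)) & bg_set
        K = len(members)
        for name, s in clean.items():
            n = len(s)
            k = len(members & s)
            a, b = k, K - k
            c, d = n - k, N - K - (n - k)
            p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
            odds = (a * d) / (b * c) if b * c > 0 else np.inf
            rows.append((mod, name, k, K, n, N, odds, min(p, 1.0)))
    table = pd.DataFrame(
        rows,
        columns=[
            "module", "set", "k", "module_size", "set_size",
            "background", "odds_ratio", "p",
        ],
    )
    table["p_adj"] = bh_adjust(table["p"]) if len(table) else []
    return EnrichmentResult(table=table, background_size=N, dropped_genes=dropped)


def relevance_score(
    result: EnrichmentResult, use_adjusted: bool = True
) -> pd.Series:
    """Per-module mean -log10 (adjusted) enrichment p over all DEG sets."""
    col = "p_adj" if use_adjusted else "p"
    t = result.table
    neglog = -np.log10(np.clip(t[col].to_numpy(), _P_FLOOR, 1.0))
    s = pd.Series(neglog, index=t["module"].to_numpy()).groupby(level=0).mean()
    s.index.name = "module"
    return s.sort_values(ascending=False)


def key_modules(
    result: EnrichmentResult,
    experiment_of_set: Mapping[str, str],
    alpha: float = 0.05,
) -> pd.Series:
    """Flag modules significantly enriched in both experiments.

    A module is key iff its BH-adjusted enrichment p is below ``alpha`` for
    at least one DEG set of each experiment named in ``experiment_of_set``.
    """
    experiments = sorted(set(experiment_of_set.values()))
    t = result.table
    sig = t[t["p_adj"] < alpha]
    flags = {}
    for mod in sorted(t["module"].unique()):
        hit = {experiment_of_set[s] for s in sig.loc[sig["module"] == mod, "set"]}
        flags[mod] = all(e in hit for e in experiments)
    out = pd.Series(flags, name="key")
    out.index.name = "module"
    return out


def select_hubs(
    kme_consensus: pd.DataFrame,
    partition: ModulePartition,
    module: int,
    degsets: Mapping[str, Iterable[str]] | None = None,
    metric: str = "kme",
    tom: np.ndarray | None = None,
) -> HubSet:
    """Hub genes of a module: members above mean + 1 sample SD.

    By default genes are scored by consensus kME (mean across datasets);
    ``metric="kin"`` instead ranks by intramodular connectivity summed from
    a TOM restricted to the module (the "most connected" reading).  The
    threshold is recomputed per module; a module of fewer than 2 genes has
    no defined spread and raises.
    """
    members = partition.members(module)
    if len(members) < 2:
        raise ValueError(f"module {module} has fewer than 2 genes; sigma undefined")
    if metric == "kme":
        scores = kme_consensus.loc[members, module]
    elif metric == "kin":
        if tom is None:
            raise ValueError("metric='kin' requires a TOM")
        gene_pos = {g: i for i, g in enumerate(partition.labels.index)}
        idx = [gene_pos[g] for g in members]
        sub = tom[np.ix_(idx, idx)].copy()
        np.fill_diagonal(sub, 0.0)
        scores = pd.Series(sub.sum(axis=1), index=members)
    else:
        raise ValueError("metric must be 'kme' or 'kin'")
    mu = float(scores.mean())
    sigma = float(scores.std(ddof=1))
    thr = mu + sigma
    ranking = scores.sort_values(ascending=False).to_frame("score")
    ranking["is_hub"] = (ranking["score"] > thr) if sigma > 0 else False
    if degsets is not None:
        ranking["deg_sets"] = [
            ",".join(sorted(name for name, s in degsets.items() if g in set(s)))
            for g in ranking.index
        ]
    ranking.index.name = "gene"
    return HubSet(module=module, ranking=ranking, threshold=thr)


def module_edges(
    tom: np.ndarray,
    genes: list[str],
    partition: ModulePartition,
    module: int,
    threshold: float = 0.1,
) -> pd.DataFrame:
    """Intramodular edge list (gene1, gene2, weight) with TOM above threshold."""
    pos = {g: i for i, g in enumerate(genes)}
    members = partition.members(module)
    rows = []
    for a_i, g1 in enumerate(members):
        for g2 in members[a_i + 1 :]:
            w = tom[pos[g1], pos[g2]]
            if w > threshold:
                rows.append((g1, g2, float(w)))
    return pd.DataFrame(rows, columns=["gene1", "gene2", "weight"])
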