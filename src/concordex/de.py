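"""Differential expression: log-CPM, empirical-Bayes moderated t, DEG calls.

The moderated t shrinks per-gene sample variances toward a pooled prior
estimated by the method of moments on the log variances (Fisher-z moments of
a scaled chi-square), following the standard empirical-Bayes formulation for
microarray/RNA-seq linear models.  With the prior degrees of freedom forced
to zero it reduces exactly to the ordinary pooled two-sample t; forced to
infinity, every gene shares the prior variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .rrho import RankedList

__all__ = [
    "DEResult",
    "DEGSet",
    "log_cpm",
    "moderated_t",
    "call_degs",
    "signed_rank_score",
]


@dataclass
class DEResult:
    """Per-gene moderated-t results for one two-group contrast.

    ``table`` has columns log2_fc, t, p, signed_score and constant (flag for
    genes with zero variance and zero fold change, reported with p = 1).
    """

    table: pd.DataFrame
    contrast: str
    df_resid: float
    d0: float
    s0_sq: float


@dataclass
class DEGSet:
    """Genes passing the DEG rule (uncorrected p and natural-scale FC cutoffs)."""

    contrast: str
    up: set[str]
    down: set[str]
    p_thresh: float
    fc_thresh: float


def log_cpm(counts: pd.DataFrame, prior_count: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with a prior count.

    entry = log2((count + prior) / (libsize + 2*prior) * 1e6).  Monotone in
    the count within a sample; the doubled prior in the denominator keeps
    values stable under library-size doubling.
    """
    if prior_count <= 0:
        raise ValueError("prior_count must be positive")
    lib = counts.sum(axis=0)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return np.log2(
        (counts + prior_count).div(lib + 2 * prior_count, axis=1) * 1e6
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _moment_prior(s2: np.ndarray, dg: int) -> tuple[float, float]:
    """Method-of-moments estimate of the prior df d0 and prior variance s0^2.

    Uses the moments of log(s^2) for s^2 ~ s0^2 * chi^2_d / d scaled
    chi-square: e_g = log s2_g - digamma(dg/2) + log(dg/2) has mean
    log s0^2 - digamma(d0/2) + log(d0/2) and excess variance trigamma(d0/2).
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return math.inf, float(np.mean(s2[ok])) if ok.any() else 0.0
    e = np.log(s2[ok]) - special.digamma(dg / 2.0) + math.log(dg / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, dg / 2.0))
    if e_var <= 0:
        return math.inf, float(math.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = math.exp(
        e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
    )
    return d0, s0_sq


def moderated_t(
    logexpr: pd.DataFrame,
    contrast: tuple,
    weights: pd.DataFrame | None = None,
    d0: float | None = None,
    contrast_name: str = "",
) -> DEResult:
    """Empirical-Bayes moderated two-group t-test per gene.

    Parameters
    ----------
    logexpr
        genes x samples matrix of log2 expression.
    contrast
        ``(ref_samples, test_samples)`` — two disjoint lists of column
        labels; the log2 fold change is test minus reference.
    weights
        optional precision weights (same shape); when given, group means and
        variances are weighted.
    d0
        override the prior degrees of freedom (0 disables shrinkage,
        ``numpy.inf`` forces complete shrinkage); estimated from the data
        when None.
    """
    ref, test = contrast
    ref = list(ref)
    test = list(test)
    if len(ref) < 2 or len(test) < 2:
        raise ValueError("each group needs at least 2 samples")
    if set(ref) & set(test):
        raise ValueError("contrast groups overlap")

    def _stats(cols):
        x = logexpr[cols].to_numpy(dtype=float)
        if weights is None:
            return x.mean(axis=1), x.var(axis=1, ddof=1), len(cols)
        w = weights[cols].to_numpy(dtype=float)
        wsum = w.sum(axis=1)
        m = (w * x).sum(axis=1) / wsum
        v = (w * (x - m[:, None]) ** 2).sum(axis=1) / (wsum * (len(cols) - 1) / len(cols))
        return m, v, len(cols)

    m1, v1, n1 = _stats(ref)
    m2, v2, n2 = _stats(test)
    dg = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / dg
    fc = m2 - m1

    if d0 is None:
        d0_est, s0_sq = _moment_prior(s2, dg)
    else:
        d0_est = float(d0)
        _, s0_sq = _moment_prior(s2, dg)

    if math.isinf(d0_est):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0_est * s0_sq + dg * s2) / (d0_est + dg)
        df_total = d0_est + dg

    c = math.sqrt(1.0 / n1 + 1.0 / n2)
    se = np.sqrt(s2_post) * c
    constant = (se == 0) | ~np.isfinite(se)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(constant, 0.0, fc / np.where(se == 0, 1.0, se))
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(np.where(constant, 1.0, p), np.finfo(float).tiny, 1.0)
    signed = -np.log10(p) * np.sign(fc)

    table = pd.DataFrame(
        {
            "log2_fc": fc,
            "t": t,
            "p": p,
            "signed_score": signed,
            "constant": constant,
        },
        index=logexpr.index,
    )
    return DEResult(
        table=table,
        contrast=contrast_name,
        df_resid=float(dg),
        d0=float(d0_est),
        s0_sq=float(s0_sq),
    )


def call_degs(de: DEResult, p_thresh: float = 0.05, fc_thresh: float = 1.3) -> DEGSet:
    """Apply the DEG rule: uncorrected p < p_thresh and |FC| > fc_thresh.

    Both inequalities are strict; the fold-change cutoff acts on the natural
    scale in either direction (2**log2_fc > fc_thresh or < 1/fc_thresh).
    """
    if not (0 < p_thresh < 1):
        raise ValueError("p_thresh must lie in (0, 1)")
    if fc_thresh <= 1:
        raise ValueError("fc_thresh must exceed 1")
    t = de.table
    sig = t["p"] < p_thresh
    fc = np.exp2(t["log2_fc"])
    up = set(t.index[sig & (fc > fc_thresh)])
    down = set(t.index[sig & (fc < 1.0 / fc_thresh)])
    return DEGSet(
        contrast=de.contrast, up=up, down=down, p_thresh=p_thresh, fc_thresh=fc_thresh
    )


def signed_rank_score(de: DEResult) -> RankedList:
    """Rank genes by signed significance, -log10(p) * sign(log2FC), descending.

    Ties break lexicographically on the gene id so the ordering is
    deterministic.  The result is a permutation of the full background.
    """
    t = de.table
    if t.index.has_duplicates:
        dups = t.index[t.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dups[:5]}")
    order = sorted(t.index, key=lambda g: (-t.at[g, "signed_score"], g))
    scores = t.loc[order, "signed_score"].to_numpy()
    return RankedList(genes=list(order), scores=scores)
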