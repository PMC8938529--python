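"""End-to-end orchestration: simulate -> DE -> RRHO -> network -> enrichment
-> hubs -> behavior, with per-stage artifacts and a machine-readable report.

The run is fully described by a :class:`RunConfig`; the config (and its
SHA-256 hash, embedded in every artifact header) is serialized into the
output directory so a run can be reproduced byte-for-byte from it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bh
from . import de as de_mod
from . import io as cio
from . import modules as mod_stats
from . import network as net
from . import rrho as rrho_mod
from .simulate import (
    CONTRASTS,
    SimConfig,
    config_from_dict,
    config_to_dict,
    simulate_behavior,
    simulate_counts,
)

__all__ = ["RunConfig", "run_pipeline", "PipelineError", "ALL_STAGES"]

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "de", "rrho", "network", "enrich", "hubs", "behavior")

#: Fig-2-style RRHO pairings: each CORT-model contrast against each
#: defeat-model contrast.
RRHO_PAIRINGS = (("WT", "SH"), ("hMet", "SH"), ("WT", "EE"), ("hMet", "EE"))


class PipelineError(RuntimeError):
    """A stage failed; the partial output directory is preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    stages: tuple = ALL_STAGES
    # DE
    prior_count: float = 0.5
    p_thresh: float = 0.05
    fc_thresh: float = 1.3
    # RRHO
    rrho_step: int | None = None  # None -> ceil(sqrt(N))
    rrho_correction: str | None = None
    # network
    beta: int | None = None  # None -> scale-free criterion per dataset, max
    beta_candidates: tuple = tuple(range(1, 21))
    r2_target: float = 0.8
    signed: bool = True
    calib_quantile: float = 0.95
    min_module_size: int = 20
    cut_height: float = 0.995
    kme_min: float = 0.35
    refine_iter: int = 5
    reseed_rounds: int = 2
    merge_height: float = 0.25
    final_min_size: int = 30
    validate_modules: bool = False
    # enrichment / hubs
    fdr_alpha: float = 0.05
    hub_metric: str = "kme"
    edge_threshold: float = 0.1
    # behavior
    control_groups: tuple = (("A", "WT-VEH"), ("B", "SH-RES"))
    out_dir: str = "concordex_run"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = config_to_dict(self.sim)
        for key in ("stages", "beta_candidates", "control_groups"):
            d[key] = list(d[key])
        d["control_groups"] = [list(t) for t in self.control_groups]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d:
            sim = d["sim"]
            d["sim"] = sim if isinstance(sim, SimConfig) else config_from_dict(sim)
        for key in ("stages", "beta_candidates"):
            if key in d:
                d[key] = tuple(d[key])
        if "control_groups" in d:
            d["control_groups"] = tuple(tuple(t) for t in d["control_groups"])
        return cls(**d)

    def hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # identical analyses hash alike wherever written
        canon = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _deg_ring_sets(degsets: dict[str, de_mod.DEGSet]) -> dict[str, set[str]]:
    """The eight directional DEG sets, one up-set per group of each contrast."""
    rings: dict[str, set[str]] = {}
    for c in CONTRASTS:
        ds = degsets[c["name"]]
        rings[f"{c['test']}_up"] = ds.up
        rings[f"{c['ref']}_up"] = ds.down
    return rings


def _ring_experiments() -> dict[str, str]:
    out = {}
    for c in CONTRASTS:
        out[f"{c['test']}_up"] = c["experiment"]
        out[f"{c['ref']}_up"] = c["experiment"]
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the report dictionary.

    Artifacts are written under ``config.out_dir``; the report is also
    saved there as ``report.json``.  Later stages reuse earlier results in
    memory, so the stage list must be a prefix-closed subset of
    :data:`ALL_STAGES`.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    comment = f"config_hash: {chash}"
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=1))

    report: dict = {"config_hash": chash, "seed": config.seed, "stages": []}
    sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
    state: dict = {}

    stage_fns = {
        "simulate": _stage_simulate,
        "de": _stage_de,
        "rrho": _stage_rrho,
        "network": _stage_network,
        "enrich": _stage_enrich,
        "hubs": _stage_hubs,
        "behavior": _stage_behavior,
    }
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        log.info("running stage %s", stage)
        try:
            stage_fns[stage](config, sim_cfg, state, report, out, comment)
        except Exception as exc:  # noqa: BLE001 - abort with stage context
            raise PipelineError(stage, exc) from exc
        report["stages"].append(stage)

    cio.write_json(report, out / "report.json")
    return report


def _stage_simulate(config, sim_cfg, state, report, out, comment):
    cm_a, cm_b, truth = simulate_counts(sim_cfg)
    state.update(cm_a=cm_a, cm_b=cm_b, truth=truth)
    cio.write_count_matrix(cm_a, out / "experimentA", comment)
    cio.write_count_matrix(cm_b, out / "experimentB", comment)
    cio.write_ground_truth(truth, out / "ground_truth.json")
    report["simulate"] = {
        "n_genes": int(cm_a.counts.shape[0]),
        "samples_a": int(cm_a.counts.shape[1]),
        "samples_b": int(cm_b.counts.shape[1]),
        "seed": sim_cfg.seed,
    }


def _stage_de(config, sim_cfg, state, report, out, comment):
    results: dict[str, de_mod.DEResult] = {}
    degsets: dict[str, de_mod.DEGSet] = {}
    ranked: dict[str, rrho_mod.RankedList] = {}
    for c in CONTRASTS:
        cm = state["cm_a"] if c["experiment"] == "A" else state["cm_b"]
        logexpr = de_mod.log_cpm(cm.counts, config.prior_count)
        samples = cm.samples
        ref = list(samples.index[samples["group"] == c["ref"]])
        test = list(samples.index[samples["group"] == c["test"]])
        res = de_mod.moderated_t(logexpr, (ref, test), contrast_name=c["name"])
        results[c["name"]] = res
        degsets[c["name"]] = de_mod.call_degs(res, config.p_thresh, config.fc_thresh)
        ranked[c["name"]] = de_mod.signed_rank_score(res)
        cio.write_table(res.table, out / f"de_{c['name']}.tsv", comment)
    state.update(de=results, degsets=degsets, ranked=ranked)
    report["de"] = {
        name: {
            "n_up": len(ds.up),
            "n_down": len(ds.down),
            "d0": results[name].d0,
        }
        for name, ds in degsets.items()
    }
    shared_up = {
        "CORT": sorted(degsets["WT"].up & degsets["hMet"].up),
        "CSDS_SUS": sorted(degsets["SH"].up & degsets["EE"].up),
    }
    report["de"]["shared"] = {k: len(v) for k, v in shared_up.items()}


def _stage_rrho(config, sim_cfg, state, report, out, comment):
    rep = {}
    maps = {}
    for name1, name2 in RRHO_PAIRINGS:
        rmap = rrho_mod.rrho_map(
            state["ranked"][name1],
            state["ranked"][name2],
            step=config.rrho_step,
            correction=config.rrho_correction,
        )
        peaks = rrho_mod.quadrant_peaks(rmap)
        key = f"{name1}_vs_{name2}"
        maps[key] = (rmap, peaks)
        for q, grid in rmap.grids.items():
            df = pd.DataFrame(
                grid, index=rmap.i_thresholds[q], columns=rmap.j_thresholds[q]
            )
            cio.write_table(df, out / f"rrho_{key}_{q}.tsv", comment)
        cio.write_json(
            {
                q: {
                    "i": p.i,
                    "j": p.j,
                    "neglog_p": p.neglog_p,
                    "present": p.present,
                    "genes": sorted(p.genes),
                }
                for q, p in peaks.items()
            },
            out / f"rrho_{key}_peaks.json",
        )
        rep[key] = {q: round(p.neglog_p, 3) for q, p in peaks.items()}
    # Venn of the concordant-up peak sets across the two susceptibility-like
    # pairings, mirroring the shared-gene counts of interest
    uu_sets = {k: maps[k][1]["UU"].genes for k in ("WT_vs_SH", "hMet_vs_SH")}
    regions = rrho_mod.intersect_peak_sets(uu_sets)
    shared = regions.get(frozenset(uu_sets), set())
    rep["UU_shared_WT_hMet_vs_SH"] = len(shared)
    state["rrho"] = maps
    report["rrho"] = rep


def _stage_network(config, sim_cfg, state, report, out, comment):
    exprs = {}
    for name, key in (("A", "cm_a"), ("B", "cm_b")):
        exprs[name] = de_mod.log_cpm(state[key].counts, config.prior_count)
    # genes must be informative in both datasets
    keep = exprs["A"].index
    n_all = len(keep)
    for e in exprs.values():
        sd = e.std(axis=1)
        keep = keep.intersection(sd.index[sd > 0])
    dropped = n_all - len(keep)
    if dropped:
        log.info("network: dropped %d zero-variance genes", dropped)
    exprs = {k: v.loc[keep] for k, v in exprs.items()}

    if config.beta is None:
        picks = {
            k: net.pick_soft_power(
                e, config.beta_candidates, config.r2_target, config.signed
            )
            for k, e in exprs.items()
        }
        beta = max(p.beta for p in picks.values())
        beta_info = {k: {"beta": p.beta, "r2": p.r_squared} for k, p in picks.items()}
    else:
        beta = config.beta
        beta_info = {"fixed": beta}

    toms = {}
    for k, e in exprs.items():
        toms[k] = net.tom(net.adjacency(e, beta=beta, signed=config.signed))
    cons = net.consensus_tom(toms["A"], toms["B"], config.calib_quantile)
    dissim = 1.0 - cons.matrix
    np.fill_diagonal(dissim, 0.0)
    detect_kwargs = dict(
        min_size=config.min_module_size,
        cut_height=config.cut_height,
        kme_min=config.kme_min,
        refine_iter=config.refine_iter,
        merge_height=config.merge_height,
        reseed_rounds=config.reseed_rounds,
        final_min_size=config.final_min_size,
    )
    part = net.detect_modules(dissim, cons.genes, exprs, **detect_kwargs)
    coherence_floor = None
    if config.validate_modules:
        coherence_floor = net.null_coherence_floor(
            exprs,
            beta,
            rng=np.random.default_rng(config.seed + 7919),
            signed=config.signed,
            calib_quantile=config.calib_quantile,
            **detect_kwargs,
        )
        part, _ = net.prune_incoherent(
            part, exprs, coherence_floor, config.merge_height
        )
    state.update(exprs=exprs, toms=toms, consensus=cons, partition=part)

    cio.write_table(part.labels.to_frame("module"), out / "modules.tsv", comment)
    for k in exprs:
        cio.write_table(
            part.eigengene_per_dataset[k], out / f"eigengenes_{k}.tsv", comment
        )
        cio.write_table(part.kme_per_dataset[k], out / f"kme_{k}.tsv", comment)
    report["network"] = {
        "beta": beta,
        "beta_selection": beta_info,
        "coherence_floor": coherence_floor,
        "n_genes": len(keep),
        "n_dropped": dropped,
        "n_modules": len(part.module_ids),
        "module_sizes": {m: len(part.members(m)) for m in part.module_ids},
    }


def _stage_enrich(config, sim_cfg, state, report, out, comment):
    rings = _deg_ring_sets(state["degsets"])
    background = list(state["partition"].labels.index)
    enr = mod_stats.fisher_enrichment(state["partition"], rings, background)
    relevance = mod_stats.relevance_score(enr)
    keys = mod_stats.key_modules(enr, _ring_experiments(), config.fdr_alpha)
    state.update(enrichment=enr, relevance=relevance, key_flags=keys, rings=rings)
    cio.write_table(enr.table, out / "enrichment.tsv", comment, index=False)
    circos = relevance.to_frame("relevance")
    circos["key"] = keys.reindex(relevance.index)
    cio.write_table(circos, out / "relevance.tsv", comment)
    report["enrich"] = {
        "relevance_ranking": [int(m) for m in relevance.index],
        "key_modules": [int(m) for m in keys.index[keys]],
    }


def _stage_hubs(config, sim_cfg, state, report, out, comment):
    part = state["partition"]
    kme_cons = part.consensus_kme()
    hubs_rep = {}
    keys = state["key_flags"]
    targets = [int(m) for m in keys.index[keys]] or part.module_ids[:2]
    for m in targets:
        hs = mod_stats.select_hubs(
            kme_cons,
            part,
            m,
            degsets=state["rings"],
            metric=config.hub_metric,
            tom=state["consensus"].matrix,
        )
        cio.write_table(hs.ranking, out / f"hubs_module{m}.tsv", comment)
        edges = mod_stats.module_edges(
            state["consensus"].matrix,
            state["consensus"].genes,
            part,
            m,
            config.edge_threshold,
        )
        cio.write_table(edges, out / f"edges_module{m}.tsv", comment, index=False)
        hubs_rep[m] = hs.hubs
    state["hubs"] = hubs_rep
    report["hubs"] = {str(m): v for m, v in hubs_rep.items()}


def _stage_behavior(config, sim_cfg, state, report, out, comment):
    bt_a, bt_b = simulate_behavior(sim_cfg)
    cio.write_behavior(bt_a, out / "behavior_A.csv", comment)
    cio.write_behavior(bt_b, out / "behavior_B.csv", comment)
    controls = dict(config.control_groups)
    rep = {}
    for name, table in (("A", bt_a), ("B", bt_b)):
        scored = bh.score_emotionality(table, controls[name])
        cio.write_table(scored, out / f"emotionality_{name}.tsv", comment)
        rep[name] = {
            g: round(float(v), 4)
            for g, v in scored.groupby("group")["emotionality"].mean().items()
        }
    # defeat-model phenotype table from the SI ratio
    pheno = pd.Series(
        bh.classify_si(bt_b.data["si_ratio"].to_numpy()), index=bt_b.data.index
    )
    housing = bt_b.data["group"].str.split("-").str[0]
    counts = pd.crosstab(pheno, housing).reindex(
        index=["SUS", "RES"], columns=["SH", "EE"], fill_value=0
    )
    props = bh.cohort_proportions(counts)
    rep["phenotype_percent"] = {
        f"{p}_{h}": int(props.rounded.loc[p, h])
        for p in props.rounded.index
        for h in props.rounded.columns
    }
    rep["phenotype_fisher_p"] = props.fisher_p
    state.update(behavior=(bt_a, bt_b))
    report["behavior"] = rep
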