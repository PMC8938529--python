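"""Synthetic paired stress-model datasets with planted structure.

Generates two bulk RNA-seq count matrices that emulate the study design this
package analyzes: experiment A crosses genotype (WT vs hMet) with chronic
oral corticosterone (VEH vs CORT); experiment B crosses housing (SH vs EE)
with the social-defeat outcome (SUS vs RES).  Gene modules are planted as
latent-factor blocks whose loadings are shared between the two experiments,
so a consensus co-expression analysis should recover them.  Two designated
modules additionally carry concordant differential-expression shifts: a
"susceptibility" module up-shifted in CORT-treated groups (both genotypes)
and in SH-SUS, and a "resilience" module up-shifted in hMet-VEH and EE-SUS.

Every draw flows from one :class:`numpy.random.Generator` seeded from
``SimConfig.seed``, so identical configs reproduce byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "CountMatrix",
    "BehaviorTable",
    "CONTRASTS",
    "simulate_counts",
    "simulate_behavior",
]

GROUPS_A = ("WT-VEH", "WT-CORT", "hMet-VEH", "hMet-CORT")
GROUPS_B = ("SH-SUS", "SH-RES", "EE-SUS", "EE-RES")

#: canonical two-group contrasts, one per genotype / housing condition;
#: log2 fold changes are test minus reference.
CONTRASTS = (
    {"name": "WT", "experiment": "A", "ref": "WT-VEH", "test": "WT-CORT"},
    {"name": "hMet", "experiment": "A", "ref": "hMet-VEH", "test": "hMet-CORT"},
    {"name": "SH", "experiment": "B", "ref": "SH-RES", "test": "SH-SUS"},
    {"name": "EE", "experiment": "B", "ref": "EE-RES", "test": "EE-SUS"},
)

# behavioral variables: (test, control mean, control sd) -- units are % for
# time in light, seconds for latencies/durations, counts for sessions,
# dimensionless for the SI ratio
BEHAVIOR_VARS_A = {
    "pct_time_light": ("light_dark", 30.0, 8.0),
    "latency_to_light": ("light_dark", 60.0, 20.0),
    "latency_to_dark": ("light_dark", 20.0, 8.0),
    "grooming_time": ("splash", 80.0, 20.0),
    "grooming_sessions": ("splash", 8.0, 2.0),
    "grooming_latency": ("splash", 40.0, 15.0),
}
BEHAVIOR_VARS_B = {
    "si_zone_time": ("social_interaction", 80.0, 20.0),
    "si_ratio": ("social_interaction", None, None),  # drawn from phenotype
}

#: sign that makes a larger directional z mean more emotionality
DIRECTIONS = {
    "pct_time_light": -1,
    "latency_to_light": +1,
    "latency_to_dark": -1,
    "grooming_time": -1,
    "grooming_sessions": -1,
    "grooming_latency": +1,
    "si_zone_time": -1,
    "si_ratio": -1,
}


class ConfigError(ValueError):
    """Raised for an internally inconsistent simulation configuration."""


def _default_affected() -> dict[int, tuple[tuple[str, str], ...]]:
    # module id -> (experiment, group) pairs receiving the up-shift
    return {
        1: (("A", "WT-CORT"), ("A", "hMet-CORT"), ("B", "SH-SUS")),
        2: (("A", "hMet-VEH"), ("B", "EE-SUS")),
    }


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the paired-experiment simulation.

    Defaults are sized for desk-scale runs that still support module
    recovery: 2000 genes, ten planted modules of 50 genes, six biological
    replicates per group, negative-binomial dispersion 0.2 and a planted
    log2 fold change of 0.6 (fold change ~1.52, just past the 1.3 DEG
    cutoff used downstream).
    """

    n_genes: int = 2000
    n_modules: int = 10
    module_size: int = 50
    groups_a: Sequence[str] = GROUPS_A
    groups_b: Sequence[str] = GROUPS_B
    n_per_group: int = 6
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    nb_dispersion: float = 0.2
    libsize_log_mean: float = 0.0
    libsize_log_sd: float = 0.25
    module_loading_range: tuple[float, float] = (0.35, 0.7)
    de_log2fc: float = 0.6
    susceptibility_module_id: int = 1
    resilience_module_id: int = 2
    affected_contrasts: Mapping[int, tuple] = field(default_factory=_default_affected)
    n_behavior_per_group: int = 10
    behavior_effect_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise ConfigError(
                f"{self.n_modules} modules x {self.module_size} genes exceed "
                f"n_genes={self.n_genes}"
            )
        if not np.isfinite(self.de_log2fc):
            raise ConfigError("de_log2fc must be finite")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        lo, hi = self.module_loading_range
        if not (0 < lo <= hi <= 1):
            raise ConfigError("module_loading_range must lie in (0, 1]")
        for mid in self.affected_contrasts:
            if not (1 <= mid <= self.n_modules):
                raise ConfigError(f"affected module {mid} not in 1..{self.n_modules}")


@dataclass
class GroundTruth:
    """Planted structure of a simulation, serialized alongside its outputs."""

    module_of_gene: dict[str, int]  # 0 = background / unassigned
    de_genes_per_contrast: dict[str, dict[str, int]]  # contrast -> gene -> sign

    def to_json(self) -> str:
        return json.dumps(
            {
                "module_of_gene": self.module_of_gene,
                "de_genes_per_contrast": self.de_genes_per_contrast,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            module_of_gene={g: int(m) for g, m in d["module_of_gene"].items()},
            de_genes_per_contrast={
                c: {g: int(s) for g, s in genes.items()}
                for c, genes in d["de_genes_per_contrast"].items()
            },
        )


@dataclass
class CountMatrix:
    """Integer gene x sample counts plus sample annotations."""

    counts: pd.DataFrame  # genes x samples, int
    samples: pd.DataFrame  # index = sample id; columns experiment, group, factor1, factor2

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class BehaviorTable:
    """Animal x variable measurements with group labels.

    ``tests`` maps each variable to the behavioral test it came from and
    ``directions`` gives the sign that orients its z-score so that larger
    means more anxiety/depression-like (emotionality).
    """

    data: pd.DataFrame  # index = animal id; columns: group + variables
    tests: dict[str, str]
    directions: dict[str, int]

    @property
    def variables(self) -> list[str]:
        return [c for c in self.data.columns if c != "group"]


def _sample_frame(groups: Sequence[str], n: int, experiment: str) -> pd.DataFrame:
    rows = []
    for g in groups:
        f1, f2 = g.split("-", 1)
        for r in range(n):
            rows.append((f"{experiment}_{g}_{r + 1}", experiment, g, f1, f2))
    return pd.DataFrame(
        rows, columns=["sample", "experiment", "group", "factor1", "factor2"]
    ).set_index("sample")


def _simulate_experiment(
    rng: np.random.Generator,
    cfg: SimConfig,
    experiment: str,
    groups: Sequence[str],
    genes: pd.Index,
    module_of: np.ndarray,
    baseline: np.ndarray,
    loading: np.ndarray,
) -> CountMatrix:
    samples = _sample_frame(groups, cfg.n_per_group, experiment)
    n_samp = len(samples)
    # one latent factor per module per sample; module genes load on it with a
    # shared positive loading so blocks are positively correlated.  Factors
    # are centered within each experimental group so that group contrasts
    # reflect the planted shifts, not factor sampling noise (which would
    # otherwise move a whole module coherently by ~loading/sqrt(n) per draw
    # and make the planted ground truth unidentifiable at replicate scale).
    factors = rng.normal(size=(cfg.n_modules + 1, n_samp))  # row 0 unused
    group_codes = samples["group"].to_numpy()
    for g in np.unique(group_codes):
        cols = group_codes == g
        factors[:, cols] -= factors[:, cols].mean(axis=1, keepdims=True)
    lib_scale = np.exp(rng.normal(cfg.libsize_log_mean, cfg.libsize_log_sd, n_samp))
    samples = samples.assign(lib_scale=lib_scale)

    shift = np.zeros((len(genes), n_samp))
    group_arr = samples["group"].to_numpy()
    for mid, targets in cfg.affected_contrasts.items():
        gene_mask = module_of == mid
        for exp_name, grp in targets:
            if exp_name != experiment:
                continue
            shift[np.ix_(gene_mask, group_arr == grp)] += cfg.de_log2fc

    log2_mu = (
        baseline[:, None]
        + loading[:, None] * factors[module_of, :]
        + shift
    )
    mu = np.exp2(log2_mu) * lib_scale[None, :]
    r = 1.0 / cfg.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    # plain (unnamed) sample-id header, matching the TSV layout on disk
    df = pd.DataFrame(
        counts, index=genes, columns=samples.index.rename(None), dtype=np.int64
    )
    return CountMatrix(counts=df, samples=samples)


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, CountMatrix, GroundTruth]:
    """Draw the paired count matrices and their ground truth.

    Module membership, baselines and loadings are drawn once and shared by
    both experiments (the consensus-network assumption); counts are negative
    binomial with gene-wise mean ``2**(baseline + loading*factor + shift)``
    scaled by a lognormal library-size factor, and a dispersion common to
    all genes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_genes
    genes = pd.Index([f"g{i:04d}" for i in range(n)], name="gene")
    module_of = np.zeros(n, dtype=int)
    assigned = rng.permutation(n)[: config.n_modules * config.module_size]
    for m in range(config.n_modules):
        module_of[assigned[m * config.module_size : (m + 1) * config.module_size]] = m + 1

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)
    lo, hi = config.module_loading_range
    loading = np.where(module_of > 0, rng.uniform(lo, hi, n), 0.0)

    cm_a = _simulate_experiment(
        rng, config, "A", config.groups_a, genes, module_of, baseline, loading
    )
    cm_b = _simulate_experiment(
        rng, config, "B", config.groups_b, genes, module_of, baseline, loading
    )

    # ground-truth DE per canonical contrast: sign of the planted shift in
    # the test group relative to the reference group
    de: dict[str, dict[str, int]] = {c["name"]: {} for c in CONTRASTS}
    for mid, targets in config.affected_contrasts.items():
        members = [genes[i] for i in np.flatnonzero(module_of == mid)]
        for c in CONTRASTS:
            in_test = (c["experiment"], c["test"]) in targets
            in_ref = (c["experiment"], c["ref"]) in targets
            sign = int(in_test) - int(in_ref)
            if sign != 0:
                for g in members:
                    de[c["name"]][g] = sign

    truth = GroundTruth(
        module_of_gene={genes[i]: int(module_of[i]) for i in range(n)},
        de_genes_per_contrast=de,
    )
    return cm_a, cm_b, truth


def _susceptible_like(experiment: str, group: str) -> bool:
    if experiment == "A":
        return group.endswith("CORT")
    return group.endswith("SUS")


def _simulate_behavior_experiment(
    rng: np.random.Generator, cfg: SimConfig, experiment: str, groups: Sequence[str]
) -> BehaviorTable:
    variables = BEHAVIOR_VARS_A if experiment == "A" else BEHAVIOR_VARS_B
    n = cfg.n_behavior_per_group
    rows: dict[str, list] = {"group": []}
    animals = []
    for g in groups:
        for r in range(n):
            animals.append(f"{experiment}_{g}_a{r + 1}")
            rows["group"].append(g)
    groups_vec = np.repeat(list(groups), n)

    for var, (test, mean, sd) in variables.items():
        if var == "si_ratio":
            # drawn so that classification by ratio > 1 matches the group label
            vals = np.empty(len(animals))
            for g in groups:
                mask = groups_vec == g
                if g.endswith("SUS"):
                    draw = rng.normal(0.7, 0.15, mask.sum())
                    vals[mask] = np.clip(draw, 0.05, 0.99)
                else:
                    draw = rng.normal(1.4, 0.25, mask.sum())
                    vals[mask] = np.maximum(draw, 1.01)
            rows[var] = list(vals)
            continue
        shift = np.where(
            [_susceptible_like(experiment, g) for g in groups_vec],
            cfg.behavior_effect_sd * sd * DIRECTIONS[var],
            0.0,
        )
        vals = rng.normal(mean, sd, len(animals)) + shift
        if var.endswith("sessions"):
            vals = np.maximum(np.round(vals), 0)
        else:
            vals = np.maximum(vals, 0.0)
        rows[var] = list(vals)

    data = pd.DataFrame(rows, index=pd.Index(animals, name="animal"))
    tests = {v: variables[v][0] for v in variables}
    dirs = {v: DIRECTIONS[v] for v in variables}
    return BehaviorTable(data=data, tests=tests, directions=dirs)


def simulate_behavior(config: SimConfig) -> tuple[BehaviorTable, BehaviorTable]:
    """Draw behavioral tables for both experiments.

    Each variable is normal with a group-specific mean: susceptible-like
    groups (CORT-treated in experiment A, defeat-susceptible in experiment
    B) are shifted by ``behavior_effect_sd`` control standard deviations in
    the emotionality-increasing direction.  The SI ratio is drawn from
    truncated normals on the proper side of 1 so phenotype classification
    reproduces the group labels.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)  # independent of the count draw
    bt_a = _simulate_behavior_experiment(rng, config, "A", config.groups_a)
    bt_b = _simulate_behavior_experiment(rng, config, "B", config.groups_b)
    return bt_a, bt_b


def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["affected_contrasts"] = {
        str(k): [list(t) for t in v] for k, v in config.affected_contrasts.items()
    }
    d["module_loading_range"] = list(config.module_loading_range)
    return d


def config_from_dict(d: Mapping) -> SimConfig:
    d = dict(d)
    if "affected_contrasts" in d:
        d["affected_contrasts"] = {
            int(k): tuple(tuple(t) for t in v)
            for k, v in d["affected_contrasts"].items()
        }
    if "module_loading_range" in d:
        d["module_loading_range"] = tuple(d["module_loading_range"])
    for key in ("groups_a", "groups_b"):
        if key in d:
            d[key] = tuple(d[key])
    return SimConfig(**d)
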