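import warnings
from fractions import Fraction
from math import comb

import pytest

from concordex.pipeline import RunConfig, run_pipeline
from concordex.simulate import SimConfig, simulate_behavior, simulate_counts

warnings.filterwarnings("ignore", category=UserWarning)


def hypergeom_tail_exact(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail P(X >= k), X ~ Hypergeom(N, K, n), by enumeration.

    Independent oracle: rational arithmetic over binomial coefficients,
    no scipy involved.
    """
    total = comb(N, n)
    acc = Fraction(0)
    for x in range(k, min(K, n) + 1):
        acc += Fraction(comb(K, x) * comb(N - K, n - x), total)
    return float(acc)


def fisher_two_sided_exact(table) -> float:
    """Exact two-sided Fisher p for a 2x2 table by full enumeration."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    N = r1 + r2

    def prob(x):
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(N, c1))

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return float(sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs))


@pytest.fixture(scope="session")
def sim_default():
    """Default paired simulation, seed 0, with ground truth."""
    cfg = SimConfig(seed=0)
    cm_a, cm_b, truth = simulate_counts(cfg)
    return cfg, cm_a, cm_b, truth


@pytest.fixture(scope="session")
def behavior_default():
    cfg = SimConfig(seed=0)
    return simulate_behavior(cfg)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run at the default configuration, seed 0."""
    out = tmp_path_factory.mktemp("run0")
    cfg = RunConfig(out_dir=str(out), seed=0)
    report = run_pipeline(cfg)
    return cfg, report, out
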