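import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from lncm6a import (
    ExpressionMatrix,
    SimulationConfig,
    filter_expressed,
    log2_transform,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """A compact cohort: fast to generate, still carries every planted layer."""
    return SimulationConfig(
        n_samples=300, n_lncrnas=60, n_mirnas=10, n_mrnas=80, seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return simulate_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_logged(small_cohort):
    expr, _, _ = small_cohort
    return log2_transform(filter_expressed(expr))


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    values = pd.DataFrame(
        [[0.0, 3.0, 7.0, 1.0], [1.0, 1.0, 0.0, 0.0], [2.0, 2.0, 2.0, 2.0]],
        index=["METTL3", "LNC1", "G1"],
        columns=["s1", "s2", "s3", "s4"],
    )
    roles = pd.Series(
        {"METTL3": "regulator", "LNC1": "lncRNA", "G1": "mRNA"}
    )
    return ExpressionMatrix(values=values, roles=roles)


# ---------------------------------------------------------------------------
# independent oracles, deliberately naive


def naive_enrichment_walk(metrics, hit_flags, weight_p=1.0):
    """Literal per-position evaluation of the running sum P_hit - P_miss."""
    n = len(metrics)
    nh = sum(hit_flags)
    nr = sum(abs(m) ** weight_p for m, h in zip(metrics, hit_flags) if h)
    walk = []
    p_hit = p_miss = 0.0
    for m, h in zip(metrics, hit_flags):
        if h:
            p_hit += abs(m) ** weight_p / nr
        else:
            p_miss += 1.0 / (n - nh)
        walk.append(p_hit - p_miss)
    peak = max(abs(v) for v in walk)
    best = next(v for v in walk if abs(v) >= peak - 1e-9)
    return best, walk


def naive_bh(p):
    """Textbook step-up: sort, scale by m/rank, enforce monotonicity, cap."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        val = min(prev, p[i] * m / rank, 1.0)
        q[i] = val
        prev = val
    return q


IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T", "D": "AGT", "R": "AG",
    "H": "ACT", "N": "ACGT",
}


def naive_motif_count(seq, pattern="DRACH"):
    seq = seq.upper().replace("U", "T")
    k = len(pattern)
    count = 0
    for i in range(len(seq) - k + 1):
        if all(seq[i + j] in IUPAC_SETS[c] for j, c in enumerate(pattern)):
            count += 1
    return count


def naive_hypergeom_upper(k, M, K, n):
    from math import comb

    total = comb(M, n)
    return sum(
        comb(K, x) * comb(M - K, n - x)
        for x in range(k, min(K, n) + 1)
    ) / total
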