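import numpy as np
import pytest

from traumapanel import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort under the default calibration profile, seed 42."""
    return generate_cohort(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def null_config():
    """Generator config with every group/severity/delayed effect zeroed, so
    analyte distributions are exchangeable across groups."""
    return GeneratorConfig(
        amplitude_mean=0.0,
        amplitude_sd=0.0,
        delayed_effect_size=0.0,
        delayed_r_level=0.0,
        iss_effect_slope=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_config():
    """Reduced cohort/panel for fast structural tests."""
    return GeneratorConfig(
        group_sizes={"ENS": 4, "R": 8, "NR": 10, "CONTROL": 3},
        n_analytes_per_family={
            "IL": 6, "CCL": 4, "CXCL": 2, "IFN": 3, "TNFSF": 2,
            "IL_R": 3, "IFN_R": 1, "TNFRSF": 2,
        },
        delayed_subset_fraction=0.2,
        seed=7,
    )


def grouping_from_meta(meta):
    def fn(sample_id):
        row = meta.loc[sample_id]
        return row["group"], row["timepoint"]

    return fn


def brute_force_bh(p):
    """Independent step-up implementation of Benjamini-Hochberg from the
    definition: sort ascending, multiply p_(i) by m/i, enforce monotone
    non-decreasing from the largest rank down, cap at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        adj[idx] = running_min
    return adj


def brute_force_auroc(labels, scores):
    """Pair-counting concordance: P(score_pos > score_neg) + 0.5 P(tie)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
    return wins / (len(pos) * len(neg))


def exact_mwu_p(a, b):
    """Full enumeration of the Mann-Whitney null: the two-tailed p is the
    fraction of label assignments whose U statistic is at least as extreme
    (in either direction) as the observed one.  Tie-free data only."""
    from itertools import combinations

    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)

    def u_of(group_a):
        rest = list(pooled)
        for x in group_a:
            rest.remove(x)
        return sum(x > y for x in group_a for y in rest)

    u_obs = u_of(a)
    n1n2 = n1 * len(b)
    dev_obs = abs(u_obs - n1n2 / 2)
    count = 0
    total = 0
    for combo in combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in combo]
        if abs(u_of(ga) - n1n2 / 2) >= dev_obs:
            count += 1
        total += 1
    return count / total
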