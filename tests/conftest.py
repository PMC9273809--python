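import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mct_kit.changes import compute_changes
from mct_kit.synthetic import SyntheticCohortConfig, generate_cohort

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def demo_cohort():
    """The packaged demo cohort: default config, fixed documented seed."""
    return generate_cohort()


@pytest.fixture(scope="session")
def demo_changes(demo_cohort):
    changes, _ = compute_changes(demo_cohort)
    return changes


@pytest.fixture(scope="session")
def big_cohort():
    """A large cohort without missingness, for Monte-Carlo checks."""
    config = SyntheticCohortConfig(n_patients=5000, seed=7, endpoint_missing_rate=0.0)
    return generate_cohort(config)


# -- independent oracles (used by unit and acceptance tests) ----------------

def midranks(values):
    """Average ranks by brute-force enumeration (1-based, ties share)."""
    ranks = []
    for xi in values:
        less = sum(1 for xj in values if xj < xi)
        equal = sum(1 for xj in values if xj == xi)
        ranks.append(less + (equal + 1) / 2.0)
    return ranks


def spearman_oracle(x, y):
    """Rank both vectors by enumeration, then Pearson on the ranks."""
    rx, ry = midranks(list(x)), midranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    sxx = sum((a - mx) ** 2 for a in rx)
    syy = sum((b - my) ** 2 for b in ry)
    return sxy / np.sqrt(sxx * syy)


def ks_oracle(a, b):
    """Max over pooled values of |F_a - F_b| (brute force)."""
    a, b = list(a), list(b)
    best = 0.0
    for v in a + b:
        fa = sum(1 for x in a if x <= v) / len(a)
        fb = sum(1 for x in b if x <= v) / len(b)
        best = max(best, abs(fa - fb))
    return best
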