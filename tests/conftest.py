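import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mpisurv as m

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240215)


def random_outcomes(rng, n, tie_times=False, event_p=0.6):
    """Random censored cohort; with tie_times, times land on a coarse grid."""
    if tie_times:
        t = rng.choice(np.arange(1.0, 8.0), size=n)
    else:
        t = rng.exponential(100.0, n) + 0.5
    d = (rng.uniform(size=n) < event_p).astype(int)
    return [m.SubjectOutcome(f"s{i}", float(t[i]), int(d[i]))
            for i in range(n)]


@pytest.fixture
def random_outcomes_factory():
    return random_outcomes


def pll_bruteforce(scores, outcomes):
    """Term-by-term enumeration of the Breslow log partial likelihood."""
    t = np.array([o.time_days for o in outcomes])
    d = np.array([o.event for o in outcomes])
    f = np.asarray(scores, dtype=float)
    total = 0.0
    for i in range(len(outcomes)):
        if d[i] == 1:
            risk = t >= t[i]
            total += f[i] - np.log(np.exp(f[risk]).sum())
    return total


@pytest.fixture
def pll_oracle():
    return pll_bruteforce


def cindex_bruteforce(scores, outcomes, horizon=None):
    """Exhaustive double-loop Harrell's C with the 1/2 tie convention."""
    t = np.array([o.time_days for o in outcomes])
    d = np.array([o.event for o in outcomes])
    f = np.asarray(scores, dtype=float)
    num = den = 0.0
    n = len(outcomes)
    for i in range(n):
        if d[i] != 1 or (horizon is not None and t[i] > horizon):
            continue
        for j in range(n):
            if j == i:
                continue
            if t[i] < t[j] or (t[i] <= t[j] and d[j] == 0):
                den += 1
                if f[i] > f[j]:
                    num += 1
                elif f[i] == f[j]:
                    num += 0.5
    return num / den


@pytest.fixture
def cindex_oracle():
    return cindex_bruteforce
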