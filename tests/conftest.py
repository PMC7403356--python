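import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from slbvic import fixtures as fx

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def events():
    return fx.event_timeline()


@pytest.fixture(scope="session")
def timeline():
    return fx.phase_timeline()


@pytest.fixture(scope="session")
def tree():
    return fx.synapsid_tree()


@pytest.fixture(scope="session")
def reference_curve():
    return fx.reference_curve(seed=0)


def random_alternating_timeline(rng, span=(100.0, 0.0), n_intervals=None):
    """A random alternating junction/disjunction timeline tiling the span."""
    from slbvic.eustasy import PhaseInterval, PhaseTimeline

    older, younger = span
    n = n_intervals or rng.integers(2, 9)
    cuts = np.sort(rng.uniform(younger, older, size=n - 1))[::-1]
    bounds = [older, *cuts.tolist(), younger]
    start_kind = "junction" if rng.uniform() < 0.5 else "disjunction"
    kinds = [
        start_kind if i % 2 == 0
        else ("disjunction" if start_kind == "junction" else "junction")
        for i in range(n)
    ]
    intervals = tuple(
        PhaseInterval(kinds[i], bounds[i], bounds[i + 1]) for i in range(n)
    )
    return PhaseTimeline(intervals, span)
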