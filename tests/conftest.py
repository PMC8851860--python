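import numpy as np
import pytest

import riskmx as rx


@pytest.fixture(scope="session")
def fixtures_by_name():
    return {s.name: s for s in rx.fixture_scenarios()}


@pytest.fixture(scope="session")
def calcium_absent(fixtures_by_name):
    return fixtures_by_name["calcium-absent"]


@pytest.fixture(scope="session")
def calcium_present(fixtures_by_name):
    return fixtures_by_name["calcium-present"]


@pytest.fixture(scope="session")
def sga_p10(fixtures_by_name):
    return fixtures_by_name["sga-p10"]


@pytest.fixture(scope="session")
def sga_p5(fixtures_by_name):
    return fixtures_by_name["sga-p5"]


def expanded_percentile(scenario, q, n=100_000):
    """Brute-force quantile oracle: expand the impact distribution into n
    individuals proportionally to the renormalised weights, then take the
    nearest-rank empirical percentile of the per-individual risk scores.

    Independent of the cumulative-weight implementation under test.
    """
    w = np.asarray(scenario.distribution.weights)
    counts = np.floor(w / 100.0 * n).astype(int)
    # hand remaining individuals to the largest fractional parts
    rem = n - counts.sum()
    order = np.argsort(-(w / 100.0 * n - counts))
    counts[order[:rem]] += 1
    impacts = np.repeat(np.arange(1, 6), counts)
    scores = scenario.band.index * np.sort(impacts)
    k = int(np.ceil(q / 100.0 * n)) - 1
    return int(scores[k])


def boundary_gap(scenario, q):
    """Distance (pp) from q to the nearest cumulative-weight boundary."""
    cum = np.cumsum(scenario.distribution.weights)
    return float(np.min(np.abs(cum - q)))
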