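import itertools

import numpy as np
import pytest

import tractolap as tl


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def figure1():
    return tl.fixture_figure1()


@pytest.fixture(scope="session")
def small_tractogram(rng):
    """20 random smooth streamlines, 12-30 points each."""
    streamlines = []
    for _ in range(20):
        n = int(rng.integers(12, 31))
        start = rng.uniform(-20, 20, size=3)
        steps = rng.normal(scale=2.0, size=(n - 1, 3))
        streamlines.append(np.vstack([start, start + np.cumsum(steps, axis=0)]))
    return tl.Tractogram(streamlines)


def mam_oracle(a, b):
    """Double-loop MAM reference implementation."""
    d_ab = np.mean([min(np.linalg.norm(x - y) for y in b) for x in a])
    d_ba = np.mean([min(np.linalg.norm(x - y) for y in a) for x in b])
    return 0.5 * (d_ab + d_ba)


def enumerate_min_assignment(cost):
    """Exhaustive minimum over all injective row->column assignments.

    Returns (best_total, lexicographically_smallest_optimal_columns).
    ``itertools.permutations`` yields in lexicographic order, so the first
    total within tolerance of the minimum is the lex-smallest optimum.
    """
    k, m = cost.shape
    perms = np.array(list(itertools.permutations(range(m), k)), dtype=np.intp)
    totals = cost[np.arange(k)[None, :], perms].sum(axis=1)
    best = totals.min()
    first = int(np.flatnonzero(totals <= best + 1e-12)[0])
    return float(best), tuple(perms[first])
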