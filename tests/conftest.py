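import numpy as np
import pytest

from wormccm import CrossMapConfig, LogisticCouplingSpec, coupled_logistic


@pytest.fixture(scope="session")
def box1_pair():
    """Canonical single-coupling benchmark pair (x drives y at lag 4)."""
    return coupled_logistic(LogisticCouplingSpec(couplings=((4, 0.1),), seed=0))


@pytest.fixture(scope="session")
def fast_cfg():
    """Small but adequate cross-map settings for quick checks."""
    return CrossMapConfig(E=2, library_size=150, n_repeats=10, rng_seed=11)


def brute_force_neighbors(points, times, k, exclusion_radius=0):
    """Independent exhaustive neighbor search: per-point distances, sorted
    by (distance, index).  Used as the oracle for the vectorized search."""
    n = len(times)
    idx = np.empty((n, k), dtype=int)
    dist = np.empty((n, k))
    for i in range(n):
        cands = []
        for j in range(n):
            if j == i or abs(int(times[i]) - int(times[j])) < exclusion_radius:
                continue
            diff = points[i] - points[j]
            cands.append((float(np.sqrt(np.sum(diff * diff))), j))
        cands.sort(key=lambda t: (t[0], t[1]))
        if len(cands) < k:
            raise AssertionError("oracle: not enough eligible neighbors")
        dist[i] = [c[0] for c in cands[:k]]
        idx[i] = [c[1] for c in cands[:k]]
    return idx, dist
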