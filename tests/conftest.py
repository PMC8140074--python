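from __future__ import annotations

import numpy as np
import pytest

from accell import phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Default phantom with 30 planted cells, no artifacts (plus ground truth)."""
    return phantom.generate_scan(phantom.PhantomSpec(n_cells=30, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)


def greedy_centroid_match(truth_centroids, detected_centroids, radius=2.0) -> int:
    """One-to-one greedy matching of centroids within a radius; returns TP count."""
    remaining = list(detected_centroids)
    matched = 0
    for tx, ty in truth_centroids:
        best, best_d = None, radius
        for j, (dx, dy) in enumerate(remaining):
            d = ((tx - dx) ** 2 + (ty - dy) ** 2) ** 0.5
            if d <= best_d:
                best, best_d = j, d
        if best is not None:
            remaining.pop(best)
            matched += 1
    return matched
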