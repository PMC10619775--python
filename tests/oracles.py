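"""Independent brute-force oracles used only by the tests."""

import numpy as np


def floyd_warshall_minutes(network) -> tuple[list, np.ndarray]:
    """All-pairs travel minutes by O(n^3) relaxation, written from scratch.

    Independent of the shortest-path implementation under test: builds the
    dense weight matrix straight from the edge attributes and relaxes over
    all intermediates.
    """
    ids, _ = network.node_array()
    pos = {nid: k for k, nid in enumerate(ids)}
    n = len(ids)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v, data in network.graph.edges(data=True):
        w = 60.0 * data["length_km"] / data["speed_kmh"]
        i, j = pos[u], pos[v]
        dist[i, j] = min(dist[i, j], w)
        dist[j, i] = min(dist[j, i], w)
    for k in range(n):
        dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
    return ids, dist


def quartile_summary(values) -> dict:
    """Sort-based order statistics with linear interpolation, from scratch."""
    v = sorted(float(x) for x in values)
    n = len(v)

    def q(p):
        h = p * (n - 1)
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    return {"median": q(0.5), "q1": q(0.25), "q3": q(0.75), "min": v[0], "max": v[-1]}
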