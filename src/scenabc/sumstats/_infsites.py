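"""Single-population infinite-sites coalescent used for neutrality-test and
mismatch p-values.

Time is measured in mutational pair-units: a pair of lineages separated for
time ``x`` accumulates ``Poisson(x)`` differences, and a pair coalesces with
hazard ``1/theta`` while the epoch parameter is ``theta``.  A piecewise
constant ``theta(x)`` supports the sudden-expansion model (theta1 for
``x < tau``, theta0 beyond).
"""

from __future__ import annotations

import numpy as np

__all__ = ["simulate_infinite_sites"]


def _coalescence_times(n: int, bounds, thetas, rng: np.random.Generator):
    """Times at which the lineage count drops n -> n-1 -> ... -> 1."""
    times = np.empty(n - 1)
    t = 0.0
    epoch = 0
    for i, k in enumerate(range(n, 1, -1)):
        pairs = k * (k - 1) / 2.0
        e = rng.exponential()
        while True:
            nxt = bounds[epoch + 1] if epoch + 1 < len(bounds) else np.inf
            dt = e * thetas[epoch] / pairs
            if t + dt <= nxt:
                t += dt
                break
            e -= (nxt - t) * pairs / thetas[epoch]
            t = nxt
            epoch += 1
        times[i] = t
    return times


def simulate_infinite_sites(n: int, thetas, bounds, rng: np.random.Generator) -> dict:
    """Simulate one sample of ``n`` sequences under a piecewise-constant theta.

    ``theta(x) = thetas[j]`` for ``bounds[j] <= x < bounds[j+1]``;
    ``bounds[0]`` must be 0, the last epoch extends to infinity.

    Returns a dict with ``s`` (segregating sites), ``kbar`` (mean pairwise
    differences), ``nh`` (haplotype count) and ``diffs`` (pairwise
    difference-count matrix).
    """
    thetas = list(thetas)
    bounds = list(bounds)
    if bounds[0] != 0:
        raise ValueError("bounds must start at 0")
    if len(thetas) != len(bounds):
        raise ValueError("thetas and bounds must have equal length")
    times = _coalescence_times(n, bounds, thetas, rng)

    n_nodes = 2 * n - 1
    node_time = np.zeros(n_nodes)
    parent = np.full(n_nodes, -1, dtype=np.int64)
    desc = np.zeros((n_nodes, n), dtype=bool)
    desc[np.arange(n), np.arange(n)] = True
    active = list(range(n))
    nxt = n
    for t in times:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[i], active[j]
        node_time[nxt] = t
        parent[a] = nxt
        parent[b] = nxt
        desc[nxt] = desc[a] | desc[b]
        for idx in sorted((i, j), reverse=True):
            active.pop(idx)
        active.append(nxt)
        nxt += 1

    # mutations: Poisson(branch_length / 2) per branch (per-lineage rate 1/2)
    branch_nodes = np.arange(n_nodes - 1)  # all but root
    blen = node_time[parent[branch_nodes]] - node_time[branch_nodes]
    muts = rng.poisson(blen / 2.0)

    D = desc[branch_nodes].astype(np.float64)  # (n_branches, n)
    m = muts.astype(np.float64)
    w = m @ D  # mutations ancestral to each tip
    shared = (D * m[:, None]).T @ D
    diffs = w[:, None] + w[None, :] - 2.0 * shared
    np.fill_diagonal(diffs, 0.0)

    carried = desc[branch_nodes][muts > 0]  # (n_seg_branches, n)
    if carried.size:
        nh = np.unique(carried.T, axis=0).shape[0]
    else:
        nh = 1
    iu = np.triu_indices(n, 1)
    return {
        "s": int(muts.sum()),
        "kbar": float(diffs[iu].mean()),
        "nh": int(nh),
        "diffs": diffs,
    }
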