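"""Structured-coalescent genealogy simulation.

Within a population of diploid effective size N, any two of k lineages
coalesce at rate ``k(k-1)/2`` divided by the gene-copy number of the marker
class: ``2N`` for autosomal loci, ``N/2`` for mtDNA (haploid, maternally
inherited, even sex ratio -> one quarter of the autosomal copy number).
Merge events move every lineage from source to sink; an admixture pulse
sends each lineage of the target independently to parent 1 with the pulse
probability, else to parent 2.  Output trees are ultrametric with branch
lengths in generations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Tree", "simulate_genealogy", "COPY_NUMBER"]

#: gene copies contributed per unit of diploid N, by marker class
COPY_NUMBER = {"autosomal": 2.0, "mtdna": 0.5}


@dataclass
class Tree:
    """A binary coalescent tree over ``n`` tips (ids ``0..n-1``).

    ``parent[i]`` is -1 for the root; ``time`` is in generations
    (tips at 0).  ``children`` holds the two child ids of each internal
    node (tips have none).  ``tip_population[i]`` records the sampling
    population label of tip i.
    """

    n: int
    parent: np.ndarray
    time: np.ndarray
    children: list[tuple[int, int] | None]
    tip_population: list[str]

    @property
    def n_nodes(self) -> int:
        return 2 * self.n - 1

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node."""
        idx = np.arange(self.n_nodes - 1)
        return self.time[self.parent[idx]] - self.time[idx]

    def preorder(self) -> list[int]:
        """Root-first traversal order."""
        order = [self.root]
        stack = [self.root]
        while stack:
            node = stack.pop()
            ch = self.children[node]
            if ch is not None:
                for c in ch:
                    order.append(c)
                    stack.append(c)
        return order

    def tmrca(self) -> float:
        return float(self.time[self.root])


def simulate_genealogy(
    sizes: dict[str, float],
    events: list[tuple],
    samples: dict[str, int],
    marker_class: str,
    rng: np.random.Generator | int | None = None,
) -> Tree:
    """Simulate one genealogy under an instantiated scenario.

    Parameters
    ----------
    sizes
        Diploid effective size per extant population (events may update the
        sink size via their ``new_size`` entry).
    events
        Output of :meth:`DemographicScenario.instantiate`: tuples
        ``('merge', t, source, sink, new_size)`` or
        ``('admix', t, target, parent1, parent2, r)``, times increasing.
    samples
        Gene copies sampled per population (already multiplied by copies
        per individual).
    marker_class
        ``'autosomal'`` or ``'mtdna'``.
    """
    if marker_class not in COPY_NUMBER:
        raise ValueError(f"unknown marker class {marker_class!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    scale = COPY_NUMBER[marker_class]
    sizes = dict(sizes)

    tips: list[str] = []
    active: dict[str, list[int]] = {}
    for pop, k in samples.items():
        if k == 0:
            continue
        if pop not in sizes:
            raise ValueError(f"samples placed in population {pop!r} with no size")
        start = len(tips)
        tips.extend([pop] * k)
        active[pop] = list(range(start, start + k))
    n = len(tips)
    if n < 2:
        raise ValueError("need at least 2 sampled gene copies")

    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    children: list[tuple[int, int] | None] = [None] * n_nodes

    # batched uniforms: the inner loop is pure python for speed
    from math import inf, log

    ubuf = rng.random(4096)
    upos = 0

    def uniform() -> float:
        nonlocal ubuf, upos
        if upos >= ubuf.size:
            ubuf = rng.random(4096)
            upos = 0
        u = ubuf[upos]
        upos += 1
        return float(u)

    t = 0.0
    nxt = n
    ev = list(events)
    ev_i = 0
    n_live = n
    while n_live > 1:
        rates = []
        rate_pops = []
        total = 0.0
        for pop, lin in active.items():
            k = len(lin)
            if k >= 2:
                rt = k * (k - 1) / 2.0 / (scale * sizes[pop])
                rates.append(rt)
                rate_pops.append(pop)
                total += rt
        t_next_ev = ev[ev_i][1] if ev_i < len(ev) else inf
        wait = -log(1.0 - uniform()) / total if total > 0 else inf
        if t + wait >= t_next_ev:
            if t_next_ev == inf:
                raise RuntimeError(
                    "lineages cannot coalesce and no further events remain"
                )
            t = t_next_ev
            e = ev[ev_i]
            ev_i += 1
            if e[0] == "merge":
                _, _, src, snk, new_size = e
                moved = active.pop(src, [])
                active.setdefault(snk, []).extend(moved)
                if new_size is not None:
                    sizes[snk] = new_size
            else:
                _, _, tgt, p1, p2, r = e
                moved = active.pop(tgt, [])
                for lineage in moved:
                    dest = p1 if uniform() < r else p2
                    active.setdefault(dest, []).append(lineage)
            continue
        t += wait
        u = uniform() * total
        acc = 0.0
        pop = rate_pops[-1]
        for p, rt in zip(rate_pops, rates):
            acc += rt
            if u <= acc:
                pop = p
                break
        lin = active[pop]
        k = len(lin)
        i = int(uniform() * k)
        j = int(uniform() * (k - 1))
        if j >= i:
            j += 1
        a, b = lin[i], lin[j]
        for idx in sorted((i, j), reverse=True):
            lin.pop(idx)
        parent[a] = nxt
        parent[b] = nxt
        children[nxt] = (a, b)
        time[nxt] = t
        lin.append(nxt)
        nxt += 1
        n_live -= 1

    return Tree(n=n, parent=parent, time=time, children=children,
                tip_population=tips)
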