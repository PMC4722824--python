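"""Mutation models layered on a genealogy: HKY for sequences (exact
per-branch transition probabilities via spectral decomposition of the rate
matrix) and a generalized stepwise model for microsatellites.
"""

from __future__ import annotations

import numpy as np

from .scenarios import LocusModel
from .simulate import Tree

__all__ = ["hky_rate_matrix", "mutate_sequence", "mutate_microsat"]


def hky_rate_matrix(kappa: float, freqs) -> np.ndarray:
    """HKY85 rate matrix (order A, C, G, T) normalized to one expected
    substitution per site per unit time."""
    pi = np.asarray(freqs, dtype=float)
    if pi.shape != (4,) or abs(pi.sum() - 1.0) > 1e-9 or (pi < 0).any():
        raise ValueError("base frequencies must be 4 nonnegative values summing to 1")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -(pi * np.diag(q)).sum()
    return q / mean_rate


def _hky_spectral(kappa: float, freqs):
    """Symmetrized eigendecomposition of the HKY generator.

    Returns (eigenvalues, left, right) with P(t) = right @ diag(exp(l t)) @ left.
    """
    pi = np.asarray(freqs, dtype=float)
    q = hky_rate_matrix(kappa, pi)
    sq = np.sqrt(np.maximum(pi, 1e-300))
    s = (q * sq[:, None]) / sq[None, :]
    s = (s + s.T) / 2.0  # symmetric for a reversible chain
    lam, u = np.linalg.eigh(s)
    right = u / sq[:, None]
    left = (u * sq[:, None]).T
    return lam, left, right


def mutate_sequence(
    tree: Tree,
    locus: LocusModel,
    mu: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Evolve an L-site sequence down the tree under HKY.

    ``mu`` is the per-site per-generation substitution rate; the root
    sequence is drawn from the stationary base frequencies.  Returns the
    ``(n_tips, L)`` uint8 matrix (A,C,G,T -> 0..3).
    """
    if locus.kind != "sequence":
        raise ValueError("locus must be a sequence model")
    if mu < 0:
        raise ValueError("mutation rate must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    L = locus.length
    pi = np.asarray(locus.base_freqs)
    n_nodes = tree.n_nodes
    seqs = np.empty((n_nodes, L), dtype=np.uint8)
    root = tree.root
    seqs[root] = rng.choice(4, size=L, p=pi)
    if mu == 0.0:
        for node in tree.preorder()[1:]:
            seqs[node] = seqs[tree.parent[node]]
        return seqs[: tree.n]

    lam, left, right = _hky_spectral(locus.kappa, pi)
    # all per-branch transition matrices at once: P(t) = right diag(e^{lam t}) left
    blen = tree.branch_lengths() * mu
    E = np.exp(np.outer(blen, lam))  # (n_branches, 4)
    P = np.einsum("ns,is,sj->nij", E, right, left)
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=2, keepdims=True)
    cumP = np.cumsum(P, axis=2)
    parent = tree.parent
    U = rng.random((n_nodes - 1, L))
    for node in tree.preorder()[1:]:
        seqs[node] = (U[node][:, None] > cumP[node][seqs[parent[node]]]).sum(axis=1)
    return seqs[: tree.n]


def gsm_steps(m: int, gsm_p: float, rng: np.random.Generator) -> np.ndarray:
    """``m`` signed GSM steps: fair sign, magnitude G >= 1 with
    ``P(G=g) = (1-p) p^(g-1)`` (``p = 0`` -> strict single steps)."""
    signs = rng.choice((-1, 1), size=m)
    if gsm_p == 0.0:
        sizes = np.ones(m, dtype=np.int64)
    else:
        sizes = rng.geometric(1.0 - gsm_p, size=m)
    return signs * sizes


def _reflect(values: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Fold integer positions into [lo, hi] by reflection at the borders."""
    span = hi - lo
    period = 2 * span
    y = np.mod(values - lo, period)
    y = np.where(y > span, period - y, y)
    return lo + y


def mutate_microsat(
    tree: Tree,
    locus: LocusModel,
    mu: float,
    gsm_p: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Evolve a microsatellite repeat count down the tree under the GSM.

    Mutations per branch are Poisson(mu * length); each moves the count by
    ±G with fair sign and geometric magnitude ``P(G=g) = (1-p)p^(g-1)``
    (``gsm_p = 0`` degenerates to strict single-step).  The root allele is
    the midpoint of the allowed range; positions exiting the range are
    reflected.  Returns one integer allele per tip.
    """
    if locus.kind != "microsat":
        raise ValueError("locus must be a microsat model")
    if not 0.0 <= gsm_p < 1.0:
        raise ValueError("GSM parameter must be in [0, 1)")
    if mu < 0:
        raise ValueError("mutation rate must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lo, hi = locus.size_min, locus.size_max
    n_nodes = tree.n_nodes
    root_val = (lo + hi) // 2

    blen = tree.branch_lengths()
    counts = rng.poisson(mu * blen)
    total = int(counts.sum())
    net = np.zeros(n_nodes - 1, dtype=np.int64)
    if total:
        steps = gsm_steps(total, gsm_p, rng)
        owner = np.repeat(np.arange(n_nodes - 1), counts)
        np.add.at(net, owner, steps)

    span = hi - lo
    period = 2 * span
    net_list = net.tolist()
    parent = tree.parent.tolist()
    values = [0] * n_nodes
    values[tree.root] = root_val
    for node in tree.preorder()[1:]:
        v = values[parent[node]] + net_list[node]
        if v < lo or v > hi:  # fold back into the range (scalar _reflect)
            y = (v - lo) % period
            if y > span:
                y = period - y
            v = lo + y
        values[node] = v
    return np.asarray(values[: tree.n], dtype=np.int64)
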