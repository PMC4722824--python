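"""Between-group differentiation: Weir–Cockerham theta for microsatellites,
sequence Phi_ST (two-group AMOVA on TN93 distances), N_ST, and the pooled
pair statistics used in the ABC summary vector."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..popdata import MultilocusDataset
from .amova import amova_from_distances
from .distances import tn93_matrix
from .diversity import _segregating_sites_fast
from .microsat import msat_group_stats

__all__ = ["PairSummary", "weir_cockerham_theta", "n_st",
           "pairwise_differentiation"]


@dataclass
class PairSummary:
    phi_st_seq: float
    theta_msat: float
    n_st: float
    he_combined: float
    s_combined: int


def weir_cockerham_theta(calls_by_pop: list[np.ndarray]) -> float:
    """Weir & Cockerham (1984) theta over loci and alleles.

    ``calls_by_pop``: one ``(n_i, n_loci, 2)`` call array per population
    (missing = -1).  Returns ``sum(a) / sum(a + b + c)``; ``nan`` when the
    total is 0 (no variation).
    """
    r = len(calls_by_pop)
    if r < 2:
        raise ValueError("theta requires at least 2 populations")
    n_loci = calls_by_pop[0].shape[1]
    num = 0.0
    den = 0.0
    for l in range(n_loci):
        per_pop = []
        for calls in calls_by_pop:
            cell = calls[:, l, :]
            per_pop.append(cell[cell[:, 0] > 0])
        pooled = np.concatenate([c.ravel() for c in per_pop])
        pooled = pooled[pooled > 0]
        alleles = np.flatnonzero(np.bincount(pooled))
        sizes = np.array([c.shape[0] for c in per_pop], dtype=float)
        if (sizes < 1).any() or sizes.sum() < 2:
            continue
        n_bar = sizes.mean()
        n_c = (r * n_bar - (sizes**2).sum() / (r * n_bar)) / (r - 1)
        if n_bar <= 1 or n_c <= 0:
            continue
        # (r, n_alleles) allele frequencies and heterozygote carrier freqs
        p_i = np.empty((r, alleles.size))
        h_i = np.empty((r, alleles.size))
        for i, c in enumerate(per_pop):
            eq = c[:, :, None] == alleles[None, None, :]
            p_i[i] = eq.sum(axis=(0, 1)) / (2.0 * c.shape[0])
            h_i[i] = (eq[:, 0, :] ^ eq[:, 1, :]).mean(axis=0)
        p_bar = (sizes[:, None] * p_i).sum(axis=0) / (r * n_bar)
        s2 = (sizes[:, None] * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (sizes[:, None] * h_i).sum(axis=0) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (1.0 / (n_bar - 1)) * (
                p_bar * (1 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0
            )
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - ((r - 1.0) / r) * s2
            - ((2 * n_bar - 1) / (4.0 * n_bar)) * h_bar
        )
        c_comp = h_bar / 2.0
        num += a.sum()
        den += (a + b + c_comp).sum()
    if den == 0:
        return float("nan")
    return float(num / den)


def n_st(d: np.ndarray, sizes: tuple[int, int]) -> float:
    """Pons & Petit (1996) N_ST = 1 - pi_S/pi_T on a molecular distance
    matrix whose first ``sizes[0]`` rows are group A and the rest group B.

    pi_S is the sample-size-weighted mean within-group pairwise distance;
    pi_T the pooled mean.  ``nan`` when pi_T == 0.
    """
    na, nb = sizes
    iu = np.triu_indices(na + nb, 1)
    pi_t = float(d[iu].mean())
    if pi_t == 0:
        return float("nan")
    da = d[:na, :na][np.triu_indices(na, 1)]
    db = d[na:, na:][np.triu_indices(nb, 1)]
    wa, wb = na * (na - 1) / 2.0, nb * (nb - 1) / 2.0
    pi_s = (da.sum() + db.sum()) / (wa + wb)
    return float(1.0 - pi_s / pi_t)


def pairwise_differentiation(
    dataset: MultilocusDataset, group_a: str, group_b: str
) -> PairSummary:
    """All pair statistics for two groups of a joint dataset.

    phi_st_seq comes from a two-group AMOVA on TN93 distances; theta_msat
    is the Weir–Cockerham estimator; combined statistics pool the two
    groups' individuals.
    """
    aln_a = dataset.group_alignment(group_a)
    aln_b = dataset.group_alignment(group_b)
    if aln_a.n == 0 or aln_b.n == 0:
        raise ValueError("both groups must be sampled for sequences")
    enc = np.vstack([aln_a.encoded(), aln_b.encoded()])
    d = tn93_matrix(enc)
    labels = [group_a] * aln_a.n + [group_b] * aln_b.n
    res = amova_from_distances(d, labels, None, n_perm=0)
    phi = res.fixation["F_ST"]
    nst = n_st(d, (aln_a.n, aln_b.n))
    s_comb = _segregating_sites_fast(enc)

    geno_a = dataset.group_genotypes(group_a)
    geno_b = dataset.group_genotypes(group_b)
    if geno_a.n == 0 or geno_b.n == 0:
        raise ValueError("both groups must be sampled for microsatellites")
    theta = weir_cockerham_theta([geno_a.calls, geno_b.calls])
    pooled = np.vstack([geno_a.calls, geno_b.calls])
    he_comb = msat_group_stats(pooled).he

    return PairSummary(
        phi_st_seq=float(phi),
        theta_msat=theta,
        n_st=float(nst) if np.isfinite(nst) else float("nan"),
        he_combined=float(he_comb),
        s_combined=int(s_comb),
    )
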