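"""The ordered summary-statistic vector driving all ABC computations.

For k groups the vector holds 6k single-group statistics followed by
4*C(k,2) pairwise statistics, in this fixed order:

* per group g (groups in the caller-supplied order):
  ``A(g), He(g), V(g), NH(g), S(g), kbar(g)``
  (microsatellite mean alleles/locus, mean unbiased genic diversity, mean
  allele-size variance; sequence haplotype count, segregating sites, mean
  pairwise differences);
* per pair (i, j), i < j in that order:
  ``He_comb(i,j), theta(i,j), S_comb(i,j), NST(i,j)``
  (pooled-pair mean genic diversity, Weir-Cockerham theta, pooled
  segregating sites, N_ST on TN93 distances).

Statistics that are undefined on a degenerate draw (no variation anywhere)
are reported as 0 so reference tables never contain missing entries.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from ..popdata import MultilocusDataset
from .distances import difference_matrix, tn93_matrix
from .differentiation import n_st, weir_cockerham_theta
from .diversity import _segregating_sites_fast, haplotype_classes

__all__ = ["summary_vector", "summary_vector_names", "summary_vector_arrays"]


def summary_vector_names(groups: list[str]) -> list[str]:
    names = []
    for g in groups:
        names += [f"A_{g}", f"He_{g}", f"V_{g}", f"NH_{g}", f"S_{g}", f"kbar_{g}"]
    for a, b in combinations(groups, 2):
        names += [f"Hecomb_{a}_{b}", f"theta_{a}_{b}", f"Scomb_{a}_{b}",
                  f"NST_{a}_{b}"]
    return names


def _msat_locus_summaries(calls: np.ndarray) -> tuple[float, float, float]:
    """(mean alleles/locus, mean unbiased He, mean allele-size variance)."""
    n_loci = calls.shape[1]
    a_vals = np.empty(n_loci)
    he_vals = np.empty(n_loci)
    v_vals = np.empty(n_loci)
    for l in range(n_loci):
        copies = calls[:, l, :].ravel()
        copies = copies[copies > 0]
        n2 = copies.size
        if n2 == 0:
            a_vals[l], he_vals[l], v_vals[l] = 0.0, 0.0, 0.0
            continue
        counts = np.bincount(copies)
        counts = counts[counts > 0]
        p = counts / n2
        a_vals[l] = counts.size
        he_vals[l] = (n2 / (n2 - 1.0)) * (1.0 - (p**2).sum()) if n2 > 1 else 0.0
        mean = copies.mean()
        v_vals[l] = ((copies - mean) ** 2).mean()
    return float(a_vals.mean()), float(he_vals.mean()), float(v_vals.mean())


def _nh_fast(enc: np.ndarray) -> int:
    if (enc < 4).all():
        rows = np.ascontiguousarray(enc)
        return len({rows[i].tobytes() for i in range(rows.shape[0])})
    return int(haplotype_classes(enc).max()) + 1


def summary_vector_arrays(
    seq_enc: np.ndarray,
    seq_group_idx: list[np.ndarray],
    msat_calls: np.ndarray,
    msat_group_idx: list[np.ndarray],
    groups: list[str],
) -> np.ndarray:
    """Array-level implementation shared by observed data and the simulator.

    ``seq_group_idx[g]`` / ``msat_group_idx[g]`` index rows of ``seq_enc`` /
    ``msat_calls`` belonging to group ``groups[g]``.
    """
    k = len(groups)
    if len(seq_group_idx) != k or len(msat_group_idx) != k:
        raise ValueError("group index lists must match the group list")
    for g, idx in zip(groups, seq_group_idx):
        if len(idx) < 2:
            raise ValueError(f"group {g!r}: need >= 2 sequences")
    for g, idx in zip(groups, msat_group_idx):
        if len(idx) < 2:
            raise ValueError(f"group {g!r}: need >= 2 genotyped individuals")

    diffs, _ = difference_matrix(seq_enc)
    tn = tn93_matrix(seq_enc)
    tn = np.where(np.isfinite(tn), tn, 0.0)  # saturated pairs: capped, logged upstream

    out: list[float] = []
    for gi in range(k):
        sidx = seq_group_idx[gi]
        midx = msat_group_idx[gi]
        a, he, v = _msat_locus_summaries(msat_calls[midx])
        sub = seq_enc[sidx]
        nh = _nh_fast(sub)
        s = _segregating_sites_fast(sub)
        dsub = diffs[np.ix_(sidx, sidx)]
        iu = np.triu_indices(len(sidx), 1)
        kbar = float(dsub[iu].mean())
        out += [a, he, v, float(nh), float(s), kbar]

    for gi, gj in combinations(range(k), 2):
        sidx = np.concatenate([seq_group_idx[gi], seq_group_idx[gj]])
        midx_i, midx_j = msat_group_idx[gi], msat_group_idx[gj]
        pooled = np.concatenate([msat_calls[midx_i], msat_calls[midx_j]])
        _, he_comb, _ = _msat_locus_summaries(pooled)
        theta = weir_cockerham_theta([msat_calls[midx_i], msat_calls[midx_j]])
        if not np.isfinite(theta):
            theta = 0.0
        s_comb = _segregating_sites_fast(seq_enc[sidx])
        dpair = tn[np.ix_(sidx, sidx)]
        nst = n_st(dpair, (len(seq_group_idx[gi]), len(seq_group_idx[gj])))
        if not np.isfinite(nst):
            nst = 0.0
        out += [he_comb, float(theta), float(s_comb), float(nst)]
    return np.asarray(out, dtype=float)


def summary_vector(
    dataset: MultilocusDataset, groups: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Summary vector of a joint dataset for an ordered list of groups.

    Both markers must be present for every named group; a missing marker
    raises with the name of the gap.  Deterministic: two calls on the same
    dataset are bit-identical, and the value is invariant to individual
    order within groups.
    """
    aln = dataset.require_alignment()
    geno = dataset.require_genotypes()
    seq_ids = aln.ids
    msat_ids = geno.ids
    seq_idx = []
    msat_idx = []
    for g in groups:
        si = [i for i, v in enumerate(seq_ids) if dataset.popmap.group_of(v) == g]
        mi = [i for i, v in enumerate(msat_ids) if dataset.popmap.group_of(v) == g]
        if not si:
            raise ValueError(f"group {g!r} has no sequence data")
        if not mi:
            raise ValueError(f"group {g!r} has no microsatellite data")
        seq_idx.append(np.asarray(si))
        msat_idx.append(np.asarray(mi))
    vec = summary_vector_arrays(aln.encoded(), seq_idx, geno.calls, msat_idx, groups)
    return vec, summary_vector_names(groups)
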