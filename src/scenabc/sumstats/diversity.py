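"""Within-group sequence diversity: haplotype counts, gene diversity,
nucleotide diversity, segregating sites and mean pairwise differences."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distances import difference_matrix, encode

__all__ = ["SeqGroupStats", "seq_group_stats", "segregating_sites", "haplotype_classes"]


@dataclass
class SeqGroupStats:
    n: int
    nh: int
    h: float
    h_sd: float
    pi: float
    pi_sd: float
    s: int
    kbar: float


def haplotype_classes(obj) -> np.ndarray:
    """Assign each sequence to a haplotype class.

    Two sequences belong to the same haplotype when they agree at every site
    where both are unambiguous.  With missing data this relation is not
    transitive; classes are formed greedily in row order (each sequence joins
    the first earlier class whose representative it matches), which is exact
    whenever the alignment is unambiguous.
    """
    enc = encode(obj)
    n = enc.shape[0]
    valid = enc < 4
    reps: list[int] = []
    labels = np.empty(n, dtype=np.int64)
    for i in range(n):
        assigned = False
        for ci, r in enumerate(reps):
            both = valid[i] & valid[r]
            if not np.any(enc[i][both] != enc[r][both]):
                labels[i] = ci
                assigned = True
                break
        if not assigned:
            labels[i] = len(reps)
            reps.append(i)
    return labels


def segregating_sites(obj) -> int:
    """Number of polymorphic sites, counting only unambiguous bases."""
    enc = encode(obj)
    s = 0
    for col in range(enc.shape[1]):
        bases = enc[:, col]
        bases = bases[bases < 4]
        if bases.size and np.unique(bases).size > 1:
            s += 1
    return int(s)


def _segregating_sites_fast(enc: np.ndarray) -> int:
    # vectorized: per column, count distinct codes < 4
    present = np.zeros((4, enc.shape[1]), dtype=bool)
    for s in range(4):
        present[s] = (enc == s).any(axis=0)
    return int((present.sum(axis=0) > 1).sum())


def seq_group_stats(obj) -> SeqGroupStats:
    """Diversity summary for one group of aligned sequences.

    * gene diversity ``h = n(1 - sum p_i^2)/(n - 1)`` over haplotype
      frequencies, variance per Nei (1987, eq. 8.12);
    * ``kbar`` = mean pairwise difference count (pairwise deletion);
    * nucleotide diversity ``pi`` = mean pairwise per-site distance,
      variance per Nei (1987, eq. 10.7);
    * ``s`` = number of polymorphic unambiguous sites.

    Requires ``n >= 2``.
    """
    enc = encode(obj)
    n = enc.shape[0]
    if n < 2:
        raise ValueError("seq_group_stats requires at least 2 sequences")

    labels = haplotype_classes(enc)
    nh = int(labels.max()) + 1
    freqs = np.bincount(labels) / n
    sum_p2 = float((freqs**2).sum())
    h = n * (1.0 - sum_p2) / (n - 1)
    sum_p3 = float((freqs**3).sum())
    var_h = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (sum_p3 - sum_p2**2) + sum_p2 - sum_p2**2
    )
    h_sd = float(np.sqrt(max(var_h, 0.0)))

    diffs, comp = difference_matrix(enc)
    iu = np.triu_indices(n, 1)
    kbar = float(diffs[iu].mean())
    with np.errstate(invalid="ignore"):
        persite = np.where(comp[iu] > 0, diffs[iu] / np.maximum(comp[iu], 1), np.nan)
    pi = float(np.nanmean(persite))

    s = _segregating_sites_fast(enc)
    L_eff = float(comp[iu].mean())
    # Nei 1987 eq. 10.7 (per site), using the mean comparable length
    if L_eff > 0:
        var_pi = ((n + 1) / (3.0 * (n - 1))) * pi / L_eff + (
            2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        ) * pi**2
    else:
        var_pi = 0.0
    pi_sd = float(np.sqrt(max(var_pi, 0.0)))

    return SeqGroupStats(n=n, nh=nh, h=float(h), h_sd=h_sd, pi=pi, pi_sd=pi_sd,
                         s=s, kbar=kbar)
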