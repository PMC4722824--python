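"""Pairwise nucleotide distances (Tamura–Nei 1993) and raw difference counts.

All functions accept either a :class:`~scenabc.popdata.SequenceAlignment` or
an already-encoded ``uint8`` matrix (A,C,G,T,N,- -> 0..5).  Sites where
either member of a pair carries ``N`` or a gap are excluded for that pair
only (pairwise deletion).  Saturated pairs, where the TN93 logarithms leave
their domain, are flagged with ``inf``.
"""

from __future__ import annotations

import numpy as np

from ..popdata import SequenceAlignment

__all__ = ["tn93_distance", "tn93_matrix", "difference_matrix", "encode"]


def encode(obj) -> np.ndarray:
    if isinstance(obj, SequenceAlignment):
        return obj.encoded()
    arr = np.asarray(obj)
    if arr.dtype == np.uint8:
        return arr
    raise TypeError("expected SequenceAlignment or uint8-encoded matrix")


def _tn93_from_counts(L, nAG, nCT, nTV, piA, piC, piG, piT):
    """Evaluate the TN93 closed form elementwise on (broadcastable) arrays.

    Parameters are counts of mutually comparable sites (``L``), of A<->G and
    C<->T transitions, of transversions, and the empirical base frequencies
    of the pair.  Returns substitutions/site; ``inf`` where the log domain is
    violated (saturation); ``nan`` where L == 0.
    """
    L = np.asarray(L, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        P1 = nAG / L
        P2 = nCT / L
        Q = nTV / L
        piR = piA + piG
        piY = piC + piT
        k1 = np.where(piR > 0, 2.0 * piA * piG / np.where(piR > 0, piR, 1.0), 0.0)
        k2 = np.where(piY > 0, 2.0 * piC * piT / np.where(piY > 0, piY, 1.0), 0.0)
        k3 = 2.0 * (piR * piY - (piA * piG * piY / np.where(piR > 0, piR, 1.0))
                    - (piC * piT * piR / np.where(piY > 0, piY, 1.0)))

        w1 = np.where(k1 > 0, 1.0 - P1 / np.where(k1 > 0, k1, 1.0)
                      - Q / np.where(piR > 0, 2.0 * piR, 1.0), 1.0)
        w2 = np.where(k2 > 0, 1.0 - P2 / np.where(k2 > 0, k2, 1.0)
                      - Q / np.where(piY > 0, 2.0 * piY, 1.0), 1.0)
        denom3 = 2.0 * piR * piY
        w3 = np.where(denom3 > 0, 1.0 - Q / np.where(denom3 > 0, denom3, 1.0), 1.0)

        bad = (w1 <= 0) | (w2 <= 0) | (w3 <= 0)
        # transitions observed while the matching k coefficient vanishes:
        # frequencies contradict the counts (tiny overlaps); treat as saturated
        bad |= (k1 == 0) & (nAG > 0)
        bad |= (k2 == 0) & (nCT > 0)
        bad |= (denom3 == 0) & (nTV > 0)

        w1 = np.where(bad, 1.0, w1)
        w2 = np.where(bad, 1.0, w2)
        w3 = np.where(bad, 1.0, w3)
        d = -(k1 * np.log(w1) + k2 * np.log(w2) + k3 * np.log(w3))
        d = np.where(bad, np.inf, d)
        d = np.where(L > 0, d, np.nan)
    # exact zeros for identical pairs regardless of rounding
    ident = (nAG + nCT + nTV) == 0
    return np.where(ident & (L > 0), 0.0, d)


def tn93_distance(seq_a, seq_b) -> float:
    """TN93 distance between two equal-length encoded sequences.

    Base frequencies are empirical, estimated from the pair over mutually
    unambiguous sites.  Symmetric by construction; 0 for identical pairs.
    """
    a = np.asarray(seq_a)
    b = np.asarray(seq_b)
    if a.dtype != np.uint8:
        a = SequenceAlignment(["a"], np.atleast_2d(a)).encoded()[0]
    if b.dtype != np.uint8:
        b = SequenceAlignment(["b"], np.atleast_2d(b)).encoded()[0]
    if a.shape != b.shape:
        raise ValueError("sequences differ in length")
    valid = (a < 4) & (b < 4)
    L = int(valid.sum())
    if L == 0:
        raise ValueError("no mutually unambiguous sites")
    av, bv = a[valid], b[valid]
    counts = np.zeros(4)
    for s in range(4):
        counts[s] = (av == s).sum() + (bv == s).sum()
    pi = counts / (2 * L)
    nAG = int((((av == 0) & (bv == 2)) | ((av == 2) & (bv == 0))).sum())
    nCT = int((((av == 1) & (bv == 3)) | ((av == 3) & (bv == 1))).sum())
    ndiff = int((av != bv).sum())
    nTV = ndiff - nAG - nCT
    return float(_tn93_from_counts(L, nAG, nCT, nTV, *pi))


def _indicator_stack(enc: np.ndarray) -> np.ndarray:
    """(5, n, L) float32 stack: indicators of A, C, G, T and validity."""
    out = np.empty((5,) + enc.shape, dtype=np.float32)
    for s in range(4):
        out[s] = enc == s
    out[4] = enc < 4
    return out


def difference_matrix(obj) -> tuple[np.ndarray, np.ndarray]:
    """Raw pairwise difference counts with pairwise deletion.

    Returns ``(diffs, comparable)``: both ``(n, n)`` integer matrices, the
    number of differing sites and the number of mutually unambiguous sites.
    """
    enc = encode(obj)
    ind = _indicator_stack(enc)
    V = ind[4]
    L = V @ V.T
    matches = sum(ind[s] @ ind[s].T for s in range(4))
    diffs = L - matches
    return np.rint(diffs).astype(np.int64), np.rint(L).astype(np.int64)


def tn93_matrix(obj) -> np.ndarray:
    """All-pairs TN93 distance matrix (pairwise deletion, per-pair empirical
    base frequencies).  Diagonal is 0."""
    enc = encode(obj)
    ind = _indicator_stack(enc)
    A, C, G, T, V = ind
    # float32 matmuls are exact for 0/1 counts up to 2^24; cast after
    L = (V @ V.T).astype(np.float64)
    nAG = (A @ G.T + G @ A.T).astype(np.float64)
    nCT = (C @ T.T + T @ C.T).astype(np.float64)
    matches = (A @ A.T + C @ C.T + G @ G.T + T @ T.T).astype(np.float64)
    nTV = (L - matches) - nAG - nCT
    with np.errstate(divide="ignore", invalid="ignore"):
        piA = (A @ V.T + V @ A.T) / (2.0 * L)
        piC = (C @ V.T + V @ C.T) / (2.0 * L)
        piG = (G @ V.T + V @ G.T) / (2.0 * L)
        piT = (T @ V.T + V @ T.T) / (2.0 * L)
    d = _tn93_from_counts(L, nAG, nCT, nTV, piA, piC, piG, piT)
    np.fill_diagonal(d, 0.0)
    return d
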