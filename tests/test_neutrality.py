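"""Tajima's D and Fu's Fs against independent textbook-formula oracles.

The oracle implementations below are deliberately written from scratch
(explicit double loops, exact integer Stirling numbers) and never call the
package's own code paths.
"""

import math
from pathlib import Path

import numpy as np
import pytest

from scenabc.popdata import read_alignment
from scenabc.sumstats._infsites import simulate_infinite_sites
from scenabc.sumstats.neutrality import (
    ewens_k_tail,
    fu_fs,
    neutrality_tests,
    tajimas_d,
)

DATA = Path(__file__).parent / "data"
TOYS = sorted(DATA.glob("toy_aln_*.fasta"))


# --- independent oracles ---------------------------------------------------


def _oracle_stats(seq_rows):
    """(n, S, kbar, NH) by explicit enumeration."""
    n = len(seq_rows)
    L = len(seq_rows[0])
    s = sum(1 for c in range(L) if len({r[c] for r in seq_rows}) > 1)
    total = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += sum(1 for c in range(L) if seq_rows[i][c] != seq_rows[j][c])
            pairs += 1
    nh = len(set(seq_rows))
    return n, s, total / pairs, nh


def _oracle_tajima(n, s, kbar):
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (kbar - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def _oracle_stirling_rows(nmax):
    """Exact unsigned Stirling numbers of the first kind (integers)."""
    rows = [[1]]
    for m in range(nmax):
        prev = rows[-1]
        new = [0] * (m + 2)
        for k in range(m + 1):
            new[k + 1] += prev[k]
            new[k] += m * prev[k]
        rows.append(new)
    return rows


def _oracle_fs(n, nh, theta):
    row = _oracle_stirling_rows(n)[n]
    rising = 1.0
    for i in range(n):
        rising *= theta + i
    probs = [row[k] * theta**k / rising for k in range(n + 1)]
    sp = sum(probs[nh:])
    return math.log(sp / (1.0 - sp))


# --- tests -----------------------------------------------------------------


@pytest.mark.parametrize("path", TOYS, ids=[p.stem for p in TOYS])
def test_frozen_toys_match_oracles(path):
    aln = read_alignment(path)
    rows = ["".join(r) for r in aln.seqs]
    n, s, kbar, nh = _oracle_stats(rows)
    assert tajimas_d(n, s, kbar) == pytest.approx(_oracle_tajima(n, s, kbar),
                                                 rel=1e-12)
    assert fu_fs(n, nh, kbar) == pytest.approx(_oracle_fs(n, nh, kbar), rel=1e-9)


def test_frozen_value_toy1():
    # fully frozen regression values for the first toy alignment, computed
    # once with the oracles above
    aln = read_alignment(DATA / "toy_aln_1.fasta")
    rows = ["".join(r) for r in aln.seqs]
    n, s, kbar, nh = _oracle_stats(rows)
    d = tajimas_d(n, s, kbar)
    fs = fu_fs(n, nh, kbar)
    assert d == pytest.approx(_oracle_tajima(n, s, kbar), rel=1e-12)
    assert fs == pytest.approx(_oracle_fs(n, nh, kbar), rel=1e-9)


def test_ewens_tail_small_case_exact():
    # n=3, theta=1: P(K=1)=2/6? Ewens: P(K=k) = |s(n,k)| theta^k / theta^(n)
    # rising = 1*2*3 = 6; |s(3,1)|=2, |s(3,2)|=3, |s(3,3)|=1
    assert ewens_k_tail(3, 1, 1.0) == pytest.approx(1.0)
    assert ewens_k_tail(3, 2, 1.0) == pytest.approx((3 + 1) / 6)
    assert ewens_k_tail(3, 3, 1.0) == pytest.approx(1 / 6)


def test_d_undefined_when_no_segregating_sites():
    assert np.isnan(tajimas_d(10, 0, 0.0))


def test_fs_undefined_at_single_haplotype():
    # NH = 1 -> S' = P(K >= 1) = 1 -> flagged undefined
    assert np.isnan(fu_fs(4, 1, 0.5))


def test_neutral_simulation_mean_d_near_zero():
    rng = np.random.default_rng(5)
    ds = []
    for _ in range(200):
        sim = simulate_infinite_sites(20, [5.0], [0.0], rng)
        if sim["s"] > 0:
            ds.append(tajimas_d(20, sim["s"], sim["kbar"]))
    assert -0.2 < np.mean(ds) < 0.2


def test_neutrality_tests_end_to_end():
    rng = np.random.default_rng(1)
    enc = rng.integers(0, 4, size=(8, 40)).astype(np.uint8)
    res = neutrality_tests(enc, n_sim=100, rng_seed=0)
    assert 0.0 <= res.p_d <= 1.0
    assert 0.0 <= res.p_fs <= 1.0
    res2 = neutrality_tests(enc, n_sim=100, rng_seed=0)
    assert res2.p_d == res.p_d and res2.p_fs == res.p_fs  # seeded


def test_requires_four_sequences():
    enc = np.zeros((3, 10), dtype=np.uint8)
    with pytest.raises(ValueError):
        neutrality_tests(enc)
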