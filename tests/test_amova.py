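"""AMOVA variance components against a direct sums-of-squares oracle."""

import numpy as np
import pytest
from scipy.stats import kstest

from scenabc.popdata import PopulationMap, SequenceAlignment
from scenabc.sumstats.amova import amova, amova_from_distances


def _oracle_one_level(d2, pops):
    """Direct SS evaluation for the 1-level analysis."""
    n = len(pops)
    uniq = sorted(set(pops), key=pops.index)
    ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_wp = 0.0
    for p in uniq:
        idx = [i for i in range(n) if pops[i] == p]
        ss_wp += sum(d2[i, j] for i in idx for j in idx if i < j) / len(idx)
    ss_ap = ss_total - ss_wp
    df_ap, df_wp = len(uniq) - 1, n - len(uniq)
    sigma_c = ss_wp / df_wp
    sizes = [pops.count(p) for p in uniq]
    n_prime = (n - sum(s * s for s in sizes) / n) / df_ap
    sigma_a = (ss_ap / df_ap - sigma_c) / n_prime
    return ss_total, ss_ap, ss_wp, sigma_a, sigma_c


def test_one_level_matches_oracle_toy():
    # 6 sequences, 3 populations of 2; squared distances arbitrary
    rng = np.random.default_rng(0)
    x = rng.random((6, 4))
    d2 = ((x[:, None] - x[None, :]) ** 2).sum(axis=2)
    pops = ["p1", "p1", "p2", "p2", "p3", "p3"]
    res = amova_from_distances(d2, pops)
    ss_total, ss_ap, ss_wp, sa, sc = _oracle_one_level(d2, pops)
    assert res.ss["total"] == pytest.approx(ss_total)
    assert res.ss["among_populations"] == pytest.approx(ss_ap)
    assert res.ss["within_populations"] == pytest.approx(ss_wp)
    assert res.components["among_populations"] == pytest.approx(sa)
    assert res.components["within_populations"] == pytest.approx(sc)
    assert res.fixation["F_ST"] == pytest.approx(sa / (sa + sc))


def test_one_level_unequal_sizes_matches_oracle():
    rng = np.random.default_rng(4)
    x = rng.random((9, 3))
    d2 = ((x[:, None] - x[None, :]) ** 2).sum(axis=2)
    pops = ["a"] * 2 + ["b"] * 3 + ["c"] * 4
    res = amova_from_distances(d2, pops)
    *_, sa, sc = _oracle_one_level(d2, pops)
    assert res.components["among_populations"] == pytest.approx(sa)
    assert res.components["within_populations"] == pytest.approx(sc)


def test_clone_populations_zero_among():
    base = np.array([[0.0, 2.0], [2.0, 0.0]])
    # 3 populations, each an identical pair of "sequences" at distance 2
    d2 = np.zeros((6, 6))
    for i in range(6):
        for j in range(6):
            d2[i, j] = base[i % 2, j % 2]
    pops = ["p1", "p1", "p2", "p2", "p3", "p3"]
    res = amova_from_distances(d2, pops)
    # the component estimate is <= 0 for clone populations (reported as
    # estimated); the floored percentage attributes nothing among populations
    assert res.components["among_populations"] <= 1e-12
    assert res.percentages["among_populations"] == pytest.approx(0.0, abs=1e-9)


def test_two_groups_fixed_difference_fct_one():
    # 2 groups x 2 populations x 2 clones; all variation between groups
    d2 = np.zeros((8, 8))
    d2[:4, 4:] = 4.0
    d2[4:, :4] = 4.0
    pops = ["a1", "a1", "a2", "a2", "b1", "b1", "b2", "b2"]
    grps = ["A"] * 4 + ["B"] * 4
    res = amova_from_distances(d2, pops, grps)
    assert res.fixation["F_CT"] == pytest.approx(1.0)
    assert res.fixation["F_ST"] == pytest.approx(1.0)
    assert res.percentages["among_groups"] == pytest.approx(100.0, abs=0.1)


def test_percentages_sum_to_100():
    rng = np.random.default_rng(9)
    x = rng.random((12, 5))
    d2 = ((x[:, None] - x[None, :]) ** 2).sum(axis=2)
    pops = [f"p{i % 4}" for i in range(12)]
    grps = ["G1" if i % 4 < 2 else "G2" for i in range(12)]
    res = amova_from_distances(d2, pops, grps)
    assert sum(res.percentages.values()) == pytest.approx(100.0, abs=0.1)
    # phi algebra consistent with its own components (after flooring)
    sa = res.components["among_groups"]
    sb = res.components["among_populations_within_groups"]
    sc = res.components["within_populations"]
    assert res.fixation["F_CT"] == pytest.approx(sa / (sa + sb + sc))


def test_amova_alignment_interface(toy_dataset):
    res = amova(toy_dataset.alignment, toy_dataset.popmap, "2-level",
                n_perm=99, rng_seed=0)
    assert res.levels == 2
    assert set(res.p_values) == {"F_CT", "F_SC", "F_ST"}
    assert all(0 < p <= 1 for p in res.p_values.values())


def test_permutation_p_uniform_without_structure():
    # on unstructured data F_ST permutation p-values are ~uniform
    rng = np.random.default_rng(2)
    pvals = []
    for rep in range(80):
        x = rng.random((16, 3))
        d2 = ((x[:, None] - x[None, :]) ** 2).sum(axis=2)
        pops = [f"p{i % 4}" for i in range(16)]
        res = amova_from_distances(d2, pops, None, n_perm=99, rng_seed=rep)
        pvals.append(res.p_values["F_ST"])
    assert kstest(pvals, "uniform").pvalue > 0.01


def test_requires_two_populations():
    with pytest.raises(ValueError):
        amova_from_distances(np.zeros((3, 3)), ["p", "p", "p"])
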