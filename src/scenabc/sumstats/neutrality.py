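"""Tajima's D and Fu's Fs with simulation p-values.

Tajima's D follows Tajima (1989) with the usual a1..e2 constants.  Fu's Fs
uses the Ewens sampling formula: ``S' = P(K >= NH_obs)`` at ``theta = kbar``
computed from unsigned Stirling numbers of the first kind in log space, and
``Fs = ln(S'/(1 - S'))``.  p-values come from constant-size coalescent
simulations at ``theta = kbar`` (lower tail, ``(b+1)/(m+1)`` corrected).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import logsumexp

from ._infsites import simulate_infinite_sites
from .distances import encode
from .diversity import seq_group_stats

__all__ = ["NeutralityResult", "tajimas_d", "fu_fs", "neutrality_tests"]


@dataclass
class NeutralityResult:
    d: float  # nan when undefined (S == 0)
    p_d: float
    fs: float  # nan when undefined (S' in {0, 1})
    p_fs: float
    n_sim: int


def tajimas_d(n: int, s: int, kbar: float) -> float:
    """Tajima's D from sample size, segregating sites and mean pairwise
    differences.  Returns ``nan`` when ``s == 0`` (undefined)."""
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    if s == 0:
        return float("nan")
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    return float((kbar - s / a1) / np.sqrt(var))


@lru_cache(maxsize=64)
def _log_stirling_row(n: int) -> tuple[float, ...]:
    """log |s(n, k)| for k = 0..n (unsigned first kind), by the recursion
    ``|s(n+1,k)| = |s(n,k-1)| + n |s(n,k)|`` carried in log space."""
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |s(0,0)| = 1
    for m in range(n):
        new = np.full(n + 1, -np.inf)
        new[1:] = row[:-1]
        with np.errstate(divide="ignore"):
            grown = row + np.log(m) if m > 0 else np.full(n + 1, -np.inf)
        new = np.logaddexp(new, grown)
        row = new
    return tuple(row)


def ewens_k_tail(n: int, k_obs: int, theta: float) -> float:
    """P(K >= k_obs) for the number of alleles K under the Ewens sampling
    formula with parameter theta in a sample of n."""
    if k_obs <= 1:
        return 1.0  # K >= 1 always
    if theta <= 0:
        return 0.0
    logrow = np.array(_log_stirling_row(n))
    k = np.arange(n + 1)
    logtheta = np.log(theta)
    log_rising = np.log(theta + np.arange(n)).sum()
    logp = logrow + k * logtheta - log_rising
    logp[0] = -np.inf
    tail = logsumexp(logp[k_obs:])
    return float(min(np.exp(tail), 1.0))


def fu_fs(n: int, nh: int, kbar: float) -> float:
    """Fu's Fs; ``nan`` when the tail probability degenerates to 0 or 1."""
    sp = ewens_k_tail(n, nh, kbar)
    if not (0.0 < sp < 1.0):
        return float("nan")
    return float(np.log(sp / (1.0 - sp)))


def neutrality_tests(obj, n_sim: int = 1000, rng_seed: int = 0) -> NeutralityResult:
    """Tajima's D and Fu's Fs for one group, with simulation p-values.

    Requires ``n >= 4``.  p-values are the lower-tail fractions of ``n_sim``
    constant-size coalescent replicates at ``theta = kbar`` whose statistic
    is <= the observed one, with the ``(b+1)/(m+1)`` correction.
    """
    enc = encode(obj)
    n = enc.shape[0]
    if n < 4:
        raise ValueError("neutrality tests require n >= 4")
    stats = seq_group_stats(enc)
    d_obs = tajimas_d(n, stats.s, stats.kbar)
    fs_obs = fu_fs(n, stats.nh, stats.kbar)

    rng = np.random.default_rng(rng_seed)
    theta = stats.kbar
    d_count = 0
    fs_count = 0
    d_total = 0
    fs_total = 0
    for _ in range(n_sim):
        sim = simulate_infinite_sites(n, [theta if theta > 0 else 1e-9], [0.0], rng)
        if sim["s"] > 0 and np.isfinite(d_obs):
            d_total += 1
            if tajimas_d(n, sim["s"], sim["kbar"]) <= d_obs:
                d_count += 1
        fs_sim = fu_fs(n, sim["nh"], sim["kbar"])
        if np.isfinite(fs_sim) and np.isfinite(fs_obs):
            fs_total += 1
            if fs_sim <= fs_obs:
                fs_count += 1
    p_d = (d_count + 1) / (d_total + 1) if np.isfinite(d_obs) else float("nan")
    p_fs = (fs_count + 1) / (fs_total + 1) if np.isfinite(fs_obs) else float("nan")
    return NeutralityResult(d=d_obs, p_d=p_d, fs=fs_obs, p_fs=p_fs, n_sim=n_sim)
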