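"""Generation-time and mutation-rate arithmetic."""

from __future__ import annotations

import numpy as np

__all__ = ["generation_time", "geometric_mean_rate", "per_generation_to_per_year"]


def generation_time(a: float, s: float) -> float:
    """Mean generation time ``T = a + s/(1 - s)`` from age at maturity ``a``
    (years) and annual adult survival ``s`` (Lande-style approximation).

    Requires ``0 <= s < 1``.
    """
    if not 0.0 <= s < 1.0:
        raise ValueError(f"annual survival must be in [0, 1), got {s}")
    if a < 0:
        raise ValueError(f"age at maturity must be >= 0, got {a}")
    return a + s / (1.0 - s)


def geometric_mean_rate(rates) -> float:
    """Geometric mean of strictly positive rates: ``exp(mean(log r))``."""
    arr = np.asarray(rates, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one rate")
    if (arr <= 0).any():
        raise ValueError("all rates must be strictly positive")
    return float(np.exp(np.log(arr).mean()))


def per_generation_to_per_year(mu_gen: float, t_years: float) -> float:
    """Convert a per-generation rate to per-year: ``mu_yr = mu_gen / T``."""
    if t_years <= 0:
        raise ValueError(f"generation time must be > 0, got {t_years}")
    return mu_gen / t_years
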