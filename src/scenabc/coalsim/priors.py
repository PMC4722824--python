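"""Uniform prior specifications and constrained sampling."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scenarios import DemographicScenario

__all__ = ["PriorSpec", "default_prior", "sample_priors"]


@dataclass
class PriorSpec:
    """Per-parameter uniform ranges plus ordering constraints.

    ``ordered`` lists tuples of parameter names that must be strictly
    increasing in every draw (enforced by rejection sampling).
    """

    ranges: dict[str, tuple[float, float]]
    ordered: list[tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValueError(f"prior for {name!r}: need lower < upper")
        for chain in self.ordered:
            for p in chain:
                if p not in self.ranges:
                    raise ValueError(f"ordered constraint on unknown parameter {p!r}")

    def range_of(self, name: str) -> tuple[float, float]:
        return self.ranges[name]


def default_prior() -> PriorSpec:
    """Priors used for scenario comparison: Ne uniform on 10-100,000, split
    times uniform on 100-50,000 generations with t1 < t2 < t3, admixture
    rate uniform (0.001, 0.999), mean sequence rate uniform 1e-9..1e-7 per
    site per generation, mean microsatellite rate uniform 1e-4..1e-2 per
    locus per generation, GSM geometric parameter uniform 0.1..0.3."""
    ranges = {
        "N_TMVB": (10.0, 100_000.0),
        "N_SMO": (10.0, 100_000.0),
        "N_SMS": (10.0, 100_000.0),
        "N_CHIS": (10.0, 100_000.0),
        "N5": (10.0, 100_000.0),
        "N6": (10.0, 100_000.0),
        "t1": (100.0, 50_000.0),
        "t2": (100.0, 50_000.0),
        "t3": (100.0, 50_000.0),
        "r": (0.001, 0.999),
        "mu_seq": (1e-9, 1e-7),
        "mu_ms": (1e-4, 1e-2),
        "gsm_p": (0.1, 0.3),
    }
    return PriorSpec(ranges=ranges, ordered=[("t1", "t2", "t3")])


def sample_priors(
    prior: PriorSpec,
    scenario: DemographicScenario | None = None,
    rng: np.random.Generator | int | None = None,
    max_tries: int = 10_000,
) -> dict[str, float]:
    """Draw one parameter dict from the prior.

    Only parameters the scenario uses are drawn when a scenario is given
    (plus the mutation-model parameters, which every scenario needs).
    Ordering constraints are satisfied by rejection; an infeasible ordered
    region raises after ``max_tries`` rejections.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if scenario is not None:
        wanted = set(scenario.parameters) | {"mu_seq", "mu_ms", "gsm_p"}
        names = [p for p in prior.ranges if p in wanted]
    else:
        names = list(prior.ranges)
    for _ in range(max_tries):
        draw = {}
        for name in names:
            lo, hi = prior.ranges[name]
            draw[name] = float(rng.uniform(lo, hi))
        ok = True
        for chain in prior.ordered:
            vals = [draw[p] for p in chain if p in draw]
            if any(b <= a for a, b in zip(vals, vals[1:])):
                ok = False
                break
        if ok:
            return draw
    raise RuntimeError("prior rejection sampling failed; ordered region "
                       "may be empty")
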