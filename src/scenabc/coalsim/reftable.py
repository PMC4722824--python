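"""Reference-table construction: (scenario, parameters, summary vector)
rows simulated from the priors.

Seed discipline: every row gets an independent RNG derived from the master
seed with ``SeedSequence(master, spawn_key=(scenario_index, row_index))``,
so tables are bit-identical however the work is batched or resumed.  A
failed simulation is retried with ``spawn_key=(si, ri, attempt)`` and
logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..sumstats.vector import summary_vector_names
from .dataset import simulate_dataset
from .priors import PriorSpec, sample_priors
from .scenarios import DemographicScenario, LocusModel, SampleConfig

logger = logging.getLogger(__name__)

__all__ = ["ReferenceTable", "build_reference_table"]

#: canonical column order for the parameter block
PARAM_COLUMNS = ["N_TMVB", "N_SMO", "N_SMS", "N_CHIS", "N5", "N6",
                 "t1", "t2", "t3", "r", "mu_seq", "mu_ms", "gsm_p"]


@dataclass
class ReferenceTable:
    """Rows of simulated (scenario, parameter vector, summary vector)."""

    data: pd.DataFrame
    stat_names: list[str]
    param_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        need = ["scenario"] + self.param_names + self.stat_names
        missing = [c for c in need if c not in self.data.columns]
        if missing:
            raise ValueError(f"reference table missing columns {missing}")
        if self.data[self.stat_names].isna().any().any():
            raise ValueError("reference table contains missing statistics")

    @property
    def scenarios(self) -> list[str]:
        return list(dict.fromkeys(self.data["scenario"]))

    def stats_matrix(self) -> np.ndarray:
        return self.data[self.stat_names].to_numpy(dtype=float)

    def save(self, path: str | Path) -> None:
        """Persist as CSV with a sidecar ``<path>.meta.json``."""
        path = Path(path)
        self.data.to_csv(path, index=False)
        side = {
            "stat_names": self.stat_names,
            "param_names": self.param_names,
            "meta": self.meta,
        }
        with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
            json.dump(side, fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceTable":
        path = Path(path)
        data = pd.read_csv(path)
        with open(path.with_suffix(path.suffix + ".meta.json")) as fh:
            side = json.load(fh)
        return cls(data=data, stat_names=side["stat_names"],
                   param_names=side["param_names"], meta=side.get("meta", {}))


def _simulate_row(scenario, prior, config, loci, master_seed, si, ri):
    """One reference-table row; deterministic in (master_seed, si, ri)."""
    last_err: Exception | None = None
    for attempt in range(5):
        key = (si, ri) if attempt == 0 else (si, ri, attempt)
        ss = np.random.SeedSequence(entropy=master_seed, spawn_key=key)
        rng = np.random.default_rng(ss)
        try:
            params = sample_priors(prior, scenario, rng)
            # per-locus microsatellite rates: Gamma(shape 2) around the mean
            n_ms = sum(1 for l in loci if l.kind == "microsat")
            rates = rng.gamma(2.0, params["mu_ms"] / 2.0, size=n_ms)
            sim = simulate_dataset(scenario, params, config, loci, rng,
                                   msat_rates=rates)
            return params, sim.summary_vector()
        except Exception as exc:  # retry with derived sub-seed
            last_err = exc
            logger.warning("simulation (%s, row %d, attempt %d) failed: %s",
                           scenario.name, ri, attempt, exc)
    raise RuntimeError(
        f"simulation failed repeatedly for {scenario.name} row {ri}"
    ) from last_err


def build_reference_table(
    scenarios: list[DemographicScenario],
    n_per_scenario: int,
    prior: PriorSpec,
    config: SampleConfig,
    loci: list[LocusModel],
    rng_seed: int,
    checkpoint_path: str | Path | None = None,
    checkpoint_every: int = 2000,
) -> ReferenceTable:
    """Simulate ``n_per_scenario`` rows per scenario.

    When ``checkpoint_path`` is given, partial tables are written there
    every ``checkpoint_every`` rows and an interrupted build resumes from
    the last checkpoint (results are identical either way thanks to the
    per-row seed scheme).
    """
    stat_names = summary_vector_names(config.groups)
    columns = ["scenario"] + PARAM_COLUMNS + stat_names

    done: dict[tuple[str, int], list] = {}
    ckpt = Path(checkpoint_path) if checkpoint_path else None
    if ckpt and ckpt.exists():
        prev = pd.read_csv(ckpt, float_precision="round_trip")
        if list(prev.columns) == columns + ["_row"]:
            for _, row in prev.iterrows():
                done[(row["scenario"], int(row["_row"]))] = row[columns].tolist()
            logger.info("resumed %d rows from checkpoint %s", len(done), ckpt)

    rows: list[list] = []
    pending = 0
    for si, scenario in enumerate(scenarios):
        for ri in range(n_per_scenario):
            key = (scenario.name, ri)
            if key in done:
                rows.append(done[key] + [ri])
                continue
            params, stats = _simulate_row(
                scenario, prior, config, loci, rng_seed, si, ri
            )
            pvec = [params.get(p, 0.0) for p in PARAM_COLUMNS]
            rows.append([scenario.name] + pvec + stats.tolist() + [ri])
            pending += 1
            if ckpt and pending >= checkpoint_every:
                pd.DataFrame(rows, columns=columns + ["_row"]).to_csv(
                    ckpt, index=False
                )
                pending = 0
    if ckpt:
        pd.DataFrame(rows, columns=columns + ["_row"]).to_csv(ckpt, index=False)

    df = pd.DataFrame(rows, columns=columns + ["_row"]).drop(columns="_row")
    meta = {
        "seed": rng_seed,
        "n_per_scenario": n_per_scenario,
        "scenarios": [s.name for s in scenarios],
        "prior": {k: list(v) for k, v in prior.ranges.items()},
        "groups": config.groups,
    }
    return ReferenceTable(data=df, stat_names=stat_names,
                          param_names=PARAM_COLUMNS, meta=meta)
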