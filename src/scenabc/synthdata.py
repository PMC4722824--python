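"""Truth-annotated synthetic fixtures emulating the study's inputs.

``make_popgen_fixture`` simulates a joint mtDNA + microsatellite dataset
under a chosen scenario preset and writes FASTA / GenePop / map TSV /
truth JSON; ``make_spectra_fixture`` writes two-peak reflectance spectra
(UV peak near 420 nm, long-wave peak at a per-group mean) plus a group TSV.
Everything is deterministic under the seed, so fixtures can be regenerated
bit-identically from their manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .coalsim.dataset import simulate_dataset
from .coalsim.priors import default_prior, sample_priors
from .coalsim.scenarios import (
    DemographicScenario,
    default_loci,
    paper_sample_config,
    scenario_preset,
)
from .popdata import write_alignment, write_genepop, write_population_map

__all__ = ["FixtureTruth", "make_popgen_fixture", "make_spectra_fixture",
           "DEFAULT_FIXTURE_PARAMS"]

#: well-separated Sc1 parameters used by the shipped regression fixture:
#: large old split (t3), moderate recent splits, small terminal sizes
DEFAULT_FIXTURE_PARAMS = {
    "N_TMVB": 2_000.0,
    "N_SMO": 8_000.0,
    "N_SMS": 6_000.0,
    "N_CHIS": 6_000.0,
    "N5": 12_000.0,
    "N6": 20_000.0,
    "t1": 1_500.0,
    "t2": 4_000.0,
    "t3": 40_000.0,
    "mu_seq": 4e-8,
    "mu_ms": 2e-3,
    "gsm_p": 0.2,
}


@dataclass
class FixtureTruth:
    scenario: str
    params: dict[str, float]
    seed: int
    files: dict[str, str] = field(default_factory=dict)  # name -> sha256

    def to_json(self) -> str:
        return json.dumps(
            {"scenario": self.scenario, "params": self.params,
             "seed": self.seed, "files": self.files},
            indent=1, sort_keys=True,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_popgen_fixture(
    scenario: str | DemographicScenario = "Sc1",
    params: dict[str, float] | str | None = None,
    outdir: str | Path = ".",
    rng_seed: int = 0,
    localities_per_group: int = 3,
    force: bool = False,
) -> FixtureTruth:
    """Write a synthetic popgen fixture (FASTA + GenePop + map + truth).

    ``params`` may be an explicit dict, ``'draw'`` (sample from the default
    prior), or None (the shipped well-separated defaults).  Group sample
    sizes follow the study configuration (mtDNA 19/70/37/27, 126 genotyped
    individuals).  Refuses to overwrite existing files unless ``force``.
    """
    if isinstance(scenario, str):
        scenario = scenario_preset(scenario)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / name for name in
             ("sequences.fasta", "genotypes.gen", "popmap.tsv", "truth.json")}
    clashes = [str(p) for p in paths.values() if p.exists()]
    if clashes and not force:
        raise FileExistsError(f"fixture files exist (use force=True): {clashes}")

    rng = np.random.default_rng(rng_seed)
    if params == "draw":
        params = sample_priors(default_prior(), scenario, rng)
    elif params is None:
        params = dict(DEFAULT_FIXTURE_PARAMS)
    config = paper_sample_config()
    loci = default_loci()
    sim = simulate_dataset(scenario, params, config, loci, rng)
    dataset = sim.to_dataset(localities_per_group=localities_per_group)

    write_alignment(dataset.alignment, paths["sequences.fasta"])
    pops = {i: dataset.popmap.individual_to_population[i]
            for i in dataset.genotypes.ids}
    write_genepop(dataset.genotypes, pops, paths["genotypes.gen"])
    write_population_map(dataset.popmap, paths["popmap.tsv"])

    truth = FixtureTruth(scenario=scenario.name,
                         params={k: float(v) for k, v in params.items()},
                         seed=rng_seed)
    for name in ("sequences.fasta", "genotypes.gen", "popmap.tsv"):
        truth.files[name] = _sha256(paths[name])
    paths["truth.json"].write_text(truth.to_json())
    return truth


def make_spectra_fixture(
    outdir: str | Path = ".",
    n_per_group: int = 10,
    group_red_peaks: dict[str, float] | None = None,
    uv_peak: float = 420.0,
    noise_sd: float = 0.5,
    rng_seed: int = 0,
    force: bool = False,
) -> dict[str, Path]:
    """Write a synthetic reflectance fixture: ``spectra.csv`` (wavelength
    column + one column per specimen, 300-1000 nm at 1 nm) and
    ``groups.tsv``.

    Spectra are a UV/blue Gaussian (mean near ``uv_peak``) plus a long-wave
    Gaussian at the group's mean (defaults: amethyst 715 nm, blue 780 nm);
    per-specimen peak positions are jittered (SD 8 nm) and heteroscedastic
    noise is added.
    """
    if n_per_group < 5:
        raise ValueError("need at least 5 spectra per group")
    if group_red_peaks is None:
        group_red_peaks = {"amethyst": 715.0, "blue": 780.0}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spectra_path = outdir / "spectra.csv"
    groups_path = outdir / "groups.tsv"
    if (spectra_path.exists() or groups_path.exists()) and not force:
        raise FileExistsError("fixture files exist (use force=True)")

    rng = np.random.default_rng(rng_seed)
    wl = np.arange(300.0, 1000.0 + 0.5, 1.0)
    names: list[str] = []
    cols: list[np.ndarray] = []
    rows: list[tuple[str, str]] = []
    for group, red_mean in group_red_peaks.items():
        for i in range(n_per_group):
            uv_mu = uv_peak + rng.normal(0.0, 8.0)
            red_mu = red_mean + rng.normal(0.0, 8.0)
            uv_amp = rng.uniform(8.0, 14.0)
            red_amp = rng.uniform(25.0, 40.0)
            base = (
                uv_amp * np.exp(-0.5 * ((wl - uv_mu) / 25.0) ** 2)
                + red_amp * np.exp(-0.5 * ((wl - red_mu) / 35.0) ** 2)
                + 1.0
            )
            noise = rng.normal(0.0, noise_sd * (0.5 + base / base.max()), wl.size)
            spec = np.maximum(base + noise, 0.0)
            name = f"{group}_{i + 1:02d}"
            names.append(name)
            cols.append(spec)
            rows.append((name, group))

    with open(spectra_path, "w") as fh:
        fh.write("wavelength," + ",".join(names) + "\n")
        mat = np.column_stack(cols)
        for j, w in enumerate(wl):
            vals = ",".join(f"{v:.6f}" for v in mat[j])
            fh.write(f"{w:.1f},{vals}\n")
    with open(groups_path, "w") as fh:
        fh.write("specimen\tgroup\n")
        for name, group in rows:
            fh.write(f"{name}\t{group}\n")
    return {"spectra": spectra_path, "groups": groups_path}
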