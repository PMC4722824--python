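"""End-to-end orchestration from a single JSON run configuration.

Stages: summary statistics -> reference table -> model choice -> parameter
estimation -> POD error rates -> model checking -> color analysis.  Every
stage writes its output file under ``output_dir`` plus a manifest recording
seeds, stage runtimes and content hashes; stages can be re-run individually
and intermediate deletion + resume reproduces files bit-identically (all
randomness is derived from the configured seeds).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import abc as abcmod
from . import colorspec, popdata, sumstats
from .coalsim.priors import PriorSpec, default_prior
from .coalsim.reftable import ReferenceTable, build_reference_table
from .coalsim.scenarios import (
    SampleConfig,
    default_loci,
    paper_sample_config,
    scenario_preset,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis", "STAGES"]

STAGES = ["stats", "reftable", "choice", "estimate", "pods", "check", "color"]


@dataclass
class RunConfig:
    """Validated run configuration (see ``RunConfig.from_json``)."""

    output_dir: Path
    fasta: Path | None = None
    genepop: Path | None = None
    popmap: Path | None = None
    spectra: Path | None = None
    spectra_groups: Path | None = None
    groups: list[str] = field(default_factory=list)
    scenarios: list[str] = field(default_factory=lambda: ["Sc1", "Sc2", "Sc3"])
    prior: PriorSpec = field(default_factory=default_prior)
    n_sims: int = 1000
    delta: float = 0.01
    n_pods: int = 50
    n_pp: int = 100
    n_perm: int = 1000
    n_neutrality_sim: int = 200
    n_boot: int = 50
    seed: int = 1
    seq_length: int = 751
    n_msat: int = 8
    sample_config: SampleConfig | None = None
    span: float = 0.25

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = json.load(fh)
        known = {
            "output_dir", "fasta", "genepop", "popmap", "spectra",
            "spectra_groups", "groups", "scenarios", "prior", "n_sims",
            "delta", "n_pods", "n_pp", "n_perm", "n_neutrality_sim",
            "n_boot", "seed", "seq_length", "n_msat", "sample_config", "span",
        }
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        base = path.parent

        def respath(key):
            if raw.get(key) is None:
                return None
            p = Path(raw[key])
            return p if p.is_absolute() else base / p

        prior = default_prior()
        if "prior" in raw:
            ranges = {k: tuple(v) for k, v in raw["prior"].get("ranges", {}).items()}
            merged = dict(prior.ranges)
            merged.update(ranges)
            prior = PriorSpec(ranges=merged,
                              ordered=[tuple(c) for c in
                                       raw["prior"].get("ordered",
                                                        [("t1", "t2", "t3")])])
        sample_config = None
        if "sample_config" in raw and raw["sample_config"]:
            sc = raw["sample_config"]
            sample_config = SampleConfig(
                seq_individuals=dict(sc["seq_individuals"]),
                msat_individuals=dict(sc["msat_individuals"]),
            )
        return cls(
            output_dir=Path(raw["output_dir"]) if Path(raw["output_dir"]).is_absolute()
            else base / raw["output_dir"],
            fasta=respath("fasta"),
            genepop=respath("genepop"),
            popmap=respath("popmap"),
            spectra=respath("spectra"),
            spectra_groups=respath("spectra_groups"),
            groups=list(raw.get("groups", [])),
            scenarios=list(raw.get("scenarios", ["Sc1", "Sc2", "Sc3"])),
            prior=prior,
            n_sims=int(raw.get("n_sims", 1000)),
            delta=float(raw.get("delta", 0.01)),
            n_pods=int(raw.get("n_pods", 50)),
            n_pp=int(raw.get("n_pp", 100)),
            n_perm=int(raw.get("n_perm", 1000)),
            n_neutrality_sim=int(raw.get("n_neutrality_sim", 200)),
            n_boot=int(raw.get("n_boot", 50)),
            seed=int(raw.get("seed", 1)),
            seq_length=int(raw.get("seq_length", 751)),
            n_msat=int(raw.get("n_msat", 8)),
            sample_config=sample_config,
            span=float(raw.get("span", 0.25)),
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_dataset(cfg: RunConfig) -> popdata.MultilocusDataset | None:
    aln = popdata.read_alignment(cfg.fasta) if cfg.fasta else None
    geno = None
    if cfg.genepop:
        geno, _ = popdata.read_genepop(cfg.genepop)
    if aln is None and geno is None:
        return None
    if cfg.popmap is None:
        raise ValueError("popmap required when marker files are given")
    return popdata.assemble_dataset(aln, geno, cfg.popmap)


def run_full_analysis(cfg: RunConfig, stages: list[str] | None = None) -> dict:
    """Run the configured stages and return the manifest dict.

    A stage failure raises with the stage name; outputs of completed stages
    stay on disk.  Stages depending on a missing marker are skipped with an
    explicit notice in the manifest.
    """
    stages = stages or STAGES
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stages {bad}")
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "skipped": {},
                      "config": {"n_sims": cfg.n_sims, "delta": cfg.delta,
                                 "n_pods": cfg.n_pods, "n_pp": cfg.n_pp,
                                 "n_perm": cfg.n_perm, "scenarios": cfg.scenarios}}
    dataset = _load_dataset(cfg)
    groups = cfg.groups or (dataset.groups if dataset else [])
    config = cfg.sample_config or paper_sample_config()
    loci = default_loci(cfg.seq_length, cfg.n_msat)
    scens = [scenario_preset(s) for s in cfg.scenarios]

    observed = None
    table: ReferenceTable | None = None
    posterior = None

    def record(stage: str, path: Path, t0: float) -> None:
        manifest["stages"][stage] = {
            "output": str(path), "sha256": _sha256(path),
            "seconds": round(time.time() - t0, 3),
        }

    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.time()
        try:
            if stage == "stats":
                if dataset is None:
                    manifest["skipped"][stage] = "no marker inputs configured"
                    continue
                path = out / "stats.csv"
                _stats_stage(cfg, dataset, groups, path)
                record(stage, path, t0)
            elif stage == "reftable":
                path = out / "ref.csv"
                table = build_reference_table(
                    scens, cfg.n_sims, cfg.prior, config, loci, cfg.seed
                )
                table.save(path)
                record(stage, path, t0)
            elif stage == "choice":
                if dataset is None or dataset.alignment is None \
                        or dataset.genotypes is None:
                    manifest["skipped"][stage] = "needs both markers"
                    continue
                table = table or ReferenceTable.load(out / "ref.csv")
                observed, _ = sumstats.summary_vector(dataset, config.groups)
                mc = abcmod.model_choice(table, observed, cfg.delta, cfg.seed)
                path = out / "choice.json"
                path.write_text(json.dumps({
                    "scenarios": mc.scenarios, "direct": mc.direct,
                    "logistic": mc.logistic,
                    "ci": {k: list(v) for k, v in mc.logistic_ci.items()},
                    "best": mc.best, "n_accepted": mc.n_accepted,
                }, indent=1))
                record(stage, path, t0)
            elif stage == "estimate":
                if observed is None:
                    manifest["skipped"][stage] = "no observed summary vector"
                    continue
                table = table or ReferenceTable.load(out / "ref.csv")
                with open(out / "choice.json") as fh:
                    best = json.load(fh)["best"]
                n_best = int((table.data["scenario"] == best).sum())
                # keep at least ~20 accepted rows on small scaled tables
                delta_eff = max(cfg.delta, min(1.0, 20.0 / max(n_best, 1)))
                posterior = abcmod.estimate_parameters(
                    table, observed, delta_eff, scenario=best,
                    min_accepted=min(20, n_best),
                )
                path = out / "params.json"
                path.write_text(json.dumps({
                    "scenario": best,
                    "summaries": posterior.summaries,
                }, indent=1))
                record(stage, path, t0)
            elif stage == "pods":
                table = table or ReferenceTable.load(out / "ref.csv")
                errors = abcmod.pods_error_rates(
                    scens, cfg.prior, config, loci, cfg.n_pods, table,
                    cfg.delta, cfg.seed,
                )
                path = out / "pods.json"
                path.write_text(json.dumps({
                    "focal": errors.focal, "type_I": errors.type_i,
                    "type_II": errors.type_ii, "n_pods": errors.n_pods,
                    "confusion": errors.confusion,
                    "n_failed": errors.n_failed,
                }, indent=1))
                record(stage, path, t0)
            elif stage == "check":
                if posterior is None or observed is None:
                    manifest["skipped"][stage] = "needs estimate stage outputs"
                    continue
                table = table or ReferenceTable.load(out / "ref.csv")
                with open(out / "choice.json") as fh:
                    best = json.load(fh)["best"]
                report = abcmod.model_check(
                    table, posterior, observed, scenario_preset(best),
                    config, loci, cfg.n_pp, cfg.seed,
                )
                path = out / "check.json"
                path.write_text(json.dumps({
                    "explained_variance": report.pca_explained.tolist(),
                    "observed_coords": report.observed_coords.tolist(),
                    "tail_probabilities": report.tail_probabilities,
                    "n_pp": report.n_pp,
                }, indent=1))
                record(stage, path, t0)
            elif stage == "color":
                if cfg.spectra is None or cfg.spectra_groups is None:
                    manifest["skipped"][stage] = "no spectra configured"
                    continue
                path = out / "color.csv"
                _color_stage(cfg, path)
                record(stage, path, t0)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _stats_stage(cfg: RunConfig, dataset, groups, path: Path) -> None:
    rows = []
    if dataset.alignment is not None:
        for gi, g in enumerate(groups):
            aln = dataset.group_alignment(g)
            if aln.n < 2:
                continue
            st = sumstats.seq_group_stats(aln)
            row = {"unit": "group", "name": g, "N": st.n, "NH": st.nh,
                   "h": st.h, "h_sd": st.h_sd, "pi": st.pi, "pi_sd": st.pi_sd,
                   "S": st.s, "kbar": st.kbar}
            if aln.n >= 4:
                nt = sumstats.neutrality_tests(
                    aln, cfg.n_neutrality_sim, cfg.seed + gi
                )
                mm = sumstats.mismatch_analysis(aln, cfg.n_boot, cfg.seed + gi)
                row.update({"tajimas_d": nt.d, "p_d": nt.p_d, "fu_fs": nt.fs,
                            "p_fs": nt.p_fs, "ssd": mm.ssd, "p_ssd": mm.p_ssd,
                            "hri": mm.hri, "p_hri": mm.p_hri, "tau": mm.tau})
            rows.append(row)
        res = sumstats.amova(dataset.alignment, dataset.popmap, "1-level",
                             cfg.n_perm, cfg.seed)
        rows.append({"unit": "amova_1level", "name": "among_populations",
                     **{f"pct_{k}": v for k, v in res.percentages.items()},
                     **{f"F_{k}" if not k.startswith("F_") else k: v
                        for k, v in res.fixation.items()},
                     **{f"p_{k}": v for k, v in res.p_values.items()}})
        if len(dataset.popmap.groups) >= 2 and len(dataset.popmap.populations) \
                > len(dataset.popmap.groups):
            res2 = sumstats.amova(dataset.alignment, dataset.popmap, "2-level",
                                  cfg.n_perm, cfg.seed)
            rows.append({"unit": "amova_2level", "name": "nested",
                         **{f"pct_{k}": v for k, v in res2.percentages.items()},
                         **res2.fixation,
                         **{f"p_{k}": v for k, v in res2.p_values.items()}})
    if dataset.genotypes is not None:
        for g in groups:
            geno = dataset.group_genotypes(g)
            if geno.n < 2:
                continue
            ms = sumstats.msat_group_stats(geno)
            rows.append({"unit": "msat_group", "name": g, "N": ms.n,
                         "A": ms.a, "He": ms.he, "Ho": ms.ho, "V": ms.v,
                         "Ar": ms.ar})
    if dataset.alignment is not None and dataset.genotypes is not None:
        for i, a in enumerate(groups):
            for b in groups[i + 1:]:
                try:
                    pr = sumstats.pairwise_differentiation(dataset, a, b)
                except ValueError:
                    continue
                rows.append({"unit": "pair", "name": f"{a}~{b}",
                             "phi_st": pr.phi_st_seq, "theta": pr.theta_msat,
                             "n_st": pr.n_st, "He_comb": pr.he_combined,
                             "S_comb": pr.s_combined})
    pd.DataFrame(rows).to_csv(path, index=False)


def _color_stage(cfg: RunConfig, path: Path) -> None:
    df = pd.read_csv(cfg.spectra)
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    groups = pd.read_csv(cfg.spectra_groups, sep="\t").set_index("specimen")["group"]
    vm = colorspec.default_visual_model()
    rows = []
    pts_by_group: dict[str, list[np.ndarray]] = {}
    for col in df.columns[1:]:
        spec = colorspec.ReflectanceSpectrum(wl, df[col].to_numpy(dtype=float),
                                             label=col)
        sm = colorspec.smooth_spectrum(spec, cfg.span)
        peaks = colorspec.hue_peaks(sm)
        point = colorspec.tetra_point(colorspec.quantum_catches(sm, vm), label=col)
        g = str(groups.get(col, ""))
        pts_by_group.setdefault(g, []).append(point.xyz)
        rows.append({
            "specimen": col, "group": g,
            "uv_peak_nm": peaks[0]["peak_nm"], "red_peak_nm": peaks[1]["peak_nm"],
            "x": point.xyz[0], "y": point.xyz[1], "z": point.xyz[2],
            "h_theta": point.h_theta, "h_phi": point.h_phi,
            "r_vec": point.r_vec, "r_max": point.r_max,
            "r_achieved": point.r_achieved,
        })
    out_df = pd.DataFrame(rows)
    out_df.to_csv(path, index=False)
    # pairwise volume overlaps as a sidecar
    names = sorted(pts_by_group)
    overlaps = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if len(pts_by_group[a]) >= 4 and len(pts_by_group[b]) >= 4:
                res = colorspec.color_volume_overlap(
                    np.array(pts_by_group[a]), np.array(pts_by_group[b])
                )
                overlaps[f"{a}~{b}"] = {
                    "vol_a": res.vol_a, "vol_b": res.vol_b,
                    "intersection": res.vol_intersection,
                    "overlap_vs_union": res.overlap_vs_union,
                    "overlap_vs_smaller": res.overlap_vs_smaller,
                }
    path.with_suffix(".overlap.json").write_text(json.dumps(overlaps, indent=1))
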