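"""Demographic scenario definitions (population merges with one optional
admixture pulse), sample configurations and per-locus mutation models.

Scenario times are in generations looking backward from the present.  Sizes
are diploid effective sizes; the simulator converts to gene-copy numbers
per marker class (autosomal ``2N``, mitochondrial ``N/2``).

Three presets mirror the competing divergence histories of the study system
(four extant groups TMVB, SMO, SMS, CHIS; two ancestral sizes N5 and N6):

* ``Sc1``: TMVB joins SMO at t1; SMO joins SMS at t2 (size N5); SMS joins
  CHIS at t3 (size N6).
* ``Sc2``: SMS joins TMVB at t1; TMVB joins SMO at t2 (size N5); SMO joins
  CHIS at t3 (size N6).
* ``Sc3``: SMS is an admixture of TMVB (weight r) and SMO formed at t1;
  TMVB joins SMO at t2 (size N5); SMO joins CHIS at t3 (size N6).

A population created by a merge keeps the sink's size unless the event
names a new size parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "MergeEvent",
    "AdmixtureEvent",
    "DemographicScenario",
    "SampleConfig",
    "LocusModel",
    "scenario_preset",
    "paper_sample_config",
    "default_loci",
    "PAPER_GROUPS",
]

PAPER_GROUPS = ["TMVB", "SMO", "SMS", "CHIS"]


@dataclass(frozen=True)
class MergeEvent:
    """At ``time_param`` (backward) all lineages of ``source`` move into
    ``sink``; ``sink_size_param`` optionally renames the sink's size."""

    time_param: str
    source: str
    sink: str
    sink_size_param: str | None = None


@dataclass(frozen=True)
class AdmixtureEvent:
    """At ``time_param`` each lineage of ``target`` joins ``parent1`` with
    probability ``rate_param``'s value, else ``parent2``."""

    time_param: str
    target: str
    parent1: str
    parent2: str
    rate_param: str = "r"


@dataclass
class DemographicScenario:
    name: str
    populations: list[str]  # extant at time 0
    size_params: dict[str, str]  # population -> size parameter name
    events: list[MergeEvent | AdmixtureEvent]
    parameters: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.parameters:
            params = list(dict.fromkeys(self.size_params.values()))
            for ev in self.events:
                params.append(ev.time_param)
                if isinstance(ev, AdmixtureEvent):
                    params.append(ev.rate_param)
                elif ev.sink_size_param:
                    params.append(ev.sink_size_param)
            self.parameters = list(dict.fromkeys(params))

    def instantiate(self, params: dict[str, float]):
        """Resolve to concrete ``(sizes, events)`` with numeric times.

        Validates that event times strictly increase and that exactly one
        population remains after the last event.
        """
        missing = [p for p in self.parameters if p not in params]
        if missing:
            raise ValueError(f"scenario {self.name}: missing parameters {missing}")
        sizes = {pop: float(params[key]) for pop, key in self.size_params.items()}
        if any(v <= 0 for v in sizes.values()):
            raise ValueError("population sizes must be > 0")
        events = []
        for ev in self.events:
            t = float(params[ev.time_param])
            if isinstance(ev, MergeEvent):
                new_size = (float(params[ev.sink_size_param])
                            if ev.sink_size_param else None)
                events.append(("merge", t, ev.source, ev.sink, new_size))
            else:
                r = float(params[ev.rate_param])
                if not 0.0 < r < 1.0:
                    raise ValueError(f"admixture rate must be in (0,1), got {r}")
                events.append(("admix", t, ev.target, ev.parent1, ev.parent2, r))
        times = [e[1] for e in events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(
                f"scenario {self.name}: event times must strictly increase "
                f"backward, got {times}"
            )
        # check a single lineage container remains
        alive = set(self.populations)
        for e in events:
            if e[0] == "merge":
                _, _, src, snk, _ = e
                alive.discard(src)
                if snk not in alive:
                    raise ValueError(f"merge sink {snk!r} not alive at event time")
            else:
                _, _, tgt, p1, p2, _ = e
                alive.discard(tgt)
                if p1 not in alive or p2 not in alive:
                    raise ValueError("admixture parent not alive at event time")
        if len(alive) != 1:
            raise ValueError(
                f"scenario {self.name}: {len(alive)} populations remain after "
                "the final event; expected exactly 1"
            )
        return sizes, events


def scenario_preset(name: str) -> DemographicScenario:
    """Return one of the shipped presets ``Sc1``, ``Sc2``, ``Sc3``."""
    sizes = {"TMVB": "N_TMVB", "SMO": "N_SMO", "SMS": "N_SMS", "CHIS": "N_CHIS"}
    if name == "Sc1":
        return DemographicScenario(
            name="Sc1",
            populations=list(PAPER_GROUPS),
            size_params=dict(sizes),
            events=[
                MergeEvent("t1", "TMVB", "SMO"),
                MergeEvent("t2", "SMO", "SMS", sink_size_param="N5"),
                MergeEvent("t3", "SMS", "CHIS", sink_size_param="N6"),
            ],
        )
    if name == "Sc2":
        return DemographicScenario(
            name="Sc2",
            populations=list(PAPER_GROUPS),
            size_params=dict(sizes),
            events=[
                MergeEvent("t1", "SMS", "TMVB"),
                MergeEvent("t2", "TMVB", "SMO", sink_size_param="N5"),
                MergeEvent("t3", "SMO", "CHIS", sink_size_param="N6"),
            ],
        )
    if name == "Sc3":
        return DemographicScenario(
            name="Sc3",
            populations=list(PAPER_GROUPS),
            size_params=dict(sizes),
            events=[
                AdmixtureEvent("t1", "SMS", "TMVB", "SMO", rate_param="r"),
                MergeEvent("t2", "TMVB", "SMO", sink_size_param="N5"),
                MergeEvent("t3", "SMO", "CHIS", sink_size_param="N6"),
            ],
        )
    raise KeyError(f"unknown scenario preset {name!r}")


@dataclass
class SampleConfig:
    """Sampled individuals per group for each marker class.

    mtDNA contributes one gene copy per individual, microsatellites two.
    """

    seq_individuals: dict[str, int]
    msat_individuals: dict[str, int]

    def __post_init__(self) -> None:
        for d in (self.seq_individuals, self.msat_individuals):
            if any(v < 0 for v in d.values()):
                raise ValueError("sample sizes must be nonnegative")
        if sum(self.seq_individuals.values()) < 2:
            raise ValueError("need at least 2 sequence samples in total")
        if sum(self.msat_individuals.values()) < 2:
            raise ValueError("need at least 2 genotyped individuals in total")

    @property
    def groups(self) -> list[str]:
        return list(self.seq_individuals)


def paper_sample_config() -> SampleConfig:
    """The study's sampling: mtDNA 19/70/37/27 (TMVB/SMO/SMS/CHIS, the TUX
    group is excluded from scenario analysis) and 126 genotyped individuals
    allocated proportionally (16/58/30/22)."""
    return SampleConfig(
        seq_individuals={"TMVB": 19, "SMO": 70, "SMS": 37, "CHIS": 27},
        msat_individuals={"TMVB": 16, "SMO": 58, "SMS": 30, "CHIS": 22},
    )


@dataclass
class LocusModel:
    """Mutation model for one locus.

    ``kind='sequence'``: HKY with ``length`` sites, transition/transversion
    ratio ``kappa`` and stationary ``base_freqs``; the per-site
    per-generation rate is supplied at simulation time (``mu``).

    ``kind='microsat'``: generalized stepwise model; each mutation moves the
    repeat count by ±G with ``P(G=g) = (1-p_gsm) p_gsm^(g-1)``; alleles are
    confined to ``[size_min, size_max]`` by reflection.
    """

    kind: str
    length: int = 1
    kappa: float = 4.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    size_min: int = 5
    size_max: int = 44  # 40 contiguous allelic states by default
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("sequence", "microsat"):
            raise ValueError(f"unknown locus kind {self.kind!r}")
        if self.kind == "sequence":
            if self.length < 1:
                raise ValueError("sequence length must be >= 1")
            if self.kappa <= 0:
                raise ValueError("kappa must be > 0")
            if abs(sum(self.base_freqs) - 1.0) > 1e-9:
                raise ValueError("base frequencies must sum to 1")
        else:
            if self.size_max <= self.size_min:
                raise ValueError("empty allele-size range")


def default_loci(seq_length: int = 751, n_msat: int = 8) -> list[LocusModel]:
    """One concatenated mtDNA sequence locus plus ``n_msat`` microsatellites."""
    loci = [LocusModel(kind="sequence", length=seq_length, name="mtDNA")]
    loci += [LocusModel(kind="microsat", name=f"msat{i + 1}") for i in range(n_msat)]
    return loci
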