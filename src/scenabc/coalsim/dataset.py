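"""Joint-marker dataset simulation: one shared mtDNA genealogy for the
concatenated sequence plus independent genealogies per microsatellite
locus, with diploid genotypes formed by pairing the two gene copies of each
individual."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..popdata import (
    MicrosatGenotypes,
    MultilocusDataset,
    PopulationMap,
    SequenceAlignment,
)
from ..sumstats.vector import summary_vector_arrays, summary_vector_names
from .mutate import mutate_microsat, mutate_sequence
from .scenarios import DemographicScenario, LocusModel, SampleConfig
from .simulate import simulate_genealogy

__all__ = ["SimulatedData", "simulate_dataset"]

CODE_TO_BASE = np.array(list("ACGT"))


@dataclass
class SimulatedData:
    """Raw arrays of one simulated dataset (fast path for reference tables)."""

    groups: list[str]
    seq: np.ndarray  # (n_seq, L) uint8, codes 0..3
    seq_groups: list[np.ndarray]  # row indices per group
    msat: np.ndarray  # (n_ind, n_loci, 2) int
    msat_groups: list[np.ndarray]

    def summary_vector(self) -> np.ndarray:
        return summary_vector_arrays(
            self.seq, self.seq_groups, self.msat, self.msat_groups, self.groups
        )

    def stat_names(self) -> list[str]:
        return summary_vector_names(self.groups)

    def to_dataset(self, localities_per_group: int = 1) -> MultilocusDataset:
        """Materialize as a validated :class:`MultilocusDataset`.

        Individuals are named ``<group>_<k>``; sequence-bearing individuals
        reuse the ids of genotyped ones where both markers are sampled.
        With ``localities_per_group > 1`` individuals are spread round-robin
        over that many localities inside each group (each group is
        panmictic, so localities are exchangeable).
        """
        ind2pop: dict[str, str] = {}
        pop2grp: dict[str, str] = {}

        def popname(group: str, i: int) -> str:
            loc = i % localities_per_group
            return f"{group}_loc{loc + 1}" if localities_per_group > 1 else group

        seq_ids: list[str] = []
        for gi, g in enumerate(self.groups):
            for k in range(len(self.seq_groups[gi])):
                name = f"{g}_{k + 1:03d}"
                seq_ids.append(name)
                pop = popname(g, k)
                ind2pop[name] = pop
                pop2grp[pop] = g
        msat_ids: list[str] = []
        for gi, g in enumerate(self.groups):
            for k in range(len(self.msat_groups[gi])):
                name = f"{g}_{k + 1:03d}"  # overlaps with sequence ids by design
                msat_ids.append(name)
                pop = popname(g, k)
                ind2pop[name] = pop
                pop2grp[pop] = g
        aln = SequenceAlignment(seq_ids, CODE_TO_BASE[self.seq])
        geno = MicrosatGenotypes(msat_ids, [f"msat{i+1}" for i in
                                            range(self.msat.shape[1])], self.msat)
        pmap = PopulationMap(ind2pop, pop2grp)
        return MultilocusDataset(popmap=pmap, alignment=aln, genotypes=geno)


def simulate_dataset(
    scenario: DemographicScenario,
    params: dict[str, float],
    config: SampleConfig,
    loci: list[LocusModel],
    rng: np.random.Generator | int | None = None,
    msat_rates: np.ndarray | None = None,
) -> SimulatedData:
    """Simulate one joint mtDNA + microsatellite dataset under a scenario.

    ``params`` must contain the scenario's demographic parameters plus
    ``mu_seq`` (per-site per-generation), ``mu_ms`` (per-locus mean rate)
    and ``gsm_p``.  ``msat_rates`` optionally fixes the per-locus
    microsatellite rates (otherwise all loci use ``mu_ms``).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sizes, events = scenario.instantiate(params)
    groups = [g for g in config.groups]

    seq_loci = [l for l in loci if l.kind == "sequence"]
    ms_loci = [l for l in loci if l.kind == "microsat"]
    if len(seq_loci) != 1:
        raise ValueError("exactly one concatenated sequence locus is expected")
    seq_locus = seq_loci[0]

    # mtDNA: one gene copy per sampled individual, one shared genealogy
    seq_samples = {g: config.seq_individuals[g] for g in groups
                   if config.seq_individuals.get(g, 0) > 0}
    tree = simulate_genealogy(sizes, events, seq_samples, "mtdna", rng)
    seq = mutate_sequence(tree, seq_locus, params["mu_seq"], rng)
    seq_groups = []
    offset = 0
    for g in groups:
        k = config.seq_individuals.get(g, 0)
        seq_groups.append(np.arange(offset, offset + k))
        offset += k

    # microsatellites: two copies per individual, independent genealogies
    msat_samples = {g: 2 * config.msat_individuals[g] for g in groups
                    if config.msat_individuals.get(g, 0) > 0}
    n_ind = sum(config.msat_individuals.get(g, 0) for g in groups)
    calls = np.empty((n_ind, len(ms_loci), 2), dtype=np.int64)
    if msat_rates is None:
        msat_rates = np.full(len(ms_loci), params["mu_ms"])
    for li, locus in enumerate(ms_loci):
        ltree = simulate_genealogy(sizes, events, msat_samples, "autosomal", rng)
        alleles = mutate_microsat(ltree, locus, float(msat_rates[li]),
                                  params["gsm_p"], rng)
        calls[:, li, 0] = alleles[0::2]
        calls[:, li, 1] = alleles[1::2]
    calls.sort(axis=2)
    msat_groups = []
    offset = 0
    for g in groups:
        k = config.msat_individuals.get(g, 0)
        msat_groups.append(np.arange(offset, offset + k))
        offset += k

    return SimulatedData(groups=groups, seq=seq, seq_groups=seq_groups,
                         msat=calls, msat_groups=msat_groups)
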