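"""Shared fixtures: small synthetic datasets and a reduced sample
configuration that keeps simulation-heavy tests fast."""

from __future__ import annotations

import numpy as np
import pytest

from scenabc.coalsim.priors import default_prior
from scenabc.coalsim.scenarios import LocusModel, SampleConfig, scenario_preset
from scenabc.popdata import (
    MicrosatGenotypes,
    MultilocusDataset,
    PopulationMap,
    SequenceAlignment,
)


@pytest.fixture(scope="session")
def small_config() -> SampleConfig:
    return SampleConfig(
        seq_individuals={"TMVB": 6, "SMO": 8, "SMS": 6, "CHIS": 6},
        msat_individuals={"TMVB": 5, "SMO": 6, "SMS": 5, "CHIS": 5},
    )


@pytest.fixture(scope="session")
def small_loci() -> list[LocusModel]:
    return [LocusModel(kind="sequence", length=300, name="mtDNA")] + [
        LocusModel(kind="microsat", name=f"ms{i}") for i in range(4)
    ]


@pytest.fixture(scope="session")
def scenarios():
    return [scenario_preset(s) for s in ("Sc1", "Sc2", "Sc3")]


@pytest.fixture(scope="session")
def prior():
    return default_prior()


@pytest.fixture()
def toy_alignment() -> SequenceAlignment:
    seqs = np.array([
        list("ACGTACGTAC"),
        list("ACGTACGTAC"),
        list("ACGAACGTAC"),
        list("ACGAACGTAC"),
    ])
    return SequenceAlignment(["i1", "i2", "i3", "i4"], seqs)


@pytest.fixture()
def toy_dataset() -> MultilocusDataset:
    """Two groups, two localities each, both markers present."""
    rng = np.random.default_rng(42)
    n = 12
    ids = [f"ind{i}" for i in range(n)]
    base = np.array(list("ACGT" * 5))
    seqs = np.tile(base, (n, 1)).astype("U1")
    # group B carries two fixed differences
    seqs[6:, 3] = "A"
    seqs[6:, 7] = "C"
    # sprinkle private variation
    seqs[1, 10] = "G"
    seqs[8, 11] = "T"
    aln = SequenceAlignment(ids, seqs)
    calls = rng.integers(10, 14, size=(n, 3, 2))
    calls[6:] += 3
    geno = MicrosatGenotypes(ids, ["L1", "L2", "L3"], calls)
    ind2pop = {f"ind{i}": ("a1" if i < 3 else "a2" if i < 6 else
                           "b1" if i < 9 else "b2") for i in range(n)}
    pop2grp = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    return MultilocusDataset(popmap=PopulationMap(ind2pop, pop2grp),
                             alignment=aln, genotypes=geno)
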