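"""Joint dataset simulation and reference-table construction."""

import numpy as np
import pytest

from scenabc.coalsim.dataset import simulate_dataset
from scenabc.coalsim.reftable import build_reference_table
from scenabc.coalsim.scenarios import scenario_preset
from scenabc.popdata import write_population_map


@pytest.fixture(scope="module")
def sc1_params():
    return {"N_TMVB": 800.0, "N_SMO": 1200.0, "N_SMS": 1000.0,
            "N_CHIS": 1000.0, "N5": 2000.0, "N6": 4000.0,
            "t1": 500.0, "t2": 3000.0, "t3": 20000.0,
            "mu_seq": 5e-8, "mu_ms": 2e-3, "gsm_p": 0.2}


def test_simulated_dataset_validates(small_config, small_loci, sc1_params,
                                     tmp_path):
    sim = simulate_dataset(scenario_preset("Sc1"), sc1_params, small_config,
                           small_loci, np.random.default_rng(0))
    ds = sim.to_dataset()
    # group sizes equal config
    counts = ds.popmap.group_counts(ds.alignment.ids)
    assert counts == small_config.seq_individuals
    mcounts = ds.popmap.group_counts(ds.genotypes.ids)
    assert mcounts == small_config.msat_individuals
    # passes assemble-style validation via a round trip of the map
    write_population_map(ds.popmap, tmp_path / "m.tsv")
    from scenabc.popdata import assemble_dataset

    ds2 = assemble_dataset(ds.alignment, ds.genotypes, tmp_path / "m.tsv")
    assert set(ds2.groups) == set(small_config.groups)


def test_summary_vector_width(small_config, small_loci, sc1_params):
    sim = simulate_dataset(scenario_preset("Sc1"), sc1_params, small_config,
                           small_loci, np.random.default_rng(1))
    assert sim.summary_vector().shape == (48,)


def test_panmixia_limit_phi_st_near_zero(small_config, small_loci):
    # huge sizes, tiny split times: groups are effectively one population
    params = {"N_TMVB": 1e6, "N_SMO": 1e6, "N_SMS": 1e6, "N_CHIS": 1e6,
              "N5": 1e6, "N6": 1e6, "t1": 1.0, "t2": 2.0, "t3": 3.0,
              "mu_seq": 5e-7, "mu_ms": 2e-3, "gsm_p": 0.2}
    from scenabc.sumstats.differentiation import n_st
    from scenabc.sumstats.distances import tn93_matrix

    rng = np.random.default_rng(2)
    vals = []
    for _ in range(40):
        sim = simulate_dataset(scenario_preset("Sc1"), params, small_config,
                               small_loci, rng)
        d = tn93_matrix(sim.seq)
        idx = np.concatenate([sim.seq_groups[0], sim.seq_groups[1]])
        vals.append(n_st(d[np.ix_(idx, idx)],
                         (len(sim.seq_groups[0]), len(sim.seq_groups[1]))))
    assert abs(np.nanmean(vals)) < 0.05


def test_mtdna_diversity_increases_with_n(small_config, small_loci):
    from scenabc.sumstats.distances import difference_matrix

    means = []
    rng = np.random.default_rng(3)
    for n in (1e3, 1e4, 1e5):
        params = {"N_TMVB": n, "N_SMO": n, "N_SMS": n, "N_CHIS": n,
                  "N5": n, "N6": n, "t1": 100.0, "t2": 200.0, "t3": 300.0,
                  "mu_seq": 2e-8, "mu_ms": 1e-3, "gsm_p": 0.2}
        kbars = []
        for _ in range(60):
            sim = simulate_dataset(scenario_preset("Sc1"), params,
                                   small_config, small_loci, rng)
            diffs, _ = difference_matrix(sim.seq)
            iu = np.triu_indices(sim.seq.shape[0], 1)
            kbars.append(diffs[iu].mean())
        means.append(np.mean(kbars))
    assert means[0] < means[1] < means[2]


class TestReferenceTable:
    def test_shape_and_columns(self, scenarios, prior, small_config,
                               small_loci):
        table = build_reference_table(scenarios, 20, prior, small_config,
                                      small_loci, rng_seed=5)
        assert len(table.data) == 60
        assert len(table.stat_names) == 48
        # width: scenario + 13 params + 48 stats
        assert table.data.shape[1] == 1 + 13 + 48
        assert table.data[table.stat_names].notna().all().all()

    def test_deterministic_under_seed(self, scenarios, prior, small_config,
                                      small_loci):
        t1 = build_reference_table(scenarios, 10, prior, small_config,
                                   small_loci, rng_seed=9)
        t2 = build_reference_table(scenarios, 10, prior, small_config,
                                   small_loci, rng_seed=9)
        assert t1.data.equals(t2.data)

    def test_checkpoint_resume_identical(self, scenarios, prior, small_config,
                                         small_loci, tmp_path):
        ck = tmp_path / "ck.csv"
        full = build_reference_table(scenarios, 8, prior, small_config,
                                     small_loci, rng_seed=3,
                                     checkpoint_path=ck, checkpoint_every=5)
        assert ck.exists()
        resumed = build_reference_table(scenarios, 8, prior, small_config,
                                        small_loci, rng_seed=3,
                                        checkpoint_path=ck)
        assert full.data.equals(resumed.data)

    def test_save_load_round_trip(self, scenarios, prior, small_config,
                                  small_loci, tmp_path):
        t = build_reference_table(scenarios[:2], 5, prior, small_config,
                                  small_loci, rng_seed=1)
        p = tmp_path / "ref.csv"
        t.save(p)
        from scenabc.coalsim.reftable import ReferenceTable

        t2 = ReferenceTable.load(p)
        assert t2.stat_names == t.stat_names
        np.testing.assert_allclose(t2.stats_matrix(), t.stats_matrix(),
                                   rtol=1e-12)

    def test_t3_marginal_matches_conditional_prior(self, scenarios, prior,
                                                   small_config, small_loci):
        # t3 | t1<t2<t3 is the max of three iid uniforms: CDF u^3
        from scipy.stats import kstest

        table = build_reference_table([scenarios[0]], 400, prior,
                                      small_config, small_loci, rng_seed=13)
        lo, hi = prior.ranges["t3"]
        u = (table.data["t3"].to_numpy() - lo) / (hi - lo)
        assert kstest(u, lambda x: x**3).pvalue > 0.01
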