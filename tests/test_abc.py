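import numpy as np
import pandas as pd
import pytest

from scenabc.abc import (
    estimate_parameters,
    model_check,
    model_choice,
    pods_error_rates,
    standardize_and_reject,
)
from scenabc.coalsim.reftable import PARAM_COLUMNS, ReferenceTable


def _gaussian_table(n_per=2000, k=3, p=6, shift=0.0, seed=0,
                    param_map=None) -> ReferenceTable:
    """Synthetic table: stats ~ N(scenario shift, 1)."""
    rng = np.random.default_rng(seed)
    rows = []
    stat_names = [f"s{i}" for i in range(p)]
    for s in range(k):
        stats = rng.normal(s * shift, 1.0, size=(n_per, p))
        for row in stats:
            rec = {"scenario": f"Sc{s + 1}"}
            rec.update({c: 0.0 for c in PARAM_COLUMNS})
            rec.update(dict(zip(stat_names, row)))
            rows.append(rec)
    df = pd.DataFrame(rows)
    return ReferenceTable(data=df, stat_names=stat_names,
                          param_names=PARAM_COLUMNS,
                          meta={"prior": {}})


class TestRejection:
    def test_delta_one_accepts_all(self):
        t = _gaussian_table(n_per=100, k=1)
        rej = standardize_and_reject(t.stats_matrix(), np.zeros(6), 1.0)
        assert len(rej.indices) == 100

    def test_observed_row_has_zero_distance(self):
        t = _gaussian_table(n_per=200, k=1)
        stats = t.stats_matrix()
        rej = standardize_and_reject(stats, stats[17], 0.05)
        assert rej.indices[0] == 17
        assert rej.distances[0] == 0.0
        assert rej.weights[0] == rej.weights.max()

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(1)
        stats = rng.normal(size=(500, 5))
        obs = rng.normal(size=5)
        rej = standardize_and_reject(stats, obs, 0.02)
        # independent oracle: same standardization, exhaustive argsort
        med = np.median(stats, axis=0)
        mad = np.median(np.abs(stats - med), axis=0)
        d = np.sqrt((((stats - obs) / mad) ** 2).sum(axis=1))
        expected = np.argsort(d, kind="stable")[:10]
        np.testing.assert_array_equal(np.sort(rej.indices), np.sort(expected))

    def test_constant_statistic_dropped(self):
        rng = np.random.default_rng(2)
        stats = rng.normal(size=(100, 3))
        stats[:, 1] = 7.0
        obs = np.array([0.0, 99.0, 0.0])
        rej = standardize_and_reject(stats, obs, 0.1)
        assert not rej.kept_stats[1]

    def test_bad_delta(self):
        t = _gaussian_table(n_per=10, k=1)
        with pytest.raises(ValueError):
            standardize_and_reject(t.stats_matrix(), np.zeros(6), 0.0)


class TestModelChoice:
    def test_identical_scenarios_near_uniform(self):
        t = _gaussian_table(n_per=4000, k=3, shift=0.0, seed=3)
        mc = model_choice(t, np.zeros(6), delta=0.1)
        for s in mc.scenarios:
            assert mc.direct[s] == pytest.approx(1 / 3, abs=0.05)
            assert mc.logistic[s] == pytest.approx(1 / 3, abs=0.05)

    def test_disjoint_clusters_certain(self):
        t = _gaussian_table(n_per=1000, k=3, shift=30.0, seed=4)
        mc = model_choice(t, np.zeros(6), delta=0.05)
        assert mc.best == "Sc1"
        assert mc.logistic["Sc1"] > 0.99

    def test_logistic_close_to_direct_when_separated(self):
        t = _gaussian_table(n_per=2000, k=2, shift=8.0, seed=5)
        mc = model_choice(t, np.full(6, 0.5), delta=0.05)
        assert abs(mc.logistic["Sc1"] - mc.direct["Sc1"]) < 0.05

    def test_posteriors_sum_to_one_with_cis(self):
        t = _gaussian_table(n_per=1500, k=3, shift=1.0, seed=6)
        mc = model_choice(t, np.full(6, 0.5), delta=0.1)
        assert sum(mc.logistic.values()) == pytest.approx(1.0, abs=1e-6)
        assert sum(mc.direct.values()) == pytest.approx(1.0, abs=1e-6)
        for s in mc.scenarios:
            lo, hi = mc.logistic_ci[s]
            assert 0.0 <= lo <= mc.logistic[s] <= hi <= 1.0

    def test_seeded_rerun_identical(self):
        t = _gaussian_table(n_per=1000, k=3, shift=0.5, seed=7)
        m1 = model_choice(t, np.zeros(6), delta=0.1, rng_seed=3)
        m2 = model_choice(t, np.zeros(6), delta=0.1, rng_seed=3)
        assert m1.logistic == m2.logistic

    def test_small_delta_does_not_crash(self):
        t = _gaussian_table(n_per=200, k=3, shift=0.5, seed=8)
        mc = model_choice(t, np.zeros(6), delta=0.005)  # 3 accepted rows
        assert sum(mc.logistic.values()) == pytest.approx(1.0, abs=1e-6)


def _regression_table(n=6000, seed=0, through="logit"):
    """One informative stat tied to parameter t3 (uniform on its prior)."""
    rng = np.random.default_rng(seed)
    lo, hi = 100.0, 50_000.0
    theta = rng.uniform(lo, hi, size=n)
    u = (theta - lo) / (hi - lo)
    if through == "logit":
        stat = np.log(u / (1 - u))
    else:
        stat = u
    noise = rng.normal(0, 1, size=(n, 2))
    rows = []
    for i in range(n):
        rec = {"scenario": "Sc1"}
        rec.update({c: 0.0 for c in PARAM_COLUMNS})
        rec["t3"] = theta[i]
        rec.update({"s0": stat[i], "s1": noise[i, 0], "s2": noise[i, 1]})
        rows.append(rec)
    return ReferenceTable(data=pd.DataFrame(rows),
                          stat_names=["s0", "s1", "s2"],
                          param_names=PARAM_COLUMNS,
                          meta={"prior": {"t3": [lo, hi]}})


class TestEstimation:
    def test_noiseless_logit_identity_collapses(self):
        t = _regression_table(through="logit")
        lo, hi = 100.0, 50_000.0
        target = 20_000.0
        u = (target - lo) / (hi - lo)
        obs = np.array([np.log(u / (1 - u)), 0.0, 0.0])
        post = estimate_parameters(t, obs, delta=0.05, parameters=["t3"])
        sample = post.samples["t3"]
        assert np.abs(sample - target).max() < 1e-6 * (hi - lo)

    def test_noiseless_linear_identity_approx(self):
        t = _regression_table(through="linear")
        lo, hi = 100.0, 50_000.0
        target = 20_000.0
        obs = np.array([(target - lo) / (hi - lo), 0.0, 0.0])
        post = estimate_parameters(t, obs, delta=0.05, parameters=["t3"])
        assert post.summaries["t3"]["median"] == pytest.approx(target,
                                                               rel=0.02)

    def test_adjusted_within_prior_bounds(self):
        for seed in range(10):
            t = _regression_table(n=2000, seed=seed)
            rng = np.random.default_rng(seed + 100)
            obs = np.array([rng.normal(), 0.0, 0.0])
            post = estimate_parameters(t, obs, delta=0.2, parameters=["t3"])
            s = post.samples["t3"]
            assert (s >= 100.0).all() and (s <= 50_000.0).all()

    def test_quantiles_ordered(self):
        t = _regression_table()
        post = estimate_parameters(t, np.array([0.0, 0.0, 0.0]), delta=0.1,
                                   parameters=["t3"])
        q = post.summaries["t3"]
        assert q["q025"] <= q["q050"] <= q["median"] <= q["q950"] <= q["q975"]

    def test_too_few_accepted_raises(self):
        t = _regression_table(n=300)
        with pytest.raises(ValueError, match="accepted"):
            estimate_parameters(t, np.zeros(3), delta=0.01, parameters=["t3"])


class TestPods:
    def test_identical_scenarios_type_one_two_thirds(
            self, prior, small_config, small_loci, scenarios):
        # three structurally identical scenarios: selection is random
        from scenabc.coalsim.reftable import build_reference_table
        from scenabc.coalsim.scenarios import scenario_preset
        import copy

        clones = []
        for name in ("Sc1", "Sc2", "Sc3"):
            s = scenario_preset("Sc1")
            s.name = name
            clones.append(s)
        table = build_reference_table(clones, 300, prior, small_config,
                                      small_loci, rng_seed=17)
        errors = pods_error_rates(clones, prior, small_config, small_loci,
                                  n_pods=60, table=table, delta=0.1,
                                  rng_seed=5)
        assert errors.type_i == pytest.approx(2 / 3, abs=0.12)
        assert 0.0 <= errors.type_ii <= 1.0
        # confusion matrix row sums equal POD counts
        for s in errors.n_pods:
            assert sum(errors.confusion[s].values()) == errors.n_pods[s]


class TestModelCheck:
    def test_report_shapes_and_tails(self, prior, small_config, small_loci,
                                     scenarios):
        from scenabc.abc import ParameterPosterior
        from scenabc.coalsim.reftable import build_reference_table

        table = build_reference_table(scenarios[:1], 150, prior, small_config,
                                      small_loci, rng_seed=23)
        obs = table.stats_matrix()[0]
        n_draw = 50
        params = {p: np.full(n_draw, table.data[p].iloc[0]) for p in
                  ("N_TMVB", "N_SMO", "N_SMS", "N_CHIS", "N5", "N6",
                   "t1", "t2", "t3", "mu_seq", "mu_ms", "gsm_p")}
        post = ParameterPosterior(
            parameters=list(params), prior_ranges={},
            samples=params, weights=np.ones(n_draw), summaries={},
        )
        report = model_check(table, post, obs, scenarios[0], small_config,
                             small_loci, n_pp=120, rng_seed=0)
        assert report.posterior_coords.shape == (120, 2)
        assert report.observed_coords.shape == (2,)
        assert all(0.0 <= v <= 1.0 for v in report.tail_probabilities.values())
        # observed comes from the prior cloud: projection inside its bounding box
        lo = report.prior_coords.min(axis=0)
        hi = report.prior_coords.max(axis=0)
        assert (report.observed_coords >= lo - 1e-9).all()
        assert (report.observed_coords <= hi + 1e-9).all()
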