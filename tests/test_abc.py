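"""Summary statistics, reference tables, model choice and estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, optimize

from msatabc import abc as ab
from msatabc import demography as dg
from msatabc import differentiation as df
from msatabc import diversity as dv

from conftest import make_dataset

SS = [6, 3, 3, 3, 3]


@pytest.fixture(scope="module")
def small_table():
    return ab.build_reference_table(
        list(dg.SCENARIO_KINDS), n_per_scenario=300, seed=99, sample_sizes=SS
    )


class TestSummaryVector:
    def test_monomorphic_dataset(self):
        genos = {p: [[(20, 20)], [(20, 20)]] for p in "ABCDE"}
        v = ab.summary_vector(make_dataset(genos))
        names = ab.summary_stat_names(5)
        s = pd.Series(v, index=names)
        assert (s.filter(like="nal_") == 1).all()
        assert (s.filter(like="het_") == 0).all()
        assert (s.filter(like="vsz_") == 0).all()
        assert (s.filter(like="dmu2_") == 0).all()

    def test_individual_order_invariance(self, rng):
        genos = {
            p: [[tuple(int(2 * x) for x in rng.integers(10, 15, 2))]
                for _ in range(6)]
            for p in "AB"
        }
        ds = make_dataset(genos)
        v1 = ab.summary_vector(ds, deme_order=["A", "B"])
        ds.records = ds.records[::-1]
        v2 = ab.summary_vector(ds, deme_order=["A", "B"])
        assert np.allclose(v1, v2)

    def test_cross_module_consistency(self, rng):
        """Each vector entry equals the corresponding dedicated operation."""
        genos = {
            p: [
                [tuple(int(2 * x) for x in rng.integers(10 + k, 16 + k, 2))
                 for k in range(3)]
                for _ in range(8)
            ]
            for p in ("A", "B")
        }
        ds = make_dataset(genos)
        v = pd.Series(ab.summary_vector(ds), index=ab.summary_stat_names(2))
        _, he_a = dv.expected_heterozygosity(ds, "A")
        assert v["het_0"] == pytest.approx(he_a)
        _, he_b = dv.expected_heterozygosity(ds, "B")
        assert v["het_1"] == pytest.approx(he_b)
        arr = ds.allele_array()
        pops = np.array([r.population_id for r in ds.records])
        nal_a = np.mean([
            len(np.unique(arr[pops == "A", j])) for j in range(3)
        ])
        assert v["nal_0"] == pytest.approx(nal_a)
        assert v["fst_0_1"] == pytest.approx(df.wc_fst(ds).global_value)
        assert v["dmu2_0_1"] == pytest.approx(df.delta_mu2(ds, ("A", "B"))[1])

    def test_holdout_matches_garza_and_das(self, rng):
        genos = {
            p: [[tuple(int(2 * x) for x in rng.integers(10, 16, 2))]
                for _ in range(6)]
            for p in ("A", "B")
        }
        ds = make_dataset(genos)
        sizes = ds.repeat_array().astype(np.int64)
        pops = ds.population_codes()
        h = pd.Series(ab.holdout_stats(sizes, pops, 2), index=ab.holdout_stat_names(2))
        assert h["gwm_0"] == pytest.approx(df.garza_m(ds, "A")[1])
        assert h["das_0_1"] == pytest.approx(
            df.shared_allele_distance(ds, ("A", "B"))
        )


class TestReferenceTable:
    def test_row_counts(self, small_table):
        assert small_table.n_rows == 4 * 300
        for i in range(4):
            assert len(small_table.rows_of(i)) == 300

    def test_determinism(self):
        a = ab.build_reference_table(
            ["simultaneous_divergence"], n_per_scenario=30, seed=5, sample_sizes=SS
        )
        b = ab.build_reference_table(
            ["simultaneous_divergence"], n_per_scenario=30, seed=5, sample_sizes=SS
        )
        assert np.array_equal(a.stats, b.stats)
        assert a.params[0].equals(b.params[0])

    def test_point_prior_matches_direct_simulation(self, rng):
        """Summary means under a point prior equal direct repeated simulation."""
        point = {k: (v, v) for k, v in {
            "N1": 1000.0, "N2": 200.0, "N3": 200.0, "N4": 200.0, "N5": 200.0,
            "N_div": 800.0, "N_anc": 5000.0, "t_div1": 100.0, "t_anc": 2000.0,
            "founder_N": 10.0, "duration": 10.0,
        }.items()}
        spec = dg.PriorSpec(point)
        table = ab.build_reference_table(
            ["simultaneous_divergence"], {"simultaneous_divergence": spec},
            n_per_scenario=150, seed=3, sample_sizes=SS,
            mutation_prior=dg.MutationPrior(rate_lo=5e-4, rate_hi=5e-4),
        )
        scen = dg.build_scenario(
            "simultaneous_divergence", {k: v[0] for k, v in point.items()}, SS
        )
        mp = dg.MutationPrior(rate_lo=5e-4, rate_hi=5e-4)
        direct = np.array([
            ab.summary_stats(
                *dg.simulate_repeat_matrix(scen, mp.draw(rng),
                                           int(rng.integers(0, 2 ** 31 - 1))),
                5,
            )
            for _ in range(150)
        ])
        het_cols = slice(5, 10)
        se = direct[:, het_cols].std(0).mean() / np.sqrt(150)
        assert np.allclose(
            table.stats[:, het_cols].mean(0), direct[:, het_cols].mean(0),
            atol=6 * se + 0.02,
        )

    def test_csv_roundtrip_columns(self, small_table, tmp_path):
        out = tmp_path / "rt.csv"
        small_table.to_csv(out, tmp_path / "prov.json")
        back = pd.read_csv(out)
        assert list(back.columns) == ["scenario"] + small_table.stat_names
        assert len(back) == small_table.n_rows


class TestModelChoice:
    def test_separated_scenario_wins(self, small_table):
        """An observed vector inside one scenario's cloud gets high posterior."""
        i = small_table.scenario_names.index("ancient_divergence")
        rows = small_table.rows_of(i)
        obs = small_table.stats[rows[7]]
        res = ab.model_choice_logistic(small_table, obs, tolerance=0.05)
        assert res.posterior.sum() == pytest.approx(1.0, abs=1e-6)
        assert res.posterior[i] == res.posterior.max()

    def test_identical_scenarios_symmetric(self):
        a = ab.build_reference_table(
            ["simultaneous_divergence"], n_per_scenario=250, seed=21, sample_sizes=SS
        )
        b = ab.build_reference_table(
            ["simultaneous_divergence"], n_per_scenario=250, seed=22, sample_sizes=SS
        )
        table = ab.ReferenceTable(
            ["s1", "s2"],
            np.concatenate([np.zeros(250, int), np.ones(250, int)]),
            np.vstack([a.stats, b.stats]),
            [a.params[0], b.params[0]],
            a.stat_names,
        )
        obs = np.median(table.stats, axis=0)
        res = ab.model_choice_logistic(table, obs, tolerance=0.2)
        assert res.posterior[0] == pytest.approx(0.5, abs=0.15)

    def test_rejection_and_logistic_agree_when_separated(self, small_table):
        i = small_table.scenario_names.index("stepping_stone")
        obs = small_table.stats[small_table.rows_of(i)[3]]
        log = ab.model_choice_logistic(small_table, obs, tolerance=0.05)
        med, mad = ab._standardize(small_table.stats)
        d = np.linalg.norm((small_table.stats - med) / mad
                           - (obs - med) / mad, axis=1)
        keep = np.argsort(d)[:log.n_retained]
        counts = np.bincount(small_table.scenario_idx[keep], minlength=4)
        rej = counts / counts.sum()
        assert np.abs(log.posterior - rej).max() < 0.25

    def test_duplicating_rows_invariant(self, small_table):
        obs = small_table.stats[3]
        doubled = small_table.concat(small_table)
        p1 = ab.model_choice_logistic(small_table, obs, tolerance=0.05).posterior
        p2 = ab.model_choice_logistic(doubled, obs, tolerance=0.05).posterior
        assert np.abs(p1 - p2).max() < 0.1


class TestEstimateParameters:
    def test_keep_all_recovers_prior(self):
        """tolerance = 1 with flat weights: the posterior is the prior."""
        table = ab.build_reference_table(
            ["simultaneous_divergence"], n_per_scenario=800, seed=13, sample_sizes=SS
        )
        obs = np.median(table.stats, axis=0)
        est = ab.estimate_parameters(
            table, obs, "simultaneous_divergence", tolerance=1.0
        )
        spec = dg.default_prior_spec("simultaneous_divergence")
        # unconditioned parameters: posterior median near the prior midpoint
        for name in ("N1", "N2", "N_div"):
            lo, hi = spec.bounds[name]
            k = est.names.index(name)
            # regression adjustment at tolerance 1 is weak; allow a wide band
            assert lo + 0.2 * (hi - lo) < est.median[k] < lo + 0.8 * (hi - lo)

    def test_adjusted_draws_respect_prior_bounds(self, small_table):
        obs = small_table.stats[small_table.rows_of(0)[0]]
        est = ab.estimate_parameters(small_table, obs, "stepping_stone", 0.05)
        spec = dg.default_prior_spec("stepping_stone")
        for name in est.names:
            lo, hi = spec.bounds[name]
            col = est.posterior_sample[name]
            assert (col >= lo).all() and (col <= hi).all()
            k = est.names.index(name)
            assert est.ci_low[k] <= est.median[k] <= est.ci_high[k]


class TestValidation:
    def test_rmae_trivial_cases(self):
        truths = pd.DataFrame({"a": [1.0, 2.0, 4.0]})
        assert ab.rmae(truths, truths)["a"] == 0.0
        assert ab.rmae(truths, 2 * truths)["a"] == 1.0

    def test_rmae_prior_median_estimator(self, rng):
        """Estimator = prior median m of U(a,b): RMAE matches the numerically
        integrated median of |m - x| / x."""
        a, b = 2.0, 10.0
        m = (a + b) / 2
        x = rng.uniform(a, b, size=40_000)
        est = np.full_like(x, m)
        observed = ab.rmae(pd.DataFrame({"p": x}), pd.DataFrame({"p": est}))["p"]

        def cdf(t):
            # P(|m - x| / x <= t) for x ~ U(a, b)
            lo = m / (1 + t)
            hi = m / (1 - t) if t < 1 else b
            return (min(b, hi) - max(a, lo)) / (b - a)

        exact = optimize.brentq(lambda t: cdf(t) - 0.5, 1e-9, 1.5)
        assert observed == pytest.approx(exact, abs=0.02)

    def test_confidence_identical_scenarios(self):
        """Indistinguishable scenarios: type I near 1 - 1/K."""
        a = ab.build_reference_table(
            ["simultaneous_divergence"], n_per_scenario=200, seed=31, sample_sizes=SS
        )
        b = ab.build_reference_table(
            ["simultaneous_divergence"], n_per_scenario=200, seed=32, sample_sizes=SS
        )
        table = ab.ReferenceTable(
            ["simultaneous_divergence", "simultaneous_divergence_b"],
            np.concatenate([np.zeros(200, int), np.ones(200, int)]),
            np.vstack([a.stats, b.stats]),
            [a.params[0], b.params[0]],
            a.stat_names,
        )
        # focal scenario can only win half the time on average
        with pytest.warns(UserWarning):
            rates = ab.confidence_evaluation(
                table, "simultaneous_divergence", n_pseudo=16, seed=8,
                tolerance=0.2, sample_sizes=SS,
                prior_specs={
                    "simultaneous_divergence_b":
                        dg.default_prior_spec("simultaneous_divergence"),
                },
                scenario_kinds={
                    "simultaneous_divergence_b": "simultaneous_divergence"
                },
            )
        assert 0.1 <= rates["type_I"] <= 0.9
        assert 0.0 <= rates["type_II"] <= 1.0

    def test_model_check_probabilities_in_range(self, small_table):
        obs_row = small_table.rows_of(2)[0]
        est = ab.estimate_parameters(
            small_table, small_table.stats[obs_row],
            "simultaneous_divergence", 0.1,
        )
        scen = dg.build_scenario(
            "simultaneous_divergence",
            {k: float(est.posterior_sample[k].iloc[0]) for k in est.names}, SS,
        )
        sizes, pops = dg.simulate_repeat_matrix(scen, dg.MutationModel.uniform(), 77)
        hold = ab.holdout_stats(sizes, pops, 5)
        p = ab.model_check(est, "simultaneous_divergence", hold, n=60, seed=6,
                           sample_sizes=SS)
        assert ((p >= 0) & (p <= 1)).all()
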