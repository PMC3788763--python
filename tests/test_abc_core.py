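"""Reference tables, rejection, model choice, regression adjustment, checking."""

import numpy as np
import pandas as pd
import pytest

import coalabc as ca
from coalabc.abc_core import _fit_multinomial_logit
from coalabc.scenarios import ConstraintSet, PriorSet, ScenarioSpec
from coalabc.synthetic import SC1_TRUTH


@pytest.fixture(scope="module")
def tiny_table(divergence_specs, small_config):
    """Small two-scenario table for structural tests."""
    return ca.build_reference_table(divergence_specs[:2], 150, small_config, seed=99)


@pytest.fixture(scope="module")
def observed_sc1(small_template):
    aln, _ = ca.generate_pseudo_observed(
        "Sc1", params=SC1_TRUTH, template=small_template, seed=31_337
    )
    return ca.summary_vector(aln)


class TestReferenceTable:
    def test_counts_and_columns(self, tiny_table):
        assert len(tiny_table) == 300
        counts = tiny_table.scenario_counts()
        assert counts["Sc1"] == 150 and counts["Sc2"] == 150
        assert list(tiny_table.stat_names) == list(ca.SUMMARY_STAT_NAMES)
        # Sc1 rows have no Sc2-only parameters
        sc1_rows = tiny_table.data[tiny_table.data.scenario == "Sc1"]
        assert sc1_rows["t_expNAG"].isna().all()
        assert sc1_rows["t_exp"].notna().all()

    def test_same_seed_identical(self, divergence_specs, small_config):
        t1 = ca.build_reference_table(divergence_specs[:1], 20, small_config, seed=5)
        t2 = ca.build_reference_table(divergence_specs[:1], 20, small_config, seed=5)
        pd.testing.assert_frame_equal(t1.data, t2.data)

    def test_csv_roundtrip(self, tiny_table, tmp_path):
        path = tmp_path / "table.csv"
        tiny_table.to_csv(path)
        back = ca.ReferenceTable.from_csv(path)
        assert back.provenance["seed"] == tiny_table.provenance["seed"]
        pd.testing.assert_frame_equal(back.data, tiny_table.data, check_exact=False, rtol=1e-12)

    def test_append_extends(self, divergence_specs, small_config):
        t1 = ca.build_reference_table(divergence_specs[:1], 10, small_config, seed=5)
        t2 = ca.build_reference_table(divergence_specs[1:2], 10, small_config, seed=5)
        both = t1.append(t2)
        assert len(both) == 20 and set(both.scenarios) == {"Sc1", "Sc2"}

    def test_restrict(self, tiny_table):
        sub = tiny_table.restrict("Sc2")
        assert set(sub.data.scenario) == {"Sc2"} and len(sub) == 150
        with pytest.raises(ValueError):
            tiny_table.restrict("Sc9")

    def test_point_prior_marginal_matches_direct_oracle(self, small_config):
        """Segregating sites under a point-mass prior match a direct
        simulation bypassing the table machinery."""
        base = ca.build_scenario("Sc1")
        point = dict(SC1_TRUTH)
        priors = PriorSet({k: (v, v * (1 + 1e-9)) for k, v in point.items()})
        spec = ScenarioSpec(
            id="Sc1pt", populations=base.populations,
            initial_sizes=base.initial_sizes, events=base.events,
            priors=priors, constraints=ConstraintSet(),
        )
        table = ca.build_reference_table([spec], 150, small_config, seed=17)
        got = table.data["segsites_SAG"].to_numpy()

        # oracle: same generative steps, independent seeds
        rng = np.random.default_rng(987)
        direct = []
        st = ca.SubstitutionSettings()
        for _ in range(150):
            g = ca.simulate_genealogy(spec, point, small_config, rng, check_draw=False)
            aln = ca.evolve_alignment(g, small_config.locus_length, st, rng, mu=point["Mu"])
            direct.append(ca.segregating_sites(aln, "SAG"))
        direct = np.array(direct, dtype=float)
        se = np.sqrt(got.var(ddof=1) / len(got) + direct.var(ddof=1) / len(direct))
        assert abs(got.mean() - direct.mean()) < 3 * se


class TestRejection:
    def test_fraction_one_keeps_everything(self, tiny_table, observed_sc1):
        sel = ca.rejection_select(observed_sc1, tiny_table, 1.0)
        assert len(sel) == len(tiny_table)

    def test_exact_record_has_distance_zero(self, tiny_table):
        row = tiny_table.stat_matrix()[42]
        sel = ca.rejection_select(row, tiny_table, 0.01)
        assert sel.distances[0] == 0.0
        assert 42 in sel.indices

    def test_matches_full_sort_oracle(self, tiny_table, observed_sc1):
        sel = ca.rejection_select(observed_sc1, tiny_table, 0.1)
        sd = tiny_table.stat_matrix().std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        z = (tiny_table.stat_matrix() - observed_sc1) / sd
        dist = np.sqrt((z**2).sum(axis=1))
        oracle = np.argsort(dist, kind="stable")[: len(sel)]
        assert np.array_equal(np.sort(sel.indices), np.sort(oracle))

    def test_bad_fraction(self, tiny_table, observed_sc1):
        for f in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                ca.rejection_select(observed_sc1, tiny_table, f)


class TestModelChoice:
    def test_single_scenario_degenerate(self, divergence_specs, small_config, observed_sc1):
        table = ca.build_reference_table(divergence_specs[:1], 60, small_config, seed=2)
        sel = ca.rejection_select(observed_sc1, table, 0.5)
        res = ca.model_choice(sel, observed_sc1, table)
        assert res.probabilities[res.scenarios.index("Sc1")] == 1.0

    def test_probabilities_sum_to_one_cis_contain_estimates(
        self, tiny_table, observed_sc1
    ):
        sel = ca.rejection_select(observed_sc1, tiny_table, 0.3)
        res = ca.model_choice(sel, observed_sc1, tiny_table)
        assert res.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        for p, (lo, hi) in zip(res.probabilities, res.conf_int):
            assert lo - 1e-12 <= p <= hi + 1e-12
            assert 0.0 <= lo <= hi <= 1.0

    def test_matches_statsmodels_mnlogit(self):
        """Dual-route check of the in-house multinomial logit fit."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(14)
        n, p, k = 600, 3, 3
        x = rng.normal(size=(n, p))
        beta = rng.normal(scale=0.8, size=(k - 1, p + 1))
        eta = np.hstack([np.zeros((n, 1)), np.column_stack([np.ones(n), x]) @ beta.T])
        prob = np.exp(eta) / np.exp(eta).sum(axis=1, keepdims=True)
        y = np.array([rng.choice(k, p=pr) for pr in prob])

        theta, cov = _fit_multinomial_logit(x, y, k, ridge=1e-8)
        fit = sm.MNLogit(y, np.column_stack([np.ones(n), x])).fit(disp=0)
        assert np.allclose(theta.T, fit.params, atol=1e-4)
        # intercept variances drive the probability CIs; compare those
        sm_cov = np.asarray(fit.cov_params())
        d = p + 1
        ours = [cov[a * d, a * d] for a in range(k - 1)]
        theirs = [sm_cov[a * d, a * d] for a in range(k - 1)]
        assert np.allclose(ours, theirs, rtol=1e-3)

    def test_duplication_invariance(self, tiny_table, observed_sc1):
        """Duplicating every reference record leaves probabilities unchanged
        (up to the CI shrink from the doubled pseudo-sample)."""
        sel = ca.rejection_select(observed_sc1, tiny_table, 0.3)
        res = ca.model_choice(sel, observed_sc1, tiny_table)
        doubled = ca.ReferenceTable(
            pd.concat([tiny_table.data, tiny_table.data], ignore_index=True),
            tiny_table.stat_names,
        )
        sel2 = ca.rejection_select(observed_sc1, doubled, 0.3)
        res2 = ca.model_choice(sel2, observed_sc1, doubled)
        assert np.allclose(res.probabilities, res2.probabilities, atol=1e-6)

    def test_complete_separation_stays_finite(self):
        """Perfectly separable classes: the ridge keeps estimates finite and
        probabilities well-defined."""
        x = np.vstack([np.full((20, 2), -2.0), np.full((20, 2), 2.0)])
        y = np.array([0] * 20 + [1] * 20)
        theta, cov = _fit_multinomial_logit(x, y, 2, ridge=1e-6)
        assert np.all(np.isfinite(theta)) and np.all(np.isfinite(cov))


class TestEstimateParameters:
    def test_adjusted_within_prior_bounds(self, tiny_table, observed_sc1, sc1):
        sub = tiny_table.restrict("Sc1")
        sel = ca.rejection_select(observed_sc1, sub, 0.5)
        post = ca.estimate_parameters(sel, observed_sc1, sc1, sub)
        for p in post.parameters:
            lo, hi = sc1.priors.bounds(p)
            assert post.adjusted[p].between(lo, hi).all()
        assert np.all(post.weights >= 0)
        s = post.summaries
        assert (s["q025"] <= s["median"]).all() and (s["median"] <= s["q975"]).all()

    def test_zero_distance_orthogonal_stats_no_adjustment(self, sc1):
        """If every retained record sits at the observed point the local
        regression has nothing to explain: adjusted == raw."""
        rng = np.random.default_rng(15)
        n = 80
        draws = [ca.sample_prior_draw(sc1, rng) for _ in range(n)]
        stats = np.tile(np.arange(12, dtype=float), (n, 1))  # all identical
        rows = []
        for d in draws:
            rows.append({"scenario": "Sc1", **d,
                         **dict(zip(ca.SUMMARY_STAT_NAMES, stats[0]))})
        table = ca.ReferenceTable(pd.DataFrame(rows))
        sel = ca.rejection_select(stats[0], table, 1.0)
        post = ca.estimate_parameters(sel, stats[0], sc1, table)
        for p in post.parameters:
            assert np.allclose(post.adjusted[p], post.raw[p], rtol=1e-6)

    def test_mixed_scenarios_rejected(self, tiny_table, observed_sc1, sc1):
        sel = ca.rejection_select(observed_sc1, tiny_table, 0.5)
        with pytest.raises(ValueError, match="restrict"):
            ca.estimate_parameters(sel, observed_sc1, sc1, tiny_table)

    def test_fraction_one_unadjusted_posterior_equals_prior(self, sc1):
        """With fraction 1 and flat statistics, the weighted sample is the
        constrained prior (KS agreement on t_3)."""
        from scipy.stats import ks_2samp

        rng = np.random.default_rng(16)
        n = 2000
        draws = [ca.sample_prior_draw(sc1, rng) for _ in range(n)]
        const = dict(zip(ca.SUMMARY_STAT_NAMES, np.zeros(12)))
        table = ca.ReferenceTable(
            pd.DataFrame([{"scenario": "Sc1", **d, **const} for d in draws])
        )
        obs = np.zeros(12)
        sel = ca.rejection_select(obs, table, 1.0)
        post = ca.estimate_parameters(sel, obs, sc1, table)
        fresh = np.array(
            [ca.sample_prior_draw(sc1, rng)["t_3"] for _ in range(n)]
        )
        # distances are all zero -> uniform weights, no regression signal
        assert ks_2samp(post.adjusted["t_3"].to_numpy(), fresh).pvalue > 1e-3


@pytest.fixture(scope="module")
def posterior(tiny_table, observed_sc1, sc1):
    sub = tiny_table.restrict("Sc1")
    sel = ca.rejection_select(observed_sc1, sub, 0.3)
    return ca.estimate_parameters(sel, observed_sc1, sc1, sub)


class TestModelCheck:
    def test_report_covers_all_statistics(
        self, sc1, posterior, observed_sc1, small_config
    ):
        rep = ca.model_check(sc1, posterior, observed_sc1, small_config, n_pod=15, seed=4)
        assert len(rep.table) == 12
        assert rep.table["tail_prob"].between(0, 1).all()
        assert rep.table["p_two_sided"].between(0, 1).all()

    def test_single_pod_tail_values(self, sc1, posterior, observed_sc1, small_config):
        rep = ca.model_check(sc1, posterior, observed_sc1, small_config, n_pod=1, seed=5)
        assert set(rep.table["tail_prob"]).issubset({0.0, 0.5, 1.0})

    def test_n_pod_validation(self, sc1, posterior, observed_sc1, small_config):
        with pytest.raises(ValueError):
            ca.model_check(sc1, posterior, observed_sc1, small_config, n_pod=0, seed=1)


def test_end_to_end_determinism_library(divergence_specs, small_config, observed_sc1):
    """Identical seeds: identical tables, choices and posteriors."""
    runs = []
    for _ in range(2):
        table = ca.build_reference_table(divergence_specs[:3], 80, small_config, seed=7)
        sel = ca.rejection_select(observed_sc1, table, 0.2)
        mc = ca.model_choice(sel, observed_sc1, table)
        sub = table.restrict("Sc1")
        sel1 = ca.rejection_select(observed_sc1, sub, 0.5)
        post = ca.estimate_parameters(sel1, observed_sc1, ca.build_scenario("Sc1"), sub)
        runs.append((mc, post))
    a, b = runs
    assert np.array_equal(a[0].probabilities, b[0].probabilities)
    pd.testing.assert_frame_equal(a[1].adjusted, b[1].adjusted)
    pd.testing.assert_frame_equal(a[1].summaries, b[1].summaries)
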