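import math

import numpy as np
import pytest
from scipy import stats

from landgen.ibr_model import (
    IBRConfig,
    build_covariance,
    effect_summary,
    gelman_rubin,
    log_posterior,
    marginal_loglik_single,
    metropolis_rw,
    prepare_covariates,
    run_chain,
)
from landgen.popgen import AlleleCountTable
from landgen.resistance import PairwiseMatrix

from _oracles import quad_marginal_oracle


def pm(values, label="distance", standardized=True):
    values = np.asarray(values, float)
    ids = [f"S{i}" for i in range(values.shape[0])]
    return PairwiseMatrix(ids, values, label, standardized=standardized)


def toy_matrices(n=4, seed=0):
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0, 10, size=(n, 2))
    D = np.hypot(*(xy[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
    E = D + rng.uniform(0.1, 1.0, size=D.shape)
    E = 0.5 * (E + E.T)
    np.fill_diagonal(E, 0)
    return pm(D), pm(E, label="resistance:2012")


class TestBuildCovariance:
    def test_zero_effects_give_constant_matrix(self):
        D, E = toy_matrices()
        om = build_covariance(D, [E], alpha0=4.0, alphaD=0.0, alphaE=[0.0])
        assert np.allclose(om, 0.25)

    def test_log_two_closed_form(self):
        D = pm([[0.0, 1.0], [1.0, 0.0]])
        om = build_covariance(D, [], alpha0=1.0, alphaD=math.log(2.0), alphaE=[])
        assert om[0, 1] == pytest.approx(0.5)
        assert om[0, 0] == pytest.approx(1.0)

    def test_offdiagonals_decrease_in_each_effect(self):
        D, E = toy_matrices()
        prev = build_covariance(D, [E], 2.0, 0.1, [0.1])
        for aE in (0.2, 0.5, 1.0):
            cur = build_covariance(D, [E], 2.0, 0.1, [aE])
            off = ~np.eye(4, dtype=bool)
            assert (cur[off] <= prev[off] + 1e-15).all()
            prev = cur
        for aD in (0.2, 0.5):
            cur = build_covariance(D, [E], 2.0, aD, [0.1])
            assert (cur[off] <= build_covariance(D, [E], 2.0, 0.1, [0.1])[off] + 1e-15).all()

    def test_nonfinite_input_rejected(self):
        D, E = toy_matrices()
        bad = D.values.copy()
        bad[0, 1] = bad[1, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            build_covariance(pm(bad), [E], 1.0, 0.1, [0.1])


class TestPrepareCovariates:
    def test_infinite_entries_replaced_and_warned(self, caplog):
        vals = np.array([[0.0, 2.0, np.inf], [2.0, 0.0, 4.0], [np.inf, 4.0, 0.0]])
        E = pm(vals, label="resistance:1860", standardized=False)
        D = pm(np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.5], [2.0, 1.5, 0.0]]),
               standardized=False)
        with caplog.at_level("WARNING"):
            _, (Ep,) = prepare_covariates(D, [E])
        assert np.isfinite(Ep.values).all()
        assert any("infinite" in r.message for r in caplog.records)

    def test_collinear_resistance_warns(self, caplog):
        D, _ = toy_matrices()
        E = pm(D.values * 3.0, label="resistance:2012")
        with caplog.at_level("WARNING"):
            prepare_covariates(D, [E])
        assert any("collinear" in r.message for r in caplog.records)


class TestLogPosterior:
    def make_counts(self, alt, m):
        alt = np.atleast_2d(alt)
        return AlleleCountTable(
            populations=[f"P{i}" for i in range(alt.shape[0])],
            locus_ids=[f"L{j}" for j in range(alt.shape[1])],
            alt_count=alt,
            allele_number=np.atleast_2d(m),
        )

    def test_extreme_counts_disfavoured_by_diffuse_dispersion(self):
        # 2 pops, 1 locus with extreme counts: tight dispersion around a
        # mid latent frequency fits worse than a diffuse one
        counts = self.make_counts([[24], [0]], [[24], [24]])
        om = np.array([[0.5, 0.1], [0.1, 0.5]])
        theta = np.array([[0.5], [0.5]])
        mu = np.array([0.5])
        tight = log_posterior(counts, om, theta, mu, np.array([500.0, 500.0]))
        diffuse = log_posterior(counts, om, theta, mu, np.array([2.0, 2.0]))
        assert diffuse > tight

    def test_empty_locus_leaves_value_unchanged(self):
        counts = self.make_counts([[5, 0]], [[20, 0]])
        base = self.make_counts([[5]], [[20]])
        om = np.array([[0.2]])
        assert log_posterior(
            counts, om, np.array([[0.3, 0.5]]), np.array([0.3, 0.5]), np.array([50.0])
        ) == pytest.approx(
            log_posterior(base, om, np.array([[0.3]]), np.array([0.3]), np.array([50.0]))
        )

    def test_never_nan_on_invalid_state(self):
        counts = self.make_counts([[5]], [[20]])
        om = np.array([[0.2]])
        bad = log_posterior(counts, om, np.array([[1.5]]), np.array([0.3]), np.array([50.0]))
        assert bad == -math.inf

    def test_marginal_matches_adaptive_quadrature(self):
        for alt, m, mu, s2, phi in [
            (3, 24, 0.4, 0.02, 50.0),
            (0, 24, 0.2, 0.01, 10.0),
            (20, 24, 0.7, 0.05, 200.0),
        ]:
            got = marginal_loglik_single(alt, m, mu, s2, phi)
            oracle = quad_marginal_oracle(alt, m, mu, s2, phi)
            assert got == pytest.approx(oracle, abs=1e-6)


class TestSampler:
    def test_normal_target_marginal_passes_ks(self):
        draws, rate = metropolis_rw(
            lambda x: -0.5 * x * x, x0=0.0, scale=2.4, n_draws=10_000, seed=7, burn=500
        )
        assert 0.20 <= rate <= 0.70
        p = stats.kstest(draws[::5], "norm").pvalue
        assert p > 0.01

    def test_chain_determinism_and_stream_independence(self, small_model):
        counts, D, E_list = small_model
        cfg = IBRConfig(n_steps=600, n_chains=1, thin=5, seed=9)
        a = run_chain(counts, D, E_list, cfg, chain_id=0)
        b = run_chain(counts, D, E_list, cfg, chain_id=0)
        c = run_chain(counts, D, E_list, cfg, chain_id=1)
        assert np.array_equal(a.log_posterior, b.log_posterior)
        assert np.array_equal(a.log_alphaE, b.log_alphaE)
        assert not np.array_equal(a.log_posterior, c.log_posterior)

    def test_acceptance_rates_reported_in_unit_interval(self, small_model):
        counts, D, E_list = small_model
        cfg = IBRConfig(n_steps=2000, n_chains=1, thin=10, seed=3)
        post = run_chain(counts, D, E_list, cfg, chain_id=0)
        for rate in post.acceptance_rates.values():
            assert math.isnan(rate) or 0.0 <= rate <= 1.0


@pytest.fixture(scope="module")
def small_model():
    from landgen.synthetic_data import SimulationSpec, simulate_study

    spec = SimulationSpec(
        grid=(4, 4), n_sites=5, inds_per_pop=8, n_loci=60,
        eras=[2012],
        cover_models={2012: {"kind": "gradient", "axis": "x", "p_min": 0.05, "p_max": 0.6}},
        alpha_d=0.05, alpha_e={2012: 0.3}, seed=17,
    )
    _, _, D, E_list, _, _, counts = simulate_study(spec)
    return counts, D, E_list


class TestGelmanRubin:
    def test_identical_chains_at_most_one(self):
        rng = np.random.default_rng(1)
        c = rng.standard_normal(200)
        rhat, upper = gelman_rubin([c, c.copy()])
        assert rhat <= 1.0

    def test_separated_chains_blow_up(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.0, 0.1, 200)
        b = rng.normal(100.0, 0.1, 200)
        rhat, _ = gelman_rubin([a, b])
        assert rhat > 10

    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(3)
        chains = [rng.standard_normal(1000) for _ in range(4)]
        rhat, upper = gelman_rubin(chains)
        assert 0.99 <= rhat <= 1.05
        assert upper >= rhat

    def test_zero_variance_flagged(self, caplog):
        with caplog.at_level("WARNING"):
            rhat, upper = gelman_rubin([np.ones(50), np.ones(50)])
        assert math.isnan(rhat)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            gelman_rubin([np.ones(50)])
        with pytest.raises(ValueError):
            gelman_rubin([np.ones(50), np.ones(40)])


class _FakePosterior:
    """Posterior stub with a constant ratio trace per covariate."""

    def __init__(self, ratios, labels, chain_id=0):
        self.chain_id = chain_id
        self.covariate_labels = labels
        self._ratios = ratios
        self.retain_fraction = 0.5

    def ratio_estimate(self, k=0):
        return self._ratios[k]


class TestEffectSummary:
    def test_constant_chains_zero_se(self):
        posts = [_FakePosterior([2.0], ["1860"], i) for i in range(3)]
        s = effect_summary(posts, ["1860"])
        assert s.mean_ratio[0] == pytest.approx(2.0)
        assert s.standard_error[0] == 0.0
        assert s.hsd_group == ["a"]

    def test_hand_computed_se(self):
        posts = [_FakePosterior([r], ["1910"]) for r in (1.0, 2.0, 3.0)]
        s = effect_summary(posts, ["1910"])
        assert s.mean_ratio[0] == pytest.approx(2.0)
        assert s.standard_error[0] == pytest.approx(1.0 / math.sqrt(3))

    def test_output_follows_label_order(self):
        posts = [
            _FakePosterior([1.0 + 0.01 * i, 5.0 + 0.01 * i], ["1860", "2012"], i)
            for i in range(3)
        ]
        s = effect_summary(posts, ["2012", "1860"])
        assert s.labels == ["2012", "1860"]
        assert s.mean_ratio[0] > s.mean_ratio[1]

    def test_single_chain_per_era_errors(self):
        posts = [_FakePosterior([2.0], ["1860"])]
        with pytest.raises(ValueError, match="SE"):
            effect_summary(posts, ["1860"])
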