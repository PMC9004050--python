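"""Gibbs sampler: imputation full conditionals, conjugate equivalence,
posterior summaries and the zone effect."""

import numpy as np
import pytest

from llinsurv.matrix import build_matrix, clean
from llinsurv.model import (
    PER_BRAND,
    ZONE_COVARIATE,
    ModelSpec,
    ModelSpecError,
    ParamState,
    SurvivalPosterior,
    fit,
    impute_step,
    or_from_coefficient,
    prepare_data,
    summarize,
    zone_effect,
)
from llinsurv.simulate import SimulationConfig, simulate_cohort

from conftest import roster_for, traj_matrix


def _data_and_params(traj, alphas, rounds=(6, 12, 24)):
    """Single-net model data with hand-set logit interval survivals."""
    m = traj_matrix([traj], rounds=rounds)
    roster = roster_for(m)
    spec = ModelSpec(variant=PER_BRAND, sigma_fixed=0.0, seed=0)
    data = prepare_data(m, roster, spec)
    params = ParamState(
        alpha=np.asarray([alphas], dtype=float),
        beta=0.0,
        u=np.zeros(data.n_households),
        sigma=0.0,
    )
    return data, params


class TestImputeStep:
    def test_certain_survival_forces_presence(self):
        # PRESENT, UNKNOWN, DISCARDED with first-interval survival ~1:
        # failing already at the unknown round has probability ~0.
        data, params = _data_and_params("PUD", alphas=(50.0, 50.0, 0.0))
        rng = np.random.default_rng(0)
        for _ in range(200):
            traj = impute_step(data, params, rng)
            assert traj.fail[0] == 3  # present at the unknown round
            assert traj.statuses(3)[0].tolist() == [True, True, False]

    def test_no_presence_after_discard(self):
        # whatever the imputation, presence probability after the
        # determined discard round is zero
        data, params = _data_and_params("PUDD", alphas=(0.0, 0.0, 0.0, 0.0), rounds=(6, 12, 24, 36))
        rng = np.random.default_rng(1)
        for _ in range(300):
            st = impute_step(data, params, rng).statuses(4)[0]
            assert not st[2] and not st[3]

    def test_symmetric_evidence_splits_evenly(self):
        # PRESENT, UNKNOWN, NOT_FOUND with p2 = 0.5 and p3 ~ 0: the two
        # latent paths (fail at round 2 / survive then fail at 3) have
        # equal likelihood 0.5, so the cell is imputed present ~50%.
        data, params = _data_and_params("PUN", alphas=(50.0, 0.0, -50.0))
        rng = np.random.default_rng(2)
        n = 4000
        present = sum(impute_step(data, params, rng).statuses(3)[0, 1] for _ in range(n))
        se = np.sqrt(0.25 / n)
        assert abs(present / n - 0.5) < 3 * se

    def test_degenerate_conditional_resolves_absent_and_is_counted(self):
        # survival 1 in every interval makes all failure paths impossible;
        # the cell resolves to the earliest absent interval
        data, params = _data_and_params("PUD", alphas=(50.0, 50.0, 50.0))
        traj = impute_step(data, params, np.random.default_rng(3))
        assert traj.n_degenerate == 1
        assert traj.fail[0] == 2

    def test_monotone_within_iteration(self):
        data, params = _data_and_params("PUUD", alphas=(0.5, 0.5, 0.5, 0.5), rounds=(6, 12, 24, 36))
        rng = np.random.default_rng(4)
        for _ in range(300):
            st = impute_step(data, params, rng).statuses(4)[0]
            # once absent, absent forever
            assert not np.any(np.diff(st.astype(int)) > 0)


class TestModelSpec:
    def test_iterations_must_exceed_burn_in(self):
        with pytest.raises(ModelSpecError):
            ModelSpec(iterations=100, burn_in=100)

    def test_two_chains_required(self):
        with pytest.raises(ModelSpecError):
            ModelSpec(chains=1)

    def test_beta_prior_requires_no_random_effects(self):
        with pytest.raises(ModelSpecError):
            ModelSpec(alpha_prior=("beta", 1, 1), sigma_fixed=None)


@pytest.fixture(scope="module")
def clean_cohort():
    cfg = SimulationConfig(
        seed=21,
        n_households=150,
        nets_per_household_mean=1.3,
        brands={"A": (0.95, 0.8, 0.75, 0.85)},
        household_sd=0.0,
        zone_log_odds=0.0,
        missingness=(0, 0, 0, 0),
        not_found_noise=0.0,
        discard_lag_prob=0.0,
    )
    roster, obs, _ = simulate_cohort(cfg)
    return roster, clean(build_matrix(roster, obs, rounds=cfg.rounds))


def test_conjugate_oracle_small(clean_cohort):
    # no missing data, no random effects, flat Beta(1,1) prior: Gibbs
    # posterior mean of each interval survival equals the closed form
    # (survivors + 1) / (at-risk + 2) up to Monte-Carlo error
    roster, matrix = clean_cohort
    spec = ModelSpec(
        variant=PER_BRAND,
        alpha_prior=("beta", 1, 1),
        sigma_fixed=0.0,
        chains=2,
        iterations=1500,
        burn_in=250,
        seed=6,
    )
    data = prepare_data(matrix, roster, spec)
    from llinsurv.model import _risk_outcome

    at_risk, survived = _risk_outcome(data, np.where(data.event, data.fa, 0))
    post = fit(matrix, roster, spec)
    for k in range(4):
        atr, srv = at_risk[:, k].sum(), survived[:, k].sum()
        oracle = (srv + 1) / (atr + 2)
        draws = post.s[:, :, 0, k]
        mcse = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - oracle) < 3 * mcse


def test_all_present_concentrates_near_one():
    m = traj_matrix(["PPPP"] * 80)
    roster = roster_for(m)
    spec = ModelSpec(variant=PER_BRAND, sigma_fixed=0.0, chains=2, iterations=1200, burn_in=200, seed=9)
    post = fit(m, roster, spec)
    cum = post.cumulative[:, :, 0, -1]
    assert cum.mean() > 0.9
    assert np.percentile(cum, 2.5) > 0.8


def test_exchangeability_under_net_permutation(clean_cohort):
    # with no latent cells the sampler's draws depend on the data only
    # through per-interval counts, so permuting nets changes nothing
    roster, matrix = clean_cohort
    spec = ModelSpec(
        variant=PER_BRAND,
        alpha_prior=("beta", 1, 1),
        sigma_fixed=0.0,
        chains=2,
        iterations=600,
        burn_in=100,
        seed=13,
    )
    post1 = fit(matrix, roster, spec)
    rng = np.random.default_rng(0)
    perm = rng.permutation(matrix.n_nets)
    from llinsurv.rates import subset_matrix

    post2 = fit(subset_matrix(matrix, perm), roster, spec)
    assert np.array_equal(post1.s, post2.s)


def test_monotone_coherence_every_retained_iteration(small_cohort):
    cfg, roster, obs, _ = small_cohort
    matrix = clean(build_matrix(roster, obs, rounds=cfg.rounds))
    spec = ModelSpec(variant=PER_BRAND, chains=2, iterations=400, burn_in=200, seed=3)
    post = fit(matrix, roster, spec, store_latent=True)
    data = prepare_data(matrix, roster, spec)
    fail = post.latent.reshape(-1, matrix.n_nets)
    k = np.arange(1, len(cfg.rounds) + 1)
    for it in range(fail.shape[0]):
        present = np.ones((matrix.n_nets, len(cfg.rounds)), dtype=bool)
        ev = fail[it] > 0
        present[ev] = k[None, :] < fail[it][ev, None]
        assert not np.any(np.diff(present.astype(int), axis=1) > 0)
    # imputed failures always lie between last presence and determined absence
    ev = data.event
    assert (fail[:, ev] >= data.lp[ev] + 1).all()
    assert (fail[:, ev] <= data.fa[ev]).all()


class TestSummaries:
    def _posterior(self, draws):
        draws = np.asarray(draws, dtype=float).reshape(2, -1)
        s = draws[:, :, None, None]
        return SurvivalPosterior(
            variant=ZONE_COVARIATE,
            brands=["pooled"],
            rounds=(6,),
            s=s,
            cumulative=s.copy(),
            sigma=np.zeros_like(draws),
            beta=draws,
            diagnostics={},
        )

    def test_constant_draws_collapse_ci(self):
        post = self._posterior(np.full(1000, 0.4))
        row = summarize(post).set_index("parameter").loc["beta"]
        assert row["ci_low"] == row["ci_high"] == pytest.approx(0.4)

    def test_equal_tailed_interval_matches_empirical_quantiles(self):
        rng = np.random.default_rng(5)
        draws = rng.beta(2, 5, 1000)
        post = self._posterior(draws)
        row = summarize(post, level=95).set_index("parameter").loc["beta"]
        assert row["ci_low"] == pytest.approx(np.percentile(draws, 2.5))
        assert row["ci_high"] == pytest.approx(np.percentile(draws, 97.5))

    def test_level_validated(self):
        with pytest.raises(ValueError):
            summarize(self._posterior(np.zeros(10)), level=0)

    def test_null_effect_gives_unit_odds_ratio(self):
        post = self._posterior(np.zeros(1000))
        eff = zone_effect(post)
        assert eff["odds_ratio"] == 1.0
        assert eff["odds_ratio_from_mean"] == 1.0

    def test_odds_ratio_summarises_exponentiated_draws(self):
        rng = np.random.default_rng(8)
        draws = rng.normal(0.9, 0.2, 2000)
        eff = zone_effect(self._posterior(draws))
        assert eff["odds_ratio"] == pytest.approx(np.exp(draws).mean())
        lo, hi = eff["odds_ratio_ci"]
        assert lo == pytest.approx(np.exp(np.percentile(draws, 2.5)), rel=1e-6)
        assert hi == pytest.approx(np.exp(np.percentile(draws, 97.5)), rel=1e-6)

    def test_zone_effect_requires_zone_variant(self):
        post = self._posterior(np.zeros(10))
        post.beta = None
        with pytest.raises(ValueError):
            zone_effect(post)

    def test_or_from_coefficient(self):
        assert or_from_coefficient(0.0) == 1.0
        assert or_from_coefficient(np.log(2.0), ndigits=3) == 2.0
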