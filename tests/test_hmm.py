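"""HMM emissions, forward filtering, smoothing and drift-parameter inference."""

import numpy as np
import pytest
from scipy.stats import binom

from drifthmm import (
    AlleleTrajectory,
    DriftModelSpec,
    TrajectorySet,
    delta_distribution,
    emission_probability,
    emission_two_stage,
    forward_backward,
    forward_filter,
    gaussian_propagator,
    infer_drift_parameter,
    make_grid,
    total_log_likelihood,
    wf_propagator,
)
from drifthmm.hmm import DegenerateLikelihoodError

from conftest import path_sum_log_marginal, path_sum_posteriors


# ---------------------------------------------------------------------------
# domain types


def test_trajectory_validation():
    with pytest.raises(ValueError):
        AlleleTrajectory("x", (0, 10), (5, 200), (100, 100))  # n > C
    with pytest.raises(ValueError):
        AlleleTrajectory("x", (10, 10), (5, 5), (100, 100))  # not increasing
    with pytest.raises(ValueError):
        AlleleTrajectory("x", (), (), ())  # empty
    t = AlleleTrajectory("x", (0, 15, 37, 59), (0, 3, 9, 2), (80, 90, 100, 70))
    assert t.n_times == 4


def test_trajectory_set_fixed_locus_filter():
    fixed = AlleleTrajectory("f", (0, 10), (0, 0), (100, 100))
    seg = AlleleTrajectory("s", (0, 10), (40, 60), (100, 100))
    ts = TrajectorySet([fixed, seg])
    assert ts.n_loci == 2
    assert [t.locus_id for t in ts.without_fixed()] == ["s"]
    with pytest.raises(ValueError):
        TrajectorySet([fixed]).without_fixed()


def test_drift_model_spec_bounds():
    with pytest.raises(ValueError):
        DriftModelSpec("WF", 1)
    with pytest.raises(ValueError):
        DriftModelSpec("Gaussian", 0.0)
    with pytest.raises(ValueError):
        DriftModelSpec("Beta", 1.0)


# ---------------------------------------------------------------------------
# emissions


def test_emission_degenerate_cases():
    assert emission_probability(100, 100, 1.0) == 1.0
    assert emission_probability(0, 100, 0.0) == 1.0
    assert emission_probability(3, 100, 0.0) == 0.0
    with pytest.raises(ValueError):
        emission_probability(101, 100, 0.5)


def test_emission_matches_log_gamma_oracle():
    from scipy.special import gammaln

    n, C, q = 50, 100, 0.5
    log_oracle = (
        gammaln(C + 1) - gammaln(n + 1) - gammaln(C - n + 1)
        + n * np.log(q) + (C - n) * np.log(1 - q)
    )
    assert emission_probability(n, C, q) == pytest.approx(np.exp(log_oracle), rel=1e-12)


def test_two_stage_emission_enumeration_oracle():
    n, C, q, P = 5, 10, 0.5, 4
    oracle = sum(
        binom.pmf(nh, P, q) * binom.pmf(n, C, nh / P) for nh in range(P + 1)
    )
    assert emission_two_stage(n, C, q, P) == pytest.approx(oracle, rel=1e-12)


def test_two_stage_converges_to_simple_for_large_pool():
    simple = emission_probability(30, 100, 0.3)
    staged = emission_two_stage(30, 100, 0.3, pool_genomes=200_000)
    assert staged == pytest.approx(simple, abs=1e-4)


def test_two_stage_degenerate_chain():
    assert emission_two_stage(0, 10, 0.0, 100) == pytest.approx(1.0, abs=1e-12)
    assert emission_two_stage(3, 10, 0.0, 100) == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# forward filtering


@pytest.mark.parametrize("C", [10, 100])
def test_single_observation_uniform_prior_marginal(C, grid401):
    # integral of Binom(n | C, q) dq over [0,1] is 1/(C+1) for any n
    for n in (0, C // 3, C):
        traj = AlleleTrajectory("x", (0,), (n,), (C,))
        res = forward_filter(traj, DriftModelSpec("WF", 400), grid401)
        assert np.exp(res.log_likelihood) == pytest.approx(1 / (C + 1), rel=0.01)


def test_absorbed_chain_has_probability_one(grid401):
    traj = AlleleTrajectory("x", (0, 10, 20), (0, 0, 0), (500, 500, 500))
    prior = delta_distribution(grid401, 0.0)
    res = forward_filter(traj, DriftModelSpec("WF", 400), grid401, prior=prior)
    assert res.log_likelihood == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("family, theta", [("WF", 4), ("Gaussian", 0.08)])
def test_forward_matches_path_sum_oracle(family, theta, grid5):
    traj = AlleleTrajectory("x", (0, 3, 8), (3, 6, 9), (10, 12, 15))
    model = DriftModelSpec(family, theta)
    gaps = {3, 5}
    if family == "WF":
        mats = {dt: wf_propagator(theta, dt, grid5, cache=False).rows for dt in gaps}
    else:
        mats = {dt: gaussian_propagator(theta, dt, grid5).rows for dt in gaps}
    from drifthmm import uniform_distribution

    prior = uniform_distribution(grid5).mass
    oracle = path_sum_log_marginal(traj, mats, grid5, prior)
    res = forward_filter(traj, model, grid5)
    assert res.log_likelihood == pytest.approx(oracle, abs=1e-9)
    for f in res.filtered:
        assert f.mass.sum() == pytest.approx(1.0, abs=1e-9)


def test_forward_backward_matches_enumeration_oracle(grid5):
    traj = AlleleTrajectory("x", (0, 2), (2, 7), (9, 11))
    model = DriftModelSpec("WF", 6)
    mats = {2: wf_propagator(6, 2, grid5, cache=False).rows}
    from drifthmm import uniform_distribution

    oracle = path_sum_posteriors(traj, mats, grid5, uniform_distribution(grid5).mass)
    posts = forward_backward(traj, model, grid5)
    assert len(posts) == 2
    for k, p in enumerate(posts):
        np.testing.assert_allclose(p.mass, oracle[k], atol=1e-9)
        assert p.mass.sum() == pytest.approx(1.0, abs=1e-9)


def test_forward_backward_single_observation_equals_filtered(grid401):
    traj = AlleleTrajectory("x", (0,), (30,), (100,))
    model = DriftModelSpec("Gaussian", 0.01)
    posts = forward_backward(traj, model, grid401)
    filt = forward_filter(traj, model, grid401).filtered
    np.testing.assert_allclose(posts[0].mass, filt[0].mass, atol=1e-12)


def test_degenerate_emission_raises_with_locus_and_time(grid401):
    # impossible data under a delta prior at the wrong boundary
    traj = AlleleTrajectory("locus_bad", (0, 10), (100, 100), (100, 100))
    prior = delta_distribution(grid401, 0.0)
    with pytest.raises(DegenerateLikelihoodError, match="locus_bad"):
        forward_filter(traj, DriftModelSpec("WF", 400), grid401, prior=prior)


# ---------------------------------------------------------------------------
# total likelihood


def test_total_likelihood_additivity(grid5):
    t1 = AlleleTrajectory("a", (0, 4), (2, 5), (10, 10))
    t2 = AlleleTrajectory("b", (0, 4), (8, 3), (10, 10))
    model = DriftModelSpec("WF", 10)
    single = {
        tid: forward_filter(t, model, grid5).log_likelihood
        for tid, t in (("a", t1), ("b", t2))
    }
    res = total_log_likelihood(TrajectorySet([t1, t2]), model, grid5)
    assert res.log_likelihood == pytest.approx(single["a"] + single["b"], abs=1e-9)
    assert res.log_likelihood == pytest.approx(
        sum(res.per_locus_log_likelihood.values()), abs=1e-9
    )


def test_duplicated_locus_doubles_likelihood(grid5):
    t1 = AlleleTrajectory("a", (0, 4), (2, 5), (10, 10))
    t2 = AlleleTrajectory("a2", (0, 4), (2, 5), (10, 10))
    model = DriftModelSpec("Gaussian", 0.05)
    one = total_log_likelihood(TrajectorySet([t1]), model, grid5).log_likelihood
    two = total_log_likelihood(TrajectorySet([t1, t2]), model, grid5).log_likelihood
    assert two == pytest.approx(2 * one, abs=1e-9)


def test_total_likelihood_invariant_to_splitting(grid5):
    trajs = [
        AlleleTrajectory(f"l{i}", (0, 2, 6), tuple(ns), (12, 12, 12))
        for i, ns in enumerate([(3, 4, 6), (10, 9, 12), (0, 1, 0), (6, 6, 5)])
    ]
    model = DriftModelSpec("WF", 8)
    whole = total_log_likelihood(TrajectorySet(trajs), model, grid5).log_likelihood
    parts = (
        total_log_likelihood(TrajectorySet(trajs[:2]), model, grid5).log_likelihood
        + total_log_likelihood(TrajectorySet(trajs[2:]), model, grid5).log_likelihood
    )
    assert whole == pytest.approx(parts, abs=1e-9)


def test_mixed_schedules_use_per_interval_propagators(grid5):
    # loci with different sampling schedules in one set
    t1 = AlleleTrajectory("a", (0, 3), (2, 5), (10, 10))
    t2 = AlleleTrajectory("b", (0, 5, 9), (8, 3, 1), (10, 10, 10))
    model = DriftModelSpec("WF", 10)
    res = total_log_likelihood(TrajectorySet([t1, t2]), model, grid5)
    expected = (
        forward_filter(t1, model, grid5).log_likelihood
        + forward_filter(t2, model, grid5).log_likelihood
    )
    assert res.log_likelihood == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# inference


def test_likelihood_continuous_in_n_across_integer_crossings(grid401):
    rng = np.random.default_rng(0)
    trajs = [
        AlleleTrajectory(f"l{i}", (0, 10, 20), tuple(rng.binomial(100, 0.5, 3)), (100,) * 3)
        for i in range(5)
    ]
    data = TrajectorySet(trajs)
    lls = [
        total_log_likelihood(data, DriftModelSpec("WF", N), grid401).log_likelihood
        for N in (399.8, 399.95, 400.0, 400.05, 400.2)
    ]
    steps = np.abs(np.diff(lls))
    # no jump at the integer crossing larger than the trend between
    # neighbouring non-integer values
    assert steps.max() < 0.01


def test_constant_noiseless_data_drives_theta_to_minimal_drift(grid401):
    trajs = [
        AlleleTrajectory(f"l{i}", (0, 10, 20, 30), (50,) * 4, (100,) * 4) for i in range(3)
    ]
    data = TrajectorySet(trajs)
    theta, _, diag = infer_drift_parameter(data, "WF", (50, 5000), grid401)
    assert diag["at_bound"] and theta > 4500
    sg, _, diag_g = infer_drift_parameter(data, "Gaussian", (1e-3, 0.3), grid401)
    assert diag_g["at_bound"] and sg < 1.2e-3


def test_infer_rejects_bad_bounds(grid401):
    t = AlleleTrajectory("a", (0, 10), (40, 60), (100, 100))
    with pytest.raises(ValueError):
        infer_drift_parameter(TrajectorySet([t]), "WF", (500, 50), grid401)
    with pytest.raises(ValueError):
        infer_drift_parameter(TrajectorySet([t]), "WF", (0, np.inf), grid401)
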