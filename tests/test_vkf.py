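import numpy as np
import pytest
from scipy.stats import norm

import revlearn as rl
from revlearn.vkf import VKFConfig, VKFState, effective_sample_size, systematic_resample


def test_kalman_step_arithmetic():
    m, w, alpha, delta = rl.kalman_step(0.0, 0.1, 1.0, 0.1, 0.2)
    assert alpha == pytest.approx(0.5)
    assert delta == pytest.approx(1.0)
    assert m == pytest.approx(0.5)
    assert w == pytest.approx(0.1)


def test_kalman_step_limits():
    m0 = 0.3
    m, w, alpha, _ = rl.kalman_step(m0, 0.1, 5.0, 0.1, 1e9)
    assert alpha < 1e-8
    assert m == pytest.approx(m0, abs=1e-6)
    m, w, alpha, delta = rl.kalman_step(0.4, 0.2, 0.4, 0.1, 0.3)
    assert delta == 0.0
    assert m == pytest.approx(0.4)
    assert w == pytest.approx((1 - alpha) * 0.3)
    with pytest.raises(ValueError):
        rl.kalman_step(0.0, -0.1, 0.0, 0.1, 0.1)


def test_propagation_is_martingale():
    """E[z'|z] = z because the Beta multiplier has mean eta."""
    rng = np.random.default_rng(0)
    z = np.ones(100_000)
    z_new, y_new = rl.propagate_particle(z, z, 0.1, 0.3, rng)
    for arr, lam in ((z_new, 0.1), (y_new, 0.3)):
        eta = 1 - lam
        a = 0.5 * eta / (1 - eta)
        var_eps = a * 0.5 / ((a + 0.5) ** 2 * (a + 1.5))
        sem = np.sqrt(var_eps / eta**2 / arr.size)
        assert abs(arr.mean() - 1.0) < 4 * sem
        # Beta mean identity: E[eps] = a/(a+0.5) = eta
        assert a / (a + 0.5) == pytest.approx(eta)


def test_slow_update_limit_keeps_z():
    rng = np.random.default_rng(1)
    z = np.ones(10_000)
    z_new, _ = rl.propagate_particle(z, z, 1e-5, 1e-5, rng)
    assert np.std(z_new) < 0.01


def test_weight_update_matches_gaussian_densities():
    m = np.array([0.0, 2.0])
    w = np.array([0.1, 0.1])
    v = np.array([0.05, 0.05])
    s = np.array([0.05, 0.05])
    o = 0.1
    dens = norm.pdf(o, loc=m, scale=np.sqrt(w + v + s))
    expected = dens / dens.sum()
    got = rl.weight_update(np.array([0.5, 0.5]), m, w, v, s, o)
    assert got == pytest.approx(expected, rel=1e-10)
    assert got.sum() == pytest.approx(1.0)


def test_weight_update_uniform_for_identical_particles():
    n = 8
    got = rl.weight_update(np.full(n, 1 / n), np.zeros(n), np.ones(n), np.ones(n), np.ones(n), 0.3)
    assert got == pytest.approx(np.full(n, 1 / n))


def test_weight_update_normalization_arithmetic():
    """Unnormalized densities 0.3 and 0.1 give weights 0.75 / 0.25."""
    raw = np.array([0.3, 0.1])
    assert raw / raw.sum() == pytest.approx([0.75, 0.25])
    # dominance: the particle predicting the outcome takes nearly all weight
    got = rl.weight_update(
        np.array([0.5, 0.5]),
        np.array([0.5, 50.0]),
        np.array([0.1, 0.1]),
        np.array([0.1, 0.1]),
        np.array([0.1, 0.1]),
        0.5,
    )
    assert got[0] > 0.999999


def _state(weights):
    n = len(weights)
    return VKFState(
        z=np.arange(1.0, n + 1),
        y=np.arange(1.0, n + 1),
        m=np.arange(float(n)),
        w=np.ones(n),
        b=np.asarray(weights, dtype=float),
    )


def test_resampling_rules():
    rng = np.random.default_rng(2)
    uniform = _state(np.full(4, 0.25))
    out = rl.maybe_resample(uniform, 0.5, rng)
    assert out is uniform  # ESS = N, untouched
    degenerate = _state([0.0, 1.0, 0.0, 0.0])
    out = rl.maybe_resample(degenerate, 0.5, rng)
    assert np.all(out.z == 2.0) and np.all(out.b == 0.25)
    # ESS/N exactly at threshold: strict inequality, no resample
    edge = _state([0.5, 0.5, 0.0, 0.0])
    assert effective_sample_size(edge.b) == pytest.approx(2.0)
    assert rl.maybe_resample(edge, 0.5, rng) is edge


def test_systematic_resample_preserves_multiplicity():
    rng = np.random.default_rng(3)
    idx = systematic_resample(np.array([0.5, 0.25, 0.25]), rng)
    counts = np.bincount(idx, minlength=3)
    assert counts[0] >= 1 and counts.sum() == 3


def test_run_vkf_converges_on_constant_outcomes():
    # joint estimation: constant outcomes are evidence of zero stochasticity
    cfg = VKFConfig(n_particles=300, seed=4)
    traj = rl.run_vkf(np.full(150, 0.8), cfg)
    assert abs(traj["m"].iloc[-1] - 0.8) < 0.05
    assert traj["s_hat"].iloc[-20:].mean() < traj["s_hat"].iloc[:5].mean()
    # with stochasticity pinned near its prior the Kalman gain decays
    frozen = VKFConfig(n_particles=300, seed=4, lambda_s=1e-6)
    traj = rl.run_vkf(np.full(150, 0.8), frozen)
    assert traj["alpha"].iloc[-20:].mean() < traj["alpha"].iloc[:5].mean()


def test_lesioned_filter_clamps_stochasticity():
    cfg = VKFConfig(n_particles=100, seed=5, lesioned=True, s_fixed=0.001)
    traj = rl.run_vkf(np.random.default_rng(0).normal(0.5, 0.2, 60), cfg)
    assert np.allclose(traj["s_hat"], 0.001)


def test_vkf_reaches_kalman_steady_state():
    """With frozen (z, y) the filtered learning rate matches the
    closed-form Kalman fixed point."""
    v, s = 0.1, 0.4
    cfg = VKFConfig(
        lambda_v=1e-6, lambda_s=1e-6, v0=v, s0=s, n_particles=200, seed=6
    )
    outcomes = np.random.default_rng(1).normal(0.5, np.sqrt(s), 300)
    traj = rl.run_vkf(outcomes, cfg)
    target = rl.kalman_steady_state_alpha(v, s)
    assert traj["alpha"].iloc[-50:].mean() == pytest.approx(target, abs=0.02)


def test_more_particles_reduce_monte_carlo_variance():
    outcomes = np.random.default_rng(2).normal(0.6, 0.15, 80)
    final_v = {n: [] for n in (25, 200)}
    for n in final_v:
        for seed in range(6):
            cfg = VKFConfig(n_particles=n, seed=seed)
            traj = rl.run_vkf(outcomes, cfg)
            final_v[n].append(traj["v_hat"].iloc[-20:].mean())
    assert np.var(final_v[200]) < np.var(final_v[25])


def test_choice_sim_probabilities():
    m = np.full(20_000, 0.5)
    choices = rl.vkf_choice_sim(m, decision_noise=3.0, seed=7)
    assert abs((choices == "play").mean() - 0.5) < 0.02
    choices = rl.vkf_choice_sim(
        np.random.default_rng(3).uniform(0, 1, 20_000), decision_noise=0.0, seed=8
    )
    assert abs((choices == "play").mean() - 0.5) < 0.02
    sure = rl.vkf_choice_sim(np.full(100, 5.0), decision_noise=3.0, seed=9)
    assert (sure == "play").mean() > 0.95


def test_config_validation():
    with pytest.raises(ValueError):
        VKFConfig(lambda_v=0.0).validate()
    with pytest.raises(ValueError):
        VKFConfig(n_particles=1).validate()
    with pytest.raises(ValueError):
        VKFConfig(s0=-1.0).validate()


def test_task_outcomes_modes(schedule):
    g = rl.task_outcomes(schedule, seed=1, mode="gaussian")
    b = rl.task_outcomes(schedule, seed=1, mode="binary")
    assert set(b["outcome"].unique()) <= {0.0, 1.0}
    # Gaussian outcomes track the reward rate at the stated noise levels
    low = g.loc[g["noise_level"] == "low"]
    resid = low["outcome"] - low["p_reward"]
    assert resid.std() == pytest.approx(0.1, abs=0.02)
    with pytest.raises(ValueError):
        rl.task_outcomes(schedule, seed=1, mode="nope")


def test_control_model_tracks_stochasticity_by_noise_level(schedule):
    """Estimated stochasticity is higher in high-noise than low-noise
    phases of the task-structured simulation."""
    sched = rl.task_outcomes(schedule, seed=2, mode="gaussian")
    cfg = VKFConfig(n_particles=300, seed=3)
    traj = rl.run_vkf_on_schedule(sched, cfg)
    merged = sched.assign(s_hat=traj["s_hat"].to_numpy(), pos=sched["trials_since_reversal"])
    late = merged.loc[merged["pos"] > 10]  # let estimates settle within blocks
    s_high = late.loc[late["noise_level"] == "high", "s_hat"].mean()
    s_low = late.loc[late["noise_level"] == "low", "s_hat"].mean()
    assert s_high > s_low
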