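"""Joint inference of volatility and stochasticity by Rao-Blackwellized
particle filtering.

The generative model: a reward rate x_t follows a Gaussian random walk
with variance v_t (volatility); outcomes o_t are Gaussian around x_t with
variance s_t (stochasticity).  The inverses z = 1/v and y = 1/s follow
multiplicative Beta-noise dynamics, z_t = eta^{-1} z_{t-1} eps_t with
eps ~ Beta(0.5 eta/(1-eta), 0.5), which makes z a martingale
(E[eps] = eta).  Here eta_v = 1 - lambda_v and eta_s = 1 - lambda_s, so
lambda_v and lambda_s act as update rates for volatility and
stochasticity.

Inference: a particle filter over (z, y); conditional on each particle a
Kalman filter tracks x with mean m and variance w.  The learning rate of
the Kalman update, alpha = (w + v) / (w + v + s), rises with volatility
and falls with stochasticity — the computational heart of the model.  The
*lesioned* variant clamps s at a small constant, forcing outcome noise to
be misattributed to volatility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

TASK_OUTCOME_VARIANCES = {"low": 0.01, "high": 0.02, "random": 0.05}


@dataclass(frozen=True)
class VKFConfig:
    lambda_v: float = 0.1
    lambda_s: float = 0.1
    v0: float = 0.1
    s0: float = 0.1
    n_particles: int = 1000
    ess_threshold: float = 0.5
    seed: int = 0
    lesioned: bool = False
    s_fixed: float = 0.001
    decision_noise: float = 3.0
    m0: float = 0.5
    w0: float = 0.1

    def validate(self) -> None:
        if not (0.0 < self.lambda_v < 1.0 and 0.0 < self.lambda_s < 1.0):
            raise ValueError("lambda_v and lambda_s must lie strictly in (0, 1)")
        if min(self.v0, self.s0, self.s_fixed, self.w0) <= 0:
            raise ValueError("variances v0, s0, s_fixed, w0 must be positive")
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")


@dataclass
class VKFState:
    """Particle ensemble: inverse volatility z, inverse stochasticity y,
    Kalman mean m and variance w, normalized weights b."""

    z: np.ndarray
    y: np.ndarray
    m: np.ndarray
    w: np.ndarray
    b: np.ndarray

    def weighted_means(self) -> dict[str, float]:
        return {
            "v_hat": float(self.b @ (1.0 / self.z)),
            "s_hat": float(self.b @ (1.0 / self.y)),
            "m": float(self.b @ self.m),
        }


def kalman_step(m: float, w: float, o: float, v: float, s: float):
    """One Kalman update; returns (m', w', alpha, delta).

    alpha = (w + v) / (w + v + s), m' = m + alpha * delta with
    delta = o - m, and w' = (1 - alpha)(w + v).
    """
    if np.any(np.asarray(w) <= 0) or np.any(np.asarray(v) <= 0) or np.any(np.asarray(s) <= 0):
        raise ValueError("variances w, v, s must be positive")
    total = w + v
    alpha = total / (total + s)
    delta = o - m
    m_new = m + alpha * delta
    w_new = (1.0 - alpha) * total
    return m_new, w_new, alpha, delta


def _beta_shape(lam: float) -> float:
    eta = 1.0 - lam
    return 0.5 * eta / (1.0 - eta)


def propagate_particle(z, y, lambda_v: float, lambda_s: float, rng: np.random.Generator):
    """Multiplicative Beta-noise transition of the inverse variances.

    z' = eta_v^{-1} z eps with eps ~ Beta(0.5 eta_v/(1-eta_v), 0.5), and
    independently for y; both are martingales (E[z'|z] = z).
    """
    z = np.asarray(z, dtype=float)
    y = np.asarray(y, dtype=float)
    eta_v = 1.0 - lambda_v
    eta_s = 1.0 - lambda_s
    eps_v = rng.beta(_beta_shape(lambda_v), 0.5, size=z.shape)
    eps_s = rng.beta(_beta_shape(lambda_s), 0.5, size=y.shape)
    return z * eps_v / eta_v, y * eps_s / eta_s


def weight_update(prev_weights, m, w, v, s, o: float) -> np.ndarray:
    """Reweight particles by the Gaussian predictive density
    N(o | m, w + v + s), renormalized; falls back to uniform weights with
    a warning if every density underflows."""
    var = np.asarray(w) + np.asarray(v) + np.asarray(s)
    log_lik = -0.5 * (np.log(2 * np.pi * var) + (o - np.asarray(m)) ** 2 / var)
    log_b = np.log(np.asarray(prev_weights, dtype=float)) + log_lik
    log_b -= log_b.max()
    b = np.exp(log_b)
    total = b.sum()
    if not np.isfinite(total) or total <= 0:
        warnings.warn("all particle densities underflowed; resetting to uniform", stacklevel=2)
        return np.full(len(b), 1.0 / len(b))
    return b / total


def effective_sample_size(weights: np.ndarray) -> float:
    weights = np.asarray(weights, dtype=float)
    return float(1.0 / np.sum(weights**2))


def systematic_resample(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Index set from systematic resampling with a single uniform offset."""
    n = len(weights)
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), positions).clip(max=n - 1)


def maybe_resample(state: VKFState, ess_threshold: float, rng: np.random.Generator) -> VKFState:
    """Systematic resampling iff ESS/N falls strictly below the threshold;
    resampled weights are reset to uniform."""
    n = len(state.b)
    if effective_sample_size(state.b) / n < ess_threshold:
        idx = systematic_resample(state.b, rng)
        return VKFState(
            z=state.z[idx],
            y=state.y[idx],
            m=state.m[idx],
            w=state.w[idx],
            b=np.full(n, 1.0 / n),
        )
    return state


def run_vkf(outcomes, config: VKFConfig) -> pd.DataFrame:
    """Filter a real-valued outcome sequence.

    Per trial: propagate the particles' (z, y), reweight by the Gaussian
    predictive density, resample if ESS drops below threshold, then apply
    the per-particle Kalman update.  Reported trajectories (volatility,
    stochasticity, learning rate, predicted mean) are weighted averages
    over particles.  Deterministic given ``config.seed``.
    """
    config.validate()
    outcomes = np.asarray(outcomes, dtype=float)
    rng = np.random.default_rng(config.seed)
    n = config.n_particles
    state = VKFState(
        z=np.full(n, 1.0 / config.v0),
        y=np.full(n, 1.0 / (config.s_fixed if config.lesioned else config.s0)),
        m=np.full(n, config.m0),
        w=np.full(n, config.w0),
        b=np.full(n, 1.0 / n),
    )
    records = []
    for t, o in enumerate(outcomes):
        z_new, y_new = propagate_particle(
            state.z, state.y, config.lambda_v, config.lambda_s, rng
        )
        if config.lesioned:
            y_new = np.full(n, 1.0 / config.s_fixed)
        state = replace(state, z=z_new, y=y_new)
        v = 1.0 / state.z
        s = 1.0 / state.y
        state = replace(state, b=weight_update(state.b, state.m, state.w, v, s, o))
        state = maybe_resample(state, config.ess_threshold, rng)
        v = 1.0 / state.z
        s = 1.0 / state.y
        m_pred = float(state.b @ state.m)
        m_new, w_new, alpha, _ = kalman_step(state.m, state.w, o, v, s)
        state = replace(state, m=m_new, w=w_new)
        records.append(
            {
                "trial": t + 1,
                "outcome": float(o),
                "m_pred": m_pred,
                "m": float(state.b @ state.m),
                "v_hat": float(state.b @ v),
                "s_hat": float(state.b @ s),
                "alpha": float(state.b @ alpha),
            }
        )
    return pd.DataFrame(records)


def kalman_steady_state_alpha(v: float, s: float) -> float:
    """Fixed point of alpha = (w*+v)/(w*+v+s), w* = (1-alpha)(w*+v):
    the positive root of s*alpha^2 + v*alpha - v = 0."""
    return float((-v + np.sqrt(v * v + 4.0 * s * v)) / (2.0 * s))


# ---------------------------------------------------------------------------
# task-structured simulation


def task_outcomes(
    schedule: pd.DataFrame,
    seed: int,
    mode: str = "gaussian",
    variances: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-stimulus outcome streams following the task's reward rates.

    ``gaussian`` mode draws o_t ~ N(p_reward, variance-by-noise-level)
    (0.01 low / 0.02 high / 0.05 random); ``binary`` mode uses the
    schedule's pre-drawn win/loss valences as o_t in {1, 0}.
    """
    rng = np.random.default_rng(seed)
    out = schedule.copy()
    if mode == "gaussian":
        var = {**TASK_OUTCOME_VARIANCES, **(variances or {})}
        sd = np.sqrt(np.array([var[lv] for lv in out["noise_level"]]))
        out["outcome"] = out["p_reward"].to_numpy() + sd * rng.standard_normal(len(out))
    elif mode == "binary":
        out["outcome"] = (out["outcome_valence"] == "win").astype(float)
    else:
        raise ValueError("mode must be 'gaussian' or 'binary'")
    return out


def run_vkf_on_schedule(
    schedule_with_outcomes: pd.DataFrame, config: VKFConfig
) -> pd.DataFrame:
    """Run one filter per stimulus over its own outcome stream and return
    trajectories aligned to the schedule's trial order."""
    frames = []
    rng = np.random.default_rng(config.seed)
    for stim, grp in schedule_with_outcomes.groupby("stimulus"):
        sub_cfg = replace(config, seed=int(rng.integers(2**31)))
        traj = run_vkf(grp["outcome"].to_numpy(), sub_cfg)
        traj.index = grp.index
        traj["trial"] = grp["trial"].to_numpy()
        traj["stimulus"] = stim
        frames.append(traj)
    out = pd.concat(frames).sort_index()
    return out


def vkf_choice_sim(
    m_trajectory,
    decision_noise: float = 3.0,
    reference: float = 0.5,
    value_scale: float = 2.0,
    seed: int | None = None,
) -> np.ndarray:
    """Sample play/pass choices from the filtered reward-rate estimate.

    The belief ``m`` lives on the reward-probability scale; the gamble's
    expected reward signal in the task's +-1 units is ``2m - 1``, so
    p(play) = logistic(decision_noise * value_scale * (m - reference))
    with reference 0.5 (the neutral rate) and value_scale 2.  Uses the
    *predictive* mean (before the trial's outcome is seen).
    """
    m = np.asarray(m_trajectory, dtype=float)
    rng = np.random.default_rng(seed)
    p_play = 1.0 / (1.0 + np.exp(-decision_noise * value_scale * (m - reference)))
    return np.where(rng.random(m.size) < p_play, "play", "pass")


def simulate_vkf_agent(
    schedule: pd.DataFrame, config: VKFConfig, seed: int, outcome_mode: str = "binary"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A full task run of a VKF agent: outcomes, filtering, choices.

    Returns (dataset, trajectories).  The dataset has the same layout as
    an RL agent's dataset (action, modality, confirmatory, R), so it can
    be fed straight into the model-fitting machinery.  Binary outcome mode
    keeps the observed stream identical to the win/loss record the fitted
    model sees.
    """
    rng = np.random.default_rng(seed)
    sched = task_outcomes(schedule, seed=int(rng.integers(2**31)), mode=outcome_mode)
    cfg = replace(config, seed=int(rng.integers(2**31)))
    traj = run_vkf_on_schedule(sched, cfg)
    actions = vkf_choice_sim(
        traj["m_pred"].to_numpy(),
        decision_noise=config.decision_noise,
        seed=int(rng.integers(2**31)),
    )
    dataset = schedule.copy()
    dataset["action"] = actions
    play = dataset["action"] == "play"
    win = dataset["outcome_valence"] == "win"
    dataset["modality"] = np.where(play, "factual", "counterfactual")
    dataset["confirmatory"] = play == win
    dataset["R"] = np.where(win, 1.0, -1.0)
    return dataset, traj


def vkf_to_eta(
    schedule: pd.DataFrame,
    config: VKFConfig,
    n_sims: int = 100,
    seed: int | None = None,
    fit_spec: str = "M3",
    n_starts: int = 5,
) -> pd.DataFrame:
    """Fit the hybrid RL model to simulated control and lesioned agents.

    For each simulation index, one control and one lesioned VKF agent play
    the task and the fitted model's eta is recorded — the lesioned model's
    misattribution of outcome noise to volatility shows up as a larger
    fitted surprise sensitivity.
    """
    from .fitting import fit_map

    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_sims):
        sim_seed = int(rng.integers(2**31))
        for lesioned in (False, True):
            cfg = replace(config, lesioned=lesioned)
            dataset, _ = simulate_vkf_agent(schedule, cfg, seed=sim_seed + lesioned)
            fit = fit_map(
                dataset, fit_spec, n_starts=n_starts, seed=int(rng.integers(2**31)), subject=i
            )
            rows.append(
                {
                    "sim": i,
                    "model": "lesioned" if lesioned else "control",
                    "eta": fit.params.eta,
                    "log_likelihood": fit.log_likelihood,
                }
            )
    return pd.DataFrame(rows)
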