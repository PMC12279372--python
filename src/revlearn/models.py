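"""Nested Pearce-Hall hybrid reinforcement-learning model family.

Four nested models of choice in the reversal task:

* ``M1`` - constant-learning-rate Q-learning with inverse temperature
  ``beta``, an additive play bias, and a logistic intercept for the
  learning rate.
* ``M2`` - the Pearce-Hall hybrid: the learning rate is gated by an
  associability trace ``A`` that tracks |prediction error| with step size
  ``eta`` (``alpha_t = kappa_t * A_t``).
* ``M3`` - M2 plus a confirmatory-feedback predictor in the logistic
  ``kappa`` term (confirmatory = factual win or counterfactual loss).
* ``M4`` - M3 plus a feedback-modality predictor (factual vs.
  counterfactual).

Value update: ``Q_{t+1} = Q_t + alpha_t * delta_t`` with
``delta_t = R_t - Q_t`` and the reward signal ``R`` coded +1/-1
internally (displayed as +-10 points).  Associability update:
``A' = eta * |delta_t| + (1 - eta) * A`` with |delta| capped at 1 so A
stays in [0, 1].  Within a trial the associability absorbs the current
|delta| before the value update, so ``alpha_t = kappa_t * A'`` and a
surprising outcome amplifies its own influence on Q — the mechanism
that makes large eta costly under misleading feedback while still
speeding adaptation at true reversals.  Choice: softmax over the biased
play value ``B_play + Q`` against a pass value fixed at 0.

Counterfactual outcomes update Q exactly like factual ones - fictive
feedback is always shown - and feedback modality influences learning only
through the kappa predictor in M4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._core import PROB_FLOOR, loglik_kernel, simulate_kernel

KAPPA_PREDICTORS = ("intercept", "confirmatory", "modality")

DATASET_COLUMNS = ["action", "modality", "confirmatory", "R"]

LATENT_COLUMNS = ["trial", "stimulus", "Q", "delta", "A", "alpha", "p_play"]


@dataclass(frozen=True)
class ModelSpec:
    """Which learning-rate machinery a model variant uses."""

    name: str
    uses_associability: bool
    kappa_predictors: tuple[str, ...] = ("intercept",)

    def __post_init__(self):
        if self.kappa_predictors[0] != "intercept":
            raise ValueError("kappa predictor list must start with 'intercept'")
        unknown = set(self.kappa_predictors) - set(KAPPA_PREDICTORS)
        if unknown:
            raise ValueError(f"unknown kappa predictors: {sorted(unknown)}")

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ["beta", "play_bias"] + [f"kappa_{p}" for p in self.kappa_predictors]
        if self.uses_associability:
            names.append("eta")
        return tuple(names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)


MODEL_SPECS: dict[str, ModelSpec] = {
    "M1": ModelSpec("M1", uses_associability=False),
    "M2": ModelSpec("M2", uses_associability=True),
    "M3": ModelSpec("M3", uses_associability=True, kappa_predictors=("intercept", "confirmatory")),
    "M4": ModelSpec(
        "M4",
        uses_associability=True,
        kappa_predictors=("intercept", "confirmatory", "modality"),
    ),
}


def get_spec(model: str | ModelSpec) -> ModelSpec:
    if isinstance(model, ModelSpec):
        return model
    try:
        return MODEL_SPECS[model]
    except KeyError:
        raise KeyError(f"unknown model {model!r}; choose from {list(MODEL_SPECS)}") from None


@dataclass
class AgentParams:
    """A parameter vector for one model variant.

    ``kappa_weights`` are ordered to match the spec's kappa predictors;
    ``eta`` must be None for specs without associability.
    """

    beta: float
    play_bias: float
    kappa_weights: tuple[float, ...]
    eta: float | None = None

    def to_vector(self, spec: ModelSpec) -> np.ndarray:
        if len(self.kappa_weights) != len(spec.kappa_predictors):
            raise ValueError(
                f"{spec.name} needs {len(spec.kappa_predictors)} kappa weights, "
                f"got {len(self.kappa_weights)}"
            )
        vec = [self.beta, self.play_bias, *self.kappa_weights]
        if spec.uses_associability:
            if self.eta is None:
                raise ValueError(f"{spec.name} requires eta")
            vec.append(self.eta)
        return np.asarray(vec, dtype=float)

    @classmethod
    def from_vector(cls, vec: np.ndarray, spec: ModelSpec) -> "AgentParams":
        vec = np.asarray(vec, dtype=float)
        if vec.size != spec.n_params:
            raise ValueError(f"{spec.name} expects {spec.n_params} parameters, got {vec.size}")
        n_k = len(spec.kappa_predictors)
        return cls(
            beta=float(vec[0]),
            play_bias=float(vec[1]),
            kappa_weights=tuple(float(v) for v in vec[2 : 2 + n_k]),
            eta=float(vec[2 + n_k]) if spec.uses_associability else None,
        )

    def as_dict(self, spec: ModelSpec) -> dict[str, float]:
        return dict(zip(spec.param_names, self.to_vector(spec)))


def logistic(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def classify_feedback(action: str, outcome_valence: str) -> tuple[str, str]:
    """Feedback modality and confirmatory status of one trial.

    Feedback is factual on a play and counterfactual on a pass;
    confirmatory feedback is a factual win or a counterfactual loss.
    """
    if action not in ("play", "pass"):
        raise ValueError(f"action must be 'play' or 'pass', got {action!r}")
    if outcome_valence not in ("win", "loss"):
        raise ValueError(f"valence must be 'win' or 'loss', got {outcome_valence!r}")
    modality = "factual" if action == "play" else "counterfactual"
    confirmatory = (modality == "factual") == (outcome_valence == "win")
    return modality, ("confirmatory" if confirmatory else "disconfirmatory")


def kappa(params: AgentParams, features) -> float:
    """Logistic learning-rate scale from the weighted predictor vector."""
    features = np.asarray(features, dtype=float)
    weights = np.asarray(params.kappa_weights, dtype=float)
    if features.shape != weights.shape:
        raise ValueError(f"feature/weight length mismatch: {features.shape} vs {weights.shape}")
    return float(logistic(weights @ features))


def update_associability(A: float, delta: float, eta: float) -> float:
    """Pearce-Hall associability update, |delta| capped at 1."""
    return eta * min(abs(delta), 1.0) + (1.0 - eta) * A


def update_value(Q: float, alpha: float, R: float) -> tuple[float, float]:
    """Delta-rule value update; returns (Q', delta)."""
    delta = R - Q
    return Q + alpha * delta, delta


def choice_probability(Q: float, play_bias: float, beta: float) -> float:
    """Softmax probability of playing, with the pass value fixed at 0."""
    return float(logistic(beta * (play_bias + Q)))


def _feature_codes(dataset: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    conf = np.where(dataset["confirmatory"].to_numpy(), 0.5, -0.5)
    mod = np.where(dataset["modality"].to_numpy() == "factual", 0.5, -0.5)
    return conf, mod


def _kernel_args(params: AgentParams, spec: ModelSpec):
    weights = dict(zip(spec.kappa_predictors, params.kappa_weights))
    return (
        float(params.beta),
        float(params.play_bias),
        float(weights["intercept"]),
        float(weights.get("confirmatory", 0.0)),
        float(weights.get("modality", 0.0)),
        float(params.eta) if params.eta is not None else 0.0,
        spec.uses_associability,
        "confirmatory" in spec.kappa_predictors,
        "modality" in spec.kappa_predictors,
    )


def simulate_agent(
    params: AgentParams,
    spec: str | ModelSpec,
    schedule: pd.DataFrame,
    seed: int,
    points_per_outcome: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one agent playing a schedule with pre-drawn outcomes.

    Returns ``(dataset, latents)``.  The dataset is the schedule plus the
    agent's actions, feedback modality/confirmatory flags, the internal
    reward signal ``R`` in {+1,-1} and the realized ``points``; its
    ``attrs['total_points']`` holds the final score (points accrue on play
    trials only).  The latents frame stores per-trial Q, delta,
    associability A, learning rate alpha and p_play.
    """
    spec = get_spec(spec)
    rng = np.random.default_rng(seed)
    stim = schedule["stimulus"].to_numpy(dtype=np.int64)
    n_stimuli = int(stim.max()) + 1
    reward = np.where(schedule["outcome_valence"].to_numpy() == "win", 1.0, -1.0)
    uniforms = rng.random(len(schedule))

    n = len(schedule)
    action = np.empty(n, dtype=np.int64)
    conf = np.empty(n)
    mod = np.empty(n)
    q = np.empty(n)
    delta = np.empty(n)
    assoc = np.empty(n)
    alpha = np.empty(n)
    p_play = np.empty(n)
    total_r = simulate_kernel(
        stim,
        reward,
        uniforms,
        n_stimuli,
        *_kernel_args(params, spec),
        action,
        conf,
        mod,
        q,
        delta,
        assoc,
        alpha,
        p_play,
    )

    dataset = schedule.copy()
    dataset["action"] = np.where(action == 1, "play", "pass")
    dataset["modality"] = np.where(action == 1, "factual", "counterfactual")
    dataset["confirmatory"] = conf > 0
    dataset["R"] = reward
    dataset["points"] = np.where(action == 1, reward * points_per_outcome, 0.0)
    dataset.attrs = dict(schedule.attrs)
    dataset.attrs["total_points"] = float(total_r * points_per_outcome)
    latents = pd.DataFrame(
        {
            "trial": schedule["trial"].to_numpy(),
            "stimulus": stim,
            "Q": q,
            "delta": delta,
            "A": assoc,
            "alpha": alpha,
            "p_play": p_play,
        }
    )
    return dataset, latents


DEFAULT_PRIOR_SCALE = 10.0  # SD of the Normal prior on unbounded parameters


def log_prior(params: AgentParams, spec: ModelSpec, scale: float = DEFAULT_PRIOR_SCALE) -> float:
    """Weak priors making MAP a lightly regularized MLE.

    Normal(0, scale^2) on play bias and kappa weights, uniform on the
    bounded beta range, and Beta(2, 2) on eta.  The Beta prior is the one
    consequential choice: the eta likelihood is shallow, and without mild
    shrinkage estimates pile up on the 0/1 bounds, degrading parameter
    recovery; inside (0, 1) it is nearly flat and leaves well-identified
    estimates in place.
    """
    unbounded = np.array([params.play_bias, *params.kappa_weights])
    lp = -0.5 * np.sum((unbounded / scale) ** 2) - unbounded.size * np.log(
        scale * np.sqrt(2 * np.pi)
    )
    if params.eta is not None:
        e = min(max(params.eta, 1e-9), 1.0 - 1e-9)
        lp += np.log(6.0) + np.log(e) + np.log(1.0 - e)  # Beta(2,2) density
    return float(lp)


def log_likelihood(
    params: AgentParams,
    spec: str | ModelSpec,
    dataset: pd.DataFrame,
    return_latents: bool = False,
):
    """Choice log-likelihood under the model, replaying the dataset's
    actions and outcomes through the identical latent recursion used by
    :func:`simulate_agent`."""
    spec = get_spec(spec)
    stim = dataset["stimulus"].to_numpy(dtype=np.int64)
    n_stimuli = int(stim.max()) + 1
    action = (dataset["action"].to_numpy() == "play").astype(np.int64)
    if "R" in dataset.columns:
        reward = dataset["R"].to_numpy(dtype=float)
    else:
        reward = np.where(dataset["outcome_valence"].to_numpy() == "win", 1.0, -1.0)
    conf, mod = _feature_codes(dataset)

    n = len(dataset)
    q = np.empty(n)
    delta = np.empty(n)
    assoc = np.empty(n)
    alpha = np.empty(n)
    p_play = np.empty(n)
    ll = loglik_kernel(
        stim,
        action,
        reward,
        conf,
        mod,
        n_stimuli,
        *_kernel_args(params, spec),
        q,
        delta,
        assoc,
        alpha,
        p_play,
    )
    if not return_latents:
        return float(ll)
    latents = pd.DataFrame(
        {
            "trial": np.arange(1, n + 1) if "trial" not in dataset else dataset["trial"].to_numpy(),
            "stimulus": stim,
            "Q": q,
            "delta": delta,
            "A": assoc,
            "alpha": alpha,
            "p_play": p_play,
        }
    )
    return float(ll), latents


def negative_log_posterior(
    params: AgentParams | np.ndarray,
    spec: str | ModelSpec,
    dataset: pd.DataFrame,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> float:
    """-(choice log-likelihood + log prior); the MAP objective.

    Finite for all in-bounds parameters thanks to the probability floor
    of ``1e-12`` inside the log.
    """
    spec = get_spec(spec)
    if not isinstance(params, AgentParams):
        params = AgentParams.from_vector(np.asarray(params), spec)
    ll = log_likelihood(params, spec, dataset)
    return -(ll + log_prior(params, spec, prior_scale))


def prepare_dataset(dataset: pd.DataFrame) -> pd.DataFrame:
    """Fill modality/confirmatory/R columns from action and valence.

    Used when loading external trial logs that carry only the observables
    (stimulus, action, outcome_valence).
    """
    out = dataset.copy()
    play = out["action"] == "play"
    win = out["outcome_valence"] == "win"
    out["modality"] = np.where(play, "factual", "counterfactual")
    out["confirmatory"] = play == win
    out["R"] = np.where(win, 1.0, -1.0)
    return out
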