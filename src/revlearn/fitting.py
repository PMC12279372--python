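"""MAP estimation, BIC, and random-effects Bayesian model selection.

Per-subject parameters are estimated by maximum a posteriori with a
multi-start bounded local search (L-BFGS-B).  Models are compared with the
Bayesian information criterion, and at the group level with the standard
variational random-effects scheme over model frequencies: a Dirichlet
posterior on frequencies, exceedance probabilities by Monte-Carlo Dirichlet
sampling, and protected exceedance probabilities that discount the
exceedance by the Bayes omnibus risk (the posterior probability that all
models are equally frequent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma, gammaln, logsumexp

from .models import AgentParams, ModelSpec, get_spec, log_likelihood, negative_log_posterior

DEFAULT_BOUNDS = {
    "beta": (0.0, 10.0),
    "play_bias": (-3.0, 3.0),
    "kappa_intercept": (-10.0, 10.0),
    "kappa_confirmatory": (-10.0, 10.0),
    "kappa_modality": (-10.0, 10.0),
    "eta": (0.0, 1.0),
}


@dataclass
class FitResult:
    subject: object
    model: str
    params: AgentParams
    log_posterior: float
    log_likelihood: float
    n_trials: int
    bic: float
    n_starts: int
    best_start_index: int
    converged: bool

    def params_dict(self) -> dict[str, float]:
        return self.params.as_dict(get_spec(self.model))


def bic(log_likelihood: float, n_params: int, n_trials: int) -> float:
    """k*ln(n) - 2*lnL."""
    return n_params * np.log(n_trials) - 2.0 * log_likelihood


def spec_bounds(spec: ModelSpec, bounds: dict | None = None) -> list[tuple[float, float]]:
    table = dict(DEFAULT_BOUNDS)
    if bounds:
        table.update(bounds)
    return [table[name] for name in spec.param_names]


def fit_map(
    dataset: pd.DataFrame,
    spec: str | ModelSpec,
    n_starts: int = 10,
    bounds: dict | None = None,
    seed: int | None = None,
    subject=None,
    prior_scale: float = 10.0,
) -> FitResult:
    """Multi-start bounded MAP fit of one model to one subject's choices.

    Runs ``n_starts`` L-BFGS-B optimizations from random in-bounds initial
    points (deterministic given ``seed``) and keeps the best.  If no start
    converges the best point found is still returned with
    ``converged=False`` rather than raising.
    """
    spec = get_spec(spec)
    if len(dataset) == 0:
        raise ValueError("cannot fit an empty dataset")
    box = spec_bounds(spec, bounds)
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])

    def objective(vec):
        return negative_log_posterior(vec, spec, dataset, prior_scale)

    best = None
    best_idx = -1
    any_success = False
    for i in range(n_starts):
        x0 = lo + rng.random(len(box)) * (hi - lo)
        res = minimize(objective, x0, method="L-BFGS-B", bounds=box)
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
            best_idx = i

    params = AgentParams.from_vector(best.x, spec)
    ll = log_likelihood(params, spec, dataset)
    return FitResult(
        subject=subject,
        model=spec.name,
        params=params,
        log_posterior=-float(best.fun),
        log_likelihood=float(ll),
        n_trials=len(dataset),
        bic=float(bic(ll, spec.n_params, len(dataset))),
        n_starts=n_starts,
        best_start_index=best_idx,
        converged=any_success,
    )


def fits_to_frame(fits) -> pd.DataFrame:
    """Cohort-level table: one row per fit with parameters, lnL and BIC."""
    rows = []
    for f in fits:
        row = {"subject": f.subject, "model": f.model}
        row.update(f.params_dict())
        row.update(
            log_likelihood=f.log_likelihood,
            log_posterior=f.log_posterior,
            bic=f.bic,
            n_trials=f.n_trials,
            converged=f.converged,
        )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class BMSResult:
    models: tuple[str, ...]
    dirichlet_alpha: np.ndarray
    expected_frequencies: np.ndarray
    exceedance: np.ndarray
    bor: float
    pxp: np.ndarray
    responsibilities: np.ndarray = field(repr=False, default=None)


def evidence_from_bic(bic_matrix: np.ndarray) -> np.ndarray:
    """-0.5*BIC as the per-subject log model evidence proxy."""
    return -0.5 * np.asarray(bic_matrix, dtype=float)


def bms(
    log_evidence: np.ndarray,
    models: tuple[str, ...] | None = None,
    alpha0: float = 1.0,
    n_samples: int = 100_000,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> BMSResult:
    """Random-effects Bayesian model selection over a subjects x models
    log-evidence matrix.

    Variational updates of the Dirichlet frequency posterior are iterated
    to convergence; exceedance probabilities are estimated by seeded
    Monte-Carlo Dirichlet sampling; the Bayes omnibus risk compares the
    free energy of the frequency model against the equal-frequency null,
    and pxp = (1 - bor) * exceedance + bor / K.
    """
    L = np.asarray(log_evidence, dtype=float)
    if L.ndim != 2 or L.shape[1] < 2:
        raise ValueError("need a subjects x models matrix with >= 2 models")
    if not np.all(np.isfinite(L)):
        raise ValueError("log evidence must be finite")
    n_sub, n_mod = L.shape
    if models is None:
        models = tuple(f"model_{k}" for k in range(n_mod))

    alpha = np.full(n_mod, alpha0, dtype=float)
    for _ in range(max_iter):
        e_log_r = digamma(alpha) - digamma(alpha.sum())
        log_u = L + e_log_r
        g = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
        new_alpha = alpha0 + g.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    e_log_r = digamma(alpha) - digamma(alpha.sum())
    log_u = L + e_log_r
    g = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))

    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    xp = np.bincount(winners, minlength=n_mod) / n_samples

    bor = _bayes_omnibus_risk(L, g, alpha, alpha0)
    pxp = (1.0 - bor) * xp + bor / n_mod
    return BMSResult(
        models=tuple(models),
        dirichlet_alpha=alpha,
        expected_frequencies=alpha / alpha.sum(),
        exceedance=xp,
        bor=float(bor),
        pxp=pxp,
        responsibilities=g,
    )


def _bayes_omnibus_risk(L, g, alpha, alpha0) -> float:
    """Posterior probability of the equal-frequency null model.

    F1 is the converged variational free energy of the random-effects
    model; F0 that of the null in which every model has frequency 1/K.
    """
    n_sub, n_mod = L.shape
    alpha0_vec = np.full(n_mod, alpha0, dtype=float)
    e_log_r = digamma(alpha) - digamma(alpha.sum())
    # KL( Dir(alpha) || Dir(alpha0) )
    kl = (
        gammaln(alpha.sum())
        - gammaln(alpha).sum()
        - gammaln(alpha0_vec.sum())
        + gammaln(alpha0_vec).sum()
        + ((alpha - alpha0_vec) * e_log_r).sum()
    )
    g_safe = np.clip(g, 1e-300, 1.0)
    f1 = (g * (L + e_log_r[None, :] - np.log(g_safe))).sum() - kl
    f0 = logsumexp(L - np.log(n_mod), axis=1).sum()
    return float(1.0 / (1.0 + np.exp(f1 - f0)))


def posterior_predictive(
    fit: FitResult,
    schedule: pd.DataFrame,
    n_agents: int = 100,
    seed: int | None = None,
    window: int = 30,
    smooth: int = 2,
) -> pd.DataFrame:
    """Simulate agents at a subject's MAP parameters and average their
    reversal-aligned accuracy curves by outcome-noise level."""
    from .analysis import reversal_curves
    from .models import simulate_agent

    rng = np.random.default_rng(seed)
    sims = []
    for _ in range(n_agents):
        dataset, _ = simulate_agent(fit.params, fit.model, schedule, seed=int(rng.integers(2**31)))
        sims.append(dataset)
    return reversal_curves(sims, window=window, smooth=smooth)
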