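"""Synthetic participant cohorts with known ground truth.

Generates labelled cohorts of simulated agents in a (baseline-performance
group) x (drug session) design so that fitting, model selection and the
group-level analyses can be exercised end to end.  The drug manipulation
is modelled as a within-subject shift of eta only — the empirical group
anchors are eta 0.33 (low performers, placebo) -> 0.24 (drug) and 0.26
(high performers, placebo) -> 0.23 — while the remaining parameters
differ between groups (higher inverse temperature and lower play bias in
high performers) but are shared across a subject's two sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import DEFAULT_BOUNDS, fit_map
from .models import AgentParams, ModelSpec, get_spec, simulate_agent


@dataclass(frozen=True)
class ParamDist:
    """A truncated-normal parameter distribution."""

    mean: float
    sd: float
    bounds: tuple[float, float]

    def draw(self, rng: np.random.Generator) -> float:
        return float(np.clip(rng.normal(self.mean, self.sd), *self.bounds))


# Inverse temperature, play bias and eta anchors are the reported group
# means; between-subject SDs follow the generator convention
# SD ~ SEM * sqrt(47) applied to the reported group SEMs.  Kappa-weight
# anchors are generator choices that reproduce the group phenotypes: low
# performers learn from confirmatory and disconfirmatory feedback alike
# (and are therefore exposed to misleading outcomes, making eta
# consequential), high performers are confirmation-biased and shielded
# (late-stage high-noise accuracy ~0.70 vs ~0.78, low-group-specific
# sensitivity to the eta shift).
DEFAULT_GROUPS: dict[str, dict] = {
    "low": {
        "beta": ParamDist(2.11, 0.55, DEFAULT_BOUNDS["beta"]),
        "play_bias": ParamDist(0.04, 0.21, DEFAULT_BOUNDS["play_bias"]),
        "kappa_intercept": ParamDist(0.5, 0.3, DEFAULT_BOUNDS["kappa_intercept"]),
        "kappa_confirmatory": ParamDist(2.0, 0.4, DEFAULT_BOUNDS["kappa_confirmatory"]),
        "eta": {"placebo": 0.33, "drug": 0.24, "sd": 0.07},
    },
    "high": {
        "beta": ParamDist(2.97, 0.34, DEFAULT_BOUNDS["beta"]),
        "play_bias": ParamDist(-0.01, 0.07, DEFAULT_BOUNDS["play_bias"]),
        "kappa_intercept": ParamDist(-0.5, 0.3, DEFAULT_BOUNDS["kappa_intercept"]),
        "kappa_confirmatory": ParamDist(3.0, 0.4, DEFAULT_BOUNDS["kappa_confirmatory"]),
        "eta": {"placebo": 0.26, "drug": 0.23, "sd": 0.07},
    },
}

SESSIONS = ("placebo", "drug")


@dataclass
class CohortSpec:
    n_per_group: int = 30
    model: str | ModelSpec = "M3"
    groups: dict = field(default_factory=lambda: DEFAULT_GROUPS)
    sessions: tuple[str, ...] = SESSIONS
    eta_session_jitter: float = 0.02
    seed: int = 0


def _draw_subject_params(
    group_cfg: dict, spec: ModelSpec, rng: np.random.Generator, sessions
) -> dict[str, AgentParams]:
    """Paired draws: one base vector per subject, eta shifted per session.

    The subject's deviation from the placebo eta mean is preserved across
    sessions (plus a small session jitter), implementing the
    within-subject design.
    """
    base = {}
    for name in spec.param_names:
        if name == "eta":
            continue
        if name not in group_cfg:
            raise ValueError(f"group distribution missing parameter {name!r}")
        base[name] = group_cfg[name].draw(rng)
    eta_cfg = group_cfg["eta"]
    lo, hi = DEFAULT_BOUNDS["eta"]
    eta_dev = rng.normal(0.0, eta_cfg["sd"])
    out = {}
    for session in sessions:
        eta = None
        if spec.uses_associability:
            eta = float(np.clip(eta_cfg[session] + eta_dev, lo, hi))
        kappa_weights = tuple(base[f"kappa_{p}"] for p in spec.kappa_predictors)
        out[session] = AgentParams(base["beta"], base["play_bias"], kappa_weights, eta)
    return out


def generate_cohort(spec: CohortSpec, schedule: pd.DataFrame):
    """Simulate a full cohort on a schedule.

    Returns ``(datasets, truth)``: a dict keyed by (subject, group,
    session) holding (dataset, latents) pairs, and a ground-truth
    DataFrame with one row per subject-session (true parameters, group
    labels, realized total points).  Outcome valences are redrawn per
    subject; a subject's two sessions share outcome and choice random
    streams, so the within-subject contrast isolates the eta shift.
    Deterministic given ``spec.seed``.
    """
    from .task import draw_outcomes

    model = get_spec(spec.model)
    rng = np.random.default_rng(spec.seed)
    datasets = {}
    truth_rows = []
    subject = 0
    for group, group_cfg in spec.groups.items():
        for _ in range(spec.n_per_group):
            per_session = _draw_subject_params(group_cfg, model, rng, spec.sessions)
            if spec.eta_session_jitter and model.uses_associability:
                lo, hi = DEFAULT_BOUNDS["eta"]
                for session, params in per_session.items():
                    params.eta = float(
                        np.clip(params.eta + rng.normal(0, spec.eta_session_jitter), lo, hi)
                    )
            # common random numbers across a subject's sessions: the paired
            # within-subject contrast then isolates the session's eta shift
            outcome_seed = int(rng.integers(2**31))
            agent_seed = int(rng.integers(2**31))
            for session, params in per_session.items():
                sched = draw_outcomes(schedule, seed=outcome_seed)
                dataset, latents = simulate_agent(params, model, sched, seed=agent_seed)
                datasets[(subject, group, session)] = (dataset, latents)
                row = {
                    "subject": subject,
                    "group": group,
                    "session": session,
                    "model": model.name,
                    "total_points": dataset.attrs["total_points"],
                }
                row.update(params.as_dict(model))
                truth_rows.append(row)
            subject += 1
    return datasets, pd.DataFrame(truth_rows)


def fit_cohort(
    datasets: dict,
    model: str | ModelSpec,
    n_starts: int = 10,
    seed: int | None = None,
) -> list:
    """MAP-fit one model to every dataset of a cohort."""
    rng = np.random.default_rng(seed)
    fits = []
    for key, (dataset, _latents) in datasets.items():
        fits.append(
            fit_map(dataset, model, n_starts=n_starts, seed=int(rng.integers(2**31)), subject=key)
        )
    return fits


def recovery_report(truth: pd.DataFrame, fits) -> pd.DataFrame:
    """Per-parameter recovery table: Pearson r, mean signed error, RMSE.

    ``fits`` must cover exactly the rows of ``truth`` (matched on the
    (subject, group, session) key used by :func:`generate_cohort`).
    """
    from .fitting import fits_to_frame

    fit_frame = fits_to_frame(fits)
    keys = pd.DataFrame(
        fit_frame["subject"].tolist(), columns=["subject", "group", "session"]
    )
    fit_frame = pd.concat([keys, fit_frame.drop(columns="subject")], axis=1)
    merged = truth.merge(
        fit_frame, on=["subject", "group", "session"], suffixes=("_true", "_fit")
    )
    if len(merged) != len(truth):
        raise ValueError("fits do not cover all ground-truth rows")
    spec = get_spec(truth["model"].iloc[0])
    rows = []
    for name in spec.param_names:
        t = merged[f"{name}_true"].to_numpy(dtype=float)
        f = merged[f"{name}_fit"].to_numpy(dtype=float)
        r = np.nan
        if np.std(t) > 0 and np.std(f) > 0:
            r = float(np.corrcoef(t, f)[0, 1])
        rows.append(
            {
                "parameter": name,
                "pearson_r": r,
                "bias": float(np.mean(f - t)),
                "rmse": float(np.sqrt(np.mean((f - t) ** 2))),
            }
        )
    return pd.DataFrame(rows)


def model_confusion(datasets_by_model: dict, candidate_models, n_starts: int = 5, seed=None):
    """Model-recovery confusion matrix.

    ``datasets_by_model`` maps a generating model name to a list of
    datasets; each dataset is fit with every candidate and assigned to the
    lowest-BIC one.  Rows are generating models, columns selected models.
    """
    rng = np.random.default_rng(seed)
    candidates = [get_spec(m).name for m in candidate_models]
    counts = pd.DataFrame(0, index=list(datasets_by_model), columns=candidates)
    for gen_name, ds_list in datasets_by_model.items():
        for dataset in ds_list:
            bics = {}
            for cand in candidates:
                fit = fit_map(dataset, cand, n_starts=n_starts, seed=int(rng.integers(2**31)))
                bics[cand] = fit.bic
            counts.loc[gen_name, min(bics, key=bics.get)] += 1
    return counts
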