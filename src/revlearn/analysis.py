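"""Descriptive and model-derived analyses of reversal-learning behavior.

Covers the reversal-aligned learning curves, structural-break segmentation
of the group curve into early/late learning stages, learning-rate
variability, the signal-to-noise contrast between updating after true
reversals and after late misleading feedback, accuracy after double
misleading feedback, the parameter-to-performance regression, and the
eta-sweep simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .models import AgentParams, get_spec, simulate_agent
from .task import label_misleading


def correct_choice(dataset: pd.DataFrame) -> pd.Series:
    """1.0 for playing a good stimulus or passing a bad one, 0.0 for the
    opposite, NaN on neutral (50%) stimuli where 'correct' is undefined."""
    play = dataset["action"] == "play"
    out = pd.Series(np.nan, index=dataset.index, dtype=float)
    good = dataset["label"] == "good"
    bad = dataset["label"] == "bad"
    out[good] = play[good].astype(float)
    out[bad] = (~play[bad]).astype(float)
    return out


def smooth_curve(values: np.ndarray, half_width: int = 2) -> np.ndarray:
    """Running mean with +-half_width trials, shrinking at the edges."""
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    for i in range(values.size):
        lo = max(0, i - half_width)
        window = values[lo : i + half_width + 1]
        out[i] = np.nanmean(window) if np.any(np.isfinite(window)) else np.nan
    return out


def reversal_curves(
    datasets, window: int = 30, smooth: int = 2, include_all: bool = True
) -> pd.DataFrame:
    """Mean probability-correct per trials-since-reversal position.

    Only post-reversal blocks contribute; neutral stimuli are excluded.
    Per-dataset curves are averaged across datasets and split by the
    outcome-noise level of the new contingency; the +-``smooth`` running
    mean is applied last.  Rows are positions 1..window; columns are noise
    levels (plus 'all').
    """
    datasets = list(datasets)
    min_block = min(
        int(d.loc[d["block"] > 1].groupby(["stimulus", "block"]).size().min()) for d in datasets
    )
    if window > min_block:
        warnings.warn(
            f"window {window} exceeds the shortest post-reversal block "
            f"({min_block} trials); positions beyond it average fewer blocks",
            stacklevel=2,
        )
    per_dataset = []
    for d in datasets:
        sel = (d["block"] > 1) & (d["trials_since_reversal"] <= window)
        sub = d.loc[sel].copy()
        sub["correct"] = correct_choice(sub)
        sub = sub.dropna(subset=["correct"])
        by_noise = sub.groupby(["noise_level", "trials_since_reversal"])["correct"].mean()
        frame = by_noise.unstack("noise_level")
        if include_all:
            frame["all"] = sub.groupby("trials_since_reversal")["correct"].mean()
        per_dataset.append(frame.reindex(np.arange(1, window + 1)))
    mean_curve = pd.concat(per_dataset).groupby(level=0).mean()
    mean_curve = mean_curve.reindex(np.arange(1, window + 1))
    mean_curve.index.name = "trials_since_reversal"
    if smooth:
        for col in mean_curve.columns:
            mean_curve[col] = smooth_curve(mean_curve[col].to_numpy(), smooth)
    return mean_curve


# ---------------------------------------------------------------------------
# structural breaks


@dataclass
class BreakResult:
    n_breaks: int
    break_positions: list[int]
    segment_fits: list[dict]
    criterion: float
    flagged: bool = False
    note: str = ""


def _segment_costs(y: np.ndarray, min_seg: int) -> np.ndarray:
    """SSE of an intercept+slope OLS fit on every admissible segment."""
    n = y.size
    x = np.arange(n, dtype=float)
    cost = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(i + min_seg - 1, n):
            ys = y[i : j + 1]
            xs = x[i : j + 1]
            xc = xs - xs.mean()
            yc = ys - ys.mean()
            sxx = (xc * xc).sum()
            sxy = (xc * yc).sum()
            syy = (yc * yc).sum()
            cost[i, j] = syy - (sxy * sxy / sxx if sxx > 0 else 0.0)
    return cost


def _segmentation_criterion(sse: float, n: int, m: int) -> float:
    """Modified Schwarz (LWZ) criterion for the number of breaks.

    Counts 2 regression parameters per segment plus one per break
    position, with the inflated penalty 0.299*(ln n)^2.1 per parameter
    that compensates for optimizing the break placement before
    penalizing — a plain BIC over-reports breaks on pure-noise curves.
    """
    p = 2 * (m + 1) + m
    return float(
        np.log(max(sse, 1e-12) / max(n - p, 1)) + p * 0.299 * np.log(n) ** 2.1 / n
    )


def detect_breaks(curve, min_seg: int = 5, max_breaks: int | None = None) -> BreakResult:
    """Segmented least-squares break detection on a learning curve.

    Dynamic programming finds, for every admissible break count m (each
    segment at least ``min_seg`` points, at most floor(n/min_seg)-1
    breaks), the exact best placement under per-segment intercept+slope
    OLS; the break count is then selected by the modified Schwarz
    criterion.  Break positions are
    1-based indices of the last point of each segment.
    """
    y = np.asarray(curve, dtype=float)
    n = y.size
    hard_max = n // min_seg - 1
    if hard_max < 1:
        return BreakResult(0, [], [], np.nan, flagged=True, note="curve too short for any break")
    if max_breaks is None:
        max_breaks = hard_max
    max_breaks = min(max_breaks, hard_max)

    cost = _segment_costs(y, min_seg)
    # best[m][j]: min SSE splitting y[0..j] into m+1 segments; arg for backtrack
    best = np.full((max_breaks + 1, n), np.inf)
    arg = np.full((max_breaks + 1, n), -1, dtype=int)
    best[0] = cost[0]
    for m in range(1, max_breaks + 1):
        for j in range((m + 1) * min_seg - 1, n):
            starts = np.arange(m * min_seg, j - min_seg + 2)
            totals = best[m - 1, starts - 1] + cost[starts, j]
            k = int(np.argmin(totals))
            best[m, j] = totals[k]
            arg[m, j] = starts[k]

    crits = [_segmentation_criterion(best[m, n - 1], n, m) for m in range(max_breaks + 1)]
    m_star = int(np.argmin(crits))

    breaks = []
    j = n - 1
    for m in range(m_star, 0, -1):
        start = int(arg[m, j])
        breaks.append(start)  # 1-based last index of the previous segment
        j = start - 1
    breaks = sorted(breaks)

    bounds = [0] + breaks + [n]
    fits = []
    x = np.arange(n, dtype=float)
    for a, b in zip(bounds[:-1], bounds[1:]):
        xs, ys = x[a:b], y[a:b]
        slope, intercept = np.polyfit(xs, ys, 1) if xs.size > 1 else (0.0, float(ys[0]))
        fits.append(
            {
                "start": a + 1,
                "end": b,
                "intercept": float(intercept),
                "slope": float(slope),
                "mean": float(ys.mean()),
            }
        )
    return BreakResult(m_star, breaks, fits, float(crits[m_star]))


def stage_split(result: BreakResult, window: int) -> tuple[np.ndarray, np.ndarray, bool]:
    """Early/late position sets from the first detected break.

    ``early`` is positions 1..b and ``late`` b+1..window.  Degenerate
    results (no break, or a break at the window end) are flagged.
    """
    positions = np.arange(1, window + 1)
    if result.n_breaks == 0:
        return positions[:0], positions, True
    b = result.break_positions[0]
    early, late = positions[positions <= b], positions[positions > b]
    return early, late, late.size == 0


# ---------------------------------------------------------------------------
# learning-rate dynamics


def _stage_mask(dataset: pd.DataFrame, stage: str, break_pos: int, window: int) -> pd.Series:
    pos = dataset["trials_since_reversal"]
    post = (dataset["block"] > 1) & (pos <= window)
    if stage == "early":
        return post & (pos <= break_pos)
    if stage == "late":
        return post & (pos > break_pos)
    if stage == "all":
        return post
    raise ValueError(f"stage must be 'early', 'late' or 'all', got {stage!r}")


def lr_variability(
    dataset: pd.DataFrame,
    latents: pd.DataFrame,
    stage: str = "all",
    break_pos: int = 10,
    window: int = 30,
    noise: str | None = None,
) -> float:
    """Population SD of the trial-wise learning rate within a stage.

    The dataset and its latent trajectory are aligned row-wise; ``noise``
    optionally restricts to one outcome-noise level.
    """
    mask = _stage_mask(dataset, stage, break_pos, window).to_numpy()
    if noise is not None:
        mask &= (dataset["noise_level"] == noise).to_numpy()
    alpha = latents["alpha"].to_numpy()[mask]
    return float(np.std(alpha)) if alpha.size else float("nan")


def snr(
    dataset: pd.DataFrame,
    latents: pd.DataFrame,
    peak_window: int = 5,
    late_start: int = 11,
) -> float:
    """Learning-rate signal-to-noise contrast.

    Signal: mean over reversals of the peak learning rate within the first
    ``peak_window`` encounters of the reversed stimulus.  Noise: mean over
    late-stage misleading-feedback events of the peak learning rate over
    the next ``peak_window`` encounters of that stimulus.  Returns
    signal - noise (NaN, with a warning, if no late misleading event has a
    following encounter).
    """
    frame = pd.DataFrame(
        {
            "stimulus": dataset["stimulus"].to_numpy(),
            "block": dataset["block"].to_numpy(),
            "pos": dataset["trials_since_reversal"].to_numpy(),
            "alpha": latents["alpha"].to_numpy(),
            "misleading": label_misleading(dataset).to_numpy(),
        }
    )
    signal_peaks = []
    noise_peaks = []
    for (_, block), grp in frame.groupby(["stimulus", "block"]):
        alpha = grp["alpha"].to_numpy()
        pos = grp["pos"].to_numpy()
        mis = grp["misleading"].to_numpy()
        if block > 1:
            signal_peaks.append(alpha[pos <= peak_window].max())
        for i in np.flatnonzero(mis & (pos >= late_start)):
            tail = alpha[i + 1 : i + 1 + peak_window]
            if tail.size:
                noise_peaks.append(tail.max())
    if not signal_peaks:
        warnings.warn("no reversals in dataset; SNR undefined", stacklevel=2)
        return float("nan")
    if not noise_peaks:
        warnings.warn("no late-stage misleading feedback events; SNR undefined", stacklevel=2)
        return float("nan")
    return float(np.mean(signal_peaks) - np.mean(noise_peaks))


def double_misleading_accuracy(
    dataset: pd.DataFrame, late_start: int = 11
) -> tuple[float, int]:
    """P(correct next choice | two consecutive late misleading feedbacks).

    Events are two consecutive encounters of the same 30/70% stimulus in
    the late stage of a block that both carry misleading feedback; the
    outcome is whether the *next* encounter of that stimulus is a correct
    choice.  Returns (probability, n_events); probability is NaN when no
    event qualifies.
    """
    frame = dataset.copy()
    frame["correct"] = correct_choice(frame)
    frame["misleading"] = label_misleading(frame)
    hits = []
    high = frame.loc[frame["noise_level"] == "high"]
    for (_, _), grp in high.groupby(["stimulus", "block"]):
        mis = grp["misleading"].to_numpy()
        pos = grp["trials_since_reversal"].to_numpy()
        corr = grp["correct"].to_numpy()
        for i in range(len(grp) - 2):
            if mis[i] and mis[i + 1] and pos[i] >= late_start and pos[i + 1] >= late_start:
                hits.append(corr[i + 2])
    if not hits:
        warnings.warn("no double-misleading events found", stacklevel=2)
        return float("nan"), 0
    return float(np.nanmean(hits)), len(hits)


# ---------------------------------------------------------------------------
# parameters -> performance


def performance_glm(param_matrix: pd.DataFrame, scores, conf_level: float = 0.95) -> pd.DataFrame:
    """OLS of task performance on z-scored parameter estimates.

    Returns one row per predictor (plus the intercept) with the
    coefficient, normal-theory confidence interval and p-value.  Raises on
    rank deficiency, naming the collinear columns.
    """
    X = param_matrix.astype(float)
    y = np.asarray(scores, dtype=float)
    sds = X.std(ddof=0)
    degenerate = list(sds.index[sds == 0])
    if degenerate:
        raise ValueError(f"constant (zero-variance) predictor columns: {degenerate}")
    Z = (X - X.mean()) / sds
    if np.linalg.matrix_rank(Z.to_numpy()) < Z.shape[1]:
        corr = Z.corr().abs()
        pairs = [
            (a, b)
            for a, b in combinations(Z.columns, 2)
            if corr.loc[a, b] > 1 - 1e-10
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {pairs}")
    model = sm.OLS(y, sm.add_constant(Z)).fit()
    ci = model.conf_int(alpha=1 - conf_level)
    return pd.DataFrame(
        {
            "coef": model.params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "pvalue": model.pvalues,
        }
    )


def eta_sweep(
    base_params: AgentParams,
    spec,
    schedule: pd.DataFrame,
    eta_grid,
    n_agents: int = 1000,
    seed: int | None = None,
    points_per_outcome: int = 10,
) -> pd.DataFrame:
    """Mean total points as a function of the associability step size eta.

    Simulates ``n_agents`` agents per grid value with all other parameters
    held at ``base_params``.  The returned frame carries the argmax eta in
    ``attrs['best_eta']``.
    """
    spec = get_spec(spec)
    if not spec.uses_associability:
        raise ValueError("eta sweep requires a model with associability (M2-M4)")
    rng = np.random.default_rng(seed)
    rows = []
    for eta in np.asarray(eta_grid, dtype=float):
        if not 0.0 <= eta <= 1.0:
            raise ValueError(f"eta must lie in [0, 1], got {eta}")
        params = AgentParams(base_params.beta, base_params.play_bias, base_params.kappa_weights, eta)
        points = np.empty(n_agents)
        for a in range(n_agents):
            dataset, _ = simulate_agent(
                params, spec, schedule, seed=int(rng.integers(2**31)),
                points_per_outcome=points_per_outcome,
            )
            points[a] = dataset.attrs["total_points"]
        rows.append({"eta": float(eta), "mean_points": float(points.mean()),
                     "sem_points": float(points.std(ddof=1) / np.sqrt(n_agents)) if n_agents > 1 else np.nan})
    out = pd.DataFrame(rows)
    out.attrs["best_eta"] = float(out.loc[out["mean_points"].idxmax(), "eta"])
    return out
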