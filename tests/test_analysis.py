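import itertools

import numpy as np
import pandas as pd
import pytest

import revlearn as rl
from revlearn.analysis import smooth_curve

from conftest import make_toy_schedule


def test_correct_choice_definition(schedule):
    ds = schedule.copy()
    ds["action"] = "play"
    correct = rl.correct_choice(ds)
    assert (correct[ds["label"] == "good"] == 1.0).all()
    assert (correct[ds["label"] == "bad"] == 0.0).all()
    assert correct[ds["label"] == "neutral"].isna().all()


def test_smoothing_running_mean():
    y = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
    out = smooth_curve(y, half_width=2)
    assert out[2] == pytest.approx(0.2)
    assert out[0] == pytest.approx(1 / 3)  # shrinking edge window


def test_reversal_curve_random_agent(schedule):
    p = rl.AgentParams(0.0, 0.0, (0.0,), 0.3)
    sims = [rl.simulate_agent(p, "M2", schedule, seed=i)[0] for i in range(15)]
    curve = rl.reversal_curves(sims, window=30)
    assert np.nanmax(np.abs(curve["all"].to_numpy() - 0.5)) < 0.06


def test_reversal_curve_perfect_agent(schedule):
    ds = schedule.copy()
    ds["action"] = np.where(ds["label"] == "good", "play", "pass")
    curve = rl.reversal_curves([ds], window=30, smooth=0)
    assert np.nanmin(curve["all"].to_numpy()) == pytest.approx(1.0)


def test_reversal_curve_window_warning(schedule):
    with pytest.warns(UserWarning, match="window"):
        ds = schedule.copy()
        ds["action"] = "play"
        rl.reversal_curves([ds], window=40)


# ---------------------------------------------------------------------------
# structural breaks


def brute_force_breaks(y, min_seg=5):
    """Exhaustive segmented-OLS search, independent of the DP route."""
    y = np.asarray(y, dtype=float)
    n = y.size
    x = np.arange(n, dtype=float)

    def seg_sse(i, j):
        xs, ys = x[i : j + 1], y[i : j + 1]
        if xs.size < 2:
            return float(((ys - ys.mean()) ** 2).sum())
        coeffs, res, *_ = np.polyfit(xs, ys, 1, full=True)
        return float(res[0]) if len(res) else 0.0

    best_by_m = {}
    max_m = n // min_seg - 1
    for m in range(max_m + 1):
        best = (np.inf, ())
        for breaks in itertools.combinations(range(min_seg, n - min_seg + 1), m):
            bounds = (0,) + breaks + (n,)
            if any(b - a < min_seg for a, b in zip(bounds[:-1], bounds[1:])):
                continue
            sse = sum(seg_sse(a, b - 1) for a, b in zip(bounds[:-1], bounds[1:]))
            if sse < best[0]:
                best = (sse, breaks)
        best_by_m[m] = best
    crits = {
        m: np.log(max(sse, 1e-12) / max(n - (2 * (m + 1) + m), 1))
        + (2 * (m + 1) + m) * 0.299 * np.log(n) ** 2.1 / n
        for m, (sse, _) in best_by_m.items()
    }
    m_star = min(crits, key=crits.get)
    return m_star, list(best_by_m[m_star][1])


@pytest.mark.parametrize("n", [12, 20, 30])
def test_breaks_match_exhaustive_enumeration(n):
    rng = np.random.default_rng(n)
    for rep in range(3):
        y = rng.normal(0.6, 0.15, size=n)
        if rep > 0:  # add genuine structure half the time
            y[n // 2 :] += 0.5 * rep
        got = rl.detect_breaks(y, min_seg=5)
        m_star, breaks = brute_force_breaks(y, min_seg=5)
        assert got.n_breaks == m_star
        assert got.break_positions == breaks


def test_step_function_localized():
    rng = np.random.default_rng(0)
    y = np.concatenate([np.full(10, 0.3), np.full(20, 0.8)]) + rng.normal(0, 0.02, 30)
    res = rl.detect_breaks(y, min_seg=5)
    assert res.n_breaks == 1
    assert abs(res.break_positions[0] - 10) <= 1


def test_constant_curve_rarely_breaks():
    """A structureless curve (constant + tiny noise) yields 0 breaks in
    nearly all draws — false positives stay in the low percent range."""
    n_breaks = [
        rl.detect_breaks(0.7 + np.random.default_rng(s).normal(0, 0.005, 30)).n_breaks
        for s in range(40)
    ]
    assert sum(b == 0 for b in n_breaks) >= 38


def test_max_reportable_breaks():
    """A 30-point curve at min segment 5 admits at most 5 breaks, and a
    6-level staircase attains them."""
    y = np.repeat([0.0, 1.0, 0.0, 1.0, 0.0, 1.0], 5)
    y += np.random.default_rng(2).normal(0, 0.01, 30)
    res = rl.detect_breaks(y, min_seg=5, max_breaks=50)
    assert res.n_breaks == 5
    assert res.break_positions == [5, 10, 15, 20, 25]


def test_short_curve_flagged():
    res = rl.detect_breaks(np.ones(7), min_seg=5)
    assert res.n_breaks == 0 and res.flagged


def test_stage_split_conventions():
    res = rl.BreakResult(1, [10], [], 0.0)
    early, late, flagged = rl.stage_split(res, window=30)
    assert early.tolist() == list(range(1, 11))
    assert late.tolist() == list(range(11, 31))
    assert not flagged
    early, late, flagged = rl.stage_split(rl.BreakResult(0, [], [], 0.0), window=30)
    assert early.size == 0 and late.size == 30 and flagged
    early, late, flagged = rl.stage_split(rl.BreakResult(1, [30], [], 0.0), window=30)
    assert late.size == 0 and flagged


# ---------------------------------------------------------------------------
# learning-rate dynamics


def _frame_pair(alpha, pos=None, block=2, label="good", p=0.7, valence="loss"):
    n = len(alpha)
    ds = pd.DataFrame(
        {
            "stimulus": 0,
            "block": block,
            "trials_since_reversal": pos if pos is not None else np.arange(1, n + 1),
            "noise_level": "high",
            "label": label,
            "p_reward": p,
            "outcome_valence": valence,
        }
    )
    lat = pd.DataFrame({"alpha": np.asarray(alpha, dtype=float)})
    return ds, lat


def test_lr_variability_conventions():
    ds, lat = _frame_pair([0.2, 0.4] * 10)
    assert rl.lr_variability(ds, lat, stage="all") == pytest.approx(0.1)
    constant_ds, constant_lat = _frame_pair([0.3] * 20)
    assert rl.lr_variability(constant_ds, constant_lat, stage="all") == pytest.approx(
        0.0, abs=1e-12
    )
    # early/late split at position 10
    assert rl.lr_variability(ds, lat, stage="early", break_pos=10) == pytest.approx(0.1)


def test_snr_constant_alpha_is_zero():
    ds, lat = _frame_pair([0.3] * 30, valence="loss")  # good + loss = misleading
    assert rl.snr(ds, lat) == pytest.approx(0.0)


def test_snr_shift_invariance():
    rng = np.random.default_rng(4)
    alpha = rng.uniform(0.1, 0.6, 30)
    ds, lat = _frame_pair(alpha)
    ds2, lat2 = _frame_pair(alpha + 0.2)
    assert rl.snr(ds2, lat2) == pytest.approx(rl.snr(ds, lat) + 0.0, abs=1e-12)


def test_snr_post_reversal_spike_positive():
    alpha = np.full(30, 0.1)
    alpha[:3] = 0.6  # spike right after the reversal
    ds, lat = _frame_pair(alpha)
    assert rl.snr(ds, lat) > 0.4


def test_snr_undefined_without_misleading_events():
    ds, lat = _frame_pair([0.3] * 30, valence="win")  # good stimulus, never misled
    with pytest.warns(UserWarning, match="misleading"):
        assert np.isnan(rl.snr(ds, lat))


def test_double_misleading_worst_case():
    """A win-stay/lose-shift agent passes a good stimulus after two
    misleading losses: probability 0 on those events."""
    n = 16
    valences = ["win"] * 10 + ["loss", "loss"] + ["win"] * 4
    ds = make_toy_schedule([0.7] * n, valences=valences)
    ds["block"] = 2
    # lose-shift: pass right after each loss
    ds["action"] = ["play"] * 12 + ["pass"] + ["play"] * 3
    prob, n_events = rl.double_misleading_accuracy(ds, late_start=11)
    assert n_events == 1
    assert prob == 0.0


def test_double_misleading_random_agent_matches_marginal(schedule):
    p = rl.AgentParams(0.0, 0.0, (0.0,), 0.3)
    hits, totals = [], []
    for i in range(30):
        ds, _ = rl.simulate_agent(p, "M2", schedule, seed=100 + i)
        prob, n = rl.double_misleading_accuracy(ds)
        if n:
            hits.append(prob * n)
            totals.append(n)
    pooled = sum(hits) / sum(totals)
    assert abs(pooled - 0.5) < 3 * np.sqrt(0.25 / sum(totals))


def test_performance_glm_recovers_construction():
    rng = np.random.default_rng(6)
    params = pd.DataFrame(
        {
            "beta": rng.normal(2, 0.5, 80),
            "eta": rng.uniform(0.1, 0.5, 80),
        }
    )
    flat = rl.performance_glm(params, np.full(80, 3.0))
    assert flat.loc[["beta", "eta"], "coef"].abs().max() < 1e-10
    scores = 2.0 * params["beta"].to_numpy()
    res = rl.performance_glm(params, scores)
    assert res.loc["beta", "coef"] == pytest.approx(2.0 * params["beta"].std(ddof=0))
    assert res.loc["eta", "coef"] == pytest.approx(0.0, abs=1e-10)


def test_performance_glm_rank_deficiency():
    rng = np.random.default_rng(7)
    x = rng.normal(size=50)
    params = pd.DataFrame({"a": x, "b": x})
    with pytest.raises(ValueError, match="collinear"):
        rl.performance_glm(params, rng.normal(size=50))
    with pytest.raises(ValueError, match="zero-variance"):
        rl.performance_glm(pd.DataFrame({"a": x, "c": np.ones(50)}), x)


def test_eta_sweep_deterministic(small_schedule):
    base = rl.AgentParams(2.5, 0.0, (0.0,), 0.3)
    a = rl.eta_sweep(base, "M2", small_schedule, [0.2, 0.8], n_agents=20, seed=3)
    b = rl.eta_sweep(base, "M2", small_schedule, [0.2, 0.8], n_agents=20, seed=3)
    pd.testing.assert_frame_equal(a, b)
    with pytest.raises(ValueError):
        rl.eta_sweep(base, "M1", small_schedule, [0.2], n_agents=2)
    with pytest.raises(ValueError):
        rl.eta_sweep(base, "M2", small_schedule, [1.5], n_agents=2)


def test_eta_degrades_double_misleading_accuracy(schedule):
    """Across agents, higher surprise sensitivity means fewer correct
    choices after two consecutive misleading feedbacks."""
    from scipy.stats import spearmanr

    rng = np.random.default_rng(8)
    etas, accs = [], []
    for _ in range(60):
        eta = float(rng.uniform(0.1, 0.8))
        sched = rl.draw_outcomes(schedule, seed=int(rng.integers(2**31)))
        ds, _ = rl.simulate_agent(
            rl.AgentParams(2.11, 0.04, (0.5, 2.0), eta), "M3", sched,
            seed=int(rng.integers(2**31)),
        )
        prob, n = rl.double_misleading_accuracy(ds)
        if n:
            etas.append(eta)
            accs.append(prob)
    rho, _ = spearmanr(etas, accs)
    assert rho < 0
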