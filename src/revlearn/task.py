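"""Reversal-learning task schedules.

The task presents three stimuli in an interleaved pseudo-random series.
Each stimulus carries a hidden reward contingency drawn from
{20, 30, 50, 70, 80}% that stays constant within a block of 30-35
encounters of that stimulus and changes without notice at every block
boundary (a *reversal*).  With 3 stimuli x 7 blocks the canonical design
has 714 trials and 18 reversals.  Outcome valences (win/loss) are
pre-drawn per trial from the contingency, independently of the agent's
action, so factual feedback on a play and fictive feedback on a pass are
two views of the same draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCHEDULE_COLUMNS = [
    "trial",
    "stimulus",
    "block",
    "trials_since_reversal",
    "p_reward",
    "noise_level",
    "label",
    "outcome_valence",
]


class ConfigurationError(ValueError):
    """Raised when a task configuration admits no valid schedule."""


@dataclass(frozen=True)
class TaskConfig:
    """Design parameters of the probabilistic reversal task."""

    n_stimuli: int = 3
    blocks_per_stimulus: int = 7
    block_length_range: tuple[int, int] = (30, 35)
    total_trials: int = 714
    probability_levels: tuple[float, ...] = (0.2, 0.3, 0.5, 0.7, 0.8)
    points_per_outcome: int = 10
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.block_length_range
        n_blocks = self.n_stimuli * self.blocks_per_stimulus
        if self.n_stimuli < 1 or self.blocks_per_stimulus < 1:
            raise ConfigurationError("need at least one stimulus and one block")
        if lo > hi or lo < 1:
            raise ConfigurationError(f"invalid block length range {self.block_length_range}")
        if not (n_blocks * lo <= self.total_trials <= n_blocks * hi):
            raise ConfigurationError(
                f"no partition of {self.total_trials} trials into {n_blocks} "
                f"blocks of length {lo}..{hi} exists"
            )
        if not self.probability_levels:
            raise ConfigurationError("probability_levels must be non-empty")
        if any(not 0.0 <= p <= 1.0 for p in self.probability_levels):
            raise ConfigurationError("probability levels must lie in [0, 1]")


def noise_level(p: float) -> str:
    """Map a reward probability to its outcome-noise label.

    50% is 'random'; contingencies far from chance (20/80%) are 'low'
    noise; contingencies nearer chance (30/70%) are 'high' noise.
    """
    if p == 0.5:
        return "random"
    return "low" if abs(p - 0.5) >= 0.3 else "high"


def good_bad_label(p: float) -> str:
    if p > 0.5:
        return "good"
    if p < 0.5:
        return "bad"
    return "neutral"


def _sample_block_lengths(config: TaskConfig, rng: np.random.Generator) -> np.ndarray:
    """Sample block lengths in range summing exactly to total_trials.

    Starts from the most even partition and applies seeded +-1 pairwise
    transfers, which random-walks over the constrained compositions
    (e.g. 21 blocks averaging 34 trials for the 714-trial default).
    """
    lo, hi = config.block_length_range
    n_blocks = config.n_stimuli * config.blocks_per_stimulus
    base, rem = divmod(config.total_trials, n_blocks)
    lengths = np.full(n_blocks, base, dtype=int)
    lengths[:rem] += 1
    if lengths.min() < lo or lengths.max() > hi:
        raise ConfigurationError("even partition outside block length range")
    for _ in range(50 * n_blocks):
        i, j = rng.integers(0, n_blocks, size=2)
        if i != j and lengths[i] < hi and lengths[j] > lo:
            lengths[i] += 1
            lengths[j] -= 1
    return lengths


def _sample_contingencies(config: TaskConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-stimulus sequence of reward probabilities, one per block.

    Consecutive blocks of a stimulus always differ, and whenever the level
    set allows it each stimulus visits both a >50% and a <50% level across
    its blocks so that good and bad phases exist for every stimulus.
    """
    levels = np.asarray(sorted(set(config.probability_levels)), dtype=float)
    has_both_sides = (levels > 0.5).any() and (levels < 0.5).any()
    # every stimulus should offer both good and bad phases; with enough
    # blocks require two of each so no schedule draw is starved of either
    min_per_side = 0
    if has_both_sides and config.blocks_per_stimulus >= 2:
        min_per_side = 2 if config.blocks_per_stimulus >= 5 else 1
    out = np.empty((config.n_stimuli, config.blocks_per_stimulus))
    for s in range(config.n_stimuli):
        for _attempt in range(10_000):
            seq = [rng.choice(levels)]
            for _ in range(config.blocks_per_stimulus - 1):
                options = levels[levels != seq[-1]]
                if options.size == 0:
                    break
                seq.append(rng.choice(options))
            if len(seq) < config.blocks_per_stimulus:
                if levels.size == 1 and config.blocks_per_stimulus > 1:
                    raise ConfigurationError(
                        "cannot change contingency at reversals with a single level"
                    )
                continue
            arr = np.asarray(seq)
            if (arr > 0.5).sum() < min_per_side or (arr < 0.5).sum() < min_per_side:
                continue
            out[s] = arr
            break
        else:  # pragma: no cover - only reachable with adversarial level sets
            raise ConfigurationError("could not sample a valid contingency sequence")
    return out


def _interleave_stimuli(
    counts: np.ndarray, rng: np.random.Generator, max_gap: int
) -> np.ndarray:
    """Pseudo-random stimulus order with bounded absences.

    Draws the next stimulus with probability proportional to its remaining
    quota, but forces any stimulus that has been absent for ``max_gap - 1``
    trials (while it still has trials left).  Absence counters are pairwise
    distinct, so at most one stimulus is ever forced at a time.
    """
    n_stimuli = counts.size
    remaining = counts.astype(float).copy()
    absence = np.zeros(n_stimuli, dtype=int)
    order = np.empty(int(counts.sum()), dtype=np.int64)
    for t in range(order.size):
        avail = remaining > 0
        forced = avail & (absence >= max_gap - 1)
        if forced.any():
            s = int(np.flatnonzero(forced)[np.argmax(absence[forced])])
        else:
            w = remaining * avail
            s = int(rng.choice(n_stimuli, p=w / w.sum()))
        order[t] = s
        remaining[s] -= 1
        absence += 1
        absence[s] = 0
    return order


def build_schedule(config: TaskConfig | None = None) -> pd.DataFrame:
    """Build a full trial-by-trial schedule, outcome valences included.

    Returns a DataFrame with one row per trial and columns
    ``trial`` (1-based), ``stimulus``, ``block`` (1-based per stimulus),
    ``trials_since_reversal`` (1-based, restarting at each contingency
    change), ``p_reward``, ``noise_level``, ``label`` and
    ``outcome_valence``.  Deterministic given ``config.seed``.
    """
    config = config or TaskConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    lengths = _sample_block_lengths(config, rng).reshape(
        config.n_stimuli, config.blocks_per_stimulus
    )
    contingencies = _sample_contingencies(config, rng)
    per_stim_totals = lengths.sum(axis=1)
    order = _interleave_stimuli(per_stim_totals, rng, max_gap=3 * config.n_stimuli)

    # per-stimulus encounter index -> block and within-block position
    block_of = []
    pos_of = []
    for s in range(config.n_stimuli):
        blocks = np.repeat(np.arange(1, config.blocks_per_stimulus + 1), lengths[s])
        pos = np.concatenate([np.arange(1, L + 1) for L in lengths[s]])
        block_of.append(blocks)
        pos_of.append(pos)

    n = order.size
    seen = np.zeros(config.n_stimuli, dtype=int)
    block = np.empty(n, dtype=int)
    pos = np.empty(n, dtype=int)
    p_reward = np.empty(n)
    for t, s in enumerate(order):
        k = seen[s]
        block[t] = block_of[s][k]
        pos[t] = pos_of[s][k]
        p_reward[t] = contingencies[s, block[t] - 1]
        seen[s] += 1

    schedule = pd.DataFrame(
        {
            "trial": np.arange(1, n + 1),
            "stimulus": order,
            "block": block,
            "trials_since_reversal": pos,
            "p_reward": p_reward,
            "noise_level": [noise_level(p) for p in p_reward],
            "label": [good_bad_label(p) for p in p_reward],
        }
    )
    schedule.attrs["config"] = config
    return draw_outcomes(schedule, seed=int(rng.integers(2**31)))


DEFAULT_SCHEDULE_SEED = 7


def canonical_schedule() -> pd.DataFrame:
    """The package's canonical 714-trial schedule (seed 7).

    The human task used one fixed pseudo-random series for all
    participants; this fixture plays that role for simulations and
    benchmarks.  Regenerated deterministically rather than shipped as a
    file.
    """
    return build_schedule(TaskConfig(seed=DEFAULT_SCHEDULE_SEED))


def draw_outcomes(schedule: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Pre-draw one Bernoulli(p_reward) outcome valence per trial.

    The draw is action-independent: it is displayed as factual feedback if
    the agent plays and as fictive feedback if it passes.
    """
    rng = np.random.default_rng(seed)
    out = schedule.copy()
    wins = rng.random(len(out)) < out["p_reward"].to_numpy()
    out["outcome_valence"] = np.where(wins, "win", "loss")
    out.attrs = dict(schedule.attrs)
    return out


def label_misleading(schedule: pd.DataFrame) -> pd.Series:
    """Flag outcomes inconsistent with the stimulus's good/bad label.

    A win for a bad stimulus or a loss for a good stimulus is misleading
    (probabilistic) feedback; neutral (50%) stimuli are never flagged.
    """
    win = schedule["outcome_valence"] == "win"
    good = schedule["label"] == "good"
    bad = schedule["label"] == "bad"
    return (bad & win) | (good & ~win)


def reversal_flags(schedule: pd.DataFrame) -> pd.Series:
    """True on the first trial of every post-reversal block."""
    return (schedule["trials_since_reversal"] == 1) & (schedule["block"] > 1)


def count_reversals(schedule: pd.DataFrame) -> int:
    return int(reversal_flags(schedule).sum())
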