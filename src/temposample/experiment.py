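"""Trial scheduling, adaptive contrast staircase, and the simulated 4AFC loop.

The default experiment geometry is 4 sessions x 4 blocks x 200 trials = 3200
trials drawn from a 400-word bank: every word is a target exactly 8 times,
twice per spatial-frequency condition, and never twice within a block. A
per-condition 1-up/1-down staircase on target contrast (start 35%, step 16%
halved at every reversal down to 1%) holds response accuracy near 50%.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .observer import ObserverModel, observer_p_correct_batch
from .stimuli import DistractorMap, generate_snr_function

__all__ = [
    "StaircaseState",
    "build_trial_schedule",
    "validate_schedule",
    "staircase_update",
    "run_simulated_experiment",
    "summarize_log",
]

N_CONDITIONS = 4
REPS_PER_CONDITION = 2
PRESENTATIONS_PER_WORD = N_CONDITIONS * REPS_PER_CONDITION  # 8

INITIAL_CONTRAST = 35.0
INITIAL_STEP = 16.0
MIN_STEP = 1.0
MIN_CONTRAST = 1.0
MAX_CONTRAST = 100.0
WARMUP_TRIALS = 20  # no staircase adjustment before this many trials
WINDOW = 10  # accuracy window, most recent trials of the adjusted condition

LOG_COLUMNS = [
    "participant_id", "session", "block", "trial_index", "condition", "word",
    "contrast", "snr_seed", "snr_values", "correct",
]


@dataclass
class StaircaseState:
    """Per-condition contrast staircase state."""

    contrast: dict = field(
        default_factory=lambda: {c: INITIAL_CONTRAST for c in range(1, 5)}
    )
    step: dict = field(default_factory=lambda: {c: INITIAL_STEP for c in range(1, 5)})
    last_direction: dict = field(default_factory=lambda: {c: "none" for c in range(1, 5)})
    history: dict = field(default_factory=lambda: {c: [] for c in range(1, 5)})


def staircase_update(
    state: StaircaseState,
    condition: int,
    recent_window: Sequence[bool],
    trial_counter: int,
) -> StaircaseState:
    """One staircase evaluation after a completed trial (pure update).

    ``recent_window`` holds the correctness of the most recent trials of
    ``condition`` (up to 10) and ``trial_counter`` the number of experimental
    trials completed so far. Nothing changes before 20 trials overall or with
    fewer than 10 trials of the condition. Accuracy above 50% over the last
    10 lowers contrast by one step, below 50% raises it, an exact tie leaves
    it alone; a reversal in adjustment direction halves the step (floor 1%).
    Contrast is kept within [1, 100] %.
    """
    new = copy.deepcopy(state)
    if trial_counter < WARMUP_TRIALS or len(recent_window) < WINDOW:
        return new
    acc = float(np.mean(np.asarray(recent_window[-WINDOW:], dtype=float)))
    if acc == 0.5:
        return new
    direction = "down" if acc > 0.5 else "up"
    step = new.step[condition]
    delta = -step if direction == "down" else step
    new.contrast[condition] = float(
        np.clip(new.contrast[condition] + delta, MIN_CONTRAST, MAX_CONTRAST)
    )
    if new.last_direction[condition] in ("up", "down") and direction != new.last_direction[condition]:
        new.step[condition] = max(step / 2.0, MIN_STEP)
    new.last_direction[condition] = direction
    return new


# --------------------------------------------------------------------------
# Schedule


def build_trial_schedule(
    words: Sequence[str],
    n_sessions: int = 4,
    blocks_per_session: int = 4,
    trials_per_block: int = 200,
    distractor_map: DistractorMap | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Randomized trial schedule honoring the word-budget constraints.

    Every word appears exactly 8 times (twice per condition), spread over as
    many distinct blocks as possible: with at least 8 blocks no word repeats
    within a block; with fewer blocks repeats are balanced evenly. Trial
    order within each block is shuffled by ``seed``. Raises if the word
    budget does not match the trial budget.
    """
    words = list(words)
    total = n_sessions * blocks_per_session * trials_per_block
    if len(words) * PRESENTATIONS_PER_WORD != total:
        raise ValueError(
            f"word budget {len(words)} x {PRESENTATIONS_PER_WORD} = "
            f"{len(words) * PRESENTATIONS_PER_WORD} trials != schedule budget {total}"
        )
    if distractor_map is not None:
        missing = [w for w in words if w not in distractor_map.distractors]
        if missing:
            raise ValueError(f"distractor map missing {len(missing)} words, e.g. {missing[:3]}")
    rng = np.random.default_rng(seed)
    n_blocks = n_sessions * blocks_per_session
    load = np.zeros(n_blocks, dtype=int)
    per_block: list[list] = [[] for _ in range(n_blocks)]
    for wi in rng.permutation(len(words)):
        word = words[wi]
        conds = rng.permutation(np.repeat(np.arange(1, N_CONDITIONS + 1), REPS_PER_CONDITION))
        in_block = np.zeros(n_blocks, dtype=int)
        for cond in conds:
            # fewest appearances of this word first, then lightest load
            keys = in_block * (total + 1) + load
            b = int(rng.choice(np.flatnonzero(keys == keys.min())))
            per_block[b].append((word, int(cond)))
            in_block[b] += 1
            load[b] += 1
    if not np.all(load == trials_per_block):
        raise RuntimeError("internal error: unbalanced block assignment")
    rows = []
    for b in range(n_blocks):
        order = rng.permutation(len(per_block[b]))
        for ti, k in enumerate(order):
            word, cond = per_block[b][k]
            rows.append({
                "session": b // blocks_per_session + 1,
                "block": b % blocks_per_session + 1,
                "trial_index": ti + 1,
                "word": word,
                "condition": cond,
                "distractors": (
                    distractor_map.distractors[word] if distractor_map is not None else ()
                ),
            })
    return pd.DataFrame(rows)


def validate_schedule(schedule: pd.DataFrame, n_sessions: int = 4,
                      blocks_per_session: int = 4, trials_per_block: int = 200) -> None:
    """Exhaustively check every schedule invariant; raise on any violation."""
    n_blocks = n_sessions * blocks_per_session
    counts = schedule.groupby(["session", "block"]).size()
    if len(counts) != n_blocks or not (counts == trials_per_block).all():
        raise AssertionError("block sizes violated")
    per_word = schedule.groupby("word").size()
    if not (per_word == PRESENTATIONS_PER_WORD).all():
        raise AssertionError("some word is not presented exactly 8 times")
    per_wc = schedule.groupby(["word", "condition"]).size()
    if not (per_wc == REPS_PER_CONDITION).all():
        raise AssertionError("some word/condition pair is not presented exactly twice")
    if n_blocks >= PRESENTATIONS_PER_WORD:
        dup = schedule.groupby(["session", "block", "word"]).size()
        if (dup > 1).any():
            raise AssertionError("word repeated within a block")


# --------------------------------------------------------------------------
# Simulated experiment loop


def run_simulated_experiment(
    schedule: pd.DataFrame,
    observer: ObserverModel,
    seed: int = 0,
    participant_id: int | str = 0,
) -> pd.DataFrame:
    """Run the 4AFC loop over a schedule with the staircase threaded through.

    Each trial draws a fresh SNR sampling function (its integer seed is
    logged so the stimulus is reproducible), asks the observer for a
    correctness probability at the condition's current staircase contrast,
    samples the response, and updates the staircase. Staircase state persists
    across blocks and sessions. Fully deterministic given the seeds.
    """
    for c in sorted(schedule["condition"].unique()):
        if int(c) not in observer.time_kernel:
            raise KeyError(f"observer undefined for condition {c}")
    ss = np.random.SeedSequence(seed)
    snr_rng, resp_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    state = StaircaseState()
    ordered = schedule.sort_values(["session", "block", "trial_index"], kind="stable")
    rows = []
    for counter, rec in enumerate(ordered.itertuples(index=False), start=1):
        cond = int(rec.condition)
        contrast = state.contrast[cond]
        snr_seed = int(snr_rng.integers(0, 2**31))
        snr = generate_snr_function(snr_seed)
        p = float(observer_p_correct_batch(observer, cond, snr.values[None, :], contrast)[0])
        correct = bool(resp_rng.random() < p)
        state.history[cond].append(correct)
        rows.append({
            "participant_id": participant_id, "session": rec.session,
            "block": rec.block, "trial_index": rec.trial_index,
            "condition": cond, "word": rec.word, "contrast": contrast,
            "snr_seed": snr_seed, "snr_values": snr.values, "correct": correct,
        })
        state = staircase_update(state, cond, state.history[cond][-WINDOW:], counter)
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


def summarize_log(log: pd.DataFrame) -> pd.DataFrame:
    """Per-condition accuracy (%) and mean contrast (%), one row per condition."""
    g = log.groupby("condition")
    return pd.DataFrame({
        "accuracy_pct": g["correct"].mean() * 100.0,
        "mean_contrast_pct": g["contrast"].mean(),
        "n_trials": g.size(),
    }).reset_index()
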