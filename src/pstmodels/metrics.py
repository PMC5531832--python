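"""Behavioural metrics computed from trial-level session tables.

All metrics operate on the long-format TrialRecord columns produced by
:mod:`pstmodels.agents` (or loaded from CSV).  Undefined quantities
(empty scopes, missing blocks) propagate as NaN, never as zero.

Percentages are on the 0-100 scale; win-stay / lose-shift are
proportions on 0-1.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .tasks import NO_RESPONSE

UNDEFINED = float("nan")

MEMORY_PHASES = ("memory_immediate", "memory_30min", "memory_24hr")


def _responded(trials: pd.DataFrame) -> pd.DataFrame:
    return trials[trials["choice"] != NO_RESPONSE]


def optimal_accuracy(
    trials: pd.DataFrame, phase: str | None = None, block: int | None = None
) -> float:
    """Percentage of responded trials choosing the higher-reward stimulus.

    NO_RESPONSE trials are excluded from the denominator; an empty scope
    returns NaN (undefined), not zero.
    """
    df = trials
    if phase is not None:
        df = df[df["phase"] == phase]
    if block is not None:
        df = df[df["block"] == block]
    df = _responded(df)
    if df.empty:
        return UNDEFINED
    return 100.0 * df["chose_optimal"].mean()


def final_learning_accuracy(trials: pd.DataFrame) -> float:
    """Optimal-choice percentage in the last learning block actually run."""
    learning = trials[trials["phase"] == "learning"]
    if learning.empty:
        return UNDEFINED
    return optimal_accuracy(learning, block=int(learning["block"].max()))


def infer_learning_pairs(trials: pd.DataFrame) -> set[str]:
    """Pair labels that appeared in the learning phase (e.g. {AB, CD})."""
    return set(trials.loc[trials["phase"] == "learning", "pair_label"].unique())


def _novel_eligible(trials: pd.DataFrame, exclude_pairs: Iterable[str] | None) -> pd.DataFrame:
    novel = trials[trials["phase"] == "novel"]
    if exclude_pairs is None:
        exclude_pairs = infer_learning_pairs(trials)
    return _responded(novel[~novel["pair_label"].isin(set(exclude_pairs))])


def choose_a(trials: pd.DataFrame, exclude_pairs: Iterable[str] | None = None) -> float:
    """Percentage of eligible novel trials where stimulus A was chosen.

    Eligible trials are novel-phase trials containing A, excluding the
    learning pairs (so AB never counts toward choose-A).  A proxy for
    positive-reinforcement expression.
    """
    df = _novel_eligible(trials, exclude_pairs)
    shown = df[(df["stim_left"] == "A") | (df["stim_right"] == "A")]
    if shown.empty:
        return UNDEFINED
    return 100.0 * (shown["choice"] == "A").mean()


def avoid_b(trials: pd.DataFrame, exclude_pairs: Iterable[str] | None = None) -> float:
    """Percentage of eligible novel trials containing B where B was avoided.

    A proxy for negative-reinforcement expression.
    """
    df = _novel_eligible(trials, exclude_pairs)
    shown = df[(df["stim_left"] == "B") | (df["stim_right"] == "B")]
    if shown.empty:
        return UNDEFINED
    return 100.0 * (shown["choice"] != "B").mean()


def novel_overall_accuracy(trials: pd.DataFrame) -> float:
    """Optimal-choice percentage over all responded novel trials."""
    return optimal_accuracy(trials, phase="novel")


def ab_novel_accuracy(trials: pd.DataFrame) -> float:
    """Accuracy on the easiest (A vs B) pair within the novel phase.

    This is the quantity the exclusion filter operates on.
    """
    novel = _responded(trials[trials["phase"] == "novel"])
    ab = novel[novel["pair_label"] == "AB"]
    if ab.empty:
        return UNDEFINED
    return 100.0 * (ab["choice"] == "A").mean()


def wsls(trials: pd.DataFrame, within_pair: bool = True) -> tuple[float, float]:
    """Win-stay and lose-shift proportions on the learning trials.

    win_stay is P(repeat previous choice | previous feedback 1) and
    lose_shift is P(switch | previous feedback 0).  By default
    transitions are defined on consecutive presentations of the *same
    pair* (``within_pair=True``); ``within_pair=False`` uses globally
    consecutive trials regardless of pair.  Either proportion is NaN when
    no qualifying transition exists.
    """
    learning = _responded(trials[trials["phase"] == "learning"]).sort_index()
    groups = learning.groupby("pair_label") if within_pair else [(None, learning)]
    win_stay_n = win_n = lose_shift_n = lose_n = 0
    for _, g in groups:
        choices = g["choice"].to_numpy()
        fb = g["feedback"].to_numpy()
        for prev in range(len(g) - 1):
            stayed = choices[prev + 1] == choices[prev]
            if fb[prev] == 1:
                win_n += 1
                win_stay_n += stayed
            elif fb[prev] == 0:
                lose_n += 1
                lose_shift_n += not stayed
    ws = win_stay_n / win_n if win_n else UNDEFINED
    ls = lose_shift_n / lose_n if lose_n else UNDEFINED
    return ws, ls


def memory_differences(
    mem_immediate: float, mem_30min: float, mem_24hr: float
) -> tuple[float, float]:
    """Signed memory-change scores in percentage points, later minus earlier.

    Returns ``(mem_diff_30_0, mem_diff_24_30)``; an increase over the
    delay is positive.  Missing blocks propagate NaN.
    """
    return mem_30min - mem_immediate, mem_24hr - mem_30min


def subject_metrics(session: pd.DataFrame) -> dict:
    """All per-session behavioural metrics for one (subject, condition)."""
    learning = session[session["phase"] == "learning"]
    block_acc = {
        f"learning_block_{int(b)}": optimal_accuracy(learning, block=int(b))
        for b in sorted(learning["block"].unique())
    }
    mem = {p: optimal_accuracy(session, phase=p) for p in MEMORY_PHASES}
    d30, d24 = memory_differences(
        mem["memory_immediate"], mem["memory_30min"], mem["memory_24hr"]
    )
    ws, ls = wsls(session)
    out = {
        "subject_id": session["subject_id"].iloc[0],
        "group": session["group"].iloc[0],
        "condition": session["condition"].iloc[0],
        "final_learning_accuracy": final_learning_accuracy(session),
        "n_learning_blocks": int(learning["block"].nunique()) if not learning.empty else 0,
        "memory_immediate": mem["memory_immediate"],
        "memory_30min": mem["memory_30min"],
        "memory_24hr": mem["memory_24hr"],
        "mem_diff_30_0": d30,
        "mem_diff_24_30": d24,
        "choose_a": choose_a(session),
        "avoid_b": avoid_b(session),
        "novel_overall": novel_overall_accuracy(session),
        "ab_novel_accuracy": ab_novel_accuracy(session),
        "win_stay": ws,
        "lose_shift": ls,
    }
    out.update(block_acc)
    return out


def cohort_metrics(sessions: pd.DataFrame) -> pd.DataFrame:
    """One metrics row per (subject, condition) across a cohort table."""
    rows = [
        subject_metrics(g)
        for _, g in sessions.groupby(["subject_id", "condition"], sort=True)
    ]
    return pd.DataFrame(rows)


def apply_filter(metrics: pd.DataFrame) -> pd.DataFrame:
    """Flag conditions whose novel-pairs data fail the AB learning check.

    A (subject, condition) is flagged ``filtered_out`` iff its accuracy
    on the A-vs-B novel pair is at or below 50% -- the subject is assumed
    not to have learned the task in that condition.  Conditions are
    checked separately, and the flag applies only to novel-pairs
    analyses: learning and memory statistics are never filtered.
    Conditions with no assessable AB trials are marked
    ``ab_unassessable`` and reported separately rather than silently
    dropped.
    """
    out = metrics.copy()
    acc = out["ab_novel_accuracy"]
    out["ab_unassessable"] = acc.isna()
    out["filtered_out"] = (acc <= 50.0).fillna(False)
    return out
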