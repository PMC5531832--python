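"""Q-learning agents with softmax choice and overnight value retention.

The agent maintains one action value per stimulus, updated by the delta
rule ``Q <- Q + alpha * (r - Q)`` with separate learning rates for
positive (``alpha_gain``) and negative (``alpha_loss``) prediction
errors.  Choices between two presented stimuli follow a softmax with
inverse temperature ``beta``.  Between the two days of a two-day session
the values shrink toward their initial value ``q0`` by a retention
fraction ``rho``; ``rho = 1`` is perfect consolidation, ``rho = 0``
forgets everything.

Any of ``alpha_gain``, ``alpha_loss``, ``beta`` and ``rho`` may be given
per medication state as a mapping ``{"ON": ..., "OFF": ...}``.  The day-1
state of a condition (e.g. the "ON" in "ON-OFF") selects the learning
rates and the retention fraction; the day-2 state selects the inverse
temperature used on the day-2 test phases, so a medication effect on the
*expression* of learned values can be simulated independently of an
effect on learning or on consolidation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .tasks import PRACTICE_STIMULI, TrialSchedule

StateParam = Union[float, Mapping[str, float]]

MED_STATES = ("ON", "OFF")


class AgentConfigurationError(ValueError):
    pass


def _check_bounds(name: str, value: StateParam, lo: float, hi: float) -> None:
    vals = value.values() if isinstance(value, Mapping) else [value]
    for v in vals:
        if not lo <= v <= hi:
            raise AgentConfigurationError(f"{name}={v} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class AgentParams:
    """Parameters of one agent.

    alpha_gain, alpha_loss : float or {"ON": float, "OFF": float}
        Learning rates in [0, 1] for positive / negative prediction errors.
    beta : float or mapping
        Softmax inverse temperature >= 0.
    q0 : float
        Initial action value (chance-level prior 0.5 by default).
    rho : float or mapping
        Overnight retention fraction in [0, 1].
    """

    alpha_gain: StateParam = 0.3
    alpha_loss: StateParam = 0.3
    beta: StateParam = 5.0
    q0: float = 0.5
    rho: StateParam = 1.0

    def __post_init__(self) -> None:
        _check_bounds("alpha_gain", self.alpha_gain, 0.0, 1.0)
        _check_bounds("alpha_loss", self.alpha_loss, 0.0, 1.0)
        _check_bounds("beta", self.beta, 0.0, math.inf)
        _check_bounds("q0", self.q0, 0.0, 1.0)
        _check_bounds("rho", self.rho, 0.0, 1.0)

    def resolve(self, name: str, state: str | None) -> float:
        """Concrete value of a possibly state-conditional parameter."""
        value = getattr(self, name)
        if isinstance(value, Mapping):
            if state is None:
                raise AgentConfigurationError(
                    f"{name} is state-conditional but no medication state given"
                )
            return float(value[state])
        return float(value)


def parse_condition(condition: str) -> tuple[str | None, str | None]:
    """Split a condition label into (day-1 state, day-2 state).

    ``"ON-OFF"`` -> ("ON", "OFF"); single-day ``"ON"`` -> ("ON", "ON");
    ``"HC"`` -> (None, None) — healthy controls carry no medication state
    and require scalar parameters.
    """
    if condition == "HC":
        return None, None
    parts = condition.split("-")
    if len(parts) == 1 and parts[0] in MED_STATES:
        return parts[0], parts[0]
    if len(parts) == 2 and all(p in MED_STATES for p in parts):
        return parts[0], parts[1]
    raise AgentConfigurationError(f"unrecognised condition label {condition!r}")


# ---------------------------------------------------------------------------
# Core operations


def q_update(
    values: dict[str, float],
    choice: str,
    feedback: int,
    params: AgentParams,
    state: str | None = None,
) -> dict[str, float]:
    """Delta-rule update of the chosen stimulus's value; others untouched.

    The learning rate is ``alpha_gain`` when the prediction error
    ``r - Q`` is positive, ``alpha_loss`` when negative; a zero
    prediction error leaves the value unchanged either way.
    """
    if choice not in values:
        raise KeyError(f"unknown stimulus {choice!r}")
    if feedback not in (0, 1):
        raise ValueError(f"feedback must be 0 or 1, got {feedback!r}")
    q = values[choice]
    pe = feedback - q
    alpha = params.resolve("alpha_gain" if pe > 0 else "alpha_loss", state)
    out = dict(values)
    out[choice] = q + alpha * pe
    return out


def softmax_choice_prob(q_a: float, q_b: float, beta: float) -> float:
    """Probability of choosing option a under a two-option softmax."""
    if beta < 0:
        raise AgentConfigurationError(f"beta must be >= 0, got {beta}")
    # logistic of beta*(q_a - q_b); stable for large |x|
    x = beta * (q_a - q_b)
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def apply_retention(
    values: dict[str, float], rho: float, q0: float
) -> dict[str, float]:
    """Overnight consolidation: shrink each value toward q0 by factor rho.

    ``Q' = q0 + rho * (Q - q0)``; rho=1 preserves the learned values,
    rho=0 resets them to the prior.
    """
    if not 0.0 <= rho <= 1.0:
        raise AgentConfigurationError(f"rho={rho} outside [0, 1]")
    return {s: q0 + rho * (q - q0) for s, q in values.items()}


# ---------------------------------------------------------------------------
# Session simulation


def _compile_schedule(schedule: TrialSchedule) -> dict:
    """One-time array compilation of a schedule for the fast simulation loop."""
    spec = schedule.spec
    stimuli = list(spec.stimuli) + list(PRACTICE_STIMULI)
    idx = {s: i for i, s in enumerate(stimuli)}
    slots = schedule.slots
    n = len(slots)
    left = np.fromiter((idx[s.stim_left] for s in slots), np.int64, n)
    right = np.fromiter((idx[s.stim_right] for s in slots), np.int64, n)
    fb_left = np.fromiter((-1 if s.fb_left is None else s.fb_left for s in slots), np.int64, n)
    fb_right = np.fromiter((-1 if s.fb_right is None else s.fb_right for s in slots), np.int64, n)
    day2 = np.fromiter((s.session_day == 2 for s in slots), bool, n)
    is_learning = np.fromiter((s.phase == "learning" for s in slots), bool, n)
    rprob = np.array([spec.reward_prob(s) for s in stimuli])
    pair_labels = sorted({s.pair_label for s in slots if s.phase == "learning"})
    pair_idx_map = {lab: i for i, lab in enumerate(pair_labels)}
    pair_idx = np.fromiter(
        (pair_idx_map.get(s.pair_label, -1) if s.phase == "learning" else -1 for s in slots),
        np.int64, n,
    )
    block = np.fromiter((s.block for s in slots), np.int64, n)
    return {
        "stimuli": stimuli,
        "left": left,
        "right": right,
        "fb_left": fb_left,
        "fb_right": fb_right,
        "day2": day2,
        "has_fb": fb_left >= 0,
        "is_learning": is_learning,
        "optimal_is_left": rprob[left] > rprob[right],
        "pair_idx": pair_idx,
        "block": block,
        "pair_order": [pair_idx_map.get(p.label) for p in spec.pairs],
    }


def simulate_session(
    params: AgentParams,
    schedule: TrialSchedule,
    condition: str,
    seed: int,
    subject_id: str = "sim",
    group: str | None = None,
) -> pd.DataFrame:
    """Simulate one agent through a schedule; returns trial records.

    Choices are sampled from the softmax on current values; values update
    only on feedback trials.  On a two-day schedule the retention
    transform is applied once, at the transition from day-1 to day-2
    slots (i.e. between the 30-min and 24-hr memory blocks).  For a
    threshold-gated spec, learning blocks after the first block whose
    per-pair accuracies all clear their thresholds are skipped, mirroring
    early exit from training.

    Deterministic given ``seed``.
    """
    day1, day2_state = parse_condition(condition)
    spec = schedule.spec
    rng = np.random.default_rng(seed)
    if group is None:
        group = "HC" if condition == "HC" else "PD"

    comp = getattr(schedule, "_compiled", None)
    if comp is None:
        comp = _compile_schedule(schedule)
        schedule._compiled = comp

    ag = params.resolve("alpha_gain", day1)
    al = params.resolve("alpha_loss", day1)
    beta1 = params.resolve("beta", day1)
    beta2 = params.resolve("beta", day2_state)
    rho = params.resolve("rho", day1)
    q0 = params.q0

    n = len(schedule.slots)
    u = rng.random(n)
    q = [q0] * len(comp["stimuli"])
    left, right = comp["left"], comp["right"]
    fb_l, fb_r = comp["fb_left"], comp["fb_right"]
    day2 = comp["day2"]
    has_fb = comp["has_fb"]
    is_learning = comp["is_learning"]
    opt_left = comp["optimal_is_left"]
    pair_idx, block = comp["pair_idx"], comp["block"]

    chose_left = np.zeros(n, dtype=bool)
    feedback = np.full(n, np.nan)
    keep = np.ones(n, dtype=bool)

    gated = spec.threshold_gated
    thresholds = spec.pass_thresholds if gated else None
    n_pairs = len(spec.pairs)
    correct = [0] * n_pairs
    counts = [0] * n_pairs
    skip_learning = False
    current_block = -1
    on_day2 = False

    for t in range(n):
        if is_learning[t]:
            if gated:
                if block[t] != current_block and current_block >= 0:
                    passed = all(
                        counts[j] > 0 and correct[j] / counts[j] > thresholds[j]
                        for j in range(n_pairs)
                    )
                    if passed:
                        skip_learning = True
                    correct = [0] * n_pairs
                    counts = [0] * n_pairs
                current_block = block[t]
                if skip_learning:
                    keep[t] = False
                    continue
        if day2[t] and not on_day2:
            q = [q0 + rho * (v - q0) for v in q]
            on_day2 = True
        beta = beta2 if day2[t] else beta1
        li, ri = left[t], right[t]
        x = beta * (q[li] - q[ri])
        if x >= 0:
            p_left = 1.0 / (1.0 + math.exp(-x)) if x < 700 else 1.0
        else:
            e = math.exp(x)
            p_left = e / (1.0 + e)
        cl = u[t] < p_left
        chose_left[t] = cl
        if has_fb[t]:
            r = fb_l[t] if cl else fb_r[t]
            feedback[t] = r
            ci = li if cl else ri
            pe = r - q[ci]
            q[ci] += (ag if pe > 0 else al) * pe
            if gated and is_learning[t]:
                j = pair_idx[t]
                counts[j] += 1
                correct[j] += int(cl == opt_left[t])

    stim_arr = np.array(comp["stimuli"], dtype=object)
    choice = np.where(chose_left, stim_arr[left], stim_arr[right])
    chose_optimal = chose_left == opt_left

    df = pd.DataFrame(
        {
            "subject_id": subject_id,
            "group": group,
            "condition": condition,
            "session_day": np.where(day2, 2, 1),
            "phase": [s.phase for s in schedule.slots],
            "block": block,
            "trial": [s.trial for s in schedule.slots],
            "pair_label": [s.pair_label for s in schedule.slots],
            "stim_left": stim_arr[left],
            "stim_right": stim_arr[right],
            "choice": choice,
            "chose_optimal": chose_optimal,
            "feedback": feedback,
        }
    )
    df = df[keep].reset_index(drop=True)
    df["seed"] = seed
    df["spec_name"] = spec.name
    return df


def n_learning_blocks_completed(session: pd.DataFrame) -> int:
    """Number of learning blocks actually run in a (possibly gated) session."""
    learning = session[session["phase"] == "learning"]
    if learning.empty:
        return 0
    return int(learning["block"].nunique())
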