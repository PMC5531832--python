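"""Probabilistic Selection Task (PST) variants and trial-schedule generation.

The PST presents pairs of stimuli with fixed, complementary reward
probabilities (e.g. stimulus A in pair AB is rewarded on 80% of choices,
B on 20%).  After learning, a feedback-free recombination ("novel pairs")
test presents every pairwise combination of the stimuli, from which
positive- and negative-reinforcement expression (choose-A / avoid-B) are
measured.

Two variants are provided:

* :func:`modified_pst` -- 2 pairs (80-20% and 65-35%), 240 learning trials
  in three blocks of 80, 40-trial feedback-free memory blocks, and a
  90-trial novel-pairs test (6 combinations x 15 repetitions).
* :func:`original_pst` -- 3 pairs (80-20%, 70-30%, 60-40%), learning in
  blocks of 60 (20 per pair) gated by per-pair accuracy thresholds with a
  hard cap of 7 blocks, and a 90-trial novel-pairs test
  (15 combinations x 6 repetitions).

Schedules pre-realise the feedback outcome for *each possible choice* on
every feedback trial, so a schedule plus a deterministic agent yields a
fully reproducible session.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

NO_RESPONSE = "NO_RESPONSE"

#: Phases in canonical session order.
PHASES = (
    "practice",
    "learning",
    "memory_immediate",
    "memory_30min",
    "memory_24hr",
    "novel",
)

#: Phases in which feedback is delivered.
FEEDBACK_PHASES = frozenset({"practice", "learning"})

#: Phases administered on day 2 of a two-day session.
DAY2_PHASES = frozenset({"memory_24hr", "novel"})

PRACTICE_STIMULI = ("P1", "P2")
PRACTICE_P_HI = 0.80


class TaskConfigurationError(ValueError):
    """Raised when a task specification violates its design invariants."""


@dataclass(frozen=True)
class PairSpec:
    """One learning pair: a high- and a low-probability stimulus."""

    hi: str
    lo: str
    p_hi: float

    @property
    def label(self) -> str:
        return self.hi + self.lo

    def __post_init__(self) -> None:
        if not 0.5 < self.p_hi <= 1.0:
            raise TaskConfigurationError(
                f"pair {self.hi}{self.lo}: p_hi must lie in (0.5, 1], got {self.p_hi}"
            )


@dataclass(frozen=True)
class TaskSpec:
    """Full parameterisation of a PST variant.

    Parameters
    ----------
    name : str
        Variant label, e.g. ``"modified"`` or ``"original"``.
    pairs : tuple of PairSpec
        Learning pairs.  The low stimulus of each pair is rewarded with
        probability ``1 - p_hi``.
    trials_per_learning_block : int
        Must be divisible by the number of pairs.
    n_learning_blocks : int
        Number of learning blocks; for a threshold-gated variant this is
        the maximum before training terminates unconditionally.
    threshold_gated : bool
        If True, training exits early once every pair's block accuracy
        strictly exceeds its entry in ``pass_thresholds``.
    pass_thresholds : tuple of float or None
        Per-pair accuracy thresholds (threshold-gated variants only).
    practice_trials : int
        Feedback trials on two dedicated practice stimuli (80-20%).
    memory_block_trials : int
        Trials per feedback-free memory block (0 disables memory blocks).
    novel_reps : int
        Repetitions of each unordered stimulus combination in the
        novel-pairs test.
    two_day : bool
        Whether the memory_24hr and novel phases fall on a second day
        (overnight retention applies between days).
    """

    name: str
    pairs: tuple[PairSpec, ...]
    trials_per_learning_block: int
    n_learning_blocks: int
    threshold_gated: bool = False
    pass_thresholds: tuple[float, ...] | None = None
    practice_trials: int = 40
    memory_block_trials: int = 0
    novel_reps: int = 15
    two_day: bool = False
    max_trial_duration: float = 2.0
    feedback_duration: float = 2.0

    def __post_init__(self) -> None:
        if not self.pairs:
            raise TaskConfigurationError("at least one learning pair is required")
        if self.trials_per_learning_block % len(self.pairs) != 0:
            raise TaskConfigurationError(
                f"trials_per_learning_block={self.trials_per_learning_block} is not "
                f"divisible by the number of pairs ({len(self.pairs)})"
            )
        if self.threshold_gated:
            if self.pass_thresholds is None or len(self.pass_thresholds) != len(self.pairs):
                raise TaskConfigurationError(
                    "threshold-gated variant needs one pass threshold per pair"
                )
        stims = [s for p in self.pairs for s in (p.hi, p.lo)]
        if len(set(stims)) != len(stims):
            raise TaskConfigurationError("stimulus ids must be unique across pairs")

    @property
    def stimuli(self) -> tuple[str, ...]:
        """All learning-phase stimuli in pair order (hi, lo, hi, lo, ...)."""
        return tuple(s for p in self.pairs for s in (p.hi, p.lo))

    @property
    def learning_pair_labels(self) -> tuple[str, ...]:
        return tuple(p.label for p in self.pairs)

    def reward_prob(self, stim: str) -> float:
        """Generative reward probability of a stimulus (practice included)."""
        for p in self.pairs:
            if stim == p.hi:
                return p.p_hi
            if stim == p.lo:
                return 1.0 - p.p_hi
        if stim == PRACTICE_STIMULI[0]:
            return PRACTICE_P_HI
        if stim == PRACTICE_STIMULI[1]:
            return 1.0 - PRACTICE_P_HI
        raise KeyError(f"unknown stimulus {stim!r}")


def modified_pst(novel_reps: int = 15) -> TaskSpec:
    """The two-pair variant: 80-20% and 65-35%, 240 learning trials."""
    return TaskSpec(
        name="modified",
        pairs=(PairSpec("A", "B", 0.80), PairSpec("C", "D", 0.65)),
        trials_per_learning_block=80,
        n_learning_blocks=3,
        practice_trials=40,
        memory_block_trials=40,
        novel_reps=novel_reps,
        two_day=True,
    )


def original_pst(novel_reps: int = 6) -> TaskSpec:
    """The three-pair variant: 80-20/70-30/60-40%, threshold-gated blocks of 60."""
    return TaskSpec(
        name="original",
        pairs=(
            PairSpec("A", "B", 0.80),
            PairSpec("C", "D", 0.70),
            PairSpec("E", "F", 0.60),
        ),
        trials_per_learning_block=60,
        n_learning_blocks=7,
        threshold_gated=True,
        pass_thresholds=(0.65, 0.60, 0.50),
        practice_trials=40,
        memory_block_trials=0,
        novel_reps=novel_reps,
        max_trial_duration=4.0,
    )


def get_variant(name: str, **kwargs) -> TaskSpec:
    if name == "modified":
        return modified_pst(**kwargs)
    if name == "original":
        return original_pst(**kwargs)
    raise TaskConfigurationError(f"unknown variant {name!r}")


# ---------------------------------------------------------------------------
# Trial slots and schedules


@dataclass(frozen=True)
class TrialSlot:
    """One pre-realised trial: what is shown and what each choice earns.

    ``fb_left``/``fb_right`` give the feedback (1 reward, 0 punishment)
    delivered if the left/right stimulus is chosen; ``None`` on
    feedback-free trials.
    """

    phase: str
    block: int
    trial: int
    pair_label: str
    stim_left: str
    stim_right: str
    fb_left: int | None
    fb_right: int | None
    session_day: int = 1


@dataclass
class TrialSchedule:
    """An ordered list of trial slots plus provenance."""

    spec: TaskSpec
    seed: int
    slots: list[TrialSlot] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.slots)

    def __iter__(self):
        return iter(self.slots)

    def phase_slots(self, phase: str) -> list[TrialSlot]:
        return [s for s in self.slots if s.phase == phase]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "phase": s.phase,
                "block": s.block,
                "trial": s.trial,
                "pair_label": s.pair_label,
                "stim_left": s.stim_left,
                "stim_right": s.stim_right,
                "fb_left": s.fb_left,
                "fb_right": s.fb_right,
                "session_day": s.session_day,
            }
            for s in self.slots
        ]
        df = pd.DataFrame(rows)
        df["spec_name"] = self.spec.name
        df["seed"] = self.seed
        return df

    def extend(self, other: "TrialSchedule") -> "TrialSchedule":
        return TrialSchedule(self.spec, self.seed, self.slots + other.slots)


def _interleave_pairs(
    labels: Sequence[str], counts: dict[str, int], rng: np.random.Generator, max_run: int = 3
) -> list[str]:
    """Pseudorandom interleaving of a pair-label multiset, runs capped at ``max_run``.

    Labels are drawn sequentially with probability proportional to their
    remaining count, excluding any label already shown ``max_run`` times
    in a row; rare dead-ends near the end of a sequence trigger a
    restart.  Degenerate multisets (a single label) fall through to a
    plain repetition after the attempt cap.
    """
    labs = list(labels)
    total = sum(counts[l] for l in labs)
    if len(labs) == 1:
        return labs * counts[labs[0]]
    for _ in range(1000):
        rem = dict(counts)
        out: list[str] = []
        run_lab, run_len = None, 0
        u = rng.random(total)
        for t in range(total):
            cand = [l for l in labs if rem[l] > 0 and (l != run_lab or run_len < max_run)]
            if not cand:
                break
            wsum = sum(rem[l] for l in cand)
            r = u[t] * wsum
            acc = 0.0
            pick = cand[-1]
            for l in cand:
                acc += rem[l]
                if r < acc:
                    pick = l
                    break
            out.append(pick)
            rem[pick] -= 1
            run_len = run_len + 1 if pick == run_lab else 1
            run_lab = pick
        if len(out) == total:
            return out
    return [lab for lab in labs for _ in range(counts[lab])]


def _balanced_sides(n: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean array: hi stimulus on the left, True on floor(n/2) trials."""
    sides = np.zeros(n, dtype=bool)
    sides[: n // 2] = True
    rng.shuffle(sides)
    return sides


def _realise_feedback(
    n: int, p: float, rng: np.random.Generator, mode: str
) -> np.ndarray:
    if mode == "bernoulli":
        return (rng.random(n) < p).astype(int)
    if mode == "exact":
        n_hi = int(round(p * n))
        out = np.zeros(n, dtype=int)
        out[:n_hi] = 1
        rng.shuffle(out)
        return out
    raise TaskConfigurationError(f"unknown feedback mode {mode!r}")


def _feedback_block(
    pair_order: list[str],
    pairs: dict[str, PairSpec],
    fb_streams: dict[str, tuple[list[int], list[int]]],
    sides_by_pair: dict[str, np.ndarray],
    phase: str,
    block: int,
    trial_offset: int,
    session_day: int = 1,
) -> list[TrialSlot]:
    slots = []
    seen: dict[str, int] = {lab: 0 for lab in pairs}
    for i, lab in enumerate(pair_order):
        pair = pairs[lab]
        k = seen[lab]
        seen[lab] += 1
        hi_left = bool(sides_by_pair[lab][k])
        fb_hi, fb_lo = fb_streams[lab][0].pop(0), fb_streams[lab][1].pop(0)
        slots.append(
            TrialSlot(
                phase=phase,
                block=block,
                trial=trial_offset + i,
                pair_label=lab,
                stim_left=pair.hi if hi_left else pair.lo,
                stim_right=pair.lo if hi_left else pair.hi,
                fb_left=fb_hi if hi_left else fb_lo,
                fb_right=fb_lo if hi_left else fb_hi,
                session_day=session_day,
            )
        )
    return slots


def build_learning_schedule(
    spec: TaskSpec, seed: int, feedback_mode: str = "bernoulli"
) -> TrialSchedule:
    """Generate all learning blocks with pre-realised feedback.

    Each block contains every pair equally often, no more than three
    consecutive presentations of the same pair, and the high stimulus on
    the left on exactly half of each pair's trials per block (floor for
    odd counts).  In ``"exact"`` feedback mode the feedback multiset of
    each stimulus matches its nominal probability exactly over the whole
    schedule; the default draws i.i.d. Bernoulli outcomes per trial.
    """
    rng = np.random.default_rng(seed)
    pairs = {p.label: p for p in spec.pairs}
    n_per_pair_block = spec.trials_per_learning_block // len(spec.pairs)
    n_blocks = spec.n_learning_blocks
    total_per_pair = n_per_pair_block * n_blocks

    # Whole-schedule feedback streams per pair, consumed block by block.
    fb_streams: dict[str, tuple[list[int], list[int]]] = {}
    for lab, pair in pairs.items():
        hi = list(_realise_feedback(total_per_pair, pair.p_hi, rng, feedback_mode))
        lo = list(_realise_feedback(total_per_pair, 1.0 - pair.p_hi, rng, feedback_mode))
        fb_streams[lab] = (hi, lo)

    sched = TrialSchedule(spec, seed)
    for b in range(n_blocks):
        counts = {lab: n_per_pair_block for lab in pairs}
        order = _interleave_pairs(list(pairs), counts, rng)
        sides = {lab: _balanced_sides(n_per_pair_block, rng) for lab in pairs}
        sched.slots.extend(
            _feedback_block(order, pairs, fb_streams, sides, "learning", b, 0)
        )
    return sched


def build_practice_schedule(
    spec: TaskSpec, seed: int, feedback_mode: str = "bernoulli"
) -> TrialSchedule:
    """Practice block on two dedicated stimuli with an 80-20% contingency."""
    rng = np.random.default_rng(seed)
    n = spec.practice_trials
    pair = PairSpec(PRACTICE_STIMULI[0], PRACTICE_STIMULI[1], PRACTICE_P_HI)
    fb_streams = {
        pair.label: (
            list(_realise_feedback(n, pair.p_hi, rng, feedback_mode)),
            list(_realise_feedback(n, 1 - pair.p_hi, rng, feedback_mode)),
        )
    }
    sides = {pair.label: _balanced_sides(n, rng)}
    sched = TrialSchedule(spec, seed)
    sched.slots.extend(
        _feedback_block([pair.label] * n, {pair.label: pair}, fb_streams, sides, "practice", 0, 0)
    )
    return sched


def build_memory_schedule(spec: TaskSpec, phase: str, seed: int) -> TrialSchedule:
    """One feedback-free memory block, trials split equally across pairs."""
    if phase not in {"memory_immediate", "memory_30min", "memory_24hr"}:
        raise TaskConfigurationError(f"not a memory phase: {phase!r}")
    rng = np.random.default_rng(seed)
    n = spec.memory_block_trials
    n_per_pair = n // len(spec.pairs)
    pairs = {p.label: p for p in spec.pairs}
    order = _interleave_pairs(list(pairs), {lab: n_per_pair for lab in pairs}, rng)
    sides = {lab: _balanced_sides(n_per_pair, rng) for lab in pairs}
    day = 2 if (phase == "memory_24hr" and spec.two_day) else 1
    sched = TrialSchedule(spec, seed)
    seen = {lab: 0 for lab in pairs}
    for i, lab in enumerate(order):
        pair = pairs[lab]
        hi_left = bool(sides[lab][seen[lab]])
        seen[lab] += 1
        sched.slots.append(
            TrialSlot(
                phase=phase,
                block=0,
                trial=i,
                pair_label=lab,
                stim_left=pair.hi if hi_left else pair.lo,
                stim_right=pair.lo if hi_left else pair.hi,
                fb_left=None,
                fb_right=None,
                session_day=day,
            )
        )
    return sched


def build_novel_schedule(spec: TaskSpec, seed: int) -> TrialSchedule:
    """Feedback-free test of every unordered stimulus combination.

    Contains C(n_stimuli, 2) combinations, each ``spec.novel_reps`` times,
    in random order with random left/right placement balanced per
    combination.
    """
    rng = np.random.default_rng(seed)
    combos = list(itertools.combinations(spec.stimuli, 2))
    slots: list[tuple[str, str]] = []
    for a, b in combos:
        sides = _balanced_sides(spec.novel_reps, rng)
        for first_left in sides:
            slots.append((a, b) if first_left else (b, a))
    idx = rng.permutation(len(slots))
    day = 2 if spec.two_day else 1
    sched = TrialSchedule(spec, seed)
    for i, j in enumerate(idx):
        left, right = slots[j]
        sched.slots.append(
            TrialSlot(
                phase="novel",
                block=0,
                trial=i,
                pair_label="".join(sorted((left, right))),
                stim_left=left,
                stim_right=right,
                fb_left=None,
                fb_right=None,
                session_day=day,
            )
        )
    return sched


def build_session_schedule(
    spec: TaskSpec, seed: int, feedback_mode: str = "bernoulli"
) -> TrialSchedule:
    """Complete session: practice, learning, memory blocks (if any), novel.

    Child seeds are spawned deterministically from ``seed`` so each phase
    has its own stream; the whole schedule is bit-identical for identical
    ``(spec, seed)``.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(6)
    phase_seed = lambda i: int(children[i].generate_state(1)[0] % (2**31))

    sched = build_practice_schedule(spec, phase_seed(0), feedback_mode)
    sched = sched.extend(build_learning_schedule(spec, phase_seed(1), feedback_mode))
    if spec.memory_block_trials > 0:
        sched = sched.extend(build_memory_schedule(spec, "memory_immediate", phase_seed(2)))
        sched = sched.extend(build_memory_schedule(spec, "memory_30min", phase_seed(3)))
        if spec.two_day:
            sched = sched.extend(build_memory_schedule(spec, "memory_24hr", phase_seed(4)))
    if spec.novel_reps > 0:
        sched = sched.extend(build_novel_schedule(spec, phase_seed(5)))
    return TrialSchedule(spec, seed, sched.slots)


def check_block_thresholds(
    block_accuracies: Sequence[float], spec: TaskSpec
) -> bool:
    """True iff every pair's block accuracy *strictly* exceeds its threshold.

    Used by the threshold-gated variant to decide whether training exits
    after a block; ties fail.  Training terminates unconditionally after
    ``spec.n_learning_blocks`` regardless.
    """
    if not spec.threshold_gated:
        raise TaskConfigurationError("spec is not threshold-gated")
    if len(block_accuracies) != len(spec.pairs):
        raise ValueError(
            f"expected {len(spec.pairs)} accuracies, got {len(block_accuracies)}"
        )
    for acc in block_accuracies:
        if not 0.0 <= acc <= 1.0:
            raise ValueError(f"accuracy {acc} outside [0, 1]")
    return all(
        acc > thr for acc, thr in zip(block_accuracies, spec.pass_thresholds)
    )


# ---------------------------------------------------------------------------
# Stimulus-version counterbalancing

GREEK = ("psi", "xi", "phi", "zeta", "omega", "eta", "mu", "nu", "rho", "tau")


def version_symbol_map(spec: TaskSpec, version: int) -> dict[str, str]:
    """Map stimulus roles (A, B, ...) to display symbols for a task version.

    Each version uses a distinct symbol set, and which of the pair's two
    symbols plays the high-probability role alternates across versions
    (bit ``version & 1``), so roles are counterbalanced over versions.
    """
    if version < 0:
        raise TaskConfigurationError("version index must be >= 0")
    mapping: dict[str, str] = {}
    flip = bool(version & 1)
    for i, pair in enumerate(spec.pairs):
        s1 = f"v{version}_{GREEK[2 * i % len(GREEK)]}"
        s2 = f"v{version}_{GREEK[(2 * i + 1) % len(GREEK)]}"
        mapping[pair.hi], mapping[pair.lo] = (s2, s1) if flip else (s1, s2)
    return mapping
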