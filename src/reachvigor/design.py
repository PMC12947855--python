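"""Experimental design: trial schedules, reward assignment, and derived quantities.

The task is a four-target out-and-back reaching "bandit": targets sit on a
10 cm ring at 45, 135, 225 and 315 degrees, and within a block each target
carries one of the reward probabilities {0, 1/3, 2/3, 1} (a bijection).  The
135 and 315 degree targets lie along the arm's high-inertia axis and are
coded as high-effort.  Schedules are pseudorandomized in sets of 36 single
trials: every target is cued exactly 9 times per set and rewarded exactly
round(9 p) times, so realized reward frequency matches the nominal
probability exactly within every complete set.

Two schedule modes exist:

* ``instructed`` — probabilities announced to the participant; 180 single
  trials per block (5 sets of 36).
* ``learned`` — probabilities hidden; 144 single trials (4 sets) followed by
  36 two-alternative choice trials (each of the 6 unordered target pairs
  6 times) with no reward feedback.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TARGET_ANGLES = {1: 45.0, 2: 135.0, 3: 225.0, 4: 315.0}
HIGH_EFFORT_TARGETS = frozenset({2, 4})  # 135 and 315 degrees: high effective mass
DESIGN_PROBABILITIES = (Fraction(0), Fraction(1, 3), Fraction(2, 3), Fraction(1))

SET_SIZE = 36
CUES_PER_SET = 9
N_CHOICE_TRIALS = 36
N_PAIR_REPEATS = 6
N_BLOCKS = 4
BLOCK_TRIALS = 180


class InvalidDesignError(ValueError):
    """Raised when a schedule request violates the design constraints."""


@dataclass(frozen=True)
class TargetSpec:
    """One reach target: identity, direction, reward probability, effort class."""

    target_id: int
    angle: float
    reward_prob: Fraction
    high_effort: bool

    def __post_init__(self) -> None:
        if self.target_id not in TARGET_ANGLES:
            raise InvalidDesignError(f"unknown target id {self.target_id}")
        if self.angle != TARGET_ANGLES[self.target_id]:
            raise InvalidDesignError(
                f"target {self.target_id} must sit at {TARGET_ANGLES[self.target_id]} deg"
            )
        if self.high_effort != (self.target_id in HIGH_EFFORT_TARGETS):
            raise InvalidDesignError("high_effort flag inconsistent with target angle")


@dataclass
class BlockSchedule:
    """Ordered trial list for one 180-trial block (plus optional familiarization)."""

    block_id: int
    probabilities: dict[int, Fraction]
    mode: str
    trials: pd.DataFrame = field(repr=False)

    @property
    def n_single(self) -> int:
        t = self.trials
        return int(((t.trial_type == "single") & ~t.familiarization).sum())

    @property
    def n_choice(self) -> int:
        t = self.trials
        return int(((t.trial_type == "choice") & ~t.familiarization).sum())


def _validate_probabilities(probabilities: Mapping[int, object]) -> dict[int, Fraction]:
    probs = {int(k): Fraction(v).limit_denominator(3) for k, v in probabilities.items()}
    if sorted(probs) != [1, 2, 3, 4]:
        raise InvalidDesignError("probability map must cover targets 1..4")
    if sorted(probs.values()) != sorted(DESIGN_PROBABILITIES):
        raise InvalidDesignError(
            "probabilities must be a bijection onto {0, 1/3, 2/3, 1}"
        )
    return probs


def target_specs(probabilities: Mapping[int, object]) -> list[TargetSpec]:
    """Build the four :class:`TargetSpec` objects for one block."""
    probs = _validate_probabilities(probabilities)
    return [
        TargetSpec(t, TARGET_ANGLES[t], probs[t], t in HIGH_EFFORT_TARGETS)
        for t in sorted(probs)
    ]


def _single_trial_set(
    probs: dict[int, Fraction], rng: np.random.Generator
) -> list[tuple[int, int]]:
    """One pseudorandomized 36-trial set: (target, reward) with exact counts."""
    trials: list[tuple[int, int]] = []
    for t, p in probs.items():
        n_rewarded = round(CUES_PER_SET * float(p))
        rewards = np.zeros(CUES_PER_SET, dtype=int)
        rewards[rng.choice(CUES_PER_SET, size=n_rewarded, replace=False)] = 1
        trials.extend((t, int(r)) for r in rewards)
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


def _choice_trial_block(rng: np.random.Generator) -> list[tuple[int, int]]:
    """36 choice trials: each unordered pair of the 4 targets, 6 times, shuffled."""
    pairs = list(itertools.combinations(sorted(TARGET_ANGLES), 2))
    reps = pairs * N_PAIR_REPEATS
    order = rng.permutation(len(reps))
    return [reps[i] for i in order]


def build_block_schedule(
    probabilities: Mapping[int, object],
    mode: str = "learned",
    seed: int = 0,
    block_id: int = 1,
    familiarization: bool = False,
) -> BlockSchedule:
    """Construct one block's pseudorandomized schedule.

    Parameters
    ----------
    probabilities
        Map target id (1..4) -> reward probability; must be a bijection onto
        {0, 1/3, 2/3, 1}.
    mode
        ``"instructed"`` (180 single trials) or ``"learned"`` (144 single +
        36 choice trials).
    seed
        Seeds the within-set permutations and reward-slot assignment; equal
        seeds give identical schedules.
    familiarization
        Prepend reward-free familiarization trials (16 single; plus 8 choice
        in learned mode), flagged ``familiarization=True``.
    """
    probs = _validate_probabilities(probabilities)
    if mode not in ("instructed", "learned"):
        raise InvalidDesignError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, block_id]))

    rows: list[dict] = []

    def add_single(target: int, reward: int, fam: bool) -> None:
        rows.append(
            dict(
                block=block_id,
                trial_type="single",
                target=target,
                alt_target=pd.NA,
                e_r=float(probs[target]),
                reward=reward,
                familiarization=fam,
                cue_delay_ms=float(rng.uniform(800.0, 1000.0)),
            )
        )

    def add_choice(a: int, b: int, fam: bool) -> None:
        rows.append(
            dict(
                block=block_id,
                trial_type="choice",
                target=a,
                alt_target=b,
                e_r=np.nan,
                reward=0,
                familiarization=fam,
                cue_delay_ms=float(rng.uniform(800.0, 1000.0)),
            )
        )

    if familiarization:
        fam_targets = [t for t in sorted(probs) for _ in range(4)]
        for i in rng.permutation(len(fam_targets)):
            add_single(fam_targets[i], 0, True)
        if mode == "learned":
            pairs = list(itertools.combinations(sorted(TARGET_ANGLES), 2))
            picks = rng.choice(len(pairs), size=8, replace=True)
            for i in picks:
                add_choice(*pairs[i], True)

    n_sets = 5 if mode == "instructed" else 4
    for _ in range(n_sets):
        for target, reward in _single_trial_set(probs, rng):
            add_single(target, reward, False)
    if mode == "learned":
        for a, b in _choice_trial_block(rng):
            add_choice(a, b, False)

    trials = pd.DataFrame(rows)
    trials.insert(1, "trial", np.arange(1, len(trials) + 1))
    return BlockSchedule(block_id=block_id, probabilities=probs, mode=mode, trials=trials)


def build_experiment_schedule(
    block_probabilities: Sequence[Mapping[int, object]] | None = None,
    mode: str = "learned",
    seed: int = 0,
    familiarization: bool = False,
) -> list[BlockSchedule]:
    """Four-block experiment; probability-target assignment rotates per block
    unless explicit per-block maps are given."""
    if block_probabilities is None:
        base = list(DESIGN_PROBABILITIES)
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 977]))
        block_probabilities = []
        for _ in range(N_BLOCKS):
            perm = rng.permutation(4)
            block_probabilities.append({t: base[perm[t - 1]] for t in (1, 2, 3, 4)})
    return [
        build_block_schedule(
            probs,
            mode=mode,
            seed=seed,
            block_id=i + 1,
            familiarization=familiarization and i == 0,
        )
        for i, probs in enumerate(block_probabilities)
    ]


def compute_rpe(reward: float, expectation: float) -> float:
    """Reward prediction error: received reward minus expected reward probability."""
    if reward not in (0, 1):
        raise ValueError(f"reward must be binary, got {reward}")
    if not 0.0 <= expectation <= 1.0:
        raise ValueError(f"expectation must lie in [0, 1], got {expectation}")
    return float(reward) - float(expectation)


def enumerate_design_rpes() -> set[Fraction]:
    """Distinct achievable RPE values over all (probability, outcome) pairs.

    Outcomes with zero schedule probability (reward at p=0, omission at p=1)
    are unreachable and excluded; the design yields exactly five RPE levels,
    symmetric about zero.
    """
    rpes: set[Fraction] = set()
    for p in DESIGN_PROBABILITIES:
        for r in (0, 1):
            prob_of_outcome = p if r == 1 else 1 - p
            if prob_of_outcome > 0:
                rpes.add(Fraction(r) - p)
    return rpes


def max_expected_chosen_reward() -> Fraction:
    """Best possible summed chosen expectation over all choice trials.

    Each of the 6 unordered pairs of {0, 1/3, 2/3, 1} contributes its larger
    probability once per block; each pair repeats 6 times but the published
    normalizer counts each pair once per block across the 4 blocks: 4 x 14/3
    = 56/3.
    """
    pairs = itertools.combinations(DESIGN_PROBABILITIES, 2)
    per_block = sum(max(a, b) for a, b in pairs)
    return N_BLOCKS * per_block


def max_expected_chosen_reward_printed() -> float:
    """Two-decimal display form of the bonus denominator (truncated, 18.66)."""
    exact = float(max_expected_chosen_reward())
    return np.floor(exact * 100.0) / 100.0


def bonus_compensation(chosen_expectations: Iterable[float]) -> float:
    """Performance bonus in dollars: sum of chosen E[R], normalized by the
    maximum potential expected chosen reward (56/3), times $5; clipped to [0, 5]."""
    allowed = {float(p) for p in DESIGN_PROBABILITIES}
    total = 0.0
    for e in chosen_expectations:
        if not any(np.isclose(float(e), a, atol=1e-9) for a in allowed):
            raise ValueError(f"chosen expectation {e} is not a design probability")
        total += float(e)
    dollars = total / float(max_expected_chosen_reward()) * 5.0
    return float(np.clip(dollars, 0.0, 5.0))


def schedule_to_frame(schedules: Sequence[BlockSchedule]) -> pd.DataFrame:
    """Concatenate block schedules into the canonical trial table."""
    return pd.concat([s.trials for s in schedules], ignore_index=True)
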