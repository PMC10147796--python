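"""Behavioral scheduling: rotational stimulus schemes, sessions, criterion.

A training session has 10 two-alternative trials; the rewarded (positive)
stimulus appears on each tank side exactly 5 times and never more than
twice in a row on the same side.  Such a balanced, run-limited left/right
sequence is a *rotational scheme*; four schemes fixed before the
experiment are cycled over every four sessions (two sessions per day).
The learning criterion is >= 7 correct choices out of 10 in three
consecutive sessions, detected at its first attainment.

The habituation (novelty) group instead receives food-paired stimulus
presentations: 4 trials per session, 3 sessions per day over the
habituation days, and a single session on the final day followed later by
one novel-stimulus presentation; the inter-event delays (30 s stimulus to
food, stimulus off 2 min after food, 5 min between trials) are carried as
schedule metadata.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialScheme",
    "SessionRecord",
    "HabituationSchedule",
    "validate_scheme",
    "generate_scheme",
    "count_valid_schemes",
    "enumerate_valid_schemes",
    "schedule_sessions",
    "criterion_met",
    "simulate_learner",
]

N_TRIALS = 10
N_PER_SIDE = 5
MAX_RUN = 2
CRITERION_CORRECT = 7
CRITERION_WINDOW = 3


def _max_run_length(sides: Sequence[str]) -> int:
    longest = run = 0
    prev = None
    for s in sides:
        run = run + 1 if s == prev else 1
        prev = s
        longest = max(longest, run)
    return longest


def validate_scheme(sides: Sequence[str], n_per_side: int = N_PER_SIDE,
                    max_run: int = MAX_RUN) -> bool:
    """True iff the sequence is 5/5 balanced with no run of 3+ same sides."""
    sides = list(sides)
    if len(sides) != 2 * n_per_side or set(sides) - {"L", "R"}:
        return False
    if sides.count("L") != n_per_side:
        return False
    return _max_run_length(sides) <= max_run


@dataclass(frozen=True)
class TrialScheme:
    """Side sequence of the positive stimulus for one 10-trial session."""

    sides: tuple[str, ...]

    def __post_init__(self) -> None:
        if not validate_scheme(self.sides):
            raise ValueError(
                f"invalid rotational scheme {''.join(self.sides)!r}: must be "
                f"{N_PER_SIDE}/{N_PER_SIDE} balanced with runs <= {MAX_RUN}")

    @classmethod
    def from_string(cls, s: str) -> "TrialScheme":
        return cls(tuple(s))

    def __str__(self) -> str:
        return "".join(self.sides)


def generate_scheme(seed: int | np.random.Generator) -> TrialScheme:
    """Draw a scheme uniformly from the valid set by rejection sampling.

    Balanced 5L/5R permutations are drawn uniformly and resampled until the
    run constraint holds, which leaves the distribution uniform over the
    (84-element) valid set.
    """
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    base = np.array(["L"] * N_PER_SIDE + ["R"] * N_PER_SIDE)
    while True:
        perm = rng.permutation(base)
        if _max_run_length(perm) <= MAX_RUN:
            return TrialScheme(tuple(perm))


def enumerate_valid_schemes(n_trials: int = N_TRIALS,
                            n_per_side: int = N_PER_SIDE,
                            max_run: int = MAX_RUN) -> list[str]:
    """All valid schemes, by exhaustive enumeration of balanced sequences."""
    if 2 * n_per_side != n_trials:
        raise ValueError("need n_per_side * 2 == n_trials")
    out = []
    for pos in itertools.combinations(range(n_trials), n_per_side):
        sides = ["R"] * n_trials
        for p in pos:
            sides[p] = "L"
        if _max_run_length(sides) <= max_run:
            out.append("".join(sides))
    return out


def count_valid_schemes(n_trials: int = N_TRIALS, n_per_side: int = N_PER_SIDE,
                        max_run: int = MAX_RUN) -> int:
    """Exact number of valid schemes (84 for the 10-trial session)."""
    return len(enumerate_valid_schemes(n_trials, n_per_side, max_run))


@dataclass(frozen=True)
class SessionRecord:
    """Outcome of one 10-trial session."""

    session_index: int  # 1-based
    trials: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.trials) != N_TRIALS:
            raise ValueError(
                f"session {self.session_index} has {len(self.trials)} trials, "
                f"expected {N_TRIALS}")

    @property
    def n_correct(self) -> int:
        return int(sum(self.trials))

    @classmethod
    def from_count(cls, session_index: int, n_correct: int) -> "SessionRecord":
        if not 0 <= n_correct <= N_TRIALS:
            raise ValueError("n_correct must lie in [0, 10]")
        return cls(session_index,
                   tuple([True] * n_correct + [False] * (N_TRIALS - n_correct)))


def schedule_sessions(schemes: Sequence[TrialScheme], n_sessions: int,
                      sessions_per_day: int = 2) -> pd.DataFrame:
    """Cycle the four rotational schemes over consecutive sessions.

    Session ``s`` (1-based) uses scheme ``(s - 1) mod 4``; with two
    sessions per day at fixed times, the frame also labels day and slot.
    """
    if len(schemes) != 4:
        raise ValueError(f"exactly 4 rotational schemes required, got {len(schemes)}")
    if n_sessions < 0:
        raise ValueError("n_sessions must be >= 0")
    rows = [{
        "session_index": s,
        "day": (s - 1) // sessions_per_day + 1,
        "slot": (s - 1) % sessions_per_day + 1,
        "scheme_index": (s - 1) % 4 + 1,
        "scheme": str(schemes[(s - 1) % 4]),
    } for s in range(1, n_sessions + 1)]
    return pd.DataFrame(rows, columns=["session_index", "day", "slot",
                                       "scheme_index", "scheme"])


def criterion_met(sessions: Sequence[SessionRecord],
                  n_correct_min: int = CRITERION_CORRECT,
                  window: int = CRITERION_WINDOW) -> int | None:
    """First session index completing >= 7/10 in three consecutive sessions.

    Returns the 1-based position (within the ordered list) of the session
    that completes the first qualifying window, or ``None``.
    """
    counts = [s.n_correct for s in sessions]
    for end in range(window, len(counts) + 1):
        if all(c >= n_correct_min for c in counts[end - window:end]):
            return end
    return None


def simulate_learner(p_correct_by_session: Sequence[float],
                     seed: int | np.random.Generator = 0,
                     ) -> list[SessionRecord]:
    """Bernoulli learner: per-session success probability, 10 trials each."""
    ps = np.asarray(p_correct_by_session, dtype=float)
    if ps.size and (ps.min() < 0 or ps.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    return [SessionRecord(i + 1, tuple(rng.random(N_TRIALS) < p))
            for i, p in enumerate(ps)]


@dataclass(frozen=True)
class HabituationSchedule:
    """Habituation–dishabituation timetable of the novelty group.

    Habituation days carry ``sessions_per_day`` sessions of
    ``trials_per_session`` food-paired stimulus presentations; the final
    day has a single session, and the novel stimulus is shown once, later
    that day, for 30 s.  Delays are metadata, in seconds.
    """

    n_days: int = 5
    trials_per_session: int = 4
    sessions_per_day: int = 3
    final_day_sessions: int = 1
    stimulus_to_food_s: float = 30.0
    stimulus_off_after_food_s: float = 120.0
    inter_trial_s: float = 300.0
    dishabituation_presentation_s: float = 30.0

    def __post_init__(self) -> None:
        if min(self.n_days, self.trials_per_session, self.sessions_per_day,
               self.final_day_sessions) < 1:
            raise ValueError("schedule counts must be >= 1")

    def sessions_on_day(self, day: int) -> int:
        if not 1 <= day <= self.n_days:
            raise ValueError(f"day {day} outside schedule of {self.n_days} days")
        return self.final_day_sessions if day == self.n_days else \
            self.sessions_per_day

    @property
    def total_sessions(self) -> int:
        return sum(self.sessions_on_day(d) for d in range(1, self.n_days + 1))

    @property
    def total_trials(self) -> int:
        return self.total_sessions * self.trials_per_session

    def to_frame(self) -> pd.DataFrame:
        """One row per trial: day, session, trial and event delays."""
        rows = [{
            "day": d, "session": s, "trial": t,
            "stimulus_to_food_s": self.stimulus_to_food_s,
            "stimulus_off_after_food_s": self.stimulus_off_after_food_s,
            "inter_trial_s": self.inter_trial_s,
        }
            for d in range(1, self.n_days + 1)
            for s in range(1, self.sessions_on_day(d) + 1)
            for t in range(1, self.trials_per_session + 1)]
        return pd.DataFrame(rows)
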