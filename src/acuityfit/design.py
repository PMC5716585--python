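"""Pseudo-randomized 2AFC session schedules.

A session is an ordered list of trials, each showing the rewarded grating on
the left or the right at one spatial frequency.  Two presentation modes are
supported:

* ``dog_interleaved`` — frequencies are interleaved in pseudo-random order,
  the first scored trial is always the lowest (easiest) frequency, and two
  unscored warm-up trials at the lowest frequency precede data collection.
* ``human_blocked`` — each frequency is tested in a contiguous block of
  trials, blocks in ascending frequency order, no warm-ups.

In both modes the rewarded side is pseudo-randomized under two constraints:
the correct side never repeats more than twice in a row, and within each
frequency the left/right counts of scored trials are balanced to within one.

Generation assigns sides trial by trial, choosing uniformly among the sides
that keep both constraints satisfiable, and restarts from scratch on a dead
end; a bounded retry cap makes impossible requests fail loudly rather than
loop.  All randomness flows through a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Trial",
    "SessionSchedule",
    "ScheduleGenerationError",
    "generate_dog_session",
    "generate_human_session",
    "validate_schedule",
    "schedule_to_frame",
    "schedule_from_frame",
]

SIDES = ("left", "right")
MAX_CONSECUTIVE_SIDE = 2


class ScheduleGenerationError(RuntimeError):
    """Raised when the constraint set cannot be satisfied within the retry cap."""


@dataclass(frozen=True)
class Trial:
    frequency: float
    correct_side: str
    warmup: bool = False

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError(f"frequency must be positive, got {self.frequency}")
        if self.correct_side not in SIDES:
            raise ValueError(f"correct_side must be one of {SIDES}")


@dataclass(frozen=True)
class SessionSchedule:
    trials: tuple[Trial, ...]
    mode: str  # "dog_interleaved" | "human_blocked"
    seed: int

    @property
    def scored(self) -> tuple[Trial, ...]:
        return tuple(t for t in self.trials if not t.warmup)

    @property
    def frequencies(self) -> tuple[float, ...]:
        return tuple(sorted({t.frequency for t in self.scored}))


def _assign_sides(
    freq_order: list[float],
    warmup_flags: list[bool],
    rng: np.random.Generator,
    max_restarts: int,
) -> list[str]:
    """Sequential side assignment under the run and balance constraints.

    Scored trials draw from per-frequency quotas (n//2 each side plus a
    randomly-assigned extra for odd counts); warm-ups are quota-free.  A
    trial with no admissible side triggers a restart.
    """
    scored_counts: dict[float, int] = {}
    for f, w in zip(freq_order, warmup_flags):
        if not w:
            scored_counts[f] = scored_counts.get(f, 0) + 1

    for _ in range(max_restarts):
        quota = {}
        for f, n in scored_counts.items():
            left = n // 2 + (int(rng.integers(2)) if n % 2 else 0)
            quota[f] = {"left": left, "right": n - left}
        sides: list[str] = []
        ok = True
        for f, w in zip(freq_order, warmup_flags):
            allowed = [
                s
                for s in SIDES
                if (w or quota[f][s] > 0)
                and not (len(sides) >= 2 and sides[-1] == sides[-2] == s)
            ]
            if not allowed:
                ok = False
                break
            # weight by remaining quota so no side's pool drains early and
            # forces a third repeat later; warm-ups are unweighted
            if len(allowed) == 1:
                s = allowed[0]
            else:
                w0 = 1.0 if w else float(quota[f][allowed[0]])
                w1 = 1.0 if w else float(quota[f][allowed[1]])
                s = allowed[0] if rng.random() * (w0 + w1) < w0 else allowed[1]
            sides.append(s)
            if not w:
                quota[f][s] -= 1
        if ok:
            return sides
    raise ScheduleGenerationError(
        f"could not satisfy side constraints within {max_restarts} restarts"
    )


def generate_dog_session(
    frequencies: list[float],
    trials_per_freq: int,
    seed: int,
    *,
    n_warmup: int = 2,
    max_restarts: int = 10_000,
) -> SessionSchedule:
    """Interleaved session: pseudo-random frequency order, lowest frequency first.

    Returns ``n_warmup`` warm-up trials at the lowest frequency followed by
    ``len(frequencies) * trials_per_freq`` scored trials.  Reproducible from
    ``seed``.
    """
    if not frequencies:
        raise ValueError("frequencies must be non-empty")
    if trials_per_freq < 1:
        raise ValueError("trials_per_freq must be >= 1")
    rng = np.random.default_rng(seed)
    freqs = sorted(float(f) for f in frequencies)
    lowest = freqs[0]

    order = np.repeat(freqs, trials_per_freq).astype(float)
    order = list(rng.permutation(order))
    # the first scored trial is always the lowest frequency
    first_low = order.index(lowest)
    order[0], order[first_low] = order[first_low], order[0]

    full_order = [lowest] * n_warmup + order
    flags = [True] * n_warmup + [False] * len(order)
    sides = _assign_sides(full_order, flags, rng, max_restarts)
    trials = tuple(Trial(f, s, w) for f, s, w in zip(full_order, sides, flags))
    return SessionSchedule(trials=trials, mode="dog_interleaved", seed=seed)


def generate_human_session(
    frequencies: list[float],
    trials_per_freq: int,
    seed: int,
    *,
    max_restarts: int = 10_000,
) -> SessionSchedule:
    """Blocked session: ascending contiguous frequency blocks, sides randomized."""
    if not frequencies:
        raise ValueError("frequencies must be non-empty")
    if trials_per_freq < 1:
        raise ValueError("trials_per_freq must be >= 1")
    rng = np.random.default_rng(seed)
    freqs = sorted(float(f) for f in frequencies)
    order = [f for f in freqs for _ in range(trials_per_freq)]
    flags = [False] * len(order)
    sides = _assign_sides(order, flags, rng, max_restarts)
    trials = tuple(Trial(f, s, w) for f, s, w in zip(order, sides, flags))
    return SessionSchedule(trials=trials, mode="human_blocked", seed=seed)


def validate_schedule(schedule: SessionSchedule) -> list[str]:
    """Check all design invariants; return one message per violation.

    Rules checked: max two consecutive trials with the same correct side
    (warm-ups included), per-frequency scored left/right balance within one,
    lowest-frequency-first for interleaved mode, and ascending contiguous
    blocks for blocked mode.  An empty list means the schedule is valid.
    """
    violations: list[str] = []
    trials = schedule.trials

    run = 0
    for i, t in enumerate(trials):
        run = run + 1 if i > 0 and t.correct_side == trials[i - 1].correct_side else 1
        if run > MAX_CONSECUTIVE_SIDE:
            violations.append(
                f"max-2-consecutive-side: trial {i} extends a run of {run} "
                f"consecutive '{t.correct_side}' trials"
            )

    scored = [t for t in trials if not t.warmup]
    by_freq: dict[float, list[str]] = {}
    for t in scored:
        by_freq.setdefault(t.frequency, []).append(t.correct_side)
    for f, sides in sorted(by_freq.items()):
        n_left = sides.count("left")
        if abs(n_left - (len(sides) - n_left)) > 1:
            violations.append(
                f"side-balance: frequency {f} cpd has {n_left} left / "
                f"{len(sides) - n_left} right scored trials (must differ by <= 1)"
            )

    if schedule.mode == "dog_interleaved":
        if scored and scored[0].frequency != min(by_freq):
            idx = trials.index(scored[0])
            violations.append(
                f"first-trial-lowest-frequency: trial {idx} starts scoring at "
                f"{scored[0].frequency} cpd, lowest tested is {min(by_freq)} cpd"
            )
    elif schedule.mode == "human_blocked":
        seq = [t.frequency for t in scored]
        block_order = [f for i, f in enumerate(seq) if i == 0 or f != seq[i - 1]]
        if len(block_order) != len(set(block_order)) or block_order != sorted(block_order):
            violations.append(
                "ascending-blocks: scored frequencies are not in ascending "
                f"contiguous blocks (block sequence {block_order})"
            )
    else:
        violations.append(f"unknown-mode: {schedule.mode!r}")
    return violations


def schedule_to_frame(schedule: SessionSchedule) -> pd.DataFrame:
    """Serialize as a table with columns trial_index, frequency_cpd, correct_side, warmup."""
    return pd.DataFrame(
        {
            "trial_index": range(len(schedule.trials)),
            "frequency_cpd": [t.frequency for t in schedule.trials],
            "correct_side": [t.correct_side for t in schedule.trials],
            "warmup": [t.warmup for t in schedule.trials],
        }
    )


def schedule_from_frame(
    frame: pd.DataFrame, mode: str = "dog_interleaved", seed: int = -1
) -> SessionSchedule:
    frame = frame.sort_values("trial_index")
    trials = tuple(
        Trial(float(r.frequency_cpd), str(r.correct_side), bool(r.warmup))
        for r in frame.itertuples()
    )
    return SessionSchedule(trials=trials, mode=mode, seed=seed)
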