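"""Synthetic 2AFC observer driven by a Weibull psychometric function.

The response model is

    psi(x) = gamma + (1 - gamma - lambda) * (1 - exp(-(x / a) ** b))

with guess rate gamma = 0.5 (two-alternative forced choice: the lower
asymptote is chance), lapse rate lambda in [0, 0.2] (the upper asymptote is
1 - lambda: even trivially easy trials are missed at the lapse rate), scale
a > 0 and steepness b > 0.

AXIS CONVENTION (important).  psi as written above is *increasing* in x,
but discrimination performance *falls* as grating spatial frequency rises.
The model is therefore evaluated on a reversed performance axis

    x' = axis_origin - frequency,   axis_origin = top of the tested grid,

so that x' = 0 (performance exactly at chance) sits at the highest tested
frequency and x' grows toward easy, low-frequency gratings.  All thresholds
are mapped back to cycles per degree on the original axis.  This is one
consistent way to drive an increasing Weibull with a decreasing performance
curve; it is a modelling choice of this package, stated openly because the
mapping is not uniquely determined by the functional form alone.

The module simulates Bernoulli trial-by-trial responses on a session
schedule and aggregates them to per-frequency (n_correct, n_total) counts —
the shape of a real observer's data sheet — so every downstream stage
(fitting, binomial criteria, the pipeline) can be exercised without any
study data.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import SessionSchedule, generate_dog_session, generate_human_session

__all__ = [
    "PsychometricParams",
    "ChoiceData",
    "STUDY_PROFILES",
    "psi",
    "weibull_quantile",
    "performance_axis",
    "params_for_threshold",
    "simulate_choices",
    "make_study_fixture",
]

GUESS_RATE_2AFC = 0.5
MAX_LAPSE = 0.2


@dataclass(frozen=True)
class PsychometricParams:
    """Weibull psychometric-function parameters (a, b, gamma, lambda).

    ``a`` is the scale (the stimulus value, on the performance axis, at
    which the function has covered 1 - 1/e of its rise), ``b`` the
    steepness, ``gamma`` the guess rate and ``lambda_`` the lapse rate.
    """

    a: float
    b: float
    gamma: float = GUESS_RATE_2AFC
    lambda_: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"a must be positive, got {self.a}")
        if self.b <= 0:
            raise ValueError(f"b must be positive, got {self.b}")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError(f"gamma must lie in [0, 1), got {self.gamma}")
        if not 0.0 <= self.lambda_ <= MAX_LAPSE:
            raise ValueError(f"lambda_ must lie in [0, {MAX_LAPSE}], got {self.lambda_}")

    @property
    def upper_asymptote(self) -> float:
        return 1.0 - self.lambda_


@dataclass(frozen=True)
class ChoiceData:
    """Per-frequency correct/total counts for one subject in one condition.

    ``records`` is a tuple of (frequency_cpd, n_correct, n_total).
    ``axis_origin`` is the top of the frequency grid the subject was tested
    on; it anchors the reversed performance axis for fitting and simulation.
    ``notes`` carries provenance flags (e.g. a fixture whose true threshold
    lies outside the grid span).
    """

    subject_id: str
    species: str  # "dog" | "human"
    condition: str  # "bright" | "dim"
    records: tuple[tuple[float, int, int], ...]
    axis_origin: float | None = None
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        freqs = [r[0] for r in self.records]
        if any(f <= 0 for f in freqs):
            raise ValueError("frequencies must be positive")
        if len(set(freqs)) != len(freqs):
            raise ValueError("frequencies must be distinct")
        for f, k, n in self.records:
            if not 0 <= k <= n:
                raise ValueError(f"need 0 <= n_correct <= n_total, got {k}/{n} at {f} cpd")

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([r[0] for r in self.records], dtype=float)

    @property
    def n_correct(self) -> np.ndarray:
        return np.array([r[1] for r in self.records], dtype=int)

    @property
    def n_total(self) -> np.ndarray:
        return np.array([r[2] for r in self.records], dtype=int)

    @property
    def origin(self) -> float:
        return self.axis_origin if self.axis_origin is not None else float(self.frequencies.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "species": self.species,
                "condition": self.condition,
                "frequency_cpd": self.frequencies,
                "n_correct": self.n_correct,
                "n_total": self.n_total,
            }
        )


def psi(x, params: PsychometricParams):
    """Probability of a correct choice at performance-axis value ``x`` >= 0.

    Rises monotonically from the guess rate at x = 0 to ``1 - lambda_``.
    Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("performance-axis values must be non-negative")
    span = 1.0 - params.gamma - params.lambda_
    out = params.gamma + span * (1.0 - np.exp(-((x / params.a) ** params.b)))
    return float(out) if out.ndim == 0 else out


def weibull_quantile(params: PsychometricParams, level: float) -> float:
    """Performance-axis value where psi crosses ``level`` (closed-form inverse)."""
    if not params.gamma <= level <= 1.0 - params.lambda_:
        raise ValueError(
            f"level {level} outside attainable range "
            f"[{params.gamma}, {1.0 - params.lambda_}]"
        )
    if level == params.gamma:
        return 0.0
    frac = (level - params.gamma) / (1.0 - params.gamma - params.lambda_)
    return params.a * (-math.log1p(-frac)) ** (1.0 / params.b)


def performance_axis(frequency, axis_origin: float):
    """Map spatial frequency (cpd) to the reversed performance axis."""
    x = axis_origin - np.asarray(frequency, dtype=float)
    if np.any(x < 0):
        raise ValueError(
            f"frequency exceeds axis_origin {axis_origin}; the reversed axis "
            "is only defined up to the top of the tested grid"
        )
    return float(x) if x.ndim == 0 else x


def params_for_threshold(
    true_threshold: float,
    axis_origin: float,
    *,
    b: float = 3.0,
    lambda_: float = 0.05,
    level: float = 0.75,
) -> PsychometricParams:
    """Solve for the scale ``a`` that puts the ``level`` crossing at ``true_threshold`` cpd.

    The threshold must lie strictly below ``axis_origin`` (at the origin
    performance is pinned to chance, so no finite scale can place the 75%
    point there).
    """
    if true_threshold >= axis_origin:
        raise ValueError(
            f"true_threshold {true_threshold} cpd must lie below the axis origin "
            f"{axis_origin} cpd (performance is at chance at the origin)"
        )
    x_thr = axis_origin - true_threshold
    frac = (level - GUESS_RATE_2AFC) / (1.0 - GUESS_RATE_2AFC - lambda_)
    a = x_thr / (-math.log1p(-frac)) ** (1.0 / b)
    return PsychometricParams(a=a, b=b, gamma=GUESS_RATE_2AFC, lambda_=lambda_)


def simulate_choices(
    schedule: SessionSchedule,
    params: PsychometricParams,
    seed: int,
    *,
    axis_origin: float | None = None,
    subject_id: str = "sim",
    species: str = "dog",
    condition: str = "bright",
    max_scored_per_freq: int | None = 20,
) -> ChoiceData:
    """Simulate trial-level Bernoulli responses on ``schedule`` and aggregate.

    Each scored trial is an independent success with probability
    ``psi(axis_origin - frequency, params)``; warm-ups are ignored.  Only
    the first ``max_scored_per_freq`` trials of each frequency are scored
    (pass ``None`` to score all), mirroring a first-20-choices analysis
    rule.  Reproducible from ``seed``.
    """
    scored = schedule.scored
    if axis_origin is None:
        axis_origin = max(t.frequency for t in scored)
    rng = np.random.default_rng(seed)
    p_at: dict[float, float] = {}
    counts: dict[float, list[int]] = {}
    for t in scored:
        k_n = counts.setdefault(t.frequency, [0, 0])
        if max_scored_per_freq is not None and k_n[1] >= max_scored_per_freq:
            continue
        p = p_at.get(t.frequency)
        if p is None:
            p = p_at[t.frequency] = psi(performance_axis(t.frequency, axis_origin), params)
        k_n[0] += int(rng.random() < p)
        k_n[1] += 1
    records = tuple((f, k, n) for f, (k, n) in sorted(counts.items()))
    return ChoiceData(
        subject_id=subject_id,
        species=species,
        condition=condition,
        records=records,
        axis_origin=axis_origin,
    )


# Frequency grids of the four study conditions (cpd).  Dogs in bright light
# were tested on 2-16 cpd, extended up to 30 cpd for individuals that kept
# scoring highly; humans in bright light viewed the same cards from farther
# away (30-78 cpd).  Dim-light grids are coarser and lower.
STUDY_PROFILES: dict[str, dict] = {
    "dog_bright": {
        "species": "dog",
        "condition": "bright",
        "grid": tuple(range(2, 17, 2)),
        "extended_grid": tuple(range(2, 31, 2)),
        "extend_above": 12.0,
        "mode": "dog_interleaved",
    },
    "dog_dim": {
        "species": "dog",
        "condition": "dim",
        "grid": (0.5, 2, 4, 6, 8, 10),
        "mode": "dog_interleaved",
    },
    "human_bright": {
        "species": "human",
        "condition": "bright",
        "grid": (30, 39, 44, 50, 64, 70, 78),
        "mode": "human_blocked",
    },
    "human_dim": {
        "species": "human",
        "condition": "dim",
        "grid": (0.5, 2, 4, 6, 8, 10, 12, 14),
        "mode": "human_blocked",
    },
}

TRIALS_PER_FREQUENCY = 20

# Default synthetic-observer shape per light condition, anchored to the
# reported study outcomes: upper asymptotes were 80-89% correct in bright
# light and 87.5-95% in dim light (lapse defaults are the mid-points of the
# implied lapse ranges), and the dim-light curves plateaued within the
# tested grid, which on the reversed performance axis requires a steeper
# rise than the gradual bright-light fall-off.
CONDITION_OBSERVER_DEFAULTS: dict[str, dict[str, float]] = {
    "bright": {"b": 3.0, "lambda_": 0.15},
    "dim": {"b": 6.0, "lambda_": 0.09},
}


def profile_grid(profile: str, true_threshold: float) -> tuple[float, ...]:
    """Frequency grid used for ``profile`` given the observer's true threshold.

    The bright-light dog grid is extended beyond 16 cpd for observers whose
    threshold approaches the top of the base grid, as extra high frequencies
    were added for individuals still scoring highly.
    """
    prof = STUDY_PROFILES[profile]
    grid = prof["grid"]
    if "extended_grid" in prof and true_threshold > prof["extend_above"]:
        grid = prof["extended_grid"]
    return tuple(float(f) for f in grid)


def make_study_fixture(
    profile: str,
    true_threshold: float,
    seed: int,
    *,
    b: float | None = None,
    lambda_: float | None = None,
    trials_per_freq: int = TRIALS_PER_FREQUENCY,
    subject_id: str | None = None,
) -> ChoiceData:
    """Simulated subject on the exact frequency grid of one study condition.

    Builds the profile's session schedule, solves the Weibull scale so the
    75%-correct point equals ``true_threshold``, and simulates 20 choices
    per frequency.  Steepness and lapse default to the light-condition
    values in :data:`CONDITION_OBSERVER_DEFAULTS`.  A threshold outside the
    grid span is allowed but the returned data carry a note (a fit will
    have to extrapolate).
    """
    if profile not in STUDY_PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(STUDY_PROFILES)}")
    prof = STUDY_PROFILES[profile]
    defaults = CONDITION_OBSERVER_DEFAULTS[prof["condition"]]
    if b is None:
        b = defaults["b"]
    if lambda_ is None:
        lambda_ = defaults["lambda_"]
    grid = profile_grid(profile, true_threshold)
    origin = max(grid)
    params = params_for_threshold(true_threshold, origin, b=b, lambda_=lambda_)

    # derive independent sub-seeds for schedule layout and responses
    ss = np.random.SeedSequence([seed, zlib.crc32(profile.encode()) % (2**31)])
    sched_seed, resp_seed = (int(s) % (2**31) for s in ss.generate_state(2))
    if prof["mode"] == "dog_interleaved":
        schedule = generate_dog_session(list(grid), trials_per_freq, sched_seed)
    else:
        schedule = generate_human_session(list(grid), trials_per_freq, sched_seed)

    data = simulate_choices(
        schedule,
        params,
        resp_seed,
        axis_origin=origin,
        subject_id=subject_id or f"{profile}_thr{true_threshold:g}",
        species=prof["species"],
        condition=prof["condition"],
        max_scored_per_freq=trials_per_freq,
    )
    if not min(grid) <= true_threshold <= max(grid):
        data = replace(data, notes=("true_threshold_outside_grid_span",))
    return data
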