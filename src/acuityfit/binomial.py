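"""Exact one-tailed binomial criteria for 2AFC performance.

With 20 forced choices at chance level 0.5, the smallest count that is
significantly better than guessing at one-tailed alpha = 0.05 is 15 of 20 —
which is why 75% correct is the canonical acuity criterion: the threshold
level and the significance cut-off coincide.  The same machinery scores
training criteria (15/20 on two consecutive occasions in bright light; a
run of six straight correct choices in dim light, chance probability
2^-6 ~ 0.016) and provides a model-free alternative acuity estimate: the
highest tested frequency at which the choice counts are significantly
biased away from chance.

All tail probabilities are exact sums (scipy's binomial survival function),
never a normal approximation — at n = 20 the approximation error would be
material to the criterion itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import binom

from .observer import ChoiceData

__all__ = [
    "CriterionResult",
    "one_tailed_binomial_p",
    "min_significant_count",
    "significance_threshold_acuity",
    "check_learning_criterion",
]

DEFAULT_ALPHA = 0.05
BRIGHT_CRITERION_N = 20
BRIGHT_CRITERION_K = 15
DIM_CRITERION_RUN = 6


@dataclass(frozen=True)
class CriterionResult:
    """Outcome of the highest-significant-frequency acuity estimate.

    ``frequency`` is nan when no tested frequency reaches significance.
    """

    frequency: float
    k: int
    n: int
    p_value: float
    significant: bool
    alpha: float = DEFAULT_ALPHA

    @property
    def defined(self) -> bool:
        return math.isfinite(self.frequency)


def one_tailed_binomial_p(k: int, n: int, p0: float = 0.5) -> float:
    """Exact upper-tail probability P(X >= k | n, p0) for X ~ Binomial(n, p0)."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must lie in (0, 1), got {p0}")
    return float(binom.sf(k - 1, n, p0))


def min_significant_count(n: int, alpha: float = DEFAULT_ALPHA, p0: float = 0.5) -> int | None:
    """Smallest k with P(X >= k | n, p0) < alpha, or None if even k = n is not enough."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    for k in range(n + 1):
        if one_tailed_binomial_p(k, n, p0) < alpha:
            return k
    return None


def significance_threshold_acuity(
    data: ChoiceData, alpha: float = DEFAULT_ALPHA
) -> CriterionResult:
    """Highest tested frequency whose correct-choice count is significantly biased.

    The maximum is taken over all tested frequencies regardless of
    non-significant gaps below it — no monotonicity is imposed on the raw
    counts.  When no frequency is significant the result carries
    ``frequency = nan`` (and the lowest frequency's counts for context).
    """
    if not data.records:
        raise ValueError("data has no records")
    significant = [
        (f, k, n, p)
        for f, k, n in data.records
        if (p := one_tailed_binomial_p(k, n)) < alpha
    ]
    if significant:
        f, k, n, p = max(significant)
        return CriterionResult(frequency=f, k=k, n=n, p_value=p, significant=True, alpha=alpha)
    f, k, n = min(data.records)
    return CriterionResult(
        frequency=math.nan, k=k, n=n,
        p_value=one_tailed_binomial_p(k, n), significant=False, alpha=alpha,
    )


def check_learning_criterion(session_scores, rule: str) -> bool:
    """Has the subject met the training criterion for the given light condition?

    ``rule="bright"``: ``session_scores`` is a list of per-occasion
    (k, n) tuples with n = 20; passes iff two *consecutive* occasions each
    scored at least 15/20.

    ``rule="dim"``: ``session_scores`` is a trial-level binary sequence
    (1 = correct); passes iff it contains a run of at least six consecutive
    correct choices.
    """
    scores = list(session_scores)
    if not scores:
        raise ValueError("session_scores must be non-empty")
    if rule == "bright":
        hits = []
        for k, n in scores:
            if n != BRIGHT_CRITERION_N:
                raise ValueError(
                    f"bright-light criterion is defined on occasions of "
                    f"{BRIGHT_CRITERION_N} trials, got n={n}"
                )
            hits.append(k >= BRIGHT_CRITERION_K)
        return any(a and b for a, b in zip(hits, hits[1:]))
    if rule == "dim":
        run = best = 0
        for c in scores:
            run = run + 1 if c else 0
            best = max(best, run)
        return best >= DIM_CRITERION_RUN
    raise ValueError(f"rule must be 'bright' or 'dim', got {rule!r}")
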