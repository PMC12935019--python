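"""Matching-probability confidence elicitation.

The matching-probability rule is a proper scoring rule for eliciting a
subjective probability of success ``p``.  On each trial a uniform integer
``n1`` in 1..100 is drawn.  If the reported probability (in percent) exceeds
``n1``, payment is determined by the correctness of the choice (the *skill*
branch); otherwise a second uniform integer ``n2`` is drawn and the payment is
won iff ``n2 <= n1`` (the *lottery* branch).  Low reports therefore shift
payment from skill to an increasingly favorable lottery, which makes truthful
reporting optimal: the expected reward

    E(p, s) = r * [ p*s + (1 - p^2) / 2 ]

is uniquely maximized at ``p = s``, where ``s`` is the true probability of
success and ``r`` the prize.  The continuous expression above idealizes the
discrete 1..100 lottery; the O(1/100) granularity gap is tolerated in tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ElicitationOutcome",
    "matching_probability_payout",
    "expected_matching_reward",
    "simulate_matching_payouts",
]


@dataclass(frozen=True)
class ElicitationOutcome:
    """Result of applying the matching-probability rule to one trial."""

    reported_p: float
    n1: int
    n2: int | None
    payout: float
    branch: str  # "skill" or "lottery"


def matching_probability_payout(
    reported_p: float,
    is_correct: bool,
    n1: int,
    n2: int,
    r: float = 15.0,
) -> ElicitationOutcome:
    """Apply the matching-probability payout rule to a single trial.

    Parameters
    ----------
    reported_p
        Reported probability of success, on [0.5, 1] (the task's confidence
        scale starts at 50%).
    is_correct
        Whether the judged choice was correct.
    n1, n2
        Uniform integers on {1..100}; ``n2`` is only consulted on the lottery
        branch but must always be supplied.
    r
        Prize for a win (default 15, the task's points per correct choice).
    """
    if not 0.5 <= reported_p <= 1.0:
        raise ValueError(f"reported_p must be in [0.5, 1], got {reported_p}")
    for name, n in (("n1", n1), ("n2", n2)):
        if not (isinstance(n, (int, np.integer)) and 1 <= n <= 100):
            raise ValueError(f"{name} must be an integer in 1..100, got {n}")
    # round guards binary-float artifacts (100 * 0.6 is not exactly 60)
    if round(100.0 * reported_p, 9) > n1:
        payout = r if is_correct else 0.0
        return ElicitationOutcome(reported_p, int(n1), None, payout, "skill")
    payout = r if n2 <= n1 else 0.0
    return ElicitationOutcome(reported_p, int(n1), int(n2), payout, "lottery")


def expected_matching_reward(p: float, s: float, r: float = 15.0) -> float:
    """Closed-form expected payout ``r * [p*s + (1 - p^2)/2]``.

    ``p`` is the reported probability, ``s`` the true success probability.
    The partial derivative in ``p`` is ``r*(s - p)``: reporting truthfully
    (``p = s``) is the unique maximizer.
    """
    p = float(p)
    s = float(s)
    if not (0.0 <= p <= 1.0 and 0.0 <= s <= 1.0):
        raise ValueError("p and s must lie in [0, 1]")
    return r * (p * s + (1.0 - p * p) / 2.0)


def simulate_matching_payouts(
    p: float,
    s: float,
    n_draws: int,
    rng: np.random.Generator,
    r: float = 15.0,
) -> np.ndarray:
    """Monte-Carlo payouts under the discrete rule; converges to the closed form.

    Correctness is drawn Bernoulli(s) independently per trial; n1, n2 are
    uniform on {1..100}.  Returns the array of payouts.
    """
    n1 = rng.integers(1, 101, size=n_draws)
    n2 = rng.integers(1, 101, size=n_draws)
    correct = rng.random(n_draws) < s
    skill = round(100.0 * p, 9) > n1
    won = np.where(skill, correct, n2 <= n1)
    return np.where(won, r, 0.0)
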