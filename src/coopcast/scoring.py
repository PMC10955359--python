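"""Incentive layer: quadratic scoring of beliefs, flat pay per correct guess.

A belief statement earns ``max_belief_payment * (1 - (d / w)**2)`` where
``d = |belief - actual| / 100`` and ``w`` is the scoring window (default 1/6):
maximal for an exact belief, falling quadratically to zero at the window edge,
zero beyond it. Binary guesses earn a flat amount each when correct. The
dollar constants are free parameters of the schedule.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["PaymentSchedule", "quadratic_belief_payment", "guess_payment", "payouts_frame"]


@dataclass(frozen=True)
class PaymentSchedule:
    max_belief_payment: float = 0.50
    per_correct_guess: float = 0.02
    qsr_window: float = 1.0 / 6.0

    def __post_init__(self) -> None:
        if self.max_belief_payment < 0 or self.per_correct_guess < 0:
            raise ValueError("payments must be nonnegative")
        if not 0.0 < self.qsr_window <= 1.0:
            raise ValueError("qsr_window must lie in (0, 1]")


def quadratic_belief_payment(
    belief: float, actual: float, schedule: PaymentSchedule
) -> float:
    """Quadratic-scoring payment for one belief statement (percent scale)."""
    if not (0.0 <= belief <= 100.0 and 0.0 <= actual <= 100.0):
        raise ValueError("belief and actual must lie in [0, 100]")
    d = abs(belief - actual) / 100.0
    if d > schedule.qsr_window:
        return 0.0
    return schedule.max_belief_payment * (1.0 - (d / schedule.qsr_window) ** 2)


def guess_payment(n_correct: int, schedule: PaymentSchedule) -> float:
    if n_correct < 0:
        raise ValueError("n_correct must be nonnegative")
    return n_correct * schedule.per_correct_guess


def payouts_frame(
    raters: pd.DataFrame,
    guesses: pd.DataFrame,
    actual_male_pct: float,
    actual_female_pct: float,
    schedule: PaymentSchedule,
) -> pd.DataFrame:
    """Per-rater payout table: the two belief payments, the guess payment
    over both rounds, and the total."""
    n_correct = guesses.groupby("rater_id")["correct"].sum()
    rows = []
    for r in raters.itertuples():
        pay_m = quadratic_belief_payment(r.belief_male, actual_male_pct, schedule)
        pay_f = quadratic_belief_payment(r.belief_female, actual_female_pct, schedule)
        pay_g = guess_payment(int(n_correct.get(r.rater_id, 0)), schedule)
        rows.append((r.rater_id, pay_m, pay_f, pay_g, pay_m + pay_f + pay_g))
    return pd.DataFrame(
        rows,
        columns=[
            "rater_id",
            "belief_payment_male",
            "belief_payment_female",
            "guess_payment",
            "total",
        ],
    )
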