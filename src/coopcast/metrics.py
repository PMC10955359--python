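"""Signal-detection measurement of guess performance.

Per rater and round, the cooperator detection rate H is the share of correct
guesses among players whose true choice was Split, and the cheater detection
rate R the share among players who chose Take All. Rates of exactly 0 or 1
are clamped to 1/100000 and 99999/100000 before the probit transform so that
z-scores stay finite. Accuracy is ``Z(H) - Z(1 - R)`` (zero at chance) and
bias is ``-0.5 [Z(H) + Z(1 - R)]`` (negative = leaning towards guessing
Split), with ``Z`` the standard normal quantile function. Correctness (mean
percent correct) and a Haldane–Anscombe-corrected odds ratio serve as
alternative accuracy measures, and belief accuracy is summarised by the
signed/absolute belief error and the "sufficiently correct" dummy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .pd_engine import Choice

__all__ = [
    "RateSummary",
    "SDTSummary",
    "BeliefAccuracy",
    "detection_rates",
    "clamp_rate",
    "z_score",
    "sdt_accuracy",
    "sdt_bias",
    "correctness",
    "odds_ratio",
    "belief_error_measures",
    "sdt_summary_frame",
    "beliefs_eval_frame",
]

logger = logging.getLogger(__name__)

RATE_FLOOR = 1.0 / 100_000.0
RATE_CEIL = 99_999.0 / 100_000.0


@dataclass(frozen=True)
class RateSummary:
    n_split_truth: int
    n_take_truth: int
    H: Optional[float]  # None when no Split-truth records exist
    R: Optional[float]  # None when no TakeAll-truth records exist


@dataclass(frozen=True)
class SDTSummary:
    accuracy: float
    bias: float
    correctness: float
    odds_ratio: float


@dataclass(frozen=True)
class BeliefAccuracy:
    signed_error: float
    absolute_error: float
    sufficiently_correct: int


def detection_rates(records: pd.DataFrame) -> RateSummary:
    """H and R for one rater-round block of guess records.

    ``records`` needs ``truth`` (choice labels) and ``correct`` (0/1) columns.
    A rate whose truth class is empty is reported as ``None``.
    """
    if len(records) == 0:
        raise ValueError("detection rates need at least one record")
    split_mask = records["truth"].to_numpy() == Choice.SPLIT.value
    correct = records["correct"].to_numpy().astype(bool)
    n_split = int(split_mask.sum())
    n_take = int((~split_mask).sum())
    H = float(correct[split_mask].mean()) if n_split else None
    R = float(correct[~split_mask].mean()) if n_take else None
    return RateSummary(n_split, n_take, H, R)


def clamp_rate(rate: float) -> float:
    """Pull exact 0/1 rates just inside (0, 1); interior rates pass through."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must lie in [0, 1], got {rate}")
    if rate == 0.0:
        return RATE_FLOOR
    if rate == 1.0:
        return RATE_CEIL
    return rate


def z_score(p) -> float:
    """Standard normal quantile function Z(.)."""
    return norm.ppf(p)


def sdt_accuracy(H: float, R: float) -> float:
    """Z(H) - Z(1 - R) after clamping; zero means chance-level discrimination."""
    Hc = clamp_rate(H)
    Rc = clamp_rate(R)
    return float(z_score(Hc) - z_score(1.0 - Rc))


def sdt_bias(H: float, R: float) -> float:
    """-0.5 [Z(H) + Z(1 - R)] after clamping; negative values lean Split."""
    Hc = clamp_rate(H)
    Rc = clamp_rate(R)
    return float(-0.5 * (z_score(Hc) + z_score(1.0 - Rc)))


def correctness(records) -> float:
    """Percent of correct guesses."""
    arr = (
        records["correct"].to_numpy()
        if isinstance(records, pd.DataFrame)
        else np.asarray(records)
    )
    if arr.size == 0:
        raise ValueError("correctness needs at least one record")
    return float(100.0 * arr.mean())


def odds_ratio(table) -> float:
    """Cross-product ratio (a*d)/(b*c) of the 2x2 guess-by-truth table
    ``[[hits, misses], [false_alarms, correct_rejections]]``, with the
    Haldane–Anscombe +0.5 applied to every cell when any cell is zero."""
    t = np.asarray(table, dtype=float).reshape(2, 2)
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    if (t == 0).any():
        t = t + 0.5
    return float((t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0]))


def belief_error_measures(
    belief: float, actual_rate: float, gender_majority_cooperative: bool
) -> BeliefAccuracy:
    """Signed and absolute belief error in percentage points, plus the
    sufficiently-correct dummy: 1 when a belief >= 50% points at a
    majority-cooperative gender, or a belief < 50% at a majority-non-
    cooperative one."""
    if not (0.0 <= belief <= 100.0 and 0.0 <= actual_rate <= 100.0):
        raise ValueError("belief and actual rate must lie in [0, 100]")
    signed = belief - actual_rate
    sufficient = int((belief >= 50.0) == bool(gender_majority_cooperative))
    return BeliefAccuracy(signed, abs(signed), sufficient)


# ---------------------------------------------------------------------------
# Frame-level summaries


def sdt_summary_frame(guesses: pd.DataFrame) -> pd.DataFrame:
    """Per rater-per-round signal-detection summary over all guesses in the
    round (never from pooled rates across raters).

    Raters with an empty truth class get NaN rates and NaN accuracy/bias for
    that round; a warning is logged because they drop out of conditional
    summaries.
    """
    df = guesses.assign(
        truth_split=guesses["truth"] == Choice.SPLIT.value,
        hit=lambda d: (d["correct"] == 1) & (d["truth"] == Choice.SPLIT.value),
        cr=lambda d: (d["correct"] == 1) & (d["truth"] != Choice.SPLIT.value),
    )
    agg = (
        df.groupby(["rater_id", "round"], sort=True)
        .agg(
            n=("correct", "size"),
            n_split_truth=("truth_split", "sum"),
            hits=("hit", "sum"),
            crs=("cr", "sum"),
            mean_correct=("correct", "mean"),
        )
        .reset_index()
    )
    agg["n_take_truth"] = agg["n"] - agg["n_split_truth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        H = agg["hits"] / agg["n_split_truth"]
        R = agg["crs"] / agg["n_take_truth"]
    H = H.where(agg["n_split_truth"] > 0)
    R = R.where(agg["n_take_truth"] > 0)
    if H.isna().any() or R.isna().any():
        logger.warning(
            "%d rater-round blocks have an empty truth class; their accuracy/"
            "bias are reported as NaN",
            int((H.isna() | R.isna()).sum()),
        )
    Hc = H.clip(RATE_FLOOR, RATE_CEIL)
    Rc = R.clip(RATE_FLOOR, RATE_CEIL)
    zH = norm.ppf(Hc)
    zF = norm.ppf(1.0 - Rc)  # false-alarm side
    agg["H"] = H
    agg["R"] = R
    agg["accuracy"] = zH - zF
    agg["bias"] = -0.5 * (zH + zF)
    agg["correctness"] = 100.0 * agg["mean_correct"]
    misses = agg["n_split_truth"] - agg["hits"]
    fas = agg["n_take_truth"] - agg["crs"]
    cells = np.stack([agg["hits"], misses, fas, agg["crs"]], axis=1).astype(float)
    corr = (cells == 0).any(axis=1)
    cells[corr] += 0.5
    agg["odds_ratio"] = (cells[:, 0] * cells[:, 3]) / (cells[:, 1] * cells[:, 2])
    return agg[
        [
            "rater_id",
            "round",
            "n_split_truth",
            "n_take_truth",
            "H",
            "R",
            "accuracy",
            "bias",
            "correctness",
            "odds_ratio",
        ]
    ]


def beliefs_eval_frame(
    raters: pd.DataFrame, actual_male_pct: float, actual_female_pct: float
) -> pd.DataFrame:
    """Evaluate each rater's two gender beliefs against the cohort's realized
    Round-1 cooperation rates (percent)."""
    rows = []
    for target, belief_col, actual in (
        ("Male", "belief_male", actual_male_pct),
        ("Female", "belief_female", actual_female_pct),
    ):
        majority = actual >= 50.0
        for r in raters.itertuples():
            acc = belief_error_measures(getattr(r, belief_col), actual, majority)
            rows.append(
                (
                    r.rater_id,
                    target,
                    getattr(r, belief_col),
                    actual,
                    acc.signed_error,
                    acc.absolute_error,
                    acc.sufficiently_correct,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "rater_id",
            "target_gender",
            "belief",
            "actual",
            "signed_error",
            "absolute_error",
            "sufficiently_correct",
        ],
    )
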