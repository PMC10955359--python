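"""Synthetic raters: beliefs, information treatments and guess strategies.

Raters hold correlated gender-specific prior beliefs about how often male and
female players cooperate, elicited as Split percentages (the Take-All
percentage is the complement, so only the Split side is stored). Four
between-subject treatments control what a rater sees about each player:

* ``NONE``   — an ID number only,
* ``LABEL``  — ID plus the player's gender,
* ``PHOTO``  — gender plus a static appearance cue,
* ``VIDEO``  — gender plus a dynamic appearance cue.

Appearance is modelled as a noisy binary cue about the player's Round-1
choice with configurable validity (probability the cue matches the truth).
A first-round guess mixes a threshold rule (guess the more likely outcome)
with probability matching, governed by ``lambda_optimize``; a second-round
guess applies a tit-for-tat mirror heuristic to the revealed Round-1 history
with probability ``heuristic_adherence`` and otherwise falls back to the
first-impression rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .pd_engine import (
    Choice,
    GameConfig,
    Gender,
    Match,
    PlayerProfile,
    player_round_table,
)

__all__ = [
    "Treatment",
    "RaterGender",
    "BeliefPair",
    "RaterProfile",
    "InformationSet",
    "RaterConfig",
    "draw_belief_pairs",
    "belief_about_players",
    "sample_appearance_cue",
    "combine_belief_and_cue",
    "build_information_set",
    "guess_round1",
    "guess_round2",
    "generate_raters",
    "apply_exclusions",
    "simulate_rating_study",
    "raters_to_frame",
    "raters_from_frame",
]


class Treatment(str, Enum):
    NONE = "None"
    LABEL = "Label"
    PHOTO = "Photo"
    VIDEO = "Video"


class RaterGender(str, Enum):
    MALE = "Male"
    FEMALE = "Female"
    OTHER = "Other"


@dataclass(frozen=True)
class BeliefPair:
    """Elicited Split percentages for male and female players, in [0, 100]."""

    belief_male: float
    belief_female: float

    def __post_init__(self) -> None:
        for v in (self.belief_male, self.belief_female):
            if not 0.0 <= v <= 100.0:
                raise ValueError("beliefs must lie in [0, 100]")


@dataclass(frozen=True)
class RaterProfile:
    rater_id: int
    gender: RaterGender
    treatment: Treatment
    beliefs: BeliefPair
    lambda_optimize: float
    cue_weight: float
    heuristic_adherence: float
    flag_small_screen: bool
    duration_s: float

    def __post_init__(self) -> None:
        for name in ("lambda_optimize", "heuristic_adherence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class InformationSet:
    """What one rater sees about one player for one round's guess."""

    shows_gender: bool
    gender: Optional[Gender] = None
    cue: Optional[Choice] = None
    cue_validity: Optional[float] = None
    history: Optional[tuple[Choice, Choice]] = None  # (own_r1, partner_r1)


@dataclass(frozen=True)
class RaterConfig:
    """Rater cohort composition, belief moments and strategy parameters.

    Treatment counts default to the kept sample (108/101/108/105); the
    exclusion fixture adds 11 small-screen and 12 too-fast records on top,
    disjoint by construction. Belief means differ by rater gender (male
    raters 46.3/61.8, female raters 42.2/66.5, others at the pooled
    44.2/63.9); the shared standard deviation is a free parameter (20) and
    the male/female belief correlation defaults to 0.503.
    """

    n_none: int = 108
    n_label: int = 101
    n_photo: int = 108
    n_video: int = 105
    share_male: float = 0.4853
    share_female: float = 0.4898
    belief_mean_male_raters: tuple[float, float] = (46.3, 61.8)
    belief_mean_female_raters: tuple[float, float] = (42.2, 66.5)
    belief_mean_other_raters: tuple[float, float] = (44.2, 63.9)
    belief_sd: float = 20.0
    belief_rho: float = 0.503
    lambda_optimize: float = 0.5
    cue_weight: float = 1.0
    heuristic_adherence: float = 0.8
    cue_validity_photo: float = 0.55
    cue_validity_video: float = 0.55
    n_excluded_small_screen: int = 11
    n_excluded_fast: int = 12
    min_duration_s: float = 480.0
    duration_mean_s: float = 1464.0

    def __post_init__(self) -> None:
        for name in ("n_none", "n_label", "n_photo", "n_video"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.lambda_optimize <= 1.0:
            raise ValueError("lambda_optimize must lie in [0, 1]")
        if not 0.0 <= self.heuristic_adherence <= 1.0:
            raise ValueError("heuristic_adherence must lie in [0, 1]")
        for name in ("cue_validity_photo", "cue_validity_video"):
            if not 0.5 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0.5, 1]")
        if not -1.0 < self.belief_rho < 1.0:
            raise ValueError("belief_rho must lie strictly in (-1, 1)")
        if self.belief_sd < 0:
            raise ValueError("belief_sd must be nonnegative")

    @property
    def n_kept(self) -> int:
        return self.n_none + self.n_label + self.n_photo + self.n_video

    def cue_validity(self, treatment: Treatment) -> Optional[float]:
        if treatment is Treatment.PHOTO:
            return self.cue_validity_photo
        if treatment is Treatment.VIDEO:
            return self.cue_validity_video
        return None

    def belief_means(self, gender: RaterGender) -> tuple[float, float]:
        if gender is RaterGender.MALE:
            return self.belief_mean_male_raters
        if gender is RaterGender.FEMALE:
            return self.belief_mean_female_raters
        return self.belief_mean_other_raters


def draw_belief_pairs(
    n: int,
    mean_male: float,
    mean_female: float,
    sd_male: float,
    sd_female: float,
    rho: float,
    rng: np.random.Generator,
) -> list[BeliefPair]:
    """Draw correlated (male, female) belief pairs from a bivariate normal
    with the given moments, censored to [0, 100]."""
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must lie strictly in (-1, 1)")
    if sd_male < 0 or sd_female < 0:
        raise ValueError("standard deviations must be nonnegative")
    cov = np.array(
        [
            [sd_male**2, rho * sd_male * sd_female],
            [rho * sd_male * sd_female, sd_female**2],
        ]
    )
    draws = rng.multivariate_normal([mean_male, mean_female], cov, size=n)
    draws = np.clip(draws, 0.0, 100.0)
    return [BeliefPair(float(m), float(f)) for m, f in draws]


def belief_about_players(pair: BeliefPair) -> float:
    """Belief about the mixed-gender player population: the unweighted mean
    of the two gender-specific beliefs."""
    return (pair.belief_male + pair.belief_female) / 2.0


def sample_appearance_cue(
    truth_r1: Choice, validity: float, rng: np.random.Generator
) -> Choice:
    """Noisy appearance cue: equals the player's Round-1 truth with
    probability ``validity`` (anti-diagnostic cues below 0.5 are disallowed)."""
    if not 0.5 <= validity <= 1.0:
        raise ValueError("cue validity must lie in [0.5, 1]")
    return truth_r1 if rng.random() < validity else truth_r1.flipped()


def combine_belief_and_cue(
    prior: float,
    cue: Optional[Choice],
    validity: float,
    cue_weight: float,
) -> float:
    """Fold an appearance cue into a prior Split percentage on the log-odds
    scale; an absent cue leaves the prior unchanged."""
    if cue is None:
        return prior
    p = np.clip(prior, 0.1, 99.9) / 100.0
    sign = 1.0 if cue is Choice.SPLIT else -1.0
    shift = cue_weight * sign * np.log(validity / (1.0 - validity))
    return float(100.0 * expit(logit(p) + shift))


def build_information_set(
    treatment: Treatment,
    player: PlayerProfile,
    match: Match,
    round_no: int,
    config: RaterConfig,
    rng: np.random.Generator,
) -> InformationSet:
    """Assemble what a rater in ``treatment`` sees about ``player`` before a
    Round-``round_no`` guess. Round 2 adds the pair's Round-1 history in every
    treatment."""
    if round_no not in (1, 2):
        raise ValueError("round must be 1 or 2")
    shows_gender = treatment is not Treatment.NONE
    gender = player.gender if shows_gender else None
    validity = config.cue_validity(treatment)
    cue = None
    if validity is not None:
        (a1, b1) = match.choices[0]
        own_r1 = a1 if match.id_a == player.player_id else b1
        cue = sample_appearance_cue(own_r1, validity, rng)
    history = None
    if round_no == 2:
        (a1, b1) = match.choices[0]
        if match.id_a == player.player_id:
            history = (a1, b1)
        else:
            history = (b1, a1)
    return InformationSet(shows_gender, gender, cue, validity, history)


def _effective_prior(rater: RaterProfile, info: InformationSet) -> float:
    if info.shows_gender:
        if info.gender is Gender.MALE:
            return rater.beliefs.belief_male
        return rater.beliefs.belief_female
    return belief_about_players(rater.beliefs)


def guess_round1(
    rater: RaterProfile, info: InformationSet, rng: np.random.Generator
) -> Choice:
    """First-impression guess: with probability ``lambda_optimize`` apply the
    threshold rule (Split iff the posterior is >= 50%, ties to Split),
    otherwise probability-match on the posterior."""
    prior = _effective_prior(rater, info)
    posterior = combine_belief_and_cue(
        prior, info.cue, info.cue_validity or 0.5, rater.cue_weight
    )
    if rng.random() < rater.lambda_optimize:
        return Choice.SPLIT if posterior >= 50.0 else Choice.TAKE_ALL
    return Choice.SPLIT if rng.random() < posterior / 100.0 else Choice.TAKE_ALL


def heuristic_prediction(own_r1: Choice, partner_r1: Choice) -> Choice:
    """Tit-for-tat mirror: a Round-1 defector is predicted to defect again; a
    Round-1 cooperator is predicted to copy the partner's Round-1 choice."""
    if own_r1 is Choice.TAKE_ALL:
        return Choice.TAKE_ALL
    return partner_r1


def guess_round2(
    rater: RaterProfile, info: InformationSet, rng: np.random.Generator
) -> Choice:
    """Second-impression guess: with probability ``heuristic_adherence`` apply
    the tit-for-tat mirror to the revealed history, otherwise fall back to the
    first-impression rule on the same information set."""
    if info.history is None:
        raise ValueError("Round-2 guesses require the Round-1 history")
    if rng.random() < rater.heuristic_adherence:
        return heuristic_prediction(*info.history)
    return guess_round1(rater, info, rng)


# ---------------------------------------------------------------------------
# Cohort generation and exclusions


def _draw_rater_gender(rng: np.random.Generator, config: RaterConfig) -> RaterGender:
    u = rng.random()
    if u < config.share_male:
        return RaterGender.MALE
    if u < config.share_male + config.share_female:
        return RaterGender.FEMALE
    return RaterGender.OTHER


def _kept_duration(rng: np.random.Generator, config: RaterConfig) -> float:
    # Gamma(2) shifted above the exclusion threshold; mean = duration_mean_s.
    scale = max(config.duration_mean_s - config.min_duration_s, 1.0) / 2.0
    return config.min_duration_s + rng.gamma(2.0, scale)


def generate_raters(config: RaterConfig, rng: np.random.Generator) -> list[RaterProfile]:
    """Generate the full recruited sample: kept raters with the exact
    per-treatment counts, plus the disjoint exclusion fixture (small-screen
    and too-fast records cycled over treatments)."""
    treatments = (
        [Treatment.NONE] * config.n_none
        + [Treatment.LABEL] * config.n_label
        + [Treatment.PHOTO] * config.n_photo
        + [Treatment.VIDEO] * config.n_video
    )
    cycle = [Treatment.NONE, Treatment.LABEL, Treatment.PHOTO, Treatment.VIDEO]
    n_excl = config.n_excluded_small_screen + config.n_excluded_fast
    treatments += [cycle[i % 4] for i in range(n_excl)]

    raters: list[RaterProfile] = []
    for i, treatment in enumerate(treatments):
        gender = _draw_rater_gender(rng, config)
        mean_m, mean_f = config.belief_means(gender)
        (pair,) = draw_belief_pairs(
            1, mean_m, mean_f, config.belief_sd, config.belief_sd, config.belief_rho, rng
        )
        idx_excl = i - config.n_kept
        small_screen = 0 <= idx_excl < config.n_excluded_small_screen
        fast = idx_excl >= config.n_excluded_small_screen
        if fast:
            duration = float(rng.uniform(60.0, config.min_duration_s - 1.0))
        else:
            duration = float(_kept_duration(rng, config))
        raters.append(
            RaterProfile(
                rater_id=i + 1,
                gender=gender,
                treatment=treatment,
                beliefs=pair,
                lambda_optimize=config.lambda_optimize,
                cue_weight=config.cue_weight,
                heuristic_adherence=config.heuristic_adherence,
                flag_small_screen=small_screen,
                duration_s=duration,
            )
        )
    return raters


def apply_exclusions(
    raters: Sequence[RaterProfile], min_duration_s: float = 480.0
) -> tuple[list[RaterProfile], dict[str, int]]:
    """Drop small-screen raters, then raters faster than the duration floor.

    Returns the kept raters and an audit dictionary whose counts always sum
    back to the input size.
    """
    small = [r for r in raters if r.flag_small_screen]
    remaining = [r for r in raters if not r.flag_small_screen]
    fast = [r for r in remaining if r.duration_s < min_duration_s]
    kept = [r for r in remaining if r.duration_s >= min_duration_s]
    audit = {
        "input": len(raters),
        "excluded_small_screen": len(small),
        "excluded_fast": len(fast),
        "kept": len(kept),
    }
    return kept, audit


# ---------------------------------------------------------------------------
# Vectorised rating study

_TREAT_CODE = {t: i for i, t in enumerate(Treatment)}


def simulate_rating_study(
    players: Sequence[PlayerProfile],
    matches: Sequence[Match],
    raters: Sequence[RaterProfile],
    config: RaterConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Every rater guesses every player's choice in Rounds 1 and 2.

    All Round-1 guesses are made first; Round-2 guesses then condition on the
    revealed Round-1 history. Guesses are drawn from the per-record Bernoulli
    probability implied by the mixture strategies, which is distributionally
    identical to the two-stage per-guess draws of :func:`guess_round1` and
    :func:`guess_round2`.
    """
    ptab = player_round_table(players, matches)
    n_p = len(ptab)
    n_r = len(raters)
    is_male = (ptab.gender == Gender.MALE.value).to_numpy()
    truth1 = ptab.own_r1_split.to_numpy()
    truth2 = ptab.own_r2_split.to_numpy()
    partner1 = ptab.partner_r1_split.to_numpy()
    h_split = truth1 & partner1  # tit-for-tat mirror predicts Split only here
    player_ids = ptab.player_id.to_numpy()

    bm = np.array([r.beliefs.belief_male for r in raters])
    bf = np.array([r.beliefs.belief_female for r in raters])
    lam = np.array([r.lambda_optimize for r in raters])
    w = np.array([r.cue_weight for r in raters])
    adh = np.array([r.heuristic_adherence for r in raters])
    validity = np.array(
        [config.cue_validity(r.treatment) or np.nan for r in raters]
    )
    shows_gender = np.array([r.treatment is not Treatment.NONE for r in raters])
    has_cue = ~np.isnan(validity)

    prior = np.where(
        shows_gender[:, None],
        np.where(is_male[None, :], bm[:, None], bf[:, None]),
        ((bm + bf) / 2.0)[:, None],
    )
    p = np.clip(prior, 0.1, 99.9) / 100.0
    log_prior = logit(p)
    with np.errstate(invalid="ignore"):
        cue_strength = w * np.log(validity / (1.0 - validity))

    frames = []
    rater_ids = np.array([r.rater_id for r in raters])
    for rnd, truth in ((1, truth1), (2, truth2)):
        cue_split = rng.random((n_r, n_p)) < validity[:, None]
        cue_split = np.where(cue_split, truth1[None, :], ~truth1[None, :])
        shift = np.where(
            has_cue[:, None],
            np.where(cue_split, 1.0, -1.0) * np.nan_to_num(cue_strength)[:, None],
            0.0,
        )
        post = expit(log_prior + shift)
        p1 = lam[:, None] * (post >= 0.5) + (1.0 - lam[:, None]) * post
        if rnd == 1:
            p_split = p1
        else:
            p_split = adh[:, None] * h_split[None, :] + (1.0 - adh[:, None]) * p1
        guess_split = rng.random((n_r, n_p)) < p_split
        correct = guess_split == truth[None, :]
        frames.append(
            pd.DataFrame(
                {
                    "rater_id": np.repeat(rater_ids, n_p),
                    "player_id": np.tile(player_ids, n_r),
                    "round": rnd,
                    "guess": np.where(
                        guess_split.ravel(), Choice.SPLIT.value, Choice.TAKE_ALL.value
                    ),
                    "truth": np.where(
                        np.tile(truth, n_r), Choice.SPLIT.value, Choice.TAKE_ALL.value
                    ),
                    "correct": correct.ravel().astype(int),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Tabular I/O


def raters_to_frame(raters: Sequence[RaterProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rater_id": [r.rater_id for r in raters],
            "gender": [r.gender.value for r in raters],
            "treatment": [r.treatment.value for r in raters],
            "belief_male": [r.beliefs.belief_male for r in raters],
            "belief_female": [r.beliefs.belief_female for r in raters],
            "lambda_optimize": [r.lambda_optimize for r in raters],
            "cue_weight": [r.cue_weight for r in raters],
            "heuristic_adherence": [r.heuristic_adherence for r in raters],
            "flag_small_screen": [r.flag_small_screen for r in raters],
            "duration_s": [r.duration_s for r in raters],
        }
    )


def raters_from_frame(df: pd.DataFrame) -> list[RaterProfile]:
    return [
        RaterProfile(
            rater_id=int(r.rater_id),
            gender=RaterGender(r.gender),
            treatment=Treatment(r.treatment),
            beliefs=BeliefPair(float(r.belief_male), float(r.belief_female)),
            lambda_optimize=float(r.lambda_optimize),
            cue_weight=float(r.cue_weight),
            heuristic_adherence=float(r.heuristic_adherence),
            flag_small_screen=bool(r.flag_small_screen),
            duration_s=float(r.duration_s),
        )
        for r in df.itertuples()
    ]
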