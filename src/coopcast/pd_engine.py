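"""Split-or-Take-All repeated Prisoner's Dilemma engine.

Simulates a cohort of players matched into fixed anonymous pairs who play a
Prisoner's Dilemma variant with intuitive action labels: mutual ``Split`` pays
$5 each, a unilateral ``Take All`` pays $10 against $0, and mutual ``Take All``
pays nothing. Non-cooperation weakly (not strictly) dominates. Pairs play a
guaranteed two rounds and then continue under a random-stopping rule with
continuation probability ``base**(1 - n)`` from current round ``n``.

Players come in two behavioural types. A *conditional cooperator* opens with
Split and thereafter mirrors the partner's previous realized choice
(tit-for-tat); a *non-cooperator* always intends Take All. A small symmetric
execution error ("tremble") flips the intended choice with fixed probability
each round, which is what separates the pure heuristic from observed play.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Choice",
    "PlayerType",
    "Gender",
    "HistoryCategory",
    "GameConfig",
    "PlayerProfile",
    "Match",
    "payoff",
    "continuation_probability",
    "sample_match_length",
    "generate_players",
    "round_choice",
    "simulate_matches",
    "history_category",
    "players_to_frame",
    "matches_to_frame",
    "players_from_frame",
    "matches_from_frame",
    "player_round_table",
]


class Choice(str, Enum):
    """The two actions; SPLIT encodes cooperation, TAKE_ALL non-cooperation."""

    SPLIT = "Split"
    TAKE_ALL = "TakeAll"

    def flipped(self) -> "Choice":
        return Choice.TAKE_ALL if self is Choice.SPLIT else Choice.SPLIT


class PlayerType(str, Enum):
    CONDITIONAL_COOPERATOR = "ConditionalCooperator"
    NON_COOPERATOR = "NonCooperator"


class Gender(str, Enum):
    MALE = "Male"
    FEMALE = "Female"


class HistoryCategory(str, Enum):
    """Four-way classification of a pair's Round-1 outcome, from the focal
    player's perspective."""

    BOTH_TAKE = "BothTakeAll"
    TAKE_PARTNER_SPLIT = "TakeAllPartnerSplit"
    SPLIT_PARTNER_TAKE = "SplitPartnerTakeAll"
    BOTH_SPLIT = "BothSplit"


@dataclass(frozen=True)
class GameConfig:
    """Payoffs, stopping rule and cohort composition.

    Defaults are calibrated to the study conditions: 51 men with conditional-
    cooperator propensity 0.614 and 45 women with 0.860, $5/$10/$0 payoffs,
    stopping base 4 with a guaranteed two rounds, and a 5% tremble.
    """

    payoff_mutual_split: float = 5.0
    payoff_sucker: float = 0.0
    payoff_temptation: float = 10.0
    payoff_mutual_take: float = 0.0
    stopping_base: float = 4.0
    min_rounds: int = 2
    max_rounds_cap: int = 10
    n_male: int = 51
    n_female: int = 45
    p_coop_male: float = 0.614
    p_coop_female: float = 0.860
    tremble: float = 0.05

    def __post_init__(self) -> None:
        if not (self.payoff_temptation > self.payoff_mutual_split > self.payoff_mutual_take):
            raise ValueError("payoffs must satisfy temptation > mutual split > mutual take")
        if self.payoff_sucker != self.payoff_mutual_take:
            raise ValueError("sucker payoff must equal the mutual take-all payoff")
        if self.stopping_base <= 1:
            raise ValueError("stopping_base must exceed 1")
        if self.min_rounds < 2:
            raise ValueError("at least two rounds are guaranteed")
        if self.max_rounds_cap < self.min_rounds:
            raise ValueError("max_rounds_cap must be >= min_rounds")
        for name in ("p_coop_male", "p_coop_female"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if not 0.0 <= self.tremble < 0.5:
            raise ValueError("tremble must lie in [0, 0.5)")


@dataclass(frozen=True)
class PlayerProfile:
    player_id: int
    gender: Gender
    ptype: PlayerType
    tremble: float


@dataclass
class Match:
    """Round-by-round realized history of one fixed pair."""

    match_id: int
    id_a: int
    id_b: int
    choices: list[tuple[Choice, Choice]]
    payoffs: list[tuple[float, float]]

    @property
    def length(self) -> int:
        return len(self.choices)


_DEFAULT_GAME = GameConfig()


def payoff(a: Choice, b: Choice, config: GameConfig | None = None) -> tuple[float, float]:
    """Payoff pair (to ``a``, to ``b``) for one round."""
    cfg = config or _DEFAULT_GAME
    if a is Choice.SPLIT and b is Choice.SPLIT:
        return (cfg.payoff_mutual_split, cfg.payoff_mutual_split)
    if a is Choice.SPLIT and b is Choice.TAKE_ALL:
        return (cfg.payoff_sucker, cfg.payoff_temptation)
    if a is Choice.TAKE_ALL and b is Choice.SPLIT:
        return (cfg.payoff_temptation, cfg.payoff_sucker)
    return (cfg.payoff_mutual_take, cfg.payoff_mutual_take)


def continuation_probability(n: int, base: float = 4.0) -> float:
    """Probability of continuing to another round from current round ``n``,
    equal to ``base**(1 - n)``: 1, 1/4, 1/16, ... for base 4."""
    if n < 1:
        raise ValueError(f"round index must be >= 1, got {n}")
    if base <= 1:
        raise ValueError("base must exceed 1")
    return float(base) ** (1 - n)


def sample_match_length(rng: np.random.Generator, config: GameConfig | None = None) -> int:
    """Draw a match length: the guaranteed minimum, then one uniform draw per
    completed round against the continuation probability, truncated at the cap."""
    cfg = config or _DEFAULT_GAME
    length = cfg.min_rounds
    while length < cfg.max_rounds_cap:
        if rng.random() >= continuation_probability(length, cfg.stopping_base):
            break
        length += 1
    return length


def generate_players(config: GameConfig, rng: np.random.Generator) -> list[PlayerProfile]:
    """Draw a cohort: each male is a conditional cooperator with probability
    ``p_coop_male``, each female with ``p_coop_female``."""
    total = config.n_male + config.n_female
    if total % 2 != 0:
        raise ValueError(f"player count must be even for pairing, got {total}")
    players: list[PlayerProfile] = []
    for i in range(total):
        gender = Gender.MALE if i < config.n_male else Gender.FEMALE
        p = config.p_coop_male if gender is Gender.MALE else config.p_coop_female
        ptype = (
            PlayerType.CONDITIONAL_COOPERATOR
            if rng.random() < p
            else PlayerType.NON_COOPERATOR
        )
        players.append(PlayerProfile(i + 1, gender, ptype, config.tremble))
    return players


def round_choice(
    ptype: PlayerType,
    partner_prev: Optional[Choice],
    tremble: float,
    rng: np.random.Generator,
) -> Choice:
    """Realized choice for one round.

    ``partner_prev`` is ``None`` exactly in Round 1. The intended choice is
    Take All for a non-cooperator, and for a conditional cooperator Split in
    Round 1 then a copy of the partner's previous realized choice. The intended
    choice flips with probability ``tremble``.
    """
    if ptype is PlayerType.NON_COOPERATOR:
        intended = Choice.TAKE_ALL
    elif partner_prev is None:
        intended = Choice.SPLIT
    else:
        intended = partner_prev
    if rng.random() < tremble:
        return intended.flipped()
    return intended


def simulate_matches(
    players: Sequence[PlayerProfile],
    config: GameConfig,
    rng: np.random.Generator,
) -> list[Match]:
    """Pair the cohort by uniform random perfect matching (gender-blind) and
    simulate each pair to its sampled length."""
    if len(players) % 2 != 0:
        raise ValueError(f"player count must be even for pairing, got {len(players)}")
    order = rng.permutation(len(players))
    matches: list[Match] = []
    for m, k in enumerate(range(0, len(players), 2)):
        pa = players[order[k]]
        pb = players[order[k + 1]]
        length = sample_match_length(rng, config)
        choices: list[tuple[Choice, Choice]] = []
        pays: list[tuple[float, float]] = []
        prev_a: Optional[Choice] = None
        prev_b: Optional[Choice] = None
        for _ in range(length):
            ca = round_choice(pa.ptype, prev_b, pa.tremble, rng)
            cb = round_choice(pb.ptype, prev_a, pb.tremble, rng)
            choices.append((ca, cb))
            pays.append(payoff(ca, cb, config))
            prev_a, prev_b = ca, cb
        matches.append(Match(m + 1, pa.player_id, pb.player_id, choices, pays))
    return matches


def history_category(own_r1: Choice, partner_r1: Choice) -> HistoryCategory:
    if own_r1 is Choice.TAKE_ALL:
        return (
            HistoryCategory.TAKE_PARTNER_SPLIT
            if partner_r1 is Choice.SPLIT
            else HistoryCategory.BOTH_TAKE
        )
    return (
        HistoryCategory.BOTH_SPLIT
        if partner_r1 is Choice.SPLIT
        else HistoryCategory.SPLIT_PARTNER_TAKE
    )


# ---------------------------------------------------------------------------
# Tabular I/O


def players_to_frame(players: Sequence[PlayerProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "player_id": [p.player_id for p in players],
            "gender": [p.gender.value for p in players],
            "ptype": [p.ptype.value for p in players],
            "tremble": [p.tremble for p in players],
        }
    )


def players_from_frame(df: pd.DataFrame) -> list[PlayerProfile]:
    return [
        PlayerProfile(int(r.player_id), Gender(r.gender), PlayerType(r.ptype), float(r.tremble))
        for r in df.itertuples()
    ]


def matches_to_frame(matches: Sequence[Match]) -> pd.DataFrame:
    rows = []
    for m in matches:
        for rnd, ((ca, cb), (ya, yb)) in enumerate(zip(m.choices, m.payoffs), start=1):
            rows.append((m.match_id, m.id_a, m.id_b, rnd, ca.value, cb.value, ya, yb))
    return pd.DataFrame(
        rows,
        columns=["match_id", "id_a", "id_b", "round", "choice_a", "choice_b", "pay_a", "pay_b"],
    )


def matches_from_frame(df: pd.DataFrame) -> list[Match]:
    matches = []
    for mid, grp in df.groupby("match_id", sort=True):
        grp = grp.sort_values("round")
        choices = [(Choice(a), Choice(b)) for a, b in zip(grp.choice_a, grp.choice_b)]
        pays = [(float(a), float(b)) for a, b in zip(grp.pay_a, grp.pay_b)]
        matches.append(
            Match(int(mid), int(grp.id_a.iloc[0]), int(grp.id_b.iloc[0]), choices, pays)
        )
    return matches


def player_round_table(
    players: Sequence[PlayerProfile], matches: Sequence[Match]
) -> pd.DataFrame:
    """Per-player view of the first two rounds, sorted by player id.

    Columns: gender, ptype, own_r1/own_r2/partner_r1 (choice labels), the
    corresponding ``*_split`` booleans and the behavioural-history category.
    Every match has length >= 2, so both rounds exist for every player.
    """
    by_id = {p.player_id: p for p in players}
    rows = []
    for m in matches:
        (a1, b1), (a2, b2) = m.choices[0], m.choices[1]
        for pid, own1, own2, part1 in ((m.id_a, a1, a2, b1), (m.id_b, b1, b2, a1)):
            prof = by_id[pid]
            rows.append(
                {
                    "player_id": pid,
                    "gender": prof.gender.value,
                    "ptype": prof.ptype.value,
                    "own_r1": own1.value,
                    "own_r2": own2.value,
                    "partner_r1": part1.value,
                    "own_r1_split": own1 is Choice.SPLIT,
                    "own_r2_split": own2 is Choice.SPLIT,
                    "partner_r1_split": part1 is Choice.SPLIT,
                    "history": history_category(own1, part1).value,
                }
            )
    return pd.DataFrame(rows).sort_values("player_id").reset_index(drop=True)
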