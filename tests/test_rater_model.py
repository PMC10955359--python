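"""Rater synthesis: beliefs, information sets, guess strategies, exclusions."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import norm

from coopcast.pd_engine import (
    Choice,
    GameConfig,
    Gender,
    generate_players,
    simulate_matches,
)
from coopcast.rater_model import (
    BeliefPair,
    InformationSet,
    RaterConfig,
    RaterProfile,
    RaterGender,
    Treatment,
    apply_exclusions,
    belief_about_players,
    build_information_set,
    combine_belief_and_cue,
    draw_belief_pairs,
    generate_raters,
    guess_round1,
    guess_round2,
    sample_appearance_cue,
    simulate_rating_study,
)

S, T = Choice.SPLIT, Choice.TAKE_ALL


def make_rater(
    belief_male=44.2,
    belief_female=63.9,
    treatment=Treatment.NONE,
    lambda_optimize=0.5,
    cue_weight=1.0,
    adherence=0.8,
):
    return RaterProfile(
        rater_id=1,
        gender=RaterGender.FEMALE,
        treatment=treatment,
        beliefs=BeliefPair(belief_male, belief_female),
        lambda_optimize=lambda_optimize,
        cue_weight=cue_weight,
        heuristic_adherence=adherence,
        flag_small_screen=False,
        duration_s=1000.0,
    )


class TestBeliefs:
    def test_degenerate_sd_returns_means(self, rng):
        pairs = draw_belief_pairs(50, 44.2, 63.9, 0.0, 0.0, 0.503, rng)
        assert all(p.belief_male == 44.2 and p.belief_female == 63.9 for p in pairs)

    def test_zero_correlation(self, rng):
        pairs = draw_belief_pairs(40_000, 50, 50, 10, 10, 0.0, rng)
        arr = np.array([(p.belief_male, p.belief_female) for p in pairs])
        assert abs(np.corrcoef(arr.T)[0, 1]) < 0.02

    def test_censored_moments_match_numeric_oracle(self, rng):
        # censored-normal mean: 100*(1-Phi(beta)) + mu*(Phi(beta)-Phi(alpha))
        #                       - sigma*(phi(beta)-phi(alpha)), alpha=(0-mu)/s
        n = 100_000
        pairs = draw_belief_pairs(n, 44.2, 63.9, 20, 20, 0.503, rng)
        arr = np.array([(p.belief_male, p.belief_female) for p in pairs])
        for col, mu in ((0, 44.2), (1, 63.9)):
            a, b = (0 - mu) / 20, (100 - mu) / 20
            expected = (
                100 * (1 - norm.cdf(b))
                + mu * (norm.cdf(b) - norm.cdf(a))
                - 20 * (norm.pdf(b) - norm.pdf(a))
            )
            assert arr[:, col].mean() == pytest.approx(expected, abs=0.3)
        assert arr.min() >= 0 and arr.max() <= 100

    def test_invalid_parameters(self, rng):
        with pytest.raises(ValueError):
            draw_belief_pairs(5, 50, 50, -1, 10, 0.0, rng)
        with pytest.raises(ValueError):
            draw_belief_pairs(5, 50, 50, 10, 10, 1.0, rng)

    @pytest.mark.parametrize(
        "pair,expected",
        [((44.2, 63.9), 54.05), ((50, 50), 50.0), ((0, 100), 50.0)],
    )
    def test_belief_about_players_is_unweighted_mean(self, pair, expected):
        assert belief_about_players(BeliefPair(*pair)) == pytest.approx(expected)


class TestAppearanceCue:
    def test_perfect_validity(self, rng):
        assert all(
            sample_appearance_cue(S, 1.0, rng) is S for _ in range(100)
        )

    def test_validity_is_match_probability(self, rng):
        n = 50_000
        hits = np.mean([sample_appearance_cue(S, 0.75, rng) is S for _ in range(n)])
        assert hits == pytest.approx(0.75, abs=4 * np.sqrt(0.75 * 0.25 / n))

    def test_anti_diagnostic_cue_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_appearance_cue(S, 0.4, rng)


class TestCombineBeliefAndCue:
    def test_absent_cue_is_identity(self):
        assert combine_belief_and_cue(63.9, None, 0.75, 1.0) == 63.9

    def test_even_prior_with_cue_gives_validity(self):
        # logistic(ln 3) = 0.75
        assert combine_belief_and_cue(50.0, S, 0.75, 1.0) == pytest.approx(75.0)

    def test_take_cue_shifts_down_by_log_odds(self):
        # logistic(logit(0.442) - ln 1.5) as percent, computed independently
        expected = 100 / (1 + np.exp(-(np.log(0.442 / 0.558) - np.log(1.5))))
        got = combine_belief_and_cue(44.2, T, 0.6, 1.0)
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(34.558, abs=0.01)

    def test_extreme_priors_are_clipped_not_infinite(self):
        assert 0 < combine_belief_and_cue(0.0, T, 0.9, 1.0) < 100
        assert 0 < combine_belief_and_cue(100.0, S, 0.9, 1.0) < 100


class TestInformationSets:
    @pytest.fixture
    def cohort(self, rng, game_config):
        players = generate_players(game_config, rng)
        matches = simulate_matches(players, game_config, rng)
        return players, matches

    def test_none_treatment_reveals_nothing(self, cohort, rng):
        players, matches = cohort
        info = build_information_set(
            Treatment.NONE, players[0], matches[0], 1, RaterConfig(), rng
        )
        assert not info.shows_gender
        assert info.gender is None and info.cue is None and info.history is None

    def test_label_reveals_gender_only(self, cohort, rng):
        players, matches = cohort
        female = next(p for p in players if p.gender is Gender.FEMALE)
        match = next(m for m in matches if female.player_id in (m.id_a, m.id_b))
        info = build_information_set(Treatment.LABEL, female, match, 1, RaterConfig(), rng)
        assert info.shows_gender and info.gender is Gender.FEMALE
        assert info.cue is None

    def test_video_round2_has_cue_and_history(self, cohort, rng):
        players, matches = cohort
        player = players[0]
        match = next(m for m in matches if player.player_id in (m.id_a, m.id_b))
        info = build_information_set(Treatment.VIDEO, player, match, 2, RaterConfig(), rng)
        assert info.cue is not None and info.history is not None
        own, partner = info.history
        idx = 0 if match.id_a == player.player_id else 1
        assert own is match.choices[0][idx]
        assert partner is match.choices[0][1 - idx]

    def test_information_nesting_across_treatments(self, cohort, rng):
        # NONE ⊂ LABEL ⊂ PHOTO = VIDEO in revealed fields
        players, matches = cohort
        player, match = players[0], matches[0]

        def fields(t):
            info = build_information_set(t, player, match, 1, RaterConfig(), rng)
            return (info.shows_gender, info.cue is not None)

        assert fields(Treatment.NONE) == (False, False)
        assert fields(Treatment.LABEL) == (True, False)
        assert fields(Treatment.PHOTO) == (True, True)
        assert fields(Treatment.VIDEO) == (True, True)


class TestGuessStrategies:
    def test_threshold_rater_is_deterministic(self, rng):
        rater = make_rater(lambda_optimize=1.0)
        info = InformationSet(shows_gender=False)
        assert all(guess_round1(rater, info, rng) is S for _ in range(50))

    def test_threshold_tie_at_fifty_guesses_split(self, rng):
        rater = make_rater(belief_male=50.0, belief_female=50.0, lambda_optimize=1.0)
        assert guess_round1(rater, InformationSet(False), rng) is S

    def test_certain_belief_always_split(self, rng):
        rater = make_rater(belief_male=100, belief_female=100, lambda_optimize=0.0)
        assert all(guess_round1(rater, InformationSet(False), rng) is S for _ in range(50))

    def test_probability_matching_limit(self, rng):
        # with lambda=0 and no cue the long-run Split rate equals the prior
        rater = make_rater(belief_male=54, belief_female=54, lambda_optimize=0.0)
        n = 50_000
        share = np.mean(
            [guess_round1(rater, InformationSet(False), rng) is S for _ in range(n)]
        )
        assert share == pytest.approx(0.54, abs=4 * np.sqrt(0.54 * 0.46 / n))

    @pytest.mark.parametrize(
        "history,expected",
        [((S, S), S), ((S, T), T), ((T, S), T), ((T, T), T)],
    )
    def test_full_adherence_follows_heuristic(self, rng, history, expected):
        rater = make_rater(adherence=1.0)
        info = InformationSet(False, history=history)
        assert guess_round2(rater, info, rng) is expected

    def test_round2_requires_history(self, rng):
        with pytest.raises(ValueError, match="history"):
            guess_round2(make_rater(), InformationSet(False), rng)


class TestRatingStudy:
    def test_record_count_is_raters_by_players_by_rounds(
        self, rng, cohort94_config, small_rater_config
    ):
        players = generate_players(cohort94_config, rng)
        matches = simulate_matches(players, cohort94_config, rng)
        raters = generate_raters(small_rater_config, rng)
        kept, _ = apply_exclusions(raters)
        guesses = simulate_rating_study(players, matches, kept, small_rater_config, rng)
        assert len(guesses) == len(kept) * 94 * 2
        per = guesses.groupby(["rater_id", "player_id", "round"]).size()
        assert (per == 1).all()

    def test_round1_records_precede_round2(self, rng, cohort94_config, small_rater_config):
        players = generate_players(cohort94_config, rng)
        matches = simulate_matches(players, cohort94_config, rng)
        kept, _ = apply_exclusions(generate_raters(small_rater_config, rng))
        guesses = simulate_rating_study(players, matches, kept, small_rater_config, rng)
        rounds = guesses["round"].to_numpy()
        assert (np.diff(rounds) >= 0).all()

    def test_optimisers_with_certain_beliefs_guess_all_split(self, rng, game_config):
        cfg = dataclasses.replace(
            RaterConfig(),
            n_none=10,
            n_label=0,
            n_photo=0,
            n_video=0,
            n_excluded_small_screen=0,
            n_excluded_fast=0,
            lambda_optimize=1.0,
            heuristic_adherence=0.0,
            belief_mean_male_raters=(100.0, 100.0),
            belief_mean_female_raters=(100.0, 100.0),
            belief_mean_other_raters=(100.0, 100.0),
            belief_sd=0.0,
        )
        players = generate_players(game_config, rng)
        matches = simulate_matches(players, game_config, rng)
        kept, _ = apply_exclusions(generate_raters(cfg, rng))
        guesses = simulate_rating_study(players, matches, kept, cfg, rng)
        r1 = guesses[guesses["round"] == 1]
        assert (r1["guess"] == S.value).all()

    def test_full_adherence_on_tremble_free_cohort_is_perfect_in_round2(self, rng):
        game = dataclasses.replace(GameConfig(), tremble=0.0)
        cfg = dataclasses.replace(
            RaterConfig(),
            n_none=15,
            n_label=15,
            n_photo=10,
            n_video=10,
            n_excluded_small_screen=0,
            n_excluded_fast=0,
            heuristic_adherence=1.0,
        )
        players = generate_players(game, rng)
        matches = simulate_matches(players, game, rng)
        kept, _ = apply_exclusions(generate_raters(cfg, rng))
        guesses = simulate_rating_study(players, matches, kept, cfg, rng)
        r2 = guesses[guesses["round"] == 2]
        assert (r2["correct"] == 1).all()


class TestExclusions:
    def test_printed_fixture_keeps_422(self, rng):
        raters = generate_raters(RaterConfig(), rng)
        assert len(raters) == 445
        kept, audit = apply_exclusions(raters)
        assert audit == {
            "input": 445,
            "excluded_small_screen": 11,
            "excluded_fast": 12,
            "kept": 422,
        }
        assert len(kept) == 422

    def test_kept_treatment_counts(self, rng):
        kept, _ = apply_exclusions(generate_raters(RaterConfig(), rng))
        counts = {t: 0 for t in Treatment}
        for r in kept:
            counts[r.treatment] += 1
        assert counts == {
            Treatment.NONE: 108,
            Treatment.LABEL: 101,
            Treatment.PHOTO: 108,
            Treatment.VIDEO: 105,
        }

    def test_no_flags_keeps_everyone(self, rng):
        cfg = dataclasses.replace(
            RaterConfig(), n_excluded_small_screen=0, n_excluded_fast=0
        )
        raters = generate_raters(cfg, rng)
        kept, audit = apply_exclusions(raters)
        assert len(kept) == len(raters)
        assert audit["excluded_small_screen"] == audit["excluded_fast"] == 0

    def test_all_flagged_keeps_none(self, rng):
        raters = [
            dataclasses.replace(r, flag_small_screen=True)
            for r in generate_raters(RaterConfig(), rng)[:10]
        ]
        kept, audit = apply_exclusions(raters)
        assert kept == []
        assert audit["excluded_small_screen"] == audit["input"] == 10

    def test_conservation(self, rng):
        raters = generate_raters(RaterConfig(), rng)
        _, audit = apply_exclusions(raters)
        assert (
            audit["kept"] + audit["excluded_small_screen"] + audit["excluded_fast"]
            == audit["input"]
        )
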