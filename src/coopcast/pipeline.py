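"""Orchestration: simulate -> rate -> measure -> test -> report.

A single :class:`RunConfig` (flat JSON/YAML document) owns the seed and every
sub-configuration. :func:`run` executes the full study on synthetic cohorts
and writes all artifacts to the output directory; identical config and seed
produce byte-identical CSV payloads. Child random streams are spawned
deterministically per stage from the root seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .inference import (
    paired_round_test,
    permutation_group_test,
    permutation_sign_test,
    recover_parameters,
)
from .metrics import beliefs_eval_frame, sdt_summary_frame
from .pd_engine import (
    Choice,
    GameConfig,
    Gender,
    generate_players,
    matches_to_frame,
    player_round_table,
    simulate_matches,
)
from .rater_model import (
    RaterConfig,
    apply_exclusions,
    generate_raters,
    raters_to_frame,
    simulate_rating_study,
)
from .pd_engine import players_to_frame
from .scoring import PaymentSchedule, payouts_frame

__all__ = ["InferenceConfig", "RunConfig", "summarize", "run", "simulate_study"]

logger = logging.getLogger(__name__)

ARTIFACTS = [
    "players.csv",
    "matches.csv",
    "raters.csv",
    "guesses.csv",
    "sdt_summary.csv",
    "beliefs_eval.csv",
    "payouts.csv",
    "summary_tables.csv",
    "tests.json",
    "recovery.json",
    "run_manifest.json",
]


@dataclass(frozen=True)
class InferenceConfig:
    n_perm: int = 10_000
    n_boot: int = 200

    def __post_init__(self) -> None:
        if self.n_perm < 999:
            raise ValueError("n_perm must be at least 999")
        if self.n_boot < 10:
            raise ValueError("n_boot must be at least 10")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    game: GameConfig = field(default_factory=GameConfig)
    rater: RaterConfig = field(default_factory=RaterConfig)
    payments: PaymentSchedule = field(default_factory=PaymentSchedule)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    output_dir: str = "coopcast_run"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")

        def build(key, klass):
            sub = data.get(key, {})
            if isinstance(sub, klass):
                return sub
            extra = set(sub) - {f.name for f in dataclasses.fields(klass)}
            if extra:
                raise ValueError(f"unknown keys in '{key}' config: {sorted(extra)}")
            # YAML lists become tuples where the dataclass expects them
            for f in dataclasses.fields(klass):
                if f.name in sub and isinstance(sub[f.name], list):
                    sub[f.name] = tuple(sub[f.name])
            return klass(**sub)

        return cls(
            seed=int(data.get("seed", 0)),
            game=build("game", GameConfig),
            rater=build("rater", RaterConfig),
            payments=build("payments", PaymentSchedule),
            inference=build("inference", InferenceConfig),
            output_dir=str(data.get("output_dir", "coopcast_run")),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)  # YAML superset also parses JSON
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    names = ["players", "matches", "raters", "guesses", "tests", "recovery"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ["players", "matches", "raters", "guesses", "tests", "recovery"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def simulate_study(
    config: RunConfig, rngs: Optional[dict[str, np.random.Generator]] = None
) -> dict:
    """Generate one full synthetic study (no file I/O).

    Returns a dict with players, matches, kept raters, the exclusion audit and
    the guess table — the in-memory core reused by :func:`run` and by
    replication loops.
    """
    rngs = rngs or _stage_rngs(config.seed)
    players = generate_players(config.game, rngs["players"])
    matches = simulate_matches(players, config.game, rngs["matches"])
    all_raters = generate_raters(config.rater, rngs["raters"])
    kept, audit = apply_exclusions(all_raters, config.rater.min_duration_s)
    guesses = simulate_rating_study(players, matches, kept, config.rater, rngs["guesses"])
    return {
        "players": players,
        "matches": matches,
        "all_raters": all_raters,
        "kept_raters": kept,
        "audit": audit,
        "guesses": guesses,
    }


def actual_split_percentages(players, matches) -> dict[str, float]:
    """Realized Round-1/Round-2 Split percentages, overall and by gender."""
    ptab = player_round_table(players, matches)
    male = ptab.gender == Gender.MALE.value
    return {
        "round1_overall": 100.0 * ptab.own_r1_split.mean(),
        "round2_overall": 100.0 * ptab.own_r2_split.mean(),
        "round1_male": 100.0 * ptab.own_r1_split[male].mean(),
        "round1_female": 100.0 * ptab.own_r1_split[~male].mean(),
    }


def summarize(
    guesses: pd.DataFrame, matches, raters: pd.DataFrame, players=None
) -> pd.DataFrame:
    """Treatment-by-round summary: guessed-Split %, correctness %, actual-
    Split % (panel A), plus the Round-2 breakdown by behavioural-history
    category (panel B). Percentages are reported to one decimal."""
    tmap = raters.set_index("rater_id")["treatment"]
    g = guesses.assign(
        treatment=guesses["rater_id"].map(tmap),
        guess_split=guesses["guess"] == Choice.SPLIT.value,
        truth_split=guesses["truth"] == Choice.SPLIT.value,
    )
    actual = g.drop_duplicates(["player_id", "round"]).groupby("round")["truth_split"].mean()

    panel_a = (
        g.groupby(["treatment", "round"], sort=True)
        .agg(guessed_split_pct=("guess_split", "mean"), correctness_pct=("correct", "mean"))
        .reset_index()
    )
    panel_a["actual_split_pct"] = panel_a["round"].map(actual)
    panel_a.insert(0, "panel", "A")
    panel_a.insert(2, "history", "All")

    if players is not None:
        hist_map = player_round_table(players, matches).set_index("player_id")["history"]
    else:
        mdf = matches if isinstance(matches, pd.DataFrame) else matches_to_frame(matches)
        from .pd_engine import history_category

        r1 = mdf[mdf["round"] == 1]
        records = {}
        for row in r1.itertuples():
            records[row.id_a] = history_category(Choice(row.choice_a), Choice(row.choice_b)).value
            records[row.id_b] = history_category(Choice(row.choice_b), Choice(row.choice_a)).value
        hist_map = pd.Series(records)

    g2 = g[g["round"] == 2].assign(history=lambda d: d["player_id"].map(hist_map))
    panel_b = (
        g2.groupby(["treatment", "history"], sort=True)
        .agg(
            guessed_split_pct=("guess_split", "mean"),
            correctness_pct=("correct", "mean"),
            actual_split_pct=("truth_split", "mean"),
        )
        .reset_index()
    )
    panel_b.insert(0, "panel", "B")
    panel_b.insert(2, "round", 2)
    panel_b["actual_split_pct"] = panel_b["actual_split_pct"].astype(float)

    out = pd.concat([panel_a, panel_b], ignore_index=True)
    for col in ("guessed_split_pct", "correctness_pct", "actual_split_pct"):
        out[col] = (100.0 * out[col].astype(float)).round(1)
    return out


def run(config: RunConfig) -> Path:
    """Execute the full pipeline and write all artifacts to the output dir."""
    out = Path(config.output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise ValueError(f"output directory {out} is not writable: {exc}") from exc

    digest = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    logger.info("run: seed=%d config_digest=%s", config.seed, digest)

    rngs = _stage_rngs(config.seed)
    seeds = _stage_seeds(config.seed)
    sim = simulate_study(config, rngs)
    players, matches = sim["players"], sim["matches"]
    kept, guesses = sim["kept_raters"], sim["guesses"]

    players_df = players_to_frame(players)
    matches_df = matches_to_frame(matches)
    raters_df = raters_to_frame(sim["all_raters"])
    kept_df = raters_to_frame(kept)
    logger.info(
        "players=%d matches=%d raters=%d kept=%d guesses=%d",
        len(players_df),
        matches_df.match_id.nunique(),
        len(raters_df),
        len(kept_df),
        len(guesses),
    )

    sdt = sdt_summary_frame(guesses)
    rates = actual_split_percentages(players, matches)
    beliefs_eval = beliefs_eval_frame(kept_df, rates["round1_male"], rates["round1_female"])
    payouts = payouts_frame(
        kept_df, guesses, rates["round1_male"], rates["round1_female"], config.payments
    )
    summary = summarize(guesses, matches, kept_df, players)

    acc = sdt.pivot(index="rater_id", columns="round", values="accuracy").dropna()
    treatment = kept_df.set_index("rater_id")["treatment"].loc[acc.index]
    n_perm = config.inference.n_perm
    rng_t = rngs["tests"]
    tests = [
        dataclasses.asdict(t)
        for t in (
            permutation_sign_test(acc[1], n_perm, rng_t, seeds["tests"]),
            permutation_sign_test(acc[2], n_perm, rng_t, seeds["tests"]),
            paired_round_test(acc[1], acc[2], n_perm, rng_t, seeds["tests"]),
            permutation_group_test(acc[1], treatment, n_perm, rng_t, seeds["tests"]),
            permutation_group_test(acc[2], treatment, n_perm, rng_t, seeds["tests"]),
        )
    ]
    labels = [
        "accuracy_round1_above_chance",
        "accuracy_round2_above_chance",
        "round2_minus_round1_accuracy",
        "accuracy_round1_by_treatment",
        "accuracy_round2_by_treatment",
    ]
    for label, t in zip(labels, tests):
        t["label"] = label

    true_vals = {
        "p_coop_male": config.game.p_coop_male,
        "p_coop_female": config.game.p_coop_female,
        "tremble": config.game.tremble,
        "lambda_optimize": config.rater.lambda_optimize,
        "heuristic_adherence": config.rater.heuristic_adherence,
    }
    recovery = [
        dataclasses.asdict(r)
        for r in recover_parameters(
            players_df,
            matches_df,
            guesses,
            kept_df,
            true_values=true_vals,
            n_boot=config.inference.n_boot,
            rng=rngs["recovery"],
        )
    ]

    frames = {
        "players.csv": players_df,
        "matches.csv": matches_df,
        "raters.csv": raters_df,
        "guesses.csv": guesses,
        "sdt_summary.csv": sdt,
        "beliefs_eval.csv": beliefs_eval,
        "payouts.csv": payouts,
        "summary_tables.csv": summary,
    }
    for name, df in frames.items():
        df.to_csv(out / name, index=False, lineterminator="\n")
    (out / "tests.json").write_text(json.dumps(tests, indent=2) + "\n")
    (out / "recovery.json").write_text(json.dumps(recovery, indent=2) + "\n")

    manifest = {
        "seed": config.seed,
        "config_digest": digest,
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "versions": {
            "coopcast": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "row_counts": {name: len(df) for name, df in frames.items()},
        "exclusion_audit": sim["audit"],
        "artifacts": ARTIFACTS,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return out
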