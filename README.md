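# coopcast

**Can people predict who will cooperate?** In a two-part experimental design,
players interact in a repeated "Split or Take All" Prisoner's Dilemma
(mutual Split pays $5 each, a lone Take All pays $10 against $0, mutual Take
All pays nothing) with a random-stopping rule — continuation probability
`4^(1−n)` from round `n`, with two rounds guaranteed. A separate cohort of
online raters then guesses each player's Round-1 choice from a first
impression and, after seeing the pair's Round-1 history, each player's
Round-2 choice. Four between-subject treatments vary what raters see about a
player: nothing (`None`), a gender label (`Label`), a static appearance cue
(`Photo`), or a dynamic one (`Video`).

`coopcast` is a fully synthetic, generative re-implementation of that design
for methodologists who want a tested sandbox for cooperation-prediction
measurement: no human data are ingested; instead, calibrated cohorts are
simulated end to end and the measurement layer is applied to them.

## The model in brief

**Players.** Each player is a conditional cooperator (probability 0.614 for
men, 0.860 for women) or a non-cooperator. Conditional cooperators open with
Split and then mirror the partner's previous realized choice (tit-for-tat);
non-cooperators always intend Take All. A symmetric execution error
("tremble", default 0.05) flips the intended choice each round.

**Raters.** Each rater holds correlated gender-specific beliefs
`(b_m, b_f)` about Split rates (bivariate normal, censored to [0, 100],
correlation 0.503). A first-round guess uses the belief matched to what the
treatment reveals — the average `(b_m + b_f)/2` when gender is hidden — plus
a noisy appearance cue folded in on the log-odds scale in the Photo/Video
arms. With probability `λ` the rater plays a threshold strategy (guess Split
iff the posterior ≥ 50%), otherwise probability-matches. Second-round
guesses follow the tit-for-tat mirror of the revealed history with
probability `a` (heuristic adherence), falling back to the first-impression
rule otherwise.

**Measurement.** Per rater and round, the cooperator detection rate `H`
(correct | player Split) and cheater detection rate `R` (correct | player
Take All) give signal-detection accuracy `Z(H) − Z(1−R)` and bias
`−½[Z(H) + Z(1−R)]`, with rates of 0/1 clamped to 1/100000 and 99999/100000.
Correctness (% correct) and a Haldane–Anscombe-corrected odds ratio are
alternative measures; belief quality is scored by signed/absolute error and
a "sufficiently correct" dummy. Beliefs are paid by a quadratic scoring rule
inside a 1/6 error window; directional claims are tested by sign-flip and
label-shuffle permutation tests, and a recovery harness re-estimates every
generating parameter from the emitted tables.

## Worked example

```
coopcast --seed 7 --out demo all
coopcast --seed 7 --out demo report
```

writes eleven artifacts (players/matches/raters/guesses CSVs, the
signal-detection and belief summaries, payouts, summary tables, permutation
tests, recovery report, and a manifest) and prints, for panel A:

```
panel treatment history  round  guessed_split_pct  correctness_pct  actual_split_pct
    A     Label     All      1               55.5             56.6              71.9
    A     Label     All      2               53.3             83.8              59.4
    A      None     All      1               56.0             52.6              71.9
    A      None     All      2               52.7             82.6              59.4
    A     Photo     All      1               55.9             56.1              71.9
    A     Photo     All      2               52.6             83.7              59.4
    A     Video     All      1               58.6             57.0              71.9
    A     Video     All      2               53.0             83.7              59.4
```

Reading this: the simulated cohort cooperated 71.9% of the time in Round 1
and 59.4% in Round 2 (defection spreads through tit-for-tat retaliation);
raters guessed Split ~55% of the time and were right ~55% of the time on
first impressions, but ~84% of the time once they could apply the
conditional-cooperation heuristic to the revealed history. The accompanying
`tests.json` shows per-rater accuracy above chance in both rounds and a
strongly significant Round-2 improvement (permutation p ≈ 1e−4), and
`recovery.json` recovers the generating parameters (e.g. adherence 0.8)
with percentile-bootstrap intervals.

The same pipeline is available stage by stage (`simulate`, `rate`,
`analyze`, `recover`, `report`), with `--config` accepting a YAML/JSON
document whose full default set `coopcast config --defaults` prints.

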