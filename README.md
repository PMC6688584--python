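# commitval

Commitment-based player motion models and pass decision valuation for
tracked invasion team sports, with a seeded synthetic match generator so
the whole pipeline is testable without proprietary tracking data.

The package implements two coupled methods:

1. **Commitment modeling** — a probabilistic motion model fit on observed
   player commitment to contests. Each contest (a spoil or contested mark
   following a kick) yields one training row per player within 35 m:
   `(velocity, time_to_point, rel_x, rel_y)` plus a binary label (ended
   within 2 m of the contest at contest time). Two 4-D Gaussian kernel
   density estimators (bandwidth 1.5, no standardization) are combined
   through the class-prior weight `w`:

   `Pr(x) = w f1(x) / (w f1(x) + (1 - w) f0(x))`

2. **Pass decision valuation** — per-cell team influence (summed player
   commitment probabilities), dominance (influence share), pass risk
   (dominance x influence), expected outcome (probability-weighted field
   equity of the four pass outcomes), a distance-dependent kicking-scatter
   smoothing, and the decision value of an executed pass relative to the
   best teammate option within the 60 m kicking radius (clamped below at
   -1).

Field equity is pluggable (`SurrogateEquity` is an antisymmetric
parametric stand-in scaled to +/-6 points; `LookupEquity` loads an
external gridded table).

## Layout

| Module                 | Contents |
| ---------------------- | -------- |
| `commitval.tracking`   | CSV data model, kinematics (velocity / displacement direction / relative frames), stream consolidation |
| `commitval.commitment` | contest extraction, observation building, KDE model fit / evaluation, motion-model grids |
| `commitval.control`    | influence, dominance, mark probability, outcome probabilities on grids |
| `commitval.equity`     | field-equity providers |
| `commitval.decision`   | expected outcome, kick smoothing, alternative search, decision value, match evaluation |
| `commitval.synthetic`  | seeded match generator with ground-truth commitment ledger, miniature fixtures |
| `commitval.analysis`   | descriptive stats, Mann-Whitney U, Spearman rho, density profiles, team reports |

## CLI

```bash
# generate a synthetic match (tracking.csv, transactions.csv, ledger.csv)
commitval simulate --seed 7 --plays 200 --out match/

# schema + consolidation diagnostics
commitval validate --tracking match/tracking.csv --transactions match/transactions.csv

# fit the commitment model from an observations CSV
commitval fit-commitment --observations obs.csv --bandwidth 1.5 --out model/

# motion-model surface at a given velocity / time-to-point
commitval motion-grid --model model/ --velocity 4 --time 2 --out grid.csv

# control surfaces for a single formation
commitval control --model model/ --formation F.csv --ball-x 0 --ball-y 0 \
    --attacking-team team_a --out surf.csv

# evaluate every mark->kick->mark pass of a match
commitval evaluate --tracking match/tracking.csv --transactions match/transactions.csv \
    --model model/ --equity surrogate --out passes.csv

# summary statistics and (optional) team comparison
commitval analyze --passes passes.csv --team-a team_a --team-b team_b --out report/
```

## Data formats

* tracking CSV: `timestamp,player_id,team_id,x,y` — 10 Hz frames, meters,
  float seconds.
* transactions CSV: `timestamp,event_type,player_id,x,y` — whole-second
  events, `event_type` in `{kick, mark, contested_mark, spoil}`.
* observations CSV: `velocity,time_to_point,rel_x,rel_y,committed`.
* evaluations CSV: one row per pass,
  `match_id,t_p,kicker_id,...,dom_dec,...,dom_alt,...,dv` (see
  `commitval.decision.EVALUATION_COLUMNS`).

Coordinates are centered on the field; the team in possession attacks
toward +x. Displacement direction is measured clockwise from +y.

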