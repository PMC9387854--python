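# chasekit

Analysis pipeline for **within-session chasing** in round-level online-gambling
tracking logs, paired with a generative simulator of a slot-grid dice game and
of player behaviour, so that every pipeline stage can be exercised at desk
scale against known ground truth.

The pipeline decomposes chasing into three facets, computed per player from
the previous round's outcome:

1. **When to stop** — conditional probabilities of ending a session after a
   win / a loss, normalised by the player's overall stop probability into
   relative likelihoods of stopping.
2. **Change in stake** — probability of changing the stake, and the mean
   signed stake change in euro cents.
3. **Speed of play** — mean within-player z-scored first-column response
   time, with a loss-minus-win difference score.

Each facet feeds a statistical battery: a 2×2 mixed ANOVA (involvement group ×
prior outcome, Type-III sums of squares, generalized eta squared) plus five
pairwise contrasts (paired t within groups, Welch t between groups and on
difference scores), with Holm-corrected p-values, default-prior (Cauchy scale
0.707) log Bayes factors, Hedges' g, and Morey-corrected within-subject CIs.

## Layout

| module               | role                                                                 |
|----------------------|----------------------------------------------------------------------|
| `chasekit.game`      | deterministic scoring + stochastic simulation of single game rounds  |
| `chasekit.simulate`  | synthetic players/cohorts with controllable, known chasing effects   |
| `chasekit.tracking`  | tracking-CSV I/O, validation, >10-minute-break session resegmentation|
| `chasekit.facets`    | the three facet indicators, inclusion filters, 12-parameter summary  |
| `chasekit.inference` | t-tests, Holm, Hedges' g, JZS Bayes factors, mixed ANOVA, battery    |
| `chasekit.cli`       | `simulate` / `analyze` / `full` subcommands, config + logging        |

The game's face values, prize-conversion rate, interior stake levels and
bonus-mini-game payout are not publicly documented, so they are configurable;
the shipped defaults (face values {5,10,15,20,25,30,40,50,100} + one bonus
face, prize = points/100 × stake, 150 bonus points, ladder
{0.25, 0.50, 0.75, 1, 1.50, 2, 3, 5, 10, 20} €) are explicitly invented.
Under these defaults the measured per-round win probability is ≈3.9% and the
bonus trigger rate ≈1.9% (uniform random placement).

## CLI

```bash
# simulate a cohort (tracking.csv + truth.csv + run.log)
chasekit simulate --seed 1 --out out/

# analyze a tracking CSV (needs player_id,group labels)
chasekit analyze --tracking out/tracking.csv --groups out/groups.csv \
    --out out/analysis --sensitivity --plot

# end to end
chasekit full --seed 1 --out out/ --sensitivity
```

All knobs (game rules, per-group player-parameter distributions, inclusion
filters `min_wins`/`min_after_outcome` = 5, RT cutoff 5000 ms, break threshold
600,000 ms, α = .05, Bayes-factor prior r = .707) live in one YAML config
passed via `--config`; `--seed` overrides the config seed. Outputs are CSVs
plus a markdown report that embeds the config hash and seed.

The tracking CSV contract (header columns, money parsed as exact euro cents)
is documented in `chasekit/tracking.py`.

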