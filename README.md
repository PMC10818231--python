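# surveysift

Multilayer fraud detection for web-based survey responses, plus the
agreement statistics needed to compare competing fraud classifiers.

Compensated, open web surveys attract fraud: bots submitting scripted
batches, duplicate submitters chasing incentive payments, and off-shore
actors misrepresenting eligibility. Survey platforms ship proprietary
fraud scores, but they are black boxes — researchers cannot tell how
they alter sample composition. `surveysift` implements a transparent,
rule-based alternative and the tooling to compare any two classifiers:

* **Real-time exclusion rules (stage 1)** — neighborhood name vs
  residential address (with adjacency), address existence against a
  gazetteer, rapid submission (same start *and* stop times ± 1 minute as
  ≥ 2 other surveys), repeated email addresses, nonstandard zip codes,
  residential addresses already reported by ≥ 2 earlier respondents,
  unrecognized recruitment URLs, and a honeypot check.
* **Post hoc *k*-strike rules (stage 2)** — applied to stage-1
  survivors: duplicate free-text comments (tiered: ≥ 1 word repeated
  ≥ 100×, ≥ 2 words ≥ 10×, ≥ 3 words ≥ 3×), VPN/data-center/foreign IP
  origin, and screener-vs-main inconsistency on key items. Each
  criterion is only a *strike*; a response is fraud when at least
  *k* = 2 strikes accumulate (*k* = 1 and 3 are sensitivity variants).
* **Platform adapter** — reproduces a platform's classification from its
  exported scores: reCAPTCHA v3 < 0.5, RelevantID fraud score ≥ 30, or
  RelevantID duplicate score ≥ 75.
* **Agreement statistics** — 2×2 confusion matrices and Cohen's κ,

      κ = (p_o − p_e) / (1 − p_e),   SE = √( p_o(1 − p_o) / ( n (1 − p_e)² ) ),

  with 95% CI κ ± 1.96·SE and both conventional qualitative scales
  (Landis–Koch and McHugh); subgroup means with normal-approximation
  CIs; χ², Welch *t* and Mann–Whitney *U* comparisons; windowed
  fraud-proportion time series.
* **Synthetic cohorts** — a seeded generator of response streams mixing
  genuine respondents with six fraud archetypes and ground-truth labels,
  so sensitivity and specificity can be measured end to end.

## Worked example

Simulate a cohort of 120 genuine respondents plus 84 planted fraudsters,
then run both classifiers:

```sh
$ cat spec.yaml
n_genuine: 120
archetype_counts:
  bot_burst: 30
  duplicate_farm: 12
  vpn_actor: 12
  inconsistent_screener: 9
  address_reuser: 9
  url_spoofer: 12

$ surveysift simulate --spec spec.yaml --seed 7 \
    --out responses.csv --truth truth.csv --gazetteer-out gaz/
wrote 204 responses (84 true fraud) to responses.csv

$ surveysift run --responses responses.csv --gazetteer gaz/ --out-dir out/
INFO surveysift.pipeline: stage 1: 54/204 fraud
INFO surveysift.pipeline: stage 2: 30/150 fraud
n=204  realtime_fraud=54  posthoc_fraud=30  multilayer_valid=120 (58.82%)  platform_fraud=61
report -> out/report.json
```

Stage 1 catches the 30 rapid-submission bots, 12 spoofed URLs, 9
duplicate emails (the farms' repeat entries) and 3 over-used addresses;
stage 2 catches the remaining 30 two-strike actors, recovering exactly
the 84 planted fraudsters. `out/report.json` carries the per-rule
counts, the confusion matrix against the platform-score classifier, and
κ with its CI and qualitative bands:

```json
"confusion": {"full": {"a": 57, "b": 27, "c": 4, "d": 116, "n": 204}},
"kappa":     {"kappa": 0.673, "se": 0.054, "ci_low": 0.567, "ci_high": 0.779,
              "landis_koch": "substantial", "mchugh": "moderate"}
```

Here the two systems agree on 57 fraud and 116 valid responses; the 27
cases flagged only by the multilayer rules are mostly planted actors the
simulated platform scores missed, giving κ = 0.67 ("substantial" /
"moderate" agreement). Stage-wise CLI commands (`classify realtime`,
`classify posthoc`, `classify platform`, `compare`) expose each step
separately; everything is also available as a library
(`surveysift.run_pipeline`, `surveysift.cohen_kappa`, ...).

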