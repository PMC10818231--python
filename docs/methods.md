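# Methods

## The detection model

`surveysift` treats survey fraud detection as a deterministic rule
cascade over a batch of submitted responses, mirroring how study teams
actually operate a compensated open web survey:

1. **Stage 1 (real-time exclusion).** Eight data checks run over the
   full batch; any firing rule labels the response fraud. Three rules
   are *batch* rules whose outcome depends on other responses (rapid
   submission, duplicate email, address overuse); the rest are pure
   per-row predicates against a gazetteer of reference lookups.
2. **Stage 2 (post hoc k-strike).** Only stage-1 survivors are
   examined. Three criteria — duplicate free text, bad IP origin,
   screener/main inconsistency — each raise a strike; a survivor is
   fraud when at least `k` strikes accumulate (default `k = 2`,
   balancing each criterion's individual false-positive risk against
   the need to exclude strongly suspicious entries; `k = 1`/`k = 3`
   are the sensitivity variants).
3. **Platform adapter.** Independently of stages 1–2, every response is
   classified from its three exported platform scores, so two complete
   systems can be compared on the same batch.

The assumption underlying the cascade is that rules are *evidence*, not
verdicts: stage-1 rules encode near-certain violations (an address that
does not exist, a referral link never distributed), while stage-2
criteria are individually fallible and therefore only count in
combination.

### Rule semantics worth stating precisely

* **Timestamps** are truncated to whole minutes before comparison. Two
  responses are "rapid" partners when both their start times and their
  end times differ by at most the window (default 1 minute); a response
  is flagged when it has at least `rapid_min_others` (default 2) such
  partners, evaluated pairwise with no transitive chaining.
* **Chronology.** Duplicate-email and address-overuse order the batch
  by start time (response id as tiebreak); the first occurrence of an
  email is never flagged, and only the third and later users of an
  address are flagged — the first two are never retro-flagged once a
  third appears.
* **First-match attribution.** A fraud case may fire several rules; all
  are retained as flags, but the per-rule counts attribute each case to
  its first firing rule in the criteria's listed order, so counts
  partition the fraud set.
* **Duplicate free text** is counted within the stage-1 survivor set
  only (stage 2 never sees excluded rows), after normalization
  (lowercase, whitespace collapse). Matching is exact; fuzzy matching
  is deliberately out of scope. Every response sharing an
  over-threshold string is struck, including its first submitter,
  because a strike is suspicion, not a verdict.
* **IP origin** uses longest-prefix match against a static intelligence
  table. Unmatched IPs are *not* flagged: the criterion requires
  positive evidence of VPN/data-center/foreign origin. Malformed IPs
  warn and resolve to unknown.
* **Platform thresholds** follow the documented boundary semantics
  exactly: strict `< 0.5` for reCAPTCHA, `>= 30` and `>= 75` for the
  two RelevantID scores. Missing scores never flag; responses with no
  scores at all are counted in an audit tally. Out-of-range scores warn
  but are still compared.
* **Normalization.** Emails: lowercase + strip, no plus-addressing
  collapse (the duplicate-email rule claims only literal reuse).
  Addresses: additionally punctuation-insensitive. URLs: scheme- and
  trailing-slash-insensitive. The address scheme is a documented
  package choice; no authoritative normalization standard exists for
  colloquial address entry.

## Agreement statistics

Cohen's κ is computed from the 2×2 cross-classification of two methods'
labels: `po = (a + d)/n`, `pe` from the marginals, `κ = (po − pe)/(1 −
pe)`. The standard error is the large-sample form

    SE = sqrt( po (1 − po) / ( n (1 − pe)^2 ) )

with CI `κ ± z·SE`. More elaborate variance formulas (e.g. Fleiss)
exist; this form is used because it reproduces the published intervals
this package is validated against, and the package's own tests
cross-check the point estimate against scikit-learn. Degenerate
marginals (`pe = 1`, e.g. both methods all-valid) raise an explicit
error; the pipeline reports κ as not computable in that stratum.

Qualitative bands use both conventional scales — Landis–Koch
(0/0.20/0.40/0.60/0.80 cutpoints) and McHugh (0.20/0.39/0.59/0.79/0.90)
— since practitioners quote either.

Subgroup means use z-based normal-approximation CIs (`z = 1.96` at
95%), not t intervals, matching the convention of the summary tables
they reproduce. Group comparisons delegate to scipy: Pearson χ²
(without Yates correction by default; a config switch enables it),
Welch's t, and Mann–Whitney U. The U test enumerates the exact
permutation distribution when the pooled sample is ≤ 10 (midranks for
ties) and otherwise uses the tie-corrected normal approximation with
continuity correction; the two paths agree within 0.02 on tie-free data
at pooled n = 10, which the tests verify.

The fraud-proportion time series is a centered moving-window proportion
per calendar day (default 7-day window); days whose window contains no
responses are missing. A locally weighted smoother is deliberately not
provided — the windowed series carries the same information without
smoothing parameters.

## The synthetic cohort generator

The generator emulates the response stream of a city-wide, compensated,
open web survey. What it does model:

* **Arrivals**: days are weighted 6:1 inside advertised campaign
  windows (defaults mirror a ~15-week study with three campaigns);
  bot bursts arrive uniformly over the whole period and therefore also
  flood the quiet stretches, reproducing the off-campaign episodes that
  motivate time-series monitoring.
* **Durations**: log-normal around a median of 23.46 minutes
  (σ = 0.55, matching an IQR of roughly 18–38 minutes).
* **Genuine respondents**: unique gazetteer-registered addresses with
  matching neighborhoods, distinct emails, consistent screener/main
  answers, in-country IPs, distributed URLs, and free text drawn half
  empty, else from a Zipf-weighted pool of one-word comments (kept far
  below every duplicate tier, so genuine duplicate-text strikes are
  rare but possible) or a unique long-tail phrase.
* **Platform scores**: genuine reCAPTCHA ~ N(0.85, 0.12) clipped to
  [0, 1] with RelevantID scores below threshold, plus a 5% contamination
  probability of a platform-breaching score — this models the
  disagreement between systems; fraud archetypes breach their natural
  thresholds with configurable probabilities (bots 0.9 low-reCAPTCHA,
  farms 0.8 high duplicate score, others 0.6/0.4). No public
  description of the proprietary score distributions exists; these
  defaults are declared assumptions, tunable via the spec.
* **Archetype strike profiles**: archetypes targeted at stage-1 rules
  (bot bursts, URL spoofers, the repeat entries of farms and address
  re-users) violate exactly those rules. Archetypes that *survive*
  stage 1 (VPN actors, inconsistent screeners, the first entry of each
  farm, the first two users of a shared address) additionally paste
  canned multi-word comments — the behaviour fraud farms exhibit in
  practice — so they deterministically carry the two strikes the k = 2
  rule needs. A single-strike actor is undetectable at k = 2 by
  construction; giving post-hoc archetypes a paired strike is the
  design choice that makes ground-truth recovery a meaningful target.
  Canned texts rotate through a pool sized so each phrase repeats at
  least three times among survivors.

Default mixture (320 genuine + 295 fraud ≈ 615 responses) scales the
study conditions to about a tenth of their volume so the full property
suite runs in seconds; the per-archetype proportions follow the
study's per-rule attribution (rapid bots dominating, then spoofed URLs
and reused addresses, then two-strike post hoc actors, then a small
email farm).

What it does **not** model: real geography (neighborhoods are an
invented 12-node ring), adversarial bots that mimic human timing or
text, platform score correlations with respondent demographics, partial
completions, or multi-language rendering. Passing tests therefore
demonstrate the *pipeline's* correctness and the detectability of the
stated archetypes, not field performance on real streams, where fraud
signatures are noisier and rules inevitably misclassify some legitimate
respondents.

`build_planted_cohort` is the deterministic variant for flowchart
arithmetic: it plants exact stage-1 and stage-2 counts (bot clusters +
URL spoofers; two-strike VPN actors) and places all other responses on
a 1-minute start grid with durations cycling 20/23/26/29/32 minutes, so
two responses with starts within ±1 minute always differ in end time by
more than 1 minute and the rapid rule cannot fire coincidentally.

## Numerical and degenerate-input choices

* All randomness flows through one `numpy` Generator seeded from the
  spec; identical specs give identical cohorts, and the response-id
  stream embeds the seed.
* Config cutoffs are validated against their score ranges at
  construction; `k` outside {1, 2, 3} is a configuration error.
* Empty zip codes are not "nonstandard" (eligibility screening owns
  that case); empty addresses cannot match an existing address and are
  flagged invalid; whitespace-only honeypot answers normalize to empty
  and do not flag.
* Undefined detection ratios (no true fraud, or no positive
  predictions) are reported as missing rather than 0 or 1.
* The exact Mann-Whitney path is O(C(n, nx)) and capped at pooled
  n = 10 (252 subsets at worst).

## Known limitations

* The rule engine is O(n·k) in batch size for the sliding-window rapid
  rule but assumes the batch fits in memory; streams of millions of
  rows would need chunked chronological processing.
* The IP-intelligence table is static; real deployments refresh VPN/
  data-center lists continuously.
* Human review — part of any multilayered strategy in practice — is out
  of scope; the package automates only the data-driven layers.
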