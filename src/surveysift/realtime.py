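"""Stage 1: real-time exclusion criteria.

Seven data checks applied to every submitted response — neighborhood/
address consistency against a gazetteer, rapid-submission timing clusters,
duplicate emails, nonstandard zip codes, over-used residential addresses
and unrecognized recruitment URLs — plus the honeypot check.  A response
failing any criterion is labeled fraud; per-rule counts attribute each
fraud case to its first firing rule in the criteria's listed order, so the
counts partition the fraud set.

Timestamps are compared at minute resolution after truncation, matching
the +/- 1 minute wording of the rapid-submission criterion.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Set

from ._text import normalize_address, normalize_email, normalize_text, normalize_url
from .types import (
    REALTIME_RULE_ORDER,
    Config,
    Gazetteer,
    Label,
    RuleFlag,
    RuleId,
    SurveyResponse,
)


def _minute(ts) -> int:
    """Epoch minutes after truncating sub-minute precision."""
    return int(ts.replace(second=0, microsecond=0).timestamp()) // 60


def rule_neighborhood_mismatch(r: SurveyResponse, g: Gazetteer) -> bool:
    """Reported neighborhood is neither the address's neighborhood nor adjacent.

    Addresses absent from the gazetteer return False here; the invalid-
    address criterion owns that case.
    """
    hood = g.neighborhood_of(r.street_address)
    if hood is None:
        return False
    reported = normalize_text(r.neighborhood_name)
    accepted = {hood} | g.adjacency.get(hood, set())
    return reported not in {normalize_text(h) for h in accepted}


def rule_invalid_address(r: SurveyResponse, g: Gazetteer) -> bool:
    """Residential address does not match any existing indexed address."""
    return normalize_address(r.street_address) not in g.address_index


def rule_rapid_submission(
    batch: Iterable[SurveyResponse],
    window_minutes: float = 1.0,
    min_others: int = 2,
) -> Set[str]:
    """Responses sharing start AND stop times (+/- window) with >= min_others.

    The relation is evaluated pairwise per response; no transitive
    chaining.  Result is invariant to the input order of the batch.
    """
    batch = list(batch)
    w = window_minutes
    starts = [_minute(r.start_time) for r in batch]
    ends = [_minute(r.end_time) for r in batch]
    order = sorted(range(len(batch)), key=starts.__getitem__)
    flagged: Set[str] = set()
    lo = 0
    # sliding window over start times; counterpart end check is explicit
    for pos, i in enumerate(order):
        while starts[order[lo]] < starts[i] - w:
            lo += 1
        matches = 0
        for j in order[lo:]:
            if starts[j] > starts[i] + w:
                break
            if j != i and abs(ends[i] - ends[j]) <= w:
                matches += 1
                if matches >= min_others:
                    flagged.add(batch[i].response_id)
                    break
    return flagged


def rule_duplicate_email(batch: Iterable[SurveyResponse]) -> Set[str]:
    """All occurrences after the first of each repeated nonempty email.

    The batch is processed in chronological order (start_time, then
    response_id), so "previously enrolled" means temporally earlier.
    """
    seen: Set[str] = set()
    flagged: Set[str] = set()
    for r in _chronological(batch):
        email = normalize_email(r.email)
        if not email:
            continue
        if email in seen:
            flagged.add(r.response_id)
        seen.add(email)
    return flagged


def rule_nonstandard_zip(r: SurveyResponse, g: Gazetteer) -> bool:
    """Zip code is a PO-box or unique (non-residential) code."""
    return r.zip_code.strip() in g.nonstandard_zips


def rule_address_overuse(
    batch: Iterable[SurveyResponse], prior_count: int = 2
) -> Set[str]:
    """Address already reported by >= prior_count earlier respondents.

    With the default of 2, the third and later users of an address are
    flagged; the first two are never retro-flagged.
    """
    counts: Counter = Counter()
    flagged: Set[str] = set()
    for r in _chronological(batch):
        addr = normalize_address(r.street_address)
        if not addr:
            continue
        if counts[addr] >= prior_count:
            flagged.add(r.response_id)
        counts[addr] += 1
    return flagged


def rule_invalid_referral(r: SurveyResponse, g: Gazetteer) -> bool:
    """Referral URL is not one of the distributed recruitment links."""
    valid = {normalize_url(u) for u in g.valid_urls}
    return normalize_url(r.referral_url) not in valid


def rule_honeypot(r: SurveyResponse) -> bool:
    """Any (non-whitespace) answer to the hidden honeypot item."""
    return bool(r.honeypot_answer.strip())


@dataclass
class RealtimeResult:
    """Stage-1 labels, all flags raised, and first-match per-rule counts."""

    labels: Dict[str, Label]
    flags: List[RuleFlag]
    counts_by_rule: Dict[RuleId, int] = field(default_factory=dict)

    @property
    def fraud_ids(self) -> Set[str]:
        return {rid for rid, lab in self.labels.items() if lab is Label.FRAUD}

    @property
    def valid_ids(self) -> Set[str]:
        return {rid for rid, lab in self.labels.items() if lab is Label.VALID}


def apply_realtime_stage(
    batch: List[SurveyResponse], g: Gazetteer, cfg: Config
) -> RealtimeResult:
    """Run all real-time criteria over a batch and label each response.

    A response is fraud iff any rule fires.  ``counts_by_rule`` attributes
    each fraud case to its first firing rule in criteria order, so the
    per-rule counts sum to the fraud count; every firing rule is still
    recorded in ``flags``.
    """
    if not batch:
        raise ValueError("batch must be nonempty")
    rapid = rule_rapid_submission(batch, cfg.rapid_window_minutes, cfg.rapid_min_others)
    dup_email = rule_duplicate_email(batch)
    overuse = rule_address_overuse(batch, cfg.address_overuse_prior_count)

    labels: Dict[str, Label] = {}
    flags: List[RuleFlag] = []
    counts: Dict[RuleId, int] = {}
    fired_by_id: Dict[str, List[RuleId]] = defaultdict(list)
    for r in batch:
        checks = {
            RuleId.NEIGHBORHOOD_MISMATCH: rule_neighborhood_mismatch(r, g),
            RuleId.INVALID_ADDRESS: rule_invalid_address(r, g),
            RuleId.RAPID_SUBMISSION: r.response_id in rapid,
            RuleId.DUPLICATE_EMAIL: r.response_id in dup_email,
            RuleId.NONSTANDARD_ZIP: rule_nonstandard_zip(r, g),
            RuleId.ADDRESS_OVERUSE: r.response_id in overuse,
            RuleId.INVALID_URL: rule_invalid_referral(r, g),
            RuleId.HONEYPOT: rule_honeypot(r),
        }
        fired = [rule for rule in REALTIME_RULE_ORDER if checks[rule]]
        fired_by_id[r.response_id] = fired
        if fired:
            labels[r.response_id] = Label.FRAUD
            counts[fired[0]] = counts.get(fired[0], 0) + 1
            flags.extend(
                RuleFlag(r.response_id, rule, evidence=_evidence(r, rule))
                for rule in fired
            )
        else:
            labels[r.response_id] = Label.VALID
    return RealtimeResult(labels=labels, flags=flags, counts_by_rule=counts)


def _evidence(r: SurveyResponse, rule: RuleId) -> str:
    return {
        RuleId.NEIGHBORHOOD_MISMATCH: f"reported {r.neighborhood_name!r}",
        RuleId.INVALID_ADDRESS: f"address {r.street_address!r}",
        RuleId.RAPID_SUBMISSION: f"start {r.start_time:%Y-%m-%d %H:%M}",
        RuleId.DUPLICATE_EMAIL: f"email {r.email!r}",
        RuleId.NONSTANDARD_ZIP: f"zip {r.zip_code!r}",
        RuleId.ADDRESS_OVERUSE: f"address {r.street_address!r}",
        RuleId.INVALID_URL: f"url {r.referral_url!r}",
        RuleId.HONEYPOT: "honeypot answered",
    }[rule]


def _chronological(batch: Iterable[SurveyResponse]) -> List[SurveyResponse]:
    return sorted(batch, key=lambda r: (r.start_time, r.response_id))
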