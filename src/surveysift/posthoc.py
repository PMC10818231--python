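"""Stage 2: automated post hoc strike criteria and the k-strike rule.

Three criteria — duplicate free-text comments (tiered by word count),
VPN/data-center/foreign IP origin, and screener-vs-main inconsistency on
key items — each raise a *strike* against a stage-1 survivor.  Because
each criterion alone only marks an entry as suspicious, a response is
labeled fraud only when at least ``k`` criteria fire (study default
k = 2; 1 and 3 are the sensitivity variants).

Duplicate-text repeat counts are computed within the stage-1-valid set
only, matching the pipeline topology in which stage 2 sees survivors.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Set

from ._text import normalize_text, word_count
from .types import Config, ConfigurationError, Gazetteer, Label, RuleId, SurveyResponse

_NUMERIC_ITEMS = frozenset({"age", "adults_home", "minors_home"})


def flag_duplicate_free_text(
    texts: Mapping[str, str],
    tiers: Iterable = ((1, 100), (2, 10), (3, 3)),
) -> Set[str]:
    """Responses whose normalized comment is repeated beyond a tier threshold.

    A text with word count w repeated c times is flagged when some tier
    (min_words, min_repeats) has w >= min_words and c >= min_repeats.
    Every response sharing an over-threshold string is flagged, including
    the first submitter.  Empty comments never flag.
    """
    normalized = {rid: normalize_text(t) for rid, t in texts.items()}
    counts = Counter(t for t in normalized.values() if t)
    flagged: Set[str] = set()
    for rid, t in normalized.items():
        if not t:
            continue
        w, c = word_count(t), counts[t]
        if any(w >= mw and c >= mr for mw, mr in tiers):
            flagged.add(rid)
    return flagged


def flag_bad_ip(ip: str, g: Gazetteer, allowed_country: str = "US") -> bool:
    """IP belongs to a VPN/data center or originates outside the allowed country.

    Uses longest-prefix match against the gazetteer's IP-intelligence
    table; IPs with no matching prefix are not flagged (the criterion
    requires positive evidence).
    """
    rec = g.ip_lookup(ip)
    if rec is None:
        return False
    is_vpn, country = rec
    return is_vpn or country != allowed_country.upper()


def flag_screener_inconsistency(
    r: SurveyResponse, key_items: Iterable[str]
) -> bool:
    """Main-survey answer contradicts the screener on >= 1 key item.

    Items missing on either side are skipped.  Numeric items (age,
    household counts) compare numerically; categorical items compare
    after text normalization.
    """
    for item in key_items:
        s, m = r.screener_answers.get(item), r.main_answers.get(item)
        if s is None or m is None or str(s).strip() == "" or str(m).strip() == "":
            continue
        if _values_differ(item, str(s), str(m)):
            return True
    return False


def _values_differ(item: str, s: str, m: str) -> bool:
    if item in _NUMERIC_ITEMS:
        try:
            return float(s) != float(m)
        except ValueError:
            pass  # fall back to text comparison
    return normalize_text(s) != normalize_text(m)


def apply_k_strike(
    strikes: Mapping[str, Set[RuleId]], k: int
) -> Dict[str, Label]:
    """Fraud iff a response accumulated at least k strikes; k in {1, 2, 3}."""
    if k not in (1, 2, 3):
        raise ConfigurationError(f"k_strike must be 1, 2 or 3; got {k}")
    return {
        rid: Label.FRAUD if len(s) >= k else Label.VALID
        for rid, s in strikes.items()
    }


@dataclass
class PosthocResult:
    """Per-response strike sets and the resulting stage-2 labels."""

    strikes: Dict[str, Set[RuleId]]
    labels: Dict[str, Label]
    k_used: int

    @property
    def fraud_ids(self) -> Set[str]:
        return {rid for rid, lab in self.labels.items() if lab is Label.FRAUD}

    @property
    def valid_ids(self) -> Set[str]:
        return {rid for rid, lab in self.labels.items() if lab is Label.VALID}

    def strike_counts(self) -> Dict[RuleId, int]:
        """How many responses each criterion struck (not mutually exclusive)."""
        counts: Counter = Counter()
        for s in self.strikes.values():
            counts.update(s)
        return dict(counts)


def apply_posthoc_stage(
    stage1_valid: List[SurveyResponse], g: Gazetteer, cfg: Config
) -> PosthocResult:
    """Run the three post hoc criteria over stage-1 survivors and apply k-strike."""
    dup_text = flag_duplicate_free_text(
        {r.response_id: r.free_text_comment for r in stage1_valid}, cfg.text_tiers
    )
    strikes: Dict[str, Set[RuleId]] = {}
    for r in stage1_valid:
        s: Set[RuleId] = set()
        if r.response_id in dup_text:
            s.add(RuleId.DUP_FREE_TEXT)
        if flag_bad_ip(r.ip_address, g, cfg.allowed_country):
            s.add(RuleId.BAD_IP)
        if flag_screener_inconsistency(r, cfg.key_items):
            s.add(RuleId.SCREENER_INCONSISTENCY)
        strikes[r.response_id] = s
    labels = apply_k_strike(strikes, cfg.k_strike)
    return PosthocResult(strikes=strikes, labels=labels, k_used=cfg.k_strike)
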