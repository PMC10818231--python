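"""Platform-score fraud classification (Qualtrics-style adapter).

The survey platform exports three opaque scores per response: a
reCAPTCHA v3 bot-likelihood score in [0, 1] (fraud when *under* 0.5), a
RelevantID fraud score in [0, 130] (fraud at >= 30) and a RelevantID
duplicate score in [0, 100] (duplicate at >= 75).  This adapter
reproduces the platform's classification from those scores alone;
the scoring models themselves are proprietary and out of scope.

Missing scores never flag; responses with all three scores missing are
counted in a no-score audit tally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List

from .types import (
    ClassificationRecord,
    Config,
    ConfigurationError,
    Label,
    Method,
    RuleFlag,
    RuleId,
    Stage,
    SurveyResponse,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlatformThresholds:
    """Score cutoffs; defaults are the platform's recommended values."""

    recaptcha_cutoff: float = 0.5   # fraud if score < cutoff
    fraud_score_cutoff: float = 30.0  # fraud if score >= cutoff
    dup_score_cutoff: float = 75.0    # duplicate if score >= cutoff

    def __post_init__(self) -> None:
        if not 0.0 <= self.recaptcha_cutoff <= 1.0:
            raise ConfigurationError("recaptcha_cutoff outside [0, 1]")
        if not 0.0 <= self.fraud_score_cutoff <= 130.0:
            raise ConfigurationError("fraud_score_cutoff outside [0, 130]")
        if not 0.0 <= self.dup_score_cutoff <= 100.0:
            raise ConfigurationError("dup_score_cutoff outside [0, 100]")

    @classmethod
    def from_config(cls, cfg: Config) -> "PlatformThresholds":
        return cls(cfg.recaptcha_cutoff, cfg.fraud_score_cutoff, cfg.dup_score_cutoff)


def classify_platform(
    r: SurveyResponse, t: PlatformThresholds = PlatformThresholds()
) -> ClassificationRecord:
    """Label one response fraud iff any of the three thresholds is breached.

    Boundary semantics follow the platform's documentation exactly:
    strict "<" for reCAPTCHA, ">=" for both RelevantID scores.  Every
    breached threshold is recorded as a flag.
    """
    flags: List[RuleFlag] = []
    if r.recaptcha_v3 is not None and r.recaptcha_v3 < t.recaptcha_cutoff:
        flags.append(RuleFlag(r.response_id, RuleId.PLATFORM_RECAPTCHA,
                              f"recaptcha {r.recaptcha_v3}"))
    if r.relevantid_fraud is not None and r.relevantid_fraud >= t.fraud_score_cutoff:
        flags.append(RuleFlag(r.response_id, RuleId.PLATFORM_FRAUD_SCORE,
                              f"fraud score {r.relevantid_fraud}"))
    if r.relevantid_dup is not None and r.relevantid_dup >= t.dup_score_cutoff:
        flags.append(RuleFlag(r.response_id, RuleId.PLATFORM_DUP_SCORE,
                              f"dup score {r.relevantid_dup}"))
    if flags:
        return ClassificationRecord(r.response_id, Method.PLATFORM,
                                    Label.FRAUD, Stage.PLATFORM, flags)
    return ClassificationRecord(r.response_id, Method.PLATFORM, Label.VALID, Stage.NONE)


@dataclass
class PlatformResult:
    """Batch platform labels with per-threshold counts and a no-score tally."""

    records: List[ClassificationRecord]
    counts_by_rule: Dict[RuleId, int] = field(default_factory=dict)
    n_no_score: int = 0

    @property
    def labels(self) -> Dict[str, Label]:
        return {rec.response_id: rec.label for rec in self.records}

    @property
    def fraud_count(self) -> int:
        return sum(1 for rec in self.records if rec.label is Label.FRAUD)


def classify_platform_batch(
    batch: Iterable[SurveyResponse], t: PlatformThresholds = PlatformThresholds()
) -> PlatformResult:
    """Apply :func:`classify_platform` to a batch.

    ``counts_by_rule`` counts every breached threshold (criteria are not
    mutually exclusive, matching how platform totals are reported).
    """
    records = []
    counts: Dict[RuleId, int] = {}
    no_score = 0
    for r in batch:
        rec = classify_platform(r, t)
        records.append(rec)
        for f in rec.flags:
            counts[f.rule_id] = counts.get(f.rule_id, 0) + 1
        if r.recaptcha_v3 is None and r.relevantid_fraud is None and r.relevantid_dup is None:
            no_score += 1
    if no_score:
        logger.info("%d responses had no platform scores; labeled valid", no_score)
    return PlatformResult(records=records, counts_by_rule=counts, n_no_score=no_score)
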