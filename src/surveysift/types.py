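"""Domain types shared by every stage of the fraud-detection pipeline."""

from __future__ import annotations

import enum
import ipaddress
import logging
from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional

from ._text import normalize_address

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """A configuration file or column map is invalid or incomplete."""


class DataError(ValueError):
    """An input data file is malformed or internally inconsistent."""


class SurveyType(str, enum.Enum):
    ADULT = "adult"
    PARENT = "parent"
    YOUTH = "youth"


class Label(str, enum.Enum):
    VALID = "valid"
    FRAUD = "fraud"


class Stage(str, enum.Enum):
    REALTIME = "realtime"
    POSTHOC = "posthoc"
    PLATFORM = "platform"
    NONE = "none"


class Method(str, enum.Enum):
    MULTILAYER = "multilayer"
    PLATFORM = "platform"


class RuleId(str, enum.Enum):
    # real-time exclusion criteria, in precedence order
    NEIGHBORHOOD_MISMATCH = "neighborhood_mismatch"
    INVALID_ADDRESS = "invalid_address"
    RAPID_SUBMISSION = "rapid_submission"
    DUPLICATE_EMAIL = "duplicate_email"
    NONSTANDARD_ZIP = "nonstandard_zip"
    ADDRESS_OVERUSE = "address_overuse"
    INVALID_URL = "invalid_url"
    HONEYPOT = "honeypot"
    # post hoc strike criteria
    DUP_FREE_TEXT = "dup_free_text"
    BAD_IP = "bad_ip"
    SCREENER_INCONSISTENCY = "screener_inconsistency"
    # platform score thresholds
    PLATFORM_RECAPTCHA = "platform_recaptcha"
    PLATFORM_FRAUD_SCORE = "platform_fraud_score"
    PLATFORM_DUP_SCORE = "platform_dup_score"


#: The real-time criteria in the precedence order used for first-match
#: attribution of fraud counts (criteria 1-7, then the honeypot check).
REALTIME_RULE_ORDER = (
    RuleId.NEIGHBORHOOD_MISMATCH,
    RuleId.INVALID_ADDRESS,
    RuleId.RAPID_SUBMISSION,
    RuleId.DUPLICATE_EMAIL,
    RuleId.NONSTANDARD_ZIP,
    RuleId.ADDRESS_OVERUSE,
    RuleId.INVALID_URL,
    RuleId.HONEYPOT,
)

POSTHOC_RULES = (
    RuleId.DUP_FREE_TEXT,
    RuleId.BAD_IP,
    RuleId.SCREENER_INCONSISTENCY,
)

#: Valid ranges of the three platform-exported scores.
SCORE_RANGES = {
    "recaptcha_v3": (0.0, 1.0),
    "relevantid_fraud": (0.0, 130.0),
    "relevantid_dup": (0.0, 100.0),
}


@dataclass
class SurveyResponse:
    """One submitted survey row.

    Timestamps carry minute precision or finer; optional fields use the
    empty string (text) or ``None`` (scores) when absent.
    """

    response_id: str
    start_time: datetime
    end_time: datetime
    survey_type: SurveyType
    email: str = ""
    street_address: str = ""
    zip_code: str = ""
    neighborhood_name: str = ""
    ip_address: str = ""
    referral_url: str = ""
    free_text_comment: str = ""
    honeypot_answer: str = ""
    completed: bool = True
    screener_answers: dict = field(default_factory=dict)
    main_answers: dict = field(default_factory=dict)
    demographics: dict = field(default_factory=dict)
    outcome_answers: dict = field(default_factory=dict)
    recaptcha_v3: Optional[float] = None
    relevantid_fraud: Optional[float] = None
    relevantid_dup: Optional[float] = None

    def __post_init__(self) -> None:
        if isinstance(self.survey_type, str) and not isinstance(self.survey_type, SurveyType):
            self.survey_type = SurveyType(self.survey_type)
        if self.end_time < self.start_time:
            raise DataError(
                f"response {self.response_id!r}: end_time precedes start_time"
            )
        for name, (lo, hi) in SCORE_RANGES.items():
            v = getattr(self, name)
            if v is not None and not lo <= v <= hi:
                logger.warning(
                    "response %s: %s=%s outside [%s, %s]",
                    self.response_id, name, v, lo, hi,
                )


@dataclass
class Gazetteer:
    """Reference lookups used by the address, URL and IP rules.

    ``address_index`` maps *normalized* street addresses to canonical
    neighborhood names; ``adjacency`` is a symmetric neighborhood graph;
    ``ip_intel`` is a static longest-prefix-match table standing in for a
    live proxy/VPN intelligence service.
    """

    address_index: dict = field(default_factory=dict)
    adjacency: dict = field(default_factory=dict)
    nonstandard_zips: set = field(default_factory=set)
    valid_urls: set = field(default_factory=set)
    ip_intel: list = field(default_factory=list)  # (ip_network, is_vpn, country)

    def __post_init__(self) -> None:
        # symmetrize adjacency and guarantee an entry per indexed neighborhood
        for a in list(self.adjacency):
            for b in self.adjacency[a]:
                self.adjacency.setdefault(b, set()).add(a)
        for hood in set(self.address_index.values()):
            self.adjacency.setdefault(hood, set())
        self.ip_intel = sorted(
            self.ip_intel, key=lambda rec: rec[0].prefixlen, reverse=True
        )

    def neighborhood_of(self, street_address: str) -> Optional[str]:
        """Canonical neighborhood for an address, or None if not indexed."""
        return self.address_index.get(normalize_address(street_address))

    def ip_lookup(self, ip: str):
        """Longest-prefix-match record ``(is_vpn, country)`` or None.

        Malformed IP strings log a row-level warning and resolve to None.
        """
        try:
            addr = ipaddress.ip_address(ip.strip())
        except ValueError:
            if ip.strip():
                logger.warning("malformed IP address %r", ip)
            return None
        for net, is_vpn, country in self.ip_intel:
            if addr.version == net.version and addr in net:
                return (is_vpn, country)
        return None


@dataclass(frozen=True)
class RuleFlag:
    """One rule firing on one response, with human-readable evidence."""

    response_id: str
    rule_id: RuleId
    evidence: str = ""


@dataclass
class ClassificationRecord:
    """Final valid/fraud label for one response under one method."""

    response_id: str
    method: Method
    label: Label
    stage: Stage
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label is Label.VALID and self.stage is not Stage.NONE:
            raise DataError(
                f"response {self.response_id!r}: valid label requires stage 'none'"
            )
        if self.label is Label.FRAUD and not self.flags:
            raise DataError(
                f"response {self.response_id!r}: fraud label requires >=1 flag"
            )


@dataclass
class Config:
    """All pipeline thresholds, with the study's operating values as defaults.

    ``column_map`` remaps canonical field names to arbitrary source-file
    headers; ``text_tiers`` are (min_words, min_repeats) pairs for the
    duplicate free-text criterion; ``k_strike`` is the number of post hoc
    criteria required to label a stage-1 survivor as fraud.
    """

    column_map: dict = field(default_factory=dict)
    k_strike: int = 2
    rapid_window_minutes: float = 1.0
    rapid_min_others: int = 2
    address_overuse_prior_count: int = 2
    text_tiers: list = field(default_factory=lambda: [(1, 100), (2, 10), (3, 3)])
    recaptcha_cutoff: float = 0.5
    fraud_score_cutoff: float = 30.0
    dup_score_cutoff: float = 75.0
    key_items: list = field(
        default_factory=lambda: [
            "age",
            "zip",
            "adults_home",
            "minors_home",
            "hispanic",
            "ever_tested",
            "vaccinated",
        ]
    )
    allowed_country: str = "US"
    chi_square_yates: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_strike < 1:
            raise ConfigurationError("k_strike must be >= 1")
        if not 0.0 <= self.recaptcha_cutoff <= 1.0:
            raise ConfigurationError("recaptcha_cutoff must lie in [0, 1]")
        if not 0.0 <= self.fraud_score_cutoff <= 130.0:
            raise ConfigurationError("fraud_score_cutoff must lie in [0, 130]")
        if not 0.0 <= self.dup_score_cutoff <= 100.0:
            raise ConfigurationError("dup_score_cutoff must lie in [0, 100]")
        self.text_tiers = [tuple(t) for t in self.text_tiers]
        if self.text_tiers != sorted(self.text_tiers, key=lambda t: t[0]):
            raise ConfigurationError("text_tiers must be sorted by min_words ascending")
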