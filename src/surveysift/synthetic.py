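"""Seeded synthetic respondent cohorts with ground-truth fraud labels.

The generator emulates the response stream of a compensated, open
web-based survey: genuine residents submitting during advertised
campaign windows, mixed with the fraud archetypes such surveys attract —

* ``bot_burst``      — scripted submissions in clusters sharing start and
                       stop times within +/- 1 minute (plus bot-like
                       reCAPTCHA scores);
* ``duplicate_farm`` — repeat submitters reusing an email address across
                       several entries;
* ``vpn_actor``      — off-shore/data-center actors behind flagged IP
                       prefixes;
* ``inconsistent_screener`` — respondents whose main-survey answers
                       contradict their eligibility screener;
* ``address_reuser`` — three or more submissions sharing one residential
                       address;
* ``url_spoofer``    — entries arriving from links never distributed by
                       the study.

Fraud operations rarely trip exactly one wire: actors who evade the
real-time rules (the first submission of a farm, the first two users of
a shared address, VPN actors, inconsistent screeners) also paste canned
thank-you comments, so by default they carry the paired duplicate-text
strike that makes them detectable under the 2-strike post hoc rule.
Every archetype therefore violates its targeted rule deterministically,
and residual classification error comes only from coincidental
collisions among genuine respondents.

``build_planted_cohort`` is the deterministic variant used for pipeline
arithmetic: it plants exact stage-1 and stage-2 fraud counts and places
genuine arrivals on a staggered start/duration grid on which no
accidental rapid-submission triple can occur.
"""

from __future__ import annotations

import ipaddress
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

from .types import Gazetteer, Label, SurveyType, SurveyResponse

ARCHETYPES = (
    "bot_burst",
    "duplicate_farm",
    "vpn_actor",
    "inconsistent_screener",
    "address_reuser",
    "url_spoofer",
)

_NEIGHBORHOODS = [
    "riverside", "old mill", "cedar park", "brickyard", "lakeview",
    "northgate", "southwark", "elm hollow", "foundry", "garden court",
    "highland", "ironworks",
]
_STREETS = [
    "Maple", "Oak", "Cedar", "Pine", "Walnut", "Chestnut", "Spruce",
    "Juniper", "Poplar", "Willow", "Sycamore", "Locust", "Magnolia",
    "Hawthorn", "Linden", "Mulberry", "Dogwood", "Hickory", "Alder",
    "Birch",
]
_STANDARD_ZIPS = [f"191{i:02d}" for i in range(3, 55, 3)]
_NONSTANDARD_ZIPS = {"19092", "19093", "19099"}
_VALID_URLS = [
    "https://study.example.org/fb1",
    "https://study.example.org/ig2",
    "https://study.example.org/tw3",
    "https://study.example.org/partner4",
]
_SPOOF_URL = "http://win-gift-cards.example.net/survey"
_CANNED_TEXTS = [
    "very helpful survey thanks",
    "great survey thank you",
    "good survey i liked it",
    "nice study thank you team",
    "thanks for the gift card",
]
#: short genuine comments; one-word phrases sit far below the (1, 100) tier
_GENUINE_SHORT_COMMENTS = [
    "thanks", "none", "no", "nothing", "n/a", "nope", "good", "ok",
    "fine", "interesting",
]
_RACE_CATEGORIES = [
    ("white", 0.54), ("black", 0.23), ("hispanic", 0.15), ("asian", 0.04),
    ("multiracial", 0.02), ("other", 0.02),
]


@dataclass(frozen=True)
class TruthLabel:
    """Ground-truth fraud status of one generated response."""

    response_id: str
    is_fraud: bool
    archetype: Optional[str] = None


@dataclass(frozen=True)
class DetectionMetrics:
    """Classifier performance against ground truth; None when undefined."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]


@dataclass
class CohortSpec:
    """Parameters of a synthetic respondent stream.

    Defaults emulate the source study scaled to roughly a tenth of its
    volume: ~320 genuine respondents and ~295 fraudulent ones whose
    archetype mixture follows the study's per-rule attribution (rapid
    bots dominating, then spoofed URLs, reused addresses, two-strike
    post hoc actors, and a small email-duplication farm).  Survey
    durations are drawn log-normally around the study's median of about
    23.5 minutes (IQR roughly 18-38); arrivals concentrate inside the
    advertised campaign windows, while bot bursts arrive uniformly and
    so also flood the quiet periods.
    """

    n_genuine: int = 320
    archetype_counts: Dict[str, int] = field(default_factory=lambda: {
        "bot_burst": 141,
        "duplicate_farm": 20,
        "vpn_actor": 35,
        "inconsistent_screener": 20,
        "address_reuser": 39,
        "url_spoofer": 40,
    })
    study_start: datetime = datetime(2021, 11, 1)
    study_days: int = 105
    campaign_windows: List[Tuple[int, int]] = field(
        default_factory=lambda: [(2, 17), (28, 51), (98, 101)]
    )
    bot_cluster_size: int = 3
    farm_size: int = 4
    reuse_group_size: int = 3
    #: probability a fraudulent response also breaches a platform threshold
    p_bot_low_recaptcha: float = 0.9
    p_farm_high_dup: float = 0.8
    p_fraud_high_score: float = 0.6
    #: probability a genuine response draws a platform-breaching score anyway
    genuine_contamination: float = 0.05
    genuine_empty_text_p: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.archetype_counts) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")
        if self.n_genuine < 0 or any(v < 0 for v in self.archetype_counts.values()):
            raise ValueError("counts must be nonnegative")
        for lo, hi in self.campaign_windows:
            if not 0 <= lo <= hi <= self.study_days:
                raise ValueError("campaign windows must lie within the study period")


class _CohortBuilder:
    """Accumulates responses, truth labels and a consistent gazetteer."""

    def __init__(self, seed: int, study_start: datetime):
        self.rng = np.random.default_rng(seed)
        self.seed = seed
        self.study_start = study_start
        self.responses: List[SurveyResponse] = []
        self.truths: List[TruthLabel] = []
        self.address_index: Dict[str, str] = {}
        self._counter = 0
        self._addr_counter = 0
        self._canned_cursor = 0

    def next_id(self) -> str:
        self._counter += 1
        return f"S{self.seed}-{self._counter:05d}"

    def new_address(self) -> Tuple[str, str]:
        """Fresh unique address registered to a (cyclic) neighborhood."""
        self._addr_counter += 1
        street = _STREETS[self._addr_counter % len(_STREETS)]
        num = 100 + self._addr_counter
        address = f"{num} {street} St"
        hood = _NEIGHBORHOODS[self._addr_counter % len(_NEIGHBORHOODS)]
        self.address_index[address.lower()] = hood
        return address, hood

    def canned_text(self, pool_size: int) -> str:
        text = _CANNED_TEXTS[self._canned_cursor % max(pool_size, 1)]
        self._canned_cursor += 1
        return text

    def genuine_ip(self) -> str:
        return f"198.51.{self.rng.integers(0, 256)}.{self.rng.integers(1, 255)}"

    def vpn_ip(self) -> str:
        # half data-center/VPN prefix, half foreign origin
        if self.rng.random() < 0.5:
            return f"203.0.113.{self.rng.integers(1, 255)}"
        return f"192.0.2.{self.rng.integers(1, 255)}"

    def duration_minutes(self) -> float:
        # log-normal around the study's median completion time (~23.5 min)
        return max(5.0, float(self.rng.lognormal(mean=np.log(23.46), sigma=0.55)))

    def screener(self) -> Dict[str, str]:
        return {
            "age": str(int(self.rng.integers(18, 80))),
            "zip": str(self.rng.choice(_STANDARD_ZIPS)),
            "adults_home": str(int(self.rng.integers(1, 5))),
            "minors_home": str(int(self.rng.integers(0, 4))),
            "hispanic": str(self.rng.choice(["yes", "no"], p=[0.15, 0.85])),
            "ever_tested": str(self.rng.choice(["yes", "no"], p=[0.88, 0.12])),
            "vaccinated": str(self.rng.choice(["yes", "no"], p=[0.9, 0.1])),
        }

    def demographics(self, screener: Mapping[str, str]) -> Dict[str, str]:
        cats, probs = zip(*_RACE_CATEGORIES)
        race = "hispanic" if screener["hispanic"] == "yes" else str(self.rng.choice(cats, p=np.array(probs) / sum(probs)))
        return {
            "age": screener["age"],
            "race_ethnicity": race,
            "gender": str(self.rng.choice(["woman", "man", "other"], p=[0.55, 0.43, 0.02])),
            "education": str(self.rng.choice(
                ["high_school", "some_college", "college", "graduate"],
                p=[0.15, 0.25, 0.45, 0.15],
            )),
        }

    def genuine_scores(self, contamination: float = 0.0):
        if self.rng.random() < contamination:
            # occasional false platform flag: shared devices, privacy browsers
            kind = self.rng.integers(0, 3)
            if kind == 0:
                return (round(float(self.rng.uniform(0.0, 0.5)), 2),
                        round(float(self.rng.uniform(0, 25)), 1),
                        round(float(self.rng.uniform(0, 60)), 1))
            if kind == 1:
                return (round(float(np.clip(self.rng.normal(0.85, 0.12), 0, 1)), 2),
                        round(float(self.rng.uniform(30, 100)), 1),
                        round(float(self.rng.uniform(0, 60)), 1))
            return (round(float(np.clip(self.rng.normal(0.85, 0.12), 0, 1)), 2),
                    round(float(self.rng.uniform(0, 25)), 1),
                    round(float(self.rng.uniform(75, 100)), 1))
        return (round(float(np.clip(self.rng.normal(0.85, 0.12), 0, 1)), 2),
                round(float(self.rng.uniform(0, 25)), 1),
                round(float(self.rng.uniform(0, 60)), 1))

    def add(self, *, archetype: Optional[str], start: datetime, duration: float,
            address: str, hood: str, email: str, ip: str, url: str,
            free_text: str, scores, screener: Dict[str, str],
            main_override: Optional[Dict[str, str]] = None,
            zip_code: Optional[str] = None,
            survey_type: Optional[SurveyType] = None) -> SurveyResponse:
        rid = self.next_id()
        start = start.replace(second=0, microsecond=0)
        main = dict(screener)
        if main_override:
            main.update(main_override)
        r = SurveyResponse(
            response_id=rid,
            start_time=start,
            end_time=start + timedelta(minutes=float(duration)),
            survey_type=survey_type or SurveyType(
                self.rng.choice(["adult", "parent", "youth"], p=[0.2, 0.73, 0.07])
            ),
            email=email,
            street_address=address,
            zip_code=zip_code or screener["zip"],
            neighborhood_name=hood,
            ip_address=ip,
            referral_url=url,
            free_text_comment=free_text,
            screener_answers=screener,
            main_answers=main,
            demographics=self.demographics(screener),
            outcome_answers={"vaccine_confidence": str(int(self.rng.random() < 0.8))},
            recaptcha_v3=scores[0],
            relevantid_fraud=scores[1],
            relevantid_dup=scores[2],
        )
        self.responses.append(r)
        self.truths.append(TruthLabel(rid, archetype is not None, archetype))
        return r

    def gazetteer(self) -> Gazetteer:
        # ring adjacency over the invented neighborhoods
        k = len(_NEIGHBORHOODS)
        adjacency = {
            _NEIGHBORHOODS[i]: {_NEIGHBORHOODS[(i - 1) % k], _NEIGHBORHOODS[(i + 1) % k]}
            for i in range(k)
        }
        return Gazetteer(
            address_index=dict(self.address_index),
            adjacency=adjacency,
            nonstandard_zips=set(_NONSTANDARD_ZIPS),
            valid_urls=set(_VALID_URLS),
            ip_intel=[
                (ipaddress.ip_network("198.51.0.0/16"), False, "US"),
                (ipaddress.ip_network("203.0.113.0/24"), True, "US"),
                (ipaddress.ip_network("192.0.2.0/24"), False, "GB"),
            ],
        )


def _campaign_day(rng, study_days: int, windows) -> int:
    weights = np.ones(study_days)
    for lo, hi in windows:
        weights[lo:hi + 1] += 5.0
    weights /= weights.sum()
    return int(rng.choice(study_days, p=weights))


def _random_start(b: _CohortBuilder, study_days: int, windows) -> datetime:
    day = _campaign_day(b.rng, study_days, windows)
    minute = int(b.rng.integers(8 * 60, 23 * 60))
    return b.study_start + timedelta(days=day, minutes=minute)


def generate_cohort(
    spec: CohortSpec,
) -> Tuple[List[SurveyResponse], List[TruthLabel], Gazetteer]:
    """Generate a seeded response stream, its truth labels and a gazetteer.

    Deterministic for a fixed spec (including seed); distinct seeds give
    distinct response-id streams.  Responses are returned sorted by start
    time with response-id tiebreak.
    """
    b = _CohortBuilder(spec.seed, spec.study_start)
    counts = {a: spec.archetype_counts.get(a, 0) for a in ARCHETYPES}
    n_posthoc_text = (
        counts["vpn_actor"] + counts["inconsistent_screener"]
        + -(-counts["duplicate_farm"] // spec.farm_size)
        + 2 * -(-counts["address_reuser"] // spec.reuse_group_size)
    )
    pool = max(1, min(len(_CANNED_TEXTS), n_posthoc_text // 3)) if n_posthoc_text else 1

    # --- genuine respondents -------------------------------------------------
    for i in range(spec.n_genuine):
        address, hood = b.new_address()
        scr = b.screener()
        if b.rng.random() < spec.genuine_empty_text_p:
            text = ""
        elif b.rng.random() < 0.3:
            # Zipf-like short comments, kept far below every duplicate tier
            ranks = np.arange(1, len(_GENUINE_SHORT_COMMENTS) + 1, dtype=float)
            text = str(b.rng.choice(_GENUINE_SHORT_COMMENTS, p=(1 / ranks) / (1 / ranks).sum()))
        else:
            text = f"overall a clear survey respondent {b.rng.integers(1, 10**9)}"
        b.add(
            archetype=None,
            start=_random_start(b, spec.study_days, spec.campaign_windows),
            duration=b.duration_minutes(),
            address=address, hood=hood,
            email=f"user{b.seed}.{i}@example.com",
            ip=b.genuine_ip(),
            url=str(b.rng.choice(_VALID_URLS)),
            free_text=text,
            scores=b.genuine_scores(spec.genuine_contamination),
            screener=scr,
        )

    # --- bot bursts: clusters sharing start and stop times -------------------
    remaining = counts["bot_burst"]
    while remaining > 0:
        size = min(max(spec.bot_cluster_size, 3), remaining) if remaining >= 3 else remaining
        if remaining - size in (1, 2):  # avoid a trailing under-sized cluster
            size = remaining
        anchor = b.study_start + timedelta(
            days=int(b.rng.integers(0, spec.study_days)),
            minutes=int(b.rng.integers(0, 24 * 60)),
        )
        duration = float(b.rng.integers(8, 15))
        for _ in range(size):
            address, hood = b.new_address()
            low = b.rng.random() < spec.p_bot_low_recaptcha
            scores = (
                round(float(b.rng.uniform(0.0, 0.49)), 2) if low
                else round(float(np.clip(b.rng.normal(0.85, 0.12), 0, 1)), 2),
                round(float(b.rng.uniform(0, 25)), 1),
                round(float(b.rng.uniform(0, 60)), 1),
            )
            b.add(
                archetype="bot_burst", start=anchor, duration=duration,
                address=address, hood=hood,
                email=f"bot{b.seed}.{b._counter}@mailbox.example",
                ip=b.genuine_ip(), url=str(b.rng.choice(_VALID_URLS)),
                free_text="", scores=scores, screener=b.screener(),
            )
        remaining -= size

    # --- duplicate farms: one email reused across a farm ---------------------
    remaining = counts["duplicate_farm"]
    farm = 0
    while remaining > 0:
        size = min(spec.farm_size, remaining)
        farm += 1
        email = f"farm{b.seed}.{farm}@freebie.example"
        base = _random_start(b, spec.study_days, spec.campaign_windows)
        for j in range(size):
            address, hood = b.new_address()
            high_dup = b.rng.random() < spec.p_farm_high_dup
            scores = (
                round(float(np.clip(b.rng.normal(0.7, 0.2), 0, 1)), 2),
                round(float(b.rng.uniform(0, 25)), 1),
                round(float(b.rng.uniform(75, 100)), 1) if high_dup
                else round(float(b.rng.uniform(0, 60)), 1),
            )
            b.add(
                archetype="duplicate_farm",
                start=base + timedelta(minutes=float(30 + 17 * j)),
                duration=b.duration_minutes(),
                address=address, hood=hood, email=email,
                ip=b.vpn_ip(), url=str(b.rng.choice(_VALID_URLS)),
                # only the farm's first entry survives stage 1, so only it
                # draws from the rotating pool that must stay over-threshold
                free_text=b.canned_text(pool) if j == 0 else _CANNED_TEXTS[0],
                scores=scores, screener=b.screener(),
            )
        remaining -= size

    # --- VPN / offshore actors ----------------------------------------------
    for _ in range(counts["vpn_actor"]):
        address, hood = b.new_address()
        high = b.rng.random() < spec.p_fraud_high_score
        scores = (
            round(float(np.clip(b.rng.normal(0.7, 0.2), 0, 1)), 2),
            round(float(b.rng.uniform(30, 110)), 1) if high
            else round(float(b.rng.uniform(0, 25)), 1),
            round(float(b.rng.uniform(0, 60)), 1),
        )
        b.add(
            archetype="vpn_actor",
            start=_random_start(b, spec.study_days, spec.campaign_windows),
            duration=b.duration_minutes(),
            address=address, hood=hood,
            email=f"vpn{b.seed}.{b._counter}@mailbox.example",
            ip=b.vpn_ip(), url=str(b.rng.choice(_VALID_URLS)),
            free_text=b.canned_text(pool),
            scores=scores, screener=b.screener(),
        )

    # --- screener-inconsistent respondents -----------------------------------
    for _ in range(counts["inconsistent_screener"]):
        address, hood = b.new_address()
        scr = b.screener()
        override = {"age": str(int(scr["age"]) + int(b.rng.integers(3, 15)))}
        b.add(
            archetype="inconsistent_screener",
            start=_random_start(b, spec.study_days, spec.campaign_windows),
            duration=b.duration_minutes(),
            address=address, hood=hood,
            email=f"inc{b.seed}.{b._counter}@mailbox.example",
            ip=b.genuine_ip(), url=str(b.rng.choice(_VALID_URLS)),
            free_text=b.canned_text(pool),
            scores=b.genuine_scores(0.3), screener=scr, main_override=override,
        )

    # --- address re-users: >= 3 submissions per address ----------------------
    remaining = counts["address_reuser"]
    while remaining > 0:
        size = min(max(spec.reuse_group_size, 3), remaining) if remaining >= 3 else remaining
        if remaining - size in (1, 2):
            size = remaining
        address, hood = b.new_address()
        base = _random_start(b, spec.study_days, spec.campaign_windows)
        for j in range(size):
            b.add(
                archetype="address_reuser",
                start=base + timedelta(minutes=float(45 + 23 * j)),
                duration=b.duration_minutes(),
                address=address, hood=hood,
                email=f"reuse{b.seed}.{b._counter}@mailbox.example",
                ip=b.vpn_ip(), url=str(b.rng.choice(_VALID_URLS)),
                # members 3+ are caught in real time; keep the rotating pool
                # for the two survivors
                free_text=b.canned_text(pool) if j < 2 else _CANNED_TEXTS[0],
                scores=b.genuine_scores(0.4), screener=b.screener(),
            )
        remaining -= size

    # --- URL spoofers ---------------------------------------------------------
    for _ in range(counts["url_spoofer"]):
        address, hood = b.new_address()
        b.add(
            archetype="url_spoofer",
            start=_random_start(b, spec.study_days, spec.campaign_windows),
            duration=b.duration_minutes(),
            address=address, hood=hood,
            email=f"spoof{b.seed}.{b._counter}@mailbox.example",
            ip=b.genuine_ip(), url=_SPOOF_URL,
            free_text="", scores=b.genuine_scores(0.4), screener=b.screener(),
        )

    order = sorted(range(len(b.responses)),
                   key=lambda i: (b.responses[i].start_time, b.responses[i].response_id))
    responses = [b.responses[i] for i in order]
    truths = [b.truths[i] for i in order]
    return responses, truths, b.gazetteer()


def build_planted_cohort(
    n_total: int = 7950,
    n_realtime: int = 4207,
    n_posthoc: int = 515,
    seed: int = 0,
) -> Tuple[List[SurveyResponse], List[TruthLabel], Gazetteer]:
    """Deterministic cohort with exact planted stage-1 and stage-2 fraud counts.

    Stage-1 violations are split between rapid-submission bot clusters
    and URL spoofers; stage-2 violations are VPN actors pasting canned
    comments (two strikes each).  All other responses are clean: genuine
    arrivals sit on a 1-minute start grid with durations cycling
    20/23/26/29/32 minutes, so no two near-simultaneous starts can share
    an end time within +/- 1 minute and the rapid-submission rule cannot
    fire on them coincidentally.
    """
    if n_realtime + n_posthoc > n_total:
        raise ValueError("planted fraud counts exceed the total")
    n_valid = n_total - n_realtime - n_posthoc
    n_bot = 3 * (n_realtime // 5)
    n_spoof = n_realtime - n_bot
    pool = max(1, min(len(_CANNED_TEXTS), n_posthoc // 3)) if n_posthoc else 1

    b = _CohortBuilder(seed, datetime(2021, 11, 1))
    grid = 0

    def grid_start_duration() -> Tuple[datetime, float]:
        nonlocal grid
        start = b.study_start + timedelta(minutes=grid)
        duration = 20.0 + 3.0 * (grid % 5)
        grid += 1
        return start, duration

    for i in range(n_valid):
        address, hood = b.new_address()
        start, duration = grid_start_duration()
        text = "" if i % 2 else f"overall a clear survey respondent {i}"
        b.add(
            archetype=None, start=start, duration=duration,
            address=address, hood=hood,
            email=f"user{b.seed}.{i}@example.com", ip=b.genuine_ip(),
            url=_VALID_URLS[i % len(_VALID_URLS)], free_text=text,
            scores=b.genuine_scores(0.05), screener=b.screener(),
        )

    for i in range(n_spoof):
        address, hood = b.new_address()
        start, duration = grid_start_duration()
        b.add(
            archetype="url_spoofer", start=start, duration=duration,
            address=address, hood=hood,
            email=f"spoof{b.seed}.{i}@mailbox.example", ip=b.genuine_ip(),
            url=_SPOOF_URL, free_text="",
            scores=b.genuine_scores(0.4), screener=b.screener(),
        )

    for i in range(n_posthoc):
        address, hood = b.new_address()
        start, duration = grid_start_duration()
        b.add(
            archetype="vpn_actor", start=start, duration=duration,
            address=address, hood=hood,
            email=f"vpn{b.seed}.{i}@mailbox.example", ip=b.vpn_ip(),
            url=_VALID_URLS[i % len(_VALID_URLS)],
            free_text=b.canned_text(pool),
            scores=b.genuine_scores(0.4), screener=b.screener(),
        )

    # bot clusters occupy a separate time region beyond the grid
    bot_base = b.study_start + timedelta(minutes=grid + 60)
    for c in range(n_bot // 3):
        anchor = bot_base + timedelta(minutes=3 * c)
        for _ in range(3):
            address, hood = b.new_address()
            b.add(
                archetype="bot_burst", start=anchor, duration=12.0,
                address=address, hood=hood,
                email=f"bot{b.seed}.{b._counter}@mailbox.example",
                ip=b.genuine_ip(), url=_VALID_URLS[c % len(_VALID_URLS)],
                free_text="",
                scores=(round(float(b.rng.uniform(0.0, 0.49)), 2),
                        round(float(b.rng.uniform(0, 25)), 1),
                        round(float(b.rng.uniform(0, 60)), 1)),
                screener=b.screener(),
            )

    return b.responses, b.truths, b.gazetteer()


def evaluate_classifier(
    predictions: Mapping[str, Label], truth: List[TruthLabel]
) -> DetectionMetrics:
    """Sensitivity/specificity/PPV/NPV of fraud predictions vs ground truth."""
    truth_ids = {t.response_id for t in truth}
    if truth_ids != set(predictions):
        diff = sorted(truth_ids ^ set(predictions))
        raise ValueError(f"prediction and truth ids differ: {diff[:10]}")
    tp = fn = tn = fp = 0
    for t in truth:
        predicted_fraud = predictions[t.response_id] is Label.FRAUD
        if t.is_fraud:
            tp, fn = tp + predicted_fraud, fn + (not predicted_fraud)
        else:
            fp, tn = fp + predicted_fraud, tn + (not predicted_fraud)

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den else None

    return DetectionMetrics(
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
    )
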