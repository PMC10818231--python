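import ipaddress
from datetime import datetime, timedelta

import pytest

from surveysift.types import Gazetteer, SurveyResponse, SurveyType


@pytest.fixture
def gazetteer():
    """Tiny neighborhood gazetteer with one VPN and one foreign IP prefix."""
    return Gazetteer(
        address_index={
            "1 main st": "fishtown",
            "2 main st": "fishtown",
            "9 oak ave": "kensington",
            "5 hill rd": "chestnut hill",
        },
        adjacency={"fishtown": {"kensington"}},
        nonstandard_zips={"19092", "19099"},
        valid_urls={"https://study.example.org/fb1", "https://study.example.org/ig2"},
        ip_intel=[
            (ipaddress.ip_network("198.51.0.0/16"), False, "US"),
            (ipaddress.ip_network("203.0.113.0/24"), True, "US"),
            (ipaddress.ip_network("192.0.2.0/24"), False, "CA"),
        ],
    )


@pytest.fixture
def make_response():
    """Factory for responses that pass every rule unless overridden."""
    counter = iter(range(10_000))

    def _make(**kwargs):
        i = next(counter)
        defaults = dict(
            response_id=f"r{i:04d}",
            start_time=datetime(2021, 11, 5, 10, 0) + timedelta(minutes=7 * i),
            end_time=datetime(2021, 11, 5, 10, 0) + timedelta(minutes=7 * i + 20 + (i % 5)),
            survey_type=SurveyType.ADULT,
            email=f"person{i}@example.com",
            street_address="1 Main St",
            zip_code="19103",
            neighborhood_name="Fishtown",
            ip_address=f"198.51.4.{(i % 250) + 1}",
            referral_url="https://study.example.org/fb1",
            free_text_comment="",
            screener_answers={"age": "34", "zip": "19103"},
            main_answers={"age": "34", "zip": "19103"},
            recaptcha_v3=0.9,
            relevantid_fraud=5.0,
            relevantid_dup=10.0,
        )
        start = kwargs.pop("start_time", None)
        if start is not None:
            defaults["start_time"] = start
            defaults["end_time"] = start + timedelta(minutes=20)
        defaults.update(kwargs)
        return SurveyResponse(**defaults)

    return _make
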