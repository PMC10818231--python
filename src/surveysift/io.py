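"""Delimited-file readers and writers for responses, gazetteers and configs.

The response table is a plain CSV with one header row (UTF-8).  Canonical
column names are listed in :data:`SCALAR_FIELDS`; a ``column_map`` in
:class:`~surveysift.types.Config` remaps arbitrary source headers (for
example a survey platform's export dialect) onto the canonical names.
Screener/main/demographic/outcome answer maps are flattened into prefixed
columns (``screener_age``, ``main_zip``, ``demo_race_ethnicity`` ...).
"""

from __future__ import annotations

import csv
import ipaddress
import logging
from datetime import datetime
from pathlib import Path
from typing import Iterable, List, Optional

import yaml

from .types import (
    Config,
    ConfigurationError,
    DataError,
    Gazetteer,
    SurveyResponse,
    SurveyType,
)
from ._text import normalize_address

logger = logging.getLogger(__name__)

#: canonical scalar columns; mandatory ones must resolve via column_map
MANDATORY_FIELDS = ("response_id", "start_time", "end_time", "survey_type")
OPTIONAL_FIELDS = (
    "email",
    "street_address",
    "zip_code",
    "neighborhood_name",
    "ip_address",
    "referral_url",
    "free_text_comment",
    "honeypot_answer",
    "completed",
    "recaptcha_v3",
    "relevantid_fraud",
    "relevantid_dup",
)
SCALAR_FIELDS = MANDATORY_FIELDS + OPTIONAL_FIELDS

_MAP_PREFIXES = {
    "screener_": "screener_answers",
    "main_": "main_answers",
    "demo_": "demographics",
    "outcome_": "outcome_answers",
}

_SCORE_FIELDS = ("recaptcha_v3", "relevantid_fraud", "relevantid_dup")

_TS_FORMATS = ("%Y-%m-%d %H:%M:%S", "%Y-%m-%d %H:%M", "%Y-%m-%dT%H:%M:%S", "%Y-%m-%dT%H:%M")


def _parse_timestamp(value: str, row: int, column: str) -> datetime:
    v = value.strip()
    for fmt in _TS_FORMATS:
        try:
            return datetime.strptime(v, fmt)
        except ValueError:
            continue
    raise DataError(f"row {row}: unparseable timestamp {value!r} in column {column!r}")


def _parse_score(value: str) -> Optional[float]:
    v = value.strip()
    return float(v) if v else None


def read_responses(path, config: Optional[Config] = None) -> List[SurveyResponse]:
    """Read a response CSV into :class:`SurveyResponse` records, in file order.

    Raises :class:`ConfigurationError` when a mandatory canonical field has
    no resolvable source column, and :class:`DataError` (with the row
    number) on unparseable timestamps.
    """
    config = config or Config()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        source_for = {f: config.column_map.get(f, f) for f in SCALAR_FIELDS}
        for f in MANDATORY_FIELDS:
            if source_for[f] not in header:
                raise ConfigurationError(
                    f"mandatory field {f!r} not found: no column {source_for[f]!r} in {path}"
                )
        responses = []
        for i, row in enumerate(reader, start=2):  # header is line 1
            kwargs = {}
            for f in SCALAR_FIELDS:
                raw = row.get(source_for[f])
                if raw is None:
                    continue
                if f in ("start_time", "end_time"):
                    kwargs[f] = _parse_timestamp(raw, i, source_for[f])
                elif f in _SCORE_FIELDS:
                    kwargs[f] = _parse_score(raw)
                elif f == "survey_type":
                    try:
                        kwargs[f] = SurveyType(raw.strip().lower())
                    except ValueError:
                        raise DataError(f"row {i}: unknown survey_type {raw!r}") from None
                elif f == "completed":
                    kwargs[f] = raw.strip().lower() not in ("false", "0", "no", "")
                else:
                    kwargs[f] = raw
            maps = {attr: {} for attr in _MAP_PREFIXES.values()}
            for col, val in row.items():
                if col is None or val is None:
                    continue
                for prefix, attr in _MAP_PREFIXES.items():
                    if col.startswith(prefix) and val != "":
                        maps[attr][col[len(prefix):]] = val
                        break
            responses.append(SurveyResponse(**kwargs, **maps))
    return responses


def write_responses(path, responses: Iterable[SurveyResponse]) -> None:
    """Write responses to CSV in the canonical dialect (round-trip safe)."""
    responses = list(responses)
    map_columns: list = []
    for prefix, attr in _MAP_PREFIXES.items():
        keys = sorted({k for r in responses for k in getattr(r, attr)})
        map_columns.extend((prefix + k, attr, k) for k in keys)
    header = list(SCALAR_FIELDS) + [c for c, _, _ in map_columns]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for r in responses:
            row = []
            for f in SCALAR_FIELDS:
                v = getattr(r, f)
                if f in ("start_time", "end_time"):
                    row.append(v.strftime("%Y-%m-%d %H:%M:%S"))
                elif f == "survey_type":
                    row.append(v.value)
                elif f == "completed":
                    row.append("true" if v else "false")
                elif v is None:
                    row.append("")
                else:
                    row.append(v)
            for _, attr, key in map_columns:
                row.append(getattr(r, attr).get(key, ""))
            writer.writerow(row)


def read_gazetteer(directory) -> Gazetteer:
    """Assemble a :class:`Gazetteer` from its directory of CSV lookups.

    Files: ``addresses.csv`` (address,neighborhood), ``adjacency.csv``
    (neighborhood_a,neighborhood_b), ``zips.csv`` (zip,status),
    ``urls.csv`` (url), ``ip_intel.csv`` (prefix,is_vpn,country).
    Asymmetric adjacency rows are repaired with a logged warning;
    conflicting duplicate addresses raise :class:`DataError`.
    """
    d = Path(directory)
    address_index: dict = {}
    for row in _read_csv(d / "addresses.csv"):
        key = normalize_address(row["address"])
        hood = row["neighborhood"].strip()
        if key in address_index and address_index[key] != hood:
            raise DataError(
                f"conflicting neighborhoods for address {row['address']!r}: "
                f"{address_index[key]!r} vs {hood!r}"
            )
        address_index[key] = hood

    directed = {
        (row["neighborhood_a"].strip(), row["neighborhood_b"].strip())
        for row in _read_csv(d / "adjacency.csv")
    }
    for a, b in sorted(directed):
        if (b, a) not in directed:
            logger.warning("adjacency %r -> %r missing reverse edge; repaired", a, b)
    adjacency: dict = {}
    for a, b in directed:
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)

    nonstandard = set()
    for row in _read_csv(d / "zips.csv"):
        if row.get("status", "nonstandard").strip().lower() != "standard":
            nonstandard.add(row["zip"].strip())

    urls = {row["url"].strip() for row in _read_csv(d / "urls.csv")}

    ip_intel = []
    for row in _read_csv(d / "ip_intel.csv"):
        net = ipaddress.ip_network(row["prefix"].strip(), strict=False)
        is_vpn = row["is_vpn"].strip().lower() in ("true", "1", "yes")
        ip_intel.append((net, is_vpn, row["country"].strip().upper()))

    return Gazetteer(
        address_index=address_index,
        adjacency=adjacency,
        nonstandard_zips=nonstandard,
        valid_urls=urls,
        ip_intel=ip_intel,
    )


def write_gazetteer(directory, g: Gazetteer) -> None:
    """Write a gazetteer to its directory-of-CSVs representation."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    _write_csv(d / "addresses.csv", ("address", "neighborhood"),
               sorted(g.address_index.items()))
    # both directions are written so a round-trip is warning-free
    edges = sorted((a, b) for a, bs in g.adjacency.items() for b in bs)
    _write_csv(d / "adjacency.csv", ("neighborhood_a", "neighborhood_b"), edges)
    _write_csv(d / "zips.csv", ("zip", "status"),
               [(z, "nonstandard") for z in sorted(g.nonstandard_zips)])
    _write_csv(d / "urls.csv", ("url",), [(u,) for u in sorted(g.valid_urls)])
    _write_csv(d / "ip_intel.csv", ("prefix", "is_vpn", "country"),
               [(str(net), str(v).lower(), c) for net, v, c in g.ip_intel])


def load_config(path) -> Config:
    """Load a YAML/JSON config file; unknown keys raise ConfigurationError."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    valid = set(Config.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return Config(**data)


def _read_csv(path: Path):
    if not path.exists():
        return []
    with open(path, newline="", encoding="utf-8") as fh:
        yield from csv.DictReader(fh)


def _write_csv(path: Path, header, rows) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(rows)
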