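"""Text normalization helpers shared by the rule stages.

All rule comparisons (emails, addresses, free-text duplicates, referral
URLs, categorical screener answers) run on normalized strings so that
trivially re-encoded submissions ("123 Main St." vs "123 main st") are
treated as identical.
"""

from __future__ import annotations

import re
import string

_WS = re.compile(r"\s+")
_PUNCT_TABLE = str.maketrans("", "", string.punctuation)


def normalize_text(s: str) -> str:
    """Lowercase, strip, and collapse internal whitespace to single spaces.

    Idempotent: ``normalize_text(normalize_text(s)) == normalize_text(s)``.
    """
    return _WS.sub(" ", s.strip().lower())


def normalize_address(s: str) -> str:
    """Address-comparison variant of :func:`normalize_text`.

    Additionally punctuation-insensitive, so "123 Main St." and
    "123 main st" compare equal.
    """
    return normalize_text(s.translate(_PUNCT_TABLE))


def normalize_email(s: str) -> str:
    """Lowercase and strip; no plus-addressing collapse."""
    return s.strip().lower()


def normalize_url(s: str) -> str:
    """Scheme- and trailing-slash-insensitive URL form."""
    u = s.strip().lower()
    for scheme in ("https://", "http://"):
        if u.startswith(scheme):
            u = u[len(scheme):]
            break
    return u.rstrip("/")


def word_count(s: str) -> int:
    """Number of whitespace-delimited words after normalization."""
    n = normalize_text(s)
    return len(n.split(" ")) if n else 0
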