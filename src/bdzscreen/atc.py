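"""WHO ATC code grammar and prefix matching.

ATC codes are hierarchical 7-character drug classification codes
(letter, two digits, letter, letter, two digits) that may be truncated
at the five level boundaries: 1, 3, 4, 5 or 7 characters.
"""

from __future__ import annotations

import re

# one regex per legal truncation level
_LEVEL_PATTERNS = (
    re.compile(r"^[A-Z]$"),
    re.compile(r"^[A-Z][0-9]{2}$"),
    re.compile(r"^[A-Z][0-9]{2}[A-Z]$"),
    re.compile(r"^[A-Z][0-9]{2}[A-Z]{2}$"),
    re.compile(r"^[A-Z][0-9]{2}[A-Z]{2}[0-9]{2}$"),
)

VALID_LENGTHS = (1, 3, 4, 5, 7)


class AtcError(ValueError):
    """Raised on a string that violates the ATC grammar."""


def is_valid_atc(code: str) -> bool:
    """True iff ``code`` is a well-formed ATC code or legal truncation."""
    if not isinstance(code, str):
        return False
    c = code.strip().upper()
    return any(p.match(c) for p in _LEVEL_PATTERNS)


def normalize_atc(code: str) -> str:
    """Uppercase and strip; raise :class:`AtcError` if malformed."""
    if not isinstance(code, str):
        raise AtcError(f"ATC code must be a string, got {type(code).__name__}")
    c = code.strip().upper()
    if not is_valid_atc(c):
        raise AtcError(f"malformed ATC code: {code!r}")
    return c


def atc_matches(code: str, prefix: str) -> bool:
    """True iff ``code`` begins with ``prefix`` at a legal level boundary.

    Both arguments must pass the ATC grammar; matching is
    case-insensitive and never silently false on malformed input.
    """
    c = normalize_atc(code)
    p = normalize_atc(prefix)
    return c.startswith(p)
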