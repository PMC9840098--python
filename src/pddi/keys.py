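"""Matching-key construction: canonicalize identifier attributes and hash them.

Japanese person records carry a name in two scripts (kanji and kana), a
birth date, sex, and an address.  Where no national identifier exists,
linkage keys are built by concatenating a chosen combination of these
attributes and matching exactly.  Each institution compresses the
concatenation with a cryptographic hash so only unique, irreversible
digests enter the protocol.

Canonicalization is deliberately minimal — Unicode NFKC, whitespace strip,
ISO dates, one-letter sex codes — because the experiment measures how raw
exact matching degrades under realistic entry errors, not how clever the
normalizer is.
"""

from __future__ import annotations

import hashlib
import itertools
import re
import unicodedata
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "KeyAttribute",
    "AttributeCombination",
    "CompressedKey",
    "CanonicalizationError",
    "DEFAULT_ATTRIBUTES",
    "FEMALE_ONLY_ATTRIBUTES",
    "canonicalize",
    "make_key",
    "enumerate_combinations",
]


class KeyAttribute(str, Enum):
    """Identifier attributes usable as matching keys."""

    family_kanji = "family_kanji"
    family_kana = "family_kana"
    first_kanji = "first_kanji"
    first_kana = "first_kana"
    birth_date = "birth_date"
    sex = "sex"
    address = "address"


# The six attributes of the default matching experiment.  Address is a
# legitimate key but is excluded from the default enumeration; sex is
# additionally dropped when every screening subject is female (breast
# screening), because it then carries no information.
DEFAULT_ATTRIBUTES: tuple[KeyAttribute, ...] = (
    KeyAttribute.family_kanji,
    KeyAttribute.family_kana,
    KeyAttribute.first_kanji,
    KeyAttribute.first_kana,
    KeyAttribute.birth_date,
    KeyAttribute.sex,
)

FEMALE_ONLY_ATTRIBUTES: tuple[KeyAttribute, ...] = tuple(
    a for a in DEFAULT_ATTRIBUTES if a is not KeyAttribute.sex
)

# Column names in the CSV schema, by attribute.
ATTRIBUTE_COLUMNS: dict[KeyAttribute, str] = {
    KeyAttribute.family_kanji: "family_name_kanji",
    KeyAttribute.family_kana: "family_name_kana",
    KeyAttribute.first_kanji: "first_name_kanji",
    KeyAttribute.first_kana: "first_name_kana",
    KeyAttribute.birth_date: "birth_date",
    KeyAttribute.sex: "sex",
    KeyAttribute.address: "address",
}

AttributeCombination = tuple[KeyAttribute, ...]
CompressedKey = bytes  # 32-byte SHA-256 digest

_SEPARATOR = "\x1f"  # US separator: cannot appear in canonical values

_DATE_PATTERNS = (
    re.compile(r"^(\d{4})-(\d{1,2})-(\d{1,2})$"),
    re.compile(r"^(\d{4})/(\d{1,2})/(\d{1,2})$"),
    re.compile(r"^(\d{4})\.(\d{1,2})\.(\d{1,2})$"),
    re.compile(r"^(\d{4})年(\d{1,2})月(\d{1,2})日$"),
    re.compile(r"^(\d{8})$"),
)

_SEX_CODES = {
    "m": "M", "male": "M", "男": "M", "男性": "M", "1": "M",
    "f": "F", "female": "F", "女": "F", "女性": "F", "2": "F",
    "": "U", "u": "U", "unknown": "U", "不明": "U", "0": "U",
}


class CanonicalizationError(ValueError):
    """A raw attribute value cannot be normalized; carries the raw value."""

    def __init__(self, attribute: "KeyAttribute", raw: str, reason: str):
        self.attribute = attribute
        self.raw = raw
        super().__init__(f"cannot canonicalize {attribute.value}={raw!r}: {reason}")


def _canonical_date(text: str, attr: KeyAttribute) -> str:
    for pat in _DATE_PATTERNS:
        m = pat.match(text)
        if not m:
            continue
        if len(m.groups()) == 1:  # YYYYMMDD
            y, mo, d = text[:4], text[4:6], text[6:8]
        else:
            y, mo, d = m.groups()
        try:
            import datetime

            dt = datetime.date(int(y), int(mo), int(d))
        except ValueError as exc:
            raise CanonicalizationError(attr, text, str(exc)) from exc
        return dt.isoformat()
    raise CanonicalizationError(attr, text, "unrecognized date format")


def canonicalize(record: Mapping[str, str], attr: KeyAttribute) -> str:
    """Canonical text for one attribute of a record (a column mapping).

    NFKC-normalizes (mapping full-width digits/letters to ASCII), strips
    surrounding whitespace, renders birth dates as ISO-8601 YYYY-MM-DD and
    sex as one of {M, F, U}.  A missing value canonicalizes to the empty
    string so two records missing the same field still agree on it.
    Deterministic: identical raw values canonicalize identically anywhere.
    """
    raw = record.get(ATTRIBUTE_COLUMNS[attr], "")
    if raw is None:
        raw = ""
    text = unicodedata.normalize("NFKC", str(raw)).strip()
    if attr is KeyAttribute.birth_date:
        return _canonical_date(text, attr) if text else ""
    if attr is KeyAttribute.sex:
        code = _SEX_CODES.get(text.lower())
        if code is None:
            raise CanonicalizationError(attr, text, "unrecognized sex code")
        return code
    return text


def make_key(record: Mapping[str, str], combo: Sequence[KeyAttribute]) -> CompressedKey:
    """Compressed matching key: SHA-256 of the canonical attribute values.

    Values are joined in the fixed attribute-enumeration order (so the
    caller's combination ordering is irrelevant) with U+001F separators.
    Two records produce equal digests iff they agree on *all* attributes of
    the combination after canonicalization.
    """
    if len(combo) < 2:
        raise ValueError("a matching-key combination needs at least 2 attributes")
    ordered = [a for a in KeyAttribute if a in set(combo)]
    parts = [a.value + "=" + canonicalize(record, a) for a in ordered]
    return hashlib.sha256(_SEPARATOR.join(parts).encode("utf-8")).digest()


def canonical_values(
    record: Mapping[str, str], attrs: Iterable[KeyAttribute] = KeyAttribute
) -> dict[KeyAttribute, str]:
    """Canonicalize several attributes at once (fast path for sweeps)."""
    return {a: canonicalize(record, a) for a in attrs}


def make_key_from_canonical(
    canon: Mapping[KeyAttribute, str], combo: Sequence[KeyAttribute]
) -> CompressedKey:
    """As :func:`make_key`, but from already-canonicalized attribute values."""
    if len(combo) < 2:
        raise ValueError("a matching-key combination needs at least 2 attributes")
    ordered = [a for a in KeyAttribute if a in set(combo)]
    parts = [a.value + "=" + canon[a] for a in ordered]
    return hashlib.sha256(_SEPARATOR.join(parts).encode("utf-8")).digest()


def enumerate_combinations(
    attrs: Iterable[KeyAttribute], min_size: int = 2
) -> list[AttributeCombination]:
    """All attribute subsets of size >= min_size, ordered by size then position.

    Six attributes give C(6,2)+...+C(6,6) = 57 combinations; dropping sex
    (all-female screening) gives 26.
    """
    pool = list(dict.fromkeys(attrs))
    if not pool:
        raise ValueError("attribute set is empty")
    if min_size < 2:
        raise ValueError("min_size must be at least 2 (single-key matching is inadequate)")
    out: list[AttributeCombination] = []
    for size in range(min_size, len(pool) + 1):
        out.extend(itertools.combinations(pool, size))
    return out


def combo_label(combo: Sequence[KeyAttribute]) -> str:
    return "+".join(a.value for a in combo)


def parse_combo(text: str) -> AttributeCombination:
    """Parse 'birth_date,first_kana' into an attribute combination."""
    parts = [p.strip() for p in text.replace("+", ",").split(",") if p.strip()]
    try:
        return tuple(KeyAttribute(p) for p in parts)
    except ValueError as exc:
        valid = ", ".join(a.value for a in KeyAttribute)
        raise ValueError(f"unknown attribute in {text!r}; valid: {valid}") from exc
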