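"""Error operators: the taxonomy of identifier errors found in Japanese registries.

Ten categories are modelled, grouped the way registry managers classify
them — data-entry errors (typing, IME kanji-conversion, misreading of a
name, missing letters, omission of a component), orthographic variants
(variant kanji, address-format differences), and true data changes (name
change on marriage, use of an alias, moving house).

Each operator perturbs exactly the targeted attribute field(s) of a record
copy, never the hidden person UID, and reports which matching-key
attributes it touched.  Operators are constructed so the *canonical* value
changes (a perturbation that NFKC normalization would undo, like a width
change alone, would not be an error at matching time); the pair builder
audits this.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from random import Random

from ..keys import KeyAttribute
from .lexicons import Lexicons, NameEntry

__all__ = ["ErrorCategory", "RowAttr", "ErrorOperator", "apply_error"]


class ErrorCategory(str, Enum):
    typing = "typing"
    kanji_conversion = "kanji_conversion"
    misreading = "misreading"
    missing_letter = "missing_letter"
    omission = "omission"
    variant_kanji = "variant_kanji"
    address_format = "address_format"
    name_change = "name_change"
    alias = "alias"
    moving = "moving"


class RowAttr(str, Enum):
    """Attribute granularity of the error-plan table rows."""

    name = "name"
    birth_date = "birth_date"
    address = "address"
    sex = "sex"


# Which table attribute rows each category may target.
CATEGORY_ATTRS: dict[ErrorCategory, tuple[RowAttr, ...]] = {
    ErrorCategory.typing: (RowAttr.name, RowAttr.birth_date, RowAttr.address, RowAttr.sex),
    ErrorCategory.kanji_conversion: (RowAttr.name, RowAttr.address),
    ErrorCategory.misreading: (RowAttr.name,),
    ErrorCategory.missing_letter: (RowAttr.name,),
    ErrorCategory.omission: (RowAttr.name, RowAttr.address),
    ErrorCategory.variant_kanji: (RowAttr.name,),
    ErrorCategory.address_format: (RowAttr.address,),
    ErrorCategory.name_change: (RowAttr.name,),
    ErrorCategory.alias: (RowAttr.name,),
    ErrorCategory.moving: (RowAttr.address,),
}

# Name categories that edit a single script field and can therefore be
# applied to both name components in one go (dual-component promotion).
_SINGLE_FIELD_NAME_CATEGORIES = {
    ErrorCategory.typing,
    ErrorCategory.kanji_conversion,
    ErrorCategory.misreading,
    ErrorCategory.missing_letter,
    ErrorCategory.variant_kanji,
}

# Script fixed by the category semantics: an IME conversion error changes
# the kanji while the reading stays right; a misreading changes the kana
# while the kanji is untouched; a variant character is a kanji matter.
_FIXED_SCRIPT = {
    ErrorCategory.kanji_conversion: "kanji",
    ErrorCategory.misreading: "kana",
    ErrorCategory.variant_kanji: "kanji",
}


@dataclass(frozen=True)
class ErrorOperator:
    """One planned error: category, table attribute row, and name targeting.

    ``component``/``script`` select the concrete name field; ``dual``
    applies the category to both the family and the first name (one table
    entry touching two key attributes).
    """

    category: ErrorCategory
    attribute: RowAttr
    component: str | None = None  # 'family' | 'first'
    script: str | None = None  # 'kanji' | 'kana'
    dual: bool = False

    def __post_init__(self) -> None:
        if self.attribute not in CATEGORY_ATTRS[self.category]:
            raise ValueError(
                f"{self.category.value} errors cannot target {self.attribute.value}"
            )
        if self.dual and self.category not in _SINGLE_FIELD_NAME_CATEGORIES:
            raise ValueError(f"{self.category.value} cannot be dual-component")

    def name_field(self, component: str) -> str:
        script = _FIXED_SCRIPT.get(self.category, self.script or "kana")
        return f"{component}_name_{script}"

    def target_attrs(self) -> set[KeyAttribute]:
        """Matching-key attributes this operator will perturb."""
        cat, row = self.category, self.attribute
        if row is RowAttr.birth_date:
            return {KeyAttribute.birth_date}
        if row is RowAttr.sex:
            return {KeyAttribute.sex}
        if row is RowAttr.address:
            return {KeyAttribute.address}
        if cat is ErrorCategory.name_change:
            return {KeyAttribute.family_kanji, KeyAttribute.family_kana}
        if cat is ErrorCategory.alias:
            return {KeyAttribute.first_kanji, KeyAttribute.first_kana}
        comps = ("family", "first") if self.dual else (self.component or "family",)
        if cat is ErrorCategory.omission:
            out: set[KeyAttribute] = set()
            for c in comps:
                out |= {KeyAttribute(f"{c}_kanji"), KeyAttribute(f"{c}_kana")}
            return out
        script = _FIXED_SCRIPT.get(cat, self.script or "kana")
        return {KeyAttribute(f"{c}_{script}") for c in comps}


_DAKUTEN_PAIRS = "かが,きぎ,くぐ,けげ,こご,さざ,しじ,すず,せぜ,そぞ,ただ,ちぢ,つづ,てで,とど,はば,ひび,ふぶ,へべ,ほぼ"
_KANA_SWAP = {}
for _pair in _DAKUTEN_PAIRS.split(","):
    _KANA_SWAP[_pair[0]] = _pair[1]
    _KANA_SWAP[_pair[1]] = _pair[0]
_KANA_POOL = "あいうえおかきくけこさしすせそたちつてとなにぬねのはひふへほまみむめもやゆよらりるれろわん"


def _substitute_char(text: str, idx: int, new: str) -> str:
    return text[:idx] + new + text[idx + 1 :]


def _perturb_kana(text: str, rng: Random) -> str:
    """Change one kana character (dakuten toggle preferred)."""
    candidates = [i for i, ch in enumerate(text) if ch in _KANA_SWAP]
    if candidates:
        i = rng.choice(candidates)
        return _substitute_char(text, i, _KANA_SWAP[text[i]])
    if text:
        i = rng.randrange(len(text))
        new = rng.choice([c for c in _KANA_POOL if c != text[i]])
        return _substitute_char(text, i, new)
    return "ん"


def _perturb_any_char(text: str, rng: Random, lex: Lexicons) -> str:
    """Generic one-character substitution/transposition guaranteeing change."""
    if len(text) >= 2:
        idxs = [i for i in range(len(text) - 1) if text[i] != text[i + 1]]
        if idxs and rng.random() < 0.5:
            i = rng.choice(idxs)
            return text[:i] + text[i + 1] + text[i] + text[i + 2 :]
    if not text:
        return "々"
    i = rng.randrange(len(text))
    pool = "".join(e.kanji for e in lex.family_names[:10]) + _KANA_POOL
    new = rng.choice([c for c in pool if c != text[i]])
    return _substitute_char(text, i, new)


def _typing_birth_date(value: str, rng: Random) -> str:
    y, m, d = value.split("-")
    new_day = rng.choice([x for x in range(1, 29) if x != int(d)])
    return f"{y}-{m}-{new_day:02d}"


def _kanji_conversion(text: str, rng: Random, lex: Lexicons) -> str:
    candidates = [i for i, ch in enumerate(text) if ch in lex.homophone_chars]
    if candidates:
        i = rng.choice(candidates)
        alts = [a for a in lex.homophone_chars[text[i]] if a != text[i]]
        if alts:
            return _substitute_char(text, i, rng.choice(alts))
    return _perturb_any_char(text, rng, lex)


def _variant_kanji(text: str, rng: Random, lex: Lexicons) -> str:
    fwd = lex.variant_kanji
    rev = {v: k for k, v in fwd.items()}
    candidates = [i for i, ch in enumerate(text) if ch in fwd or ch in rev]
    if candidates:
        i = rng.choice(candidates)
        ch = text[i]
        return _substitute_char(text, i, fwd.get(ch) or rev[ch])
    return _perturb_any_char(text, rng, lex)


def _misreading(record: dict, field: str, rng: Random, lex: Lexicons) -> str:
    """Alternative reading of the same kanji, from the lexicon when known."""
    component = "family" if field.startswith("family") else "first"
    kanji = record[f"{component}_name_kanji"]
    current = record[field]
    pools: tuple[NameEntry, ...] = (
        lex.family_names if component == "family" else lex.given_names(record.get("sex", "F"))
    )
    for entry in pools:
        if entry.kanji == kanji and entry.alt_kana and entry.alt_kana != current:
            return entry.alt_kana
    return _perturb_kana(current, rng)


_BLOCK_RE = re.compile(r"(\d+)-(\d+)-(\d+)$")
_CHOME_RE = re.compile(r"(\d+)丁目(\d+)番地?(\d+)号?$")


def _address_format(text: str, rng: Random) -> str:
    m = _BLOCK_RE.search(text)
    if m:
        a, b, c = m.groups()
        return text[: m.start()] + f"{a}丁目{b}番地{c}号"
    m = _CHOME_RE.search(text)
    if m:
        a, b, c = m.groups()
        return text[: m.start()] + f"{a}-{b}-{c}"
    return text + "1丁目"


def _fresh_address(current: str, rng: Random, lex: Lexicons) -> str:
    for _ in range(20):
        stem = rng.choice(lex.address_stems)
        new = f"{stem}{rng.randrange(1, 7)}-{rng.randrange(1, 30)}-{rng.randrange(1, 20)}"
        if new != current:
            return new
    raise RuntimeError("could not draw a fresh address")


def _fresh_name(current_kanji: str, pool: tuple[NameEntry, ...], rng: Random) -> NameEntry:
    options = [e for e in pool if e.kanji != current_kanji]
    if not options:
        raise ValueError("name lexicon too small to draw a replacement")
    return rng.choice(options)


def apply_error(
    record: dict,
    operator: ErrorOperator,
    rng: Random,
    lexicons: Lexicons,
) -> tuple[dict, set[KeyAttribute]]:
    """Apply one error operator to a copy of ``record``.

    Returns the perturbed copy and the set of matching-key attributes
    changed.  The person UID is never touched.
    """
    out = dict(record)
    cat, row = operator.category, operator.attribute

    if row is RowAttr.sex:
        out["sex"] = "M" if record["sex"] == "F" else "F"
    elif row is RowAttr.birth_date:
        out["birth_date"] = _typing_birth_date(record["birth_date"], rng)
    elif row is RowAttr.address:
        if cat is ErrorCategory.typing:
            addr = record["address"]
            digits = [i for i, ch in enumerate(addr) if ch.isdigit()]
            if digits:
                i = rng.choice(digits)
                new = rng.choice([d for d in "0123456789" if d != addr[i]])
                out["address"] = _substitute_char(addr, i, new)
            else:
                out["address"] = _perturb_any_char(addr, rng, lexicons)
        elif cat is ErrorCategory.kanji_conversion:
            out["address"] = _kanji_conversion(record["address"], rng, lexicons)
        elif cat is ErrorCategory.omission:
            addr = record["address"]
            stripped = re.sub(r"-\d+$", "", addr)
            out["address"] = stripped if stripped != addr else addr[:-1]
        elif cat is ErrorCategory.address_format:
            out["address"] = _address_format(record["address"], rng)
        elif cat is ErrorCategory.moving:
            out["address"] = _fresh_address(record["address"], rng, lexicons)
        else:
            raise ValueError(f"{cat.value} cannot target address")
    elif cat is ErrorCategory.name_change:
        entry = _fresh_name(record["family_name_kanji"], lexicons.family_names, rng)
        out["family_name_kanji"], out["family_name_kana"] = entry.kanji, entry.kana
    elif cat is ErrorCategory.alias:
        pool = lexicons.given_names(record.get("sex", "F"))
        entry = _fresh_name(record["first_name_kanji"], pool, rng)
        out["first_name_kanji"], out["first_name_kana"] = entry.kanji, entry.kana
    else:
        comps = ("family", "first") if operator.dual else (operator.component or "family",)
        for comp in comps:
            if cat is ErrorCategory.omission:
                out[f"{comp}_name_kanji"] = ""
                out[f"{comp}_name_kana"] = ""
                continue
            fld = operator.name_field(comp)
            if cat is ErrorCategory.typing:
                if fld.endswith("kana"):
                    out[fld] = _perturb_kana(record[fld], rng)
                else:
                    out[fld] = _perturb_any_char(record[fld], rng, lexicons)
            elif cat is ErrorCategory.kanji_conversion:
                out[fld] = _kanji_conversion(record[fld], rng, lexicons)
            elif cat is ErrorCategory.misreading:
                out[fld] = _misreading(record, fld, rng, lexicons)
            elif cat is ErrorCategory.missing_letter:
                text = record[fld]
                i = rng.randrange(len(text)) if text else 0
                out[fld] = text[:i] + text[i + 1 :] if text else ""
            elif cat is ErrorCategory.variant_kanji:
                out[fld] = _variant_kanji(record[fld], rng, lexicons)
            else:  # pragma: no cover - exhaustiveness guard
                raise ValueError(f"unhandled category {cat.value}")

    assert out.get("person_uid") == record.get("person_uid")
    return out, operator.target_attrs()
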