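"""Built-in Japanese lexicons for the pseudo-person generator.

Shipped as small editable TSV files so the substitution tables (homophones,
variant characters, alternative readings) can be audited or swapped for
another language.  Lines starting with '#' are comments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

__all__ = ["Lexicons", "load_default_lexicons"]


def _read_tsv(name: str) -> list[list[str]]:
    text = resources.files("pddi.data").joinpath(name).read_text(encoding="utf-8")
    rows = []
    for line in text.splitlines():
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


@dataclass(frozen=True)
class NameEntry:
    kanji: str
    kana: str
    alt_kana: str = ""       # plausible misreading of the same kanji
    homophone_kanji: str = ""  # different kanji, same reading


@dataclass(frozen=True)
class Lexicons:
    family_names: tuple[NameEntry, ...]
    given_names_f: tuple[NameEntry, ...]
    given_names_m: tuple[NameEntry, ...]
    variant_kanji: dict[str, str]          # standard char -> variant char
    homophone_chars: dict[str, tuple[str, ...]]  # char -> same-reading alternatives
    address_stems: tuple[str, ...]

    def given_names(self, sex: str) -> tuple[NameEntry, ...]:
        return self.given_names_f if sex == "F" else self.given_names_m

    def validate(self) -> None:
        for pool_name in ("family_names", "given_names_f", "given_names_m",
                          "address_stems"):
            if not getattr(self, pool_name):
                raise ValueError(f"lexicon {pool_name} is empty")


def load_default_lexicons() -> Lexicons:
    fams = tuple(
        NameEntry(*(r + [""] * (4 - len(r)))[:4]) for r in _read_tsv("family_names.tsv")
    )
    givens = [
        (r[0], NameEntry(*(r[1:] + [""] * (3 - len(r[1:])))[:3]))
        for r in _read_tsv("given_names.tsv")
    ]
    variants = {r[0]: r[1] for r in _read_tsv("variant_kanji.tsv")}
    homophones = {r[0]: tuple(r[2].split(",")) for r in _read_tsv("homophone_chars.tsv")}
    stems = tuple(r[0] for r in _read_tsv("municipalities.tsv"))
    lex = Lexicons(
        family_names=fams,
        given_names_f=tuple(e for s, e in givens if s == "F"),
        given_names_m=tuple(e for s, e in givens if s == "M"),
        variant_kanji=variants,
        homophone_chars=homophones,
        address_stems=stems,
    )
    lex.validate()
    return lex
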