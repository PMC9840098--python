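"""Pseudo-person generation: internally consistent Japanese identity records.

Each record carries a hidden ground-truth person UID (never perturbed by
any error operator), a family and given name in both kanji and kana, sex,
a birth date, and an address.  Name pairs are drawn jointly from the
lexicon so the kana field is always a legitimate reading of the kanji
field, which is what makes the misreading/kanji-conversion error operators
meaningful.
"""

from __future__ import annotations

import datetime
from random import Random

import pandas as pd

from .lexicons import Lexicons, load_default_lexicons

__all__ = ["generate_population"]

IDENTIFIER_COLUMNS = [
    "person_uid",
    "family_name_kanji",
    "family_name_kana",
    "first_name_kanji",
    "first_name_kana",
    "sex",
    "birth_date",
    "address",
]


def _random_birth_date(rng: Random) -> str:
    start = datetime.date(1935, 1, 1).toordinal()
    end = datetime.date(1995, 12, 31).toordinal()
    return datetime.date.fromordinal(rng.randrange(start, end + 1)).isoformat()


def _random_address(rng: Random, lex: Lexicons) -> str:
    stem = rng.choice(lex.address_stems)
    return f"{stem}{rng.randrange(1, 7)}-{rng.randrange(1, 30)}-{rng.randrange(1, 20)}"


def generate_population(
    n: int,
    seed: int,
    lexicons: Lexicons | None = None,
    sex: str | None = None,
    uid_prefix: str = "P",
) -> pd.DataFrame:
    """Generate ``n`` pseudo-person records, deterministically per seed.

    ``sex`` forces a single sex for every record (the all-female breast
    screening setting); otherwise sex is drawn 50/50.  UIDs are unique and
    sequential; identity attributes are random lexicon combinations, so
    distinct UIDs may rarely share a full attribute tuple, exactly as
    homonymous strangers do in real rosters.
    """
    if n <= 0:
        raise ValueError("population size must be positive")
    if sex is not None and sex not in ("F", "M"):
        raise ValueError("sex must be 'F' or 'M'")
    lex = lexicons or load_default_lexicons()
    rng = Random(seed)
    rows = []
    for i in range(n):
        s = sex or rng.choice("FM")
        fam = rng.choice(lex.family_names)
        giv = rng.choice(lex.given_names(s))
        rows.append(
            {
                "person_uid": f"{uid_prefix}{i:07d}",
                "family_name_kanji": fam.kanji,
                "family_name_kana": fam.kana,
                "first_name_kanji": giv.kanji,
                "first_name_kana": giv.kana,
                "sex": s,
                "birth_date": _random_birth_date(rng),
                "address": _random_address(rng, lex),
            }
        )
    return pd.DataFrame(rows, columns=IDENTIFIER_COLUMNS)
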