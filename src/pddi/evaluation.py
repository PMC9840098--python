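"""Scoring a linkage run against ground truth.

The screening dataset is the reference population.  For every screening
record the linkage either finds registry data (positive) or does not
(negative), and the planted ground truth says whether that record truly has
a registry counterpart.  Cross-tabulating gives the matching confusion
counts, from which matching sensitivity and specificity follow.  ``sweep``
repeats the experiment over a list of attribute combinations, either on a
plaintext fast path (hash-join on compressed keys — the oracle the
cryptographic protocol must agree with) or through the full protocol.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from . import keys as K
from .accuracy_model import round_half_up

__all__ = [
    "ConfusionCounts",
    "MatchingAccuracy",
    "score_run",
    "accuracy",
    "match_pairs_plaintext",
    "sweep",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Linkage confusion counts over screening records.

    A false positive is a screening record erroneously linked to a
    different person's registry data; a false negative is a screening
    record whose true counterpart was not linked.
    """

    tp: int
    fp: int
    fn: int
    tn: int


@dataclass(frozen=True)
class MatchingAccuracy:
    sensitivity: float  # percent, 2 decimals
    specificity: float  # percent, 2 decimals


def score_run(
    matched: Mapping[int, set[int]],
    ground_truth: pd.DataFrame,
    n_screening: int,
) -> ConfusionCounts:
    """Confusion counts from per-screening-record match sets.

    ``matched`` maps screening row index -> set of registry row indices the
    linkage returned (absent or empty = unmatched).  ``ground_truth`` has
    columns (person_uid, screening_row, registry_row) listing all true
    pairs.  Per screening record: linked to its true counterpart -> tp;
    true counterpart exists but not linked -> fn; no counterpart and linked
    to someone -> fp; no counterpart and unlinked -> tn.  A record linked
    both to its counterpart and to a stranger counts one tp and one fp, so
    multi-matches are never silently absorbed.
    """
    required = {"person_uid", "screening_row", "registry_row"}
    if not required.issubset(ground_truth.columns):
        raise ValueError(f"ground truth must have columns {sorted(required)}")
    truth_rows = ground_truth.groupby("screening_row")["registry_row"].apply(set)
    bad = [i for i in truth_rows.index if not 0 <= int(i) < n_screening]
    if bad:
        raise ValueError(f"ground truth references screening rows out of range: {bad[:5]}")
    truth: dict[int, set[int]] = {int(i): set(map(int, v)) for i, v in truth_rows.items()}

    tp = fp = fn = tn = 0
    for s_idx in range(n_screening):
        m = matched.get(s_idx, set())
        t = truth.get(s_idx)
        if t is not None:
            if m & t:
                tp += 1
            else:
                fn += 1
            if m - t:
                fp += 1  # also matched a stranger
        else:
            if m:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def accuracy(counts: ConfusionCounts) -> MatchingAccuracy:
    """Matching sensitivity and specificity in percent (2 decimals, half-up)."""
    if counts.tp + counts.fn == 0:
        raise ZeroDivisionError("sensitivity undefined: no true common records")
    if counts.tn + counts.fp == 0:
        raise ZeroDivisionError("specificity undefined: no non-common records")
    return MatchingAccuracy(
        sensitivity=round_half_up(100 * counts.tp / (counts.tp + counts.fn), 2),
        specificity=round_half_up(100 * counts.tn / (counts.tn + counts.fp), 2),
    )


def _canonical_table(df: pd.DataFrame) -> list[dict[K.KeyAttribute, str]]:
    return [K.canonical_values(row) for row in df.to_dict("records")]


def match_pairs_plaintext(
    screening: pd.DataFrame,
    registry: pd.DataFrame,
    combo: Sequence[K.KeyAttribute],
    _canon_cache: tuple[list, list] | None = None,
) -> dict[int, set[int]]:
    """Plaintext exact-match linkage on compressed keys (oracle fast path)."""
    canon_s, canon_r = _canon_cache or (
        _canonical_table(screening),
        _canonical_table(registry),
    )
    registry_index: dict[bytes, set[int]] = {}
    for r_idx, canon in enumerate(canon_r):
        registry_index.setdefault(K.make_key_from_canonical(canon, combo), set()).add(r_idx)
    out: dict[int, set[int]] = {}
    for s_idx, canon in enumerate(canon_s):
        hit = registry_index.get(K.make_key_from_canonical(canon, combo))
        if hit:
            out[s_idx] = set(hit)
    return out


def sweep(
    screening: pd.DataFrame,
    registry: pd.DataFrame,
    ground_truth: pd.DataFrame,
    combinations: Sequence[Sequence[K.KeyAttribute]],
    mode: str = "plaintext",
    session_factory=None,
) -> pd.DataFrame:
    """Score every attribute combination; one row per combination.

    ``mode='plaintext'`` hash-joins on compressed keys; ``mode='protocol'``
    runs the full encrypted session per combination (``session_factory``
    must map a combination to a matched-pairs dict, see
    :func:`pddi.protocol.match_pairs_protocol`).  Both paths produce
    identical confusion counts on the same inputs — that equivalence is the
    core correctness check of the protocol.
    """
    if mode not in ("plaintext", "protocol"):
        raise ValueError("mode must be 'plaintext' or 'protocol'")
    if mode == "protocol" and session_factory is None:
        raise ValueError("protocol mode needs a session_factory")
    cache = (_canonical_table(screening), _canonical_table(registry))
    rows = []
    for combo in combinations:
        if mode == "plaintext":
            matched = match_pairs_plaintext(screening, registry, combo, _canon_cache=cache)
        else:
            matched = session_factory(combo)
        counts = score_run(matched, ground_truth, n_screening=len(screening))
        acc = accuracy(counts)
        rows.append(
            {
                "combination": K.combo_label(combo),
                "n_attributes": len(combo),
                "tp": counts.tp,
                "fp": counts.fp,
                "fn": counts.fn,
                "tn": counts.tn,
                "sensitivity": acc.sensitivity,
                "specificity": acc.specificity,
            }
        )
    return pd.DataFrame(rows)
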