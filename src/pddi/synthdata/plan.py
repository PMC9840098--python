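"""Error-plan allocation: hit every marginal of the error table exactly.

An :class:`ErrorPlan` prescribes, for one dataset pair, how many of the
planted common records carry each (error category, attribute) entry, how
many carry errors on two or more distinct matching-key attributes
("multi-key" records, the ones no 2-attribute key combination can rescue),
and how many carry any error at all.  Real registry audits assign these by
expert judgment; here a deterministic greedy allocator reproduces the same
marginals constructively:

1. categories that inherently touch two key attributes (name change, alias,
   omission of a whole name component) seed multi-key records on their own;
2. remaining multi-key records are filled with pairs of single-attribute
   errors whose realized target attributes differ;
3. if the instance budget cannot supply enough pairs, a single-field name
   error is promoted to both name components (one table entry, two
   attributes) — the same economy of errors a human editor uses;
4. leftover instances become single-error records or stack onto existing
   multi-key records (never two entries of the same table row on one record,
   which would break the row's record count).

An audit pass after application verifies every marginal against what
actually changed canonically, so an infeasible plan or a vacuous operator
fails loudly instead of silently skewing the experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from random import Random

from ..keys import KeyAttribute
from .errors import (
    CATEGORY_ATTRS,
    ErrorCategory,
    ErrorOperator,
    RowAttr,
    _SINGLE_FIELD_NAME_CATEGORIES,
)

__all__ = ["ErrorPlan", "PlanError", "allocate_operators"]


class PlanError(ValueError):
    """The plan's marginals are inconsistent or combinatorially infeasible."""


# Categories whose single table entry necessarily touches >= 2 key attributes.
_INHERENT_MULTI = {
    (ErrorCategory.name_change, RowAttr.name),
    (ErrorCategory.alias, RowAttr.name),
    (ErrorCategory.omission, RowAttr.name),
}


@dataclass(frozen=True)
class ErrorPlan:
    """Marginal targets: record counts per (category, attribute) table entry,
    records with errors on multiple keys, and total records with errors."""

    counts: tuple[tuple[ErrorCategory, RowAttr, int], ...]
    multi_key: int
    total: int

    def __post_init__(self) -> None:
        seen = set()
        for cat, row, n in self.counts:
            if n < 0:
                raise PlanError(f"negative count for ({cat.value}, {row.value})")
            if row not in CATEGORY_ATTRS[cat]:
                raise PlanError(f"{cat.value} cannot target {row.value}")
            if (cat, row) in seen:
                raise PlanError(f"duplicate table entry ({cat.value}, {row.value})")
            seen.add((cat, row))
        if self.multi_key > self.total:
            raise PlanError("multi-key record count exceeds total perturbed records")
        if self.n_instances < self.total:
            raise PlanError("fewer error entries than records to perturb")

    @property
    def n_instances(self) -> int:
        return sum(n for _, _, n in self.counts)

    @staticmethod
    def zero() -> "ErrorPlan":
        return ErrorPlan(counts=(), multi_key=0, total=0)


def _compatible(a: tuple[ErrorCategory, RowAttr], b: tuple[ErrorCategory, RowAttr]) -> bool:
    """Can two instances share a record and still perturb 2 distinct attrs?"""
    if a == b:
        return False  # would break the table row's record count
    if a[1] == b[1] and a[1] is not RowAttr.name:
        return False  # same single-attribute row (two address errors etc.)
    return True


def allocate_operators(plan: ErrorPlan, rng: Random) -> list[list[ErrorOperator]]:
    """Concrete per-record operator lists satisfying every plan marginal.

    Returns ``plan.total`` records' worth of operators; which common records
    they land on is the caller's (seeded) choice.  Raises :class:`PlanError`
    naming the violated marginal when the plan is infeasible.
    """
    if plan.total == 0:
        if plan.n_instances:
            raise PlanError("plan has error entries but zero records to perturb")
        return []

    instances: list[tuple[ErrorCategory, RowAttr]] = []
    for cat, row, n in plan.counts:
        instances.extend([(cat, row)] * n)

    inherent = [i for i in instances if i in _INHERENT_MULTI]
    regular = [i for i in instances if i not in _INHERENT_MULTI]
    n_singles = plan.total - plan.multi_key
    if len(regular) < n_singles:
        raise PlanError(
            "not enough single-attribute error entries to fill the single-error records"
        )

    # 1. inherent two-attribute entries seed multi-key records
    seeds = min(len(inherent), plan.multi_key)
    records: list[list[tuple]] = [[i] for i in inherent[:seeds]]
    stack_later = list(inherent[seeds:])
    remaining_multi = plan.multi_key - seeds

    avail = len(regular) - n_singles
    if avail < remaining_multi:
        raise PlanError("instance budget cannot cover the multi-key record count")

    # 3. dual-component promotions where pairs cannot be afforded
    n_dual = max(0, 2 * remaining_multi - avail)
    n_pairs = remaining_multi - n_dual

    buckets: dict[tuple[ErrorCategory, RowAttr], int] = {}
    for i in regular:
        buckets[i] = buckets.get(i, 0) + 1

    def take(key: tuple) -> None:
        buckets[key] -= 1
        if buckets[key] == 0:
            del buckets[key]

    promotable = [
        k
        for k in buckets
        if k[1] is RowAttr.name and k[0] in _SINGLE_FIELD_NAME_CATEGORIES
    ]
    if n_dual > sum(buckets[k] for k in promotable):
        raise PlanError(
            "multi-key count infeasible: not enough promotable name errors"
        )
    for _ in range(n_dual):
        key = max(
            (k for k in buckets if k[1] is RowAttr.name and k[0] in _SINGLE_FIELD_NAME_CATEGORIES),
            key=lambda k: (buckets[k], k[0].value),
        )
        records.append([(key, "dual")])
        take(key)

    # 2. pair two compatible single-attribute entries per multi-key record
    for _ in range(n_pairs):
        ordered = sorted(buckets, key=lambda k: (-buckets[k], k[0].value, k[1].value))
        first = ordered[0]
        partner = next((k for k in ordered[1:] if _compatible(first, k)), None)
        if partner is None:
            raise PlanError(
                "multi-key count infeasible: no compatible error pair remains"
            )
        records.append([first, partner])
        take(first)
        take(partner)

    # 4. leftovers: extras stack onto multi-key records, the rest are singles
    n_extras = sum(buckets.values()) - n_singles
    extras: list[tuple[ErrorCategory, RowAttr]] = []
    for _ in range(n_extras):
        key = max(buckets, key=lambda k: (buckets[k], k[0].value, k[1].value))
        extras.append(key)
        take(key)
    for key in stack_later + extras:
        # feasibility-aware: the host must not hold this table row already and
        # must still admit a disjoint field assignment with the new entry
        candidates = sorted(range(len(records)), key=lambda i: (len(records[i]), i))
        host = next(
            (
                records[i]
                for i in candidates
                if key not in _entries(records[i])
                and _assign_fields(records[i] + [key]) is not None
            ),
            None,
        )
        if host is None:
            raise PlanError(f"cannot stack extra {key} without breaking a marginal")
        host.append(key)

    singles = []
    for key, n in sorted(buckets.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)):
        singles.extend([key] * n)
    records.extend([[key] for key in singles])
    if len(records) != plan.total:
        raise PlanError("internal allocation error: record count mismatch")

    # realize concrete operators with pairwise-disjoint target fields
    out: list[list[ErrorOperator]] = []
    for rec in records:
        assignment = _assign_fields(rec, rng)
        if assignment is None:
            raise PlanError("no collision-free field assignment for a record")
        out.append(assignment)

    rng.shuffle(out)
    return out


def _entries(rec: list) -> list[tuple[ErrorCategory, RowAttr]]:
    return [e if isinstance(e[0], ErrorCategory) else e[0] for e in rec]


def _field_options(
    cat: ErrorCategory, row: RowAttr, dual: bool
) -> list[ErrorOperator]:
    """Concrete operator variants for one table entry, by target field."""
    if row is not RowAttr.name:
        return [ErrorOperator(category=cat, attribute=row)]
    if cat in (ErrorCategory.name_change, ErrorCategory.alias):
        return [ErrorOperator(category=cat, attribute=row)]
    if dual:
        return [ErrorOperator(category=cat, attribute=row, dual=True)]
    if cat is ErrorCategory.omission:
        return [
            ErrorOperator(category=cat, attribute=row, component=c)
            for c in ("family", "first")
        ]
    scripts = (
        ("kanji",)
        if cat in (ErrorCategory.kanji_conversion, ErrorCategory.variant_kanji)
        else ("kana",)
        if cat is ErrorCategory.misreading
        else ("kana", "kanji")
    )
    return [
        ErrorOperator(category=cat, attribute=row, component=c, script=s)
        for c in ("family", "first")
        for s in scripts
    ]


def _assign_fields(rec: list, rng: Random | None = None) -> list[ErrorOperator] | None:
    """Backtracking search for operators with pairwise-disjoint target attrs.

    Disjointness guarantees no field is touched twice, so no later operator
    can mask or undo an earlier one and the realized changed-attribute set
    equals the targeted one exactly.
    """
    entries = []
    for e in rec:
        key, dual = (e, False) if isinstance(e[0], ErrorCategory) else (e[0], True)
        options = _field_options(key[0], key[1], dual)
        if rng is not None and len(options) > 1:
            rng.shuffle(options)
        entries.append(options)
    order = sorted(range(len(entries)), key=lambda i: len(entries[i]))

    chosen: dict[int, ErrorOperator] = {}

    def search(pos: int, used: frozenset) -> bool:
        if pos == len(order):
            return True
        i = order[pos]
        for op in entries[i]:
            attrs = op.target_attrs()
            if attrs & used:
                continue
            chosen[i] = op
            if search(pos + 1, used | attrs):
                return True
            del chosen[i]
        return False

    if not search(0, frozenset()):
        return None
    return [chosen[i] for i in range(len(entries))]
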