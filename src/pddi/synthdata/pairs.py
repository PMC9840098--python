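"""Linked dataset-pair construction with planted ground truth.

A screening table and a registry table are built over one pseudo-person
population: ``n_common`` persons appear in both (the true links), the rest
are unique to one side.  The registry copies of the common records are
perturbed according to the error plan — the screening side stays clean, as
when a screening roster is matched against an independently keyed registry.
The ground-truth link table (person UID, screening row, registry row) is
fixed before any error is injected and is invariant under it.

After application an audit recomputes, from the canonical attribute values,
which matching keys actually changed on each record and verifies every plan
marginal exactly; a vacuous operator or infeasible plan fails loudly.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from random import Random

import pandas as pd

from .. import keys as K
from .errors import apply_error
from .lexicons import Lexicons, load_default_lexicons
from .plan import ErrorPlan, PlanError, allocate_operators
from .population import IDENTIFIER_COLUMNS, generate_population

__all__ = ["DatasetSpec", "LinkedPair", "build_linked_pair"]

SCREENING_PAYLOAD = ["serial", "exam_date", "test_result", "risk_assessment"]
REGISTRY_PAYLOAD = ["serial", "icd10_code", "diagnosis_name", "diagnosis_date"]

_ICD10 = {
    "colorectal": [("C18.9", "結腸癌"), ("C19", "直腸S状結腸移行部癌"), ("C20", "直腸癌")],
    "breast": [("C50.9", "乳癌"), ("C50.4", "乳癌(上外側)"), ("C50.2", "乳癌(上内側)")],
}
_DEFAULT_ICD10 = [("C80.9", "悪性新生物")]


@dataclass(frozen=True)
class DatasetSpec:
    """Sizes, cancer-type label, error plan and seed for one dataset pair."""

    n_screening: int
    n_registry: int
    n_common: int
    cancer_type: str = "generic"
    error_plan: ErrorPlan = field(default_factory=ErrorPlan.zero)
    seed: int = 0
    sex: str | None = None  # force single-sex population (breast screening)

    def __post_init__(self) -> None:
        if min(self.n_screening, self.n_registry) < 1:
            raise ValueError("dataset sizes must be positive")
        if not 0 <= self.n_common <= min(self.n_screening, self.n_registry):
            raise ValueError("n_common must not exceed either dataset size")
        if self.error_plan.total > self.n_common:
            raise PlanError("error plan perturbs more records than exist in common")


@dataclass
class LinkedPair:
    screening: pd.DataFrame
    registry: pd.DataFrame
    ground_truth: pd.DataFrame  # person_uid, screening_row, registry_row
    perturbed_attrs: dict[str, set[K.KeyAttribute]]  # person_uid -> changed keys


def _changed_attrs(original: dict, perturbed: dict) -> set[K.KeyAttribute]:
    return {
        a
        for a in K.KeyAttribute
        if K.canonicalize(original, a) != K.canonicalize(perturbed, a)
    }


def _audit(plan: ErrorPlan, applied: list[tuple[list, set[K.KeyAttribute]]]) -> None:
    if len(applied) != plan.total:
        raise PlanError(
            f"audit: perturbed {len(applied)} records, plan demands {plan.total}"
        )
    realized: dict[tuple, int] = {}
    for ops, _ in applied:
        rows = [(op.category, op.attribute) for op in ops]
        if len(rows) != len(set(rows)):
            raise PlanError("audit: a record carries two errors from the same table row")
        for key in set(rows):
            realized[key] = realized.get(key, 0) + 1
    for cat, row, n in plan.counts:
        if realized.get((cat, row), 0) != n:
            raise PlanError(
                f"audit: ({cat.value}, {row.value}) touched "
                f"{realized.get((cat, row), 0)} records, plan demands {n}"
            )
    multi = sum(1 for _, attrs in applied if len(attrs) >= 2)
    if multi != plan.multi_key:
        raise PlanError(
            f"audit: {multi} records changed on >=2 keys, plan demands {plan.multi_key}"
        )
    for ops, attrs in applied:
        if not attrs:
            raise PlanError("audit: an error operator left a record canonically unchanged")
        expected = set().union(*(op.target_attrs() for op in ops))
        if attrs != expected:
            raise PlanError(
                f"audit: realized changed attributes {sorted(a.value for a in attrs)} "
                f"differ from targeted {sorted(a.value for a in expected)}"
            )


def _screening_payload(n: int, rng: Random) -> pd.DataFrame:
    base = datetime.date(2020, 1, 6).toordinal()
    return pd.DataFrame(
        {
            "serial": [f"S{i:06d}" for i in range(n)],
            "exam_date": [
                datetime.date.fromordinal(base + rng.randrange(300)).isoformat()
                for _ in range(n)
            ],
            "test_result": [rng.choice(["positive", "negative"]) for _ in range(n)],
            "risk_assessment": [rng.choice(["high", "low"]) for _ in range(n)],
        }
    )


def _registry_payload(n: int, cancer_type: str, rng: Random) -> pd.DataFrame:
    codes = _ICD10.get(cancer_type, _DEFAULT_ICD10)
    base = datetime.date(2020, 3, 2).toordinal()
    picks = [rng.choice(codes) for _ in range(n)]
    return pd.DataFrame(
        {
            "serial": [f"R{i:06d}" for i in range(n)],
            "icd10_code": [c for c, _ in picks],
            "diagnosis_name": [d for _, d in picks],
            "diagnosis_date": [
                datetime.date.fromordinal(base + rng.randrange(300)).isoformat()
                for _ in range(n)
            ],
        }
    )


def build_linked_pair(
    spec: DatasetSpec, lexicons: Lexicons | None = None
) -> LinkedPair:
    """Generate the (screening, registry, ground truth) triple for a spec.

    Deterministic per spec+seed down to row order.  The plan's marginals
    are enforced exactly (constructive allocation, then audit).
    """
    lex = lexicons or load_default_lexicons()
    # independent streams per concern: the population, row order and ground
    # truth must be invariant under changes to the error plan
    rng_pop = Random(f"pddi-pop-{spec.seed}")
    rng_err = Random(f"pddi-err-{spec.seed}")
    rng_rows = Random(f"pddi-rows-{spec.seed}")
    rng_payload = Random(f"pddi-payload-{spec.seed}")
    n_total = spec.n_screening + spec.n_registry - spec.n_common
    population = generate_population(
        n_total, seed=rng_pop.randrange(2**31), lexicons=lex, sex=spec.sex
    ).to_dict("records")

    common = population[: spec.n_common]
    screening_only = population[spec.n_common : spec.n_screening]
    registry_only = population[spec.n_screening :]

    # error injection on the registry copies of common records
    operators = allocate_operators(spec.error_plan, rng_err)
    target_idx = sorted(rng_err.sample(range(spec.n_common), len(operators)))
    registry_common = [dict(r) for r in common]
    applied = []
    for idx, ops in zip(target_idx, operators):
        rec = registry_common[idx]
        for op in ops:
            rec, _ = apply_error(rec, op, rng_err, lex)
        registry_common[idx] = rec
        applied.append((ops, _changed_attrs(common[idx], rec)))
    _audit(spec.error_plan, applied)
    perturbed = {
        common[idx]["person_uid"]: attrs for idx, (_, attrs) in zip(target_idx, applied)
    }

    # assemble tables with shuffled row order
    s_rows = common + screening_only
    r_rows = registry_common + registry_only
    s_order = list(range(len(s_rows)))
    r_order = list(range(len(r_rows)))
    rng_rows.shuffle(s_order)
    rng_rows.shuffle(r_order)
    screening = pd.DataFrame([s_rows[i] for i in s_order], columns=IDENTIFIER_COLUMNS)
    registry = pd.DataFrame([r_rows[i] for i in r_order], columns=IDENTIFIER_COLUMNS)
    screening = pd.concat(
        [screening, _screening_payload(len(screening), rng_payload)], axis=1
    )
    registry = pd.concat(
        [registry, _registry_payload(len(registry), spec.cancer_type, rng_payload)], axis=1
    )

    s_pos = {orig: pos for pos, orig in enumerate(s_order)}
    r_pos = {orig: pos for pos, orig in enumerate(r_order)}
    ground_truth = pd.DataFrame(
        {
            "person_uid": [common[i]["person_uid"] for i in range(spec.n_common)],
            "screening_row": [s_pos[i] for i in range(spec.n_common)],
            "registry_row": [r_pos[i] for i in range(spec.n_common)],
        }
    )
    return LinkedPair(
        screening=screening,
        registry=registry,
        ground_truth=ground_truth,
        perturbed_attrs=perturbed,
    )
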