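"""Synthetic population, error operators, and plan-marginal fidelity."""

from random import Random

import pytest

from pddi import keys as K
from pddi.synthdata import (
    BREAST_PLAN,
    COLORECTAL_PLAN,
    DatasetSpec,
    ErrorCategory,
    ErrorOperator,
    ErrorPlan,
    PlanError,
    RowAttr,
    apply_error,
    build_linked_pair,
    generate_population,
    preset_spec,
)
from pddi.evaluation import accuracy, match_pairs_plaintext, score_run

A = K.KeyAttribute


class TestPopulation:
    def test_deterministic_per_seed(self):
        a = generate_population(10, seed=42)
        b = generate_population(10, seed=42)
        assert a.equals(b)
        assert not a.equals(generate_population(10, seed=43))

    def test_uids_unique(self):
        pop = generate_population(10_000, seed=0)
        assert pop["person_uid"].is_unique

    def test_birth_dates_canonicalize(self):
        pop = generate_population(200, seed=1)
        for rec in pop.to_dict("records"):
            assert len(K.canonicalize(rec, A.birth_date)) == 10

    def test_kana_is_reading_of_kanji(self, lexicons):
        readings = {e.kanji: e.kana for e in lexicons.family_names}
        pop = generate_population(100, seed=2)
        for rec in pop.to_dict("records"):
            assert readings[rec["family_name_kanji"]] == rec["family_name_kana"]

    def test_forced_sex(self):
        pop = generate_population(50, seed=3, sex="F")
        assert set(pop["sex"]) == {"F"}

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError):
            generate_population(0, seed=0)


class TestErrorOperators:
    def _record(self):
        return generate_population(1, seed=9).to_dict("records")[0]

    def test_missing_letter_shortens_field(self, lexicons):
        rec = self._record()
        op = ErrorOperator(ErrorCategory.missing_letter, RowAttr.name,
                           component="family", script="kana")
        out, attrs = apply_error(rec, op, Random(0), lexicons)
        assert len(out["family_name_kana"]) == len(rec["family_name_kana"]) - 1
        assert attrs == {A.family_kana}

    def test_misreading_touches_only_kana(self, lexicons):
        rec = self._record()
        op = ErrorOperator(ErrorCategory.misreading, RowAttr.name, component="first")
        out, attrs = apply_error(rec, op, Random(1), lexicons)
        assert out["first_name_kanji"] == rec["first_name_kanji"]
        assert out["first_name_kana"] != rec["first_name_kana"]
        assert attrs == {A.first_kana}

    def test_kanji_conversion_keeps_reading_field(self, lexicons):
        rec = self._record()
        op = ErrorOperator(ErrorCategory.kanji_conversion, RowAttr.name, component="family")
        out, _ = apply_error(rec, op, Random(2), lexicons)
        assert out["family_name_kana"] == rec["family_name_kana"]
        assert out["family_name_kanji"] != rec["family_name_kanji"]

    def test_typing_birth_date_stays_valid(self, lexicons):
        rec = self._record()
        op = ErrorOperator(ErrorCategory.typing, RowAttr.birth_date)
        out, _ = apply_error(rec, op, Random(3), lexicons)
        assert out["birth_date"] != rec["birth_date"]
        assert len(K.canonicalize(out, A.birth_date)) == 10

    def test_address_format_survives_nfkc(self, lexicons):
        """A format change must still differ after canonicalization."""
        rec = self._record()
        op = ErrorOperator(ErrorCategory.address_format, RowAttr.address)
        out, _ = apply_error(rec, op, Random(4), lexicons)
        assert K.canonicalize(out, A.address) != K.canonicalize(rec, A.address)

    def test_name_change_replaces_both_scripts(self, lexicons):
        rec = self._record()
        op = ErrorOperator(ErrorCategory.name_change, RowAttr.name)
        out, attrs = apply_error(rec, op, Random(5), lexicons)
        assert attrs == {A.family_kanji, A.family_kana}
        assert out["family_name_kanji"] != rec["family_name_kanji"]

    @pytest.mark.parametrize(
        "category,row",
        [(c, r) for c in ErrorCategory for r in (RowAttr.name, RowAttr.address,
                                                 RowAttr.birth_date, RowAttr.sex)],
    )
    def test_every_operator_perturbs_only_its_targets(self, category, row, lexicons):
        from pddi.synthdata.errors import CATEGORY_ATTRS

        if row not in CATEGORY_ATTRS[category]:
            with pytest.raises(ValueError):
                ErrorOperator(category, row, component="family")
            return
        rec = generate_population(1, seed=17).to_dict("records")[0]
        op = ErrorOperator(category, row, component="family")
        out, attrs = apply_error(rec, op, Random(6), lexicons)
        assert out["person_uid"] == rec["person_uid"]
        changed = {a for a in A if K.canonicalize(out, a) != K.canonicalize(rec, a)}
        assert changed == attrs  # exactly the declared targets, nothing else

    def test_untouched_combination_key_is_stable(self, lexicons):
        rec = self._record()
        op = ErrorOperator(ErrorCategory.moving, RowAttr.address)
        out, _ = apply_error(rec, op, Random(7), lexicons)
        combo = (A.birth_date, A.first_kana)
        assert K.make_key(rec, combo) == K.make_key(out, combo)


class TestPlans:
    def test_colorectal_marginals(self, small_colorectal_pair):
        perturbed = small_colorectal_pair.perturbed_attrs
        assert len(perturbed) == 51
        assert sum(1 for a in perturbed.values() if len(a) >= 2) == 25

    def test_breast_marginals(self, small_breast_pair):
        perturbed = small_breast_pair.perturbed_attrs
        assert len(perturbed) == 36
        assert sum(1 for a in perturbed.values() if len(a) >= 2) == 14

    def test_plan_tables_match_marginal_declarations(self):
        assert COLORECTAL_PLAN.n_instances == 80 and COLORECTAL_PLAN.total == 51
        assert BREAST_PLAN.n_instances == 47 and BREAST_PLAN.total == 36

    def test_infeasible_plan_rejected(self):
        with pytest.raises(PlanError):
            ErrorPlan(
                counts=((ErrorCategory.moving, RowAttr.address, 2),),
                multi_key=0,
                total=5,  # more records than error entries
            )

    def test_impossible_multi_key_target_rejected(self):
        plan = ErrorPlan(
            counts=(
                (ErrorCategory.moving, RowAttr.address, 2),
                (ErrorCategory.address_format, RowAttr.address, 1),
            ),
            multi_key=3,  # only 3 instances, all single-attribute, no pairs possible
            total=3,
        )
        from pddi.synthdata.plan import allocate_operators

        with pytest.raises(PlanError):
            allocate_operators(plan, Random(0))


class TestLinkedPairs:
    def test_reproducible_byte_identical(self):
        spec = preset_spec("colorectal", seed=21, scale=0.03)
        a = build_linked_pair(spec)
        b = build_linked_pair(spec)
        assert a.screening.to_csv(index=False) == b.screening.to_csv(index=False)
        assert a.registry.to_csv(index=False) == b.registry.to_csv(index=False)
        assert a.ground_truth.equals(b.ground_truth)

    def test_ground_truth_invariant_under_error_plan(self):
        base = DatasetSpec(n_screening=80, n_registry=300, n_common=60, seed=8)
        with_errors = DatasetSpec(
            n_screening=80, n_registry=300, n_common=60, seed=8,
            error_plan=COLORECTAL_PLAN,
        )
        a = build_linked_pair(base)
        b = build_linked_pair(with_errors)
        assert a.ground_truth.equals(b.ground_truth)

    def test_common_records_present_on_both_sides(self, small_colorectal_pair):
        p = small_colorectal_pair
        s_uids = set(p.screening["person_uid"])
        r_uids = set(p.registry["person_uid"])
        truth_uids = set(p.ground_truth["person_uid"])
        assert truth_uids <= s_uids and truth_uids <= r_uids

    def test_zero_error_plan_gives_perfect_sensitivity(self):
        spec = DatasetSpec(n_screening=80, n_registry=300, n_common=40, seed=5)
        pair = build_linked_pair(spec)
        matched = match_pairs_plaintext(pair.screening, pair.registry, tuple(A)[:6])
        counts = score_run(matched, pair.ground_truth, n_screening=80)
        assert counts.fn == 0
        assert accuracy(counts).sensitivity == 100.0

    def test_plan_larger_than_common_subset_rejected(self):
        with pytest.raises(PlanError):
            DatasetSpec(
                n_screening=100, n_registry=100, n_common=10,
                error_plan=COLORECTAL_PLAN, seed=0,
            )
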