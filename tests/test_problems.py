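"""Worked Bayesian problems: solving, error prediction, and policy reports."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fourfold import (
    ProblemSpec,
    bayes_invert,
    collapse_monty,
    conditionalize,
    fixture,
    from_counts,
    is_undefined,
    monty_hall,
    predict_errors,
    solve,
    titanic_policy_report,
)
from fourfold.problems import (
    Given,
    fixture_names,
    problem_table,
    switch_stick_posteriors,
)
from fourfold.render import format_percent

probs = st.floats(0.001, 0.999)


class TestBayesInvert:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((0.01, 0.80, 0.096), 0.008 / 0.10304),
            ((0.15, 0.80, 0.20), 0.12 / 0.29),  # cab problem, prints as 41%
        ],
    )
    def test_closed_form(self, args, expected):
        assert bayes_invert(*args) == pytest.approx(expected, abs=1e-12)

    @given(probs, probs)
    @settings(max_examples=100, derandomize=True)
    def test_uninformative_likelihoods_return_prior(self, prior, likelihood):
        assert bayes_invert(prior, likelihood, likelihood) == pytest.approx(
            prior, abs=1e-9
        )

    def test_zero_evidence_is_undefined(self):
        assert is_undefined(bayes_invert(0.0, 0.5, 0.0))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bayes_invert(1.2, 0.5, 0.5)


class TestSolve:
    def test_mammography_standard_prints_7_8_percent(self):
        answer = solve(fixture("mammography:standard"))
        assert format_percent(answer.value) == "7.8%"

    def test_mammography_short_menu_is_8_out_of_103(self):
        answer = solve(fixture("mammography:short_frequencies"))
        assert answer.value == pytest.approx(8 / 103)

    def test_cab_posterior_is_41_percent(self):
        answer = solve(fixture("cab"))
        assert answer.value == pytest.approx(0.12 / 0.29, abs=1e-12)
        assert format_percent(answer.value, 0) == "41%"

    def test_format_equivalence(self):
        """All three mammography formats share the (8, 95) top row and
        agree on the printed answer."""
        answers = {}
        for name in ("mammography:standard", "mammography:natural_frequencies",
                     "mammography:short_frequencies"):
            spec = fixture(name)
            answers[name] = format_percent(solve(spec).value)
        assert set(answers.values()) == {"7.8%"}
        nat = problem_table(fixture("mammography:natural_frequencies"))
        assert nat.cells() == (8, 95, 2, 895)
        std = problem_table(fixture("mammography:standard"))
        assert std.a == Fraction(8)
        assert float(std.b) == pytest.approx(95.04)

    def test_short_menu_under_determined_question_raises(self):
        spec = fixture("mammography:short_frequencies")
        bad = ProblemSpec(
            name=spec.name,
            format_variant=spec.format_variant,
            givens=spec.givens,
            question={"metric": "NPV"},  # needs the unknown bottom-row split
            partially_determined=True,
        )
        with pytest.raises(ValueError, match="under-determined"):
            solve(bad)

    @given(probs, probs, probs)
    @settings(max_examples=150, derandomize=True)
    def test_pipeline_equals_closed_form_bayes(self, prior, lpos, lneg):
        """Construct -> conditionalize -> focus agrees with Bayes' theorem
        to 1e-9 on random fully determined probability-format specs."""
        spec = ProblemSpec(
            name="random",
            format_variant="standard_probability",
            givens={
                "prevalence": Given("probability", prior),
                "sensitivity": Given("probability", lpos),
                "false_positive_rate": Given("probability", lneg),
            },
            question={"metric": "PPV"},
        )
        assert solve(spec).value == pytest.approx(
            bayes_invert(prior, lpos, lneg), abs=1e-9
        )

    def test_fixture_registry(self):
        assert "cab" in fixture_names()
        with pytest.raises(KeyError, match="available"):
            fixture("two-envelopes")

    def test_spec_json_round_trip(self):
        spec = fixture("cab")
        assert ProblemSpec.from_dict(spec.to_dict()) == spec

    def test_annotations_are_metadata_only(self):
        spec = fixture("mammography:standard")
        assert spec.annotations["empirical_correct_rate"] == 0.04
        assert solve(spec).value != spec.annotations["modal_wrong_answer"]


class TestMontyHall:
    def test_six_base_cases_two_per_column(self):
        cases = monty_hall("D1", 0.5)
        assert cases.total == 6
        assert cases.column_sums() == (2, 2, 2)
        assert cases.count("D2", "C1") == 1
        assert cases.count("D3", "C1") == 1
        assert cases.count("D3", "C2") == 2
        assert cases.count("D2", "C3") == 2

    def test_chosen_door_row_is_zero(self):
        for choice in ("D1", "D2", "D3"):
            cases = monty_hall(choice, 0.3)
            row = cases.counts[cases.DOORS.index(choice)]
            assert all(v == 0 for v in row)
            assert cases.total == 6

    def test_full_bias_forces_branch(self):
        cases = monty_hall("D1", 1.0)
        assert cases.count("D2", "C1") == 2
        assert cases.count("D3", "C1") == 0

    def test_by_column_conditional_is_uniform_at_even_bias(self):
        table = collapse_monty(monty_hall("D1", 0.5))
        cond = conditionalize(table, "by_column")
        assert all(v == pytest.approx(0.5) for v in cond.cells())

    def test_switching_doubles_the_chances(self):
        table = collapse_monty(monty_hall("D1", 0.5))
        stick, switch = switch_stick_posteriors(table)
        assert stick == pytest.approx(1 / 3)
        assert switch == pytest.approx(2 / 3)

    def test_biased_host_forced_opening_reveals_everything(self):
        # host always prefers D2; if D3 opens anyway, the car must block D2
        table = collapse_monty(monty_hall("D1", 1.0))
        stick, switch = switch_stick_posteriors(table, opened_door="D3")
        assert stick == pytest.approx(0.0)
        assert switch == pytest.approx(1.0)

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=100, derandomize=True)
    def test_posteriors_sum_to_one_for_any_bias(self, bias):
        table = collapse_monty(monty_hall("D1", bias))
        for opened in ("D2", "D3"):
            stick, switch = switch_stick_posteriors(table, opened)
            if is_undefined(stick):
                continue  # extreme bias empties one row
            assert stick + switch == pytest.approx(1.0, abs=1e-9)

    def test_solve_returns_switch_posterior(self):
        assert solve(fixture("monty_hall")).value == pytest.approx(2 / 3)


class TestPredictedErrors:
    def test_cab_both_routes_give_80_percent(self):
        errors = {e.error_id.value: e.predicted_value
                  for e in predict_errors(fixture("cab"))}
        assert errors["E1_false_inputs"] == pytest.approx(0.80)
        assert errors["E2_false_measure"] == pytest.approx(0.80)

    def test_mammography_false_measure_is_sensitivity(self):
        errors = {e.error_id.value: e.predicted_value
                  for e in predict_errors(fixture("mammography:standard"))}
        assert errors["E2_false_measure"] == pytest.approx(0.80)
        assert errors["E1_false_inputs"] == pytest.approx(0.80 / (0.80 + 0.096))

    def test_monty_hall_all_errors_collapse_to_one_half(self):
        errors = predict_errors(fixture("monty_hall"))
        assert len(errors) == 3
        assert all(e.predicted_value == pytest.approx(0.5) for e in errors)

    @pytest.mark.parametrize(
        "name", ["mammography:standard", "cab", "monty_hall"]
    )
    def test_errors_never_equal_the_correct_solution(self, name):
        spec = fixture(name)
        correct = solve(spec).value
        for error in predict_errors(spec):
            assert abs(error.predicted_value - correct) > 1e-6

    def test_partial_problem_rejected(self):
        with pytest.raises(ValueError, match="determined"):
            predict_errors(fixture("mammography:short_frequencies"))


class TestTitanicPolicy:
    def test_rates_and_odds(self, titanic):
        report = titanic_policy_report(titanic)
        assert format_percent(report["survival_rate_priority"].value, 0) == "70%"
        assert format_percent(report["survival_rate_others"].value, 0) == "20%"
        assert format_percent(report["ARR"].value, 0) == "50%"
        assert report["conflict_odds"].value == pytest.approx(338 / 161)
        assert len(report["verdict_notes"]) == 2

    def test_opposite_readings_flagged(self, titanic):
        notes = " ".join(titanic_policy_report(titanic)["verdict_notes"])
        assert "higher absolute rate" in notes
        assert "not" in notes  # the conflict-odds reading disagrees

    def test_no_conflict_cases(self):
        table = problem_table(fixture("titanic"))
        clean = from_counts(int(table.a), 0, 0, int(table.d), table.frame)
        report = titanic_policy_report(clean)
        assert is_undefined(report["conflict_odds"].value)
        assert any("fully satisfied" in n for n in report["verdict_notes"])
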