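"""The metric catalog: values, identities, aliases, and perspective effects."""

import json
import math

import pytest
from scipy.stats import chi2_contingency

from fourfold import (
    Perspective,
    chi_square,
    compute,
    delta_p,
    from_counts,
    is_undefined,
    mcc,
    resolve,
    risk_measures,
)
from fourfold.metrics import MetricDef, catalog, catalog_json
from fourfold.tables import enumerate_layouts


class TestWorkedValues:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("PPV", 8 / 103),
            ("accuracy", 0.903),
            ("sensitivity", 0.80),
            ("specificity", 895 / 990),
            ("bias", 0.103),
            ("prevalence", 0.01),
            ("DOR", (8 * 895) / (95 * 2)),
            ("F1", 2 * 8 / (2 * 8 + 95 + 2)),
            ("LR_plus", 0.80 / (95 / 990)),
            ("NPV", 895 / 897),
        ],
    )
    def test_mammography_metrics(self, mammography, name, expected):
        assert compute(mammography, name).value == pytest.approx(expected)

    def test_undefined_when_margin_empty(self):
        t = from_counts(0, 3, 0, 7)
        value = compute(t, "sensitivity").value
        assert is_undefined(value)
        assert "zero denominator" in value.reason

    def test_zero_cell_odds_ratio_is_infinite(self):
        assert compute(from_counts(5, 0, 3, 7), "DOR").value == math.inf

    def test_zero_over_zero_is_undefined(self):
        assert is_undefined(compute(from_counts(5, 0, 0, 5), "row_odds").value)


class TestDeltaP:
    def test_mammography_by_column(self, mammography):
        assert delta_p(mammography, "by_column").value == pytest.approx(
            0.80 - 95 / 990
        )

    def test_independent_table_has_zero_contingency(self):
        # cells proportional to products of margins: 2x3 outer 4x6
        t = from_counts(8, 12, 16, 24)
        for perspective in ("by_row", "by_column"):
            assert delta_p(t, perspective).value == pytest.approx(0.0, abs=1e-12)

    def test_perfect_association(self):
        t = from_counts(1, 0, 0, 1)
        for perspective in ("by_row", "by_column"):
            assert delta_p(t, perspective).value == pytest.approx(1.0)

    def test_diagonal_perspective_rejected(self, mammography):
        with pytest.raises(ValueError):
            delta_p(mammography, Perspective.BY_DIAGONAL)


class TestChiSquareAndMCC:
    def test_mammography_against_scipy(self, mammography):
        """The deltaP-product score equals the classical (uncorrected)
        chi-square statistic."""
        observed = [[8, 95], [2, 895]]
        oracle = chi2_contingency(observed, correction=False).statistic
        assert chi_square(mammography).value == pytest.approx(oracle, rel=1e-12)
        assert mcc(mammography).value == pytest.approx(
            math.sqrt(oracle / 1000), rel=1e-12
        )

    def test_independent_table(self):
        t = from_counts(8, 12, 16, 24)
        assert chi_square(t).value == pytest.approx(0.0, abs=1e-12)
        assert mcc(t).value == pytest.approx(0.0, abs=1e-12)

    def test_perfect_classifier(self):
        assert mcc(from_counts(1, 0, 0, 1)).value == pytest.approx(1.0)
        assert mcc(from_counts(0, 1, 1, 0)).value == pytest.approx(-1.0)

    def test_zero_margin_undefined(self):
        assert is_undefined(chi_square(from_counts(0, 3, 0, 7)).value)
        assert is_undefined(mcc(from_counts(0, 3, 0, 7)).value)


COMPLEMENT_PAIRS = [
    ("sensitivity", "false_negative_rate"),
    ("specificity", "false_positive_rate"),
    ("PPV", "FDR"),
    ("NPV", "FOR"),
    ("accuracy", "error_rate"),
]


class TestIdentitySuite:
    def test_identities_on_random_tables(self, random_tables):
        """DOR = LR+/LR- = ad/bc; F1 = 2a/(2a+b+c); chi2 via deltaP product
        equals the classical formula; MCC^2 = chi2/N; LR+ = sens/FPR;
        complements sum to one. Checked on 120 seeded tables with
        nonzero margins."""
        for t in random_tables(120):
            a, b, c, d = (float(v) for v in t.cells())
            n = a + b + c + d
            dor = compute(t, "DOR").value
            lr_plus = compute(t, "LR_plus").value
            lr_minus = compute(t, "LR_minus").value
            assert dor == pytest.approx((a * d) / (b * c), rel=1e-9)
            assert dor == pytest.approx(lr_plus / lr_minus, rel=1e-9)
            assert lr_plus == pytest.approx(
                compute(t, "sensitivity").value
                / compute(t, "false_positive_rate").value,
                rel=1e-9,
            )
            assert compute(t, "F1").value == pytest.approx(
                2 * a / (2 * a + b + c), rel=1e-9
            )
            chi = chi_square(t).value
            classical = chi2_contingency([[a, b], [c, d]],
                                         correction=False).statistic
            assert chi == pytest.approx(classical, rel=1e-9, abs=1e-9)
            assert mcc(t).value ** 2 == pytest.approx(chi / n, rel=1e-9, abs=1e-12)
            for name, complement in COMPLEMENT_PAIRS:
                total = compute(t, name).value + compute(t, complement).value
                assert total == pytest.approx(1.0, abs=1e-9)

    def test_relative_risk_formula_matches_lr_plus(self, random_tables):
        for t in random_tables(50, seed=4):
            assert compute(t, "relative_risk").value == pytest.approx(
                compute(t, "LR_plus").value, rel=1e-12
            )


class TestPerspectiveDependence:
    def test_predictive_values_track_prevalence(self, mammography):
        """Rescaling the condition-positive column changes PPV but not
        sensitivity or specificity; DOR survives both row and column
        rescaling."""
        a, b, c, d = mammography.cells()
        shifted = from_counts(a * 10, b, c * 10, d)  # tenfold prevalence
        assert compute(shifted, "PPV").value != pytest.approx(
            compute(mammography, "PPV").value
        )
        for invariant in ("sensitivity", "specificity", "DOR"):
            assert compute(shifted, invariant).value == pytest.approx(
                compute(mammography, invariant).value
            )
        row_scaled = from_counts(a * 3, b * 3, c, d)
        assert compute(row_scaled, "DOR").value == pytest.approx(
            compute(mammography, "DOR").value
        )

    def test_cell_ratio_metrics_layout_invariant(self, mammography):
        """Semantic addressing makes every ratio metric identical across
        the eight spatial arrangements."""
        reference = {
            name: compute(mammography, name).value
            for name in ("PPV", "sensitivity", "accuracy", "prevalence")
        }
        for variant in enumerate_layouts(mammography):
            rebuilt = from_counts(
                variant.cell("C", "T"), variant.cell("nC", "T"),
                variant.cell("C", "nT"), variant.cell("nC", "nT"),
                mammography.frame,
            )
            for name, expected in reference.items():
                assert compute(rebuilt, name).value == pytest.approx(expected)


class TestCatalogAndAliases:
    def test_required_metrics_present(self):
        names = {d.canonical_name for d in catalog()}
        assert names >= {
            "prevalence", "bias", "sensitivity", "specificity",
            "false_positive_rate", "false_negative_rate", "PPV", "NPV",
            "FDR", "FOR", "accuracy", "error_rate", "LR_plus", "LR_minus",
            "DOR", "F1", "chi_square", "MCC", "deltaP_row", "deltaP_col",
            "absolute_risk_exposed", "absolute_risk_unexposed", "ARR",
            "relative_risk", "relative_increase", "NNT", "row_odds",
        }

    @pytest.mark.parametrize(
        "alias, domain, canonical",
        [
            ("recall", "classification", "sensitivity"),
            ("recall", "information_retrieval", "sensitivity"),
            ("precision", "information_retrieval", "PPV"),
            ("odds_ratio", "risk", "DOR"),
            ("TPR", None, "sensitivity"),
        ],
    )
    def test_alias_resolution(self, alias, domain, canonical):
        assert resolve(alias, domain).canonical_name == canonical

    def test_unknown_metric_suggests_near_misses(self, mammography):
        with pytest.raises(KeyError, match="did you mean"):
            compute(mammography, "sensitivty")

    def test_ambiguous_alias_requires_domain(self):
        from fourfold.metrics import _REGISTRY, _register

        _register(
            MetricDef(
                canonical_name="test_only_metric",
                description="synthetic registry entry for the ambiguity path",
                formula_class="cell_ratio",
                numerator=frozenset("a"),
                denominator=frozenset("ab"),
                aliases={"other_domain": ("recall",)},
            )
        )
        try:
            with pytest.raises(ValueError, match="ambiguous"):
                resolve("recall")
            assert resolve("recall", "classification").canonical_name == "sensitivity"
        finally:
            del _REGISTRY["test_only_metric"]

    def test_catalog_export_is_json_serializable(self):
        payload = catalog_json()
        json.dumps(payload)
        by_name = {entry["name"]: entry for entry in payload}
        assert by_name["PPV"]["numerator"] == ["a"]
        assert by_name["PPV"]["denominator"] == ["a", "b"]
        assert by_name["DOR"]["components"] == ["LR_plus", "LR_minus"]


class TestRiskMeasures:
    def test_titanic_panel(self, titanic):
        panel = risk_measures(titanic, "rescue_category", "Alive")
        assert panel["AR_exposed"].value == pytest.approx(373 / 534)
        assert panel["AR_unexposed"].value == pytest.approx(338 / 1667)
        assert panel["ARR"].value == pytest.approx(373 / 534 - 338 / 1667)
        assert panel["row_odds"].value == pytest.approx(338 / 161)

    def test_exposure_on_rows_reorients(self, titanic):
        """Passing the row dimension as exposure transposes the analysis."""
        panel = risk_measures(titanic, "survival", "women_children")
        assert panel["AR_exposed"].value == pytest.approx(373 / 711)

    def test_equal_rate_columns(self):
        panel = risk_measures(from_counts(10, 20, 10, 20),
                              "condition", "T")
        assert panel["ARR"].value == pytest.approx(0.0)
        assert panel["RR"].value == pytest.approx(1.0)

    def test_zero_exposure_column_undefined(self):
        panel = risk_measures(from_counts(0, 5, 0, 5), "condition", "T")
        assert is_undefined(panel["AR_exposed"].value)
        assert is_undefined(panel["ARR"].value)

    def test_unknown_dimension(self, titanic):
        with pytest.raises(KeyError):
            risk_measures(titanic, "class", "Alive")
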