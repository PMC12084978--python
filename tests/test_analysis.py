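"""Test-and-learn arithmetic, conversions, and the GC-stratified analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dopacycle.analysis import (
    BuildRecord,
    StrainResult,
    analysis_report,
    build_records_from_frame,
    convert_mM_to_mg_per_L,
    dopa_accumulation_flags,
    estimate_optimal_expression_ratio,
    fold_change,
    funnel_counts,
    gc_stratified_analysis,
    molar_mass,
    percent_increase,
    report_to_markdown,
    specific_yield,
    success_rate,
)
from dopacycle.errors import InsufficientDataError, ValidationError

from _oracles import DOPAMINE_MASS, LDOPA_MASS, TYROSINE_MASS


class TestScalarOps:
    @pytest.mark.parametrize(
        "num, den, expected",
        [(51, 56, 91.1), (48, 56, 85.7), (0, 56, 0.0), (56, 56, 100.0)],
    )
    def test_success_rate(self, num, den, expected):
        assert success_rate(num, den) == expected

    def test_success_rate_validation(self):
        with pytest.raises(ValidationError):
            success_rate(57, 56)
        with pytest.raises(ValidationError):
            success_rate(1, 0)

    @given(st.integers(0, 200), st.integers(0, 55))
    def test_success_rate_monotone(self, a, b):
        n = 256
        assert success_rate(min(a + b, n), n) >= success_rate(min(a, n), n)

    @pytest.mark.parametrize(
        "new, bench, expected",
        [(69.03, 27.0, 2.6), (34.34, 5.17, 6.6), (3.3, 3.3, 1.0)],
    )
    def test_fold_change(self, new, bench, expected):
        assert fold_change(new, bench) == expected

    @pytest.mark.parametrize(
        "new, old, expected", [(0.83, 0.60, 38.0), (1.0, 1.0, 0.0), (1.5, 1.0, 50.0)]
    )
    def test_percent_increase(self, new, old, expected):
        assert percent_increase(new, old) == expected

    @given(st.floats(0.1, 100.0), st.floats(0.1, 100.0))
    def test_fold_and_percent_consistent(self, new, old):
        fold = fold_change(new, old, rounded=False)
        pct = percent_increase(new, old, rounded=False)
        assert pct == pytest.approx(100.0 * (fold - 1.0))

    def test_validation_of_benchmarks(self):
        with pytest.raises(ValidationError):
            fold_change(1.0, 0.0)
        with pytest.raises(ValidationError):
            percent_increase(1.0, 0.0)


class TestConversions:
    def test_molar_masses_match_hand_sums(self):
        assert molar_mass("dopamine") == pytest.approx(DOPAMINE_MASS)
        assert molar_mass("dopa") == pytest.approx(LDOPA_MASS)
        assert molar_mass("tyrosine") == pytest.approx(TYROSINE_MASS)

    def test_one_mM_dopamine(self):
        assert convert_mM_to_mg_per_L(1.0, "dopamine") == pytest.approx(153.18, abs=0.005)

    def test_five_mM_ldopa(self):
        assert convert_mM_to_mg_per_L(5.0, "dopa") == pytest.approx(985.95, abs=0.005)

    def test_zero_and_unknown(self):
        assert convert_mM_to_mg_per_L(0.0, "tyrosine") == 0.0
        with pytest.raises(ValidationError):
            convert_mM_to_mg_per_L(1.0, "serotonin")

    def test_specific_yield_headline(self):
        # biomass back-computed from the two headline values 69.03 mg/L, 34.34 mg/g
        assert specific_yield(69.03, 69.03 / 34.34) == pytest.approx(34.34)
        assert specific_yield(0.0, 2.0) == 0.0
        assert specific_yield(7.7, 1.0) == 7.7

    @given(st.floats(0.1, 500.0), st.floats(0.1, 10.0), st.floats(0.5, 4.0))
    def test_yield_scales_with_titre(self, titre, biomass, factor):
        assert specific_yield(titre * factor, biomass) == pytest.approx(
            factor * specific_yield(titre, biomass)
        )


def _cohort(rows):
    return pd.DataFrame(
        rows,
        columns=["design_id", "dopamine_mg_per_L", "dopa_mg_per_L", "biomass_g_per_L",
                 "gc_hpaBC", "gc_ddc"],
    )


class TestGCStratifiedAnalysis:
    def test_planted_negative_trend_in_gc_ddc(self):
        """Titre falling in gc_ddc at GC-rich hpaBC: negative direction."""
        rows = [
            (f"s{i}", 80.0 - 60.0 * gc_d, 1.0, 2.0, 0.9, gc_d)
            for i, gc_d in enumerate(np.linspace(0, 1, 8))
        ]
        rows.append(("out", 500.0, 1.0, 2.0, 0.3, 0.5))  # outside band, ignored
        trend = gc_stratified_analysis(_cohort(rows), fixed_context="hpaBC", gc_band=(0.8, 1.0))
        assert trend.direction == "negative"
        assert trend.rank_correlation == pytest.approx(-1.0)
        assert trend.n == 8

    def test_mirrored_positive_trend_in_gc_hpaBC(self):
        """Titre falling as gc_hpaBC falls, at GC-rich ddc: positive direction."""
        rows = [
            (f"s{i}", 10.0 + 55.0 * gc_h, 1.0, 2.0, gc_h, 1.0)
            for i, gc_h in enumerate(np.linspace(0, 1, 8))
        ]
        trend = gc_stratified_analysis(_cohort(rows), fixed_context="ddc", gc_band=(0.8, 1.0))
        assert trend.direction == "positive"
        assert trend.rank_correlation == pytest.approx(1.0)

    def test_flat_titres_report_none(self):
        rows = [(f"s{i}", 5.0, 1.0, 2.0, 0.9, gc) for i, gc in enumerate([0.0, 0.5, 1.0])]
        trend = gc_stratified_analysis(_cohort(rows), fixed_context="hpaBC")
        assert trend.direction == "none"

    def test_insufficient_in_band(self):
        rows = [("a", 1.0, 0.0, 2.0, 0.1, 0.5), ("b", 2.0, 0.0, 2.0, 0.9, 0.5)]
        with pytest.raises(InsufficientDataError):
            gc_stratified_analysis(_cohort(rows), fixed_context="hpaBC")


class TestDopaAccumulation:
    def test_planted_accumulators_flagged_exactly(self):
        rows = [
            ("A.01", 10.0, 25.0, 2.0, 0.5, 0.5),  # ratio 2.5 -> flagged
            ("A.02", 50.0, 5.0, 2.0, 0.5, 0.5),
            ("B.03", 0.0, 3.0, 2.0, 0.5, 0.5),  # no dopamine -> flagged
            ("B.04", 20.0, 0.0, 2.0, 0.5, 0.5),  # no l-DOPA -> never flagged
            ("B.05", 4.0, 8.0, 2.0, 0.5, 0.5),  # ratio 2 -> flagged
        ]
        assert dopa_accumulation_flags(_cohort(rows), threshold_ratio=1.0) == [
            "A.01", "B.03", "B.05",
        ]

    def test_replicates_averaged_before_threshold(self):
        rows = [("X", 10.0, 15.0, 2.0, 0.5, 0.5), ("X", 10.0, 3.0, 2.0, 0.5, 0.5)]
        assert dopa_accumulation_flags(_cohort(rows), threshold_ratio=1.0) == []

    def test_threshold_validated(self):
        with pytest.raises(ValidationError):
            dopa_accumulation_flags(_cohort([]), threshold_ratio=0.0)


class TestBuildRecords:
    def test_stage_ladder_enforced(self):
        with pytest.raises(ValidationError):
            BuildRecord("x", pcr_ok=False, assembled_ok=True, sequence_verified=False)
        with pytest.raises(ValidationError):
            BuildRecord("x", pcr_ok=True, assembled_ok=False, sequence_verified=True)

    def test_funnel_counts(self):
        frame = pd.DataFrame(
            {
                "design_id": ["a", "b", "c"],
                "pcr_ok": [True, True, False],
                "assembled_ok": [True, False, False],
                "sequence_verified": [True, False, False],
            }
        )
        counts = funnel_counts(build_records_from_frame(frame))
        assert counts == {
            "designed": 3, "pcr_ok": 2, "assembled_ok": 1, "sequence_verified": 1,
        }


class TestOptimalRatioEstimator:
    def test_recovers_noise_free_quadratic_vertex(self, rng):
        opt = 2.6
        tir_h = np.exp(rng.uniform(-1, 2, 60))
        tir_d = np.exp(rng.uniform(-1, 2, 60))
        lrho = np.log(tir_h / tir_d)
        titre = np.exp(1.0 + 0.5 * np.log(tir_h) - (lrho - np.log(opt)) ** 2 / 1.3)
        est = estimate_optimal_expression_ratio(tir_h, tir_d, titre)
        assert est == pytest.approx(opt, rel=1e-6)

    def test_convex_response_rejected(self, rng):
        tir_h = np.exp(rng.uniform(-1, 1, 30))
        tir_d = np.exp(rng.uniform(-1, 1, 30))
        titre = np.exp(np.log(tir_h / tir_d) ** 2)  # convex: no interior peak
        with pytest.raises(InsufficientDataError):
            estimate_optimal_expression_ratio(tir_h, tir_d, titre)


class TestReport:
    def test_report_contents(self):
        rows = [
            ("A.01", 60.0, 5.0, 2.0, 1.0, 0.0),
            ("A.02", 30.0, 2.0, 2.0, 0.83, 0.17),
            ("B.01", 10.0, 20.0, 2.0, 0.83, 0.83),
            ("B.02", 5.0, 25.0, 2.0, 0.9, 1.0),
        ]
        builds = pd.DataFrame(
            {
                "design_id": ["A.01", "A.02", "B.01", "B.02"],
                "pcr_ok": [True] * 4,
                "assembled_ok": [True, True, True, False],
                "sequence_verified": [True, True, False, False],
            }
        )
        report = analysis_report(_cohort(rows), build_records_from_frame(builds))
        assert report["designed"] == 4
        assert report["construction_success_rate_pct"] == 75.0
        assert report["sequencing_success_rate_pct"] == 50.0
        assert report["best_design"] == "A.01"
        assert report["titre_fold_vs_benchmark"] == pytest.approx(2.2)
        assert report["dopa_accumulating_designs"] == ["B.01", "B.02"]
        text = report_to_markdown(report)
        assert "A.01" in text and "75.0%" in text

    def test_strain_result_validation(self):
        with pytest.raises(ValidationError):
            StrainResult("x", -1.0, 0.0, 2.0, 0.5, 0.5)
        with pytest.raises(ValidationError):
            StrainResult("x", 1.0, 0.0, 0.0, 0.5, 0.5)
        with pytest.raises(ValidationError):
            StrainResult("x", 1.0, 0.0, 2.0, 1.5, 0.5)
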