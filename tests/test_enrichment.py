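"""Enrichment-factor statistic, filters, labeling calls and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rrnasip.enrichment import (
    EmptyFractionError,
    abundance_filter,
    analyze_gradients,
    call_labeled,
    compute_ef,
    display_value,
    enrichment_table,
    relative_abundance,
    summarize_labels,
)
from tests.conftest import make_gradient


class TestRelativeAbundance:
    @pytest.mark.parametrize(
        "counts,pseudocount,expected",
        [
            ([10, 30], 0, [0.25, 0.75]),
            ([5], 3, [1.0]),
            ([0, 100], 1, [1 / 102, 101 / 102]),
        ],
    )
    def test_worked_examples(self, counts, pseudocount, expected):
        np.testing.assert_allclose(relative_abundance(counts, pseudocount), expected)

    def test_empty_fraction_raises(self):
        with pytest.raises(EmptyFractionError):
            relative_abundance([0, 0, 0], pseudocount=1)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            relative_abundance([3, -1])


class TestComputeEf:
    @pytest.mark.parametrize(
        "inputs,expected",
        [
            ((0.40, 0.10, 0.10, 0.10), 3.0),
            ((0.2, 0.2, 0.2, 0.2), 0.0),
            ((0.05, 0.10, 0.10, 0.10), -0.5),
        ],
    )
    def test_worked_examples(self, inputs, expected):
        assert compute_ef(*inputs) == pytest.approx(expected)

    def test_zero_light_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            compute_ef(0.4, 0.0, 0.1, 0.1)

    @settings(derandomize=True, max_examples=200)
    @given(
        h13=st.floats(0.0, 1.0),
        l13=st.floats(0.01, 1.0),
        h12=st.floats(0.0, 1.0),
        l12=st.floats(0.01, 1.0),
    )
    def test_antisymmetry_under_isotope_swap(self, h13, l13, h12, l12):
        ef = compute_ef(h13, l13, h12, l12)
        assert compute_ef(h12, l12, h13, l13) == pytest.approx(-ef, abs=1e-12)


class TestAbundanceFilter:
    def test_retained_when_any_cell_exceeds_threshold(self):
        kept = abundance_filter({"t": [0.01, 0.03]}, threshold=0.02)
        assert kept == ["t"]

    def test_boundary_is_strict(self):
        assert abundance_filter({"t": [0.02, 0.02]}, threshold=0.02) == []

    def test_protist_exempt_regardless_of_abundance(self):
        kept = abundance_filter(
            {"p": [0.001]}, threshold=0.02, groups={"p": "protist"}
        )
        assert kept == ["p"]


class TestCallLabeled:
    @pytest.mark.parametrize(
        "efs,expected",
        [([0.6, -0.2], True), ([0.5], False), ([-0.1, 0.0, 0.49], False)],
    )
    def test_any_cell_rule_with_strict_threshold(self, efs, expected):
        assert call_labeled(efs) is expected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            call_labeled([])


class TestDisplayValue:
    def test_log10_of_positive_ef(self):
        assert display_value(3.0) == pytest.approx(0.4771, abs=1e-4)
        assert display_value(1.0) == 0.0

    def test_negative_ef_floored_when_labeled_elsewhere(self):
        assert display_value(-0.5, labeled_elsewhere=True) == -1.5

    def test_tiny_positive_ef_floored(self):
        assert display_value(1e-6) == -1.5


def _paired_tables(counts13, counts12):
    t13 = make_gradient(counts13, isotope="13C")
    t12 = make_gradient(counts12, isotope="12C")
    return t13, t12


class TestEnrichmentTable:
    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = rng.integers(2, 11)
            names = [f"t{i}" for i in range(n)]
            c13 = {t: rng.integers(0, 500, size=2).tolist() for t in names}
            c12 = {t: rng.integers(0, 500, size=2).tolist() for t in names}
            t13, t12 = _paired_tables(c13, c12)
            tab = enrichment_table(t13, t12, pseudocount=1)
            # independent per-taxon recomputation from raw counts
            s13h = sum(v[0] + 1 for v in c13.values())
            s13l = sum(v[1] + 1 for v in c13.values())
            s12h = sum(v[0] + 1 for v in c12.values())
            s12l = sum(v[1] + 1 for v in c12.values())
            for t in names:
                expected = ((c13[t][0] + 1) / s13h) / ((c13[t][1] + 1) / s13l) - (
                    (c12[t][0] + 1) / s12h
                ) / ((c12[t][1] + 1) / s12l)
                assert tab.loc[t, "ef"] == pytest.approx(expected, rel=1e-12)

    def test_null_invariance_identical_tables_give_zero_ef(self):
        counts = {"a": [120, 80], "b": [30, 70], "c": [50, 50]}
        t13, t12 = _paired_tables(counts, counts)
        tab = enrichment_table(t13, t12)
        np.testing.assert_array_equal(tab["ef"].to_numpy(), 0.0)

    def test_scale_invariance_with_zero_pseudocount(self):
        rng = np.random.default_rng(3)
        counts13 = {f"t{i}": (rng.integers(1, 200, 2)).tolist() for i in range(6)}
        counts12 = {f"t{i}": (rng.integers(1, 200, 2)).tolist() for i in range(6)}
        t13, t12 = _paired_tables(counts13, counts12)
        scaled13 = {k: [7 * x for x in v] for k, v in counts13.items()}
        scaled12 = {k: [7 * x for x in v] for k, v in counts12.items()}
        s13, s12 = _paired_tables(scaled13, scaled12)
        a = enrichment_table(t13, t12, pseudocount=0)["ef"]
        b = enrichment_table(s13, s12, pseudocount=0)["ef"]
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), rtol=1e-12)

    def test_taxon_missing_from_control_treated_as_zero_count(self):
        t13 = make_gradient({"a": [90, 10], "b": [10, 90]}, isotope="13C")
        t12 = make_gradient({"a": [50, 50]}, isotope="12C")
        tab = enrichment_table(t13, t12)
        # b absent from control: counts 0, pseudocounted to 1 in both fractions
        assert tab.loc["b", "c12_heavy"] == pytest.approx(tab.loc["b", "c12_light"])

    def test_mismatched_pairing_rejected(self):
        t13 = make_gradient({"a": [1, 1]}, isotope="13C", substrate="glucose")
        t12 = make_gradient({"a": [1, 1]}, isotope="12C", substrate="cellulose")
        with pytest.raises(ValueError, match="share substrate"):
            enrichment_table(t13, t12)


class TestAnalyzeAndSummarize:
    def _records(self):
        c13 = {
            "hot": [400, 40],  # strong heavy enrichment
            "warm": [60, 45],
            "cold": [40, 400],
        }
        c12 = {"hot": [40, 40], "warm": [45, 45], "cold": [40, 400]}
        pairs = [
            _paired_tables(c13, c12),
            (
                make_gradient(c12, isotope="13C", timepoint="32d"),
                make_gradient(c12, isotope="12C", timepoint="32d"),
            ),
        ]
        return analyze_gradients(pairs, groups={"hot": "bacteria", "cold": "fungi"})

    def test_labeling_call_propagates_across_cells(self):
        rec = self._records()
        hot = rec[rec["taxon"] == "hot"]
        assert hot["labeled"].all()  # labeled at 8d -> taxon labeled everywhere
        assert (hot[hot["timepoint"] == "8d"]["ef"] > 0.5).all()

    def test_unlabeled_taxa_have_nan_display(self):
        rec = self._records()
        cold = rec[rec["taxon"] == "cold"]
        assert not cold["labeled"].any()
        assert cold["display_value"].isna().all()

    def test_summary_matrix_marks(self):
        rec = self._records()
        matrix = summarize_labels(rec)
        row = matrix.loc[("bacteria", "hot")]
        assert row[("glucose", "8d")] == "++"  # EF>0.5 and heavy abundance >= 0.10
        assert row[("glucose", "32d")] == ""  # identical tables at 32d: EF 0
        assert ("fungi", "cold") not in matrix.index

    def test_summary_requires_complete_cells(self):
        rec = self._records()
        broken = rec.drop(rec[(rec["taxon"] == "hot") & (rec["timepoint"] == "32d")].index)
        with pytest.raises(ValueError, match="incomplete"):
            summarize_labels(broken)

    def test_plus_mark_for_weakly_abundant_labeled_cell(self):
        rec = pd.DataFrame(
            {
                "taxon": ["x", "x"],
                "group": ["bacteria"] * 2,
                "substrate": ["glucose"] * 2,
                "timepoint": ["8d", "32d"],
                "ef": [0.8, 0.1],
                "heavy_abundance": [0.05, 0.05],
                "labeled": [True, True],
            }
        )
        matrix = summarize_labels(rec)
        assert matrix.loc[("bacteria", "x"), ("glucose", "8d")] == "+"
        assert matrix.loc[("bacteria", "x"), ("glucose", "32d")] == ""
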