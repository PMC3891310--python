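"""Metrics arithmetic, nested vs biased LOOCV, and the permutation test."""

import math

import numpy as np
import pytest

from gwps import (
    ConfusionMatrix,
    LabelVector,
    SimulationConfig,
    biased_loocv,
    majority_baseline,
    metrics,
    nested_loocv,
    permutation_test,
    simulate,
)
from conftest import make_gm, make_labels


class TestMetrics:
    def test_published_cohort_confusion_matrix(self):
        # 623-subject cohort: 302 cases (187 called case), 321 controls (184 called control)
        m = metrics(ConfusionMatrix(tp=187, fn=115, fp=137, tn=184)).as_percent()
        assert m["accuracy"] == 59.55
        assert m["sensitivity"] == 61.92
        assert m["specificity"] == 57.32
        assert m["precision"] == 57.72  # = 187/324

    def test_published_validation_confusion_matrix(self):
        # 2287-subject validation cohort
        m = metrics(ConfusionMatrix(tp=683, fn=462, fp=447, tn=695)).as_percent()
        assert m["accuracy"] == 60.25
        assert m["precision"] == 60.44
        assert m["sensitivity"] == 59.65
        assert m["specificity"] == 60.86

    def test_perfect_classifier(self):
        m = metrics(ConfusionMatrix(tp=40, fn=0, fp=0, tn=40)).as_percent()
        assert all(v == 100.0 for v in m.values())

    def test_undefined_ratios_are_nan_not_zero(self):
        m = metrics(ConfusionMatrix(tp=0, fn=0, fp=0, tn=10))
        assert math.isnan(m.precision) and math.isnan(m.sensitivity)
        assert m.specificity == 1.0 and m.accuracy == 1.0

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError):
            metrics(ConfusionMatrix(0, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fn=0, fp=0, tn=0)


class TestMajorityBaseline:
    def test_cohort_baselines(self):
        lv = make_labels([1] * 302 + [0] * 321)
        assert round(majority_baseline(lv) * 100, 2) == 51.52
        lv = make_labels([1] * 1145 + [0] * 1142)
        assert round(majority_baseline(lv) * 100, 2) == 50.07
        lv = make_labels([1] * 50 + [0] * 50)
        assert majority_baseline(lv) == 0.5


@pytest.fixture(scope="module")
def small_signal():
    return simulate(
        SimulationConfig(
            n_cases=20, n_controls=20, n_snps=120,
            n_effect_snps=20, effect_delta=0.45, seed=33,
        )
    )


class TestNestedLoocv:
    def test_fold_count_partitions_cohort(self, small_signal):
        ds = small_signal
        res = nested_loocv(ds.genotypes, ds.labels, m=20, seed=1)
        assert len(res.fold_records) == 40
        assert res.cm.total == 40
        assert res.cm.tp + res.cm.fn == ds.labels.n_cases
        assert res.cm.fp + res.cm.tn == ds.labels.n_controls
        assert res.mode == "nested"

    def test_metrics_recompute_from_stored_cm(self, small_signal):
        ds = small_signal
        res = nested_loocv(ds.genotypes, ds.labels, m=20, seed=1)
        m = metrics(res.cm)
        assert (m.accuracy, m.precision, m.sensitivity, m.specificity) == (
            res.accuracy, res.precision, res.sensitivity, res.specificity,
        )

    def test_determinism(self, small_signal):
        ds = small_signal
        a = nested_loocv(ds.genotypes, ds.labels, m=20, seed=5)
        b = nested_loocv(ds.genotypes, ds.labels, m=20, seed=5)
        assert a.accuracy == b.accuracy
        assert [f["predicted"] for f in a.fold_records] == [
            f["predicted"] for f in b.fold_records
        ]

    def test_held_out_genotypes_do_not_leak_into_selection(self, small_signal):
        """Changing subject 0's genotypes must not change the SNP panel or k
        used by the fold that holds subject 0 out."""
        from gwps import GenotypeMatrix

        ds = small_signal
        res1 = nested_loocv(ds.genotypes, ds.labels, m=20, seed=2)
        values = ds.genotypes.values.copy()
        values[0] = np.where(values[0] == 1, 3, 1)
        gm2 = GenotypeMatrix(values, ds.genotypes.snp_ids, ds.genotypes.subject_ids)
        res2 = nested_loocv(gm2, ds.labels, m=20, seed=2)
        assert res1.fold_records[0]["selected_snp_ids"] == res2.fold_records[0]["selected_snp_ids"]
        assert res1.fold_records[0]["chosen_k"] == res2.fold_records[0]["chosen_k"]

    def test_class_size_guard(self):
        gm = make_gm(np.random.default_rng(0).integers(1, 4, size=(15, 10)))
        labels = make_labels([1] * 5 + [0] * 10)
        with pytest.raises(ValueError):
            nested_loocv(gm, labels, m=5, r=10)


class TestBiasedLoocv:
    def test_mode_flag_and_report_warning(self, small_signal):
        ds = small_signal
        res = biased_loocv(ds.genotypes, ds.labels, m=20, seed=1)
        assert res.mode == "biased"
        assert "biased" in res.report()

    def test_vacuous_selection_equals_nested(self, small_signal):
        """With m = all SNPs the selection step cannot leak anything, so the
        biased and nested procedures coincide exactly (same seeds, same folds)."""
        ds = small_signal
        m_all = ds.genotypes.n_snps
        a = nested_loocv(ds.genotypes, ds.labels, m=m_all, seed=4)
        b = biased_loocv(ds.genotypes, ds.labels, m=m_all, seed=4)
        assert a.accuracy == b.accuracy
        assert [f["predicted"] for f in a.fold_records] == [
            f["predicted"] for f in b.fold_records
        ]

    def test_biased_exceeds_nested_on_null_high_dimensional_data(self):
        # small version of the selection-bias demonstration (full size in acceptance)
        ds = simulate(SimulationConfig(n_cases=30, n_controls=30, n_snps=2000, seed=41))
        b = biased_loocv(ds.genotypes, ds.labels, m=100, seed=6)
        n = nested_loocv(ds.genotypes, ds.labels, m=100, seed=6)
        assert b.accuracy - n.accuracy >= 0.15


class TestPermutationTest:
    def test_strong_signal_reaches_minimal_p(self, small_signal):
        ds = small_signal
        res = permutation_test(ds.genotypes, ds.labels, m=20, B=19, seed=8)
        assert res.observed_accuracy >= 0.9
        assert res.exceed_count == 0
        assert res.p_value == pytest.approx(1 / 20)

    def test_p_value_formula_and_range(self, small_signal):
        ds = small_signal
        res = permutation_test(ds.genotypes, ds.labels, m=20, B=19, seed=8)
        assert res.p_value == (res.exceed_count + 1) / (res.B + 1)
        assert 0 < res.p_value <= 1

    def test_invalid_b_raises(self, small_signal):
        ds = small_signal
        with pytest.raises(ValueError):
            permutation_test(ds.genotypes, ds.labels, m=20, B=0)
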