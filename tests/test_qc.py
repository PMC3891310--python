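"""Quality-control filters: MAF, HWE chi-square, and the combined one-pass filter."""

import numpy as np
import pytest

from gwps import (
    EmptyControlsError,
    EmptyPanelError,
    MafUndefinedError,
    SimulationConfig,
    apply_qc,
    hwe_test,
    minor_allele_frequency,
    simulate,
)
from conftest import make_gm, make_labels


class TestMinorAlleleFrequency:
    @pytest.mark.parametrize(
        "codes,expected",
        [
            ([1, 1, 1, 1], 0.0),           # monomorphic wild type
            ([1, 2, 3, 2], 0.5),           # 0+1+2+1 = 4 variant alleles of 8
            ([3, 3, 3, 3], 0.0),           # variant is the major allele
            ([1, 1, 1, 2], 0.125),
            ([1, 0, 2, 0], 0.25),          # missing calls drop from the denominator
        ],
    )
    def test_hand_counted_examples(self, codes, expected):
        assert minor_allele_frequency(codes) == pytest.approx(expected)

    def test_all_missing_column_is_undefined(self):
        with pytest.raises(MafUndefinedError):
            minor_allele_frequency([0, 0, 0])

    def test_always_in_folded_range(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            col = rng.integers(1, 4, size=rng.integers(1, 30))
            assert 0.0 <= minor_allele_frequency(col) <= 0.5


class TestHweTest:
    def test_exact_hwe_proportions_give_zero_statistic(self):
        col = [1] * 25 + [2] * 50 + [3] * 25
        chi2, p = hwe_test(col)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_total_heterozygote_deficit(self):
        # observed (50, 0, 50) vs expected (25, 50, 25): chi2 = 25+50+25 = 100
        col = [1] * 50 + [3] * 50
        chi2, p = hwe_test(col)
        assert chi2 == pytest.approx(100.0)
        assert p < 1e-20

    def test_monomorphic_column_passes(self):
        chi2, p = hwe_test([1] * 100)
        assert (chi2, p) == (0.0, 1.0)
        chi2, p = hwe_test([3] * 40)
        assert (chi2, p) == (0.0, 1.0)

    def test_empty_controls_error(self):
        with pytest.raises(EmptyControlsError):
            hwe_test([0, 0])


class TestApplyQC:
    def test_clean_hwe_matrix_survives_entirely(self):
        rng = np.random.default_rng(3)
        q = 0.3
        gm = make_gm(rng.choice([1, 2, 3], p=[(1-q)**2, 2*q*(1-q), q**2], size=(400, 50)))
        labels = make_labels([1] * 200 + [0] * 200)
        filtered, report = apply_qc(gm, labels)
        assert report.n_surviving == 50
        assert list(filtered.snp_ids) == list(gm.snp_ids)

    def test_single_missing_call_is_absolute(self):
        # perfect HWE and common MAF, but one missing call: removed regardless
        col = [1] * 25 + [2] * 50 + [3] * 25
        values = np.array([col, col]).T
        values[0, 1] = 0
        gm = make_gm(values)
        labels = make_labels([1] * 50 + [0] * 50)
        filtered, report = apply_qc(gm, labels)
        assert report.failed_by("missing") == ["snp1"]
        assert list(filtered.snp_ids) == ["snp0"]
        # diagnostics still computed on the available calls
        row = report.table.set_index("snp_id").loc["snp1"]
        assert np.isfinite(row["maf"]) and np.isfinite(row["hwe_p"])
        assert row["failed_filters"] == "missing"

    def test_planted_violations_are_removed(self):
        ds = simulate(
            SimulationConfig(
                n_cases=1000, n_controls=1000, n_snps=500,
                maf_range=(0.1, 0.5),
                n_hwe_violating=10, hwe_inbreeding_f=0.8,
                n_low_maf=10, low_maf_value=0.01,
                n_missing_snps=10, missing_rate=0.05, seed=23,
            )
        )
        filtered, report = apply_qc(ds.genotypes, ds.labels)
        assert set(ds.missing_snps) == set(report.failed_by("missing"))
        # power-dependent filters: at n=2000 nearly all planted violations caught
        assert len(set(ds.low_maf_snps) & set(report.failed_by("maf"))) >= 9
        assert len(set(ds.hwe_violating_snps) & set(report.failed_by("hwe"))) >= 9

    def test_boundary_maf_exactly_five_percent_survives(self):
        # 40 subjects, 4 variant alleles of 80 -> MAF exactly 0.05
        col = [2] * 4 + [1] * 36
        hwe_ok = [1] * 10 + [2] * 20 + [3] * 10
        gm = make_gm(np.array([col, hwe_ok]).T)
        labels = make_labels([1] * 20 + [0] * 20)
        _, strict = apply_qc(gm, labels, hwe_alpha=1e-6)
        assert "snp0" in strict.surviving_snp_ids
        _, inclusive = apply_qc(gm, labels, hwe_alpha=1e-6, maf_strict=False)
        assert "snp0" not in inclusive.surviving_snp_ids

    def test_idempotence(self, planted_dataset):
        ds = planted_dataset
        filtered, _ = apply_qc(ds.genotypes, ds.labels)
        refiltered, report2 = apply_qc(filtered, ds.labels)
        assert list(refiltered.snp_ids) == list(filtered.snp_ids)
        assert report2.n_failed == 0

    def test_counts_partition_the_input(self, planted_dataset):
        ds = planted_dataset
        _, report = apply_qc(ds.genotypes, ds.labels)
        assert report.n_surviving + report.n_failed == ds.genotypes.n_snps

    def test_all_snps_removed_raises_empty_panel(self):
        values = np.zeros((10, 3), dtype=np.int8)
        values[0] = [1, 1, 1]  # every column has missing calls
        gm = make_gm(values)
        labels = make_labels([1] * 5 + [0] * 5)
        with pytest.raises(EmptyPanelError):
            apply_qc(gm, labels)

    def test_no_controls_raises(self):
        gm = make_gm([[1, 2], [2, 3]])
        with pytest.raises(EmptyControlsError):
            apply_qc(gm, make_labels([1, 1]))
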