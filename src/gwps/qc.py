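"""SNP-level quality control: missing calls, HWE in controls, minor allele frequency.

Three filters, applied in a single pass over the input matrix:

1. any missing call anywhere removes the SNP unconditionally;
2. a Pearson chi-square (1 df) Hardy-Weinberg test in controls with
   p below ``hwe_alpha`` (default 0.001) removes the SNP;
3. minor allele frequency below ``maf_min`` (default 0.05, strict
   inequality: exactly 5% survives) removes the SNP.

MAF is computed over all subjects by default (the common GWAS QC
convention); HWE is always assessed in controls.  For a SNP that fails
the missingness filter, MAF and HWE statistics are still computed on
the available calls for diagnostics, but only "missing" is recorded as
its failure — the other filters are not adjudicated for it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gwps.datatypes import MISSING, GenotypeMatrix, LabelVector
from gwps.exceptions import EmptyControlsError, EmptyPanelError, MafUndefinedError

__all__ = ["QCReport", "minor_allele_frequency", "hwe_test", "apply_qc"]


def minor_allele_frequency(column) -> float:
    """Minor allele frequency of one genotype column.

    Codes contribute 0/1/2 variant alleles for 1/2/3; the frequency of
    the rarer allele among ``2 x (non-missing subjects)`` chromosomes is
    returned, so the result is in [0, 0.5].
    """
    col = np.asarray(column)
    called = col[col != MISSING]
    if called.size == 0:
        raise MafUndefinedError("MAF is undefined for an all-missing genotype column")
    f_variant = float((called - 1).sum()) / (2.0 * called.size)
    return min(f_variant, 1.0 - f_variant)


def hwe_test(column) -> tuple:
    """Pearson chi-square (1 df) Hardy-Weinberg test on one genotype column.

    The column should already be restricted to control subjects.
    Observed genotype counts are compared with the HWE expectation at
    the estimated allele frequency.  Monomorphic columns return
    ``(0.0, 1.0)``.
    """
    col = np.asarray(column)
    called = col[col != MISSING]
    if called.size == 0:
        raise EmptyControlsError(
            "HWE must be assessed in controls, but no called control genotypes were given"
        )
    n = called.size
    n2 = int((called == 2).sum())
    n3 = int((called == 3).sum())
    q = (n2 + 2 * n3) / (2.0 * n)
    if q == 0.0 or q == 1.0:
        return 0.0, 1.0
    expected = np.array([n * (1 - q) ** 2, n * 2 * q * (1 - q), n * q**2])
    observed = np.array([n - n2 - n3, n2, n3], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


@dataclass
class QCReport:
    """Per-SNP filter outcomes and the surviving SNP set.

    ``table`` has one row per input SNP with columns ``snp_id``,
    ``n_missing``, ``maf``, ``hwe_chi2``, ``hwe_p``, the boolean
    ``fail_missing`` / ``fail_hwe`` / ``fail_maf`` flags and a
    ``failed_filters`` summary string.
    """

    table: pd.DataFrame

    @property
    def surviving_snp_ids(self) -> list:
        keep = ~(
            self.table["fail_missing"]
            | self.table["fail_hwe"]
            | self.table["fail_maf"]
        )
        return list(self.table.loc[keep, "snp_id"])

    @property
    def n_surviving(self) -> int:
        return len(self.surviving_snp_ids)

    @property
    def n_failed(self) -> int:
        return len(self.table) - self.n_surviving

    def failed_by(self, filter_name: str) -> list:
        """SNP ids that failed one named filter ('missing', 'hwe' or 'maf')."""
        col = {"missing": "fail_missing", "hwe": "fail_hwe", "maf": "fail_maf"}[filter_name]
        return list(self.table.loc[self.table[col], "snp_id"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _column_stats(values: np.ndarray, control_mask: np.ndarray):
    """Vectorised per-SNP missingness, MAF (all subjects) and HWE (controls)."""
    called = values != MISSING
    n_missing = (~called).sum(axis=0)

    variant_alleles = np.where(called, values - 1, 0).sum(axis=0, dtype=np.int64)
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_variant = variant_alleles / (2.0 * n_called)
    maf = np.minimum(f_variant, 1.0 - f_variant)
    maf[n_called == 0] = np.nan

    ctrl = values[control_mask]
    ctrl_called = ctrl != MISSING
    nc = ctrl_called.sum(axis=0)
    c2 = ((ctrl == 2)).sum(axis=0)
    c3 = ((ctrl == 3)).sum(axis=0)
    c1 = nc - c2 - c3
    with np.errstate(invalid="ignore", divide="ignore"):
        q = (c2 + 2.0 * c3) / (2.0 * nc)
        e1 = nc * (1 - q) ** 2
        e2 = nc * 2 * q * (1 - q)
        e3 = nc * q**2
        chi2 = (c1 - e1) ** 2 / e1 + (c2 - e2) ** 2 / e2 + (c3 - e3) ** 2 / e3
    mono = (q == 0.0) | (q == 1.0)
    chi2 = np.where(mono, 0.0, chi2)
    hwe_p = stats.chi2.sf(chi2, df=1)
    hwe_p = np.where(mono, 1.0, hwe_p)
    chi2[nc == 0] = np.nan
    hwe_p[nc == 0] = np.nan
    return n_missing, maf, chi2, hwe_p


def apply_qc(
    gm: GenotypeMatrix,
    labels: LabelVector,
    maf_min: float = 0.05,
    hwe_alpha: float = 0.001,
    maf_strict: bool = True,
) -> tuple:
    """Apply the three SNP filters and return (filtered matrix, QCReport).

    Filters are evaluated on the original matrix in one pass (no
    re-estimation after removals) and independently of each other,
    except that a SNP with any missing call fails on missingness alone.
    ``maf_strict=True`` removes a SNP iff its MAF is strictly below
    ``maf_min`` (a MAF of exactly ``maf_min`` survives); ``False`` makes
    the boundary fail as well.

    Raises
    ------
    EmptyControlsError
        If there are no control subjects (HWE cannot be assessed).
    EmptyPanelError
        If no SNP survives all three filters.
    """
    labels.check_aligned(gm)
    control_mask = labels.y == 0
    if not control_mask.any():
        raise EmptyControlsError("QC requires at least one control subject for the HWE filter")

    n_missing, maf, chi2, hwe_p = _column_stats(gm.values, control_mask)

    fail_missing = n_missing > 0
    with np.errstate(invalid="ignore"):
        if maf_strict:
            maf_low = maf < maf_min
        else:
            maf_low = maf <= maf_min
        hwe_dev = hwe_p < hwe_alpha
    # Missing-call SNPs fail on missingness alone; stats stay diagnostic.
    fail_hwe = hwe_dev & ~fail_missing
    fail_maf = maf_low & ~fail_missing

    failed_filters = []
    for m_, h_, f_ in zip(fail_missing, fail_hwe, fail_maf):
        tags = [t for t, flag in (("missing", m_), ("hwe", h_), ("maf", f_)) if flag]
        failed_filters.append(",".join(tags))

    table = pd.DataFrame(
        {
            "snp_id": gm.snp_ids,
            "n_missing": n_missing.astype(int),
            "maf": maf,
            "hwe_chi2": chi2,
            "hwe_p": hwe_p,
            "fail_missing": fail_missing,
            "fail_hwe": fail_hwe,
            "fail_maf": fail_maf,
            "failed_filters": failed_filters,
        }
    )
    report = QCReport(table)

    keep = ~(fail_missing | fail_hwe | fail_maf)
    if not keep.any():
        raise EmptyPanelError("quality control removed every SNP; nothing left to analyse")
    filtered = gm.subset_snps(np.flatnonzero(keep))
    return filtered, report
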