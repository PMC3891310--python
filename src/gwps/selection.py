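"""MeanDiff univariate feature ranking and top-m SNP selection.

The MeanDiff score of a SNP is the absolute difference between the mean
genotype code of the cases and the mean genotype code of the controls:
``|mu_case - mu_control|``.  It is zero for an irrelevant SNP, grows
with the between-class allele-frequency gap, and for codes in {1,2,3}
is bounded by 2.  Selection keeps the m largest scores; ties at the
selection boundary are broken by ascending SNP index so the selected
set is deterministic across runs and platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from gwps.datatypes import MISSING, GenotypeMatrix, LabelVector
from gwps.exceptions import SingleClassError

__all__ = ["FeatureRanking", "meandiff", "meandiff_scores", "select_top_m"]


def meandiff_scores(values: np.ndarray, y: np.ndarray) -> np.ndarray:
    """MeanDiff score for every column of a subjects x SNPs matrix.

    ``y`` is the 1 = case / 0 = control coding.  Inputs must be fully
    called: quality control guarantees no missing values reach ranking.
    """
    values = np.asarray(values)
    y = np.asarray(y)
    case_mask = y == 1
    if not case_mask.any() or case_mask.all():
        raise SingleClassError("MeanDiff needs both cases and controls")
    if values.size and values.min() == MISSING:
        raise ValueError("MeanDiff input contains missing calls; run QC first")
    mu_case = values[case_mask].mean(axis=0)
    mu_ctrl = values[~case_mask].mean(axis=0)
    return np.abs(mu_case - mu_ctrl)


def meandiff(column, labels: LabelVector) -> float:
    """MeanDiff score of a single genotype column."""
    col = np.asarray(column).reshape(-1, 1)
    return float(meandiff_scores(col, labels.y)[0])


@dataclass
class FeatureRanking:
    """Scores for every candidate SNP plus the selected top-m subset."""

    snp_ids: np.ndarray
    scores: np.ndarray
    selected_index: np.ndarray  # positions into snp_ids, ranking order
    m: int

    @property
    def selected_ids(self) -> list:
        return [str(s) for s in self.snp_ids[self.selected_index]]

    def to_frame(self):
        import pandas as pd

        sel = np.zeros(len(self.snp_ids), dtype=bool)
        sel[self.selected_index] = True
        return pd.DataFrame(
            {"snp_id": self.snp_ids, "meandiff": self.scores, "selected": sel}
        )


def select_top_m(gm: GenotypeMatrix, labels: LabelVector, m: int = 500) -> FeatureRanking:
    """Rank every SNP by MeanDiff and select the m largest.

    Ranking order is by descending score, then ascending SNP index for
    exact-score ties (scores arise from small-integer rational
    arithmetic, so exact float ties are meaningful).  If m exceeds the
    number of SNPs it is clamped with a warning.
    """
    if gm.n_snps == 0:
        raise ValueError("cannot rank an empty genotype matrix")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    labels.check_aligned(gm)
    if m > gm.n_snps:
        warnings.warn(
            f"m={m} exceeds the {gm.n_snps} available SNPs; clamping",
            stacklevel=2,
        )
        m = gm.n_snps
    scores = meandiff_scores(gm.values, labels.y)
    order = np.lexsort((np.arange(len(scores)), -scores))
    return FeatureRanking(gm.snp_ids, scores, order[:m], m)
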