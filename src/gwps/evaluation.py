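"""Nested LOOCV, the biased non-nested variant, metrics, and permutation testing.

Leave-one-out cross-validation of the full select-then-fit procedure:
for each subject j the whole BestKNN pipeline — MeanDiff feature
selection AND internal k-selection — is re-run on the other N-1
subjects, and the resulting classifier predicts j.  Running feature
selection once on the full dataset before cross-validating ("biased"
mode) leaks held-out information into the SNP panel and inflates the
apparent accuracy dramatically when the SNP count far exceeds the
subject count; both modes are provided so the gap itself can be
measured.  Statistical significance of an observed accuracy is
assessed by a label-permutation test that repeats the complete
"permute, learn, evaluate" pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from gwps.bestknn import DEFAULT_K_GRID, best_knn_fit
from gwps.datatypes import GenotypeMatrix, LabelVector
from gwps.selection import select_top_m

__all__ = [
    "ConfusionMatrix",
    "Metrics",
    "EvalResult",
    "PermutationResult",
    "metrics",
    "majority_baseline",
    "nested_loocv",
    "biased_loocv",
    "permutation_test",
    "m_sweep",
]


def _pct(x: float) -> float:
    """Proportion -> percentage rounded half-up to 2 decimal places."""
    if x != x:  # NaN stays NaN
        return float("nan")
    return float(Decimal(repr(x * 100)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """2x2 counts: rows are actual case/control, columns predicted case/control."""

    tp: int  # actual case, predicted case
    fn: int  # actual case, predicted control
    fp: int  # actual control, predicted case
    tn: int  # actual control, predicted control

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative count {name}")

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if y_true.shape != y_pred.shape:
            raise ValueError("prediction / truth length mismatch")
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        )

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __str__(self) -> str:
        w = max(len(str(v)) for v in (self.tp, self.fn, self.fp, self.tn))
        return (
            "                 Predicted\n"
            f"                 {'Case':>{w + 2}} {'Control':>{w + 2}}\n"
            f"Actual Case      {self.tp:>{w + 2}} {self.fn:>{w + 2}}\n"
            f"Actual Control   {self.fp:>{w + 2}} {self.tn:>{w + 2}}"
        )


@dataclass
class Metrics:
    """Derived classification metrics; undefined ratios are NaN, never 0."""

    accuracy: float
    precision: float
    sensitivity: float
    specificity: float

    def as_percent(self) -> dict:
        return {
            "accuracy": _pct(self.accuracy),
            "precision": _pct(self.precision),
            "sensitivity": _pct(self.sensitivity),
            "specificity": _pct(self.specificity),
        }


def _ratio(num: int, den: int) -> float:
    return num / den if den else float("nan")


def metrics(cm: ConfusionMatrix) -> Metrics:
    """Accuracy, precision, sensitivity (recall) and specificity from counts.

    accuracy = (tp+tn)/total, precision = tp/(tp+fp),
    sensitivity = tp/(tp+fn), specificity = tn/(tn+fp).
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return Metrics(
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
        precision=_ratio(cm.tp, cm.tp + cm.fp),
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
    )


def majority_baseline(labels: LabelVector) -> float:
    """Accuracy of always predicting the majority class."""
    if labels.n_subjects == 0:
        raise ValueError("empty label vector")
    return max(labels.n_cases, labels.n_controls) / labels.n_subjects


@dataclass
class EvalResult:
    """Outcome of one cross-validated evaluation run."""

    cm: ConfusionMatrix
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    fold_records: list  # per held-out subject: id, truth, prediction, chosen k, SNP panel
    mode: str  # "nested" or "biased"
    seed: int

    def report(self) -> str:
        pct = Metrics(
            self.accuracy, self.precision, self.sensitivity, self.specificity
        ).as_percent()
        lines = [f"LOOCV evaluation (mode={self.mode}, seed={self.seed})", str(self.cm)]
        for name in ("accuracy", "precision", "sensitivity", "specificity"):
            v = pct[name]
            lines.append(f"{name:>12}: {'undefined' if v != v else f'{v:.2f}%'}")
        if self.mode == "biased":
            lines.append(
                "WARNING: feature selection saw the full dataset; this apparent "
                "accuracy is optimistically biased and is not an unbiased estimate."
            )
        return "\n".join(lines)


def _subject_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-fold sub-seeds below 2**31."""
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def _result_from_folds(y_true, y_pred, fold_records, mode, seed) -> EvalResult:
    cm = ConfusionMatrix.from_predictions(y_true, y_pred)
    m = metrics(cm)
    return EvalResult(
        cm=cm,
        accuracy=m.accuracy,
        precision=m.precision,
        sensitivity=m.sensitivity,
        specificity=m.specificity,
        fold_records=fold_records,
        mode=mode,
        seed=seed,
    )


def nested_loocv(
    gm: GenotypeMatrix,
    labels: LabelVector,
    m: int = 500,
    k_grid=DEFAULT_K_GRID,
    r: int = 10,
    seed: int = 0,
    record_panels: bool = True,
) -> EvalResult:
    """Correctly nested leave-one-out evaluation of MeanDiff + BestKNN.

    For each subject j, BestKNN (including its per-fold MeanDiff
    re-selection and the final top-m selection) runs on the other N-1
    subjects only, then predicts j.  ``record_panels=False`` drops the
    per-fold SNP id lists from the log to save memory on large runs.
    """
    labels.check_aligned(gm)
    n = gm.n_subjects
    if min(labels.n_cases, labels.n_controls) < r + 1:
        raise ValueError(
            f"nested LOOCV needs each class > r={r} members so every "
            "leave-one-out training set supports the internal folds"
        )
    seeds = _subject_seeds(seed, n)
    all_idx = np.arange(n)
    y_pred = np.empty(n, dtype=np.int8)
    fold_records = []
    for j in range(n):
        train_idx = np.delete(all_idx, j)
        model, trace = best_knn_fit(
            gm.subset_subjects(train_idx),
            labels.subset(train_idx),
            m=m,
            k_grid=k_grid,
            r=r,
            seed=int(seeds[j]),
        )
        cols = gm.snp_index(model.selected_snp_ids)
        pred = int(model.predict(gm.values[j, cols]))
        y_pred[j] = pred
        fold_records.append(
            {
                "subject_id": str(gm.subject_ids[j]),
                "true": int(labels.y[j]),
                "predicted": pred,
                "chosen_k": trace.chosen_k,
                "selected_snp_ids": model.selected_snp_ids if record_panels else None,
            }
        )
    return _result_from_folds(labels.y, y_pred, fold_records, "nested", seed)


def biased_loocv(
    gm: GenotypeMatrix,
    labels: LabelVector,
    m: int = 500,
    k_grid=DEFAULT_K_GRID,
    r: int = 10,
    seed: int = 0,
) -> EvalResult:
    """The deliberately leaky variant: feature selection runs ONCE on all data.

    The top-m SNP panel is fixed from the full dataset before
    cross-validation begins; the leave-one-out loop then tunes only k
    (still per fold, on the N-1 training subjects restricted to the
    fixed panel).  The single difference from :func:`nested_loocv` is
    therefore the feature-selection leakage, and the result is flagged
    ``mode="biased"`` — it must never be read as an unbiased estimate.
    """
    labels.check_aligned(gm)
    n = gm.n_subjects
    if min(labels.n_cases, labels.n_controls) < r + 1:
        raise ValueError(
            f"LOOCV needs each class > r={r} members for the internal folds"
        )
    ranking = select_top_m(gm, labels, m)  # the leak: selection sees every subject
    panel = ranking.selected_ids
    gm_red = gm.subset_snps(ranking.selected_index)
    m_eff = len(panel)
    seeds = _subject_seeds(seed, n)
    all_idx = np.arange(n)
    y_pred = np.empty(n, dtype=np.int8)
    fold_records = []
    for j in range(n):
        train_idx = np.delete(all_idx, j)
        model, trace = best_knn_fit(
            gm_red.subset_subjects(train_idx),
            labels.subset(train_idx),
            m=m_eff,  # selection inside is vacuous: the panel is already fixed
            k_grid=k_grid,
            r=r,
            seed=int(seeds[j]),
        )
        cols = gm_red.snp_index(model.selected_snp_ids)
        pred = int(model.predict(gm_red.values[j, cols]))
        y_pred[j] = pred
        fold_records.append(
            {
                "subject_id": str(gm.subject_ids[j]),
                "true": int(labels.y[j]),
                "predicted": pred,
                "chosen_k": trace.chosen_k,
                "selected_snp_ids": panel,
            }
        )
    return _result_from_folds(labels.y, y_pred, fold_records, "biased", seed)


@dataclass
class PermutationResult:
    """Permutation-test outcome for an observed cross-validated accuracy."""

    observed_accuracy: float
    permuted_accuracies: list
    exceed_count: int
    p_value: float

    @property
    def B(self) -> int:
        return len(self.permuted_accuracies)


def permutation_test(
    gm: GenotypeMatrix,
    labels: LabelVector,
    m: int = 500,
    k_grid=DEFAULT_K_GRID,
    r: int = 10,
    B: int = 100,
    seed: int = 0,
) -> PermutationResult:
    """Label-permutation significance test of the nested LOOCV accuracy.

    The observed accuracy comes from nested LOOCV on the true labels.
    Each of the B rounds permutes the labels uniformly (class counts
    preserved), destroying any genotype-phenotype signal, and re-runs
    the complete learn-and-evaluate pipeline.  The p-value uses the
    add-one estimator p = (#{permuted >= observed} + 1) / (B + 1), so
    it is never zero; ties count as exceedances (conservative).
    """
    if B < 1:
        raise ValueError(f"need at least one permutation, got B={B}")
    ss = np.random.SeedSequence(seed).generate_state(B + 2) % (2**31)
    observed = nested_loocv(
        gm, labels, m=m, k_grid=k_grid, r=r, seed=int(ss[0]), record_panels=False
    ).accuracy
    rng = np.random.default_rng(int(ss[1]))
    permuted = []
    for b in range(B):
        y_perm = rng.permutation(labels.y)
        lab_perm = LabelVector(y_perm, labels.subject_ids)
        res = nested_loocv(
            gm, lab_perm, m=m, k_grid=k_grid, r=r, seed=int(ss[b + 2]), record_panels=False
        )
        permuted.append(res.accuracy)
    exceed = sum(1 for a in permuted if a >= observed)
    return PermutationResult(
        observed_accuracy=observed,
        permuted_accuracies=permuted,
        exceed_count=exceed,
        p_value=(exceed + 1) / (B + 1),
    )


def m_sweep(
    gm: GenotypeMatrix,
    labels: LabelVector,
    m_grid=tuple(range(500, 1501, 100)),
    k_grid=DEFAULT_K_GRID,
    r: int = 10,
    seed: int = 0,
) -> dict:
    """Nested LOOCV accuracy for each panel size m (sensitivity analysis)."""
    return {
        int(m): nested_loocv(
            gm, labels, m=m, k_grid=k_grid, r=r, seed=seed, record_panels=False
        ).accuracy
        for m in m_grid
    }
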