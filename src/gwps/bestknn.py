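"""BestKNN: choose k by internal cross-validation with per-fold feature re-selection.

Choosing k by its leave-one-out score on the full training data would
tune a parameter on the data it is judged by.  BestKNN instead splits
the training data into r disjoint folds; for each fold i and each
candidate k it re-runs MeanDiff selection on the fold's complement
only, fits KNN there, and scores on the held-out fold.  The k with the
highest mean fold accuracy (the high-watermark) wins, smallest k on
ties.  The final classifier is then fitted on all of the data with the
winning k and a fresh top-m selection over the full training set.

Because the complement differs between folds, the m selected SNPs
typically differ between folds too — that re-selection is the point:
no information from a held-out fold reaches the selection that will be
judged on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gwps.datatypes import GenotypeMatrix, LabelVector
from gwps.knn import FittedKNN, fit_knn
from gwps.selection import select_top_m

__all__ = ["KSelectionTrace", "make_folds", "best_knn_fit"]

DEFAULT_K_GRID = (1, 3, 5, 7)


def make_folds(labels: LabelVector, r: int = 10, seed: int = 0) -> np.ndarray:
    """Assign each subject to one of r disjoint, class-stratified folds.

    Within each class, subjects are shuffled with the seeded generator
    and dealt round-robin, so per-class fold sizes differ by at most one
    and the assignment is deterministic given the seed.
    """
    n = labels.n_subjects
    if r < 2:
        raise ValueError(f"need at least 2 folds, got r={r}")
    if r > n:
        raise ValueError(f"r={r} folds but only {n} subjects")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=np.intp)
    for cls in (1, 0):
        idx = np.flatnonzero(labels.y == cls)
        idx = rng.permutation(idx)
        assignment[idx] = np.arange(len(idx)) % r
    return assignment


@dataclass
class KSelectionTrace:
    """Record of the internal cross-validation that chose k."""

    k_grid: tuple
    fold_accuracies: dict  # k -> array of r per-fold accuracies
    scores: dict  # k -> mean fold accuracy
    chosen_k: int
    fold_assignment: np.ndarray
    seed: int

    @property
    def r(self) -> int:
        return len(next(iter(self.fold_accuracies.values())))

    def to_dict(self) -> dict:
        return {
            "k_grid": list(self.k_grid),
            "fold_accuracies": {int(k): [float(a) for a in v] for k, v in self.fold_accuracies.items()},
            "scores": {int(k): float(v) for k, v in self.scores.items()},
            "chosen_k": int(self.chosen_k),
            "fold_assignment": [int(f) for f in self.fold_assignment],
            "seed": int(self.seed),
        }


def best_knn_fit(
    gm: GenotypeMatrix,
    labels: LabelVector,
    m: int = 500,
    k_grid=DEFAULT_K_GRID,
    r: int = 10,
    seed: int = 0,
) -> tuple:
    """Run BestKNN and return ``(FittedKNN, KSelectionTrace)``.

    Requires each class to have at least r members so that every fold
    complement retains both classes.
    """
    labels.check_aligned(gm)
    k_grid = tuple(sorted(set(int(k) for k in k_grid)))
    if not k_grid or k_grid[0] < 1:
        raise ValueError(f"invalid k grid {k_grid!r}")
    if min(labels.n_cases, labels.n_controls) < r:
        raise ValueError(
            f"each class needs >= r={r} members "
            f"(got {labels.n_cases} cases / {labels.n_controls} controls)"
        )
    folds = make_folds(labels, r=r, seed=seed)

    fold_acc = {k: np.zeros(r) for k in k_grid}
    for i in range(r):
        test_mask = folds == i
        train_idx = np.flatnonzero(~test_mask)
        test_idx = np.flatnonzero(test_mask)
        gm_tr = gm.subset_subjects(train_idx)
        y_tr = labels.y[train_idx]
        lab_tr = labels.subset(train_idx)
        ranking = select_top_m(gm_tr, lab_tr, m)  # selection sees this fold's complement only
        cols = ranking.selected_index
        train_red = gm_tr.values[:, cols]
        test_red = gm.values[np.ix_(test_idx, cols)]
        y_te = labels.y[test_idx]
        for k in k_grid:
            model = fit_knn(ranking.selected_ids, train_red, y_tr, k)
            pred = model.predict(test_red)
            fold_acc[k][i] = float((pred == y_te).mean()) if len(y_te) else np.nan

    scores = {k: float(np.nanmean(v)) for k, v in fold_acc.items()}
    best = max(scores.values())
    chosen_k = min(k for k, s in scores.items() if s == best)

    final_ranking = select_top_m(gm, labels, m)
    final = fit_knn(
        final_ranking.selected_ids,
        gm.values[:, final_ranking.selected_index],
        labels.y,
        chosen_k,
    )
    trace = KSelectionTrace(k_grid, fold_acc, scores, chosen_k, folds, seed)
    return final, trace
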