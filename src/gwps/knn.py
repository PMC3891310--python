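"""K-nearest-neighbour classifier over selected SNPs.

Distance is the squared Euclidean (L2) distance between two genotype
code vectors, d(p, q) = sum_i (p_i - q_i)^2.  A query is assigned the
majority vote of its k nearest training subjects.  Because genotype
codes are small integers, distances are computed in exact integer
arithmetic, so ties are exact and the documented tie-breaks are
reproducible: distance ties at the k-th neighbour are resolved by
ascending training-subject index (exactly k neighbours always vote),
and a tied vote falls back to the training-set majority class (control
if the training set itself is balanced).  With binary labels and odd k
the vote tie-break never triggers, but the contract is total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["sq_euclidean", "FittedKNN", "fit_knn", "predict"]


def sq_euclidean(p, q) -> float:
    """Squared Euclidean distance between two equal-length code vectors."""
    p = np.asarray(p)
    q = np.asarray(q)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    diff = p.astype(np.int64) - q.astype(np.int64) if np.issubdtype(
        p.dtype, np.integer
    ) and np.issubdtype(q.dtype, np.integer) else p - q
    return float((diff * diff).sum())


@dataclass
class FittedKNN:
    """A trained KNN classifier: SNP panel, stored training data, and k."""

    selected_snp_ids: list
    train_matrix: np.ndarray  # subjects x m genotype codes
    train_labels: np.ndarray  # 1 = case, 0 = control
    k: int

    def __post_init__(self) -> None:
        self.train_matrix = np.asarray(self.train_matrix)
        self.train_labels = np.asarray(self.train_labels, dtype=np.int8)
        n = self.train_matrix.shape[0]
        if self.train_matrix.ndim != 2 or self.train_matrix.shape[1] != len(
            self.selected_snp_ids
        ):
            raise ValueError("training matrix columns must align with selected_snp_ids")
        if len(self.train_labels) != n:
            raise ValueError("training labels must align with training matrix rows")
        if not 1 <= self.k <= n:
            raise ValueError(f"k={self.k} out of range for {n} training subjects")

    @property
    def majority_label(self) -> int:
        n_case = int(self.train_labels.sum())
        n_ctrl = len(self.train_labels) - n_case
        return 1 if n_case > n_ctrl else 0  # balanced training set -> control

    def predict(self, X) -> np.ndarray:
        return predict(self, X)


def fit_knn(selected_snp_ids, train_matrix, train_labels, k: int) -> FittedKNN:
    """Construct a FittedKNN (KNN 'training' just stores the data)."""
    return FittedKNN(list(selected_snp_ids), train_matrix, train_labels, k)


def predict(model: FittedKNN, X) -> np.ndarray:
    """Predict labels (1 = case, 0 = control) for one or more query vectors.

    ``X`` is a single m-vector or an (n_query x m) matrix aligned to
    ``model.selected_snp_ids``.
    """
    X = np.asarray(X)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    train = model.train_matrix
    if X.shape[1] != train.shape[1]:
        raise ValueError(
            f"query has {X.shape[1]} features but the model stores {train.shape[1]}"
        )
    # Exact integer distances keep tie detection exact.
    Xi = X.astype(np.int64)
    Ti = train.astype(np.int64)
    d = (
        (Xi * Xi).sum(axis=1)[:, None]
        + (Ti * Ti).sum(axis=1)[None, :]
        - 2 * (Xi @ Ti.T)
    )
    n_train = train.shape[0]
    train_index = np.arange(n_train)
    out = np.empty(X.shape[0], dtype=np.int8)
    for row in range(X.shape[0]):
        order = np.lexsort((train_index, d[row]))  # distance, then training index
        votes = model.train_labels[order[: model.k]]
        n_case = int(votes.sum())
        n_ctrl = model.k - n_case
        if n_case > n_ctrl:
            out[row] = 1
        elif n_ctrl > n_case:
            out[row] = 0
        else:
            out[row] = model.majority_label
    return out[0] if single else out
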