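"""Core in-memory containers: genotype matrix and phenotype labels.

Genotypes use the additive 1/2/3 coding: 1 = wild-type homozygote,
2 = heterozygote, 3 = variant homozygote.  Missing calls are stored as
the sentinel 0 in the integer matrix (written as "." in text formats),
which is unambiguous against the valid codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Missing-call sentinel in the integer genotype matrix.
MISSING: int = 0

CASE: str = "case"
CONTROL: str = "control"

#: Internal numeric label coding: 1 = case, 0 = control.
CASE_CODE: int = 1
CONTROL_CODE: int = 0

_VALID_CODES = frozenset({MISSING, 1, 2, 3})


def _as_id_array(ids) -> np.ndarray:
    arr = np.asarray(ids, dtype=object)
    if arr.ndim != 1:
        raise ValueError("identifier list must be one-dimensional")
    return arr


@dataclass
class GenotypeMatrix:
    """A subjects x SNPs integer genotype matrix with aligned identifiers.

    Parameters
    ----------
    values
        Integer array of shape ``(n_subjects, n_snps)`` with entries in
        ``{0, 1, 2, 3}`` (0 is the missing sentinel).
    snp_ids, subject_ids
        Ordered, unique identifiers matching the matrix dimensions.
    """

    values: np.ndarray
    snp_ids: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D subjects x SNPs array")
        if not np.issubdtype(self.values.dtype, np.integer):
            self.values = self.values.astype(np.int8)
        self.snp_ids = _as_id_array(self.snp_ids)
        self.subject_ids = _as_id_array(self.subject_ids)
        n_sub, n_snp = self.values.shape
        if len(self.subject_ids) != n_sub:
            raise ValueError(
                f"{len(self.subject_ids)} subject ids for {n_sub} matrix rows"
            )
        if len(self.snp_ids) != n_snp:
            raise ValueError(f"{len(self.snp_ids)} SNP ids for {n_snp} matrix columns")
        for name, ids in (("snp", self.snp_ids), ("subject", self.subject_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} identifiers")
        if self.values.size:
            bad = ~np.isin(self.values, (MISSING, 1, 2, 3))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    f"invalid genotype code {self.values[i, j]} for subject "
                    f"{self.subject_ids[i]!r}, SNP {self.snp_ids[j]!r}; "
                    "expected 0 (missing), 1, 2 or 3"
                )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def subset_snps(self, index) -> "GenotypeMatrix":
        """Column subset (by positional index array), preserving order given."""
        index = np.asarray(index)
        return GenotypeMatrix(
            self.values[:, index], self.snp_ids[index], self.subject_ids
        )

    def subset_subjects(self, index) -> "GenotypeMatrix":
        """Row subset (by positional index or boolean mask)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            self.values[index], self.snp_ids, self.subject_ids[index]
        )

    def snp_index(self, snp_ids) -> np.ndarray:
        """Positions of the given SNP ids, in the requested order."""
        lookup = {s: i for i, s in enumerate(self.snp_ids)}
        try:
            return np.array([lookup[s] for s in snp_ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown SNP id {exc.args[0]!r}") from None


@dataclass
class LabelVector:
    """Per-subject binary phenotype aligned to subject identifiers.

    Internally labels are coded 1 = case, 0 = control; :meth:`as_strings`
    renders the external ``case``/``control`` vocabulary.
    """

    y: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int8)
        self.subject_ids = _as_id_array(self.subject_ids)
        if self.y.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if len(self.y) != len(self.subject_ids):
            raise ValueError("label / subject-id length mismatch")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject identifiers")
        if self.y.size and not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be coded 0 (control) / 1 (case)")

    @classmethod
    def from_strings(cls, labels, subject_ids) -> "LabelVector":
        mapping = {CASE: CASE_CODE, CONTROL: CONTROL_CODE}
        try:
            y = np.array([mapping[str(l).strip().lower()] for l in labels], dtype=np.int8)
        except KeyError as exc:
            raise ValueError(
                f"unknown label {exc.args[0]!r}; expected 'case' or 'control'"
            ) from None
        return cls(y, subject_ids)

    def as_strings(self) -> list:
        return [CASE if v == CASE_CODE else CONTROL for v in self.y]

    @property
    def n_subjects(self) -> int:
        return len(self.y)

    @property
    def n_cases(self) -> int:
        return int((self.y == CASE_CODE).sum())

    @property
    def n_controls(self) -> int:
        return int((self.y == CONTROL_CODE).sum())

    def subset(self, index) -> "LabelVector":
        index = np.asarray(index)
        return LabelVector(self.y[index], self.subject_ids[index])

    def check_aligned(self, gm: GenotypeMatrix) -> None:
        """Raise if this label vector is not aligned with a genotype matrix."""
        if len(self.y) != gm.n_subjects or not np.array_equal(
            self.subject_ids, gm.subject_ids
        ):
            raise ValueError("labels are not aligned with the genotype matrix")
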