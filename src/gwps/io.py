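"""Readers and writers for the native genotype format, VCF import, and run config.

Native format: a tab-separated genotype file with header row
``snp_id<TAB>subject1<TAB>subject2...``, one row per SNP, cells in
{1, 2, 3, .} (``.`` is a missing call); and a companion label file with
header ``subject_id<TAB>label`` and labels ``case``/``control``.  The
matrix is stored SNPs-by-subjects on disk (the conventional orientation
for wide genotype tables) and transposed to subjects x SNPs in memory.
Gzip-compressed inputs (``.gz``) are handled transparently.

VCF import maps diploid GT calls of biallelic sites to the additive
coding: 0/0 -> 1, 0/1 or 1/0 -> 2, 1/1 -> 3, ./. -> missing.  Code 3 is
always the ALT homozygote regardless of which allele is minor: this
differs from the simulator's minor-allele orientation but is
reproducible without estimating frequencies.  Phase separators are
irrelevant to the coding.  Multiallelic records and records containing
half-missing calls are skipped, with the skip count logged.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from gwps.datatypes import MISSING, GenotypeMatrix, LabelVector
from gwps.exceptions import ConfigError, ParseError

__all__ = [
    "read_native",
    "write_native",
    "read_labels",
    "write_labels",
    "write_truth",
    "import_vcf",
    "RunConfig",
]

logger = logging.getLogger("gwps")

_CELL_CODES = {"1": 1, "2": 2, "3": 3, ".": MISSING}
_CODE_CELLS = {v: k for k, v in _CELL_CODES.items()}


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_genotypes(path) -> GenotypeMatrix:
    """Read the native genotype TSV (rows = SNPs) into a subjects x SNPs matrix."""
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file")
        fields = header.split("\t")
        if fields[0] != "snp_id":
            raise ParseError(f"{path}, line 1: header must start with 'snp_id'")
        subject_ids = fields[1:]
        if len(set(subject_ids)) != len(subject_ids):
            raise ParseError(f"{path}, line 1: duplicate subject ids in header")
        rows = []
        snp_ids = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(subject_ids) + 1:
                raise ParseError(
                    f"{path}, line {lineno}: expected {len(subject_ids) + 1} "
                    f"columns, found {len(parts)}"
                )
            snp_ids.append(parts[0])
            row = np.empty(len(subject_ids), dtype=np.int8)
            for col, cell in enumerate(parts[1:]):
                try:
                    row[col] = _CELL_CODES[cell]
                except KeyError:
                    raise ParseError(
                        f"{path}, line {lineno}, column {col + 2} "
                        f"(SNP {parts[0]!r}, subject {subject_ids[col]!r}): "
                        f"invalid genotype cell {cell!r}; expected 1, 2, 3 or '.'"
                    ) from None
            rows.append(row)
    if len(set(snp_ids)) != len(snp_ids):
        raise ParseError(f"{path}: duplicate SNP ids")
    values = np.array(rows, dtype=np.int8).T if rows else np.empty((len(subject_ids), 0), np.int8)
    logger.info("read %d SNPs x %d subjects from %s", len(snp_ids), len(subject_ids), path)
    return GenotypeMatrix(values, np.array(snp_ids, dtype=object), np.array(subject_ids, dtype=object))


def read_labels(path, subject_ids=None) -> LabelVector:
    """Read the companion label TSV; if subject_ids given, check exact agreement."""
    ids, labels = [], []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["subject_id", "label"]:
            raise ParseError(f"{path}, line 1: header must be 'subject_id<TAB>label'")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}, line {lineno}: expected 2 columns")
            ids.append(parts[0])
            labels.append(parts[1])
    try:
        lv = LabelVector.from_strings(labels, np.array(ids, dtype=object))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None
    if subject_ids is not None:
        if set(ids) != set(map(str, subject_ids)):
            missing = set(map(str, subject_ids)) - set(ids)
            extra = set(ids) - set(map(str, subject_ids))
            raise ParseError(
                f"{path}: labels do not match the genotype subjects "
                f"(missing {sorted(missing)[:3]}..., extra {sorted(extra)[:3]}...)"
                if missing or extra
                else f"{path}: label/genotype subject mismatch"
            )
        order = {s: i for i, s in enumerate(ids)}
        reorder = [order[str(s)] for s in subject_ids]
        lv = lv.subset(np.array(reorder, dtype=np.intp))
    return lv


def read_native(genotype_path, label_path) -> tuple:
    """Read the native genotype + label pair; labels are aligned to the matrix."""
    gm = read_genotypes(genotype_path)
    labels = read_labels(label_path, subject_ids=gm.subject_ids)
    return gm, labels


def write_native(gm: GenotypeMatrix, path) -> None:
    """Write the genotype matrix in the native TSV layout (rows = SNPs)."""
    with _open_text(path, "wt") as fh:
        fh.write("snp_id\t" + "\t".join(str(s) for s in gm.subject_ids) + "\n")
        vt = gm.values.T
        for snp, row in zip(gm.snp_ids, vt):
            fh.write(str(snp) + "\t" + "\t".join(_CODE_CELLS[int(v)] for v in row) + "\n")


def write_labels(labels: LabelVector, path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("subject_id\tlabel\n")
        for sid, lab in zip(labels.subject_ids, labels.as_strings()):
            fh.write(f"{sid}\t{lab}\n")


def write_truth(truth: dict, path) -> None:
    """Write the simulator's planted-structure ground truth as a JSON sidecar."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")


def import_vcf(vcf_path, label_path) -> tuple:
    """Import genotypes from a VCF (GT field) plus a native label file.

    Site id is the ID column when present, else ``CHROM:POS:REF:ALT``.
    Returns the same (GenotypeMatrix, LabelVector) pair as
    :func:`read_native`.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(vcf_path))
    subject_ids = list(vcf.samples)
    if not subject_ids:
        raise ParseError(f"{vcf_path}: VCF has no samples")
    rows, snp_ids = [], []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_skipped += 1
            continue
        if variant.FORMAT is None or "GT" not in variant.FORMAT:
            raise ParseError(f"{vcf_path}: record {variant.CHROM}:{variant.POS} has no GT field")
        row = np.empty(len(subject_ids), dtype=np.int8)
        ok = True
        for i, g in enumerate(variant.genotypes):
            alleles = [a for a in g[:-1]]  # last element is the phase flag
            if len(alleles) != 2:
                ok = False
                break
            a0, a1 = alleles
            if a0 < 0 and a1 < 0:
                row[i] = MISSING
            elif a0 < 0 or a1 < 0:
                ok = False  # half-missing call: skip the record
                break
            else:
                row[i] = 1 + (a0 > 0) + (a1 > 0)
        if not ok:
            n_skipped += 1
            continue
        sid = variant.ID or f"{variant.CHROM}:{variant.POS}:{variant.REF}:{variant.ALT[0]}"
        snp_ids.append(sid)
        rows.append(row)
    if n_skipped:
        logger.info("skipped %d multiallelic/half-missing VCF records", n_skipped)
    values = np.array(rows, dtype=np.int8).T if rows else np.empty((len(subject_ids), 0), np.int8)
    gm = GenotypeMatrix(values, np.array(snp_ids, dtype=object), np.array(subject_ids, dtype=object))
    gm.n_skipped_records = n_skipped
    labels = read_labels(label_path, subject_ids=gm.subject_ids)
    return gm, labels


@dataclass
class RunConfig:
    """All pipeline parameters with their study defaults."""

    m: int = 500
    k_grid: tuple = (1, 3, 5, 7)
    r: int = 10
    maf_min: float = 0.05
    hwe_alpha: float = 0.001
    B: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.m < 1:
            raise ConfigError(f"m must be >= 1, got {self.m}")
        if not self.k_grid or any(k < 1 for k in self.k_grid):
            raise ConfigError(f"invalid k_grid {self.k_grid!r}")
        if self.r < 2:
            raise ConfigError(f"r must be >= 2, got {self.r}")
        if not 0.0 <= self.maf_min <= 0.5:
            raise ConfigError(f"maf_min must be in [0, 0.5], got {self.maf_min}")
        if not 0.0 < self.hwe_alpha < 1.0:
            raise ConfigError(f"hwe_alpha must be in (0, 1), got {self.hwe_alpha}")
        if self.B < 1:
            raise ConfigError(f"B must be >= 1, got {self.B}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with _open_text(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "k_grid" in raw:
            raw["k_grid"] = tuple(raw["k_grid"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["k_grid"] = list(self.k_grid)
        return d
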