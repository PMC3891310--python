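"""Synthetic case-control SNP genotype generator with known planted structure.

The generator emulates the statistical structure of a genome-wide
case-control genotyping cohort: a roughly balanced case/control split,
per-SNP minor allele frequencies in (0, 0.5], Hardy-Weinberg-consistent
genotypes in controls, a small set of "effect" SNPs whose allele
frequency is shifted in cases, plus injectable quality-control
violations (missing calls, inbreeding-style HWE distortion, rare
variants below the MAF threshold).  All planted SNP identities are
returned as ground truth so downstream QC, feature selection and
evaluation can be tested against a known answer.

For a null SNP with variant-allele frequency ``q`` the three genotype
codes are drawn from the Hardy-Weinberg proportions
``((1-q)^2, 2q(1-q), q^2)`` mapped to codes (1, 2, 3), identically in
cases and controls.  Effect SNPs keep ``q`` in controls and use
``q + effect_delta`` (capped at 0.999) in cases, each group in HWE
internally.  HWE-violating SNPs are drawn, in all subjects, from the
inbreeding-distorted proportions
``((1-q)^2 + Fq(1-q), 2q(1-q)(1-F), q^2 + Fq(1-q))``.

The model draws every genotype independently: there is no linkage
disequilibrium between SNPs and no population structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from gwps.datatypes import MISSING, GenotypeMatrix, LabelVector
from gwps.exceptions import ConfigError

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate",
    "planted_effect_meandiff",
]

#: Shifted case allele frequencies are capped here to keep genotype
#: probabilities strictly valid.
_FREQ_CAP = 0.999


@dataclass
class SimulationConfig:
    """Parameters of one simulated cohort.

    Defaults mirror the class balance of a genotyped breast-cancer cohort
    (302 cases / 321 controls) with a post-QC allele-frequency spectrum;
    the SNP count defaults to a desk-scale 10,000.  All planted-structure
    counts default to zero, so structure is strictly opt-in.
    """

    n_cases: int = 302
    n_controls: int = 321
    n_snps: int = 10_000
    maf_range: tuple = (0.05, 0.5)
    n_effect_snps: int = 0
    effect_delta: float = 0.0
    n_hwe_violating: int = 0
    hwe_inbreeding_f: float = 0.0
    n_low_maf: int = 0
    low_maf_value: float = 0.01
    n_missing_snps: int = 0
    missing_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_cases",
            "n_controls",
            "n_snps",
            "n_effect_snps",
            "n_hwe_violating",
            "n_low_maf",
            "n_missing_snps",
        ):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigError(f"{name} must be a non-negative integer, got {v!r}")
        planted = (
            self.n_effect_snps
            + self.n_hwe_violating
            + self.n_low_maf
            + self.n_missing_snps
        )
        if planted > self.n_snps:
            raise ConfigError(
                f"planted SNP counts sum to {planted} > n_snps={self.n_snps}"
            )
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range!r}")
        if not 0.0 <= self.effect_delta <= 0.5:
            raise ConfigError(f"effect_delta must be in [0, 0.5], got {self.effect_delta!r}")
        if not 0.0 <= self.hwe_inbreeding_f <= 1.0:
            raise ConfigError(
                f"hwe_inbreeding_f must be in [0, 1], got {self.hwe_inbreeding_f!r}"
            )
        if not 0.0 < self.low_maf_value < 0.05:
            raise ConfigError(
                f"low_maf_value must be a frequency below 0.05, got {self.low_maf_value!r}"
            )
        if not 0.0 < self.missing_rate <= 1.0:
            raise ConfigError(f"missing_rate must be in (0, 1], got {self.missing_rate!r}")


@dataclass
class SimulatedDataset:
    """A simulated cohort plus the ground truth of its planted structure."""

    genotypes: GenotypeMatrix
    labels: LabelVector
    effect_snps: list
    hwe_violating_snps: list
    low_maf_snps: list
    missing_snps: list
    config: SimulationConfig

    @property
    def truth(self) -> dict:
        return {
            "effect_snps": list(self.effect_snps),
            "hwe_violating_snps": list(self.hwe_violating_snps),
            "low_maf_snps": list(self.low_maf_snps),
            "missing_snps": list(self.missing_snps),
        }


def _hwe_probs(q: np.ndarray) -> tuple:
    """Genotype probabilities (codes 1, 2, 3) under HWE at variant frequency q."""
    return (1.0 - q) ** 2, 2.0 * q * (1.0 - q), q**2


def _inbred_probs(q: np.ndarray, f: float) -> tuple:
    """Inbreeding-distorted genotype probabilities (Wright's F model)."""
    het = 2.0 * q * (1.0 - q)
    return (1.0 - q) ** 2 + f * q * (1.0 - q), het * (1.0 - f), q**2 + f * q * (1.0 - q)


def _draw_block(rng: np.random.Generator, n: int, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Draw an n x len(p1) genotype block from per-SNP probabilities."""
    if n == 0:
        return np.empty((0, len(p1)), dtype=np.int8)
    u = rng.random((n, len(p1)))
    geno = np.ones((n, len(p1)), dtype=np.int8)
    geno += (u >= p1[None, :]).astype(np.int8)
    geno += (u >= (p1 + p2)[None, :]).astype(np.int8)
    return geno


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Generate a seeded case-control cohort per the configuration.

    The same configuration (including seed) always yields an identical
    dataset: the random stream is consumed in a fixed order (planted-SNP
    placement, per-SNP frequencies, case block, control block, missing
    masks).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_snps = config.n_snps
    n = config.n_cases + config.n_controls

    # Place planted categories at disjoint random positions.
    perm = rng.permutation(n_snps)
    cursor = 0
    idx_effect = np.sort(perm[cursor : cursor + config.n_effect_snps]); cursor += config.n_effect_snps
    idx_hwe = np.sort(perm[cursor : cursor + config.n_hwe_violating]); cursor += config.n_hwe_violating
    idx_low = np.sort(perm[cursor : cursor + config.n_low_maf]); cursor += config.n_low_maf
    idx_miss = np.sort(perm[cursor : cursor + config.n_missing_snps])

    lo, hi = config.maf_range
    q = rng.uniform(lo, hi, size=n_snps)
    q[idx_low] = config.low_maf_value

    # Control-group probabilities: HWE everywhere except the inbred SNPs.
    p1_ctrl, p2_ctrl, _ = _hwe_probs(q)
    if len(idx_hwe):
        a, b, _ = _inbred_probs(q[idx_hwe], config.hwe_inbreeding_f)
        p1_ctrl[idx_hwe], p2_ctrl[idx_hwe] = a, b

    # Case-group probabilities: same, but effect SNPs get a shifted frequency.
    p1_case, p2_case = p1_ctrl.copy(), p2_ctrl.copy()
    if len(idx_effect):
        q_case = np.minimum(q[idx_effect] + config.effect_delta, _FREQ_CAP)
        a, b, _ = _hwe_probs(q_case)
        p1_case[idx_effect], p2_case[idx_effect] = a, b

    geno_cases = _draw_block(rng, config.n_cases, p1_case, p2_case)
    geno_ctrls = _draw_block(rng, config.n_controls, p1_ctrl, p2_ctrl)
    values = np.vstack([geno_cases, geno_ctrls])

    # Inject missing calls; each planted missing-call SNP gets at least one.
    for j in idx_miss:
        mask = rng.random(n) < config.missing_rate
        if not mask.any() and n:
            mask[rng.integers(n)] = True
        values[mask, j] = MISSING

    width = max(len(str(n_snps)), 1)
    snp_ids = np.array([f"snp{i:0{width}d}" for i in range(n_snps)], dtype=object)
    swidth = max(len(str(n)), 1)
    subject_ids = np.array([f"subj{i:0{swidth}d}" for i in range(n)], dtype=object)
    y = np.concatenate(
        [np.ones(config.n_cases, dtype=np.int8), np.zeros(config.n_controls, dtype=np.int8)]
    )

    return SimulatedDataset(
        genotypes=GenotypeMatrix(values, snp_ids, subject_ids),
        labels=LabelVector(y, subject_ids),
        effect_snps=[str(s) for s in snp_ids[idx_effect]],
        hwe_violating_snps=[str(s) for s in snp_ids[idx_hwe]],
        low_maf_snps=[str(s) for s in snp_ids[idx_low]],
        missing_snps=[str(s) for s in snp_ids[idx_miss]],
        config=config,
    )


def planted_effect_meandiff(q_control: float, q_case: float) -> float:
    """Expected MeanDiff score of a planted effect SNP, in closed form.

    Under HWE at variant frequency q the expected genotype code is
    ``1*(1-q)^2 + 2*2q(1-q) + 3*q^2 = 1 + 2q``, so the expected absolute
    difference of per-class code means is ``2 * |q_case - q_control|``.
    """
    for name, qv in (("q_control", q_control), ("q_case", q_case)):
        if not 0.0 <= qv <= 1.0:
            raise ConfigError(f"{name} must be a frequency in [0, 1], got {qv!r}")
    return 2.0 * abs(q_case - q_control)
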