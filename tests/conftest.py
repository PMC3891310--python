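import numpy as np
import pytest

from gwps import GenotypeMatrix, LabelVector, SimulationConfig, simulate


def make_gm(values):
    """GenotypeMatrix with auto ids from a plain nested list / array."""
    values = np.asarray(values, dtype=np.int8)
    return GenotypeMatrix(
        values,
        np.array([f"snp{j}" for j in range(values.shape[1])], dtype=object),
        np.array([f"s{i}" for i in range(values.shape[0])], dtype=object),
    )


def make_labels(y):
    y = np.asarray(y, dtype=np.int8)
    return LabelVector(y, np.array([f"s{i}" for i in range(len(y))], dtype=object))


@pytest.fixture(scope="session")
def planted_dataset():
    """Small cohort with every kind of planted structure."""
    return simulate(
        SimulationConfig(
            n_cases=100,
            n_controls=100,
            n_snps=500,
            n_effect_snps=20,
            effect_delta=0.25,
            n_hwe_violating=10,
            hwe_inbreeding_f=0.8,
            n_low_maf=10,
            low_maf_value=0.01,
            n_missing_snps=10,
            missing_rate=0.05,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def null_dataset():
    """Pure-null balanced cohort: no planted structure at all."""
    return simulate(
        SimulationConfig(n_cases=60, n_controls=60, n_snps=400, seed=9)
    )
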