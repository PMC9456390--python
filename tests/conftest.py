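import numpy as np
import pytest

from osteopgs import (GenotypeMatrix, SimConfig, VariantRecord, WeightTable,
                      simulate_cohort)


@pytest.fixture(scope="session")
def toy_panel() -> WeightTable:
    """Three-variant panel with odds ratios 1.5, 2.0, 1.2."""
    return WeightTable([
        VariantRecord("rs1", "1", 101, "A", "G", 1.5),
        VariantRecord("rs2", "1", 202, "C", "T", 2.0),
        VariantRecord("rs3", "2", 303, "G", "A", 1.2),
    ])


@pytest.fixture()
def toy_matrix(toy_panel) -> GenotypeMatrix:
    """Three samples genotyped on the toy panel, no missingness."""
    return GenotypeMatrix(
        sample_ids=["s1", "s2", "s3"],
        variants=list(toy_panel),
        dosage=np.array([[1, 2, 0], [0, 1, 1], [2, 2, 2]]),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small complete synthetic cohort reused across read-only tests."""
    return simulate_cohort(SimConfig(
        seed=7, n_samples=150, n_snps=40, n_causal=30,
        maf_range=(0.05, 0.45)))


def make_matrix(dosage, missing=None, chrom="1"):
    """GenotypeMatrix from a plain dosage array with auto-made variants."""
    dosage = np.asarray(dosage)
    n, m = dosage.shape
    variants = [VariantRecord(f"v{j}", chrom, 1000 + j, "A", "G", 1.0)
                for j in range(m)]
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        variants=variants, dosage=dosage, missing=missing)
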