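"""Core in-memory containers for the PGS pipeline.

A cohort is represented by three objects:

* :class:`WeightTable` — the scoring panel: one row per biallelic SNP with
  its effect allele, other allele and effect size (an odds ratio from prior
  association studies).
* :class:`GenotypeMatrix` — samples x variants effect-allele dosages in
  {0, 1, 2} with an explicit missingness mask (missing dosage is never a
  sentinel value mixed into arithmetic).
* a phenotype table — a plain :class:`pandas.DataFrame` validated by
  :func:`validate_phenotypes`, carrying fracture status, BMD T-score and its
  WHO class, and optional ethnicity / age / BMI covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGT")

#: dosage value used in the integer array where the mask is True
MISSING = -1

PHENOTYPE_COLUMNS = ["sample_id", "fracture", "t_score", "bmd_class",
                     "ethnicity", "age_years", "bmi"]

FRACTURE_LEVELS = frozenset({"case", "control", "unknown"})
BMD_LEVELS = frozenset({"normal", "osteopenia", "osteoporosis", "unknown"})


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNP of the scoring panel.

    ``effect_size`` is the odds ratio of the effect allele; downstream
    scoring takes ``ln(OR)`` by default.
    """

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    effect_size: float

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_BASES:
            raise ValueError(
                f"{self.variant_id}: effect allele {self.effect_allele!r} "
                "is not a single nucleotide")
        if self.other_allele not in VALID_BASES:
            raise ValueError(
                f"{self.variant_id}: other allele {self.other_allele!r} "
                "is not a single nucleotide")
        if self.effect_allele == self.other_allele:
            raise ValueError(
                f"{self.variant_id}: effect and other allele are both "
                f"{self.effect_allele!r}")
        if not self.effect_size > 0:
            raise ValueError(
                f"{self.variant_id}: effect size (OR) must be > 0, got "
                f"{self.effect_size}")
        if self.position < 1:
            raise ValueError(
                f"{self.variant_id}: position must be >= 1 (1-based), got "
                f"{self.position}")

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.effect_allele, self.other_allele))


class WeightTable:
    """Ordered collection of :class:`VariantRecord` with unique IDs."""

    def __init__(self, variants: Iterable[VariantRecord]):
        self.variants = list(variants)
        seen: set[str] = set()
        for v in self.variants:
            if v.variant_id in seen:
                raise ValueError(f"duplicate variant_id {v.variant_id!r}")
            seen.add(v.variant_id)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    def __getitem__(self, i: int) -> VariantRecord:
        return self.variants[i]

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    @property
    def effect_sizes(self) -> np.ndarray:
        return np.array([v.effect_size for v in self.variants], dtype=float)

    def subset(self, ids: Sequence[str]) -> "WeightTable":
        wanted = set(ids)
        return WeightTable(v for v in self.variants if v.variant_id in wanted)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": [v.variant_id for v in self.variants],
                "chr": [v.chromosome for v in self.variants],
                "pos": [v.position for v in self.variants],
                "effect_allele": [v.effect_allele for v in self.variants],
                "other_allele": [v.other_allele for v in self.variants],
                "OR": [v.effect_size for v in self.variants],
            }
        )


@dataclass
class GenotypeMatrix:
    """samples x variants effect-allele dosage matrix, ploidy 2.

    ``dosage[i, j]`` counts copies of the effect allele of variant ``j``
    carried by sample ``i`` (0, 1 or 2). ``missing[i, j]`` is True where the
    genotype failed; the corresponding dosage entry is ``MISSING`` and must
    never enter arithmetic unmasked.
    """

    sample_ids: list[str]
    variants: list[VariantRecord]
    dosage: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.missing is None:
            self.missing = np.zeros(self.dosage.shape, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        n, m = self.dosage.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"dosage has {n} rows but {len(self.sample_ids)} sample ids")
        if m != len(self.variants):
            raise ValueError(
                f"dosage has {m} columns but {len(self.variants)} variants")
        if self.missing.shape != self.dosage.shape:
            raise ValueError("missing mask shape differs from dosage shape")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        observed = self.dosage[~self.missing]
        if observed.size and (observed.min() < 0 or observed.max() > 2):
            raise ValueError("non-missing dosages must lie in {0, 1, 2}")
        if self.ploidy != 2:
            raise ValueError("only diploid data supported (ploidy 2)")
        self.dosage[self.missing] = MISSING

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def masked_dosage(self) -> np.ma.MaskedArray:
        """Dosages as a float masked array, safe for arithmetic."""
        return np.ma.masked_array(self.dosage.astype(float), mask=self.missing)

    def sample_call_rate(self) -> np.ndarray:
        """Fraction of non-missing genotypes per sample."""
        if self.n_variants == 0:
            return np.ones(self.n_samples)
        return 1.0 - self.missing.mean(axis=1)

    def variant_call_rate(self) -> np.ndarray:
        """Fraction of non-missing genotypes per variant."""
        if self.n_samples == 0:
            return np.ones(self.n_variants)
        return 1.0 - self.missing.mean(axis=0)

    def effect_allele_frequency(self) -> np.ndarray:
        """Observed effect-allele frequency per variant (ignoring missing)."""
        md = self.masked_dosage()
        freq = md.mean(axis=0) / 2.0
        return np.asarray(freq.filled(np.nan))

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in index],
            variants=self.variants,
            dosage=self.dosage[index].copy(),
            missing=self.missing[index].copy(),
        )

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            sample_ids=self.sample_ids,
            variants=[self.variants[j] for j in index],
            dosage=self.dosage[:, index].copy(),
            missing=self.missing[:, index].copy(),
        )

    def genotype_counts(self, j: int) -> tuple[int, int, int]:
        """(hom other, het, hom effect) counts at variant ``j``."""
        col = self.dosage[~self.missing[:, j], j]
        return (int(np.sum(col == 0)), int(np.sum(col == 1)),
                int(np.sum(col == 2)))


def classify_t_score(t_score: float) -> str:
    """WHO T-criterion class for a BMD T-score.

    ``> -1.0`` normal; ``-2.5 <= t <= -1.0`` osteopenia; ``< -2.5``
    osteoporosis. Both boundary values fall in the osteopenia band.
    """
    if np.isnan(t_score):
        return "unknown"
    if t_score > -1.0:
        return "normal"
    if t_score >= -2.5:
        return "osteopenia"
    return "osteoporosis"


def validate_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Validate (and lightly normalize) a phenotype table.

    Requires unique ``sample_id``, categorical ``fracture`` and ``bmd_class``
    levels, and consistency of ``bmd_class`` with ``t_score`` where both are
    present. Returns the frame with missing optional columns added as NA.
    """
    pheno = pheno.copy()
    if "sample_id" not in pheno.columns:
        raise ValueError("phenotype table must have a sample_id column")
    if pheno["sample_id"].duplicated().any():
        dups = pheno.loc[pheno["sample_id"].duplicated(), "sample_id"]
        raise ValueError(f"duplicate sample_ids: {sorted(set(dups))}")
    for col in PHENOTYPE_COLUMNS:
        if col not in pheno.columns:
            pheno[col] = np.nan
    pheno["fracture"] = pheno["fracture"].fillna("unknown")
    bad = set(pheno["fracture"]) - FRACTURE_LEVELS
    if bad:
        raise ValueError(f"invalid fracture levels: {sorted(bad)}")
    pheno["bmd_class"] = pheno["bmd_class"].fillna("unknown")
    bad = set(pheno["bmd_class"]) - BMD_LEVELS
    if bad:
        raise ValueError(f"invalid bmd_class levels: {sorted(bad)}")
    has_t = pheno["t_score"].notna()
    expected = pheno.loc[has_t, "t_score"].map(classify_t_score)
    stated = pheno.loc[has_t, "bmd_class"]
    mismatch = (stated != "unknown") & (stated != expected)
    if mismatch.any():
        ids = pheno.loc[has_t].loc[mismatch, "sample_id"].tolist()
        raise ValueError(
            f"bmd_class inconsistent with t_score for samples {ids[:5]}")
    return pheno


@dataclass
class ScoreSet:
    """Raw and normalized polygenic scores for a cohort.

    ``raw_prs`` follows the average-score convention: the weighted
    risk-allele sum divided by ploidy times the per-sample count of
    non-missing panel variants (``n_used``). ``z_prs`` is the cohort
    z-normalization of ``raw_prs``.
    """

    sample_ids: list[str]
    raw_prs: np.ndarray
    z_prs: np.ndarray | None
    n_used: np.ndarray
    weight_transform: str

    def to_frame(self) -> pd.DataFrame:
        from .scoring import score_percentiles
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "raw_prs": self.raw_prs,
                "z_prs": self.z_prs,
                "n_used": self.n_used,
                "percentile": score_percentiles(self),
            }
        )
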