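"""Seeded synthetic case-control cohorts for the scoring pipeline.

Emulates a small postmenopausal osteoporosis panel study: ~700 women
genotyped at ~150 biallelic SNPs with MAF 1-49%, of which a handful fail
Hardy-Weinberg or duplicate another locus (so QC has real work to do), and
three nested phenotype contrasts — fracture, low BMD by T-criterion, and
their comorbid combination — generated from a liability-threshold model
with correlated trait liabilities.

Every operation takes its randomness from the `SimConfig` seed and is
bit-reproducible. The generator also retains the generative truth
(`TrueModel`: causal effects, genetic values, latent liabilities) so
downstream estimates can be validated against an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (GenotypeMatrix, VariantRecord, WeightTable,
                         classify_t_score, validate_phenotypes)

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Generative parameters of a synthetic cohort.

    Defaults mirror the motivating study design: 701 postmenopausal women,
    a 150-SNP panel with MAF uniform on [0.01, 0.49] of which 10 loci are
    QC casualties (5 Hardy-Weinberg violators with inbreeding-like
    distortion F = 0.5, 5 near-duplicates), fracture prevalence 294/701,
    BMD measured in 496/701 with 324/496 below the T-criterion. Liability
    heritabilities (variance explained by the panel) default to 0.25
    (fracture) and 0.35 (BMD) with cross-trait liability correlation 0.6.
    """

    seed: int
    n_samples: int = 701
    n_snps: int = 150
    maf_range: tuple[float, float] = (0.01, 0.49)
    n_causal: int = 140
    or_range: tuple[float, float] = (1.05, 1.5)
    fracture_prevalence: float = 294 / 701
    bmd_measured_fraction: float = 496 / 701
    low_bmd_prevalence: float = 324 / 496
    h2_fracture: float = 0.25
    h2_bmd: float = 0.35
    cross_trait_corr: float = 0.6
    missing_rate: float = 0.0
    n_hwe_violators: int = 0
    n_ld_duplicates: int = 0
    fst: float = 0.0

    def __post_init__(self) -> None:
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        if self.n_hwe_violators + self.n_ld_duplicates > self.n_snps:
            raise ValueError("more engineered violations than SNPs")
        for name in ("fracture_prevalence", "bmd_measured_fraction",
                     "low_bmd_prevalence", "missing_rate", "fst"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0 and not (name == "bmd_measured_fraction"
                                           and v == 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        for name in ("h2_fracture", "h2_bmd"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        lo, hi = self.maf_range
        if not 0.0 < lo < hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo < hi <= 0.5")
        if not 0.0 < self.or_range[0] <= self.or_range[1]:
            raise ValueError("or_range must be positive and ordered")


@dataclass
class TrueModel:
    """Generative truth retained for oracle checks."""

    betas: np.ndarray               # per-panel-variant causal log-OR
    genetic_value: np.ndarray       # per-sample sum of beta * dosage
    liability_fracture: np.ndarray
    liability_bmd: np.ndarray
    threshold_fracture: float
    threshold_bmd: float

    def __post_init__(self) -> None:
        for arr in (self.genetic_value, self.liability_fracture,
                    self.liability_bmd):
            if arr.shape != self.genetic_value.shape:
                raise ValueError("per-sample arrays differ in length")


@dataclass
class SimulatedCohort:
    """Everything one simulation produced."""

    config: SimConfig
    weights: WeightTable
    allele_freqs: np.ndarray
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    truth: TrueModel
    subpopulation: np.ndarray | None = None
    hwe_violators: list[str] = field(default_factory=list)
    ld_duplicates: list[str] = field(default_factory=list)
    #: source variant copied by each LD duplicate, same order
    ld_duplicate_sources: list[str] = field(default_factory=list)


def sample_panel(cfg: SimConfig,
                 rng: np.random.Generator) -> tuple[WeightTable, np.ndarray]:
    """Draw a SNP panel: positions, alleles, frequencies and weights.

    MAFs are uniform on ``maf_range``; the effect allele is the minor or
    major allele with equal probability, so effect-allele frequencies span
    both sides of 0.5. ``n_causal`` variants get odds ratios drawn
    log-uniformly from ``or_range``; the rest get OR = 1.

    Returns the weight table and the per-variant effect-allele frequency.
    """
    m = cfg.n_snps
    mafs = rng.uniform(*cfg.maf_range, size=m)
    flip = rng.random(m) < 0.5
    freqs = np.where(flip, 1.0 - mafs, mafs)
    causal = np.zeros(m, dtype=bool)
    causal[rng.choice(m, size=cfg.n_causal, replace=False)] = True
    log_or = np.where(
        causal,
        rng.uniform(np.log(cfg.or_range[0]), np.log(cfg.or_range[1]),
                    size=m),
        0.0)
    chroms = (np.arange(m) % 22) + 1
    positions = 1_000_000 + (np.arange(m) // 22 + 1) * 50_000
    variants = []
    for j in range(m):
        ea, oa = rng.choice(_BASES, size=2, replace=False)
        variants.append(VariantRecord(
            variant_id=f"rs{900000 + j}",
            chromosome=str(chroms[j]),
            position=int(positions[j]),
            effect_allele=str(ea),
            other_allele=str(oa),
            effect_size=float(np.exp(log_or[j])),
        ))
    return WeightTable(variants), freqs


def simulate_genotypes(panel: WeightTable, freqs: np.ndarray,
                       cfg: SimConfig, rng: np.random.Generator
                       ) -> tuple[GenotypeMatrix, np.ndarray | None]:
    """Hardy-Weinberg genotypes, optionally with two-subpopulation drift.

    With ``fst = 0`` dosages are Binomial(2, p). With ``fst > 0`` each of
    two equal subpopulations draws its own allele frequency from the
    Balding-Nichols Beta around the ancestral frequency, giving the
    Fst-controlled differentiation PCA should detect. Missingness (MCAR at
    ``missing_rate``) is injected here.
    """
    n, m = cfg.n_samples, len(panel)
    subpop = None
    if cfg.fst > 0.0:
        subpop = np.zeros(n, dtype=int)
        subpop[n // 2:] = 1
        a = freqs * (1.0 - cfg.fst) / cfg.fst
        b = (1.0 - freqs) * (1.0 - cfg.fst) / cfg.fst
        pop_freqs = np.stack([rng.beta(a, b), rng.beta(a, b)])
        p_per_sample = pop_freqs[subpop]         # n x m
        dosage = rng.binomial(2, p_per_sample)
    else:
        dosage = rng.binomial(2, freqs, size=(n, m))
    missing = np.zeros((n, m), dtype=bool)
    if cfg.missing_rate > 0.0:
        missing = rng.random((n, m)) < cfg.missing_rate
    G = GenotypeMatrix(
        sample_ids=[f"S{i:05d}" for i in range(n)],
        variants=list(panel),
        dosage=dosage.astype(np.int8),
        missing=missing)
    return G, subpop


def inject_qc_violations(G: GenotypeMatrix, freqs: np.ndarray,
                         cfg: SimConfig, rng: np.random.Generator,
                         avoid: np.ndarray | None = None
                         ) -> tuple[GenotypeMatrix, list[str], list[str],
                                    list[str]]:
    """Engineer HWE violators and LD near-duplicates into a matrix.

    HWE violators get their column redrawn with heterozygote depletion
    (inbreeding coefficient F = 0.5 at the variant's own frequency); they
    are drawn from variants with frequency in [0.1, 0.9], where the
    distortion is well-powered. LD duplicates emulate a redundant assay:
    a copy of another variant's dosages with 1% of entries resampled and
    2% of calls dropped, so the duplicate is strictly the lower-call-rate
    member of its pair. ``avoid`` marks columns (e.g. causal loci) exempt
    from tampering so the generative phenotype model stays intact. Returns
    the new matrix and the truth labels of both violation sets.
    """
    n_bad = cfg.n_hwe_violators + cfg.n_ld_duplicates
    if n_bad == 0:
        return G, [], [], []
    eligible = np.arange(G.n_variants)
    if avoid is not None:
        eligible = eligible[~np.asarray(avoid, dtype=bool)]
    if eligible.size < n_bad:
        raise ValueError("not enough non-causal variants to tamper with")
    common = eligible[(freqs[eligible] >= 0.1) & (freqs[eligible] <= 0.9)]
    if common.size >= cfg.n_hwe_violators:
        hwe_idx = rng.choice(common, size=cfg.n_hwe_violators,
                             replace=False)
    else:
        # too few common loci: fall back to the most-intermediate
        # frequencies available, where the distortion is best powered
        order = eligible[np.argsort(np.abs(freqs[eligible] - 0.5),
                                    kind="stable")]
        hwe_idx = order[:cfg.n_hwe_violators]
    rest = np.setdiff1d(eligible, hwe_idx)
    dup_idx = rng.choice(rest, size=cfg.n_ld_duplicates, replace=False)
    chosen = np.concatenate([hwe_idx, dup_idx])
    dosage = G.dosage.copy()
    missing = G.missing.copy()
    n = G.n_samples
    sources: list[str] = []
    F = 0.5
    for j in hwe_idx:
        p = freqs[j]
        probs = np.array([
            (1 - p) ** 2 + F * p * (1 - p),
            2 * p * (1 - p) * (1 - F),
            p ** 2 + F * p * (1 - p)])
        dosage[:, j] = rng.choice(3, size=n, p=probs / probs.sum())
    for j in dup_idx:
        pool = np.setdiff1d(np.arange(G.n_variants), chosen)
        src = int(rng.choice(pool))
        sources.append(G.variant_ids[src])
        col = dosage[:, src].copy()
        flip = rng.random(n) < 0.01
        col[flip] = rng.binomial(2, freqs[src], size=int(flip.sum()))
        dosage[:, j] = col
        dropped = rng.choice(n, size=max(1, int(round(0.02 * n))),
                             replace=False)
        missing[dropped, j] = True
        # duplicates must share a chromosome with their source to be
        # prunable; relabel the variant onto the source's chromosome
        v = G.variants[src]
        old = G.variants[j]
        G.variants[j] = VariantRecord(
            variant_id=old.variant_id, chromosome=v.chromosome,
            position=v.position + 1, effect_allele=old.effect_allele,
            other_allele=old.other_allele, effect_size=old.effect_size)
    G2 = GenotypeMatrix(sample_ids=G.sample_ids, variants=G.variants,
                        dosage=dosage, missing=missing)
    return (G2, [G.variant_ids[j] for j in hwe_idx],
            [G.variant_ids[j] for j in dup_idx], sources)


def liability_phenotypes(G: GenotypeMatrix, panel: WeightTable,
                         cfg: SimConfig, rng: np.random.Generator,
                         dosage_complete: np.ndarray | None = None
                         ) -> tuple[pd.DataFrame, TrueModel]:
    """Liability-threshold phenotypes from the panel's causal effects.

    The genetic value g = Σ beta_i·dosage_i (beta = ln OR) is standardized
    and each trait's liability is sqrt(h²)·g + sqrt(1-h²)·e with the two
    environmental deviates correlated so the total liability correlation
    approaches ``cross_trait_corr``. Fracture cases are the top
    ``fracture_prevalence`` of fracture liability. BMD is measured in a
    random ``bmd_measured_fraction`` subset; T-scores are an affine map of
    BMD liability with the low-BMD threshold pinned at T = -1, giving
    ``low_bmd_prevalence`` below threshold and WHO classes consistent with
    the scores. Comorbid cases (fracture AND low BMD) arise by
    construction as the intersection.
    """
    betas = np.log([v.effect_size for v in panel])
    dos = (dosage_complete if dosage_complete is not None
           else G.dosage).astype(float)
    if np.any(dos < 0):
        raise ValueError("phenotype generation needs complete dosages")
    g = dos @ betas
    g_sd = g.std()
    g_std = (g - g.mean()) / g_sd if g_sd > 0 else np.zeros_like(g)

    h1, h2 = cfg.h2_fracture, cfg.h2_bmd
    e_sd1, e_sd2 = np.sqrt(1 - h1), np.sqrt(1 - h2)
    if e_sd1 == 0 or e_sd2 == 0:
        raise ValueError("degenerate environmental variance (h² = 1)")
    target = cfg.cross_trait_corr
    rho_e = (target - np.sqrt(h1 * h2)) / (e_sd1 * e_sd2)
    rho_e = float(np.clip(rho_e, -1.0, 1.0))
    n = G.n_samples
    e1 = rng.standard_normal(n)
    e2 = rho_e * e1 + np.sqrt(1 - rho_e ** 2) * rng.standard_normal(n)
    liab_frac = np.sqrt(h1) * g_std + e_sd1 * e1
    liab_bmd = np.sqrt(h2) * g_std + e_sd2 * e2

    thr_frac = float(np.quantile(liab_frac, 1 - cfg.fracture_prevalence))
    fracture = np.where(liab_frac > thr_frac, "case", "control")

    measured = rng.random(n) < cfg.bmd_measured_fraction
    thr_bmd = float(np.quantile(liab_bmd, 1 - cfg.low_bmd_prevalence))
    t_score = np.where(measured, -1.0 - (liab_bmd - thr_bmd), np.nan)
    # nudge exact-threshold values onto the low side is unnecessary:
    # t = -1 is osteopenia, matching liability == threshold being a case
    bmd_class = [classify_t_score(t) for t in t_score]

    ethnicity = rng.choice(["tatar", "russian", "other"], size=n,
                           p=[0.45, 0.45, 0.10])
    age = rng.normal(61.95, 7.94, size=n).clip(45, 90)
    bmi = rng.normal(27.5, 3.7, size=n).clip(16, 45)
    pheno = pd.DataFrame({
        "sample_id": G.sample_ids,
        "fracture": fracture,
        "t_score": t_score,
        "bmd_class": bmd_class,
        "ethnicity": ethnicity,
        "age_years": np.round(age, 1),
        "bmi": np.round(bmi, 1),
    })
    model = TrueModel(
        betas=betas, genetic_value=g,
        liability_fracture=liab_frac, liability_bmd=liab_bmd,
        threshold_fracture=thr_frac, threshold_bmd=thr_bmd)
    return validate_phenotypes(pheno), model


def oracle_auc(model: TrueModel, labels) -> float:
    """AUC of the true genetic values against a label vector.

    The reference any score built from the true betas must match: a score
    that is a monotone function of g has exactly this AUC.
    """
    from .evaluate import empirical_auc
    return empirical_auc(model.genetic_value, labels)


def simulate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Run the whole generator: panel, genotypes, violations, phenotypes.

    Phenotypes are generated from the complete (pre-tampering,
    pre-missingness) dosages of the causal loci, so engineered QC
    violations and missing calls act purely as measurement artifacts.
    """
    rng = np.random.default_rng(cfg.seed)
    panel, freqs = sample_panel(cfg, rng)
    # genotypes drawn complete; missingness held until after phenotypes
    clean_cfg = cfg
    G, subpop = simulate_genotypes(panel, freqs,
                                   _no_missing(cfg), rng)
    complete_dosage = G.dosage.copy()
    causal = np.array([v.effect_size != 1.0 for v in panel])
    G, hwe_ids, dup_ids, dup_src = inject_qc_violations(
        G, freqs, cfg, rng, avoid=causal)
    pheno, truth = liability_phenotypes(
        G, panel, clean_cfg, rng, dosage_complete=complete_dosage)
    if cfg.missing_rate > 0.0:
        mcar = rng.random(G.dosage.shape) < cfg.missing_rate
        G = GenotypeMatrix(sample_ids=G.sample_ids, variants=G.variants,
                           dosage=G.dosage.copy(),
                           missing=G.missing | mcar)
    return SimulatedCohort(
        config=cfg, weights=panel, allele_freqs=freqs, genotypes=G,
        phenotypes=pheno, truth=truth, subpopulation=subpop,
        hwe_violators=hwe_ids, ld_duplicates=dup_ids,
        ld_duplicate_sources=dup_src)


def _no_missing(cfg: SimConfig) -> SimConfig:
    from dataclasses import replace
    return replace(cfg, missing_rate=0.0)
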