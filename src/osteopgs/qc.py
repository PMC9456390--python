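"""Genotype quality control.

First stage of the scoring pipeline: drop samples and variants failing
call-rate, minor-allele-frequency, Hardy-Weinberg and linkage-disequilibrium
criteria, in that fixed order, so that every removal has exactly one primary
reason and reports are reproducible.

The Hardy-Weinberg test is the exact conditional test (enumeration over all
heterozygote counts compatible with the observed allele counts), computed in
exact rational arithmetic — stable for the rare alleles typical of curated
SNP panels, where the chi-square approximation is unreliable. LD is measured
as squared Pearson correlation of dosages (composite LD), the standard
phase-free surrogate for haplotype r².

Cochran's Q and I² for effect-weight heterogeneity are provided for panel
curation; they are not part of the default filtering path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .containers import GenotypeMatrix

FILTER_ORDER = ("call_rate", "maf", "hwe", "ld")


@dataclass
class QcConfig:
    """Thresholds for the QC pass.

    Defaults follow common practice for small curated panels: 97% call rate
    for samples and variants, MAF window 1-49%, HWE exact p < 0.05,
    dosage r² > 0.8 for pruning. ``heterogeneity_alpha`` applies to
    Cochran-Q screening of effect weights (p < 0.1 flags heterogeneity).
    """

    sample_call_rate_min: float = 0.97
    variant_call_rate_min: float = 0.97
    maf_min: float = 0.01
    maf_max: float = 0.49
    hwe_alpha: float = 0.05
    ld_r2_max: float = 0.8
    heterogeneity_alpha: float = 0.1

    def __post_init__(self) -> None:
        for name in ("sample_call_rate_min", "variant_call_rate_min",
                     "maf_min", "maf_max", "hwe_alpha", "ld_r2_max",
                     "heterogeneity_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.maf_min >= self.maf_max:
            raise ValueError("maf_min must be < maf_max")


@dataclass
class QcReport:
    """Accounting of one QC pass: what went in, what was removed and why."""

    n_variants_in: int
    n_variants_out: int
    removed: list[tuple[str, str]]
    n_samples_in: int
    n_samples_out: int
    removed_samples: list[str]
    per_variant_stats: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.n_variants_out + len(self.removed) != self.n_variants_in:
            raise ValueError("variant removal accounting does not sum")
        for _, reason in self.removed:
            if reason not in FILTER_ORDER:
                raise ValueError(f"unknown removal reason {reason!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["removed"] = [list(r) for r in self.removed]
        d["per_variant_stats"] = self.per_variant_stats.to_dict("records")
        return d


def minor_allele_frequency(dosages: np.ndarray) -> float:
    """MAF of a non-missing dosage vector: min(p, 1-p), p = mean/2."""
    dosages = np.asarray(dosages, dtype=float)
    if dosages.size == 0:
        raise ValueError("empty dosage vector")
    p = dosages.mean() / 2.0
    return float(min(p, 1.0 - p))


def _hwe_weights(n_ref: int, n_alt: int) -> tuple[list[int], list[int]]:
    """Feasible het counts and their (unnormalized) conditional weights.

    Conditional on allele counts, P(n_het = h) ∝ n!/(a! h! b!) · 2^h with
    a, b the implied homozygote counts — the number of genotype
    configurations realizing each table. Integer weights keep ties exact.
    """
    n = (n_ref + n_alt) // 2
    rare = min(n_ref, n_alt)
    hets = list(range(rare % 2, rare + 1, 2))
    weights = []
    for h in hets:
        a = (n_ref - h) // 2
        weights.append(math.comb(n, h) * math.comb(n - h, a) * 2 ** h)
    return hets, weights


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg p-value for one biallelic variant.

    Sums, over every heterozygote count consistent with the observed allele
    counts, the conditional probabilities no larger than that of the
    observed genotype table. Comparisons are exact (rational arithmetic),
    so the test is strictly invariant to swapping the homozygote classes.
    """
    for name, v in (("n_hom_ref", n_hom_ref), ("n_het", n_het),
                    ("n_hom_alt", n_hom_alt)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no genotypes observed")
    n_ref = 2 * n_hom_ref + n_het
    n_alt = 2 * n_hom_alt + n_het
    hets, weights = _hwe_weights(n_ref, n_alt)
    w_obs = weights[hets.index(n_het)]
    p = Fraction(sum(w for w in weights if w <= w_obs), sum(weights))
    return float(p)


def ld_r2(d1: np.ndarray, d2: np.ndarray,
          m1: np.ndarray | None = None,
          m2: np.ndarray | None = None) -> float:
    """Squared dosage correlation between two variants.

    Computed over pairwise-complete entries. Returns ``nan`` when either
    variant is monomorphic on that subset (callers treat nan as r² = 0 for
    pruning purposes).
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape:
        raise ValueError("dosage vectors differ in length")
    keep = np.ones(d1.shape, dtype=bool)
    if m1 is not None:
        keep &= ~np.asarray(m1, dtype=bool)
    if m2 is not None:
        keep &= ~np.asarray(m2, dtype=bool)
    x, y = d1[keep], d2[keep]
    if x.size < 2:
        raise ValueError("fewer than 2 pairwise-complete entries")
    if x.std() == 0.0 or y.std() == 0.0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def cochran_q(effects: np.ndarray,
              std_errors: np.ndarray) -> tuple[float, int, float, float]:
    """Cochran's Q heterogeneity test and I² for a set of log-OR estimates.

    Returns ``(Q, df, p, I²)`` with inverse-variance weights, chi-square
    reference with k-1 degrees of freedom, and I² = max(0, (Q-df)/Q)·100.
    """
    effects = np.asarray(effects, dtype=float)
    std_errors = np.asarray(std_errors, dtype=float)
    if effects.size < 2:
        raise ValueError("need at least 2 effects for heterogeneity")
    if effects.shape != std_errors.shape:
        raise ValueError("effects and std_errors differ in length")
    if np.any(std_errors <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / std_errors ** 2
    beta_bar = np.sum(w * effects) / np.sum(w)
    q = float(np.sum(w * (effects - beta_bar) ** 2))
    df = effects.size - 1
    p = float(stats.chi2.sf(q, df))
    i2 = 0.0 if q <= 0 else max(0.0, (q - df) / q) * 100.0
    return q, df, p, i2


def call_rate_filter(
    G: GenotypeMatrix, cfg: QcConfig
) -> tuple[GenotypeMatrix, list[str], list[str]]:
    """Drop low-call-rate samples, then low-call-rate variants.

    Variant call rates are computed on the retained samples. Returns the
    filtered matrix plus the removed sample and variant IDs.
    """
    if G.n_samples == 0 or G.n_variants == 0:
        raise ValueError("empty genotype matrix")
    keep_s = G.sample_call_rate() >= cfg.sample_call_rate_min
    removed_samples = [s for s, k in zip(G.sample_ids, keep_s) if not k]
    if not keep_s.any():
        raise ValueError("call-rate filter removed every sample")
    G = G.take_samples(np.flatnonzero(keep_s))
    keep_v = G.variant_call_rate() >= cfg.variant_call_rate_min
    removed_variants = [v for v, k in zip(G.variant_ids, keep_v) if not k]
    G = G.take_variants(np.flatnonzero(keep_v))
    return G, removed_samples, removed_variants


def _prune_preference(call_rate: float, maf: float, order: int):
    # higher call rate wins, then higher MAF, then earlier map position
    return (-call_rate, -maf, order)


def ld_prune(G: GenotypeMatrix,
             cfg: QcConfig) -> tuple[GenotypeMatrix, list[str]]:
    """Greedy per-chromosome LD pruning in map order.

    Walking variants in map order, a variant conflicting (r² > threshold)
    with an already-kept variant on the same chromosome is resolved in
    favour of the higher call rate (ties: higher MAF, then map order).
    """
    call_rates = G.variant_call_rate()
    mafs = np.array([
        minor_allele_frequency(G.dosage[~G.missing[:, j], j])
        if (~G.missing[:, j]).any() else 0.0
        for j in range(G.n_variants)
    ])
    kept: list[int] = []
    removed: set[int] = set()
    for j in range(G.n_variants):
        conflicts = []
        for k in kept:
            if G.variants[k].chromosome != G.variants[j].chromosome:
                continue
            r2 = ld_r2(G.dosage[:, k], G.dosage[:, j],
                       G.missing[:, k], G.missing[:, j])
            if not math.isnan(r2) and r2 > cfg.ld_r2_max:
                conflicts.append(k)
        if not conflicts:
            kept.append(j)
            continue
        pref_j = _prune_preference(call_rates[j], mafs[j], j)
        if all(pref_j < _prune_preference(call_rates[k], mafs[k], k)
               for k in conflicts):
            for k in conflicts:
                kept.remove(k)
                removed.add(k)
            kept.append(j)
        else:
            removed.add(j)
    removed_ids = [G.variant_ids[j] for j in sorted(removed)]
    return G.take_variants(np.array(sorted(kept), dtype=int)), removed_ids


class GenotypeQC(BaseEstimator):
    """Quality-control transformer for genotype matrices.

    ``fit`` decides, on a cohort, which samples and variants to drop;
    ``transform`` applies those decisions. Filters run in a fixed order —
    sample call rate, variant call rate, MAF window, HWE exact test,
    LD pruning — and each removed variant is attributed to the first filter
    it failed.

    Parameters mirror :class:`QcConfig`. ``hwe_on_controls`` restricts the
    HWE test to control samples when a control mask is passed to ``fit``
    (case ascertainment distorts genotype frequencies at truly associated
    loci); with no mask the whole cohort is tested.
    """

    def __init__(self, sample_call_rate_min: float = 0.97,
                 variant_call_rate_min: float = 0.97,
                 maf_min: float = 0.01, maf_max: float = 0.49,
                 hwe_alpha: float = 0.05, ld_r2_max: float = 0.8,
                 hwe_on_controls: bool = True):
        self.sample_call_rate_min = sample_call_rate_min
        self.variant_call_rate_min = variant_call_rate_min
        self.maf_min = maf_min
        self.maf_max = maf_max
        self.hwe_alpha = hwe_alpha
        self.ld_r2_max = ld_r2_max
        self.hwe_on_controls = hwe_on_controls

    def _config(self) -> QcConfig:
        return QcConfig(
            sample_call_rate_min=self.sample_call_rate_min,
            variant_call_rate_min=self.variant_call_rate_min,
            maf_min=self.maf_min, maf_max=self.maf_max,
            hwe_alpha=self.hwe_alpha, ld_r2_max=self.ld_r2_max)

    def _single_pass(self, G: GenotypeMatrix, cfg: QcConfig,
                     controls: np.ndarray | None):
        removed: list[tuple[str, str]] = []
        all_sample_ids = list(G.sample_ids)
        G1, removed_samples, cr_variants = call_rate_filter(G, cfg)
        removed += [(v, "call_rate") for v in cr_variants]
        if controls is not None:
            kept_set = set(G1.sample_ids)
            controls = np.array(
                [c for s, c in zip(all_sample_ids, controls)
                 if s in kept_set])

        if self.hwe_on_controls and controls is not None:
            hwe_matrix = G1.take_samples(np.flatnonzero(controls))
        else:
            hwe_matrix = G1
        call_rates = G1.variant_call_rate()
        stats_rows = []
        keep = np.ones(G1.n_variants, dtype=bool)
        for j in range(G1.n_variants):
            obs = G1.dosage[~G1.missing[:, j], j]
            maf = minor_allele_frequency(obs) if obs.size else 0.0
            n0, n1, n2 = hwe_matrix.genotype_counts(j)
            hwe_p = hwe_exact_test(n0, n1, n2) if n0 + n1 + n2 else 1.0
            stats_rows.append({"variant_id": G1.variant_ids[j],
                               "call_rate": float(call_rates[j]),
                               "maf": maf, "hwe_p": hwe_p})
            if not (cfg.maf_min <= maf <= cfg.maf_max):
                removed.append((G1.variant_ids[j], "maf"))
                keep[j] = False
            elif hwe_p < cfg.hwe_alpha:
                removed.append((G1.variant_ids[j], "hwe"))
                keep[j] = False
        G2 = G1.take_variants(np.flatnonzero(keep))

        G3, ld_removed = ld_prune(G2, cfg)
        removed += [(v, "ld") for v in ld_removed]
        stats = pd.DataFrame(
            stats_rows, columns=["variant_id", "call_rate", "maf", "hwe_p"])
        return G3, removed, removed_samples, controls, stats

    def fit(self, G: GenotypeMatrix, y=None, *,
            controls: np.ndarray | None = None) -> "GenotypeQC":
        """Run the QC decision passes on a cohort.

        The full filter sequence is repeated until no sample or variant is
        removed (dropping variants can push a sample's call rate on the
        surviving panel below threshold, and vice versa), so QC is
        idempotent: re-running it on its own output removes nothing.

        ``controls`` is an optional boolean mask over ``G.sample_ids``
        marking control samples for the HWE test.
        """
        cfg = self._config()
        n_samples_in, n_variants_in = G.n_samples, G.n_variants
        if controls is not None:
            controls = np.asarray(controls, dtype=bool)
            if controls.shape != (n_samples_in,):
                raise ValueError("controls mask length must match samples")

        removed: list[tuple[str, str]] = []
        removed_samples: list[str] = []
        first_stats: pd.DataFrame | None = None
        while True:
            G, pass_removed, pass_samples, controls, stats = \
                self._single_pass(G, cfg, controls)
            removed += pass_removed
            removed_samples += pass_samples
            if first_stats is None:
                first_stats = stats
            if not pass_removed and not pass_samples:
                break
        if G.n_variants == 0:
            raise ValueError("no variants survived QC")

        self.keep_sample_ids_ = list(G.sample_ids)
        self.keep_variant_ids_ = list(G.variant_ids)
        self.report_ = QcReport(
            n_variants_in=n_variants_in,
            n_variants_out=G.n_variants,
            removed=removed,
            n_samples_in=n_samples_in,
            n_samples_out=G.n_samples,
            removed_samples=removed_samples,
            per_variant_stats=first_stats,
        )
        return self

    def transform(self, G: GenotypeMatrix) -> GenotypeMatrix:
        """Apply the fitted sample/variant selection to a matrix."""
        if not hasattr(self, "keep_variant_ids_"):
            raise RuntimeError("GenotypeQC is not fitted")
        s_idx = [i for i, s in enumerate(G.sample_ids)
                 if s in set(self.keep_sample_ids_)]
        v_idx = [j for j, v in enumerate(G.variant_ids)
                 if v in set(self.keep_variant_ids_)]
        return G.take_samples(np.array(s_idx, dtype=int)).take_variants(
            np.array(v_idx, dtype=int))

    def fit_transform(self, G: GenotypeMatrix, y=None, **fit_params):
        return self.fit(G, y, **fit_params).transform(G)


def run_qc(G: GenotypeMatrix, cfg: QcConfig | None = None, *,
           controls: np.ndarray | None = None
           ) -> tuple[GenotypeMatrix, QcReport]:
    """One-shot QC: returns the filtered matrix and its report."""
    cfg = cfg or QcConfig()
    qc = GenotypeQC(
        sample_call_rate_min=cfg.sample_call_rate_min,
        variant_call_rate_min=cfg.variant_call_rate_min,
        maf_min=cfg.maf_min, maf_max=cfg.maf_max,
        hwe_alpha=cfg.hwe_alpha, ld_r2_max=cfg.ld_r2_max)
    out = qc.fit_transform(G, controls=controls)
    return out, qc.report_
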