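"""Per-individual polygenic score computation and normalization.

For sample *j* the raw score is

    PRS_j = Σ_i s_i · G_ij / (P · M_j)

where the sum runs over the panel variants with a called genotype for
sample *j*, ``s_i`` is the variant weight — ``ln(OR_i)`` under the default
``log`` transform, or the odds ratio itself under ``identity`` — ``G_ij``
the effect-allele dosage, ``P = 2`` the ploidy, and ``M_j`` the number of
non-missing panel variants for that sample (the average-score convention:
a sample is never penalized for genotypes that failed). Raw scores are then
z-normalized over the cohort.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .containers import GenotypeMatrix, ScoreSet, WeightTable

PLOIDY = 2


def compute_prs(G: GenotypeMatrix, weights: WeightTable,
                transform: str = "log",
                missing_policy: str = "observed") -> ScoreSet:
    """Raw polygenic scores for every sample (no normalization).

    ``weights`` must be a subset of the matrix variants (matched by
    variant_id); every sample needs at least one called genotype on the
    panel.

    ``missing_policy`` governs failed genotypes: ``"observed"`` restricts
    the sum to called variants and shrinks the denominator to 2·M_j (the
    printed formula); ``"impute_freq"`` substitutes the cohort expected
    dosage 2p̂ for each missing call and keeps the full 2·N denominator —
    the default behaviour of PLINK ``--score``, which avoids the
    missing-pattern noise the shrunken denominator admits.
    """
    if transform not in ("log", "identity"):
        raise ValueError(f"transform must be 'log' or 'identity', "
                         f"got {transform!r}")
    if missing_policy not in ("observed", "impute_freq"):
        raise ValueError("missing_policy must be 'observed' or "
                         f"'impute_freq', got {missing_policy!r}")
    col = {v: j for j, v in enumerate(G.variant_ids)}
    absent = [v.variant_id for v in weights if v.variant_id not in col]
    if absent:
        raise ValueError(
            f"weight-table variants absent from genotypes: {absent[:5]}"
            + ("..." if len(absent) > 5 else ""))
    idx = np.array([col[v.variant_id] for v in weights], dtype=int)
    s = weights.effect_sizes
    s = np.log(s) if transform == "log" else s

    dos = G.dosage[:, idx].astype(float)
    miss = G.missing[:, idx]
    dos[miss] = 0.0
    n_used = (~miss).sum(axis=1)
    if np.any(n_used == 0):
        bad = [G.sample_ids[i] for i in np.flatnonzero(n_used == 0)]
        raise ValueError(f"samples with no called panel genotype: {bad[:5]}")
    if missing_policy == "impute_freq":
        with np.errstate(invalid="ignore"):
            freq = np.ma.masked_array(dos, mask=miss).mean(axis=0) / 2.0
        exp_dosage = 2.0 * np.asarray(freq.filled(0.0))
        dos = dos + miss * exp_dosage
        raw = (dos @ s) / (PLOIDY * len(idx))
    else:
        raw = (dos @ s) / (PLOIDY * n_used)
    return ScoreSet(sample_ids=list(G.sample_ids), raw_prs=raw,
                    z_prs=None, n_used=n_used, weight_transform=transform)


def normalize_scores(raw_prs: np.ndarray) -> np.ndarray:
    """Cohort z-scores: (x - mean) / sample SD (n-1 denominator)."""
    raw_prs = np.asarray(raw_prs, dtype=float)
    if raw_prs.size < 2:
        raise ValueError("need >= 2 samples to normalize")
    sd = raw_prs.std(ddof=1)
    if sd == 0.0:
        raise ValueError("degenerate cohort: zero score variance")
    return (raw_prs - raw_prs.mean()) / sd


def score_percentiles(scores: ScoreSet) -> np.ndarray:
    """Percentile rank in [0, 100] of each sample's raw score.

    Midpoint convention with average ranks for ties: rank r of n maps to
    100·(r - 0.5)/n, so an all-tied cohort sits at 50.
    """
    ranks = stats.rankdata(scores.raw_prs, method="average")
    return 100.0 * (ranks - 0.5) / ranks.size


class PGSScorer(BaseEstimator):
    """Polygenic-score transformer with cohort normalization.

    ``fit`` computes raw scores on a reference cohort and learns the
    normalization (mean/SD); ``transform`` scores a matrix and applies the
    fitted normalization, so external samples can be placed on the fitted
    cohort's z-scale.

    Parameters
    ----------
    weights : WeightTable
        Scoring panel (effect alleles and odds ratios).
    weight_transform : {"log", "identity"}
        Per-variant weight: ln(OR) (default, additive on the log-odds
        scale) or the raw OR.
    normalize : {"cohort", "none"}
        Whether ``transform`` outputs z-scores or raw scores.
    """

    def __init__(self, weights: WeightTable,
                 weight_transform: str = "log", normalize: str = "cohort",
                 missing_policy: str = "impute_freq"):
        self.weights = weights
        self.weight_transform = weight_transform
        self.normalize = normalize
        self.missing_policy = missing_policy

    def fit(self, G: GenotypeMatrix, y=None) -> "PGSScorer":
        if self.normalize not in ("cohort", "none"):
            raise ValueError("normalize must be 'cohort' or 'none'")
        raw = compute_prs(G, self.weights, self.weight_transform,
                          self.missing_policy).raw_prs
        self.mean_ = float(raw.mean())
        sd = float(raw.std(ddof=1)) if raw.size > 1 else 0.0
        if self.normalize == "cohort" and sd == 0.0:
            raise ValueError("degenerate cohort: zero score variance")
        self.sd_ = sd
        return self

    def transform_scores(self, G: GenotypeMatrix) -> ScoreSet:
        """Score a matrix, returning the full :class:`ScoreSet`."""
        if not hasattr(self, "mean_"):
            raise RuntimeError("PGSScorer is not fitted")
        ss = compute_prs(G, self.weights, self.weight_transform,
                         self.missing_policy)
        if self.normalize == "cohort":
            ss.z_prs = (ss.raw_prs - self.mean_) / self.sd_
        return ss

    def transform(self, G: GenotypeMatrix) -> np.ndarray:
        """Scores as a column vector (z if normalizing, else raw)."""
        ss = self.transform_scores(G)
        out = ss.z_prs if self.normalize == "cohort" else ss.raw_prs
        return np.asarray(out)[:, None]

    def fit_transform(self, G: GenotypeMatrix, y=None) -> np.ndarray:
        return self.fit(G).transform(G)


def score_cohort(G: GenotypeMatrix, weights: WeightTable,
                 transform: str = "log",
                 missing_policy: str = "impute_freq") -> ScoreSet:
    """Compute raw and cohort-normalized scores in one pass.

    Cohort scoring defaults to frequency imputation of missing genotypes
    (see :func:`compute_prs`); the shrunken-denominator convention is a
    call away for exact agreement with the printed per-sample formula.
    """
    ss = compute_prs(G, weights, transform, missing_policy)
    ss.z_prs = normalize_scores(ss.raw_prs)
    return ss
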