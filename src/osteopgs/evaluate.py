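"""Case-control evaluation of polygenic scores.

One contrast (fracture, low BMD, or the comorbid combination) is evaluated
with the standard battery: Mann-Whitney AUC with a DeLong (or bootstrap)
95% CI, the ROC curve and its Youden operating point, odds ratio per SD of
the normalized score from univariable logistic regression (Firth-penalized
under separation), a top-vs-bottom-decile 2x2 odds ratio, a decile risk
table with a Cochran-Armitage trend test, and per-group score summaries
for density plotting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn import metrics as skm


# ---------------------------------------------------------------------------
# contrasts

@dataclass(frozen=True)
class ContrastSpec:
    """A named case/control definition over a phenotype table."""

    name: str
    case_rule: Callable[[pd.DataFrame], pd.Series]
    control_rule: Callable[[pd.DataFrame], pd.Series]

    def masks(self, pheno: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
        case = self.case_rule(pheno).astype(bool)
        control = self.control_rule(pheno).astype(bool)
        if (case & control).any():
            raise ValueError(f"{self.name}: case and control sets overlap")
        if not case.any() or not control.any():
            raise ValueError(f"{self.name}: empty case or control set")
        return case, control


def _low_bmd(p: pd.DataFrame) -> pd.Series:
    return p["bmd_class"].isin(["osteopenia", "osteoporosis"])


#: The three standard contrasts: fracture vs no fracture; low BMD
#: (osteopenia or osteoporosis by T-criterion) vs normal BMD; and the
#: comorbid contrast (fracture AND low BMD vs neither).
STANDARD_CONTRASTS: dict[str, ContrastSpec] = {
    "fracture": ContrastSpec(
        "fracture",
        lambda p: p["fracture"] == "case",
        lambda p: p["fracture"] == "control"),
    "low_bmd": ContrastSpec(
        "low_bmd",
        _low_bmd,
        lambda p: p["bmd_class"] == "normal"),
    "comorbid": ContrastSpec(
        "comorbid",
        lambda p: (p["fracture"] == "case") & _low_bmd(p),
        lambda p: (p["fracture"] == "control")
        & (p["bmd_class"] == "normal")),
}


# ---------------------------------------------------------------------------
# AUC / ROC

def _check_two_class(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both cases (1) and "
                         "controls (0)")
    return labels


def empirical_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(case score > control score) + ½·P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_class(labels)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    ranks = stats.rankdata(scores, method="average")
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    """DeLong variance of the empirical AUC via placement values."""
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    n1, n0 = cases.size, controls.size
    # V10[i]: fraction of controls below case i (ties half)
    order = np.sort(controls)
    v10 = (np.searchsorted(order, cases, side="left")
           + np.searchsorted(order, cases, side="right")) / (2.0 * n0)
    order = np.sort(cases)
    v01 = 1.0 - (np.searchsorted(order, controls, side="left")
                 + np.searchsorted(order, controls, side="right")) / (2.0 * n1)
    s10 = v10.var(ddof=1) if n1 > 1 else 0.0
    s01 = v01.var(ddof=1) if n0 > 1 else 0.0
    return s10 / n1 + s01 / n0


def auc_ci(scores, labels, level: float = 0.95,
           method: str = "delong", n_boot: int = 2000,
           seed: int = 0) -> tuple[float, float]:
    """Confidence interval for the empirical AUC, clipped to [0, 1].

    ``delong`` uses the DeLong variance with a normal approximation;
    ``bootstrap`` resamples cases and controls independently (percentile
    interval, seeded).
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_class(labels)
    auc = empirical_auc(scores, labels)
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        cases = scores[labels == 1]
        controls = scores[labels == 0]
        boots = np.empty(n_boot)
        lab = np.r_[np.ones(cases.size, int), np.zeros(controls.size, int)]
        for b in range(n_boot):
            sc = np.r_[rng.choice(cases, cases.size),
                       rng.choice(controls, controls.size)]
            boots[b] = empirical_auc(sc, lab)
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
        return float(lo), float(hi)
    if method != "delong":
        raise ValueError("method must be 'delong' or 'bootstrap'")
    var = _delong_variance(scores, labels)
    if var <= 0.0:
        warnings.warn("degenerate DeLong variance; returning the widest "
                      "informative interval [0, 1]")
        return 0.0, 1.0
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return float(max(0.0, auc - half)), float(min(1.0, auc + half))


def roc_curve(scores, labels) -> pd.DataFrame:
    """Stepwise ROC curve over all distinct thresholds.

    Columns ``threshold``, ``tpr``, ``fpr``; includes the (0,0) and (1,1)
    endpoints. Trapezoidal area under this curve equals the Mann-Whitney
    AUC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_class(labels)
    fpr, tpr, thr = skm.roc_curve(labels, scores, drop_intermediate=False)
    return pd.DataFrame({"threshold": thr, "tpr": tpr, "fpr": fpr})


def youden_operating_point(roc: pd.DataFrame) -> tuple[float, float, float]:
    """(threshold, sensitivity, specificity) maximizing Youden's J.

    Ties are broken toward higher sensitivity.
    """
    j = roc["tpr"] - roc["fpr"]
    best = roc.loc[(j == j.max())].sort_values("tpr", ascending=False)
    row = best.iloc[0]
    return float(row["threshold"]), float(row["tpr"]), float(1 - row["fpr"])


# ---------------------------------------------------------------------------
# odds ratios

def _firth_logistic(x: np.ndarray, y: np.ndarray,
                    max_iter: int = 200, tol: float = 1e-10):
    """Firth-penalized univariable logistic fit (intercept + slope).

    Returns (beta, se) for the slope. Used when ordinary ML separates.
    """
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        pi = 1.0 / (1.0 + np.exp(-eta))
        w = pi * (1.0 - pi)
        XtW = X.T * w
        info = XtW @ X
        info_inv = np.linalg.inv(info)
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * w
        score = X.T @ (y - pi + h * (0.5 - pi))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    pi = 1.0 / (1.0 + np.exp(-eta))
    w = pi * (1.0 - pi)
    cov = np.linalg.inv((X.T * w) @ X)
    return float(beta[1]), float(np.sqrt(cov[1, 1]))


def logistic_or_per_sd(z_scores, labels
                       ) -> tuple[float, float, float, float]:
    """Odds ratio per 1 SD of score from univariable logistic regression.

    Returns ``(OR, ci_lo, ci_hi, p)`` (Wald, 95%). Under complete
    separation the ML estimate diverges; a Firth-penalized fit is
    reported instead, with a warning.
    """
    z = np.asarray(z_scores, dtype=float)
    y = _check_two_class(labels).astype(float)
    separated = (z[y == 1].min() > z[y == 0].max()
                 or z[y == 1].max() < z[y == 0].min())
    beta = se = None
    if not separated:
        X = sm.add_constant(z)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if fit.mle_retvals.get("converged", False) and \
                    np.isfinite(fit.bse[1]) and fit.bse[1] < 1e3:
                beta, se = float(fit.params[1]), float(fit.bse[1])
        except Exception:
            beta = None
    if beta is None:
        warnings.warn("logistic fit separated or failed to converge; "
                      "reporting Firth-penalized estimate")
        beta, se = _firth_logistic(z, y)
    z_stat = beta / se
    p = 2.0 * stats.norm.sf(abs(z_stat))
    half = stats.norm.ppf(0.975) * se
    return (float(np.exp(beta)), float(np.exp(beta - half)),
            float(np.exp(beta + half)), float(p))


def odds_ratio_2x2(a: int, b: int, c: int, d: int
                   ) -> tuple[float, float, float, float]:
    """Odds ratio of a 2x2 table [[a, b], [c, d]] with Woolf 95% CI.

    ``a``/``b`` are exposed/unexposed cases, ``c``/``d`` controls. The
    Haldane-Anscombe 0.5 correction is applied when any cell is zero; the
    p-value is the Pearson chi-square test of the uncorrected table.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("cell counts must be non-negative")
    table = cells.reshape(2, 2)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("2x2 table has an empty row or column")
    if np.any(cells == 0):
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    or_ = (a_ * d_) / (b_ * c_)
    se = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    half = stats.norm.ppf(0.975) * se
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return (float(or_), float(np.exp(np.log(or_) - half)),
            float(np.exp(np.log(or_) + half)), float(p))


# ---------------------------------------------------------------------------
# deciles

def decile_table(scores, labels, sample_ids=None) -> pd.DataFrame:
    """Case counts within each tenth of the score distribution.

    Samples are ranked by score (ties resolved by sample_id for a stable,
    reproducible order) and cut into 10 contiguous groups; when the cohort
    size is not a multiple of 10 the lower deciles take the remainder.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_class(labels)
    n = scores.size
    if n < 10:
        raise ValueError("need a cohort of >= 10 to form deciles")
    if sample_ids is None:
        sample_ids = np.arange(n)
    order = np.lexsort((np.asarray(sample_ids), scores))
    sizes = np.full(10, n // 10)
    sizes[: n % 10] += 1
    rows = []
    start = 0
    for dec, size in enumerate(sizes, start=1):
        lab = labels[order[start:start + size]]
        n_cases = int(lab.sum())
        rows.append({"decile": dec, "n": int(size), "n_cases": n_cases,
                     "n_controls": int(size - n_cases),
                     "case_fraction": n_cases / size})
        start += size
    return pd.DataFrame(rows)


def decile_trend_test(table: pd.DataFrame) -> float:
    """Cochran-Armitage test for trend in case fraction across deciles.

    Decile indices 1..10 are the dose scores; returns the two-sided
    normal p-value (1.0 when the statistic is exactly zero).
    """
    s = table["decile"].to_numpy(dtype=float)
    n_i = table["n"].to_numpy(dtype=float)
    a_i = table["n_cases"].to_numpy(dtype=float)
    n = n_i.sum()
    a = a_i.sum()
    t_stat = float(np.sum(s * a_i) - a * np.sum(s * n_i) / n)
    p_bar = a / n
    var = p_bar * (1 - p_bar) * (np.sum(n_i * s ** 2)
                                 - np.sum(n_i * s) ** 2 / n)
    if var <= 0 or t_stat == 0.0:
        return 1.0
    z = t_stat / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def group_summary(scores, labels) -> dict[str, float]:
    """Medians and means of the score in cases and controls."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_class(labels)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    return {
        "median_case": float(np.median(cases)),
        "median_control": float(np.median(controls)),
        "mean_case": float(cases.mean()),
        "mean_control": float(controls.mean()),
    }


# ---------------------------------------------------------------------------
# report

@dataclass
class EvalReport:
    """Full evaluation of one case-control contrast."""

    contrast: str
    n_cases: int
    n_controls: int
    auc: float
    auc_ci: tuple[float, float]
    threshold: float
    sensitivity: float
    specificity: float
    or_per_sd: float
    or_per_sd_ci: tuple[float, float]
    or_per_sd_p: float
    or_extreme_deciles: float
    or_extreme_deciles_ci: tuple[float, float]
    or_extreme_deciles_p: float
    group_medians: dict[str, float]
    trend_p: float
    decile_table: pd.DataFrame = field(repr=False)
    roc: pd.DataFrame = field(repr=False)
    case_scores: np.ndarray = field(repr=False, default=None)
    control_scores: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC out of [0, 1]")
        lo, hi = self.auc_ci
        if not lo <= self.auc <= hi:
            raise ValueError("AUC outside its confidence interval")
        if len(self.decile_table) != 10:
            raise ValueError("decile table must have 10 rows")
        if int(self.decile_table["n"].sum()) != self.n_cases + \
                self.n_controls:
            raise ValueError("decile counts do not sum to cohort size")

    def to_dict(self) -> dict:
        return {
            "contrast": self.contrast,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "or_per_sd": self.or_per_sd,
            "or_per_sd_ci": list(self.or_per_sd_ci),
            "or_per_sd_p": self.or_per_sd_p,
            "or_extreme_deciles": self.or_extreme_deciles,
            "or_extreme_deciles_ci": list(self.or_extreme_deciles_ci),
            "or_extreme_deciles_p": self.or_extreme_deciles_p,
            "group_medians": self.group_medians,
            "trend_p": self.trend_p,
            "decile_table": self.decile_table.to_dict("records"),
            "roc": self.roc.to_dict("records"),
            "case_scores": ([] if self.case_scores is None
                            else list(map(float, self.case_scores))),
            "control_scores": ([] if self.control_scores is None
                               else list(map(float, self.control_scores))),
        }


def evaluate_contrast(scores, labels, name: str = "contrast",
                      sample_ids=None, ci_method: str = "delong",
                      seed: int = 0) -> EvalReport:
    """Run the full evaluation battery on one contrast.

    ``scores`` should be the cohort-normalized z-scores restricted to the
    contrast's cases and controls; ``labels`` 1 for case, 0 for control.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_class(labels)
    auc = empirical_auc(scores, labels)
    ci = auc_ci(scores, labels, method=ci_method, seed=seed)
    roc = roc_curve(scores, labels)
    thr, sens, spec = youden_operating_point(roc)
    or_sd, or_lo, or_hi, or_p = logistic_or_per_sd(scores, labels)
    deciles = decile_table(scores, labels, sample_ids)
    top, bottom = deciles.iloc[-1], deciles.iloc[0]
    g_or, g_lo, g_hi, g_p = odds_ratio_2x2(
        int(top["n_cases"]), int(bottom["n_cases"]),
        int(top["n_controls"]), int(bottom["n_controls"]))
    summ = group_summary(scores, labels)
    return EvalReport(
        contrast=name,
        n_cases=int(labels.sum()),
        n_controls=int(labels.size - labels.sum()),
        auc=auc, auc_ci=ci,
        threshold=thr, sensitivity=sens, specificity=spec,
        or_per_sd=or_sd, or_per_sd_ci=(or_lo, or_hi), or_per_sd_p=or_p,
        or_extreme_deciles=g_or, or_extreme_deciles_ci=(g_lo, g_hi),
        or_extreme_deciles_p=g_p,
        group_medians=summ, trend_p=decile_trend_test(deciles),
        decile_table=deciles, roc=roc,
        case_scores=scores[labels == 1],
        control_scores=scores[labels == 0],
    )
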