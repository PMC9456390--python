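"""End-to-end orchestration of the five-stage scoring workflow.

Stage order is fixed: (1) genotype QC, (2) PCA stratification check,
(3) raw score computation, (4) cohort normalization, (5) per-contrast
evaluation and model comparison. Every run produces a manifest recording
the seed, a hash of the configuration and per-stage record counts, so two
runs with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as io_mod
from .containers import GenotypeMatrix
from .evaluate import (STANDARD_CONTRASTS, ContrastSpec, EvalReport,
                       evaluate_contrast)
from .pca import GenotypePCA, PcaResult, stratification_test
from .qc import QcConfig, QcReport, run_qc
from .scoring import score_cohort
from .simulate import SimConfig, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """What to run and on what.

    Exactly one input source: file paths (``ped``+``map`` or ``vcf``, plus
    ``weights`` and ``phenotypes``) or a :class:`SimConfig`.
    """

    seed: int
    sim: SimConfig | None = None
    ped: str | None = None
    map: str | None = None
    vcf: str | None = None
    weights: str | None = None
    phenotypes: str | None = None
    qc: QcConfig = field(default_factory=QcConfig)
    pca_k: int = 2
    pca_perms: int = 999
    contrasts: list[str] = field(
        default_factory=lambda: ["fracture", "low_bmd", "comorbid"])
    weight_transform: str = "log"
    ci_method: str = "delong"
    outdir: str | None = None

    def __post_init__(self) -> None:
        has_files = self.vcf is not None or self.ped is not None
        if (self.sim is None) == (not has_files):
            raise ValueError(
                "exactly one of sim-config or input paths must be given")
        if has_files and self.weights is None:
            raise ValueError("file input requires a weight table")
        if not self.contrasts:
            raise ValueError("at least one contrast must be requested")
        unknown = set(self.contrasts) - set(STANDARD_CONTRASTS)
        if unknown:
            raise ValueError(f"unknown contrasts: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class PipelineResult:
    manifest: dict
    qc_report: QcReport
    pca: PcaResult
    stratification_p: float | None
    scores: "pd.DataFrame"
    reports: dict[str, EvalReport]
    ranking: pd.DataFrame


def _load_inputs(cfg: PipelineConfig):
    if cfg.sim is not None:
        sim = simulate_cohort(cfg.sim)
        return sim.genotypes, sim.weights, sim.phenotypes
    weights = io_mod.read_weight_table(cfg.weights)
    if cfg.vcf is not None:
        G = io_mod.read_vcf(cfg.vcf, weights)
    else:
        if cfg.map is None:
            raise ValueError("PED input requires a MAP path")
        G = io_mod.read_plink_text(cfg.ped, cfg.map, weights)
    pheno = (io_mod.read_phenotypes(cfg.phenotypes)
             if cfg.phenotypes else None)
    return G, weights, pheno


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute QC, PCA, scoring, normalization and evaluation."""
    counts: dict[str, int] = {}
    G, weights, pheno = _load_inputs(cfg)
    counts["input_samples"] = G.n_samples
    counts["input_variants"] = G.n_variants
    logger.info("stage 1/5 QC: %d samples x %d variants in",
                G.n_samples, G.n_variants)

    controls = None
    if pheno is not None:
        # HWE on the fracture-contrast controls: one QC pass for all models
        by_id = pheno.set_index("sample_id")["fracture"]
        controls = np.array(
            [by_id.get(s, "unknown") == "control" for s in G.sample_ids])
        if not controls.any():
            controls = None
    Gq, qc_report = run_qc(G, cfg.qc, controls=controls)
    counts["qc_samples"] = Gq.n_samples
    counts["qc_variants"] = Gq.n_variants
    logger.info("stage 1/5 QC: %d samples x %d variants retained",
                Gq.n_samples, Gq.n_variants)

    pca_est = GenotypePCA(n_components=cfg.pca_k).fit(Gq)
    pca = pca_est.result_()
    strat_p = None
    if pheno is not None:
        eth = pheno.set_index("sample_id")["ethnicity"].reindex(
            Gq.sample_ids)
        labels = eth.fillna("unknown").to_numpy()
        counts_per = pd.Series(labels).value_counts()
        if (counts_per >= 2).sum() >= 2:
            keep = np.isin(labels, counts_per[counts_per >= 2].index)
            strat_p = stratification_test(
                PcaResult(components=pca.components[keep],
                          eigenvalues=pca.eigenvalues,
                          explained_fraction=pca.explained_fraction,
                          sample_ids=list(np.array(Gq.sample_ids)[keep])),
                labels[keep], n_perm=cfg.pca_perms, seed=cfg.seed)
    logger.info("stage 2/5 PCA: top eigenvalue %.4f, stratification p=%s",
                pca.eigenvalues[0], strat_p)

    panel = weights.subset(Gq.variant_ids)
    score_set = score_cohort(Gq, panel, transform=cfg.weight_transform)
    scores_df = score_set.to_frame()
    counts["scored_samples"] = len(scores_df)
    counts["scored_variants"] = len(panel)
    logger.info("stage 3/5 + 4/5 scoring: %d samples scored on %d "
                "variants (%s weights), normalized to z-scores",
                len(scores_df), len(panel), cfg.weight_transform)

    reports: dict[str, EvalReport] = {}
    if pheno is not None:
        ph = pheno.set_index("sample_id").reindex(Gq.sample_ids)
        z = np.asarray(score_set.z_prs)
        for name in cfg.contrasts:
            spec: ContrastSpec = STANDARD_CONTRASTS[name]
            case, control = spec.masks(ph.reset_index())
            mask = (case | control).to_numpy()
            labels = case.to_numpy()[mask].astype(int)
            reports[name] = evaluate_contrast(
                z[mask], labels, name=name,
                sample_ids=np.array(Gq.sample_ids)[mask],
                ci_method=cfg.ci_method, seed=cfg.seed)
            logger.info("stage 5/5 %s: AUC=%.3f OR/SD=%.2f", name,
                        reports[name].auc, reports[name].or_per_sd)
    ranking = (compare_contrasts(list(reports.values()))
               if len(reports) >= 2 else pd.DataFrame())
    if len(ranking):
        logger.info("most sensitive and specific model: %s",
                    ranking.iloc[0]["contrast"])

    manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": cfg.to_dict(),
        "counts": counts,
        "contrasts": {n: {"auc": r.auc, "or_per_sd": r.or_per_sd}
                      for n, r in reports.items()},
        "best_model": (str(ranking.iloc[0]["contrast"])
                       if len(ranking) else None),
        "stratification_p": strat_p,
    }
    result = PipelineResult(
        manifest=manifest, qc_report=qc_report, pca=pca,
        stratification_p=strat_p, scores=scores_df, reports=reports,
        ranking=ranking)
    if cfg.outdir:
        _write_outputs(result, Gq, cfg)
    return result


def compare_contrasts(reports: list[EvalReport]) -> pd.DataFrame:
    """Rank contrasts by AUC, flagging overlapping confidence intervals.

    No superiority claim is made where CIs overlap; the flag says whether
    a model's CI overlaps the next-ranked model's.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    df = pd.DataFrame({
        "contrast": [r.contrast for r in reports],
        "auc": [r.auc for r in reports],
        "auc_lo": [r.auc_ci[0] for r in reports],
        "auc_hi": [r.auc_ci[1] for r in reports],
    }).sort_values("auc", ascending=False, kind="stable",
                   ignore_index=True)
    df["rank"] = df["auc"].rank(method="min", ascending=False).astype(int)
    overlap = []
    for i in range(len(df)):
        if i + 1 < len(df):
            overlap.append(df.loc[i, "auc_lo"] <= df.loc[i + 1, "auc_hi"])
        else:
            overlap.append(False)
    df["ci_overlaps_next"] = overlap
    return df


def _write_outputs(result: PipelineResult, Gq: GenotypeMatrix,
                   cfg: PipelineConfig) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True,
                  default=str)
        fh.write("\n")
    with open(out / "qc_report.json", "w") as fh:
        json.dump(result.qc_report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    result.qc_report.per_variant_stats.to_csv(
        out / "qc_variant_stats.tsv", sep="\t", index=False)
    k = result.pca.components.shape[1]
    pc_df = pd.DataFrame(result.pca.components,
                         columns=[f"PC{i + 1}" for i in range(k)])
    pc_df.insert(0, "sample_id", result.pca.sample_ids)
    pc_df.to_csv(out / "pca_scores.tsv", sep="\t", index=False)
    result.scores.to_csv(out / "scores.tsv", sep="\t", index=False)
    for name, report in result.reports.items():
        io_mod.write_eval_report(report, out / f"eval_{name}.json")
    if len(result.ranking):
        result.ranking.to_csv(out / "model_ranking.tsv", sep="\t",
                              index=False)
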