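"""Readers and writers for the formats the pipeline touches.

Genotypes come in as PLINK text (PED/MAP) or VCF 4.x and are converted to
effect-allele dosages against a weight table at read time. Weight and
phenotype tables are TSV. Evaluation reports go out as JSON (complete,
machine-readable, including decile and ROC coordinates) plus TSV extracts
for plotting.

Variant joining follows PLINK-style conventions: the key is
chromosome + position + unordered allele pair; an effect/other swap versus
REF/ALT flips the dosage (d -> 2 - d); ID disagreements are warnings
(rsID drift is common), strand-ambiguous A/T and C/G sites are joined by
allele match with a warning.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import (MISSING, GenotypeMatrix, VariantRecord, WeightTable,
                         validate_phenotypes)
from .evaluate import EvalReport

logger = logging.getLogger(__name__)

WEIGHT_COLUMNS = ["variant_id", "chr", "pos", "effect_allele",
                  "other_allele", "OR"]

_AMBIGUOUS = (frozenset("AT"), frozenset("CG"))


# ---------------------------------------------------------------------------
# weight table

def read_weight_table(path) -> WeightTable:
    """Read a TSV weight table (variant_id, chr, pos, alleles, OR)."""
    df = pd.read_csv(path, sep="\t", dtype={"chr": str})
    missing_cols = [c for c in WEIGHT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"weight table {path} lacks columns {missing_cols}")
    records = [
        VariantRecord(variant_id=str(r.variant_id), chromosome=str(r.chr),
                      position=int(r.pos), effect_allele=str(r.effect_allele),
                      other_allele=str(r.other_allele),
                      effect_size=float(r.OR))
        for r in df.itertuples()
    ]
    return WeightTable(records)


def write_weight_table(weights: WeightTable, path) -> None:
    weights.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PLINK text PED/MAP

def read_plink_text(ped_path, map_path,
                    weights: WeightTable) -> GenotypeMatrix:
    """Read PED/MAP genotypes as effect-allele dosages.

    MAP variants are joined to the weight table by variant ID (positions
    cross-checked with a warning on mismatch). Alleles "0 0" become
    missing; an allele matching neither allele of the joined variant is a
    hard error naming the variant and sample.
    """
    by_id = {v.variant_id: v for v in weights}
    variants: list[VariantRecord] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise ValueError(
                    f"{map_path}:{lineno}: expected 4 MAP columns, got "
                    f"{len(fields)}")
            chrom, vid, _cm, pos = fields
            if vid not in by_id:
                raise ValueError(
                    f"{map_path}:{lineno}: variant {vid} not in weight "
                    "table; cannot orient alleles")
            rec = by_id[vid]
            if rec.chromosome != chrom or rec.position != int(pos):
                logger.warning(
                    "variant %s: MAP coordinates %s:%s differ from weight "
                    "table %s:%d", vid, chrom, pos, rec.chromosome,
                    rec.position)
            variants.append(rec)
    m = len(variants)

    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise ValueError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields "
                    f"({m} variants), got {len(fields)}")
            sid = fields[1]
            sample_ids.append(sid)
            dos = np.zeros(m, dtype=np.int8)
            miss = np.zeros(m, dtype=bool)
            for j, rec in enumerate(variants):
                a1, a2 = fields[6 + 2 * j], fields[7 + 2 * j]
                if a1 == "0" or a2 == "0":
                    if (a1 == "0") != (a2 == "0"):
                        logger.warning(
                            "half-called genotype for sample %s at %s; "
                            "treated as missing", sid, rec.variant_id)
                    miss[j] = True
                    continue
                d = 0
                for a in (a1, a2):
                    if a == rec.effect_allele:
                        d += 1
                    elif a != rec.other_allele:
                        raise ValueError(
                            f"{ped_path}:{lineno}: allele {a!r} of sample "
                            f"{sid} at {rec.variant_id} matches neither "
                            f"{rec.effect_allele} nor {rec.other_allele}")
                dos[j] = d
            rows.append(dos)
            masks.append(miss)
    return GenotypeMatrix(sample_ids=sample_ids, variants=variants,
                          dosage=np.vstack(rows), missing=np.vstack(masks))


def write_plink_text(G: GenotypeMatrix, ped_path, map_path,
                     phenotypes: pd.DataFrame | None = None) -> None:
    """Write genotypes in PLINK text (PED/MAP) form.

    PED phenotype column is 2/1 for fracture case/control when a phenotype
    table is supplied, else -9.
    """
    with open(map_path, "w") as fh:
        for v in G.variants:
            fh.write(f"{v.chromosome}\t{v.variant_id}\t0\t{v.position}\n")
    code = {}
    if phenotypes is not None:
        mapping = {"case": "2", "control": "1", "unknown": "-9"}
        code = {r.sample_id: mapping.get(r.fracture, "-9")
                for r in phenotypes.itertuples()}
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(G.sample_ids):
            fields = [sid, sid, "0", "0", "2", code.get(sid, "-9")]
            for j, v in enumerate(G.variants):
                if G.missing[i, j]:
                    fields += ["0", "0"]
                else:
                    d = int(G.dosage[i, j])
                    fields += ([v.effect_allele] * d
                               + [v.other_allele] * (2 - d))
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# VCF

def read_vcf(vcf_path, weights: WeightTable) -> GenotypeMatrix:
    """Read a VCF 4.x as effect-allele dosages against a weight table.

    Sites are joined on chromosome + position + unordered {REF, ALT} pair;
    when REF is the effect allele the ALT dosage is flipped (2 - d).
    Multi-allelic sites are skipped with a warning; ``./.`` genotypes are
    missing. Raises if no site joins the weight table.
    """
    key = {(v.chromosome, v.position, v.alleles): v for v in weights}
    vcf = VCF(str(vcf_path))
    sample_ids = list(vcf.samples)
    variants: list[VariantRecord] = []
    cols: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    for site in vcf:
        if len(site.ALT) != 1:
            logger.warning("skipping multi-allelic site %s:%d",
                           site.CHROM, site.POS)
            continue
        alleles = frozenset((site.REF, site.ALT[0]))
        rec = key.get((site.CHROM, site.POS, alleles))
        if rec is None:
            continue
        if site.ID and site.ID != rec.variant_id:
            logger.warning("site %s:%d ID %s differs from weight table %s",
                           site.CHROM, site.POS, site.ID, rec.variant_id)
        if alleles in _AMBIGUOUS:
            logger.warning(
                "strand-ambiguous alleles at %s; joined by allele match "
                "(strand assumed consistent)", rec.variant_id)
        flip = site.REF == rec.effect_allele
        gts = site.genotypes  # [allele1, allele2, phased] per sample
        d = np.zeros(len(sample_ids), dtype=np.int8)
        miss = np.zeros(len(sample_ids), dtype=bool)
        for i, gt in enumerate(gts):
            a = gt[:2]
            if -1 in a:
                miss[i] = True
            else:
                alt_count = int(a[0] == 1) + int(a[1] == 1)
                d[i] = 2 - alt_count if flip else alt_count
        variants.append(rec)
        cols.append(d)
        masks.append(miss)
    if not variants:
        raise ValueError(
            f"no site in {vcf_path} overlaps the weight table")
    return GenotypeMatrix(sample_ids=sample_ids, variants=variants,
                          dosage=np.column_stack(cols),
                          missing=np.column_stack(masks))


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write genotypes as a minimal uncompressed VCF 4.2.

    REF is the other allele and ALT the effect allele, so ALT dosage
    equals effect-allele dosage.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        for chrom in dict.fromkeys(v.chromosome for v in G.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.sample_ids) + "\n")
        gt_for = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, v in enumerate(G.variants):
            gts = [gt_for[int(G.dosage[i, j])]
                   if not G.missing[i, j] else "./."
                   for i in range(G.n_samples)]
            fh.write(f"{v.chromosome}\t{v.position}\t{v.variant_id}\t"
                     f"{v.other_allele}\t{v.effect_allele}\t.\t.\t.\tGT\t"
                     + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# phenotypes

def read_phenotypes(path) -> pd.DataFrame:
    """Read and validate a TSV phenotype table."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_phenotypes(df)


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# evaluation reports

def write_eval_report(report: EvalReport, path) -> None:
    """Write an evaluation report as JSON plus TSV extracts.

    ``path`` is the JSON file; ``<stem>_deciles.tsv`` and
    ``<stem>_roc.tsv`` are written next to it so decile and ROC figures
    can be replotted without re-running the pipeline.
    """
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    report.decile_table.to_csv(path.with_name(path.stem + "_deciles.tsv"),
                               sep="\t", index=False)
    report.roc.to_csv(path.with_name(path.stem + "_roc.tsv"),
                      sep="\t", index=False)


def read_eval_report(path) -> EvalReport:
    """Read back a JSON report written by :func:`write_eval_report`."""
    with open(path) as fh:
        d = json.load(fh)
    return EvalReport(
        contrast=d["contrast"], n_cases=d["n_cases"],
        n_controls=d["n_controls"], auc=d["auc"],
        auc_ci=tuple(d["auc_ci"]), threshold=d["threshold"],
        sensitivity=d["sensitivity"], specificity=d["specificity"],
        or_per_sd=d["or_per_sd"], or_per_sd_ci=tuple(d["or_per_sd_ci"]),
        or_per_sd_p=d["or_per_sd_p"],
        or_extreme_deciles=d["or_extreme_deciles"],
        or_extreme_deciles_ci=tuple(d["or_extreme_deciles_ci"]),
        or_extreme_deciles_p=d["or_extreme_deciles_p"],
        group_medians=d["group_medians"], trend_p=d["trend_p"],
        decile_table=pd.DataFrame(d["decile_table"]),
        roc=pd.DataFrame(d["roc"]),
        case_scores=np.array(d["case_scores"]),
        control_scores=np.array(d["control_scores"]),
    )
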