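"""Config-driven orchestration of the full transcriptomic-distance analysis.

Stages run in order: io -> references -> TD ratios (+ purity adjustment)
-> specificity -> pathway scores -> enrichment -> group summaries.  All
outputs are TSV tables plus a YAML run manifest recording seeds and
thresholds, which suffices to reproduce every table.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .containers import ExpressionMatrix, GeneSetCollection, ReferenceProfile
from .distance import td_ratio
from .enrichment import geometric_log2_fold_change, preranked_gsea
from .pathways import score_pathways, DEFAULT_N_ITER
from .specificity import adjust_ratios_for_purity, specificity_analysis
from .stats import bh_fdr, wilcoxon_rank_sum, wilcoxon_signed_rank

logger = logging.getLogger(__name__)

ALL_STAGES = ("td_ratios", "summary", "specificity", "pathways", "enrichment")


class _Flat:
    """Stand-in test result for fully tied paired data: p = 1."""

    p = 1.0


_FlatP = _Flat()


@dataclass
class RunConfig:
    """Paths, assignments and thresholds of one analysis invocation."""

    normal_matrix: str = ""
    tumor_matrix: str = ""
    normal_annotation: str = ""
    tumor_annotation: str = ""
    gene_sets: str = ""
    state: str = "cpm"               # normalization tag of the input matrices
    measure: str = "euclidean"
    reference_statistic: str = "median"   # mean for sparse single-cell data
    overlap_threshold: float = 0.9        # 0.7 for single-cell
    min_group_size: int = 3
    n_iter: int = DEFAULT_N_ITER
    fdr_threshold: float = 0.1
    seed: int = 1206
    stages: tuple = ALL_STAGES
    specificity_true_tt: str = ""         # empty: use each group's annotated TT

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def build_references(normals: ExpressionMatrix, normal_ann: pd.DataFrame,
                     statistic: str = "median") -> dict[str, ReferenceProfile]:
    """One central profile per normal tissue present in the annotation."""
    refs = {}
    norm = normal_ann[normal_ann["role"] == "normal"]
    for tissue, sub in norm.groupby("origin_tissue"):
        refs[tissue] = eio.build_reference_profile(
            normals, tissue, list(sub["sample_id"]), statistic)
    if not refs:
        raise ValueError("no normal samples found to build references from")
    return refs


def cohort_td_ratios(matrix: ExpressionMatrix, annotation: pd.DataFrame,
                     references: dict[str, ReferenceProfile],
                     measure: str = "euclidean") -> pd.DataFrame:
    """Per-sample TD(OT), TD(TT) and TD ratio for every annotated tumor sample.

    The annotation must already be pseudo-sample-expanded (one target
    tissue per row); expression for a pseudo-sample is looked up via its
    source sample id.
    """
    log_space = matrix.state == "log_space"
    rows = []
    tumor = annotation[annotation["role"].isin(["primary", "metastatic"])]
    for rec in tumor.itertuples():
        tts = rec.target_tissues
        if len(tts) != 1:
            logger.warning("sample %s has %d target tissues; skipped (expand first)",
                           rec.sample_id, len(tts))
            continue
        ot, tt = rec.origin_tissue, tts[0]
        if ot not in references or tt not in references:
            logger.warning("sample %s: missing reference for %s or %s",
                           rec.sample_id, ot, tt)
            continue
        source = eio.pseudo_sample_source(rec.sample_id)
        x = matrix.data[source].to_numpy()
        res = td_ratio(x, references[ot], references[tt], measure=measure,
                       sample_id=rec.sample_id, log_space=log_space)
        rows.append({"sample_id": rec.sample_id, "patient_id": rec.patient_id,
                     "role": rec.role, "cancer_type": rec.cancer_type,
                     "origin_tissue": ot, "target_tissue": tt,
                     "measure": measure, "td_ot": res.td_ot, "td_tt": res.td_tt,
                     "ratio": res.ratio, "degenerate": res.degenerate,
                     "purity": rec.purity})
    return pd.DataFrame(rows)


def summarize_groups(td_results: pd.DataFrame,
                     fdr_threshold: float = 0.1,
                     ratio_column: str = "ratio") -> pd.DataFrame:
    """Metastatic-vs-primary comparison per (cancer type, target tissue).

    Paired cohorts (shared patient ids) use a one-sided signed-rank test
    of metastatic ratio > primary ratio; unpaired use the rank-sum test.
    The raw Euclidean distance to the TT is compared in the opposite
    direction (metastatic closer).  BH FDR runs across comparisons.
    """
    def _paired_p(a, b, alternative):
        if np.all(a - b == 0):  # fully tied: no evidence either way
            return _FlatP
        return wilcoxon_signed_rank(a, b, alternative=alternative)

    rows = []
    for (ct, tt), sub in td_results.groupby(["cancer_type", "target_tissue"]):
        pri = sub[sub["role"] == "primary"]
        met = sub[sub["role"] == "metastatic"]
        paired = pri.set_index("patient_id")[ratio_column].dropna()
        met_by_pt = met.set_index("patient_id")[ratio_column].dropna()
        shared = paired.index.intersection(met_by_pt.index)
        row = {"cancer_type": ct, "target_tissue": tt,
               "n_primary": len(pri), "n_metastatic": len(met),
               "median_primary": float(pri[ratio_column].median()),
               "median_metastatic": float(met[ratio_column].median())}
        if len(shared) >= 3:
            res = _paired_p(met_by_pt[shared].to_numpy(),
                            paired[shared].to_numpy(), "greater")
            d = _paired_p(met.set_index("patient_id")["td_tt"][shared].to_numpy(),
                          pri.set_index("patient_id")["td_tt"][shared].to_numpy(),
                          "less")
            row.update(test="signed_rank", n_pairs=len(shared))
        elif len(pri) >= 3 and len(met) >= 3:
            res = wilcoxon_rank_sum(met[ratio_column].to_numpy(),
                                    pri[ratio_column].to_numpy(),
                                    alternative="greater")
            d = wilcoxon_rank_sum(met["td_tt"].to_numpy(),
                                  pri["td_tt"].to_numpy(), alternative="less")
            row.update(test="rank_sum", n_pairs=0)
        else:
            row.update(test="skipped:too_few_samples", n_pairs=len(shared),
                       p=np.nan, distance_p=np.nan)
            rows.append(row)
            continue
        row.update(p=res.p, distance_p=d.p,
                   direction="metastatic_greater"
                   if row["median_metastatic"] > row["median_primary"]
                   else "primary_greater_or_equal")
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        tested = out["p"].notna()
        out.loc[tested, "fdr"] = bh_fdr(out.loc[tested, "p"].to_numpy())
        out["significant"] = out.get("fdr", np.nan) < fdr_threshold
    return out


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Execute the configured stages and write one TSV per stage plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "stages": {}}
    manifest["config"]["stages"] = list(cfg.stages)

    def _stage(name):
        t0 = time.time()
        logger.info("stage %s: start", name)
        return t0

    try:
        t0 = _stage("io")
        normals = eio.read_expression_matrix(cfg.normal_matrix, cfg.state)
        tumors = eio.read_expression_matrix(cfg.tumor_matrix, cfg.state)
        normal_ann = eio.read_sample_annotation(cfg.normal_annotation)
        tumor_ann = eio.read_sample_annotation(cfg.tumor_annotation)
        gene_sets = (eio.read_gene_sets_gmt(cfg.gene_sets)
                     if cfg.gene_sets else GeneSetCollection({}))
        normals, tumors = eio.harmonize_genes([normals, tumors])
        tumor_ann = eio.expand_pseudo_samples(tumor_ann)
        manifest["stages"]["io"] = {"seconds": round(time.time() - t0, 3),
                                    "n_genes": tumors.n_genes}
    except Exception as exc:
        raise RuntimeError(f"stage io failed: {exc}") from exc

    references = build_references(normals, normal_ann, cfg.reference_statistic)
    results: dict[str, pd.DataFrame] = {}

    for stage in cfg.stages:
        t0 = _stage(stage)
        try:
            if stage == "td_ratios":
                td = cohort_td_ratios(tumors, tumor_ann, references, cfg.measure)
                adj = adjust_ratios_for_purity(td["ratio"].to_numpy(),
                                               td["purity"].to_numpy(),
                                               td["role"].to_numpy())
                td["residual"] = adj.residuals if adj.adjusted else np.nan
                td["purity_adjusted"] = adj.adjusted
                results["td_ratios"] = td
            elif stage == "summary":
                td = results["td_ratios"]
                col = "residual" if td["purity_adjusted"].any() else "ratio"
                results["summary"] = summarize_groups(td, cfg.fdr_threshold,
                                                      ratio_column=col)
            elif stage == "specificity":
                results["specificity"] = _specificity_stage(tumors, tumor_ann,
                                                            references, cfg)
            elif stage == "pathways":
                if not len(gene_sets):
                    logger.warning("no gene sets supplied; skipping pathways")
                    continue
                results["pathways"] = score_pathways(
                    tumors, tumor_ann, references, gene_sets,
                    overlap_threshold=cfg.overlap_threshold,
                    min_group_size=cfg.min_group_size, n_iter=cfg.n_iter,
                    seed=cfg.seed, fdr_threshold=cfg.fdr_threshold)
            elif stage == "enrichment":
                if not len(gene_sets):
                    continue
                results["enrichment"] = _enrichment_stage(tumors, tumor_ann,
                                                          gene_sets, cfg)
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}

    for name, table in results.items():
        table.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return out


def _specificity_stage(tumors, tumor_ann, references, cfg: RunConfig) -> pd.DataFrame:
    frames = []
    met = tumor_ann[tumor_ann["role"] == "metastatic"]
    for (ct, ot), sub in met.groupby(["cancer_type", "origin_tissue"]):
        tts = sorted({t for lst in sub["target_tissues"] for t in lst})
        true_tt = cfg.specificity_true_tt or (tts[0] if tts else "")
        candidates = {t: r for t, r in references.items() if t != ot}
        samples = [s for s, lst in zip(sub["sample_id"], sub["target_tissues"])
                   if true_tt in lst]
        if len(samples) < 3 or true_tt not in candidates or len(candidates) < 2:
            logger.warning("specificity skipped for (%s, %s)", ct, ot)
            continue
        res = specificity_analysis(tumors, samples, references[ot], candidates,
                                   true_tt, measure=cfg.measure,
                                   alpha=cfg.fdr_threshold)
        tab = res.table.copy()
        tab.insert(0, "cancer_type", ct)
        tab.insert(1, "true_tt", true_tt)
        tab["specificity_score"] = res.specificity_score
        frames.append(tab)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def _enrichment_stage(tumors, tumor_ann, gene_sets, cfg: RunConfig) -> pd.DataFrame:
    pri = tumor_ann[tumor_ann["role"] == "primary"]["sample_id"]
    met = tumor_ann[tumor_ann["role"] == "metastatic"]["sample_id"]
    pri = [eio.pseudo_sample_source(s) for s in pri]
    met = [eio.pseudo_sample_source(s) for s in met]
    pri = [s for s in dict.fromkeys(pri) if s in tumors.data.columns]
    met = [s for s in dict.fromkeys(met) if s in tumors.data.columns]
    ranks = geometric_log2_fold_change(tumors.subset_samples(pri),
                                       tumors.subset_samples(met))
    return preranked_gsea(ranks, gene_sets, n_perm=min(cfg.n_iter, 2000),
                          seed=cfg.seed)
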