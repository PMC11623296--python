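"""Pathway-restricted TD ratios / PMT scores, their deltas, and empirical nulls.

For each group of tumor samples — a (cancer type, primary/metastatic
class, target tissue) combination with at least ``min_group_size``
samples — and each gene set passing the overlap filter, the
pathway-specific value is the group median of the per-sample ratio
computed on the pathway's genes only.  The delta is that median divided
by the group's all-genes median, so delta > 1 marks a pathway whose
expression sits closer to the target tissue than the transcriptome-wide
tendency.

Significance comes from an empirical null: random gene sets of the same
size drawn from the analyzed genes, with P = (r + 1) / (n + 1) where r
counts null deltas at least as large as the observed one, folded
two-sided via min(P, 1 - P), then Benjamini-Hochberg corrected across
all rows.  Nulls are cached per (group, set size): draws of a given size
are exchangeable across pathways, so re-use is exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSetCollection, ReferenceProfile
from .distance import td_ratio_block, pmt_score_block
from .stats import bh_fdr

logger = logging.getLogger(__name__)

DEFAULT_N_ITER = 10_000
DEFAULT_SEED = 1206
DEFAULT_OVERLAP_BULK = 0.9
DEFAULT_OVERLAP_SINGLE_CELL = 0.7
FDR_THRESHOLD = 0.1


def pathway_gene_subset(genes_available, gene_set, overlap_threshold: float = 0.9):
    """Intersect a gene set with the analyzed genes, subject to an overlap filter.

    Returns the intersection (in gene-set order) when at least
    ``overlap_threshold`` of the set's genes are present (boundary
    inclusive), else ``None``.  The thresholds used in practice are 0.9
    for bulk data and 0.7 for sparse single-cell data.
    """
    if not 0 < overlap_threshold <= 1:
        raise ValueError("overlap_threshold must be in (0, 1]")
    if len(gene_set) == 0:
        raise ValueError("empty gene set")
    available = set(genes_available)
    present = [g for g in gene_set if g in available]
    if len(present) / len(gene_set) >= overlap_threshold:
        return present
    return None


def draw_random_gene_sets(genes_available, size: int, n_iter: int,
                          seed: int | np.random.Generator = DEFAULT_SEED) -> list[list]:
    """``n_iter`` uniform without-replacement draws of ``size`` genes."""
    genes_available = list(genes_available)
    if size > len(genes_available):
        raise ValueError(f"size {size} exceeds available genes {len(genes_available)}")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = np.asarray(genes_available, dtype=object)
    return [list(genes[rng.choice(len(genes), size=size, replace=False)])
            for _ in range(n_iter)]


# ---------------------------------------------------------------------------
# group machinery


@dataclass
class _Group:
    """One (cancer_type, class, target_tissue) cell of the analysis."""

    cancer_type: str
    role: str
    target_tissue: str
    log_block: np.ndarray          # genes x samples, log2 scale
    log_ot: np.ndarray
    log_tt: np.ndarray
    log_primary: np.ndarray | None = None  # aligned pairs, pmt mode only
    all_genes_value: float = np.nan
    null_cache: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.log_block.shape[1]

    def per_sample_values(self, idx: np.ndarray, kind: str) -> np.ndarray:
        if kind == "td_ratio":
            return td_ratio_block(self.log_block[idx], self.log_ot[idx], self.log_tt[idx])
        return pmt_score_block(self.log_block[idx], self.log_primary[idx], self.log_tt[idx])

    def median_value(self, idx: np.ndarray, kind: str) -> float:
        vals = self.per_sample_values(idx, kind)
        finite = vals[np.isfinite(vals)]
        n_inf = len(vals) - len(finite)
        if n_inf:
            logger.info("dropping %d degenerate per-sample value(s) from group median", n_inf)
        return float(np.median(finite)) if len(finite) else np.nan


def _to_log(values: np.ndarray, state: str, pseudocount: float = 1.0) -> np.ndarray:
    if state == "log_space":
        return np.asarray(values, dtype=float)
    return np.log2(np.asarray(values, dtype=float) + pseudocount)


def _build_groups(matrix: ExpressionMatrix, annotation: pd.DataFrame,
                  references: dict[str, ReferenceProfile], value_kind: str,
                  min_group_size: int) -> list[_Group]:
    logM = _to_log(matrix.data.to_numpy(), matrix.state)
    sample_pos = {s: j for j, s in enumerate(matrix.samples)}
    log_refs = {t: _to_log(r.values.to_numpy(), r.state) for t, r in references.items()}

    ann = annotation[annotation["sample_id"].isin(sample_pos)]
    groups: list[_Group] = []
    tumor = ann[ann["role"].isin(["primary", "metastatic"])]
    roles = ["metastatic"] if value_kind == "pmt_score" else ["primary", "metastatic"]
    for (ct, role), sub in tumor.groupby(["cancer_type", "role"], dropna=False):
        if role not in roles:
            continue
        for tt in sorted({t for tts in sub["target_tissues"] for t in tts}):
            members = sub[[tt in tts for tts in sub["target_tissues"]]]
            ots = members["origin_tissue"].dropna().unique()
            if len(ots) != 1:
                raise ValueError(f"group ({ct}, {role}, {tt}) has origin tissues {list(ots)}")
            ot = ots[0]
            if ot not in log_refs or tt not in log_refs:
                logger.warning("skipping group (%s, %s, %s): missing reference", ct, role, tt)
                continue
            cols = [sample_pos[s] for s in members["sample_id"]]
            log_primary = None
            if value_kind == "pmt_score":
                primaries = ann[ann["role"] == "primary"].set_index("patient_id")["sample_id"]
                pairs = [(sample_pos[row.sample_id], sample_pos[primaries[row.patient_id]])
                         for row in members.itertuples()
                         if row.patient_id in primaries.index]
                if len(pairs) < min_group_size:
                    continue
                cols = [m for m, _ in pairs]
                log_primary = logM[:, [p for _, p in pairs]]
            if len(cols) < min_group_size:
                continue
            groups.append(_Group(cancer_type=ct, role=str(role), target_tissue=tt,
                                 log_block=logM[:, cols], log_ot=log_refs[ot],
                                 log_tt=log_refs[tt], log_primary=log_primary))
    return groups


def pathway_value_table(matrix: ExpressionMatrix, annotation: pd.DataFrame,
                        references: dict[str, ReferenceProfile],
                        gene_sets: GeneSetCollection,
                        value_kind: str = "td_ratio",
                        measure: str = "euclidean",
                        overlap_threshold: float = DEFAULT_OVERLAP_BULK,
                        min_group_size: int = 3) -> pd.DataFrame:
    """Pathway-specific group medians and deltas (no p-values yet).

    One row per retained (cancer_type, class, target_tissue) group and
    accepted pathway, with the group's pathway-restricted median value,
    its all-genes median, and their ratio (the delta).
    """
    if value_kind not in ("td_ratio", "pmt_score"):
        raise ValueError(f"unknown value_kind {value_kind!r}")
    if measure != "euclidean":
        raise NotImplementedError("pathway-level values are defined on euclidean TDs")
    groups = _build_groups(matrix, annotation, references, value_kind, min_group_size)
    if not groups:
        logger.warning("no group meets min_group_size=%d; empty table", min_group_size)
    gene_index = {g: i for i, g in enumerate(matrix.genes)}
    all_idx = np.arange(matrix.n_genes)
    rows = []
    for grp in groups:
        grp.all_genes_value = grp.median_value(all_idx, value_kind)
        for name, gset in gene_sets.items():
            subset = pathway_gene_subset(matrix.genes, gset, overlap_threshold)
            if subset is None:
                logger.info("pathway %s rejected: overlap below %.0f%%",
                            name, 100 * overlap_threshold)
                continue
            idx = np.fromiter((gene_index[g] for g in subset), dtype=int)
            value = grp.median_value(idx, value_kind)
            rows.append({
                "cancer_type": grp.cancer_type, "class": grp.role,
                "target_tissue": grp.target_tissue, "pathway": name,
                "n_samples": grp.n_samples, "n_genes": len(idx),
                "pathway_value": value,
                "all_genes_value": grp.all_genes_value,
                "delta": value / grp.all_genes_value,
            })
    table = pd.DataFrame(rows, columns=["cancer_type", "class", "target_tissue",
                                        "pathway", "n_samples", "n_genes",
                                        "pathway_value", "all_genes_value", "delta"])
    table.attrs["value_kind"] = value_kind
    return table


def _null_deltas(grp: _Group, size: int, n_genes: int, kind: str,
                 n_iter: int, rng: np.random.Generator) -> np.ndarray:
    """Null delta distribution for one group and set size (cached on the group)."""
    if size not in grp.null_cache:
        deltas = np.empty(n_iter)
        for i in range(n_iter):
            idx = rng.choice(n_genes, size=size, replace=False)
            deltas[i] = grp.median_value(idx, kind) / grp.all_genes_value
        grp.null_cache[size] = deltas
    return grp.null_cache[size]


def empirical_pvalues(observed_delta: np.ndarray, null_deltas: list[np.ndarray],
                      fdr_threshold: float = FDR_THRESHOLD) -> pd.DataFrame:
    """Fold per-row empirical P values from pre-built null delta distributions.

    P = (r + 1)/(n + 1) with r the number of null deltas >= the observed
    delta; adjusted_p = min(P, 1 - P) makes both tails (closer to TT or
    to OT than random genes) significant; BH-FDR runs across all rows.
    """
    observed_delta = np.asarray(observed_delta, dtype=float)
    p = np.empty(len(observed_delta))
    for i, (obs, null) in enumerate(zip(observed_delta, null_deltas)):
        null = np.asarray(null)
        if null.size == 0:
            raise ValueError("empty null distribution")
        r = int((null >= obs).sum())
        p[i] = (r + 1) / (null.size + 1)
    adjusted = np.minimum(p, 1 - p)
    out = pd.DataFrame({"empirical_p": p, "adjusted_p": adjusted})
    if len(out):
        out["fdr"] = bh_fdr(adjusted)
        out["significant"] = out["fdr"] < fdr_threshold
    else:
        out["fdr"] = []
        out["significant"] = []
    return out


def score_pathways(matrix: ExpressionMatrix, annotation: pd.DataFrame,
                   references: dict[str, ReferenceProfile],
                   gene_sets: GeneSetCollection,
                   value_kind: str = "td_ratio",
                   overlap_threshold: float = DEFAULT_OVERLAP_BULK,
                   min_group_size: int = 3,
                   n_iter: int = DEFAULT_N_ITER,
                   seed: int = DEFAULT_SEED,
                   fdr_threshold: float = FDR_THRESHOLD) -> pd.DataFrame:
    """Full pathway analysis: values, deltas, empirical P, adjusted P, FDR.

    This is the main entry point; it composes :func:`pathway_value_table`
    with per-(group, size) empirical nulls and :func:`empirical_pvalues`.
    """
    table = pathway_value_table(matrix, annotation, references, gene_sets,
                                value_kind=value_kind,
                                overlap_threshold=overlap_threshold,
                                min_group_size=min_group_size)
    if table.empty:
        for col in ("empirical_p", "adjusted_p", "fdr", "significant"):
            table[col] = []
        return table
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    groups = _build_groups(matrix, annotation, references, value_kind, min_group_size)
    group_map = {(g.cancer_type, g.role, g.target_tissue): g for g in groups}
    all_idx = np.arange(matrix.n_genes)
    for grp in group_map.values():
        grp.all_genes_value = grp.median_value(all_idx, value_kind)
    # one reproducible stream per group keeps nulls independent across groups
    rngs = {key: np.random.default_rng(np.random.SeedSequence([int(seed), i]))
            for i, key in enumerate(sorted(group_map))}
    null_rows = []
    keys = zip(table["cancer_type"], table["class"], table["target_tissue"],
               table["n_genes"])
    for ct, cls, tt, n_genes in keys:
        grp = group_map[(ct, cls, tt)]
        null_rows.append(_null_deltas(grp, int(n_genes), matrix.n_genes,
                                      value_kind, n_iter, rngs[(ct, cls, tt)]))
    pvals = empirical_pvalues(table["delta"].to_numpy(), null_rows, fdr_threshold)
    return pd.concat([table.reset_index(drop=True), pvals], axis=1)
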