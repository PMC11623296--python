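"""Reading, normalizing and harmonizing expression data, annotations and gene sets.

All on-disk formats are plain text: tab-separated expression matrices
(first column gene symbols, header row of sample ids), tab-separated
sample annotations, and GMT gene-set files.  Written matrices carry a
YAML sidecar recording their normalization state.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ExpressionMatrix, GeneSetCollection, ReferenceProfile

logger = logging.getLogger(__name__)

ROLES = ("primary", "metastatic", "normal")

ANNOTATION_COLUMNS = [
    "sample_id",
    "patient_id",
    "role",
    "cancer_type",
    "origin_tissue",
    "target_tissues",
    "purity",
]


def read_expression_matrix(path: str | Path, state: str) -> ExpressionMatrix:
    """Read a gene x sample TSV into an :class:`ExpressionMatrix`.

    Duplicate gene rows are collapsed by their mean (with a warning);
    duplicate sample ids are a hard error, as are non-numeric cells.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dupes = sorted({s for s in header if header.count(s) > 1})
    if dupes:
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any() or numeric.isna().to_numpy().any():
        mask = numeric.isna()
        row = mask.index[mask.any(axis=1)][0]
        col = mask.columns[mask.loc[row]][0]
        raise ValueError(f"{path}: non-numeric value at gene {row!r}, sample {col!r}")
    if numeric.index.duplicated().any():
        dupes = numeric.index[numeric.index.duplicated()].unique().tolist()
        warnings.warn(f"{path}: collapsing duplicate gene rows by mean: {dupes[:5]}")
        numeric = numeric.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(numeric, state)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix as TSV with a ``<path>.yaml`` sidecar holding its state."""
    path = Path(path)
    m.data.to_csv(path, sep="\t", index_label="gene")
    sidecar = {"state": m.state, "n_genes": m.n_genes, "n_samples": m.n_samples}
    Path(str(path) + ".yaml").write_text(yaml.safe_dump(sidecar))


def read_sample_annotation(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample annotation TSV.

    Required columns: ``sample_id`` and ``role`` (primary/metastatic/normal,
    case-insensitive).  Optional: ``patient_id``, ``cancer_type``,
    ``origin_tissue``, ``target_tissues`` (semicolon-delimited, parsed to a
    list) and ``purity`` in [0, 1].
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "role"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df = df.copy()
    df["role"] = df["role"].str.strip().str.lower()
    bad_roles = set(df["role"]) - set(ROLES)
    if bad_roles:
        raise ValueError(f"{path}: unknown roles {sorted(bad_roles)}; expected {ROLES}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    for col in ("patient_id", "cancer_type", "origin_tissue"):
        if col not in df.columns:
            df[col] = pd.NA
    if "target_tissues" in df.columns:
        df["target_tissues"] = [
            [] if pd.isna(v) or v == "" else [t.strip() for t in str(v).split(";") if t.strip()]
            for v in df["target_tissues"]
        ]
    else:
        df["target_tissues"] = [[] for _ in range(len(df))]
    if "purity" in df.columns:
        df["purity"] = pd.to_numeric(df["purity"], errors="raise")
        pur = df["purity"].dropna()
        if ((pur < 0) | (pur > 1)).any():
            raise ValueError(f"{path}: purity values outside [0, 1]")
    else:
        df["purity"] = np.nan
    return df[ANNOTATION_COLUMNS]


def write_sample_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    out = ann.copy()
    out["target_tissues"] = [";".join(v) for v in out["target_tissues"]]
    out.to_csv(path, sep="\t", index=False)


def read_gene_sets_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (name, description, genes...) into a collection.

    Duplicate genes within a set are dropped keeping the first occurrence;
    duplicate set names are an error.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        warnings.warn(f"{path}: empty GMT file")
        return GeneSetCollection({}, {})
    for i, line in enumerate(lines, 1):
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{i}: GMT line needs >=3 fields, got {len(fields)}")
        name, desc, *genes = fields
        if name in sets:
            raise ValueError(f"{path}:{i}: duplicate gene-set name {name!r}")
        seen: dict[str, None] = {}
        for g in genes:
            if g and g not in seen:
                seen[g] = None
        sets[name] = list(seen)
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name, genes in collection.items():
        desc = collection.descriptions.get(name, "na")
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# normalization


def _tmm_factor(obs: np.ndarray, ref: np.ndarray, log_ratio_trim: float = 0.3,
                abs_expr_trim: float = 0.05) -> float:
    """Trimmed mean of M-values factor of one sample against the reference.

    Doubly trimmed (30% of M-values each tail, 5% of A-values each tail)
    weighted mean of per-gene log ratios, with inverse asymptotic-variance
    precision weights, following the published TMM definition.
    """
    n_obs, n_ref = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.abs(m).max() < 1e-6:  # identical relative profiles
        return 1.0
    n = len(m)
    lo_m, hi_m = np.floor(n * log_ratio_trim) + 1, n - np.floor(n * log_ratio_trim)
    lo_a, hi_a = np.floor(n * abs_expr_trim) + 1, n - np.floor(n * abs_expr_trim)
    rank_m = np.argsort(np.argsort(m)) + 1
    rank_a = np.argsort(np.argsort(a)) + 1
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 1.0
    f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    return float(2.0 ** f)


def tmm_factors(counts: np.ndarray) -> np.ndarray:
    """TMM scaling factors (geometric mean 1) for a genes x samples count matrix.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean across samples.
    """
    lib = counts.sum(axis=0)
    uq = np.array([np.quantile(counts[:, j][counts[:, j] > 0] / lib[j], 0.75)
                   if (counts[:, j] > 0).any() else 0.0
                   for j in range(counts.shape[1])])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array([_tmm_factor(counts[:, j], counts[:, ref_idx])
                        for j in range(counts.shape[1])])
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def normalize_counts(m: ExpressionMatrix, method: str) -> ExpressionMatrix:
    """Normalize a counts matrix to CPM, upper-quartile, or TMM-scaled CPM.

    * ``cpm``: each sample scaled to counts-per-million.
    * ``uq``: each sample divided by its 75th-percentile value
      (linearly interpolated quantile).
    * ``tmm_cpm``: CPM on effective library sizes (library size x TMM factor).
    """
    if m.state != "counts":
        raise ValueError(f"normalize_counts requires state='counts', got {m.state!r}")
    if method not in ("cpm", "uq", "tmm_cpm"):
        raise ValueError(f"unknown method {method!r}")
    values = m.data.to_numpy(dtype=float)
    lib = values.sum(axis=0)
    if (lib <= 0).any():
        bad = [m.samples[j] for j in np.where(lib <= 0)[0]]
        raise ValueError(f"zero library size in samples {bad}")
    if method == "cpm":
        out = values * 1e6 / lib
    elif method == "uq":
        q75 = np.quantile(values, 0.75, axis=0)
        if (q75 <= 0).any():
            bad = [m.samples[j] for j in np.where(q75 <= 0)[0]]
            raise ValueError(f"zero 75th percentile in samples {bad}")
        out = values / q75
    else:
        factors = tmm_factors(values)
        out = values * 1e6 / (lib * factors)
    return ExpressionMatrix(pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
                            method)


# ---------------------------------------------------------------------------
# harmonization and references


def harmonize_genes(matrices: list[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Restrict all matrices to the sorted intersection of their gene lists."""
    if len(matrices) < 2:
        raise ValueError("harmonize_genes needs at least two matrices")
    common = set(matrices[0].genes)
    for m in matrices[1:]:
        common &= set(m.genes)
    if not common:
        raise ValueError("empty gene intersection across matrices")
    order = sorted(common)
    return [m.subset_genes(order) for m in matrices]


def build_reference_profile(m: ExpressionMatrix, tissue: str,
                            tissue_samples: list[str],
                            statistic: str = "median") -> ReferenceProfile:
    """Per-gene central expression of one tissue's samples.

    Median for bulk data; mean for sparse single-cell data.
    """
    if not tissue_samples:
        raise ValueError("tissue_samples must be non-empty")
    sub = m.subset_samples(list(tissue_samples))
    if statistic == "median":
        vals = sub.data.median(axis=1)
    elif statistic == "mean":
        vals = sub.data.mean(axis=1)
    else:
        raise ValueError(f"statistic must be median or mean, got {statistic!r}")
    return ReferenceProfile(tissue=tissue, values=vals, statistic=statistic, state=m.state)


def select_variable_genes(matrices: list[ExpressionMatrix], k: int) -> list[str]:
    """Top-k genes by variance of pooled log2(x+1) values across all matrices.

    Ties at the cutoff are broken by lexicographic gene symbol.  Matrices
    must already share an identical gene order.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    genes = matrices[0].genes
    for m in matrices[1:]:
        if m.genes != genes:
            raise ValueError("matrices must be harmonized to identical gene order")
    pooled = np.hstack([
        m.data.to_numpy(dtype=float) if m.state == "log_space"
        else np.log2(m.data.to_numpy(dtype=float) + 1.0)
        for m in matrices
    ])
    var = pooled.var(axis=1, ddof=1)
    order = sorted(range(len(genes)), key=lambda i: (-var[i], genes[i]))
    return [genes[i] for i in order[: min(k, len(genes))]]


PSEUDO_SEP = "::"


def expand_pseudo_samples(ann: pd.DataFrame) -> pd.DataFrame:
    """Split each multi-target sample into one pseudo-sample per target tissue.

    A sample annotated with t > 1 target tissues becomes t records with ids
    ``<sample_id>::<tissue>``, each carrying a single target tissue; its
    expression column is shared (the id maps back via
    :func:`pseudo_sample_source`).  Tumor samples with no target tissue pass
    through with a warning; normals pass through silently.
    """
    rows = []
    for _, rec in ann.iterrows():
        tts = rec["target_tissues"]
        if len(tts) <= 1:
            if len(tts) == 0 and rec["role"] in ("primary", "metastatic"):
                warnings.warn(f"tumor sample {rec['sample_id']!r} has no target tissue")
            rows.append(rec)
            continue
        for tt in tts:
            new = rec.copy()
            new["sample_id"] = f"{rec['sample_id']}{PSEUDO_SEP}{tt}"
            new["target_tissues"] = [tt]
            rows.append(new)
    return pd.DataFrame(rows).reset_index(drop=True)


def pseudo_sample_source(sample_id: str) -> str:
    """Original sample id behind a pseudo-sample id (identity if not pseudo)."""
    return sample_id.split(PSEUDO_SEP, 1)[0]
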