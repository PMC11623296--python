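"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator provides ground truth for every downstream stage: normal
reference tissues with tunable pairwise separation, tumor cohorts whose
log-expression is a mixture of the origin-tissue and target-tissue
profiles, optional tumor-purity confounding, and pathway-level planted
shifts.

Model
-----
Each gene g has a base log2 mean  b_g ~ N(base_log_mean, base_log_sd).
A tissue t adds an independent per-gene shift d_{t,g} ~ N(0, separation)
and silences a ``sparsity`` fraction of genes (their log-mean is set to
``silent_log_mean``), giving the tissue log-mean mu_t.  A normal sample
of tissue t is 2^(mu_t + eps), eps ~ N(0, noise_sd), i.e. lognormal
expression on a generic linear normalized scale.

A tumor of origin tissue OT metastasizing to TT has log-mean
(1 - alpha) * mu_OT + alpha * mu_TT + delta, where alpha in [0, 1] is
the mixture weight toward the target tissue (metastases default to a
larger alpha than primaries) and delta ~ N(0, tumor_offset_sd) is a
cohort-level tumor-specific offset.  With purity mixing on, the observed
bulk sample is purity * tumor + (1 - purity) * OT profile on the linear
scale, purity ~ Beta(a, b) — exactly the confounding the purity
residualization stage is meant to remove.

Planted pathway shifts redraw only a gene set's genes with a different
mixture weight alpha_p, leaving all other genes untouched; downstream,
such a pathway should surface with delta != 1 and a small empirical P.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ExpressionMatrix, GeneSetCollection
from .io import (write_expression_matrix, write_gene_sets_gmt,
                 write_sample_annotation, ANNOTATION_COLUMNS)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort generator (defaults are the study conditions)."""

    n_genes: int = 2000
    tissues: tuple = ("colon", "liver", "lung", "brain", "breast")
    separation: float = 1.0          # sd of per-gene tissue log2 shifts
    sparsity: float = 0.1            # fraction of genes silenced per tissue
    silent_log_mean: float = -3.0
    base_log_mean: float = 4.0
    base_log_sd: float = 1.5
    n_normal_per_tissue: int = 15
    n_patients: int = 20
    paired: bool = True
    alpha_primary: float = 0.2       # mixture weight toward TT in primaries
    alpha_met: float = 0.5           # metastases shift further toward the TT
    tumor_offset_sd: float = 1.0     # cohort-level tumor-specific log shift
    noise_sd: float = 0.5            # per-sample lognormal noise
    purity_mixing: bool = False
    purity_beta: tuple = (5.0, 2.0)  # Beta(a, b) of the malignant-cell fraction
    seed: int = 1206

    def __post_init__(self) -> None:
        for name in ("alpha_primary", "alpha_met"):
            a = getattr(self, name)
            if not 0 <= a <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {a}")
        if self.noise_sd < 0 or self.tumor_offset_sd < 0 or self.separation < 0:
            raise ValueError("spreads must be non-negative")
        if not 0 <= self.sparsity < 1:
            raise ValueError("sparsity must lie in [0, 1)")


class CohortSimulator:
    """Holds the drawn tissue landscape; all cohorts come from one instance.

    The seed fully determines the output: tissue log-means are drawn at
    construction, and each generate_* call consumes the instance's random
    stream deterministically.
    """

    def __init__(self, cfg: SimulationConfig | None = None, **overrides):
        if cfg is None:
            cfg = SimulationConfig(**overrides)
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
        base = self.rng.normal(cfg.base_log_mean, cfg.base_log_sd, cfg.n_genes)
        self.tissue_log_means: dict[str, np.ndarray] = {}
        for t in cfg.tissues:
            mu = base + self.rng.normal(0.0, cfg.separation, cfg.n_genes) \
                if cfg.separation > 0 else base.copy()
            if cfg.sparsity > 0:
                silent = self.rng.random(cfg.n_genes) < cfg.sparsity
                mu = np.where(silent, cfg.silent_log_mean, mu)
            self.tissue_log_means[t] = mu
        self._last_tumor_offset: np.ndarray | None = None

    # -- normals ----------------------------------------------------------

    def generate_reference_cohort(self) -> tuple[ExpressionMatrix, pd.DataFrame]:
        """Normal samples for every configured tissue."""
        cols, ids, rows = [], [], []
        for t in self.cfg.tissues:
            mu = self.tissue_log_means[t]
            for i in range(self.cfg.n_normal_per_tissue):
                eps = self.rng.normal(0.0, self.cfg.noise_sd, self.cfg.n_genes) \
                    if self.cfg.noise_sd > 0 else 0.0
                cols.append(2.0 ** (mu + eps))
                sid = f"{t}_normal_{i:03d}"
                ids.append(sid)
                rows.append({"sample_id": sid, "patient_id": pd.NA, "role": "normal",
                             "cancer_type": pd.NA, "origin_tissue": t,
                             "target_tissues": [], "purity": np.nan})
        data = pd.DataFrame(np.column_stack(cols), index=self.genes, columns=ids)
        return ExpressionMatrix(data, "cpm"), pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)

    # -- tumors -----------------------------------------------------------

    def _tumor_log_mean(self, ot: str, tt: str, alpha: float,
                        offset: np.ndarray) -> np.ndarray:
        return (1 - alpha) * self.tissue_log_means[ot] \
            + alpha * self.tissue_log_means[tt] + offset

    def _draw_sample(self, log_mean: np.ndarray) -> np.ndarray:
        eps = self.rng.normal(0.0, self.cfg.noise_sd, self.cfg.n_genes) \
            if self.cfg.noise_sd > 0 else 0.0
        return 2.0 ** (log_mean + eps)

    def generate_tumor_cohort(self, ot: str, tt: str, cancer_type: str = "SYN",
                              alpha_primary: float | None = None,
                              alpha_met: float | None = None
                              ) -> tuple[ExpressionMatrix, pd.DataFrame]:
        """Primary (+ paired metastatic) tumors of origin ``ot`` targeting ``tt``."""
        cfg = self.cfg
        a_pri = cfg.alpha_primary if alpha_primary is None else alpha_primary
        a_met = cfg.alpha_met if alpha_met is None else alpha_met
        if not 0 <= a_met <= 1 or not 0 <= a_pri <= 1:
            raise ValueError("mixture weights must lie in [0, 1]")
        offset = self.rng.normal(0.0, cfg.tumor_offset_sd, cfg.n_genes) \
            if cfg.tumor_offset_sd > 0 else np.zeros(cfg.n_genes)
        self._last_tumor_offset = offset
        mu_pri = self._tumor_log_mean(ot, tt, a_pri, offset)
        mu_met = self._tumor_log_mean(ot, tt, a_met, offset)
        ot_linear = 2.0 ** self.tissue_log_means[ot]
        a, b = cfg.purity_beta
        cols, ids, rows = [], [], []
        for i in range(cfg.n_patients):
            patient = f"{cancer_type}_pt{i:03d}"
            for role, mu in (("primary", mu_pri), ("metastatic", mu_met)):
                if role == "metastatic" and not cfg.paired:
                    continue
                x = self._draw_sample(mu)
                purity = np.nan
                if cfg.purity_mixing:
                    purity = float(self.rng.beta(a, b))
                    x = purity * x + (1 - purity) * ot_linear
                sid = f"{patient}_{role[:3]}"
                cols.append(x)
                ids.append(sid)
                rows.append({"sample_id": sid, "patient_id": patient, "role": role,
                             "cancer_type": cancer_type, "origin_tissue": ot,
                             "target_tissues": [tt], "purity": purity})
        data = pd.DataFrame(np.column_stack(cols), index=self.genes, columns=ids)
        return ExpressionMatrix(data, "cpm"), pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)

    # -- planted pathway shifts ------------------------------------------

    def plant_pathway_shift(self, matrix: ExpressionMatrix, annotation: pd.DataFrame,
                            gene_set: list[str], alpha_p: float,
                            ot: str, tt: str) -> ExpressionMatrix:
        """Redraw one gene set's tumor expression with mixture weight ``alpha_p``.

        Only the set's genes change; the cohort-level tumor offset of the
        most recent :meth:`generate_tumor_cohort` call is kept so that
        ``alpha_p`` equal to the cohort's own mixture weight leaves the
        matrix statistically unchanged.
        """
        unknown = set(gene_set) - set(matrix.genes)
        if unknown:
            raise KeyError(f"unknown genes in set: {sorted(unknown)[:5]}")
        if not 0 <= alpha_p <= 1:
            raise ValueError("alpha_p must lie in [0, 1]")
        gene_pos = {g: i for i, g in enumerate(matrix.genes)}
        idx = np.fromiter((gene_pos[g] for g in gene_set), dtype=int)
        offset = self._last_tumor_offset
        if offset is None:
            offset = np.zeros(self.cfg.n_genes)
        mu = self._tumor_log_mean(ot, tt, alpha_p, offset)[idx]
        ot_linear = (2.0 ** self.tissue_log_means[ot])[idx]
        data = matrix.data.copy()
        ann = annotation.set_index("sample_id")
        for sid in matrix.samples:
            if ann.loc[sid, "role"] not in ("primary", "metastatic"):
                continue
            eps = self.rng.normal(0.0, self.cfg.noise_sd, len(idx)) \
                if self.cfg.noise_sd > 0 else 0.0
            x = 2.0 ** (mu + eps)
            purity = ann.loc[sid, "purity"]
            if self.cfg.purity_mixing and np.isfinite(purity):
                x = purity * x + (1 - purity) * ot_linear
            data.iloc[idx, data.columns.get_loc(sid)] = x
        return ExpressionMatrix(data, matrix.state)

    # -- gene sets --------------------------------------------------------

    def generate_gene_sets(self, n_sets: int, size_range: tuple[int, int] = (20, 60),
                           seed: int | None = None, prefix: str = "SET"
                           ) -> GeneSetCollection:
        """Reproducible random gene sets (e.g. for null calibration)."""
        lo, hi = size_range
        if not 1 <= lo <= hi <= self.cfg.n_genes:
            raise ValueError(f"size_range {size_range} invalid for {self.cfg.n_genes} genes")
        rng = self.rng if seed is None else np.random.default_rng(seed)
        genes = np.asarray(self.genes, dtype=object)
        sets = {}
        for i in range(n_sets):
            size = int(rng.integers(lo, hi + 1))
            sets[f"{prefix}_{i:04d}"] = list(genes[rng.choice(len(genes), size, replace=False)])
        return GeneSetCollection(sets)

    # -- fixture bundles --------------------------------------------------

    def write_fixture_bundle(self, out_dir: str | Path, ot: str = "colon",
                             tt: str = "liver", n_sets: int = 20,
                             planted: dict[str, float] | None = None
                             ) -> dict:
        """Emit a complete on-disk cohort: matrices, annotations, GMT, truth YAML.

        ``planted`` maps gene-set names (from the generated collection) to
        their planted mixture weight alpha_p.  Returns the ground-truth
        dict that is also written to ``ground_truth.yaml``.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        normals, normal_ann = self.generate_reference_cohort()
        tumors, tumor_ann = self.generate_tumor_cohort(ot, tt)
        gene_sets = self.generate_gene_sets(n_sets)
        planted = dict(planted or {})
        for name, alpha_p in planted.items():
            tumors = self.plant_pathway_shift(tumors, tumor_ann,
                                              gene_sets[name], alpha_p, ot, tt)
        write_expression_matrix(normals, out / "normals.tsv")
        write_expression_matrix(tumors, out / "tumors.tsv")
        write_sample_annotation(normal_ann, out / "normals_annotation.tsv")
        write_sample_annotation(tumor_ann, out / "tumors_annotation.tsv")
        write_gene_sets_gmt(gene_sets, out / "gene_sets.gmt")
        truth = {
            "config": asdict(self.cfg),
            "ot": ot, "tt": tt,
            "alpha_primary": self.cfg.alpha_primary,
            "alpha_met": self.cfg.alpha_met,
            "planted_pathways": {k: float(v) for k, v in planted.items()},
            "purity_mixing": self.cfg.purity_mixing,
        }
        truth["config"]["tissues"] = list(self.cfg.tissues)
        truth["config"]["purity_beta"] = list(self.cfg.purity_beta)
        (out / "ground_truth.yaml").write_text(yaml.safe_dump(truth))
        return truth


# -- thin functional wrappers -------------------------------------------


def generate_reference_cohort(cfg: SimulationConfig):
    return CohortSimulator(cfg).generate_reference_cohort()


def generate_tumor_cohort(cfg: SimulationConfig, ot: str, tt: str, **kw):
    sim = CohortSimulator(cfg)
    sim.generate_reference_cohort()  # keep stream position shared with bundles
    return sim.generate_tumor_cohort(ot, tt, **kw)


def write_fixture_bundle(cfg: SimulationConfig, out_dir: str | Path, **kw):
    return CohortSimulator(cfg).write_fixture_bundle(out_dir, **kw)
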