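"""Organotropism specificity scoring and tumor-purity confounder handling.

Specificity asks whether metastases shifted toward their *actual* target
tissue rather than toward normal tissue in general.  Every candidate
tissue (the true TT plus decoys, e.g. the other GTEx tissues sans the
OT) is plugged in as the TT of a normalized TD ratio,
TD(OT, TT) / TD(sample, TT); the true TT's per-sample ratios are then
compared against each decoy's with one-sided Wilcoxon signed-rank tests
and BH FDR.  The specificity score counts the decoys the true TT
significantly beats.

Tumor purity (malignant-cell fraction) can confound bulk TD ratios:
lower purity drags a sample toward normal tissue.  When the Spearman
correlation between ratio and purity is significant (p < 0.05 in the
primary or metastatic class), the ratios are replaced by the residuals
of the linear model ``ratio ~ purity``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ReferenceProfile
from .distance import normalized_td_ratio
from .stats import bh_fdr, wilcoxon_signed_rank

PURITY_ALPHA = 0.05


@dataclass
class SpecificityResult:
    true_tt: str
    table: pd.DataFrame        # per candidate: median ratio, p, fdr, counted
    ratios: pd.DataFrame       # samples x candidates normalized ratios
    specificity_score: int = 0


@dataclass
class PurityAdjustment:
    spearman_rho: float = np.nan
    spearman_p: float = np.nan
    adjusted: bool = False
    residuals: np.ndarray | None = None


def specificity_analysis(met_matrix, met_samples: list[str],
                         ot_ref: ReferenceProfile,
                         candidate_tt_refs: dict[str, ReferenceProfile],
                         true_tt: str, measure: str = "euclidean",
                         alpha: float = 0.1,
                         log_space: bool = False) -> SpecificityResult:
    """Score how specifically metastases shifted toward their true target tissue.

    Parameters
    ----------
    met_matrix:
        :class:`~tdratio.containers.ExpressionMatrix` holding (at least)
        the metastatic samples, harmonized with the references.
    met_samples:
        Sample ids of the metastases to score (>= 3; the signed-rank
        comparison is paired across candidates by sample).
    candidate_tt_refs:
        Candidate target-tissue profiles including the true TT
        (>= 2 candidates).  The OT itself should not be among them.
    """
    if true_tt not in candidate_tt_refs:
        raise ValueError(f"true target tissue {true_tt!r} missing from candidates")
    if len(candidate_tt_refs) < 2:
        raise ValueError("need at least two candidate target tissues")
    if len(met_samples) < 3:
        raise ValueError("need at least three metastatic samples for the paired test")
    log_space = log_space or met_matrix.state == "log_space"
    ratios = pd.DataFrame(index=list(met_samples),
                          columns=list(candidate_tt_refs), dtype=float)
    for tissue, ref in candidate_tt_refs.items():
        for s in met_samples:
            x = met_matrix.data[s].to_numpy()
            ratios.loc[s, tissue] = normalized_td_ratio(
                ot_ref, ref, x, measure=measure, log_space=log_space)
    true_vec = ratios[true_tt].to_numpy()
    rows = []
    for tissue in candidate_tt_refs:
        if tissue == true_tt:
            continue
        cand_vec = ratios[tissue].to_numpy()
        diffs = true_vec - cand_vec
        if np.all(diffs == 0):  # identical profile: nothing to rank
            p = 1.0
        else:
            p = wilcoxon_signed_rank(diffs, alternative="greater").p
        rows.append({"candidate_tt": tissue,
                     "median_normalized_ratio": float(np.median(cand_vec)),
                     "p": p})
    table = pd.DataFrame(rows)
    table["fdr"] = bh_fdr(table["p"].to_numpy())
    table["counted"] = table["fdr"] < alpha
    return SpecificityResult(true_tt=true_tt, table=table, ratios=ratios,
                             specificity_score=int(table["counted"].sum()))


def purity_association(ratios, purity) -> PurityAdjustment:
    """Spearman correlation between TD ratios and tumor purity (one class)."""
    ratios = np.asarray(ratios, dtype=float)
    purity = np.asarray(purity, dtype=float)
    keep = np.isfinite(ratios) & np.isfinite(purity)
    if keep.sum() < 3:
        raise ValueError("need at least three samples with purity")
    r, p = ratios[keep], purity[keep]
    if np.all(p == p[0]):
        warnings.warn("constant purity: correlation undefined, not adjustable")
        return PurityAdjustment()
    res = sps.spearmanr(r, p)
    return PurityAdjustment(spearman_rho=float(res.statistic),
                            spearman_p=float(res.pvalue))


def purity_residualize(ratios, purity) -> PurityAdjustment:
    """Replace TD ratios by the residuals of OLS ``ratio ~ purity``."""
    ratios = np.asarray(ratios, dtype=float)
    purity = np.asarray(purity, dtype=float)
    if len(ratios) < 3:
        raise ValueError("need at least three samples to residualize")
    if len(ratios) != len(purity):
        raise ValueError("ratios and purity must align")
    X = np.column_stack([np.ones_like(purity), purity])
    beta, *_ = np.linalg.lstsq(X, ratios, rcond=None)
    residuals = ratios - X @ beta
    rho, pval = sps.spearmanr(ratios, purity)
    return PurityAdjustment(spearman_rho=float(rho), spearman_p=float(pval),
                            adjusted=True, residuals=residuals)


def adjust_ratios_for_purity(ratios: np.ndarray, purity: np.ndarray,
                             roles: np.ndarray,
                             alpha: float = PURITY_ALPHA) -> PurityAdjustment:
    """Dataset-level purity correction: test per class, residualize pooled.

    The ratio-purity Spearman test runs separately in the primary and
    metastatic classes; if either is significant at ``alpha`` the whole
    dataset's ratios are residualized against purity in one pooled
    regression (the per-class tests only decide *whether* to adjust).
    Returns an unadjusted result when no class triggers or purity is
    unusable.
    """
    ratios = np.asarray(ratios, dtype=float)
    purity = np.asarray(purity, dtype=float)
    roles = np.asarray(roles)
    triggered = False
    best = PurityAdjustment()
    for role in ("primary", "metastatic"):
        mask = (roles == role) & np.isfinite(purity) & np.isfinite(ratios)
        if mask.sum() < 3:
            continue
        if np.all(purity[mask] == purity[mask][0]):
            continue
        assoc = purity_association(ratios[mask], purity[mask])
        if np.isfinite(assoc.spearman_p) and assoc.spearman_p < alpha:
            triggered = True
            best = assoc
    if not triggered:
        return best
    adj = purity_residualize(ratios, purity)
    adj.spearman_rho, adj.spearman_p = best.spearman_rho, best.spearman_p
    return adj
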