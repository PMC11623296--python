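"""Transcriptomic distances (TD), TD ratios, normalized TD ratios and PMT scores.

The TD of a tumor sample X to a normal tissue Y is the Euclidean distance
between their log2-transformed, z-score-standardized expression vectors.
The TD ratio TD(X, OT) / TD(X, TT) summarizes whether X is transcriptionally
closer to its origin tissue (ratio < 1) or metastatic target tissue
(ratio > 1).  The PMT score ED(met, paired primary) / ED(met, TT) plays the
analogous role for a metastasis against its own primary.

Alternative measures: ``spearman`` (1 - rank correlation of the log
vectors) and ``cosine`` (1 - cosine similarity of the standardized
vectors); both are this package's conventions for correlation-based
distances.

Degenerate zero denominators yield a flagged ``inf`` sentinel rather than
an exception, so cohort-level aggregation can drop them with a logged
count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .containers import ReferenceProfile, ZeroVarianceError

MEASURES = ("euclidean", "spearman", "cosine")


@dataclass
class TDResult:
    """Distances of one sample to its OT and TT references, and their ratio."""

    sample_id: str
    measure: str
    td_ot: float
    td_tt: float
    ratio: float
    degenerate: bool = False
    residual: float | None = None


@dataclass
class PMTResult:
    """Primary-vs-target closeness of one metastasis: ED(met, primary)/ED(met, TT)."""

    met_sample_id: str
    primary_sample_id: str
    tt: str
    pmt_score: float
    degenerate: bool = False


def _as_log(x: np.ndarray, pseudocount: float, log_space: bool) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if log_space:
        return x
    return np.log2(x + pseudocount)


def standardize_vector(x: np.ndarray, pseudocount: float = 1.0,
                       log_space: bool = False) -> np.ndarray:
    """z-score the log2-transformed vector: (log2(x+pc) - mean) / sd.

    The sd uses the n-1 denominator; ``log_space=True`` skips the log
    transform for data already on log scale.  A constant vector after the
    log transform raises :class:`ZeroVarianceError`.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two genes to standardize")
    if not np.all(np.isfinite(x)):
        raise ValueError("input vector must be finite")
    y = _as_log(x, pseudocount, log_space)
    sd = y.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("vector is constant after log transform")
    return (y - y.mean()) / sd


def transcriptomic_distance(x: np.ndarray, ref: ReferenceProfile | np.ndarray,
                            measure: str = "euclidean",
                            pseudocount: float = 1.0,
                            log_space: bool = False) -> float:
    """TD between a sample vector and a reference profile on shared gene order."""
    ref_values = ref.values.to_numpy() if isinstance(ref, ReferenceProfile) else np.asarray(ref)
    x = np.asarray(x, dtype=float)
    if x.shape != ref_values.shape:
        raise ValueError(f"length mismatch: sample {x.shape} vs reference {ref_values.shape}")
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    if measure == "spearman":
        lx = _as_log(x, pseudocount, log_space)
        lr = _as_log(ref_values, pseudocount, log_space)
        rho = sps.spearmanr(lx, lr).statistic
        return float(1.0 - rho)
    zx = standardize_vector(x, pseudocount, log_space)
    zr = standardize_vector(ref_values, pseudocount, log_space)
    if measure == "euclidean":
        return float(np.linalg.norm(zx - zr))
    cos = float(np.dot(zx, zr) / (np.linalg.norm(zx) * np.linalg.norm(zr)))
    return 1.0 - cos


def _safe_ratio(num: float, den: float) -> tuple[float, bool]:
    if den > 0:
        return num / den, False
    if num == 0:
        return 1.0, False  # both distances zero: sample sits on both references
    return math.inf, True


def td_ratio(x: np.ndarray, ot_ref: ReferenceProfile, tt_ref: ReferenceProfile,
             measure: str = "euclidean", sample_id: str = "",
             pseudocount: float = 1.0, log_space: bool = False) -> TDResult:
    """TD ratio of one sample: TD(X, OT) / TD(X, TT)."""
    td_ot = transcriptomic_distance(x, ot_ref, measure, pseudocount, log_space)
    td_tt = transcriptomic_distance(x, tt_ref, measure, pseudocount, log_space)
    ratio, degenerate = _safe_ratio(td_ot, td_tt)
    return TDResult(sample_id=sample_id, measure=measure, td_ot=td_ot,
                    td_tt=td_tt, ratio=ratio, degenerate=degenerate)


def normalized_td_ratio(ot_ref: ReferenceProfile, tt_ref: ReferenceProfile,
                        x: np.ndarray, measure: str = "euclidean",
                        pseudocount: float = 1.0,
                        log_space: bool = False) -> float:
    """TD(OT, TT) / TD(X, TT): the specificity-analysis variant of the ratio.

    The numerator is constant across samples for a fixed (OT, TT) pair, so
    candidate target tissues can be compared fairly.  Returns ``inf`` when
    the sample coincides with the TT reference.
    """
    num = transcriptomic_distance(ot_ref.values.to_numpy(), tt_ref, measure,
                                  pseudocount, log_space)
    den = transcriptomic_distance(x, tt_ref, measure, pseudocount, log_space)
    ratio, _ = _safe_ratio(num, den)
    return ratio


def pmt_score(met: np.ndarray, primary: np.ndarray, tt_ref: ReferenceProfile,
              met_sample_id: str = "", primary_sample_id: str = "",
              pseudocount: float = 1.0, log_space: bool = False) -> PMTResult:
    """ED(met, paired primary) / ED(met, TT) on standardized log vectors.

    Scores above 1 mean the metastasis is closer in expression to the
    target tissue than to its own paired primary tumor.
    """
    met = np.asarray(met, dtype=float)
    primary = np.asarray(primary, dtype=float)
    if met.shape != primary.shape:
        raise ValueError("met/primary vectors must share gene order")
    zm = standardize_vector(met, pseudocount, log_space)
    zp = standardize_vector(primary, pseudocount, log_space)
    num = float(np.linalg.norm(zm - zp))
    den = transcriptomic_distance(met, tt_ref, "euclidean", pseudocount, log_space)
    score, degenerate = _safe_ratio(num, den)
    return PMTResult(met_sample_id=met_sample_id, primary_sample_id=primary_sample_id,
                     tt=tt_ref.tissue, pmt_score=score, degenerate=degenerate)


# ---------------------------------------------------------------------------
# vectorized kernels used by the pathway-level analysis


def zscore_columns(log_values: np.ndarray) -> np.ndarray:
    """z-score each column of a genes x samples log-expression block (ddof=1).

    Columns with zero variance come back as NaN; callers decide whether
    that is a degenerate sample or an error.
    """
    mu = log_values.mean(axis=0, keepdims=True)
    sd = log_values.std(axis=0, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (log_values - mu) / sd


def euclidean_td_block(log_block: np.ndarray, log_ref: np.ndarray) -> np.ndarray:
    """Euclidean TD of every column of ``log_block`` to one log reference vector.

    Both inputs are already on log scale; standardization happens here.
    """
    z = zscore_columns(log_block)
    zr = zscore_columns(log_ref[:, None])[:, 0]
    return np.sqrt(((z - zr[:, None]) ** 2).sum(axis=0))


def td_ratio_block(log_block: np.ndarray, log_ot: np.ndarray,
                   log_tt: np.ndarray) -> np.ndarray:
    """Per-sample euclidean TD ratios for a (possibly gene-restricted) log block."""
    d_ot = euclidean_td_block(log_block, log_ot)
    d_tt = euclidean_td_block(log_block, log_tt)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = d_ot / d_tt
    ratio[(d_tt == 0) & (d_ot == 0)] = 1.0
    return ratio


def pmt_score_block(log_met: np.ndarray, log_primary: np.ndarray,
                    log_tt: np.ndarray) -> np.ndarray:
    """Per-pair euclidean PMT scores for aligned met/primary log blocks."""
    zm = zscore_columns(log_met)
    zp = zscore_columns(log_primary)
    ztt = zscore_columns(log_tt[:, None])[:, 0]
    num = np.sqrt(((zm - zp) ** 2).sum(axis=0))
    den = np.sqrt(((zm - ztt[:, None]) ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        score = num / den
    score[(den == 0) & (num == 0)] = 1.0
    return score
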