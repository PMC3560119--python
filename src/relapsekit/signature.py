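"""Personalized genetic signature and follow-up trajectory tracking.

For each patient the pre-treatment (cancerous) and first-remission
(cancer-free) expression profiles are compared gene by gene on the log2
scale.  Genes whose absolute difference passes a threshold form the
patient's personal signature; each signature gene carries a weight
proportional to its differential expression.  Every later follow-up visit
is then compared against both reference profiles with a Pearson correlation
(qualitative trend) and a weighted Euclidean distance (quantitative
divergence); a visit that is closer to the cancerous reference raises a
monitoring flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .containers import ValidationError

CANCEROUS = "cancerous"
CANCER_FREE = "cancer_free"


@dataclass
class SignatureProfile:
    patient_id: str
    gene_ids: list[str]
    cancerous: np.ndarray
    cancer_free: np.ndarray
    weights: np.ndarray
    differential: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.gene_ids)
        if k < 1:
            raise ValidationError("signature must contain at least one gene")
        for name in ("cancerous", "cancer_free", "weights", "differential"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (k,):
                raise ValidationError(f"{name} must have one entry per gene")
            setattr(self, name, arr)
        if abs(self.weights.sum() - 1.0) > 1e-9 or (self.weights < 0).any():
            raise ValidationError("weights must be nonnegative and sum to 1")


@dataclass
class TrajectoryPoint:
    visit: str
    corr_cancerous: float
    corr_cancer_free: float
    dist_cancerous: float
    dist_cancer_free: float
    closer_to: str

    @property
    def flag(self) -> bool:
        return self.closer_to == CANCEROUS


def extract_signature(pre_treatment: pd.Series, remission: pd.Series,
                      threshold: float = 1.0, top_k: int | None = None,
                      patient_id: str = "") -> SignatureProfile:
    """Build a per-patient signature from the two reference profiles.

    Signature genes are those with ``|log2 difference| >= threshold``;
    weights are ``|d_g| / sum |d_g|``.  When no gene passes and ``top_k`` is
    given, the ``top_k`` genes with the largest nonzero ``|d_g|`` are used
    instead; with ``top_k=None`` an empty signature is an error.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    if not pre_treatment.index.equals(remission.index):
        raise ValidationError("profiles must share one probe set")
    d = pre_treatment.astype(float) - remission.astype(float)
    abs_d = d.abs()
    genes = list(d.index[abs_d >= threshold])
    if not genes:
        nonzero = abs_d[abs_d > 0]
        if top_k is not None and not nonzero.empty:
            genes = list(nonzero.sort_values(ascending=False).index[:top_k])
        else:
            raise ValidationError(
                "no gene passes the differential threshold; lower the "
                "threshold or enable the top_k fallback")
    dg = d[genes].to_numpy()
    weights = np.abs(dg) / np.abs(dg).sum()
    return SignatureProfile(patient_id, genes,
                            pre_treatment[genes].to_numpy(float),
                            remission[genes].to_numpy(float),
                            weights, dg)


def weighted_distance(x, ref, weights) -> float:
    """sqrt(sum_g w_g (x_g - ref_g)^2); zero-weight genes are ignored."""
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if not (x.shape == ref.shape == weights.shape):
        raise ValidationError("vector and weight lengths must match")
    if (weights < 0).any():
        raise ValidationError("weights must be nonnegative")
    return float(np.sqrt(np.sum(weights * (x - ref) ** 2)))


def _correlation(x: np.ndarray, ref: np.ndarray) -> float:
    """Pearson correlation; NaN when either vector is constant."""
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(ref) == 0:
        return float("nan")
    return float(pearsonr(x, ref).statistic)


def track_trajectory(profile: SignatureProfile,
                     visits: dict[str, pd.Series]) -> list[TrajectoryPoint]:
    """Compare each follow-up visit against both reference profiles.

    ``visits`` maps visit id to an expression Series covering (at least)
    the signature genes; comparisons are restricted to those genes, so
    genes outside the signature never influence the result.  A distance tie
    assigns the visit to the cancer-free side (no spurious alarm).
    """
    if not visits:
        raise ValidationError("need at least one visit")
    points = []
    for visit_id, series in visits.items():
        missing = [g for g in profile.gene_ids if g not in series.index]
        if missing:
            raise ValidationError(f"visit {visit_id} lacks signature genes "
                                  f"{missing}")
        x = series[profile.gene_ids].to_numpy(float)
        d_c = weighted_distance(x, profile.cancerous, profile.weights)
        d_f = weighted_distance(x, profile.cancer_free, profile.weights)
        points.append(TrajectoryPoint(
            visit=visit_id,
            corr_cancerous=_correlation(x, profile.cancerous),
            corr_cancer_free=_correlation(x, profile.cancer_free),
            dist_cancerous=d_c,
            dist_cancer_free=d_f,
            closer_to=CANCEROUS if d_c < d_f else CANCER_FREE))
    return points


def trajectory_table(patient_id: str,
                     points: list[TrajectoryPoint]) -> pd.DataFrame:
    """Long-format trajectory rows matching the package TSV dialect."""
    return pd.DataFrame(
        [(patient_id, p.visit, p.corr_cancerous, p.corr_cancer_free,
          p.dist_cancerous, p.dist_cancer_free, p.closer_to)
         for p in points],
        columns=["patient_id", "visit", "corr_cancerous", "corr_cancer_free",
                 "dist_cancerous", "dist_cancer_free", "closer_to"])
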