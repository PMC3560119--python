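"""Gene ranking: moderated two-class statistics and time-course rank tests.

Two rankers share a permutation-based q-value machinery:

* :func:`sam_two_class` — per-gene moderated t-statistic
  ``d_i = (mean_1 - mean_0) / (s_i + s0)`` where ``s_i`` is the pooled
  standard error and ``s0`` an exchangeability constant taken as a quantile
  of the ``s_i`` distribution.  Null distribution by relabeling permutations.
* :func:`sam_timecourse_wilcoxon` — each patient × gene trajectory is first
  summarized by its signed trapezoidal area across visits, then the two
  patient groups are compared with a Wilcoxon rank-sum on the summaries
  (midranks for ties); q-values again by group-label permutation.

Expression values are assumed to be on the log2 scale; reported fold
changes are linear-scale ratios of class means.  Gene selection combines a
two-sided fold-change threshold (``max(ratio, 1/ratio)``) with a q-value
cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import (ExpressionMatrix, TimeCourseTensor, ValidationError,
                         check_fields)


@dataclass
class SamConfig:
    n_permutations: int = 300
    s0_quantile: float = 0.5
    fold_change_threshold: float = 1.8
    q_cutoff: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        check_fields(
            self,
            n_permutations=(lambda n: n >= 1, "must be >= 1"),
            s0_quantile=(lambda q: 0 <= q <= 1, "must be a proportion"),
            fold_change_threshold=(lambda t: t > 0, "must be positive"),
            q_cutoff=(lambda q: 0 <= q <= 1, "must be a proportion"),
        )


@dataclass
class GeneRanking:
    """Per-gene statistic, linear fold change, q-value and selection flag."""

    table: pd.DataFrame            # columns: d, fold_change, q_value, selected
    fold_change_threshold: float
    q_cutoff: float

    @property
    def selected_genes(self) -> list[str]:
        return list(self.table.index[self.table.selected])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


def _label_assignments(labels: np.ndarray, n_permutations: int, rng):
    """Permuted label vectors: exhaustive when feasible, else sampled.

    With ``C(n, n1) <= n_permutations`` every distinct assignment of the
    positive class is enumerated exactly once; otherwise ``n_permutations``
    random relabelings are drawn.
    """
    n = len(labels)
    n1 = int(labels.sum())
    total = comb(n, n1)
    if total <= n_permutations:
        out = np.zeros((total, n), dtype=int)
        for b, pos in enumerate(combinations(range(n), n1)):
            out[b, list(pos)] = 1
        return out
    out = np.empty((n_permutations, n), dtype=int)
    for b in range(n_permutations):
        out[b] = rng.permutation(labels)
    return out


def _pooled_q_values(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Permutation p-values from the pooled null, then BH step-up.

    ``null`` is the flattened |statistic| values over all permutations and
    genes.  The step-up pass makes q monotone nonincreasing in |statistic|.
    """
    null_sorted = np.sort(null)
    m = len(observed)
    # P(|null| >= |obs|), with add-one smoothing over the pooled null
    exceed = len(null_sorted) - np.searchsorted(null_sorted,
                                                np.abs(observed), side="left")
    p = (exceed + 1) / (len(null_sorted) + 1)
    order = np.argsort(p)
    q = np.empty(m)
    ranked = p[order] * m / (np.arange(m) + 1)
    q[order] = np.minimum.accumulate(ranked[::-1])[::-1]
    return np.clip(q, 0, 1)


def _d_statistic(values: np.ndarray, labels: np.ndarray,
                 s0_quantile: float) -> np.ndarray:
    """Moderated t per gene; values is genes × samples, labels binary."""
    g1 = values[:, labels == 1]
    g0 = values[:, labels == 0]
    n1, n0 = g1.shape[1], g0.shape[1]
    diff = g1.mean(axis=1) - g0.mean(axis=1)
    pooled_var = (((n1 - 1) * g1.var(axis=1, ddof=1)
                   + (n0 - 1) * g0.var(axis=1, ddof=1))
                  / (n1 + n0 - 2))
    s = np.sqrt(pooled_var * (1 / n1 + 1 / n0))
    s0 = float(np.quantile(s, s0_quantile))
    denom = s + s0
    denom[denom == 0] = 1.0     # all-constant gene: d = 0 anyway
    return diff / denom


def _linear_fold_change(values: np.ndarray, labels: np.ndarray,
                        log_base: float = 2.0) -> np.ndarray:
    linear = np.power(log_base, values)
    m1 = linear[:, labels == 1].mean(axis=1)
    m0 = linear[:, labels == 0].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(m0 > 0, m1 / m0, np.inf)


def sam_two_class(matrix: ExpressionMatrix, labels,
                  cfg: SamConfig | None = None) -> GeneRanking:
    """Rank genes by the moderated statistic with permutation q-values.

    ``labels`` is a binary vector aligned with the matrix samples (1 =
    relapse).  Both classes need at least two samples.
    """
    if cfg is None:
        cfg = SamConfig()
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (len(matrix.sample_ids),):
        raise ValidationError("labels must align with the matrix samples")
    if min((labels == 1).sum(), (labels == 0).sum()) < 2:
        raise ValidationError("each class needs at least 2 samples")
    values = matrix.values.to_numpy(float)
    d = _d_statistic(values, labels, cfg.s0_quantile)
    rng = np.random.default_rng(cfg.seed)
    perms = _label_assignments(labels, cfg.n_permutations, rng)
    null = np.concatenate([
        np.abs(_d_statistic(values, perm, cfg.s0_quantile)) for perm in perms])
    q = _pooled_q_values(d, null)
    fc = _linear_fold_change(values, labels)
    table = pd.DataFrame({"d": d, "fold_change": fc, "q_value": q},
                         index=matrix.probe_ids)
    ranking = GeneRanking(table, cfg.fold_change_threshold, cfg.q_cutoff)
    return fold_change_filter(ranking, cfg.fold_change_threshold, cfg.q_cutoff)


def fold_change_filter(ranking: GeneRanking, threshold: float,
                       q_cutoff: float | None = None) -> GeneRanking:
    """Re-flag selection: two-sided fold change >= threshold and q <= cutoff.

    The fold-change comparison is inclusive and direction-free:
    ``max(ratio, 1/ratio) >= threshold``.
    """
    if threshold <= 0:
        raise ValidationError("fold-change threshold must be positive")
    if q_cutoff is None:
        q_cutoff = ranking.q_cutoff
    table = ranking.table.copy()
    fc = table.fold_change.to_numpy(float)
    with np.errstate(divide="ignore"):
        two_sided = np.maximum(fc, np.divide(1.0, fc, out=np.full_like(fc, np.inf),
                                             where=fc > 0))
    table["selected"] = (two_sided >= threshold) & (table.q_value <= q_cutoff)
    return GeneRanking(table, threshold, q_cutoff)


# -- time-course variant -----------------------------------------------------

def trapezoid_summary(tc: TimeCourseTensor) -> np.ndarray:
    """Signed trapezoidal area of each patient × gene trajectory."""
    if tc.n_visits < 2:
        raise ValidationError("need at least 2 visits for a trajectory summary")
    return np.trapezoid(tc.values, axis=2)


def rank_sum_statistic(summaries: np.ndarray, group: np.ndarray) -> np.ndarray:
    """Standardized Wilcoxon rank-sum per gene, midranks for ties.

    ``summaries`` is patients × genes.  Returns ``(W - E[W]) / sd(W)`` for
    the group-1 rank sum, with the tie-corrected null variance; genes where
    every summary ties return 0.
    """
    n = len(group)
    n1 = int(group.sum())
    n0 = n - n1
    ranks = np.apply_along_axis(rankdata, 0, summaries)
    w = ranks[group == 1].sum(axis=0)
    mean_w = n1 * (n + 1) / 2
    # tie correction: sum over tie groups of (t^3 - t)
    var_w = np.empty(summaries.shape[1])
    for g in range(summaries.shape[1]):
        _, counts = np.unique(summaries[:, g], return_counts=True)
        tie_term = np.sum(counts ** 3 - counts)
        var_w[g] = n1 * n0 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    sd = np.sqrt(var_w)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (w - mean_w) / sd, 0.0)
    return z


def sam_timecourse_wilcoxon(tc: TimeCourseTensor, group,
                            cfg: SamConfig | None = None,
                            summary: str = "area") -> GeneRanking:
    """Two-group ranking of time-course genes via per-patient summaries.

    ``group`` is binary per patient.  ``summary`` is ``"area"`` (signed
    trapezoidal area, default) or ``"slope"`` (least-squares slope across
    visits).
    """
    if cfg is None:
        cfg = SamConfig()
    group = np.asarray(group, dtype=int)
    if group.shape != (tc.n_patients,):
        raise ValidationError("group must align with the tensor patients")
    if min((group == 1).sum(), (group == 0).sum()) < 2:
        raise ValidationError("each group needs at least 2 patients")
    if tc.n_visits < 2:
        raise ValidationError("need at least 2 visits")
    if summary == "area":
        summaries = trapezoid_summary(tc)
    elif summary == "slope":
        x = np.arange(tc.n_visits) - (tc.n_visits - 1) / 2
        summaries = (tc.values * x).sum(axis=2) / (x ** 2).sum()
    else:
        raise ValidationError(f"unknown summary {summary!r} (area|slope)")
    z = rank_sum_statistic(summaries, group)
    rng = np.random.default_rng(cfg.seed)
    perms = _label_assignments(group, cfg.n_permutations, rng)
    null = np.concatenate([np.abs(rank_sum_statistic(summaries, perm))
                           for perm in perms])
    q = _pooled_q_values(z, null)
    # mean summary difference per unit of visit time, mapped to a linear ratio
    span = tc.n_visits - 1
    diff = (summaries[group == 1].mean(axis=0)
            - summaries[group == 0].mean(axis=0)) / span
    fc = np.power(2.0, diff)
    table = pd.DataFrame({"d": z, "fold_change": fc, "q_value": q},
                         index=tc.gene_ids)
    ranking = GeneRanking(table, cfg.fold_change_threshold, cfg.q_cutoff)
    return fold_change_filter(ranking, cfg.fold_change_threshold, cfg.q_cutoff)
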