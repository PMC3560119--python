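"""Feature-table cleaning, class rebalancing and probe-level QC.

The cleaning rules follow the study conventions: features with more than
90% missing values are dropped (strict inequality), remaining gaps are
imputed with column modes (nominal) or means (numeric), and the minority
class is oversampled with SMOTE.  Expression matrices lose control probes,
duplicate probes (first occurrence kept), quality-flagged probes and probes
with a high missing fraction.

SMOTE is applied to complete tables only and — when used inside an
evaluation — must be fitted within each training fold; the evaluation
driver in :mod:`relapsekit.classify_fuse` does exactly that.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .containers import (ExpressionMatrix, FeatureTable, NOMINAL, NUMERIC,
                         ValidationError, check_fields)

logger = logging.getLogger(__name__)


@dataclass
class SmoteConfig:
    """k-NN oversampling parameters.

    ``target_ratio`` is the requested minority:majority ratio after
    oversampling; 1.0 balances the classes.
    """

    k_neighbors: int = 5
    target_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        check_fields(
            self,
            k_neighbors=(lambda k: k >= 1, "must be >= 1"),
            target_ratio=(lambda r: 0 < r <= 1,
                          "must be in (0, 1]; parity is the maximum request"),
        )


def drop_sparse_features(table: FeatureTable,
                         max_missing: float = 0.9) -> FeatureTable:
    """Drop columns whose missing fraction strictly exceeds ``max_missing``.

    A column at exactly the threshold is retained.  Column order is
    preserved and the label untouched; an empty result is legal.
    """
    if not 0 <= max_missing <= 1:
        raise ValidationError(f"max_missing={max_missing} not in [0, 1]")
    frac = table.missing_fraction()
    keep = [c for c in table.data.columns if frac[c] <= max_missing]
    dropped = [c for c in table.data.columns if c not in keep]
    if dropped:
        logger.info("dropping %d sparse features: %s", len(dropped), dropped)
    return FeatureTable(table.data[keep].copy(),
                        {c: table.kinds[c] for c in keep},
                        None if table.label is None else table.label.copy(),
                        table.synthetic.copy())


def impute(table: FeatureTable) -> FeatureTable:
    """Fill gaps with column modes (nominal) or means (numeric).

    Observed values are never altered; a completely missing column is an
    error (drop it first with :func:`drop_sparse_features`).
    """
    data = table.data.copy()
    for c in data.columns:
        col = data[c]
        if not col.isna().any():
            continue
        observed = col.dropna()
        if observed.empty:
            raise ValidationError(
                f"column {c!r} has no observed values; apply "
                "drop_sparse_features before imputing")
        if table.kinds[c] == NOMINAL:
            fill = observed.mode(dropna=True).iloc[0]
        else:
            fill = float(observed.mean())
        data[c] = col.fillna(fill)
    return FeatureTable(data, dict(table.kinds),
                        None if table.label is None else table.label.copy(),
                        table.synthetic.copy())


def smote(table: FeatureTable, cfg: SmoteConfig | None = None) -> FeatureTable:
    """Append synthetic minority rows until minority/majority >= target.

    Each synthetic sample interpolates a random minority seed toward one of
    its ``k`` nearest minority neighbors (Euclidean distance over
    standardized numeric features); nominal values are copied from the seed.
    Synthetic rows carry ``synthetic=True`` flags and fresh patient ids.
    """
    if cfg is None:
        cfg = SmoteConfig()
    if table.label is None:
        raise ValidationError("smote requires a labeled table")
    if table.data.isna().any().any():
        raise ValidationError("smote requires a fully imputed table")
    counts = table.label.value_counts()
    if len(counts) < 2:
        raise ValidationError("both classes must be present")
    minority_label = counts.idxmin()
    n_min, n_maj = counts.min(), counts.max()
    if n_min <= cfg.k_neighbors:
        raise ValidationError(
            f"minority class has {n_min} samples but k_neighbors="
            f"{cfg.k_neighbors}; choose a smaller k")
    n_needed = int(np.ceil(cfg.target_ratio * n_maj)) - n_min
    if n_needed <= 0:
        return table.copy()

    rng = np.random.default_rng(cfg.seed)
    minority = table.data[table.label == minority_label]
    numeric = table.numeric_columns()
    if numeric:
        x = minority[numeric].to_numpy(float)
        scale = x.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
        z = (x - x.mean(axis=0)) / scale
        nn = NearestNeighbors(n_neighbors=cfg.k_neighbors + 1).fit(z)
        neighbor_idx = nn.kneighbors(z, return_distance=False)[:, 1:]
    else:
        # no numeric features: fall back to uniformly random minority partners
        neighbor_idx = np.stack([
            rng.permutation([j for j in range(len(minority)) if j != i])
            [:cfg.k_neighbors] for i in range(len(minority))])

    new_rows = []
    for s in range(n_needed):
        i = int(rng.integers(len(minority)))
        j = int(neighbor_idx[i, rng.integers(neighbor_idx.shape[1])])
        gap = rng.random()
        seed_row = minority.iloc[i]
        neigh_row = minority.iloc[j]
        row = seed_row.copy()
        for c in numeric:
            row[c] = seed_row[c] + gap * (neigh_row[c] - seed_row[c])
        row.name = f"synth_{s:04d}"
        new_rows.append(row)
    synth = pd.DataFrame(new_rows)
    synth = synth.astype({c: table.data[c].dtype for c in numeric})
    data = pd.concat([table.data, synth])
    label = pd.concat([table.label,
                       pd.Series(minority_label, index=synth.index)])
    flags = pd.concat([table.synthetic,
                       pd.Series(True, index=synth.index)])
    return FeatureTable(data, dict(table.kinds), label, flags)


def filter_probes(matrix: ExpressionMatrix,
                  max_missing: float = 0.5) -> ExpressionMatrix:
    """Remove control, duplicate, low-quality and gappy probes.

    Keeps the first occurrence of each duplicate group (a probe that names a
    representative in ``duplicate_of`` is removed; the representative
    stays), drops probes flagged ``is_control`` or ``quality_flag`` and
    probes whose missing fraction exceeds ``max_missing``.  Probe order is
    preserved.
    """
    if matrix.annotation is None:
        raise ValidationError("filter_probes requires probe annotation")
    ann = matrix.annotation
    missing = matrix.missing_fraction()
    seen_groups: set[str] = set()
    keep = []
    for probe in matrix.probe_ids:
        if bool(ann.at[probe, "is_control"]) or bool(ann.at[probe, "quality_flag"]):
            continue
        if missing[probe] > max_missing:
            continue
        # a probe's duplicate group is named by its representative; keep only
        # the first group member encountered in probe order
        group = str(ann.at[probe, "duplicate_of"]) or str(probe)
        if group in seen_groups:
            continue
        seen_groups.add(group)
        keep.append(probe)
    values = matrix.values.loc[keep]
    annotation = ann.loc[keep]
    return ExpressionMatrix(values.copy(), annotation.copy())
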