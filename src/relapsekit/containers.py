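"""In-memory containers for the cohort data handled by the pipeline.

Three containers cover every stage:

* :class:`FeatureTable` — patients × mixed nominal/numeric features with an
  optional binary relapse label (clinical and imaging sources).
* :class:`ExpressionMatrix` — probes × samples one-channel intensities on a
  log2-like scale, with per-probe QC annotation.
* :class:`TimeCourseTensor` — patients × genes × ordered follow-up visits of
  blood expression.

All on-disk interchange is plain TSV: feature tables use ``NA`` for missing
values and a final ``relapse`` column; expression matrices are probes-in-rows
TSV plus a probe-annotation TSV; time courses are long-format TSV.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NOMINAL = "nominal"
NUMERIC = "numeric"

MISSING_MARKER = "NA"

#: canonical visit names for the three-slice follow-up design
DEFAULT_VISITS = ("baseline", "fu1", "fu2")


class ValidationError(ValueError):
    """Raised when a container or config violates its invariants."""


@dataclass
class FeatureTable:
    """Patients × features table with per-column type tags.

    Parameters
    ----------
    data:
        Patients in rows, features in columns.  Missing values are ``np.nan``
        (numeric columns) or ``NaN``/``None`` (nominal, object dtype).
    kinds:
        Maps every column name to ``"nominal"`` or ``"numeric"``.
    label:
        Optional binary relapse indicator aligned with ``data.index``.
    synthetic:
        Boolean flag per row marking SMOTE-generated samples.
    """

    data: pd.DataFrame
    kinds: dict[str, str]
    label: pd.Series | None = None
    synthetic: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        missing_tags = [c for c in self.data.columns if c not in self.kinds]
        if missing_tags:
            raise ValidationError(f"columns without a type tag: {missing_tags}")
        bad = {k: v for k, v in self.kinds.items()
               if k in self.data.columns and v not in (NOMINAL, NUMERIC)}
        if bad:
            raise ValidationError(f"unknown column kinds: {bad}")
        if self.label is not None:
            if len(self.label) != len(self.data):
                raise ValidationError(
                    f"label length {len(self.label)} != n_patients {len(self.data)}")
            self.label = pd.Series(np.asarray(self.label, dtype=int),
                                   index=self.data.index, name="relapse")
        if self.synthetic is None:
            self.synthetic = pd.Series(False, index=self.data.index)
        else:
            self.synthetic = pd.Series(np.asarray(self.synthetic, dtype=bool),
                                       index=self.data.index)

    # -- basic introspection -------------------------------------------------

    @property
    def patient_ids(self) -> pd.Index:
        return self.data.index

    @property
    def n_patients(self) -> int:
        return len(self.data)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def numeric_columns(self) -> list[str]:
        return [c for c in self.data.columns if self.kinds[c] == NUMERIC]

    def nominal_columns(self) -> list[str]:
        return [c for c in self.data.columns if self.kinds[c] == NOMINAL]

    def missing_fraction(self) -> pd.Series:
        """Fraction of missing entries per column."""
        return self.data.isna().mean()

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), dict(self.kinds),
                            None if self.label is None else self.label.copy(),
                            self.synthetic.copy())

    def select_features(self, names: list[str]) -> "FeatureTable":
        """Restrict to a feature subset, preserving label and flags."""
        unknown = [n for n in names if n not in self.data.columns]
        if unknown:
            raise KeyError(f"unknown features: {unknown}")
        return FeatureTable(self.data[names].copy(),
                            {n: self.kinds[n] for n in names},
                            None if self.label is None else self.label.copy(),
                            self.synthetic.copy())

    def subset_rows(self, index) -> "FeatureTable":
        """Row subset by positional index array."""
        return FeatureTable(self.data.iloc[index].copy(), dict(self.kinds),
                            None if self.label is None else self.label.iloc[index].copy(),
                            self.synthetic.iloc[index].copy())

    # -- TSV dialect ---------------------------------------------------------

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        if self.label is not None:
            out["relapse"] = self.label.values
        out.to_csv(path, sep="\t", na_rep=MISSING_MARKER, index_label="patient_id")

    @classmethod
    def from_tsv(cls, path, kinds: dict[str, str] | None = None) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", index_col="patient_id",
                         na_values=[MISSING_MARKER], keep_default_na=False)
        label = None
        if "relapse" in df.columns:
            label = df.pop("relapse").astype(int)
        if kinds is None:
            kinds = {}
            for c in df.columns:
                numeric = pd.to_numeric(df[c], errors="coerce")
                observed = df[c].notna()
                kinds[c] = NUMERIC if numeric[observed].notna().all() else NOMINAL
        for c, k in kinds.items():
            if k == NUMERIC:
                df[c] = pd.to_numeric(df[c])
        return cls(df, kinds, label)


@dataclass
class ExpressionMatrix:
    """Probes × samples intensity grid with per-probe QC annotation.

    ``annotation`` is indexed by probe id with columns ``is_control`` (bool),
    ``duplicate_of`` (probe id of the group representative, or empty string)
    and ``quality_flag`` (bool, True = low quality).
    """

    values: pd.DataFrame
    annotation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.annotation is not None:
            if not self.values.index.equals(self.annotation.index):
                raise ValidationError("annotation index must match probe ids")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return len(self.values)

    def missing_fraction(self) -> pd.Series:
        return self.values.isna().mean(axis=1)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(),
            None if self.annotation is None else self.annotation.copy())

    def to_tsv(self, values_path, annotation_path=None) -> None:
        self.values.to_csv(values_path, sep="\t", na_rep=MISSING_MARKER,
                           index_label="probe_id")
        if annotation_path is not None and self.annotation is not None:
            self.annotation.to_csv(annotation_path, sep="\t", index_label="probe_id")

    @classmethod
    def from_tsv(cls, values_path, annotation_path=None) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col="probe_id",
                             na_values=[MISSING_MARKER], keep_default_na=False)
        annotation = None
        if annotation_path is not None:
            annotation = pd.read_csv(annotation_path, sep="\t", index_col="probe_id",
                                     keep_default_na=False)
            annotation["is_control"] = annotation["is_control"].astype(bool)
            annotation["quality_flag"] = annotation["quality_flag"].astype(bool)
            annotation["duplicate_of"] = annotation["duplicate_of"].astype(str).replace("nan", "")
        return cls(values, annotation)


@dataclass
class TimeCourseTensor:
    """Blood expression over ordered follow-up visits.

    ``values[p, g, t]`` is the (log2-scale) expression of gene ``g`` for
    patient ``p`` at visit ``t``.
    """

    values: np.ndarray
    patient_ids: list[str]
    gene_ids: list[str]
    visits: tuple[str, ...] = DEFAULT_VISITS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.patient_ids), len(self.gene_ids), len(self.visits))
        if self.values.shape != expected:
            raise ValidationError(
                f"tensor shape {self.values.shape} != (patients, genes, visits) {expected}")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    def subset_patients(self, index) -> "TimeCourseTensor":
        index = np.asarray(index)
        return TimeCourseTensor(self.values[index],
                                [self.patient_ids[i] for i in index],
                                list(self.gene_ids), self.visits)

    def to_long_tsv(self, path) -> None:
        rows = []
        for p, pid in enumerate(self.patient_ids):
            for t, visit in enumerate(self.visits):
                for g, gid in enumerate(self.gene_ids):
                    rows.append((pid, visit, gid, self.values[p, g, t]))
        pd.DataFrame(rows, columns=["patient_id", "visit", "probe_id", "value"]) \
            .to_csv(path, sep="\t", index=False)

    @classmethod
    def from_long_tsv(cls, path) -> "TimeCourseTensor":
        df = pd.read_csv(path, sep="\t")
        patients = list(pd.unique(df["patient_id"]))
        genes = list(pd.unique(df["probe_id"]))
        visits = tuple(pd.unique(df["visit"]))
        wide = df.set_index(["patient_id", "probe_id", "visit"])["value"]
        values = np.empty((len(patients), len(genes), len(visits)))
        for p, pid in enumerate(patients):
            for g, gid in enumerate(genes):
                for t, visit in enumerate(visits):
                    values[p, g, t] = wide[(pid, gid, visit)]
        return cls(values, [str(p) for p in patients], [str(g) for g in genes], visits)


def check_fields(obj, **conditions) -> None:
    """Validate dataclass fields; raises naming the offending field.

    ``conditions`` maps field name to a ``(predicate, message)`` pair.
    """
    for name, (ok, message) in conditions.items():
        value = getattr(obj, name)
        if not ok(value):
            raise ValidationError(f"{type(obj).__name__}.{name}={value!r}: {message}")


def dataclass_replace(obj, **changes):
    return dataclasses.replace(obj, **changes)
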