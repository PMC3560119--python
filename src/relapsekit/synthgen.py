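"""Synthetic multimodal cohorts with known ground truth.

No public accession exists for OSCC relapse cohorts of the shape this
pipeline targets, so every downstream stage is exercised on simulated data
that emulates the study conditions: an 86-patient baseline cohort with 26
relapsers and 60 non-relapsers carrying clinical (~62 features), imaging
(~16 features), tissue-expression and blood-expression sources; and a
23-patient three-visit blood time course whose dynamics are driven by a
known ground-truth DBN.

Expression is emitted on a log2-like intensity scale: background genes are
``Normal(8, noise_sd)`` and planted differentially expressed genes are
shifted by ``log2(fold_change)`` in relapsers, so the linear-scale fold
change of a planted gene converges to the requested value as the noise
vanishes.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (DEFAULT_VISITS, ExpressionMatrix, FeatureTable,
                         NOMINAL, NUMERIC, TimeCourseTensor, ValidationError,
                         check_fields)
from .dbn.model import DbnModel
from .dbn.structure import DbnStructure

RELAPSE = "relapse"

# Probe-QC flag counts that reduce 45,015 probes to 33,491 clean ones
_N_PROBES = 45015
_N_CONTROL = 4500
_N_DUPLICATE = 4500
_N_LOW_QUALITY = 2524


@dataclass
class CohortSpec:
    """Parameters of the synthetic baseline cohort.

    Defaults reproduce the study conditions: 86 patients (26 relapsers),
    62 clinical and 16 imaging features, 45,015 probes of which QC flags
    remove 11,524 leaving 33,491.
    """

    n_patients: int = 86
    n_relapsers: int = 26
    n_clinical: int = 62
    n_imaging: int = 16
    n_probes: int = _N_PROBES
    frac_control_probes: float = _N_CONTROL / _N_PROBES
    frac_duplicate_probes: float = _N_DUPLICATE / _N_PROBES
    frac_low_quality: float = _N_LOW_QUALITY / _N_PROBES
    n_de_genes: int = 9
    fold_change: float = 2.5
    missing_heavy_features: int = 4
    missing_heavy_rate: float = 0.95
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        check_fields(
            self,
            n_patients=(lambda n: n >= 2, "need at least 2 patients"),
            n_relapsers=(lambda n: 0 <= n <= self.n_patients,
                         "must be between 0 and n_patients"),
            n_clinical=(lambda n: n >= 1, "must be positive"),
            n_imaging=(lambda n: n >= 1, "must be positive"),
            n_probes=(lambda n: n >= 1, "must be positive"),
            frac_control_probes=(lambda f: 0 <= f <= 1, "proportion in [0,1]"),
            frac_duplicate_probes=(lambda f: 0 <= f <= 1, "proportion in [0,1]"),
            frac_low_quality=(lambda f: 0 <= f <= 1, "proportion in [0,1]"),
            n_de_genes=(lambda n: n >= 0, "must be nonnegative"),
            fold_change=(lambda f: f > 1, "must exceed 1"),
            missing_heavy_features=(lambda n: 0 <= n < self.n_clinical,
                                    "must leave some observed features"),
            missing_heavy_rate=(lambda r: 0.9 < r <= 1,
                                "must lie in (0.9, 1] to trigger the sparse-"
                                "feature rule"),
            noise_sd=(lambda s: s >= 0, "must be nonnegative"),
        )
        total = (self.frac_control_probes + self.frac_duplicate_probes
                 + self.frac_low_quality)
        if total > 1:
            raise ValidationError("CohortSpec probe flag fractions sum above 1")


@dataclass
class CohortTruth:
    """Planted signal locations for a generated cohort."""

    tissue_de_genes: list[str]
    blood_de_genes: list[str]
    clinical_informative: list[str]
    imaging_informative: list[str]
    missing_heavy: list[str]


def _labels(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    labels = np.zeros(spec.n_patients, dtype=int)
    labels[:spec.n_relapsers] = 1
    rng.shuffle(labels)
    return labels


def _feature_table(prefix: str, n_features: int, n_informative: int,
                   labels: np.ndarray, patient_ids: list[str],
                   rng: np.random.Generator, noise_sd: float,
                   missing_heavy: int, missing_heavy_rate: float,
                   background_missing: float = 0.05):
    """Mixed nominal/numeric table with class-dependent informative features.

    Roughly 60% of columns are nominal with 2-4 categories; informative
    nominal columns get class-dependent category probabilities and
    informative numeric columns a one-sd class shift.
    """
    n = len(labels)
    columns, kinds = {}, {}
    informative = [f"{prefix}_f{j:02d}" for j in range(n_informative)]
    names = informative + [f"{prefix}_f{j:02d}"
                           for j in range(n_informative, n_features)]
    for j, name in enumerate(names):
        nominal = rng.random() < 0.6
        info = name in informative
        if nominal:
            k = int(rng.integers(2, 5))
            cats = list(string.ascii_lowercase[:k])
            base = rng.dirichlet(np.ones(k) * 3)
            if info:
                skew = rng.dirichlet(np.ones(k))
                shifted = 0.15 * base + 0.85 * skew
                probs = np.where(labels[:, None] == 1, shifted, base)
            else:
                probs = np.tile(base, (n, 1))
            draws = [rng.choice(cats, p=probs[i] / probs[i].sum())
                     for i in range(n)]
            columns[name] = pd.Series(draws, dtype=object)
            kinds[name] = NOMINAL
        else:
            center = rng.normal(0, 1)
            shift = 1.0 if info else 0.0
            vals = rng.normal(center + shift * labels, max(noise_sd, 1e-12))
            columns[name] = pd.Series(vals)
            kinds[name] = NUMERIC
    df = pd.DataFrame(columns)
    df.index = pd.Index(patient_ids, name="patient_id")
    # sporadic missingness on a few non-informative columns
    sparse_cols = []
    eligible = [c for c in names if c not in informative]
    for c in eligible[:missing_heavy]:
        mask = rng.random(n) < missing_heavy_rate
        # the sparse-feature rule is strict (>90%); guarantee the column
        # qualifies even on small cohorts
        while mask.mean() <= 0.9:
            mask[rng.integers(n)] = True
        df.loc[mask, c] = np.nan
        sparse_cols.append(c)
    for c in eligible[missing_heavy:]:
        if rng.random() < 0.5:
            mask = rng.random(n) < background_missing
            df.loc[mask, c] = np.nan
    table = FeatureTable(df, kinds, label=pd.Series(labels, index=df.index))
    return table, informative, sparse_cols


def _annotation(spec: CohortSpec, probe_ids: list[str],
                rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_probes
    n_control = round(spec.frac_control_probes * n)
    n_duplicate = round(spec.frac_duplicate_probes * n)
    n_low = round(spec.frac_low_quality * n)
    order = rng.permutation(n)
    control = order[:n_control]
    duplicate = order[n_control:n_control + n_duplicate]
    low = order[n_control + n_duplicate:n_control + n_duplicate + n_low]
    clean = order[n_control + n_duplicate + n_low:]
    ann = pd.DataFrame({"is_control": False, "duplicate_of": "",
                        "quality_flag": False},
                       index=pd.Index(probe_ids, name="probe_id"))
    ann.iloc[control, ann.columns.get_loc("is_control")] = True
    ann.iloc[low, ann.columns.get_loc("quality_flag")] = True
    if len(duplicate):
        # each duplicate probe mirrors a clean representative
        reps = rng.choice(clean, size=len(duplicate))
        ann.iloc[duplicate, ann.columns.get_loc("duplicate_of")] = \
            [probe_ids[r] for r in reps]
    return ann


def _expression(spec: CohortSpec, labels: np.ndarray, sample_ids: list[str],
                prefix: str, rng: np.random.Generator):
    probe_ids = [f"{prefix}_p{j:05d}" for j in range(spec.n_probes)]
    ann = _annotation(spec, probe_ids, rng)
    clean = np.flatnonzero((~ann.is_control) & (ann.duplicate_of == "")
                           & (~ann.quality_flag))
    de_idx = rng.choice(clean, size=min(spec.n_de_genes, len(clean)),
                        replace=False)
    values = rng.normal(8.0, max(spec.noise_sd, 1e-12),
                        size=(spec.n_probes, len(labels)))
    shift = np.log2(spec.fold_change)
    values[np.ix_(de_idx, np.flatnonzero(labels == 1))] += shift
    # duplicates copy their representative's values
    dup_rows = np.flatnonzero(ann.duplicate_of != "")
    pos = {p: i for i, p in enumerate(probe_ids)}
    for r in dup_rows:
        values[r] = values[pos[ann.duplicate_of.iloc[r]]]
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                     columns=sample_ids), ann)
    return matrix, [probe_ids[i] for i in sorted(de_idx)]


def generate_baseline_cohort(spec: CohortSpec):
    """Clinical, imaging, tissue and blood sources for one synthetic cohort.

    Returns ``(clinical, imaging, tissue, blood, truth)`` where ``truth``
    records the planted differentially expressed genes and informative
    features.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _labels(spec, rng)
    patients = [f"P{i:03d}" for i in range(spec.n_patients)]
    n_info_clin = max(2, spec.n_clinical // 8)
    n_info_img = max(2, spec.n_imaging // 4)
    clinical, clin_info, sparse = _feature_table(
        "clin", spec.n_clinical, n_info_clin, labels, patients, rng,
        spec.noise_sd, spec.missing_heavy_features, spec.missing_heavy_rate)
    imaging, img_info, _ = _feature_table(
        "img", spec.n_imaging, n_info_img, labels, patients, rng,
        spec.noise_sd, missing_heavy=0, missing_heavy_rate=spec.missing_heavy_rate)
    tissue, tissue_de = _expression(spec, labels, patients, "tis", rng)
    blood, blood_de = _expression(spec, labels, patients, "bld", rng)
    truth = CohortTruth(tissue_de, blood_de, clin_info, img_info, sparse)
    return clinical, imaging, tissue, blood, truth


# -- ground-truth DBN and longitudinal sampling ------------------------------

@dataclass
class GroundTruthDbn:
    """A fully specified DBN used to drive longitudinal simulation.

    Wraps a :class:`~relapsekit.dbn.model.DbnModel` (which validates CPT row
    sums and intra-slice acyclicity) and fixes the number of visits.  Gene
    states are emitted as Gaussian intensities with state-dependent means.
    """

    model: DbnModel
    n_slices: int = 3
    emission_sd: float = 0.25
    state_spacing: float = 2.0
    baseline_level: float = 8.0

    def __post_init__(self) -> None:
        if self.n_slices < 2:
            raise ValidationError("a DBN time course needs at least 2 slices")
        if self.emission_sd < 0:
            raise ValidationError("emission_sd must be nonnegative")

    @property
    def variables(self) -> tuple[str, ...]:
        return self.model.variables

    @property
    def gene_ids(self) -> list[str]:
        return [v for v in self.variables if v != RELAPSE]

    def state_means(self, var: str) -> np.ndarray:
        r = self.model.cardinalities[var]
        return self.baseline_level + self.state_spacing * (
            np.arange(r) - (r - 1) / 2)


@dataclass
class TimeCourseResult:
    tensor: TimeCourseTensor
    relapse_states: np.ndarray     # (n_patients, n_slices) binary
    states: np.ndarray             # (n_patients, n_variables, n_slices)
    variables: tuple[str, ...] = field(default=())


def _sample_slice0(truth: GroundTruthDbn, rng) -> dict[str, int]:
    model = truth.model
    states: dict[str, int] = {}
    for v in model.structure.topological_order():
        row = model.config_index(model.initial_parents(v),
                                 {(p, 0): states[p]
                                  for p, _ in model.initial_parents(v)})
        states[v] = int(rng.choice(model.cardinalities[v],
                                   p=model.initial_cpts[v][row]))
    return states


def _sample_transition(truth: GroundTruthDbn, prev: dict[str, int], rng):
    model = truth.model
    states: dict[str, int] = {}
    for v in model.structure.topological_order():
        if v == RELAPSE and prev.get(RELAPSE) == 1:
            states[v] = 1        # relapse is absorbing by construction
            continue
        parents = model.transition_parents(v)
        assignment = {(p, lag): (prev[p] if lag == -1 else states[p])
                      for p, lag in parents}
        row = model.config_index(parents, assignment)
        states[v] = int(rng.choice(model.cardinalities[v],
                                   p=model.transition_cpts[v][row]))
    return states


def _sample_patient(truth: GroundTruthDbn, rng) -> np.ndarray:
    trajectory = [_sample_slice0(truth, rng)]
    for _ in range(truth.n_slices - 1):
        trajectory.append(_sample_transition(truth, trajectory[-1], rng))
    return np.array([[sl[v] for sl in trajectory] for v in truth.variables])


def generate_timecourse(truth: GroundTruthDbn, n_patients: int,
                        n_relapsers: int | None = None,
                        seed: int = 0) -> TimeCourseResult:
    """Ancestral-sample a longitudinal cohort from a ground-truth DBN.

    ``n_relapsers`` (patients whose relapse state is 1 at the final visit)
    is enforced by rejection sampling when given; ``None`` samples the
    cohort unconditionally.  The relapse state is absorbing: once 1 it stays
    1 regardless of its parents.
    """
    if n_patients < 1:
        raise ValidationError("n_patients must be positive")
    if n_relapsers is not None and not 0 <= n_relapsers <= n_patients:
        raise ValidationError("n_relapsers must be between 0 and n_patients")
    rng = np.random.default_rng(seed)
    variables = truth.variables
    relapse_row = variables.index(RELAPSE) if RELAPSE in variables else None
    kept: list[np.ndarray] = []
    quota_pos = n_relapsers
    quota_neg = None if n_relapsers is None else n_patients - n_relapsers
    attempts = 0
    while len(kept) < n_patients:
        attempts += 1
        if attempts > 1000 * n_patients:
            raise ValidationError(
                "rejection sampling failed to meet the relapse quota; the "
                "ground-truth CPTs make a class (near-)impossible")
        states = _sample_patient(truth, rng)
        if quota_pos is not None and relapse_row is not None:
            is_pos = states[relapse_row, -1] == 1
            if is_pos:
                if quota_pos == 0:
                    continue
                quota_pos -= 1
            else:
                if quota_neg == 0:
                    continue
                quota_neg -= 1
        kept.append(states)
    states = np.stack(kept)          # (patients, variables, slices)
    gene_rows = [i for i, v in enumerate(variables) if v != RELAPSE]
    genes = [variables[i] for i in gene_rows]
    expr = np.empty((n_patients, len(genes), truth.n_slices))
    for gi, row in enumerate(gene_rows):
        expr[:, gi, :] = truth.state_means(genes[gi])[states[:, row, :]]
    if truth.emission_sd > 0:
        expr += rng.normal(0.0, truth.emission_sd, size=expr.shape)
    visits = DEFAULT_VISITS if truth.n_slices == 3 else tuple(
        f"t{t}" for t in range(truth.n_slices))
    tensor = TimeCourseTensor(expr, [f"P{i:03d}" for i in range(n_patients)],
                              genes, visits)
    relapse = (states[:, relapse_row, :] if relapse_row is not None
               else np.zeros((n_patients, truth.n_slices), dtype=int))
    return TimeCourseResult(tensor, relapse.astype(int), states, variables)


# -- ready-made ground truths ------------------------------------------------

def _copy_cpt(r: int, fidelity: float) -> np.ndarray:
    """Transition table where the child copies its parent with prob fidelity."""
    table = np.full((r, r), (1 - fidelity) / (r - 1))
    np.fill_diagonal(table, fidelity)
    return table


def default_ground_truth(n_genes: int = 9, fidelity: float = 0.85,
                         relapse_driver: str = "g1",
                         p_relapse_high: float = 0.75,
                         p_relapse_low: float = 0.05,
                         p_relapse_baseline: float = 0.15,
                         emission_sd: float = 0.25) -> GroundTruthDbn:
    """Nine-gene + relapse ground truth mirroring the scale of the final model.

    Genes are three-state (under/normal/over-expressed).  Inter-slice edges:
    persistence for g1..g3, a chain of cross-edges g1→g4, g2→g5, g3→g6, a
    relapse driver (g1 over-expression raises the relapse hazard) and the
    absorbing relapse self-edge.  g7..g9 are unconnected noise genes.
    """
    genes = [f"g{i}" for i in range(1, n_genes + 1)]
    variables = tuple(genes + [RELAPSE])
    inter = {("g1", "g1"), ("g2", "g2"), ("g3", "g3"),
             ("g1", "g4"), ("g2", "g5"), ("g3", "g6"),
             (relapse_driver, RELAPSE), (RELAPSE, RELAPSE)}
    inter = frozenset((p, c) for p, c in inter
                      if p in variables and c in variables)
    structure = DbnStructure(variables, frozenset(), inter)
    cards = {g: 3 for g in genes}
    cards[RELAPSE] = 2
    initial = {g: np.array([[1 / 3, 1 / 3, 1 / 3]]) for g in genes}
    initial[RELAPSE] = np.array([[1 - p_relapse_baseline, p_relapse_baseline]])
    transition = {}
    for g in genes:
        parents = structure.inter_parents(g)
        if parents:
            transition[g] = _copy_cpt(3, fidelity)
        else:
            transition[g] = np.array([[1 / 3, 1 / 3, 1 / 3]])
    # relapse transition parents: (driver at t, relapse at t); canonical order
    # puts the driver (earlier variable) first
    rows = []
    for driver_state in range(3):
        for prev_relapse in range(2):
            if prev_relapse == 1:
                rows.append([0.0, 1.0])
            else:
                p = p_relapse_high if driver_state == 2 else p_relapse_low
                rows.append([1 - p, p])
    transition[RELAPSE] = np.array(rows)
    model = DbnModel(structure, cards, initial, transition)
    return GroundTruthDbn(model, n_slices=3, emission_sd=emission_sd)


def deterministic_ground_truth(n_genes: int = 3,
                               emission_sd: float = 0.0) -> GroundTruthDbn:
    """Noiseless dynamics: relapse at t+1 is a deterministic function of g1.

    Gene g1 is binary at baseline (uniform), persists deterministically, and
    over-expression (state 1) forces relapse at the next visit; all other
    genes persist deterministically from random starts.  With zero emission
    noise a learner can recover the dynamics exactly.
    """
    genes = [f"g{i}" for i in range(1, n_genes + 1)]
    variables = tuple(genes + [RELAPSE])
    inter = frozenset({(g, g) for g in genes}
                      | {("g1", RELAPSE), (RELAPSE, RELAPSE)})
    structure = DbnStructure(variables, frozenset(), inter)
    cards = {g: 2 for g in genes}
    cards[RELAPSE] = 2
    initial = {g: np.array([[0.5, 0.5]]) for g in genes}
    initial[RELAPSE] = np.array([[1.0, 0.0]])
    transition = {g: np.eye(2) for g in genes}
    rows = []
    for g1_state in range(2):
        for prev_relapse in range(2):
            relapses = prev_relapse == 1 or g1_state == 1
            rows.append([0.0, 1.0] if relapses else [1.0, 0.0])
    transition[RELAPSE] = np.array(rows)
    model = DbnModel(structure, cards, initial, transition)
    return GroundTruthDbn(model, n_slices=3, emission_sd=emission_sd)


def write_cohort(out_dir, clinical: FeatureTable, imaging: FeatureTable,
                 tissue: ExpressionMatrix, blood: ExpressionMatrix) -> None:
    """Write the four baseline sources in the package's TSV dialects."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    clinical.to_tsv(out / "clinical.tsv")
    imaging.to_tsv(out / "imaging.tsv")
    tissue.to_tsv(out / "tissue_expression.tsv", out / "tissue_annotation.tsv")
    blood.to_tsv(out / "blood_expression.tsv", out / "blood_annotation.tsv")
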