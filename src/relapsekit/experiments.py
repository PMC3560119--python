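"""Reproducible simulation experiments exercising the full pipeline.

Each function runs one self-contained experiment at study scale and returns
plain numbers; the acceptance test suite asserts on them and
``scripts/acceptance.py`` reports them.  All randomness flows from an
explicit seed.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .classify_fuse import EvalReport, FusionModel, compute_metrics, fuse
from .containers import ExpressionMatrix, FeatureTable, NUMERIC, NOMINAL
from .dbn import (AnnealSchedule, DbnModel, DbnScorer, DbnStructure,
                  ScoreConfig, anneal_search, brute_force_marginal,
                  exhaustive_optimum, fit_cpts, greedy_search, infer,
                  lopo_evaluate)
from .dbn.scoring import family_counts
from .diffexpr import SamConfig, sam_two_class
from .featselect import CfsConfig, cfs_merit, cfs_select, _CorrelationCache
from .preprocess import SmoteConfig, smote
from .signature import extract_signature, track_trajectory, weighted_distance
from .synthgen import (default_ground_truth, deterministic_ground_truth,
                       generate_timecourse)


# -- 1. exact inference vs joint enumeration ---------------------------------

def _random_model(rng, n_vars, max_parents=3) -> DbnModel:
    variables = tuple(f"v{i}" for i in range(n_vars))
    order = list(rng.permutation(n_vars))
    intra = set()
    for i, a in enumerate(order):
        for b in order[i + 1:]:
            if rng.random() < 0.25:
                intra.add((variables[a], variables[b]))
    inter = {(p, c) for p in variables for c in variables
             if rng.random() < 0.25}
    structure = DbnStructure(variables, frozenset(intra), frozenset(inter))
    # trim to the parent cap, dropping random parents
    for c in variables:
        while structure.n_parents(c) > max_parents:
            parents = ([("intra", p) for p in structure.intra_parents(c)]
                       + [("inter", p) for p in structure.inter_parents(c)])
            kind, p = parents[rng.integers(len(parents))]
            if kind == "intra":
                structure = structure.with_edges(
                    intra=structure.intra_edges - {(p, c)})
            else:
                structure = structure.with_edges(
                    inter=structure.inter_edges - {(p, c)})
    cards = {v: 2 for v in variables}
    initial, transition = {}, {}
    for v in variables:
        q0 = max(1, int(np.prod([2] * len(structure.intra_parents(v)))))
        qt = max(1, int(2 ** (len(structure.intra_parents(v))
                              + len(structure.inter_parents(v)))))
        initial[v] = rng.dirichlet(np.ones(2), size=q0)
        transition[v] = rng.dirichlet(np.ones(2), size=qt)
    return DbnModel(structure, cards, initial, transition)


def inference_oracle(n_networks: int = 200, seed: int = 0) -> dict:
    """Max |posterior difference| between ``infer`` and joint enumeration.

    Random binary networks whose unrolled size stays at or below 12 nodes,
    with random evidence and queries.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_networks):
        n_slices = int(rng.integers(2, 4))
        n_vars = int(rng.integers(2, 12 // n_slices + 1))
        model = _random_model(rng, n_vars)
        nodes = [(v, t) for v in model.variables for t in range(n_slices)]
        n_ev = int(rng.integers(0, len(nodes) // 2 + 1))
        picked = rng.choice(len(nodes), size=n_ev, replace=False)
        evidence = {nodes[i]: int(rng.integers(2)) for i in picked}
        free = [n for n in nodes if n not in evidence]
        query = free[rng.integers(len(free))]
        a = infer(model, evidence, query, n_slices)
        b = brute_force_marginal(model, evidence, query, n_slices)
        worst = max(worst, float(np.abs(a - b).max()))
    return {"max_abs_error": worst, "n": n_networks}


# -- 2. structure search vs exhaustive enumeration ---------------------------

def _search_dataset(rng, n=40, n_vars=4):
    states = rng.integers(0, 2, size=(n, n_vars, 2))
    states[:, 1, 1] = states[:, 0, 0] ^ (rng.random(n) < 0.2)
    states[:, 2, 1] = states[:, 2, 0] ^ (rng.random(n) < 0.1)
    return states


def structure_search_oracle(n_datasets: int = 100, seed: int = 0) -> dict:
    """Fraction of datasets where each search attains the global optimum."""
    variables = [f"v{i}" for i in range(4)]
    cards = {v: 2 for v in variables}
    greedy_hits = anneal_hits = 0
    for k in range(n_datasets):
        rng = np.random.default_rng((seed * 100003 + k) % 2 ** 31)
        states = _search_dataset(rng)
        cfg = ScoreConfig(seed=(seed * 1009 + k) % 2 ** 31, max_parents=3)
        scorer = DbnScorer(states, variables, cards, cfg)
        _, best = exhaustive_optimum(states, variables, cards, cfg,
                                     scorer=scorer)
        g = greedy_search(states, variables, cards, cfg, n_restarts=30,
                          scorer=scorer)
        a = anneal_search(states, variables, cards, cfg,
                          AnnealSchedule(seed=cfg.seed), scorer=scorer,
                          n_restarts=4)
        greedy_hits += scorer.structure_score(g) >= best - 1e-9
        anneal_hits += scorer.structure_score(a) >= best - 1e-9
    return {"greedy_optimum_rate": greedy_hits / n_datasets,
            "anneal_optimum_rate": anneal_hits / n_datasets,
            "n": n_datasets}


# -- 3. structure and parameter recovery -------------------------------------

def recovery_experiment(n_patients: int = 200, seed: int = 0) -> dict:
    """Inter-slice edge precision/recall and transition-CPT accuracy.

    CPT accuracy is summarized two ways over rows with >= 30 observations:
    the observation-weighted mean total-variation distance (the expected-TV
    metric standard in structure-learning evaluations) and the worst row.
    """
    truth = default_ground_truth()
    res = generate_timecourse(truth, n_patients, seed=seed)
    states = res.states
    variables = list(truth.variables)
    cards = truth.model.cardinalities
    cfg = ScoreConfig(seed=seed)
    learned = greedy_search(states, variables, cards, cfg, n_restarts=3)
    truth_inter = set(truth.model.structure.inter_edges)
    found = set(learned.inter_edges)
    tp = len(truth_inter & found)
    precision = tp / len(found) if found else 0.0
    recall = tp / len(truth_inter)
    # parameter recovery on the true structure
    fitted = fit_cpts(truth.model.structure, states, variables, cards,
                      pseudocount=1.0)
    idx = {v: i for i, v in enumerate(variables)}
    prev = np.concatenate([states[:, :, t] for t in range(2)])
    nxt = np.concatenate([states[:, :, t + 1] for t in range(2)])
    tvs, weights = [], []
    for v in variables:
        inter = truth.model.structure.inter_parents(v)
        intra = truth.model.structure.intra_parents(v)
        pcards = (tuple(cards[p] for p in inter)
                  + tuple(cards[p] for p in intra))
        ps = np.column_stack([prev[:, [idx[p] for p in inter]],
                              nxt[:, [idx[p] for p in intra]]])
        counts = family_counts(nxt[:, idx[v]], ps, pcards, cards[v])
        for j in range(counts.shape[0]):
            n_obs = counts[j].sum()
            if n_obs >= 30:
                tvs.append(0.5 * float(np.abs(
                    fitted.transition_cpts[v][j]
                    - truth.model.transition_cpts[v][j]).sum()))
                weights.append(n_obs)
    tvs, weights = np.array(tvs), np.array(weights)
    return {"inter_edge_precision": precision,
            "inter_edge_recall": recall,
            "cpt_weighted_mean_tv": float((tvs * weights).sum() / weights.sum()),
            "cpt_max_row_tv": float(tvs.max()),
            "n_qualifying_rows": int(len(tvs)),
            "n": n_patients}


# -- 4. end-to-end temporal pipeline -----------------------------------------

def temporal_pipeline_experiment(seed: int = 0, n_patients: int = 14,
                                 n_shuffles: int = 20) -> dict:
    """LOPO on noiseless deterministic dynamics and on label-shuffled data."""
    truth = deterministic_ground_truth()
    res = generate_timecourse(truth, n_patients, n_patients // 2, seed=seed)
    reports = lopo_evaluate(res.tensor, res.relapse_states,
                            ScoreConfig(seed=seed))
    out = {"noiseless_accuracy_baseline": reports["baseline"].accuracy,
           "noiseless_accuracy_fu1": reports["baseline+fu1"].accuracy}
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(n_shuffles):
        perm = rng.permutation(n_patients)
        shuffled = res.relapse_states[perm]
        rep = lopo_evaluate(res.tensor, shuffled, ScoreConfig(seed=seed))
        accs.append(rep["baseline"].accuracy)
    out["shuffled_accuracy_mean"] = float(np.mean(accs))
    out["n_shuffles"] = n_shuffles
    out["n"] = n_patients
    return out


# -- 5. SAM null calibration -------------------------------------------------

def sam_null_calibration(n_genes: int = 500, n_seeds: int = 20,
                         n_samples: int = 20, q_cutoff: float = 0.1,
                         seed: int = 0) -> dict:
    """Fraction of null genes passing q <= cutoff, across seeds."""
    fractions = []
    labels = np.array([0, 1] * (n_samples // 2))
    for k in range(n_seeds):
        rng = np.random.default_rng((seed * 7717 + k) % 2 ** 31)
        values = rng.normal(8, 1, size=(n_genes, n_samples))
        matrix = ExpressionMatrix(pd.DataFrame(
            values, index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(n_samples)]))
        ranking = sam_two_class(matrix, labels,
                                SamConfig(n_permutations=100,
                                          q_cutoff=q_cutoff,
                                          seed=(seed * 131 + k) % 2 ** 31))
        fractions.append(float((ranking.table.q_value <= q_cutoff).mean()))
    fractions = np.array(fractions)
    mc_se = float(fractions.std(ddof=1) / np.sqrt(n_seeds))
    return {"null_selected_fraction": float(fractions.mean()),
            "mc_standard_error": mc_se, "n": n_seeds * n_genes}


# -- 6. SMOTE contract -------------------------------------------------------

def smote_contract(seed: int = 0) -> dict:
    """Balance a 26/60 cohort; count synthetic rows, check convexity."""
    rng = np.random.default_rng(seed)
    y = np.array([1] * 26 + [0] * 60)
    df = pd.DataFrame({"x1": rng.normal(2 * y, 1.0),
                       "x2": rng.normal(0, 1.0, 86),
                       "x3": rng.normal(-y, 2.0)},
                      index=[f"P{i}" for i in range(86)])
    table = FeatureTable(df, {c: NUMERIC for c in df.columns},
                         label=pd.Series(y, index=df.index))
    balanced = smote(table, SmoteConfig(seed=seed))
    synth = balanced.data[balanced.synthetic].to_numpy(float)
    minority = table.data[table.label == 1].to_numpy(float)
    worst = 0.0
    for row in synth:
        best = np.inf
        for i, a in enumerate(minority):
            for b in minority[i:]:
                d = b - a
                denom = float(d @ d)
                lam = 0.0 if denom == 0 else float(
                    np.clip((row - a) @ d / denom, 0, 1))
                best = min(best, float(np.linalg.norm(a + lam * d - row)))
        worst = max(worst, best)
    return {"n_synthetic_rows": int(balanced.synthetic.sum()),
            "max_convex_residual": worst, "n": 86}


# -- 7. metric panel oracle ---------------------------------------------------

def metric_panel_oracle(n_draws: int = 1000, seed: int = 0) -> dict:
    """Metric panel vs plain confusion-table / pair-counting recomputation."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_draws):
        n = int(rng.integers(4, 31))
        truth = rng.integers(0, 2, n)
        if truth.min() == truth.max():
            truth[0] = 1 - truth[0]
        pred = rng.integers(0, 2, n)
        scores = rng.random(n).round(1)
        rep = compute_metrics(pred, truth, scores)
        tp = int(((pred == 1) & (truth == 1)).sum())
        fn = int(((pred == 0) & (truth == 1)).sum())
        tn = int(((pred == 0) & (truth == 0)).sum())
        fp = int(((pred == 1) & (truth == 0)).sum())
        diffs = [rep.accuracy - (tp + tn) / n]
        if tp + fn:
            diffs.append(rep.sensitivity - tp / (tp + fn))
        if tn + fp:
            diffs.append(rep.specificity - tn / (tn + fp))
        po = (tp + tn) / n
        pe = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / n ** 2
        if abs(1 - pe) > 1e-12:
            diffs.append(rep.kappa - (po - pe) / (1 - pe))
        pairs = wins = 0.0
        for i in range(n):
            if truth[i] != 1:
                continue
            for j in range(n):
                if truth[j] == 0:
                    pairs += 1
                    wins += (1.0 if scores[i] > scores[j]
                             else 0.5 if scores[i] == scores[j] else 0.0)
        diffs.append(rep.auc - wins / pairs)
        worst = max(worst, float(np.abs(diffs).max()))
    fixed = compute_metrics([1] * 7 + [0] * 16, [1] * 11 + [0] * 12)
    return {"max_abs_error": worst,
            "fixed_confusion_sensitivity_pct": 100 * fixed.sensitivity,
            "fixed_confusion_specificity_pct": 100 * fixed.specificity,
            "n": n_draws}


# -- 8. CFS best-first vs exhaustive -----------------------------------------

def _cfs_table(rng, n=60, n_features=8):
    y = np.tile([0, 1], n // 2)
    cols, kinds = {}, {}
    n_info = int(rng.integers(1, 4))
    for j in range(n_features):
        name = f"f{j}"
        if j < n_info:
            flip = rng.random(n) < rng.uniform(0.05, 0.35)
            cols[name] = np.where(y ^ flip, "a", "b")
            kinds[name] = NOMINAL
        else:
            cols[name] = rng.normal(size=n)
            kinds[name] = NUMERIC
    df = pd.DataFrame(cols, index=[f"P{i}" for i in range(n)])
    return FeatureTable(df, kinds, label=pd.Series(y, index=df.index))


def cfs_search_oracle(n_tables: int = 100, seed: int = 0) -> dict:
    """Fraction of tables where best-first CFS equals full enumeration."""
    hits = 0
    single_ok = True
    for k in range(n_tables):
        rng = np.random.default_rng((seed * 49999 + k) % 2 ** 31)
        table = _cfs_table(rng)
        cfg = CfsConfig()
        cache = _CorrelationCache(table, cfg.discretization_bins)
        got = cfs_select(table, cfg)
        features = sorted(table.data.columns)
        best, best_merit = None, -np.inf
        for r in range(1, len(features) + 1):
            for sub in combinations(features, r):
                merit = cfs_merit(list(sub), table, cfg, _cache=cache)
                if merit > best_merit + 1e-12:
                    best, best_merit = list(sub), merit
        hits += got == best
        f = features[0]
        single_ok &= abs(cfs_merit([f], table, cfg, _cache=cache)
                         - cache.class_corr(f)) < 1e-12
    return {"optimum_agreement_rate": hits / n_tables,
            "single_feature_merit_equals_class_correlation": single_ok,
            "n": n_tables}


# -- 9. signature metric properties ------------------------------------------

def signature_properties(n_triples: int = 1000, seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    violations = 0
    for _ in range(n_triples):
        k = int(rng.integers(2, 10))
        w = rng.dirichlet(np.ones(k))
        x, y, z = rng.normal(size=(3, k)) * 5
        dxy = weighted_distance(x, y, w)
        if dxy < 0 or abs(dxy - weighted_distance(y, x, w)) > 1e-12:
            violations += 1
        if dxy > weighted_distance(x, z, w) + weighted_distance(z, y, w) + 1e-9:
            violations += 1
        if weighted_distance(x, x, w) != 0.0:
            violations += 1
    # reference identity and interpolation monotonicity on one profile
    genes = [f"g{i}" for i in range(6)]
    pre = pd.Series(rng.normal(9, 1, 6), index=genes)
    rem = pd.Series(rng.normal(7, 1, 6), index=genes)
    profile = extract_signature(pre, rem, threshold=0.5, top_k=6)
    visit = pd.Series(profile.cancer_free, index=profile.gene_ids)
    [point] = track_trajectory(profile, {"fu1": visit})
    identity_ok = (point.dist_cancer_free == 0.0
                   and abs(point.corr_cancer_free - 1.0) < 1e-9)
    monotone = True
    last = np.inf
    for lam in np.linspace(0, 1, 21):
        v = (1 - lam) * profile.cancer_free + lam * profile.cancerous
        [p] = track_trajectory(profile,
                               {"v": pd.Series(v, index=profile.gene_ids)})
        monotone &= p.dist_cancerous <= last + 1e-12
        last = p.dist_cancerous
    return {"metric_axiom_violations": violations,
            "reference_identity_ok": bool(identity_ok),
            "interpolation_monotone": bool(monotone),
            "n": n_triples}


# -- 10. fusion identities ----------------------------------------------------

def fusion_identities(seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    patients = [f"P{i}" for i in range(9)]
    single = {"clinical": pd.DataFrame(
        {"label": rng.integers(0, 2, 9)}, index=patients)}
    fused = fuse(single, FusionModel({"clinical": 1.0}))
    identity_ok = fused.label.tolist() == single["clinical"].label.tolist()
    votes = {s: pd.DataFrame({"label": rng.integers(0, 2, 9)},
                             index=patients) for s in ("a", "b", "c")}
    uniform = fuse(votes, FusionModel({s: 1.0 for s in votes}))
    stacked = np.array([votes[s].label.to_numpy() for s in votes])
    majority_ok = (uniform.label.to_numpy()
                   == (stacked.sum(axis=0) >= 2).astype(int)).all()
    tie = fuse({"a": pd.DataFrame({"label": [1]}, index=["P0"]),
                "b": pd.DataFrame({"label": [0]}, index=["P0"])},
               FusionModel({"a": 0.5, "b": 0.5}))
    tie_ok = int(tie.label.iloc[0]) == 1
    return {"single_source_identity": bool(identity_ok),
            "uniform_equals_majority": bool(majority_ok),
            "tie_resolves_to_relapse": bool(tie_ok),
            "n": 9}
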