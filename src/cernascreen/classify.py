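"""Kernel SVM evaluation of candidate features under leave-one-out CV.

Each feature set is scored by training a soft-margin SVM (linear,
polynomial, sigmoid or radial kernel) on all samples but one and
recording the held-out sample's continuous decision value; the AUC of
those leave-one-out scores against the true condition labels measures
classification accuracy.  Features are standardized per fold using
training-fold statistics only, and class weights are balanced so that
the one-sample-short class in each training fold does not bias the
decision values.  Selection is strict: a feature (set) is kept only
when its AUC exceeds the configured floor.
"""

from __future__ import annotations

import hashlib
import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.svm import SVC

from .config import PipelineConfig
from .dataset import ExpressionDataset
from .triplets import CeRNATriplet

logger = logging.getLogger("cernascreen")

_SKLEARN_KERNEL = {
    "linear": "linear",
    "polynomial": "poly",
    "sigmoid": "sigmoid",
    "radial": "rbf",
}

#: kernel used wherever a single classifier is called for (individual
#: features, class gates, triplets, baselines)
DEFAULT_KERNEL = "linear"


def loocv_scores(
    dataset: ExpressionDataset,
    feature_ids: list[str],
    kernel: str = DEFAULT_KERNEL,
    seed: int = 0,
    cost: float = 1.0,
    degree: int = 3,
) -> np.ndarray:
    """Per-sample leave-one-out decision values, aligned to sample order.

    Each score comes from an SVM trained on the other samples with the
    named kernel (cost fixed, polynomial degree 3, kernel scale
    1/n_features on standardized data) and per-fold standardization.
    Deterministic given inputs.
    """
    if kernel not in _SKLEARN_KERNEL:
        raise ValueError(f"unknown kernel {kernel!r}")
    missing = [f for f in feature_ids if f not in dataset.normalized.index]
    if missing:
        raise KeyError(f"feature(s) not in dataset: {missing[:5]}")
    if not feature_ids:
        raise ValueError("empty feature set")
    X = dataset.normalized.loc[list(feature_ids)].to_numpy(dtype=float).T
    y = dataset.condition_mask("disease").astype(int)
    n = X.shape[0]
    if min(y.sum(), n - y.sum()) < 2:
        raise ValueError("need at least 2 samples per condition")

    scores = np.empty(n)
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        Xtr, ytr = X[train], y[train]
        mean = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        zero = sd == 0
        if zero.any():
            logger.info("loocv_scores: %d feature(s) constant in a training "
                        "fold; unit scale applied", int(zero.sum()))
            sd = np.where(zero, 1.0, sd)
        clf = SVC(
            kernel=_SKLEARN_KERNEL[kernel],
            C=cost,
            degree=degree,
            gamma="auto",  # 1 / n_features on standardized input
            coef0=0.0,
            class_weight="balanced",
            random_state=seed,
        )
        clf.fit((Xtr - mean) / sd, ytr)
        scores[i] = float(clf.decision_function(((X[i] - mean) / sd)[None, :])[0])
    return scores


def passes_auc(auc_value: float, auc_min: float = 0.75) -> bool:
    """Strict selection rule: kept only when the AUC exceeds the floor.

    An AUC exactly equal to the floor is dropped (0.76 passes at the
    default floor of 0.75; 0.75 and 0.74 do not).
    """
    return auc_value > auc_min


def auc(scores, labels) -> float:
    """Mann-Whitney AUC of scores for the positive class; ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def evaluate_set(
    dataset: ExpressionDataset,
    feature_ids: list[str],
    kernel: str = DEFAULT_KERNEL,
    seed: int = 0,
    cost: float = 1.0,
    degree: int = 3,
) -> tuple[float, np.ndarray]:
    """LOO AUC (and scores) of one feature set with one kernel."""
    scores = loocv_scores(dataset, feature_ids, kernel, seed, cost, degree)
    return auc(scores, dataset.condition_mask("disease")), scores


def evaluate_feature_sets(
    dataset: ExpressionDataset,
    sets: dict[str, list[str]],
    kernels: tuple[str, ...] = (DEFAULT_KERNEL,),
    auc_min: float = 0.75,
    seed: int = 0,
    cost: float = 1.0,
    degree: int = 3,
) -> pd.DataFrame:
    """Evaluate named joint sets and their individual members.

    For every kernel: each named set is scored jointly, and each member
    feature individually.  An individual feature is ``selected`` when
    its own AUC and its parent set's AUC (same kernel) both exceed
    ``auc_min`` (strict); a joint set is selected on its own AUC.
    """
    for name, ids in sets.items():
        if not ids:
            raise ValueError(f"feature set {name!r} is empty")
    rows = []
    for kernel in kernels:
        for name, ids in sorted(sets.items()):
            joint_auc, _ = evaluate_set(dataset, ids, kernel, seed, cost, degree)
            rows.append((name, "joint", ";".join(ids), kernel, joint_auc,
                         passes_auc(joint_auc, auc_min)))
            for fid in ids:
                a, _ = evaluate_set(dataset, [fid], kernel, seed, cost, degree)
                rows.append((name, "individual", fid, kernel, a,
                             passes_auc(a, auc_min) and passes_auc(joint_auc, auc_min)))
    return pd.DataFrame(rows, columns=[
        "set_name", "level", "features", "kernel", "auc", "selected",
    ])


def biomarker_selection(
    dataset: ExpressionDataset,
    candidates: pd.DataFrame,
    triplets: list[CeRNATriplet],
    config: PipelineConfig,
) -> dict:
    """Full susceptibility-biomarker selection.

    1. Candidate genes are grouped by functional class; each class's
       joint AUC gates its members (classes failing the gate are
       excluded from individual evaluation).
    2. Individual genes in passing classes with AUC above the floor are
       the susceptibility genes.
    3. lncRNAs and miRNAs of triplets containing a susceptibility gene
       are evaluated individually the same way.

    Returns a dict with the per-class gate table and the three ranked
    biomarker frames (genes, lncRNAs, miRNAs).
    """
    kernel = DEFAULT_KERNEL if DEFAULT_KERNEL in config.kernels else config.kernels[0]
    kw = dict(seed=config.seed, cost=config.svm_cost, degree=config.poly_degree)
    empty = pd.DataFrame(columns=["feature_id", "auc"])

    if candidates.empty:
        logger.info("biomarker_selection: no candidate genes; empty report")
        return {"class_table": pd.DataFrame(
            columns=["class", "n_genes", "auc", "passes"]),
            "genes": empty.copy(), "lncrnas": empty.copy(),
            "mirnas": empty.copy()}

    by_class: dict[str, list[str]] = {}
    for _, row in candidates.iterrows():
        for cls in str(row["classes"]).split(","):
            if cls:
                by_class.setdefault(cls, []).append(row["gene"])

    all_candidates = sorted(candidates["gene"])
    gate_all = None
    if config.joint_gate == "all_candidates":
        gate_all, _ = evaluate_set(dataset, all_candidates, kernel, **kw)

    class_rows = []
    passing_genes: set[str] = set()
    for cls in sorted(by_class):
        genes = sorted(set(by_class[cls]))
        joint_auc, _ = evaluate_set(dataset, genes, kernel, **kw)
        gate_auc = gate_all if gate_all is not None else joint_auc
        passes = passes_auc(gate_auc, config.auc_min)
        class_rows.append((cls, len(genes), joint_auc, passes))
        if passes:
            passing_genes |= set(genes)
    class_table = pd.DataFrame(class_rows,
                               columns=["class", "n_genes", "auc", "passes"])

    def _individual(ids: list[str]) -> pd.DataFrame:
        rows = []
        for fid in sorted(set(ids)):
            a, _ = evaluate_set(dataset, [fid], kernel, **kw)
            if passes_auc(a, config.auc_min):
                rows.append((fid, a))
        return pd.DataFrame(rows, columns=["feature_id", "auc"]).sort_values(
            ["auc", "feature_id"], ascending=[False, True],
            kind="mergesort").reset_index(drop=True)

    genes = _individual(sorted(passing_genes))
    if genes.empty:
        logger.info("biomarker_selection: no class passed the joint gate or "
                    "no gene cleared the individual floor")
        return {"class_table": class_table, "genes": genes,
                "lncrnas": empty.copy(), "mirnas": empty.copy()}

    selected = set(genes["feature_id"])
    lnc_pool = sorted({t.lncrna_id for t in triplets if t.mrna_id in selected})
    mir_pool = sorted({t.mirna_id for t in triplets if t.mrna_id in selected})
    return {
        "class_table": class_table,
        "genes": genes,
        "lncrnas": _individual(lnc_pool),
        "mirnas": _individual(mir_pool),
    }


def random_baseline(
    dataset: ExpressionDataset,
    biomarkers: list[str],
    pools: dict[str, list[str]],
    n_draws: int = 100,
    seed: int = 0,
    kernel: str = DEFAULT_KERNEL,
    cost: float = 1.0,
    degree: int = 3,
) -> pd.DataFrame:
    """Compare the biomarker panel with random same-size feature sets.

    For each named pool, ``n_draws`` random subsets of the biomarker
    panel's size are scored jointly; the empirical p is the fraction of
    draws whose AUC is at least the panel's.
    """
    if n_draws <= 0:
        raise ValueError(f"n_draws must be positive; got {n_draws}")
    if not biomarkers:
        raise ValueError("empty biomarker set")
    panel_auc, _ = evaluate_set(dataset, list(biomarkers), kernel,
                                seed, cost, degree)
    rows = []
    for name in sorted(pools):
        pool = sorted(set(pools[name]))
        if len(pool) < len(biomarkers):
            raise ValueError(
                f"pool {name!r} ({len(pool)}) smaller than the biomarker "
                f"panel ({len(biomarkers)})"
            )
        name_entropy = int.from_bytes(
            hashlib.blake2b(name.encode(), digest_size=4).digest(), "big"
        ) & 0x7FFFFFFF
        rng = np.random.default_rng([seed & 0x7FFFFFFF, name_entropy])
        draws = np.empty(n_draws)
        for d in range(n_draws):
            pick = list(rng.choice(pool, size=len(biomarkers), replace=False))
            draws[d], _ = evaluate_set(dataset, pick, kernel, seed, cost, degree)
        rows.append((
            name, panel_auc, float(draws.mean()),
            float(np.quantile(draws, 0.05)), float(np.quantile(draws, 0.95)),
            float((draws >= panel_auc - 1e-12).mean()),
        ))
    return pd.DataFrame(rows, columns=[
        "pool", "biomarker_auc", "random_mean_auc",
        "random_q05", "random_q95", "empirical_p",
    ])


def evaluate_triplets(
    dataset: ExpressionDataset,
    triplets: list[CeRNATriplet],
    kernel: str = DEFAULT_KERNEL,
    auc_min: float = 0.75,
    seed: int = 0,
    cost: float = 1.0,
    degree: int = 3,
) -> pd.DataFrame:
    """Score each triplet as a three-feature joint classifier."""
    rows = []
    for t in triplets:
        a, _ = evaluate_set(dataset, list(t.elements), kernel, seed, cost, degree)
        rows.append((t.mrna_id, t.mirna_id, t.lncrna_id, t.condition, a,
                     passes_auc(a, auc_min)))
    return pd.DataFrame(rows, columns=[
        "mrna_id", "mirna_id", "lncrna_id", "condition", "auc", "selected",
    ])
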