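"""SVM LOOCV scoring, AUC, and the strict selection rules."""

import numpy as np
import pandas as pd
import pytest

from cernascreen import (
    ExpressionDataset,
    PipelineConfig,
    auc,
    biomarker_selection,
    evaluate_feature_sets,
    evaluate_triplets,
    loocv_scores,
    random_baseline,
)
from cernascreen.classify import evaluate_set, passes_auc
from cernascreen.triplets import CeRNATriplet

LABELS_8V8 = np.array([True] * 8 + [False] * 8)


def _dataset(features: dict, n_disease=8, n_total=16):
    norm = pd.DataFrame(features, index=[f"s{i}" for i in range(n_total)]).T
    classes = ["mRNA" if f.startswith("m") else
               ("miRNA" if f.startswith("x") else "lncRNA")
               for f in features]
    return ExpressionDataset(
        normalized=norm - min(0.0, float(norm.min().min())),
        feature_class=pd.Series(classes, index=norm.index),
        condition=pd.Series(["disease"] * n_disease
                            + ["normal"] * (n_total - n_disease),
                            index=norm.columns),
    )


# -- AUC --------------------------------------------------------------

def test_auc_worked_example():
    scores = [0.9, 0.8, 0.3, 0.7, 0.2, 0.1]
    labels = [1, 1, 1, 0, 0, 0]
    assert auc(scores, labels) == pytest.approx(8 / 9)


def test_auc_ties_and_separation():
    assert auc([5, 5, 5, 5], [1, 1, 0, 0]) == 0.5
    assert auc([3, 4, 1, 2], [1, 1, 0, 0]) == 1.0
    with pytest.raises(ValueError):
        auc([1, 2], [1, 1])


def test_auc_invariant_to_monotone_transform():
    rng = np.random.default_rng(0)
    s = rng.normal(size=16)
    a = auc(s, LABELS_8V8)
    assert auc(np.exp(s), LABELS_8V8) == pytest.approx(a)
    assert auc(3 * s + 7, LABELS_8V8) == pytest.approx(a)


# -- LOOCV ------------------------------------------------------------

def test_separable_feature_orders_conditions():
    f = np.concatenate([np.arange(8) + 20.0, np.arange(8)])
    ds = _dataset({"m0": f})
    scores = loocv_scores(ds, ["m0"], "linear")
    assert scores[:8].min() > scores[8:].max()
    a, _ = evaluate_set(ds, ["m0"], "linear")
    assert a == 1.0


def test_duplicated_feature_keeps_ranking():
    rng = np.random.default_rng(1)
    f = np.concatenate([rng.normal(3, 1, 8), rng.normal(0, 1, 8)]) + 10
    ds = _dataset({"m0": f, "m1": f.copy()})
    s1 = loocv_scores(ds, ["m0"], "linear")
    s2 = loocv_scores(ds, ["m0", "m1"], "linear")
    assert list(np.argsort(s1)) == list(np.argsort(s2))


def test_loocv_deterministic_and_all_kernels_run():
    rng = np.random.default_rng(2)
    f = rng.uniform(1, 9, 16)
    g = rng.uniform(1, 9, 16)
    ds = _dataset({"m0": f, "l0": g})
    for kernel in ("linear", "polynomial", "sigmoid", "radial"):
        a = loocv_scores(ds, ["m0", "l0"], kernel)
        b = loocv_scores(ds, ["m0", "l0"], kernel)
        assert np.array_equal(a, b)


def test_constant_training_feature_guarded():
    f = np.full(16, 4.0)
    f[0] = 5.0  # constant in all folds that exclude sample 0
    g = np.concatenate([np.arange(8) + 10.0, np.arange(8)])
    ds = _dataset({"m0": f, "m1": g})
    scores = loocv_scores(ds, ["m0", "m1"], "linear")
    assert np.isfinite(scores).all()


# -- selection rules --------------------------------------------------

def test_strict_threshold_semantics():
    assert passes_auc(0.76, 0.75)
    assert not passes_auc(0.75, 0.75)
    assert not passes_auc(0.74, 0.75)


def test_individual_selection_straddles_floor():
    """Features whose LOO AUC lands just above, exactly at, and below
    0.75 are kept / dropped / dropped under the strict rule."""
    normals = np.arange(8, dtype=float)
    above = np.concatenate([[7.5, 7.6, 7.7, 7.8, 7.9, 5.5, 2.5, 1.5], normals])
    at = np.concatenate([[7.5, 7.6, 7.7, 7.8, 7.9, 4.5, 3.5, 0.5], normals])
    below = np.concatenate([[7.5, 7.6, 7.7, 7.8, 7.9, 4.5, 2.5, 0.5], normals])
    strong = np.concatenate([np.arange(8) + 20.0, normals])
    ds = _dataset({"m_above": above, "m_at": at, "m_below": below,
                   "m_strong": strong})
    out = evaluate_feature_sets(
        ds, {"panel": ["m_above", "m_at", "m_below", "m_strong"]},
        kernels=("linear",), auc_min=0.75)
    ind = out[out.level == "individual"].set_index("features")
    assert ind.loc["m_above", "auc"] > 0.75
    assert ind.loc["m_above", "selected"].item()
    assert ind.loc["m_at", "auc"] == pytest.approx(0.75)
    assert not ind.loc["m_at", "selected"].item()
    assert not ind.loc["m_below", "selected"].item()
    joint = out[out.level == "joint"]
    assert joint["selected"].item()  # strong member carries the panel


def test_failed_joint_gate_blocks_members():
    rng = np.random.default_rng(3)
    noise = {f"m{i}": rng.uniform(1, 9, 16) for i in range(3)}
    strong = np.concatenate([np.arange(8) + 20.0, np.arange(8, dtype=float)])
    noise["m_strong"] = strong
    ds = _dataset(noise)
    out = evaluate_feature_sets(ds, {"weak": ["m0", "m1", "m2"]},
                                kernels=("linear",), auc_min=0.75)
    # if the joint AUC fails, no member can be selected even if its own
    # AUC were high
    joint_auc = out[out.level == "joint"]["auc"].item()
    if joint_auc <= 0.75:
        assert not out[out.level == "individual"]["selected"].any()


def test_biomarker_selection_gates_and_pools():
    normals = np.arange(8, dtype=float)
    strong_m = np.concatenate([np.arange(8) + 20.0, normals])
    strong_l = np.concatenate([normals, np.arange(8) + 20.0])
    rng = np.random.default_rng(4)
    weak = rng.uniform(1, 9, 16)
    ds = _dataset({"m_good": strong_m, "m_weak": weak, "l_good": strong_l,
                   "x_weak": rng.uniform(1, 9, 16)})
    candidates = pd.DataFrame({"gene": ["m_good", "m_weak"],
                               "classes": ["disease_related", "disease_related"]})
    trips = [CeRNATriplet("m_good", "x_weak", "l_good", "disease",
                          (True, False, True), True)]
    cfg = PipelineConfig(seed=0, n_baseline_draws=5)
    report = biomarker_selection(ds, candidates, trips, cfg)
    assert report["class_table"]["passes"].item()
    assert list(report["genes"]["feature_id"]) == ["m_good"]
    assert list(report["lncrnas"]["feature_id"]) == ["l_good"]
    assert report["mirnas"].empty  # weak miRNA excluded (AUC < floor)


def test_threshold_monotonicity_of_biomarker_lists():
    normals = np.arange(8, dtype=float)
    strong = np.concatenate([np.arange(8) + 20.0, normals])
    mid = np.concatenate([[7.5, 7.6, 7.7, 7.8, 7.9, 5.5, 2.5, 1.5], normals])
    ds = _dataset({"m_strong": strong, "m_mid": mid,
                   "x0": np.random.default_rng(5).uniform(1, 9, 16),
                   "l0": strong[::-1].copy()})
    candidates = pd.DataFrame({"gene": ["m_strong", "m_mid"],
                               "classes": ["c", "c"]})
    trips = [CeRNATriplet("m_strong", "x0", "l0", "disease",
                          (True, False, False), True)]
    low = biomarker_selection(ds, candidates, trips,
                              PipelineConfig(seed=0, auc_min=0.70))
    high = biomarker_selection(ds, candidates, trips,
                               PipelineConfig(seed=0, auc_min=0.90))
    assert set(high["genes"]["feature_id"]) <= set(low["genes"]["feature_id"])
    assert len(high["lncrnas"]) <= len(low["lncrnas"])


# -- baselines and triplets ------------------------------------------

def test_random_baseline_validations():
    rng = np.random.default_rng(6)
    ds = _dataset({f"m{i}": rng.uniform(1, 9, 16) for i in range(6)})
    with pytest.raises(ValueError, match="n_draws"):
        random_baseline(ds, ["m0"], {"pool": ["m1", "m2"]}, n_draws=0)
    with pytest.raises(ValueError, match="smaller"):
        random_baseline(ds, ["m0", "m1", "m2"], {"pool": ["m3", "m4"]},
                        n_draws=5)


def test_random_baseline_self_null_is_unremarkable():
    rng = np.random.default_rng(7)
    ds = _dataset({f"m{i}": rng.uniform(1, 9, 16) for i in range(8)})
    out = random_baseline(ds, ["m0", "m1"],
                          {"pool": [f"m{i}" for i in range(8)]}, n_draws=20,
                          seed=1)
    assert 0.0 <= out["empirical_p"].item() <= 1.0
    assert abs(out["biomarker_auc"].item() - 0.5) < 0.45


def test_evaluate_triplets_separable_and_noise():
    rng = np.random.default_rng(8)
    strong = np.concatenate([np.arange(8) + 20.0, np.arange(8, dtype=float)])
    ds = _dataset({"m_sep": strong, "x0": rng.uniform(1, 9, 16),
                   "l0": rng.uniform(1, 9, 16),
                   "m_noise": rng.uniform(1, 9, 16),
                   "x1": rng.uniform(1, 9, 16), "l1": rng.uniform(1, 9, 16)})
    trips = [CeRNATriplet("m_sep", "x0", "l0", "disease"),
             CeRNATriplet("m_noise", "x1", "l1", "disease")]
    out = evaluate_triplets(ds, trips, auc_min=0.75)
    sep = out[out.mrna_id == "m_sep"].iloc[0]
    assert sep["auc"] == 1.0 and sep["selected"]
    noise = out[out.mrna_id == "m_noise"].iloc[0]
    assert 0.08 <= noise["auc"] <= 0.92  # within the n=16 null band
    again = evaluate_triplets(ds, trips, auc_min=0.75)
    pd.testing.assert_frame_equal(out, again)
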