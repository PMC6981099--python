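"""Permutation differential-correlation test and BH FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cernascreen import (
    ExpressionDataset,
    fdr_adjust,
    null_deltas,
    observed_delta,
    permutation_p,
    select_differential_pairs,
    screen_pairs,
)
from cernascreen.config import PipelineConfig
from cernascreen.dataset import InteractionCatalog

MASK_8V8 = np.array([True] * 8 + [False] * 8)


def test_observed_delta_arithmetic():
    rng = np.random.default_rng(0)
    x = rng.normal(size=16)
    y = np.concatenate([-x[:8], x[8:]]) + rng.normal(0, 1e-6, 16)
    d = observed_delta(x, y, MASK_8V8)
    assert d == pytest.approx(-2.0, abs=0.01)
    same = np.tile(rng.normal(size=8), 2)
    same_y = np.tile(rng.normal(size=8), 2)
    assert observed_delta(same, same_y, MASK_8V8) == pytest.approx(0.0, abs=1e-12)


# -- BH ---------------------------------------------------------------

def test_fdr_single_p():
    assert fdr_adjust([0.04]) == pytest.approx([0.04])


def test_fdr_hand_checked_step_up():
    q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])


def test_fdr_all_ones_and_empty():
    assert np.allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)
    assert fdr_adjust([]).size == 0


def test_fdr_monotone_in_p():
    rng = np.random.default_rng(1)
    p = rng.uniform(size=50)
    q = fdr_adjust(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
def test_fdr_property_bounds_and_monotonicity(p):
    q = fdr_adjust(p)
    assert ((q >= np.asarray(p) - 1e-12) & (q <= 1.0 + 1e-12)).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


# -- permutation p ----------------------------------------------------

def test_perm_p_zero_when_observed_extreme():
    """An observed delta exceeding every null delta gives the literal
    frequency zero."""
    rng = np.random.default_rng(2)
    u = rng.normal(size=8)
    x = np.concatenate([u, rng.normal(size=8)])
    y = np.concatenate([-u + rng.normal(0, 0.05, 8), rng.normal(size=8)])
    p = permutation_p(x, y, MASK_8V8, 1000, seed=3, mode="sample")
    assert p >= 0.0
    # deterministic coupling: |delta| = 2 is reachable only by the
    # identity relabelling (or its complement); with a draw that samples
    # neither, the literal frequency is exactly zero
    x2 = np.arange(16, dtype=float)
    y2 = np.concatenate([-x2[:8], x2[8:] - 8])
    assert observed_delta(x2, y2, MASK_8V8) == pytest.approx(-2.0)
    nulls = null_deltas(x2, y2, MASK_8V8, 500, seed=4, mode="sample")
    count = int((np.abs(nulls) >= 2.0 - 1e-12).sum())
    p2 = permutation_p(x2, y2, MASK_8V8, 500, seed=4, mode="sample")
    assert p2 == count / 500
    assert p2 == 0.0


def test_perm_p_deterministic_given_seed():
    rng = np.random.default_rng(5)
    x, y = rng.normal(size=16), rng.normal(size=16)
    a = permutation_p(x, y, MASK_8V8, 500, seed=9, mode="sample")
    b = permutation_p(x, y, MASK_8V8, 500, seed=9, mode="sample")
    assert a == b


def test_perm_p_label_swap_invariant():
    rng = np.random.default_rng(6)
    x, y = rng.normal(size=16), rng.normal(size=16)
    a = permutation_p(x, y, MASK_8V8, 1000, seed=7, mode="enumerate")
    b = permutation_p(x, y, ~MASK_8V8, 1000, seed=7, mode="enumerate")
    assert a == pytest.approx(b, abs=1e-12)


def test_enumeration_has_expected_size():
    rng = np.random.default_rng(7)
    x, y = rng.normal(size=16), rng.normal(size=16)
    nulls = null_deltas(x, y, MASK_8V8, 100, seed=0, mode="enumerate")
    assert nulls.size == 12870


def test_sampled_converges_to_enumeration():
    rng = np.random.default_rng(8)
    for i in range(5):
        x = rng.normal(size=16)
        y = 0.5 * x + rng.normal(size=16)
        exact = permutation_p(x, y, MASK_8V8, 100, seed=0, mode="enumerate")
        approx = permutation_p(x, y, MASK_8V8, 4000, seed=i, mode="sample")
        se = np.sqrt(max(exact * (1 - exact), 1e-12) / 4000)
        assert abs(approx - exact) <= 3 * se + 1e-9


def test_degenerate_permutations_redrawn_or_rejected():
    # x constant except one sample: every split leaves one constant group
    x = np.ones(16)
    x[0] = 2.0
    y = np.random.default_rng(9).normal(size=16)
    with pytest.raises(ValueError):
        permutation_p(x, y, MASK_8V8, 200, seed=1, mode="sample")


def test_pseudocount_mode_never_zero():
    x2 = np.arange(16, dtype=float)
    y2 = np.concatenate([-x2[:8], x2[8:] - 8])
    p = permutation_p(x2, y2, MASK_8V8, 1000, seed=4, pseudocount=True)
    assert p == pytest.approx(1 / 1001)


# -- select_differential_pairs ---------------------------------------

def _paired_dataset(seed, n_pairs=30, coupled=0):
    """n_pairs mRNA-lncRNA pairs; the first `coupled` are disease-coupled
    and differentially expressed (mirroring the planted-triplet structure:
    a shared latent profile in the disease samples plus a between-condition
    mean shift on both members)."""
    rng = np.random.default_rng(seed)
    n = 16
    shift = np.array([4.0] * 8 + [0.0] * 8)
    rows, ids, classes = [], [], []
    for i in range(n_pairs):
        if i < coupled:
            u = rng.normal(size=8)
            m = np.concatenate([u, rng.normal(size=8)]) + shift
            l = np.concatenate([u + rng.normal(0, 0.1, 8),
                                rng.normal(size=8)]) + shift
        else:
            m, l = rng.normal(size=n), rng.normal(size=n)
        rows += [2.0 ** (5 + m), 2.0 ** (5 + l)]
        ids += [f"m{i:03d}", f"l{i:03d}"]
        classes += ["mRNA", "lncRNA"]
    cols = [f"s{j}" for j in range(n)]
    return ExpressionDataset(
        normalized=pd.DataFrame(np.vstack(rows), index=ids, columns=cols),
        feature_class=pd.Series(classes, index=ids),
        condition=pd.Series(["disease"] * 8 + ["normal"] * 8, index=cols),
    )


def test_select_differential_pairs_recovers_coupled(fast_config):
    ds = _paired_dataset(seed=10, n_pairs=25, coupled=5)
    pairs = screen_pairs(ds, InteractionCatalog.from_pairs([]))
    out = select_differential_pairs(pairs, ds, fast_config)
    sig = out[out.is_significant]
    coupled_ids = {f"m{i:03d}" for i in range(5)}
    recovered = {a for a, b in zip(sig.feature_a, sig.feature_b)
                 if b == a.replace("m", "l")} & coupled_ids
    assert len(recovered) >= 4


def test_flag_set_monotone_in_fdr_threshold(fast_config):
    ds = _paired_dataset(seed=11, n_pairs=25, coupled=5)
    pairs = screen_pairs(ds, InteractionCatalog.from_pairs([]))
    loose = select_differential_pairs(pairs, ds, fast_config)
    tight = select_differential_pairs(
        pairs, ds, fast_config.replace(diffcorr_fdr=0.01))
    loose_set = set(map(tuple, loose[loose.is_significant]
                        [["feature_a", "feature_b"]].to_numpy()))
    tight_set = set(map(tuple, tight[tight.is_significant]
                        [["feature_a", "feature_b"]].to_numpy()))
    assert tight_set <= loose_set


def test_select_differential_pairs_deterministic(fast_config):
    ds = _paired_dataset(seed=12, n_pairs=10, coupled=2)
    pairs = screen_pairs(ds, InteractionCatalog.from_pairs([]))
    a = select_differential_pairs(pairs, ds, fast_config)
    b = select_differential_pairs(pairs, ds, fast_config)
    pd.testing.assert_frame_equal(a, b)


def test_row_order_does_not_change_pvalues(fast_config):
    ds = _paired_dataset(seed=13, n_pairs=10, coupled=2)
    pairs = screen_pairs(ds, InteractionCatalog.from_pairs([]))
    shuffled = pairs.sample(frac=1.0, random_state=0).reset_index(drop=True)
    a = select_differential_pairs(pairs, ds, fast_config)
    b = select_differential_pairs(shuffled, ds, fast_config)
    key = ["feature_a", "feature_b"]
    merged = a.merge(b, on=key, suffixes=("_a", "_b"))
    assert np.allclose(merged.perm_p_a, merged.perm_p_b)


def test_pooled_scheme_runs(fast_config):
    ds = _paired_dataset(seed=14, n_pairs=15, coupled=3)
    pairs = screen_pairs(ds, InteractionCatalog.from_pairs([]))
    cfg = fast_config.replace(permutation_scheme="pooled")
    out = select_differential_pairs(pairs, ds, cfg)
    assert ((out.perm_p >= 0) & (out.perm_p <= 1)).all()
    assert out[out.is_significant].shape[0] >= 1
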