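"""Permutation test for between-condition differences in correlation.

For each screened pair the observed statistic is the difference of
Pearson correlations, ``delta = r_disease - r_normal``.  The null is
built by permuting the condition labels across all samples (preserving
the group sizes), recomputing both correlations, and recording the null
delta; the permutation p-value is the literal frequency of null deltas
at least as extreme as the observed one (two-sided via absolute values
by default), so zero is a possible return.

With ``n1 + n2`` samples only ``C(n1 + n2, n1)`` distinct label splits
exist (12,870 at 8 + 8); the test therefore offers exhaustive
enumeration of all splits alongside label resampling, and an alternative
pooled null that draws random same-type feature pairs instead of
permuting labels.  Benjamini-Hochberg FDR is applied within each
pair-type stratum by default.
"""

from __future__ import annotations

import hashlib
import logging
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .correlation import PAIR_CLASSES, correlation_values
from .dataset import ExpressionDataset

logger = logging.getLogger("cernascreen")

_MAX_REDRAW_ROUNDS = 100


def observed_delta(x, y, disease_mask: np.ndarray) -> float:
    """Observed correlation difference r_disease - r_normal for one pair."""
    from .correlation import pearson

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return pearson(x[disease_mask], y[disease_mask]) - pearson(
        x[~disease_mask], y[~disease_mask]
    )


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pair_seed(global_seed: int, feature_a: str, feature_b: str) -> list[int]:
    """Stable per-pair entropy, independent of pair-processing order."""
    digest = hashlib.blake2b(f"{feature_a}\t{feature_b}".encode(),
                             digest_size=4).digest()
    return [int(global_seed) & 0x7FFFFFFF, int.from_bytes(digest, "big") & 0x7FFFFFFF]


def _group_correlations(x: np.ndarray, y: np.ndarray, masks: np.ndarray):
    """Pearson r of (x, y) within masks and their complements, vectorized.

    masks: boolean (n_perm, n_samples), each row selecting one group.
    Returns (r_in, r_out, valid) where valid marks rows with non-constant
    sub-vectors on both sides.
    """
    def _r(b):
        k = b.sum(axis=1, keepdims=True).astype(float)
        sx = b @ x
        sy = b @ y
        sxx = b @ (x * x)
        syy = b @ (y * y)
        sxy = b @ (x * y)
        k = k[:, 0]
        num = k * sxy - sx * sy
        vx = k * sxx - sx * sx
        vy = k * syy - sy * sy
        denom2 = vx * vy
        valid = (vx > 1e-12 * np.maximum(sxx, 1.0) * k) & \
                (vy > 1e-12 * np.maximum(syy, 1.0) * k)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = num / np.sqrt(np.where(denom2 > 0, denom2, 1.0))
        return np.clip(r, -1.0, 1.0), valid

    r_in, ok_in = _r(masks)
    r_out, ok_out = _r(~masks)
    return r_in, r_out, ok_in & ok_out


def _enumerate_masks(n_total: int, n_disease: int) -> np.ndarray:
    masks = np.zeros((comb(n_total, n_disease), n_total), dtype=bool)
    for row, picks in enumerate(combinations(range(n_total), n_disease)):
        masks[row, list(picks)] = True
    return masks


def null_deltas(
    x,
    y,
    disease_mask: np.ndarray,
    n_permutations: int,
    seed,
    mode: str = "auto",
) -> np.ndarray:
    """Null distribution of the correlation difference for one pair.

    ``mode='enumerate'`` uses every distinct label split; ``'sample'``
    draws label splits uniformly with replacement; ``'auto'`` enumerates
    whenever the number of distinct splits does not exceed
    ``n_permutations``.  Sampled splits producing a constant sub-vector
    are redrawn (bounded number of rounds).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    disease_mask = np.asarray(disease_mask, dtype=bool)
    n_total = disease_mask.size
    n_disease = int(disease_mask.sum())
    n_distinct = comb(n_total, n_disease)
    if mode == "auto":
        mode = "enumerate" if n_distinct <= n_permutations else "sample"

    if mode == "enumerate":
        masks = _enumerate_masks(n_total, n_disease)
        r_in, r_out, valid = _group_correlations(x, y, masks)
        if not valid.all():
            raise ValueError(
                "constant sub-vector under enumeration; pair should have been "
                "excluded by the correlation screen"
            )
        return r_in - r_out

    rng = np.random.default_rng(seed)
    masks = rng.random((n_permutations, n_total)).argsort(axis=1) < n_disease
    r_in, r_out, valid = _group_correlations(x, y, masks)
    rounds = 0
    while not valid.all():
        rounds += 1
        if rounds > _MAX_REDRAW_ROUNDS:
            raise ValueError(
                f"could not draw non-degenerate permutations after "
                f"{_MAX_REDRAW_ROUNDS} redraw rounds"
            )
        bad = ~valid
        redraw = rng.random((int(bad.sum()), n_total)).argsort(axis=1) < n_disease
        ri, ro, ok = _group_correlations(x, y, redraw)
        r_in[bad], r_out[bad], valid[bad] = ri, ro, ok
    return r_in - r_out


def permutation_p(
    x,
    y,
    disease_mask: np.ndarray,
    n_permutations: int,
    seed,
    mode: str = "auto",
    two_sided: bool = True,
    pseudocount: bool = False,
) -> float:
    """Permutation p-value for the correlation difference of one pair.

    The literal frequency of null deltas at least as extreme as the
    observed one (``>=`` with a tiny numerical tolerance); with
    ``pseudocount`` the estimate is ``(count + 1) / (n + 1)`` for
    downstream FDR stability.
    """
    if n_permutations < 100:
        raise ValueError(f"n_permutations must be >= 100; got {n_permutations}")
    obs = observed_delta(x, y, disease_mask)
    nulls = null_deltas(x, y, disease_mask, n_permutations, seed, mode=mode)
    if two_sided:
        count = int((np.abs(nulls) >= abs(obs) - 1e-12).sum())
    else:
        count = int((nulls >= obs - 1e-12).sum())
    n = nulls.size
    if pseudocount:
        return (count + 1) / (n + 1)
    return count / n


def pooled_null_deltas(
    dataset: ExpressionDataset,
    pair_type: str,
    n_draws: int,
    seed,
    scale: str = "log2",
) -> np.ndarray:
    """Null deltas from random same-type feature pairs (pooled scheme)."""
    cls_a, cls_b = PAIR_CLASSES[pair_type]
    a_ids = dataset.features_of_class(cls_a)
    b_ids = dataset.features_of_class(cls_b)
    values = pd.DataFrame(correlation_values(dataset, scale),
                          index=dataset.normalized.index)
    d_mask = dataset.condition_mask("disease")
    rng = np.random.default_rng(seed)
    out = np.empty(n_draws)
    filled = 0
    attempts = 0
    while filled < n_draws:
        attempts += 1
        if attempts > 50 * n_draws:
            raise ValueError("could not draw enough valid random pairs")
        a = a_ids[int(rng.integers(len(a_ids)))]
        b = b_ids[int(rng.integers(len(b_ids)))]
        if a == b:
            continue
        try:
            out[filled] = observed_delta(values.loc[a].to_numpy(),
                                         values.loc[b].to_numpy(), d_mask)
        except ValueError:
            continue
        filled += 1
    return out


def select_differential_pairs(
    pairs: pd.DataFrame,
    dataset: ExpressionDataset,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Permutation-test every screened pair and control FDR.

    Pairs that passed the per-condition screen in at least one condition
    are tested; q-values are BH-adjusted within each pair-type stratum
    (or pooled, per config) and ``is_significant`` flags q below the
    configured FDR.  Deterministic given the config seed.
    """
    tested = pairs[pairs["pass_disease"] | pairs["pass_normal"]].copy()
    if tested.empty:
        out = tested.assign(delta=[], perm_p=[], q_value=[], is_significant=[])
        return out
    d_mask = dataset.condition_mask("disease")
    mode = config.permutation_mode

    pooled_nulls: dict[str, np.ndarray] = {}
    if config.permutation_scheme == "pooled":
        for pt in tested["pair_type"].unique():
            pooled_nulls[pt] = pooled_null_deltas(
                dataset, pt, config.n_permutations,
                seed=_pair_seed(config.seed, "__pooled__", pt),
                scale=config.corr_scale,
            )

    deltas = np.empty(len(tested))
    perms = np.empty(len(tested))
    xs = correlation_values(dataset, config.corr_scale)
    row_of = {fid: i for i, fid in enumerate(dataset.normalized.index)}
    for k, (_, row) in enumerate(tested.iterrows()):
        x = xs[row_of[row["feature_a"]]]
        y = xs[row_of[row["feature_b"]]]
        obs = observed_delta(x, y, d_mask)
        deltas[k] = obs
        if config.permutation_scheme == "pooled":
            nulls = pooled_nulls[row["pair_type"]]
            if config.two_sided:
                count = int((np.abs(nulls) >= abs(obs) - 1e-12).sum())
            else:
                count = int((nulls >= obs - 1e-12).sum())
            n = nulls.size
            perms[k] = (count + 1) / (n + 1) if config.perm_pseudocount else count / n
        else:
            perms[k] = permutation_p(
                x, y, d_mask, config.n_permutations,
                seed=_pair_seed(config.seed, row["feature_a"], row["feature_b"]),
                mode=mode, two_sided=config.two_sided,
                pseudocount=config.perm_pseudocount,
            )

    tested["delta"] = deltas
    tested["perm_p"] = perms
    q = np.empty(len(tested))
    if config.fdr_by_pair_type:
        for pt in tested["pair_type"].unique():
            sel = (tested["pair_type"] == pt).to_numpy()
            q[sel] = fdr_adjust(perms[sel])
    else:
        q[:] = fdr_adjust(perms)
    tested["q_value"] = q
    tested["is_significant"] = q < config.diffcorr_fdr
    return tested.reset_index(drop=True)
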