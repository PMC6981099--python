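"""Per-condition Pearson correlation screen over admissible feature pairs.

Pairs are the three ceRNA-relevant types — mRNA-miRNA, miRNA-lncRNA and
mRNA-lncRNA.  miRNA-involved pairs are admissible only when present in
the miRNA-target interaction catalog; mRNA-lncRNA pairs are
unconstrained.  A pair passes the screen in a condition when its
correlation there is significant (two-sided p below the threshold) *and*
has the required sign: negative for both miRNA-target types, positive
for mRNA-lncRNA.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import ExpressionDataset, InteractionCatalog

logger = logging.getLogger("cernascreen")

PAIR_TYPES = ("mRNA-miRNA", "miRNA-lncRNA", "mRNA-lncRNA")

#: sign each pair type must have to pass the screen
REQUIRED_SIGN = {"mRNA-miRNA": -1, "miRNA-lncRNA": -1, "mRNA-lncRNA": +1}

#: (class of feature_a, class of feature_b) in canonical order per type
PAIR_CLASSES = {
    "mRNA-miRNA": ("mRNA", "miRNA"),
    "miRNA-lncRNA": ("miRNA", "lncRNA"),
    "mRNA-lncRNA": ("mRNA", "lncRNA"),
}

CORRELATION_SCALES = ("log2", "linear")


def correlation_values(dataset: ExpressionDataset, scale: str = "log2") -> np.ndarray:
    """Feature-by-sample matrix on the scale correlations are computed on.

    ``log2`` (default) applies the variance-stabilizing transform
    ``log2(normalized + 1)``; FPKM-like values are heavily right-skewed,
    and Pearson on the raw scale is dominated by a few high-leverage
    samples at small n.  ``linear`` uses the normalized values as-is.
    """
    if scale not in CORRELATION_SCALES:
        raise ValueError(f"unknown correlation scale {scale!r}")
    values = dataset.normalized.to_numpy(dtype=float)
    if scale == "log2":
        return np.log2(values + 1.0)
    return values


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient.

    Requires equal length >= 3 and non-constant inputs; symmetric in its
    arguments and always in [-1, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations; got {x.size}")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd @ xd) * (yd @ yd))
    if denom == 0.0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.clip((xd @ yd) / denom, -1.0, 1.0))


def correlation_p(r: float, n: int) -> float:
    """Two-sided p-value of a sample correlation under the exact null.

    Uses the t-transform ``t = r * sqrt((n - 2) / (1 - r**2))`` with
    ``n - 2`` degrees of freedom; ``|r| = 1`` maps to p = 0.
    """
    if n < 3:
        raise ValueError(f"need n >= 3; got {n}")
    r = float(r)
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"|r| must be <= 1; got {r}")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def _condition_stats(values: np.ndarray, mask: np.ndarray):
    """Correlation matrix and two-sided p-matrix within one condition."""
    sub = values[:, mask]
    n = sub.shape[1]
    sd = sub.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(sub)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return r, p, constant


def screen_pairs(
    dataset: ExpressionDataset,
    catalog: InteractionCatalog,
    pair_p: float = 0.05,
    scale: str = "log2",
) -> pd.DataFrame:
    """Enumerate admissible pairs and flag per-condition screen passes.

    Returns one row per admissible pair, sorted by (pair_type,
    feature_a, feature_b), with per-condition r and p, the pass flags,
    and the catalog-membership flag.  Features constant in either
    condition are excluded from pairing (logged).  Correlations are
    computed on :func:`correlation_values` (log2 by default).
    """
    values = correlation_values(dataset, scale)
    ids = np.asarray(dataset.feature_ids)
    d_mask = dataset.condition_mask("disease")

    r_d, p_d, const_d = _condition_stats(values, d_mask)
    r_n, p_n, const_n = _condition_stats(values, ~d_mask)
    constant = const_d | const_n
    if constant.any():
        logger.info("screen_pairs: excluding %d constant feature(s) from pairing",
                    int(constant.sum()))

    index_of = {fid: i for i, fid in enumerate(ids)}
    class_arr = dataset.feature_class.to_numpy()
    usable = {
        cls: [f for f, c, bad in zip(ids, class_arr, constant)
              if c == cls and not bad]
        for cls in ("mRNA", "miRNA", "lncRNA")
    }

    if len(catalog) == 0 and (usable["miRNA"] and (usable["mRNA"] or usable["lncRNA"])):
        logger.warning("screen_pairs: empty interaction catalog; no "
                       "miRNA-involved pair is admissible")

    rows: list[tuple] = []

    def emit(a: str, b: str, pair_type: str, in_catalog: bool) -> None:
        i, j = index_of[a], index_of[b]
        sign = REQUIRED_SIGN[pair_type]
        rd, rn = float(r_d[i, j]), float(r_n[i, j])
        pd_, pn_ = float(p_d[i, j]), float(p_n[i, j])
        rows.append((
            a, b, pair_type, rd, pd_, rn, pn_,
            bool(pd_ < pair_p and np.sign(rd) == sign),
            bool(pn_ < pair_p and np.sign(rn) == sign),
            in_catalog,
        ))

    mirna_set = set(usable["miRNA"])
    mrna_set = set(usable["mRNA"])
    lnc_set = set(usable["lncRNA"])
    for mirna, target in sorted(catalog.pairs):
        if mirna not in mirna_set:
            continue
        if target in mrna_set:
            emit(target, mirna, "mRNA-miRNA", True)
        elif target in lnc_set:
            emit(mirna, target, "miRNA-lncRNA", True)
    for m in usable["mRNA"]:
        for l in usable["lncRNA"]:
            emit(m, l, "mRNA-lncRNA", True)

    df = pd.DataFrame(rows, columns=[
        "feature_a", "feature_b", "pair_type",
        "r_disease", "p_disease", "r_normal", "p_normal",
        "pass_disease", "pass_normal", "in_catalog",
    ])
    df = df.sort_values(["pair_type", "feature_a", "feature_b"],
                        kind="mergesort").reset_index(drop=True)
    return df
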