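"""Count-based differential-expression screen between two conditions.

The primary test is a negative-binomial exact-style test in the spirit of
the classical two-group count tests used for small RNA-seq designs:

1. per-sample library-size factors by the median-of-ratios method
   (ratio of each sample to the geometric-mean reference feature-wise);
2. counts adjusted to a common library size ("pseudo-counts");
3. a single common dispersion estimated across features by the method of
   moments (trimmed mean of per-feature ``(var - mean) / mean**2``);
4. per feature, an exact conditional two-sided test of the disease-group
   sum against the normal-group sum given their total, under
   negative-binomial group sums with the common dispersion (Poisson /
   binomial conditional when the dispersion is zero).

A Welch t-test on ``log2(normalized + 1)`` is available as a fallback for
datasets without counts.  P-values are deliberately left unadjusted: the
screen applies a raw p threshold, and multiple-testing control enters
later at the differential-correlation and enrichment stages.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .dataset import ExpressionDataset

logger = logging.getLogger("cernascreen")

_MAX_EXACT_TOTAL = 2_000_000  # above this, fall back to a normal approximation
_LFC_PRIOR = 0.5  # prior count stabilising log2 fold changes at low counts


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors.

    The reference is the per-feature geometric mean across samples,
    computed over features expressed in every sample; each sample's
    factor is the median of its ratios to that reference.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if positive.sum() < 5:
        # too few universally expressed features: fall back to totals
        logger.warning("size_factors: <5 features expressed everywhere; "
                       "using total-count factors")
        totals = mat.sum(axis=0)
        factors = totals / np.exp(np.mean(np.log(np.maximum(totals, 1.0))))
    else:
        logs = np.log(mat[positive])
        ref = logs.mean(axis=1)
        factors = np.exp(np.median(logs - ref[:, None], axis=0))
    return pd.Series(factors, index=counts.columns)


def estimate_common_dispersion(pseudo: np.ndarray, disease: np.ndarray) -> float:
    """Moment-based common negative-binomial dispersion.

    For each feature and condition with positive mean, the per-feature
    moment estimate is ``(var - mean) / mean**2``; the common dispersion
    is the 10%-trimmed mean of these, floored at zero (Poisson).
    """
    ests = []
    for mask in (disease, ~disease):
        grp = pseudo[:, mask]
        m = grp.mean(axis=1)
        v = grp.var(axis=1, ddof=1)
        ok = m > 0
        ests.append((v[ok] - m[ok]) / m[ok] ** 2)
    est = np.concatenate(ests)
    if est.size == 0:
        return 0.0
    phi = float(stats.trim_mean(est, 0.1))
    return max(phi, 0.0)


def nb_exact_p(y1: int, y2: int, n1: int, n2: int, mu: float,
               dispersion: float) -> float:
    """Exact conditional two-sided p-value for a two-group count split.

    Group sums are modelled as NB(size = n_i / dispersion, mean = n_i * mu)
    (Poisson when dispersion is 0); conditioning on the total ``y1 + y2``,
    the p-value sums the conditional probabilities of all splits no more
    probable than the observed one.
    """
    total = int(y1 + y2)
    if total == 0:
        return 1.0
    if total > _MAX_EXACT_TOTAL:
        return _normal_approx_p(y1, y2, n1, n2, mu, dispersion)
    k = np.arange(total + 1)
    if dispersion <= 1e-8:
        # Poisson sums -> conditional Binomial(total, n1/(n1+n2))
        logp = stats.binom.logpmf(k, total, n1 / (n1 + n2))
    else:
        r1, r2 = n1 / dispersion, n2 / dispersion
        mu1, mu2 = n1 * mu, n2 * mu
        p1, p2 = r1 / (r1 + mu1), r2 / (r2 + mu2)
        logp = stats.nbinom.logpmf(k, r1, p1) + stats.nbinom.logpmf(
            total - k, r2, p2)
        logp -= logsumexp(logp)
    obs = logp[int(y1)]
    keep = logp <= obs + 1e-10
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


def _normal_approx_p(y1, y2, n1, n2, mu, dispersion) -> float:
    var1 = n1 * mu * (1 + dispersion * mu)
    var2 = n2 * mu * (1 + dispersion * mu)
    diff = y1 / n1 - y2 / n2
    sd = np.sqrt(var1 / n1**2 + var2 / n2**2)
    if sd == 0:
        return 1.0
    return float(2 * stats.norm.sf(abs(diff) / sd))


def test_differential_expression(
    dataset: ExpressionDataset,
    de_p: float = 0.05,
    method: str = "nb-exact",
) -> pd.DataFrame:
    """Per-feature differential-expression results.

    Returns a frame with columns ``feature_id``, ``feature_class``,
    ``log2_fold_change`` (disease over normal), ``p_value`` and ``is_de``
    (``p_value < de_p``).
    """
    if method not in ("nb-exact", "welch-log"):
        raise ValueError(f"unknown DE method {method!r}")
    disease = dataset.condition_mask("disease")
    n1, n2 = int(disease.sum()), int((~disease).sum())

    if method == "nb-exact":
        if dataset.counts is None:
            raise ValueError(
                "the nb-exact differential-expression test needs raw counts; "
                "supply a counts matrix or switch to the normalized-scale "
                "fallback (method='welch-log')"
            )
        factors = size_factors(dataset.counts).to_numpy()
        pseudo = dataset.counts.to_numpy(dtype=float) / factors[None, :]
        dispersion = estimate_common_dispersion(pseudo, disease)
        pseudo_int = np.rint(pseudo).astype(np.int64)
        y1 = pseudo_int[:, disease].sum(axis=1)
        y2 = pseudo_int[:, ~disease].sum(axis=1)
        mu_common = (y1 + y2) / (n1 + n2)
        pvals = np.array([
            nb_exact_p(a, b, n1, n2, m, dispersion)
            for a, b, m in zip(y1, y2, mu_common)
        ])
        m1 = pseudo[:, disease].mean(axis=1)
        m2 = pseudo[:, ~disease].mean(axis=1)
        lfc = np.log2((m1 + _LFC_PRIOR) / (m2 + _LFC_PRIOR))
    else:
        logx = np.log2(dataset.normalized.to_numpy(dtype=float) + 1.0)
        a, b = logx[:, disease], logx[:, ~disease]
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        lfc = a.mean(axis=1) - b.mean(axis=1)

    return pd.DataFrame({
        "feature_id": dataset.feature_ids,
        "feature_class": dataset.feature_class.to_numpy(),
        "log2_fold_change": lfc,
        "p_value": pvals,
        "is_de": pvals < de_p,
    })


def de_flag_map(de_results: pd.DataFrame) -> dict[str, bool]:
    """feature id -> is_de lookup."""
    return dict(zip(de_results["feature_id"], de_results["is_de"]))
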