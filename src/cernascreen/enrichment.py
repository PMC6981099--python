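"""Hypergeometric gene-set enrichment and candidate-gene selection.

The query set is the differentially expressed mRNAs drawn from
qualifying ceRNA triplets (those containing at least one DE miRNA or
lncRNA).  Each annotation term overlapping the query is tested with the
upper-tail hypergeometric probability P(X >= k) for drawing ``k`` term
genes in a query of size ``n`` from a background of ``N`` genes of
which ``M`` belong to the term.  BH-adjusted q-values gate enrichment;
genes of enriched terms mapped to a curated functional class become the
candidate susceptibility genes.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy import stats

from .dataset import FunctionalClassMap, GeneSetAnnotation
from .diffcorr import fdr_adjust
from .triplets import CeRNATriplet

logger = logging.getLogger("cernascreen")


def hypergeom_p(k: int, M: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    ``k`` query genes overlap a term of ``M`` genes, with a query of
    size ``n`` drawn from a background of ``N`` annotated genes.
    """
    if not (0 <= k <= min(n, M) and M <= N and n <= N):
        raise ValueError(
            f"inconsistent counts: k={k}, M={M}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, M, n))


def build_query_set(
    triplets: list[CeRNATriplet],
    de_results: pd.DataFrame,
) -> set[str]:
    """DE mRNAs from triplets whose miRNA or lncRNA is also DE."""
    de_map = dict(zip(de_results["feature_id"], de_results["is_de"]))
    query = set()
    for t in triplets:
        if not t.annotated:
            raise ValueError("triplets must be DE-annotated before querying")
        if (t.de_flags[1] or t.de_flags[2]) and de_map.get(t.mrna_id, False):
            query.add(t.mrna_id)
    if not query:
        logger.warning("build_query_set: no qualifying DE mRNA in any triplet")
    return query


def enrich(
    query: set[str],
    annotation: GeneSetAnnotation,
    background: set[str] | None = None,
    enrich_fdr: float = 0.05,
) -> pd.DataFrame:
    """Test every term overlapping the query; BH-adjust across terms.

    ``background`` defaults to the annotation universe (all genes
    annotated to at least one term); the query is intersected with the
    background before testing and must be contained in it.
    """
    if background is None:
        background = set(annotation.universe)
    background = set(background)
    if len(background) < len(query):
        raise ValueError("background smaller than the query set")
    stray = set(query) - background
    if stray:
        raise ValueError(
            f"query gene(s) outside the background: {sorted(stray)[:5]}"
        )
    N = len(background)
    n = len(query)
    rows = []
    for term_id in sorted(annotation.terms):
        name, genes = annotation.terms[term_id]
        genes_bg = genes & background
        k = len(genes_bg & query)
        if k == 0:
            continue
        M = len(genes_bg)
        rows.append((term_id, name, k, n, M, N, hypergeom_p(k, M, n, N)))
    df = pd.DataFrame(rows, columns=["term_id", "term_name", "k", "n", "M", "N",
                                     "p_value"])
    if df.empty:
        logger.warning("enrich: no term overlaps the query set")
        df["q_value"] = pd.Series(dtype=float)
        df["is_enriched"] = pd.Series(dtype=bool)
        return df
    df["q_value"] = fdr_adjust(df["p_value"].to_numpy())
    df["is_enriched"] = df["q_value"] < enrich_fdr
    df = df.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(
        drop=True)
    return df


def map_classes(records: pd.DataFrame, class_map: FunctionalClassMap) -> pd.DataFrame:
    """Attach the curated functional classes of each term (may be empty)."""
    out = records.copy()
    out["mapped_classes"] = [
        ",".join(sorted(class_map.classes_of_term(t))) for t in out["term_id"]
    ]
    return out


def select_candidates(
    records: pd.DataFrame,
    class_map: FunctionalClassMap,
    annotation: GeneSetAnnotation,
    query: set[str],
) -> pd.DataFrame:
    """Candidate susceptibility genes with per-class membership.

    A query gene is a candidate when it belongs to an enriched term
    mapped to at least one curated functional class; a gene may belong
    to several classes.
    """
    if len(class_map) == 0:
        raise ValueError(
            "empty functional class map; class curation is a mandatory input"
        )
    membership: dict[str, set[str]] = {}
    if "is_enriched" in records.columns:
        enriched = records.loc[records["is_enriched"].astype(bool)]
    else:
        enriched = records
    for term_id in enriched["term_id"]:
        classes = class_map.classes_of_term(term_id)
        if not classes:
            continue
        _, genes = annotation.terms[term_id]
        for gene in genes & query:
            membership.setdefault(gene, set()).update(classes)
    return pd.DataFrame(
        [(g, ",".join(sorted(cls))) for g, cls in sorted(membership.items())],
        columns=["gene", "classes"],
    )
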