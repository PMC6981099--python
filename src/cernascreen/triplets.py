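"""Assembly and classification of condition-specific ceRNA triplets.

A triplet (mRNA, miRNA, lncRNA) is emitted for a condition when its
three constituent pairs — (mRNA, miRNA), (miRNA, lncRNA) and
(mRNA, lncRNA) — are each significantly differentially correlated *and*
each passed the per-condition sign/significance screen in that
condition.  A triplet may qualify in both conditions and is then emitted
once per condition.

Triplets are categorised by differential-expression content: category
``T1``/``T2``/``T3`` for disease-condition triplets with one, two or
three DE elements, ``NT1``..``NT3`` for normal-condition triplets, and
``none`` when no element is DE.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .dataset import CONDITIONS

CATEGORIES = ("NT1", "NT2", "NT3", "T1", "T2", "T3")


@dataclass(frozen=True)
class CeRNATriplet:
    mrna_id: str
    mirna_id: str
    lncrna_id: str
    condition: str
    de_flags: tuple[bool, bool, bool] = (False, False, False)  # (mRNA, miRNA, lncRNA)
    annotated: bool = False

    @property
    def n_de(self) -> int:
        return sum(self.de_flags)

    @property
    def category(self) -> str:
        if not self.annotated or self.n_de == 0:
            return "none"
        prefix = "T" if self.condition == "disease" else "NT"
        return f"{prefix}{self.n_de}"

    @property
    def elements(self) -> tuple[str, str, str]:
        return (self.mrna_id, self.mirna_id, self.lncrna_id)


def assemble_triplets(diff_pairs: pd.DataFrame, condition: str) -> list[CeRNATriplet]:
    """Build the triplets qualifying in one condition.

    ``diff_pairs`` is the output of
    :func:`cernascreen.diffcorr.select_differential_pairs`.  Output is
    deterministic (sorted by ids) and duplicate-free regardless of input
    row order.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    flag = "pass_disease" if condition == "disease" else "pass_normal"
    ok = diff_pairs[diff_pairs["is_significant"] & diff_pairs[flag]]

    mm: dict[str, set[str]] = {}   # miRNA -> mRNAs
    ml: dict[str, set[str]] = {}   # miRNA -> lncRNAs
    m_l: set[tuple[str, str]] = set()
    for _, row in ok.iterrows():
        a, b, pt = row["feature_a"], row["feature_b"], row["pair_type"]
        if pt == "mRNA-miRNA":
            mm.setdefault(b, set()).add(a)
        elif pt == "miRNA-lncRNA":
            ml.setdefault(a, set()).add(b)
        elif pt == "mRNA-lncRNA":
            m_l.add((a, b))

    out = set()
    for mirna in set(mm) & set(ml):
        for mrna in mm[mirna]:
            for lnc in ml[mirna]:
                if (mrna, lnc) in m_l:
                    out.add((mrna, mirna, lnc))
    return [
        CeRNATriplet(m, mi, l, condition)
        for m, mi, l in sorted(out)
    ]


def annotate_and_select(
    triplets: list[CeRNATriplet],
    de_results: pd.DataFrame,
    require_de: bool = True,
) -> list[CeRNATriplet]:
    """Fill DE flags and categories; optionally drop triplets with no DE element.

    Raises if a triplet element is missing from the DE results.
    """
    de_map = dict(zip(de_results["feature_id"], de_results["is_de"]))
    out = []
    for t in triplets:
        for fid in t.elements:
            if fid not in de_map:
                raise KeyError(
                    f"feature {fid!r} missing from differential-expression results"
                )
        flags = tuple(bool(de_map[fid]) for fid in t.elements)
        annotated = replace(t, de_flags=flags, annotated=True)
        if require_de and annotated.n_de == 0:
            continue
        out.append(annotated)
    return out


def summarize_categories(triplets: list[CeRNATriplet]) -> pd.DataFrame:
    """Category-count table with distinct DE element counts per category.

    One row per category plus a ``Total`` row whose element counts are
    the distinct union across categories (so Total can be smaller than
    the column sums).
    """
    rows = {}
    union: dict[str, set[str]] = {"mRNA": set(), "miRNA": set(), "lncRNA": set()}
    total_triplets = 0
    for cat in CATEGORIES:
        members = [t for t in triplets if t.category == cat]
        de_m = {t.mrna_id for t in members if t.de_flags[0]}
        de_mi = {t.mirna_id for t in members if t.de_flags[1]}
        de_l = {t.lncrna_id for t in members if t.de_flags[2]}
        rows[cat] = (len(members), len(de_m), len(de_mi), len(de_l))
        union["mRNA"] |= de_m
        union["miRNA"] |= de_mi
        union["lncRNA"] |= de_l
        total_triplets += len(members)
    rows["Total"] = (
        total_triplets,
        len(union["mRNA"]),
        len(union["miRNA"]),
        len(union["lncRNA"]),
    )
    return pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=["n_triplets", "de_mrna", "de_mirna", "de_lncrna"],
    ).rename_axis("category")


def triplets_to_frame(triplets: list[CeRNATriplet]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (t.mrna_id, t.mirna_id, t.lncrna_id, t.condition,
             *t.de_flags, t.n_de, t.category)
            for t in triplets
        ],
        columns=["mrna_id", "mirna_id", "lncrna_id", "condition",
                 "de_mrna", "de_mirna", "de_lncrna", "n_de", "category"],
    )
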