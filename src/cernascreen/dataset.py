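"""Core in-memory containers for the screening pipeline.

An :class:`ExpressionDataset` holds a feature-by-sample matrix of
FPKM-like normalized expression (optionally raw counts), a per-feature
molecular class (mRNA / miRNA / lncRNA), and a per-sample condition label
(disease / normal).  Every downstream stage consumes this object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("cernascreen")

FEATURE_CLASSES = ("mRNA", "miRNA", "lncRNA")
CONDITIONS = ("disease", "normal")


class FormatError(ValueError):
    """Raised when an input file or container violates its contract."""


class ConfigurationError(ValueError):
    """Raised when a configuration value violates a stated constraint."""


@dataclass
class ExpressionDataset:
    """Two-condition expression data.

    Parameters
    ----------
    normalized
        Feature-by-sample matrix of non-negative FPKM-like values.
    feature_class
        Per-feature label, one of ``mRNA``, ``miRNA``, ``lncRNA``,
        indexed like the rows of ``normalized``.
    condition
        Per-sample label, ``disease`` or ``normal``, indexed like the
        columns of ``normalized``.
    counts
        Optional integer read counts with the same shape and ordering,
        required by the count-based differential-expression test.
    """

    normalized: pd.DataFrame
    feature_class: pd.Series
    condition: pd.Series
    counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        idx = self.normalized.index
        cols = self.normalized.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate feature identifier: {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample identifier: {dup!r}")
        if not idx.equals(self.feature_class.index):
            raise FormatError("feature_class index does not match matrix rows")
        bad = set(self.feature_class) - set(FEATURE_CLASSES)
        if bad:
            raise FormatError(f"unknown feature class label(s): {sorted(bad)}")
        if not cols.equals(self.condition.index):
            raise FormatError("condition index does not match matrix columns")
        bad = set(self.condition) - set(CONDITIONS)
        if bad:
            raise FormatError(f"unknown condition label(s): {sorted(bad)}")
        for label in CONDITIONS:
            n = int((self.condition == label).sum())
            if n < 3:
                raise FormatError(
                    f"condition {label!r} has {n} samples; at least 3 required"
                )
        vals = self.normalized.to_numpy()
        if not np.isfinite(vals).all():
            raise FormatError("normalized matrix contains non-finite values")
        if (vals < 0).any():
            raise FormatError("normalized matrix contains negative values")
        if self.counts is not None:
            if not self.counts.index.equals(idx) or not self.counts.columns.equals(cols):
                raise FormatError("counts matrix shape/ordering differs from normalized")
            cv = self.counts.to_numpy()
            if (cv < 0).any():
                raise FormatError("counts matrix contains negative values")

    # -- convenience ---------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.normalized.index)

    @property
    def samples(self) -> list[str]:
        return list(self.normalized.columns)

    @property
    def n_samples(self) -> int:
        return self.normalized.shape[1]

    def features_of_class(self, cls: str) -> list[str]:
        if cls not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {cls!r}")
        return list(self.feature_class.index[self.feature_class == cls])

    def samples_of(self, condition: str) -> list[str]:
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        return list(self.condition.index[self.condition == condition])

    def condition_mask(self, condition: str) -> np.ndarray:
        """Boolean mask over samples (matrix column order)."""
        return (self.condition == condition).to_numpy()

    def values(self, feature_id: str) -> np.ndarray:
        return self.normalized.loc[feature_id].to_numpy(dtype=float)


@dataclass(frozen=True)
class InteractionCatalog:
    """Predicted miRNA-target interactions (mirCode-style lookup).

    Pairs are ``(mirna_id, target_id)`` where the target may be an mRNA
    or a lncRNA.  Membership is exact string match after whitespace
    trimming (applied at construction).
    """

    pairs: frozenset[tuple[str, str]]

    @classmethod
    def from_pairs(cls, pairs) -> "InteractionCatalog":
        cleaned = set()
        for mirna, target in pairs:
            mirna, target = str(mirna).strip(), str(target).strip()
            if not mirna or not target:
                raise FormatError("empty identifier in interaction pair")
            if mirna == target:
                raise FormatError(f"self-pair in interaction catalog: {mirna!r}")
            cleaned.add((mirna, target))
        return cls(frozenset(cleaned))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        mirna, target = pair
        return (str(mirna).strip(), str(target).strip()) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class GeneSetAnnotation:
    """Gene-set annotation (GO BP style): term id -> (name, gene set)."""

    terms: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for term_id, (_, genes) in self.terms.items():
            if len(genes) == 0:
                raise FormatError(f"term {term_id!r} has an empty gene set")
            if any(not g for g in genes):
                raise FormatError(f"term {term_id!r} contains an empty gene id")

    @property
    def universe(self) -> frozenset[str]:
        """All genes annotated to at least one term."""
        out: set[str] = set()
        for _, genes in self.terms.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class FunctionalClassMap:
    """Curated functional classes: class name -> set of term ids."""

    classes: dict[str, frozenset[str]]

    def validate_against(self, annotation: GeneSetAnnotation) -> list[str]:
        """Warn (do not fail) on term ids missing from the annotation.

        Returns the list of missing term ids.
        """
        missing = [
            t
            for terms in self.classes.values()
            for t in terms
            if t not in annotation.terms
        ]
        if missing:
            logger.warning(
                "functional class map references %d term(s) absent from the "
                "annotation: %s",
                len(missing),
                ", ".join(sorted(set(missing))[:5]),
            )
        return missing

    def classes_of_term(self, term_id: str) -> frozenset[str]:
        return frozenset(
            name for name, terms in self.classes.items() if term_id in terms
        )

    def __len__(self) -> int:
        return len(self.classes)
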