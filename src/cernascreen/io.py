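"""Readers and writers for every on-disk artifact.

Formats
-------
* expression matrix — TSV; first column ``feature_id``, second column
  ``feature_class`` (mRNA | miRNA | lncRNA), remaining columns one per
  sample.  The feature class may instead come from a two-column side file.
* condition table — TSV with columns ``sample`` and ``condition``.
* interaction catalog — two-column TSV ``mirna<TAB>target`` (no header).
* gene sets — standard GMT: ``term<TAB>description<TAB>gene...``.
* functional class map — YAML ``class name: [term ids]``.
* pipeline config — flat-key YAML mirroring :class:`PipelineConfig`.

All readers validate and reject malformed input rather than coercing it;
every writer/reader pair round-trips valid data exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import PipelineConfig
from .dataset import (
    ExpressionDataset,
    FormatError,
    FunctionalClassMap,
    GeneSetAnnotation,
    InteractionCatalog,
)

logger = logging.getLogger("cernascreen")

_CLASS_COLUMN = "feature_class"


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def read_expression(
    matrix_path,
    condition_path,
    counts_path=None,
    class_path=None,
) -> ExpressionDataset:
    """Load an expression dataset from TSV files.

    The feature class is taken from the matrix's ``feature_class`` column
    or, if ``class_path`` is given, from a two-column side file
    (``feature_id<TAB>feature_class``).
    """
    matrix = _read_matrix(matrix_path, expect_class=class_path is None)
    if class_path is not None:
        side = pd.read_csv(class_path, sep="\t", dtype=str)
        if side.shape[1] != 2:
            raise FormatError(f"{class_path}: expected two columns")
        side.columns = ["feature_id", _CLASS_COLUMN]
        feature_class = side.set_index("feature_id")[_CLASS_COLUMN]
        missing = set(matrix.index) - set(feature_class.index)
        if missing:
            raise FormatError(
                f"{class_path}: missing class for feature(s) {sorted(missing)[:5]}"
            )
        feature_class = feature_class.reindex(matrix.index)
    else:
        feature_class = matrix.pop(_CLASS_COLUMN)

    cond = pd.read_csv(condition_path, sep="\t", dtype=str)
    if list(cond.columns) != ["sample", "condition"]:
        raise FormatError(
            f"{condition_path}: expected header 'sample<TAB>condition'"
        )
    if cond["sample"].duplicated().any():
        raise FormatError(f"{condition_path}: duplicate sample identifier")
    condition = cond.set_index("sample")["condition"]
    missing = set(matrix.columns) - set(condition.index)
    if missing:
        raise FormatError(
            f"{condition_path}: no condition for sample(s) {sorted(missing)[:5]}"
        )
    condition = condition.reindex(matrix.columns)

    values = matrix.astype(float)
    counts = None
    if counts_path is not None:
        cmat = _read_matrix(counts_path, expect_class=False)
        cmat = cmat.astype(float)
        if not np.allclose(cmat.to_numpy() % 1.0, 0.0):
            raise FormatError(f"{counts_path}: non-integer count value")
        counts = cmat.astype(np.int64).reindex(
            index=values.index, columns=values.columns
        )
        if counts.isna().any().any():
            raise FormatError(
                f"{counts_path}: features/samples differ from the expression matrix"
            )
    return ExpressionDataset(
        normalized=values,
        feature_class=feature_class,
        condition=condition,
        counts=counts,
    )


def _read_matrix(path, expect_class: bool) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "feature_id":
        raise FormatError(f"{path}: first column must be 'feature_id'")
    if expect_class and _CLASS_COLUMN not in df.columns:
        raise FormatError(f"{path}: missing '{_CLASS_COLUMN}' column")
    if df["feature_id"].duplicated().any():
        dup = df.loc[df["feature_id"].duplicated(), "feature_id"].iloc[0]
        raise FormatError(f"{path}: duplicate feature identifier {dup!r}")
    df = df.set_index("feature_id")
    df.index.name = None
    sample_cols = [c for c in df.columns if c != _CLASS_COLUMN]
    out = df[([_CLASS_COLUMN] if (expect_class and _CLASS_COLUMN in df.columns) else [])
             + sample_cols].copy()
    for c in sample_cols:
        try:
            out[c] = out[c].astype(float)
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric value in column {c!r}") from exc
        if (out[c] < 0).any():
            raise FormatError(f"{path}: negative value in column {c!r}")
    return out


def write_expression(dataset: ExpressionDataset, matrix_path, condition_path,
                     counts_path=None) -> None:
    mat = dataset.normalized.copy()
    mat.insert(0, _CLASS_COLUMN, dataset.feature_class)
    mat.index.name = "feature_id"
    mat.to_csv(matrix_path, sep="\t", float_format="%.17g")
    cond = dataset.condition.rename("condition").rename_axis("sample")
    cond.to_frame().to_csv(condition_path, sep="\t")
    if counts_path is not None:
        if dataset.counts is None:
            raise ValueError("dataset has no counts to write")
        cm = dataset.counts.copy()
        cm.index.name = "feature_id"
        cm.to_csv(counts_path, sep="\t")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetAnnotation:
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            term_id, name = parts[0].strip(), parts[1].strip()
            genes = frozenset(g.strip() for g in parts[2:] if g.strip())
            if not genes:
                raise FormatError(f"{path}:{lineno}: term {term_id!r} has no genes")
            if term_id in terms:
                logger.warning("%s:%d: duplicate term %r; last wins", path, lineno,
                               term_id)
            terms[term_id] = (name, genes)
    return GeneSetAnnotation(terms)


def write_gmt(annotation: GeneSetAnnotation, path) -> None:
    with open(path, "w") as fh:
        for term_id in sorted(annotation.terms):
            name, genes = annotation.terms[term_id]
            fh.write("\t".join([term_id, name, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# interaction catalog
# ---------------------------------------------------------------------------

def read_catalog(path) -> InteractionCatalog:
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 'mirna<TAB>target'"
                )
            pairs.append((parts[0], parts[1]))
    return InteractionCatalog.from_pairs(pairs)


def write_catalog(catalog: InteractionCatalog, path) -> None:
    with open(path, "w") as fh:
        for mirna, target in sorted(catalog.pairs):
            fh.write(f"{mirna}\t{target}\n")


# ---------------------------------------------------------------------------
# functional class map
# ---------------------------------------------------------------------------

def read_class_map(path) -> FunctionalClassMap:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise FormatError(f"{path}: class map must be a mapping class -> [terms]")
    classes = {}
    for name, terms in data.items():
        if isinstance(terms, str):
            terms = [terms]
        if not isinstance(terms, list) or not terms:
            raise FormatError(f"{path}: class {name!r} must map to a term list")
        classes[str(name)] = frozenset(str(t) for t in terms)
    return FunctionalClassMap(classes)


def write_class_map(class_map: FunctionalClassMap, path) -> None:
    data = {name: sorted(terms) for name, terms in sorted(class_map.classes.items())}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# pipeline config
# ---------------------------------------------------------------------------

def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a flat key-value mapping")
    if "kernels" in data and data["kernels"] is not None:
        data["kernels"] = tuple(data["kernels"])
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
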