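"""End-to-end orchestration of the biomarker identification strategy.

Stages run in order — differential expression, per-condition correlation
screen, permutation differential-correlation test, triplet assembly,
gene-set enrichment, SVM biomarker selection — with every intermediate
written as plain TSV so any stage can be inspected or re-entered.  A
rerun with identical config and inputs is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import io as cio
from .classify import biomarker_selection, evaluate_triplets, random_baseline
from .config import PipelineConfig
from .correlation import screen_pairs
from .dataset import ExpressionDataset
from .diffcorr import select_differential_pairs
from .diffexpr import test_differential_expression
from .enrichment import build_query_set, enrich, map_classes, select_candidates
from .simulate import SyntheticConfig, generate_dataset
from .triplets import (
    annotate_and_select,
    assemble_triplets,
    summarize_categories,
    triplets_to_frame,
)

logger = logging.getLogger("cernascreen")

_FLOAT_FMT = "%.10g"


@dataclasses.dataclass
class RunReport:
    """Per-stage counts, thresholds, seed and input provenance of a run."""

    n_features: int
    n_samples: int
    n_de: int
    n_pairs_screened: int
    n_pairs_tested: int
    n_differential_pairs: int
    n_triplets_disease: int
    n_triplets_normal: int
    triplet_categories: dict
    n_query_genes: int
    n_terms_tested: int
    n_enriched_terms: int
    n_candidates: int
    biomarker_genes: list
    biomarker_lncrnas: list
    biomarker_mirnas: list
    thresholds: dict
    seed: int
    input_digests: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig, dataset: ExpressionDataset | None = None,
                 catalog=None, annotation=None, class_map=None) -> RunReport:
    """Execute the full strategy and write every intermediate table.

    Inputs are read from the configured paths unless the in-memory
    objects are supplied directly (the synthetic route).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    digests = {}
    if dataset is None:
        for key in ("expression", "conditions", "catalog", "gene_sets", "class_map"):
            if getattr(config, key) is None:
                raise ValueError(f"config is missing the {key!r} input path")
        dataset = cio.read_expression(
            config.expression, config.conditions, counts_path=config.counts,
        )
        catalog = cio.read_catalog(config.catalog)
        annotation = cio.read_gmt(config.gene_sets)
        class_map = cio.read_class_map(config.class_map)
        for key in ("expression", "counts", "conditions", "catalog",
                    "gene_sets", "class_map"):
            path = getattr(config, key)
            if path is not None:
                digests[key] = _digest(path)
    elif catalog is None or annotation is None or class_map is None:
        raise ValueError("in-memory inputs must be supplied together")
    class_map.validate_against(annotation)

    # 1. differential expression
    logger.info("stage de: %d features, %d samples",
                len(dataset.feature_ids), dataset.n_samples)
    de = test_differential_expression(dataset, de_p=config.de_p,
                                      method=config.de_method)
    _write(de, out_dir / "de_results.tsv")

    # 2. per-condition correlation screen
    pairs = screen_pairs(dataset, catalog, pair_p=config.pair_p,
                         scale=config.corr_scale)
    _write(pairs, out_dir / "pair_screen.tsv")
    logger.info("stage pairs: %d admissible pairs, %d pass in >=1 condition",
                len(pairs), int((pairs.pass_disease | pairs.pass_normal).sum()))

    # 3. permutation differential-correlation test
    diff = select_differential_pairs(pairs, dataset, config)
    _write(diff, out_dir / "differential_pairs.tsv")
    logger.info("stage diffcorr: %d tested, %d significant",
                len(diff), int(diff["is_significant"].sum()) if len(diff) else 0)

    # 4. triplets
    trip_d = assemble_triplets(diff, "disease")
    trip_n = assemble_triplets(diff, "normal")
    annotated = annotate_and_select(trip_d + trip_n, de,
                                    require_de=config.require_de)
    _write(triplets_to_frame(annotated), out_dir / "triplets.tsv")
    summary = summarize_categories(annotated)
    summary.to_csv(out_dir / "triplet_categories.tsv", sep="\t")

    # 5. enrichment
    query = build_query_set(annotated, de)
    background = (set(annotation.universe) if config.background == "annotation"
                  else set(dataset.features_of_class("mRNA")))
    query_in_bg = query & background
    if query_in_bg != query:
        logger.warning("enrich: %d query gene(s) outside the background "
                       "dropped", len(query - query_in_bg))
    records = enrich(query_in_bg, annotation, background,
                     enrich_fdr=config.enrich_fdr)
    records = map_classes(records, class_map)
    _write(records, out_dir / "enrichment.tsv")
    candidates = select_candidates(records, class_map, annotation, query_in_bg)
    _write(candidates, out_dir / "candidates.tsv")

    # 6. classification and biomarker selection
    report = biomarker_selection(dataset, candidates, annotated, config)
    _write(report["class_table"], out_dir / "class_gate.tsv")
    _write(report["genes"], out_dir / "biomarker_genes.tsv")
    _write(report["lncrnas"], out_dir / "biomarker_lncrnas.tsv")
    _write(report["mirnas"], out_dir / "biomarker_mirnas.tsv")

    gene_list = list(report["genes"]["feature_id"])
    lnc_list = list(report["lncrnas"]["feature_id"])
    mir_list = list(report["mirnas"]["feature_id"])

    # triplets containing a selected gene, scored as 3-feature panels
    biomarker_triplets = [t for t in annotated if t.mrna_id in set(gene_list)]
    trip_eval = evaluate_triplets(dataset, biomarker_triplets,
                                  auc_min=config.auc_min, seed=config.seed,
                                  cost=config.svm_cost, degree=config.poly_degree)
    _write(trip_eval, out_dir / "triplet_classification.tsv")

    # random-baseline comparison for the gene panel
    if gene_list and config.n_baseline_draws > 0:
        de_pool = list(de.loc[de["is_de"] & (de["feature_class"] == "mRNA"),
                              "feature_id"])
        sig = diff[diff["is_significant"]] if len(diff) else diff
        pair_pool = sorted(
            set(sig["feature_a"]) | set(sig["feature_b"])
        ) if len(sig) else []
        mrna_pair_pool = [f for f in pair_pool
                          if dataset.feature_class.get(f) == "mRNA"]
        pools = {}
        if len(de_pool) >= len(gene_list):
            pools["de_mrnas"] = de_pool
        if len(mrna_pair_pool) >= len(gene_list):
            pools["diffcorr_mrnas"] = mrna_pair_pool
        if pools:
            baseline = random_baseline(
                dataset, gene_list, pools, n_draws=config.n_baseline_draws,
                seed=config.seed, cost=config.svm_cost,
                degree=config.poly_degree,
            )
            _write(baseline, out_dir / "random_baseline.tsv")

    run_report = RunReport(
        n_features=len(dataset.feature_ids),
        n_samples=dataset.n_samples,
        n_de=int(de["is_de"].sum()),
        n_pairs_screened=len(pairs),
        n_pairs_tested=len(diff),
        n_differential_pairs=int(diff["is_significant"].sum()) if len(diff) else 0,
        n_triplets_disease=len(trip_d),
        n_triplets_normal=len(trip_n),
        triplet_categories={k: int(v) for k, v in
                            summary["n_triplets"].to_dict().items()},
        n_query_genes=len(query_in_bg),
        n_terms_tested=len(records),
        n_enriched_terms=int(records["is_enriched"].sum()) if len(records) else 0,
        n_candidates=len(candidates),
        biomarker_genes=gene_list,
        biomarker_lncrnas=lnc_list,
        biomarker_mirnas=mir_list,
        thresholds={
            "de_p": config.de_p, "pair_p": config.pair_p,
            "diffcorr_fdr": config.diffcorr_fdr,
            "enrich_fdr": config.enrich_fdr, "auc_min": config.auc_min,
            "n_permutations": config.n_permutations,
        },
        seed=config.seed,
        input_digests=digests,
    )
    with open(out_dir / "run_report.json", "w") as fh:
        json.dump(run_report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return run_report


def make_demo(seed: int, out_dir, synthetic: SyntheticConfig | None = None,
              n_permutations: int = 10_000) -> PipelineConfig:
    """Write a complete synthetic input bundle plus a ready-to-run config.

    The bundle reproduces the quick-start: expression + counts matrices,
    condition table, interaction catalog, GMT gene sets, functional
    class map, the ground-truth record of what was planted, and a
    pipeline config pointing at all of them.  Byte-identical for a fixed
    seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    syn = synthetic if synthetic is not None else SyntheticConfig(seed=seed)
    dataset, catalog, annotation, class_map, truth = generate_dataset(syn)

    cio.write_expression(dataset, out / "expression.tsv", out / "conditions.tsv",
                         counts_path=out / "counts.tsv")
    cio.write_catalog(catalog, out / "catalog.tsv")
    cio.write_gmt(annotation, out / "gene_sets.gmt")
    cio.write_class_map(class_map, out / "class_map.yaml")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")

    config = PipelineConfig(
        expression=str(out / "expression.tsv"),
        counts=str(out / "counts.tsv"),
        conditions=str(out / "conditions.tsv"),
        catalog=str(out / "catalog.tsv"),
        gene_sets=str(out / "gene_sets.gmt"),
        class_map=str(out / "class_map.yaml"),
        out_dir=str(out / "results"),
        n_permutations=n_permutations,
        seed=seed,
    )
    cio.save_config(config, out / "config.yaml")
    return config
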