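"""Synthetic two-condition expression data with planted ceRNA structure.

The generator emulates the statistical structure the screening pipeline
assumes: two conditions with a modest number of samples each, a small set
of planted (mRNA, miRNA, lncRNA) triplets that are miRNA-coupled in
exactly one condition and decoupled in the other, planted differentially
expressed features, and a consistent miRNA-target catalog plus gene-set
annotation in which the planted mRNAs are over-represented in a
"disease-related" functional class.

Construction of a planted triplet in its active condition: a latent
standard-normal profile ``u`` drives the miRNA on the log2 scale, while
the mRNA and lncRNA receive ``-c * u`` plus residual noise scaled by
``sqrt(1 - c**2)`` (``c`` = coupling strength).  The two target
residuals share a common component (correlation ``target_residual_corr``,
reflecting co-regulation of ceRNA partners beyond the shared miRNA), so
on the log2 scale the expected correlations are ``-c`` for each
miRNA-target pair and ``c**2 + (1 - c**2) * target_residual_corr`` for
the mRNA-lncRNA pair; at ``c = 1`` the coupling is noise-free and the
sample correlations are exactly -1 / -1 / +1.  In the inactive condition
all three profiles are independent.

Downstream correlations are computed on the exponentiated (FPKM-like)
scale, where the lognormal transform attenuates negative correlations
more than positive ones; the default ``noise_sd`` (log2-scale biological
spread between replicate samples) is chosen small enough that planted
couplings survive this attenuation while remaining within the range
observed for homogeneous bulk tissue.

Normalized values are ``2**log2`` so they are non-negative FPKM-like
quantities; integer counts are drawn from a Poisson whose mean is the
normalized value scaled by a sequencing depth and a per-sample library
factor, giving the count-based differential-expression stage realistic
integer input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dataset import (
    CONDITIONS,
    ConfigurationError,
    ExpressionDataset,
    FunctionalClassMap,
    GeneSetAnnotation,
    InteractionCatalog,
)

DISEASE_TERM = "GO:SYN0001"
DISEASE_CLASS = "disease_related"


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic generator.

    Defaults mirror the study conditions the pipeline is designed for:
    8 samples per condition, a few hundred features, strong (0.9)
    miRNA-target coupling in the active condition, a planted
    differential-expression effect of 2 on the log2 scale, and unit
    log2-scale biological noise.
    """

    n_mrna: int = 200
    n_mirna: int = 20
    n_lncrna: int = 50
    n_samples_per_condition: int = 8
    n_planted_triplets: int = 5
    coupling_strength: float = 0.9
    de_log2fc: float = 2.0
    noise_sd: float = 0.3
    fraction_de: float = 0.1
    target_residual_corr: float = 0.5
    seed: int = 0
    # plumbing knobs for the surrounding artifacts
    n_decoy_interactions: int = 150
    n_random_terms: int = 30
    term_size: int = 12
    count_depth: float = 20.0
    library_size_cv: float = 0.15

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if min(self.n_mrna, self.n_mirna, self.n_lncrna) < 1:
            raise ConfigurationError("feature counts must all be >= 1")
        if self.n_planted_triplets > min(self.n_mrna, self.n_mirna, self.n_lncrna):
            raise ConfigurationError(
                "n_planted_triplets must be <= min(n_mrna, n_mirna, n_lncrna); "
                f"got {self.n_planted_triplets}"
            )
        if self.n_planted_triplets < 0:
            raise ConfigurationError("n_planted_triplets must be >= 0")
        if self.n_samples_per_condition < 3:
            raise ConfigurationError(
                "n_samples_per_condition must be >= 3 (correlation undefined "
                f"below that); got {self.n_samples_per_condition}"
            )
        if not (0.0 < self.coupling_strength <= 1.0):
            raise ConfigurationError(
                f"coupling_strength must lie in (0, 1]; got {self.coupling_strength}"
            )
        if self.de_log2fc <= 0:
            raise ConfigurationError(f"de_log2fc must be > 0; got {self.de_log2fc}")
        if self.noise_sd <= 0:
            raise ConfigurationError(f"noise_sd must be > 0; got {self.noise_sd}")
        if not (0.0 <= self.fraction_de <= 1.0):
            raise ConfigurationError(
                f"fraction_de must lie in [0, 1]; got {self.fraction_de}"
            )
        if not (0.0 <= self.target_residual_corr < 1.0):
            raise ConfigurationError(
                "target_residual_corr must lie in [0, 1); got "
                f"{self.target_residual_corr}"
            )
        if self.count_depth <= 0 or self.library_size_cv < 0:
            raise ConfigurationError("invalid count-layer parameters")


@dataclass
class SyntheticTruth:
    """Ground-truth record of what the generator planted."""

    planted_triplets: list[tuple[str, str, str, str]]  # (mrna, mirna, lncrna, cond)
    planted_de_features: set[str]
    enriched_terms: set[str]

    def to_dict(self) -> dict:
        return {
            "planted_triplets": [list(t) for t in self.planted_triplets],
            "planted_de_features": sorted(self.planted_de_features),
            "enriched_terms": sorted(self.enriched_terms),
        }


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[ExpressionDataset, InteractionCatalog, GeneSetAnnotation,
           FunctionalClassMap, SyntheticTruth]:
    """Generate a full synthetic input bundle plus its ground truth.

    Deterministic: identical config (including seed) gives bit-identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples_per_condition
    c = config.coupling_strength

    mrna_ids = [f"mRNA_{i:04d}" for i in range(config.n_mrna)]
    mirna_ids = [f"miR_{i:03d}" for i in range(config.n_mirna)]
    lnc_ids = [f"lncRNA_{i:03d}" for i in range(config.n_lncrna)]
    feature_ids = mrna_ids + mirna_ids + lnc_ids
    classes = (["mRNA"] * config.n_mrna + ["miRNA"] * config.n_mirna
               + ["lncRNA"] * config.n_lncrna)
    samples = [f"disease_{i + 1}" for i in range(n)] + [
        f"normal_{i + 1}" for i in range(n)
    ]
    condition = ["disease"] * n + ["normal"] * n
    n_features = len(feature_ids)
    row = {fid: i for i, fid in enumerate(feature_ids)}

    # baseline: independent log2-normal noise around a per-feature mean
    mu = rng.normal(3.5, 1.5, size=n_features)
    log2x = mu[:, None] + rng.normal(0.0, config.noise_sd, size=(n_features, 2 * n))

    # planted triplets: first k features of each class, active condition
    # alternating disease, normal, disease, ...
    planted: list[tuple[str, str, str, str]] = []
    for t in range(config.n_planted_triplets):
        m_id, mi_id, l_id = mrna_ids[t], mirna_ids[t], lnc_ids[t]
        active = CONDITIONS[t % 2]
        cols = slice(0, n) if active == "disease" else slice(n, 2 * n)
        u = rng.normal(0.0, 1.0, size=n)
        resid = math.sqrt(max(0.0, 1.0 - c * c))
        rho = config.target_residual_corr
        shared = rng.normal(0.0, 1.0, size=n)
        eps_m = math.sqrt(rho) * shared + math.sqrt(1 - rho) * rng.normal(
            0.0, 1.0, size=n)
        eps_l = math.sqrt(rho) * shared + math.sqrt(1 - rho) * rng.normal(
            0.0, 1.0, size=n)
        log2x[row[mi_id], cols] = mu[row[mi_id]] + config.noise_sd * u
        log2x[row[m_id], cols] = mu[row[m_id]] + config.noise_sd * (
            -c * u + resid * eps_m
        )
        log2x[row[l_id], cols] = mu[row[l_id]] + config.noise_sd * (
            -c * u + resid * eps_l
        )
        planted.append((m_id, mi_id, l_id, active))

    # differential expression: force every element of each planted triplet
    # into the DE set (planted triplets emulate fully differentially
    # expressed ceRNA triplets, so the selection stage can recover them),
    # then top up with random features to reach fraction_de
    forced = [fid for m, mi, l, _ in planted for fid in (m, mi, l)]
    de_set: set[str] = set(forced)
    target_n_de = int(round(config.fraction_de * n_features))
    remaining = [f for f in feature_ids if f not in de_set]
    extra = max(0, target_n_de - len(de_set))
    if extra > 0:
        de_set |= set(rng.choice(remaining, size=min(extra, len(remaining)),
                                 replace=False))
    for fid in sorted(de_set):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        log2x[row[fid], :n] += sign * config.de_log2fc

    normalized = np.power(2.0, log2x)

    # count layer: Poisson around depth-scaled normalized values with
    # mild per-sample library-size variation
    lib = rng.lognormal(mean=0.0, sigma=config.library_size_cv, size=2 * n)
    lam = normalized * config.count_depth * lib[None, :]
    counts = rng.poisson(lam).astype(np.int64)

    dataset = ExpressionDataset(
        normalized=pd.DataFrame(normalized, index=feature_ids, columns=samples),
        feature_class=pd.Series(classes, index=feature_ids),
        condition=pd.Series(condition, index=samples),
        counts=pd.DataFrame(counts, index=feature_ids, columns=samples),
    )

    # interaction catalog: planted pairs plus random decoys
    pairs = set()
    for m_id, mi_id, l_id, _ in planted:
        pairs.add((mi_id, m_id))
        pairs.add((mi_id, l_id))
    targets = mrna_ids + lnc_ids
    attempts = 0
    while len(pairs) < 2 * len(planted) + config.n_decoy_interactions:
        mi = mirna_ids[int(rng.integers(config.n_mirna))]
        tg = targets[int(rng.integers(len(targets)))]
        pairs.add((mi, tg))
        attempts += 1
        if attempts > 100 * (config.n_decoy_interactions + 1):
            break  # catalog saturated (tiny feature spaces)
    catalog = InteractionCatalog.from_pairs(pairs)

    # gene sets: one planted "disease" term over-representing the planted
    # mRNAs, plus random background terms covering the mRNA universe
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    planted_mrnas = [m for m, _, _, _ in planted]
    extra_in_term = list(
        rng.choice([m for m in mrna_ids if m not in planted_mrnas],
                   size=min(5, config.n_mrna - len(planted_mrnas)), replace=False)
    ) if config.n_mrna > len(planted_mrnas) else []
    disease_genes = frozenset(planted_mrnas + extra_in_term)
    if disease_genes:
        terms[DISEASE_TERM] = ("synthetic disease-related process", disease_genes)
    size = min(config.term_size, config.n_mrna)
    for i in range(config.n_random_terms):
        genes = frozenset(rng.choice(mrna_ids, size=size, replace=False))
        terms[f"GO:SYN{1000 + i}"] = (f"synthetic background process {i}", genes)
    annotation = GeneSetAnnotation(terms)
    classes: dict[str, frozenset[str]] = {}
    if DISEASE_TERM in terms:
        classes[DISEASE_CLASS] = frozenset({DISEASE_TERM})
    if config.n_random_terms > 0:
        classes["unrelated"] = frozenset({"GO:SYN1000"})
    class_map = FunctionalClassMap(classes)

    truth = SyntheticTruth(
        planted_triplets=planted,
        planted_de_features=de_set,
        enriched_terms={DISEASE_TERM} if planted else set(),
    )
    return dataset, catalog, annotation, class_map, truth


def planted_pairs(truth: SyntheticTruth) -> list[tuple[str, str, str, str]]:
    """The three constituent pairs of every planted triplet.

    Returns tuples ``(feature_a, feature_b, pair_type, active_condition)``
    in the canonical pair ordering used by the correlation screen.
    """
    out = []
    for m, mi, l, cond in truth.planted_triplets:
        out.append((m, mi, "mRNA-miRNA", cond))
        out.append((mi, l, "miRNA-lncRNA", cond))
        out.append((m, l, "mRNA-lncRNA", cond))
    return out
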