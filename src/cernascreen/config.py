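"""Pipeline configuration: thresholds, permutation settings, file paths."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict

from .dataset import ConfigurationError

KERNELS = ("linear", "polynomial", "sigmoid", "radial")


@dataclass
class PipelineConfig:
    """All tunable settings of the screening pipeline.

    Thresholds default to the conventional values used throughout the
    strategy: a raw p of 0.05 for the differential-expression and
    per-condition correlation screens, FDR 0.05 for the
    differential-correlation and enrichment gates, and a strict AUC
    floor of 0.75 for biomarker selection.
    """

    # thresholds
    de_p: float = 0.05
    pair_p: float = 0.05
    diffcorr_fdr: float = 0.05
    enrich_fdr: float = 0.05
    auc_min: float = 0.75

    # permutation test
    n_permutations: int = 1_000_000
    permutation_mode: str = "auto"       # auto | sample | enumerate
    permutation_scheme: str = "label"    # label | pooled
    two_sided: bool = True
    perm_pseudocount: bool = False
    fdr_by_pair_type: bool = True

    # differential expression
    de_method: str = "nb-exact"          # nb-exact | welch-log

    # correlation
    corr_scale: str = "log2"             # log2 | linear

    # enrichment
    background: str = "annotation"       # annotation | measured
    require_de: bool = True

    # classification
    kernels: tuple[str, ...] = KERNELS
    svm_cost: float = 1.0
    poly_degree: int = 3
    joint_gate: str = "per_class"        # per_class | all_candidates
    n_baseline_draws: int = 100

    seed: int = 0

    # file paths (None = not configured; the CLI requires them)
    expression: str | None = None
    counts: str | None = None
    conditions: str | None = None
    catalog: str | None = None
    gene_sets: str | None = None
    class_map: str | None = None
    out_dir: str = "results"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("de_p", "pair_p", "diffcorr_fdr", "enrich_fdr", "auc_min"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigurationError(f"{name} must lie in (0, 1); got {v}")
        if self.n_permutations < 100:
            raise ConfigurationError(
                f"n_permutations must be >= 100; got {self.n_permutations}"
            )
        if self.permutation_mode not in ("auto", "sample", "enumerate"):
            raise ConfigurationError(
                f"permutation_mode must be auto|sample|enumerate; got "
                f"{self.permutation_mode!r}"
            )
        if self.permutation_scheme not in ("label", "pooled"):
            raise ConfigurationError(
                f"permutation_scheme must be label|pooled; got "
                f"{self.permutation_scheme!r}"
            )
        if self.de_method not in ("nb-exact", "welch-log"):
            raise ConfigurationError(
                f"de_method must be nb-exact|welch-log; got {self.de_method!r}"
            )
        if self.corr_scale not in ("log2", "linear"):
            raise ConfigurationError(
                f"corr_scale must be log2|linear; got {self.corr_scale!r}"
            )
        if self.background not in ("annotation", "measured"):
            raise ConfigurationError(
                f"background must be annotation|measured; got {self.background!r}"
            )
        if self.joint_gate not in ("per_class", "all_candidates"):
            raise ConfigurationError(
                f"joint_gate must be per_class|all_candidates; got "
                f"{self.joint_gate!r}"
            )
        self.kernels = tuple(self.kernels)
        bad = set(self.kernels) - set(KERNELS)
        if bad or not self.kernels:
            raise ConfigurationError(
                f"kernels must be a non-empty subset of {KERNELS}; got "
                f"{self.kernels}"
            )
        if self.svm_cost <= 0:
            raise ConfigurationError(f"svm_cost must be > 0; got {self.svm_cost}")
        if self.n_baseline_draws < 0:
            raise ConfigurationError("n_baseline_draws must be >= 0")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        """Build a config from a flat mapping; unknown keys fail fast."""
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(
                f"unknown configuration key(s): {', '.join(sorted(unknown))}"
            )
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kernels"] = list(self.kernels)
        return d

    def replace(self, **updates) -> "PipelineConfig":
        d = self.to_dict()
        d.update(updates)
        return PipelineConfig.from_dict(d)
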