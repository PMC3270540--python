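"""Run configuration: every tunable of the pipeline in one validated object.

Defaults follow the reference workflow: 8-bit grey levels (256 quantization
levels), a 3x3 averaging filter, zero edge threshold (any nonzero gradient is
an edge), the standard direction geometries, and the genetic-search /
cross-validation hyperparameters used throughout (GA seed 1, crossover 0.6,
mutation 0.033, population 20, generations 20; 5 stratified folds).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .errors import ValidationError

__all__ = ["GAParams", "RunConfig"]

_CLASSIFIER_SPECS = ("svm_poly3", "mlp", "adaboost_svm", "adaboost_mlp")


@dataclasses.dataclass(frozen=True)
class GAParams:
    """Genetic-search hyperparameters for CFS subset selection."""

    population_size: int = 20
    generations: int = 20
    crossover_prob: float = 0.6
    mutation_prob: float = 0.033
    seed: int = 1
    elitism: int = 1

    def validate(self) -> None:
        if self.population_size < 2:
            raise ValidationError("population_size must be >= 2")
        if self.generations < 1:
            raise ValidationError("generations must be >= 1")
        for name in ("crossover_prob", "mutation_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.elitism < self.population_size:
            raise ValidationError("elitism must be in [0, population_size)")


@dataclasses.dataclass(frozen=True)
class RunConfig:
    # image preparation
    levels: int = 256
    filter_kernel: int = 3
    # edge analysis
    edge_threshold: float = 0.0
    orientation_bin_deg: int = 1
    # cooccurrence geometry
    glcm2_distance: int = 1
    higher_order_distance: int = 2
    glcm3_mode: str = "avg"  # "avg" or a direction-set name such as "0_270"
    include_glcm5: bool = True
    glcm5_group: str = "0_180_90_270"
    eocm2: bool = True
    eocm3_mode: str = "avg"  # "avg", a set name, or "none"
    # other features
    laws_threshold_k: float = 1.0
    # learning phase
    ig_top_k: int = 10
    ga: GAParams = dataclasses.field(default_factory=GAParams)
    # validation phase
    cv_folds: int = 5
    eval_seed: int = 1
    classifiers: tuple[str, ...] = _CLASSIFIER_SPECS
    histogram_bins: int = 16

    def __post_init__(self) -> None:
        if not 2 <= self.levels <= 256:
            raise ValidationError(f"levels must be in [2, 256], got {self.levels}")
        if self.filter_kernel < 1 or self.filter_kernel % 2 == 0:
            raise ValidationError("filter_kernel must be odd and positive")
        if self.glcm2_distance < 1 or self.higher_order_distance < 1:
            raise ValidationError("displacement magnitudes must be >= 1")
        if self.orientation_bin_deg < 1 or 180 % self.orientation_bin_deg != 0:
            raise ValidationError("orientation_bin_deg must divide 180")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if self.ig_top_k < 0:
            raise ValidationError("ig_top_k must be >= 0")
        if self.histogram_bins < 1:
            raise ValidationError("histogram_bins must be >= 1")
        for spec in self.classifiers:
            if spec not in _CLASSIFIER_SPECS:
                raise ValidationError(
                    f"unknown classifier {spec!r}; valid: {list(_CLASSIFIER_SPECS)}"
                )
        self.ga.validate()

    # --- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["classifiers"] = list(self.classifiers)
        d["schema_version"] = 1
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d.pop("schema_version", None)
        ga = d.pop("ga", None)
        kwargs = dict(d)
        if "classifiers" in kwargs:
            kwargs["classifiers"] = tuple(kwargs["classifiers"])
        if ga is not None:
            kwargs["ga"] = GAParams(**ga)
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ValidationError(f"bad configuration: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} is not a mapping")
        return cls.from_dict(data)
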