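"""Experiment configuration: YAML round-trip, validation, canned presets."""

from __future__ import annotations

import dataclasses
import hashlib
import json

import yaml

from .classifier import ClassifierConfig
from .evaluation import (
    A_SET,
    D_SET,
    H_SET,
    PipelineConfig,
    cubic_geometries,
    cuboid_h_fixed_geometries,
    d4_grid_geometries,
)

__all__ = [
    "ConfigError",
    "ExperimentConfig",
    "load_config",
    "save_config",
    "full_scale_config",
    "desk_scale_config",
]

_FAMILIES = ("cubic", "cuboid_h_fixed", "d4_grid")


class ConfigError(ValueError):
    """Invalid experiment configuration."""


@dataclasses.dataclass(frozen=True)
class ExperimentConfig:
    """One full sweep experiment, ready to run and to serialize."""

    family: str = "cubic"
    a_values: tuple[float, ...] = A_SET
    h_values: tuple[float, ...] = H_SET
    d_values: tuple[float, ...] = D_SET
    fixed_h: float = 0.5   # cuboid_h_fixed family
    fixed_d: float = 4.0   # d4_grid family
    n_per_class: int = 1000
    sigma: float | None = None
    sigma_fraction: float = 0.1
    use_interpolated: bool = False
    classifier: ClassifierConfig = dataclasses.field(default_factory=ClassifierConfig)
    replicates: int = 1
    master_seed: int = 0
    label: str = "desk-scale"

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigError(f"family must be one of {_FAMILIES}, got {self.family!r}")
        for name in ("a_values", "h_values", "d_values"):
            values = getattr(self, name)
            if not values or any(v <= 0 for v in values):
                raise ConfigError(f"{name} must be non-empty and positive, got {values}")
        if self.n_per_class < 1:
            raise ConfigError("n_per_class must be >= 1")
        if self.sigma is not None and self.sigma <= 0:
            raise ConfigError(f"sigma must be positive, got {self.sigma}")
        if not 0 < self.sigma_fraction:
            raise ConfigError("sigma_fraction must be positive")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if self.master_seed is None:
            raise ConfigError("master_seed is required")

    def geometries(self) -> list[tuple[float, float, float]]:
        if self.family == "cubic":
            return cubic_geometries(self.a_values, self.d_values)
        if self.family == "cuboid_h_fixed":
            return cuboid_h_fixed_geometries(self.fixed_h, self.a_values, self.d_values)
        return d4_grid_geometries(self.fixed_d, self.a_values, self.h_values)

    def pipeline(self) -> PipelineConfig:
        return PipelineConfig(
            n_per_class=self.n_per_class,
            sigma=self.sigma,
            sigma_fraction=self.sigma_fraction,
            classifier=self.classifier,
            use_interpolated=self.use_interpolated,
        )

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        data["a_values"] = list(self.a_values)
        data["h_values"] = list(self.h_values)
        data["d_values"] = list(self.d_values)
        data["classifier"]["block_layers"] = list(self.classifier.block_layers)
        return data

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _from_dict(data: dict) -> ExperimentConfig:
    data = dict(data)
    known = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    classifier = data.pop("classifier", None)
    if classifier is not None:
        classifier = dict(classifier)
        if "block_layers" in classifier:
            classifier["block_layers"] = tuple(classifier["block_layers"])
        try:
            data["classifier"] = ClassifierConfig(**classifier)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid classifier section: {exc}") from exc
    for name in ("a_values", "h_values", "d_values"):
        if name in data:
            data[name] = tuple(data[name])
    try:
        return ExperimentConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path) -> ExperimentConfig:
    """Read and validate a YAML experiment configuration."""
    with open(path) as f:
        data = yaml.safe_load(f)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a YAML mapping at top level")
    return _from_dict(data)


def save_config(config: ExperimentConfig, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config.to_dict(), f, sort_keys=False)


def full_scale_config() -> ExperimentConfig:
    """The full-scale study configuration: 10,000 lesion sets per class, the
    complete geometry sets, 30-epoch dense CNN on interpolated 128x128 maps.
    Sized for a compute cluster, not a desk machine."""
    return ExperimentConfig(
        family="cubic",
        n_per_class=10_000,
        use_interpolated=True,
        classifier=ClassifierConfig(architecture="dense_se_cnn", epochs=30),
        replicates=1,
        label="cluster-scale",
    )


def desk_scale_config() -> ExperimentConfig:
    """Reduced sibling of :func:`full_scale_config`: 1,000 samples per class,
    logistic baseline on raw 6x6 maps — minutes on one CPU."""
    return ExperimentConfig(
        family="cubic",
        n_per_class=1000,
        use_interpolated=False,
        classifier=ClassifierConfig(architecture="logistic_baseline", epochs=10),
        replicates=1,
        label="desk-scale",
    )
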