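"""Noisy labelled field-map datasets for the lesion classifier.

Noiseless array readouts are paired one-to-one with Gaussian noise matrices:
noise matrix *i* is added both to the single normal readout and to abnormal
readout *i*, producing a matched normal/abnormal pair that differs only by
the lesion contribution.  Maps may be kept raw (6x6) or upsampled to
128x128 by bicubic spline interpolation over the sensor-centre lattice.
The train/validation split takes the first 80% of each class in pair order
(no shuffling, no cross-validation), so both members of a pair always land
in the same split.

The field has no absolute unit here, so the noise scale is fixed relative
to the signal: by default sigma is 10% of the maximum absolute noiseless
normal readout at the reference geometry (d = 2, a = h = 0.5 cm).
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Sequence

import h5py
import numpy as np
from scipy.interpolate import RectBivariateSpline

from .dipole import DEFAULT_K, HeartModel
from .sensors import ArrayConfig, MeasurementMatrix, SensorSpec, measure_array

__all__ = [
    "NoiseBank",
    "LabeledFieldMap",
    "Dataset",
    "generate_noise_bank",
    "assemble_final_measurements",
    "interpolate_map",
    "split_dataset",
    "calibrate_sigma",
    "dataset_arrays",
    "save_dataset",
    "load_dataset",
]

#: Sensor-centre coordinates (cm) that anchor the interpolation nodes.
DEFAULT_NODES = np.array([2.0, 6.0, 10.0, 14.0, 18.0, 22.0])

#: Reference geometry for the default noise calibration.
REFERENCE_GEOMETRY = {"a": 0.5, "h": 0.5, "d": 2.0}


@dataclasses.dataclass(frozen=True)
class NoiseBank:
    """i.i.d. Gaussian 6x6 noise matrices: entries ~ N(0, sigma^2)."""

    matrices: np.ndarray  # (n, rows, cols)
    sigma: float
    seed: int | None = None

    def __len__(self) -> int:
        return self.matrices.shape[0]


@dataclasses.dataclass(frozen=True)
class LabeledFieldMap:
    """One measurement map with its class label and originating pair index."""

    map: np.ndarray
    label: int  # 0 = normal, 1 = abnormal
    pair_index: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


@dataclasses.dataclass(frozen=True)
class Dataset:
    """Train/validation split of labelled field maps plus provenance attrs."""

    training: list[LabeledFieldMap]
    validation: list[LabeledFieldMap]
    attrs: dict = dataclasses.field(default_factory=dict)


def generate_noise_bank(n: int, sigma: float, rng) -> NoiseBank:
    """Draw ``n`` seeded-reproducible 6x6 Gaussian noise matrices."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return NoiseBank(matrices=gen.normal(0.0, sigma, size=(n, 6, 6)), sigma=sigma, seed=seed)


def _values(m) -> np.ndarray:
    return m.values if isinstance(m, MeasurementMatrix) else np.asarray(m, dtype=float)


def assemble_final_measurements(
    normal: MeasurementMatrix | np.ndarray,
    abnormal: Sequence[MeasurementMatrix | np.ndarray],
    bank: NoiseBank,
) -> list[LabeledFieldMap]:
    """Add noise matrix *i* to both the normal readout and abnormal readout *i*.

    Returns 2 * len(bank) labelled maps in pair order:
    (normal + noise_i, 0), (abnormal_i + noise_i, 1) for i = 0, 1, ...
    """
    if len(abnormal) != len(bank):
        raise ValueError(
            f"{len(abnormal)} abnormal readouts but {len(bank)} noise matrices"
        )
    normal_values = _values(normal)
    maps = []
    for i, (ab, noise) in enumerate(zip(abnormal, bank.matrices)):
        maps.append(LabeledFieldMap(map=normal_values + noise, label=0, pair_index=i))
        maps.append(LabeledFieldMap(map=_values(ab) + noise, label=1, pair_index=i))
    return maps


def interpolate_map(
    map6: np.ndarray,
    nodes: np.ndarray = DEFAULT_NODES,
    out_size: int = 128,
) -> np.ndarray:
    """Upsample a 6x6 map to ``out_size`` squared by bicubic spline.

    Nodes sit at the sensor centres; the output grid spans their extent
    ([2, 22] cm by default) with ``out_size`` uniform points per axis,
    endpoints included.  Splines reproduce the node values and any
    polynomial up to cubic degree exactly.
    """
    map6 = np.asarray(map6, dtype=float)
    if map6.shape != (len(nodes), len(nodes)):
        raise ValueError(f"expected a {len(nodes)}x{len(nodes)} map, got {map6.shape}")
    spline = RectBivariateSpline(nodes, nodes, map6, kx=3, ky=3, s=0)
    target = np.linspace(nodes[0], nodes[-1], out_size)
    return spline(target, target)


def split_dataset(
    maps: Sequence[LabeledFieldMap],
    train_fraction: float = 0.8,
    attrs: dict | None = None,
) -> Dataset:
    """First-80%-per-class split in pair order (16,000 / 4,000 at full scale).

    Both members of a pair share one pair index, so they always fall in the
    same split.  If the class counts differ from 10,000 each, a warning is
    emitted and the proportional first-80% rule is applied.
    """
    normals = [m for m in maps if m.label == 0]
    abnormals = [m for m in maps if m.label == 1]
    if len(normals) != 10_000 or len(abnormals) != 10_000:
        warnings.warn(
            f"class counts ({len(normals)}, {len(abnormals)}) differ from "
            "10,000 each; applying the proportional first-80% split",
            stacklevel=2,
        )
    training: list[LabeledFieldMap] = []
    validation: list[LabeledFieldMap] = []
    for cls in (normals, abnormals):
        cut = int(round(train_fraction * len(cls)))
        training.extend(cls[:cut])
        validation.extend(cls[cut:])
    return Dataset(training=training, validation=validation, attrs=dict(attrs or {}))


def calibrate_sigma(
    fraction: float = 0.1,
    k: float = DEFAULT_K,
    main_model: HeartModel | None = None,
) -> float:
    """Noise sigma = fraction x max|noiseless normal readout| at the reference
    geometry (d = 2, a = h = 0.5 cm)."""
    model = main_model if main_model is not None else HeartModel()
    spec = SensorSpec(a=REFERENCE_GEOMETRY["a"], h=REFERENCE_GEOMETRY["h"])
    config = ArrayConfig(d=REFERENCE_GEOMETRY["d"])
    readout = measure_array(model, config, spec, k=k)
    return fraction * float(np.abs(readout.values).max())


def dataset_arrays(
    split: Sequence[LabeledFieldMap], interpolated: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Stack one split into (X, y) arrays, optionally upsampling to 128x128."""
    if interpolated:
        X = np.stack([interpolate_map(m.map) for m in split])
    else:
        X = np.stack([m.map for m in split])
    y = np.array([m.label for m in split], dtype=np.int64)
    return X, y


def save_dataset(dataset: Dataset, path) -> None:
    """Write the dataset to HDF5 (groups /train and /val: maps, labels, pairs)."""
    with h5py.File(path, "w") as f:
        for name, split in (("train", dataset.training), ("val", dataset.validation)):
            grp = f.create_group(name)
            grp.create_dataset("maps", data=np.stack([m.map for m in split]))
            grp.create_dataset("labels", data=np.array([m.label for m in split]))
            grp.create_dataset("pairs", data=np.array([m.pair_index for m in split]))
        for key, value in dataset.attrs.items():
            f.attrs[key] = value


def load_dataset(path) -> Dataset:
    """Inverse of :func:`save_dataset`."""
    with h5py.File(path, "r") as f:
        splits = {}
        for name in ("train", "val"):
            grp = f[name]
            maps = grp["maps"][...]
            labels = grp["labels"][...]
            pairs = grp["pairs"][...]
            splits[name] = [
                LabeledFieldMap(map=maps[i], label=int(labels[i]), pair_index=int(pairs[i]))
                for i in range(maps.shape[0])
            ]
        attrs = dict(f.attrs)
    return Dataset(training=splits["train"], validation=splits["val"], attrs=attrs)
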