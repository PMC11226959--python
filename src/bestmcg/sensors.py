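"""Virtual sensor arrays with cuboid effective domains.

A magnetometer does not sample the field at a point: it integrates over a
sensing volume (the vapour cell of an OPM, the pickup coil of a SQUID).
Here each sensor's effective domain is a cuboid of bottom edge ``a`` and
height ``h`` (cm), its bottom face sitting in a plane at perpendicular
distance ``d`` above the main-dipole plane.  The readout is the plain
average of the z-component of the field over a 1-mm lattice of field points
filling the cuboid.

Lattice conventions
-------------------
The x-y field points are the global 1-mm lattice of the torso rectangle
[0, 24] x [0, 24] cm restricted to the (closed, by default) square footprint
of the sensor.  The z planes are ``d + k * 0.1`` cm for ``k = 0 .. 10h - 1``,
i.e. the half-open interval [d, d + h).  With these conventions the smallest
0.5 x 0.5 x 0.5 cm sensor at d = 2 contains exactly 125 field points on the
planes z = 2.0 .. 2.4 cm.  All lattice membership tests run on integers in
0.1-mm units so floating-point never decides whether an edge point is in.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from collections.abc import Sequence

import numpy as np

from .dipole import DEFAULT_K, HeartModel, LesionSet, superposed_bz

try:  # numba accelerates the batched readout kernel; numpy path works without it
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "TORSO_XY",
    "SensorSpec",
    "ArrayConfig",
    "FieldPointGrid",
    "MeasurementMatrix",
    "ConfigurationError",
    "sensor_centers",
    "field_point_grid",
    "array_field_points",
    "measure_sensor",
    "measure_array",
    "measure_models",
]

#: Torso rectangle in the x-y plane, cm.
TORSO_XY = ((0.0, 24.0), (0.0, 24.0))

_MM = 0.1  # lattice pitch, cm


class ConfigurationError(ValueError):
    """Invalid sensor/array geometry."""


def _to_mm(value: float, name: str) -> int:
    """Convert cm to integer 1-mm units, requiring an exact multiple of 0.1 cm."""
    scaled = value / _MM
    nearest = round(scaled)
    if abs(scaled - nearest) > 1e-6:
        raise ConfigurationError(
            f"{name} = {value} cm is not a multiple of the 0.1 cm lattice pitch"
        )
    return int(nearest)


@dataclasses.dataclass(frozen=True)
class SensorSpec:
    """Cuboid effective domain: bottom edge ``a`` and height ``h``, cm."""

    a: float
    h: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.h > 0):
            raise ConfigurationError(f"a and h must be positive, got a={self.a}, h={self.h}")
        _to_mm(self.a, "a")
        _to_mm(self.h, "h")

    @property
    def a_mm(self) -> int:
        return _to_mm(self.a, "a")

    @property
    def h_mm(self) -> int:
        return _to_mm(self.h, "h")


@dataclasses.dataclass(frozen=True)
class ArrayConfig:
    """Placement of the sensor array above the torso.

    ``d`` is the perpendicular distance (cm) from the sensor-bottom plane to
    the main-dipole plane; sensors sit on a ``rows x cols`` grid with the
    given pitch, the first bottom-centre projecting to ``first_center``.
    """

    d: float
    rows: int = 6
    cols: int = 6
    pitch: float = 4.0
    first_center: tuple[float, float] = (2.0, 2.0)

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ConfigurationError(f"d must be positive, got {self.d}")
        _to_mm(self.d, "d")
        if self.rows < 1 or self.cols < 1:
            raise ConfigurationError("rows and cols must be >= 1")
        if self.pitch <= 0:
            raise ConfigurationError("pitch must be positive")


@dataclasses.dataclass(frozen=True)
class FieldPointGrid:
    """The 1-mm field-point lattice of one sensor's effective domain."""

    points: np.ndarray  # (n, 3) cm
    spec: SensorSpec
    center: tuple[float, float]
    d: float

    @property
    def n(self) -> int:
        return self.points.shape[0]


@dataclasses.dataclass(frozen=True)
class MeasurementMatrix:
    """One array readout: a rows x cols matrix of averaged Bz values."""

    values: np.ndarray
    spec: SensorSpec
    config: ArrayConfig
    model_id: str | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        expected = (self.config.rows, self.config.cols)
        if values.shape != expected:
            raise ValueError(f"values shape {values.shape} != {expected}")
        object.__setattr__(self, "values", values)


def sensor_centers(config: ArrayConfig) -> np.ndarray:
    """Bottom-centre x-y projections, row-major (x outer, y inner), (S, 2) cm.

    The default 6x6 / 4-cm-pitch configuration reproduces the lattice
    {2, 6, 10, 14, 18, 22}^2 starting at (2, 2) and ending at (22, 22).
    """
    x0, y0 = config.first_center
    xs = x0 + config.pitch * np.arange(config.rows)
    ys = y0 + config.pitch * np.arange(config.cols)
    (x_lo, x_hi), (y_lo, y_hi) = TORSO_XY
    if xs.min() < x_lo or xs.max() > x_hi or ys.min() < y_lo or ys.max() > y_hi:
        raise ConfigurationError(
            "sensor centers fall outside the torso rectangle "
            f"[{x_lo}, {x_hi}] x [{y_lo}, {y_hi}] cm"
        )
    grid = np.array([(x, y) for x in xs for y in ys])
    return grid


def _footprint_lattice_mm(center_cm: float, a_mm: int, closed: bool) -> np.ndarray:
    """Integer-mm lattice coordinates covered by a footprint edge.

    Works in doubled (0.5-mm) units so half-millimetre edges (odd ``a_mm``)
    stay exact integers.
    """
    c2 = round(center_cm / _MM * 2)  # centre in 0.5-mm units
    if abs(center_cm / _MM * 2 - c2) > 1e-6:
        raise ConfigurationError(
            f"sensor centre {center_cm} cm is not on the 0.5-mm half-lattice"
        )
    lo2 = c2 - a_mm
    hi2 = c2 + a_mm
    first = math.ceil(lo2 / 2)
    last = math.floor(hi2 / 2)
    if not closed and last * 2 == hi2:
        last -= 1
    return np.arange(first, last + 1)


def field_point_grid(
    spec: SensorSpec,
    center: tuple[float, float],
    d: float,
    closed: bool = True,
) -> FieldPointGrid:
    """Enumerate the 1-mm field points of one sensor's cuboid domain.

    ``closed`` selects whether an x-y footprint edge landing exactly on a
    lattice line includes that line (the default) or drops the upper edge.
    The z planes are always d + k * 0.1 cm, k = 0 .. 10h - 1.
    """
    a_mm = spec.a_mm
    cx, cy = center
    xs_mm = _footprint_lattice_mm(cx, a_mm, closed)
    ys_mm = _footprint_lattice_mm(cy, a_mm, closed)
    (x_lo, x_hi), (y_lo, y_hi) = TORSO_XY
    if (
        cx - spec.a / 2 < x_lo or cx + spec.a / 2 > x_hi
        or cy - spec.a / 2 < y_lo or cy + spec.a / 2 > y_hi
    ):
        warnings.warn(
            f"sensor footprint at centre ({cx}, {cy}) with a={spec.a} cm "
            "extends beyond the torso rectangle",
            stacklevel=2,
        )
    d_mm = _to_mm(d, "d")
    zs_mm = d_mm + np.arange(spec.h_mm)
    x, y, z = np.meshgrid(xs_mm, ys_mm, zs_mm, indexing="ij")
    points = np.column_stack([x.ravel(), y.ravel(), z.ravel()]).astype(float) * _MM
    return FieldPointGrid(points=points, spec=spec, center=(cx, cy), d=d)


def array_field_points(
    config: ArrayConfig, spec: SensorSpec, closed: bool = True
) -> np.ndarray:
    """Field points of every sensor in the array, stacked as (S, n, 3)."""
    grids = [
        field_point_grid(spec, tuple(c), config.d, closed=closed)
        for c in sensor_centers(config)
    ]
    return np.stack([g.points for g in grids])


def measure_sensor(
    model: HeartModel, grid: FieldPointGrid, k: float = DEFAULT_K
) -> float:
    """Averaged z-field readout: B = (1/n) sum_k Bz(point_k)."""
    if grid.n == 0:
        raise ValueError("empty field-point grid")
    positions, moments = model.positions_moments()
    return float(superposed_bz(grid.points, positions, moments, k).mean())


def measure_array(
    model: HeartModel,
    config: ArrayConfig,
    spec: SensorSpec,
    k: float = DEFAULT_K,
    closed: bool = True,
) -> MeasurementMatrix:
    """Readout matrix of the whole array; entry (i, j) follows sensor order."""
    pts = array_field_points(config, spec, closed=closed)
    n_sensors, n_points, _ = pts.shape
    positions, moments = model.positions_moments()
    bz = superposed_bz(pts.reshape(-1, 3), positions, moments, k)
    values = bz.reshape(n_sensors, n_points).mean(axis=1)
    return MeasurementMatrix(
        values=values.reshape(config.rows, config.cols), spec=spec, config=config
    )


def _mean_bz_per_sensor_numpy(
    flat_pts: np.ndarray,
    positions: np.ndarray,
    moments: np.ndarray,
    offsets: np.ndarray,
    n_sensors: int,
    n_per_sensor: int,
    k: float,
) -> np.ndarray:
    out = np.empty((offsets.size - 1, n_sensors))
    for s in range(offsets.size - 1):
        lo, hi = offsets[s], offsets[s + 1]
        bz = superposed_bz(flat_pts, positions[lo:hi], moments[lo:hi], k)
        out[s] = bz.reshape(n_sensors, n_per_sensor).mean(axis=1)
    return out


if _HAVE_NUMBA:

    @_njit(cache=True, fastmath=True)
    def _mean_bz_per_sensor_jit(flat_pts, positions, moments, offsets, n_sensors, n_per_sensor, k):  # pragma: no cover - exercised via measure_models
        n_sets = offsets.size - 1
        out = np.zeros((n_sets, n_sensors))
        for s in range(n_sets):
            for i in range(n_sensors):
                acc = 0.0
                base = i * n_per_sensor
                for p in range(n_per_sensor):
                    x = flat_pts[base + p, 0]
                    y = flat_pts[base + p, 1]
                    z = flat_pts[base + p, 2]
                    for m in range(offsets[s], offsets[s + 1]):
                        rx = x - positions[m, 0]
                        ry = y - positions[m, 1]
                        rz = z - positions[m, 2]
                        r2 = rx * rx + ry * ry + rz * rz
                        acc += (moments[m, 0] * ry - moments[m, 1] * rx) / (r2 * np.sqrt(r2))
                out[s, i] = k * acc / n_per_sensor
        return out


def _mean_bz_per_sensor(flat_pts, positions, moments, offsets, n_sensors, n_per_sensor, k):
    """Per-set, per-sensor averaged Bz for batches of dipole sets.

    Field points never coincide with dipoles in the supported geometries
    (sensor planes sit above the source region), so the batched kernels
    skip the explicit singularity guard that the scalar paths keep.
    """
    if _HAVE_NUMBA:
        return _mean_bz_per_sensor_jit(
            flat_pts, positions, moments, offsets, n_sensors, n_per_sensor, k
        )
    return _mean_bz_per_sensor_numpy(
        flat_pts, positions, moments, offsets, n_sensors, n_per_sensor, k
    )


def measure_models(
    main_model: HeartModel,
    lesion_sets: Sequence[LesionSet],
    config: ArrayConfig,
    spec: SensorSpec,
    k: float = DEFAULT_K,
    closed: bool = True,
) -> tuple[MeasurementMatrix, list[MeasurementMatrix]]:
    """Measure the normal model and every lesioned model on one array.

    Superposition makes this cheap: the main-dipole readout is computed once
    and each abnormal readout adds only that lesion set's contribution.
    """
    pts = array_field_points(config, spec, closed=closed)
    n_sensors, n_points, _ = pts.shape
    flat = pts.reshape(-1, 3)
    positions, moments = main_model.positions_moments()
    normal_flat = superposed_bz(flat, positions, moments, k)
    normal_values = normal_flat.reshape(n_sensors, n_points).mean(axis=1)
    shape = (config.rows, config.cols)
    normal = MeasurementMatrix(
        values=normal_values.reshape(shape), spec=spec, config=config, model_id="normal"
    )
    counts = [len(s) for s in lesion_sets]
    offsets = np.zeros(len(lesion_sets) + 1, dtype=np.int64)
    np.cumsum(counts, out=offsets[1:])
    all_pos = np.concatenate(
        [[dp.position for dp in s.dipoles] for s in lesion_sets]
    ).astype(float)
    all_mom = np.concatenate(
        [[dp.moment for dp in s.dipoles] for s in lesion_sets]
    ).astype(float)
    lesion_means = _mean_bz_per_sensor(
        np.ascontiguousarray(flat), all_pos, all_mom, offsets, n_sensors, n_points, k
    )
    abnormal = [
        MeasurementMatrix(
            values=(normal_values + lesion_means[i]).reshape(shape),
            spec=spec,
            config=config,
            model_id=f"abnormal_{i}",
        )
        for i in range(len(lesion_sets))
    ]
    return normal, abnormal
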