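"""Current-dipole sources and their superposed biomagnetic fields.

The heart is modelled phenomenologically: a single strong main dipole at a
fixed position generates the normal magnetocardiographic signal, and a
random collection of weak dipoles scattered around it represents tissue
lesions.  The magnetic field of a current dipole with moment ``rho`` at a
field point ``rf`` is

    B(rf) = k * (rho x r) / |r|^3,      r = rf - position,

where ``k`` absorbs the vacuum-permeability prefactor mu0 / (4 pi).  The
simulation works in arbitrary field units with ``k = 1`` by default:
absolute units cancel downstream because classification performance depends
only on the signal-to-noise ratio.

Positions are in centimetres throughout.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_K",
    "LESION_BOX",
    "MAX_LESION_DIPOLES",
    "CurrentDipole",
    "LesionSet",
    "HeartModel",
    "SingularFieldError",
    "main_dipole",
    "dipole_field",
    "model_field",
    "superposed_field",
    "superposed_bz",
    "sample_lesion_set",
    "sample_lesion_sets",
    "lesion_sets_to_csv",
    "lesion_sets_from_csv",
]

#: mu0 / (4 pi) in the simulation's arbitrary unit system.
DEFAULT_K = 1.0

#: Axis-aligned box (cm) inside which lesion dipoles are placed:
#: x in [10, 14], y in [10, 14], z in [-1, 1].
LESION_BOX = ((10.0, 14.0), (10.0, 14.0), (-1.0, 1.0))

#: Lesion dipole count is a uniform integer in 1..MAX_LESION_DIPOLES.
MAX_LESION_DIPOLES = 10

_MAIN_POSITION = (12.0, 12.0, 0.0)
_MAIN_ORIENTATION = (1.0, 0.0, 0.0)
_MAIN_INTENSITY = 10.0


class SingularFieldError(ValueError):
    """The field point coincides with a dipole position (1/r^3 singularity)."""


def _as_vec3(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must have finite components, got {arr}")
    arr.flags.writeable = False
    return arr


@dataclasses.dataclass(frozen=True)
class CurrentDipole:
    """Point current dipole: position (cm), unit orientation, intensity >= 0.

    The dipole moment is ``intensity * orientation``.
    """

    position: np.ndarray
    orientation: np.ndarray
    intensity: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", _as_vec3(self.position, "position"))
        orientation = _as_vec3(self.orientation, "orientation")
        norm = float(np.linalg.norm(orientation))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"orientation must be a unit vector, |o| = {norm!r}")
        object.__setattr__(self, "orientation", orientation)
        intensity = float(self.intensity)
        if not np.isfinite(intensity) or intensity < 0:
            raise ValueError(f"intensity must be finite and >= 0, got {intensity!r}")
        object.__setattr__(self, "intensity", intensity)

    @property
    def moment(self) -> np.ndarray:
        """Dipole moment vector ``intensity * orientation``."""
        return self.intensity * self.orientation


def main_dipole(intensity: float = _MAIN_INTENSITY) -> CurrentDipole:
    """The fixed main dipole of the normal heart: (12, 12, 0) cm, +x, intensity 10."""
    return CurrentDipole(_MAIN_POSITION, _MAIN_ORIENTATION, intensity)


@dataclasses.dataclass(frozen=True)
class LesionSet:
    """An ordered collection of 1-10 weak lesion dipoles plus its provenance seed."""

    dipoles: tuple[CurrentDipole, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        dipoles = tuple(self.dipoles)
        if not 1 <= len(dipoles) <= MAX_LESION_DIPOLES:
            raise ValueError(
                f"a lesion set holds 1-{MAX_LESION_DIPOLES} dipoles, got {len(dipoles)}"
            )
        for i, d in enumerate(dipoles):
            for axis, (lo, hi) in enumerate(LESION_BOX):
                if not lo <= d.position[axis] <= hi:
                    raise ValueError(
                        f"lesion dipole {i} position {d.position} outside the "
                        f"allowed box (axis {axis}: [{lo}, {hi}])"
                    )
            if not 0.0 < d.intensity <= 1.0:
                raise ValueError(
                    f"lesion dipole {i} intensity {d.intensity} outside (0, 1]"
                )
        object.__setattr__(self, "dipoles", dipoles)

    def __len__(self) -> int:
        return len(self.dipoles)


@dataclasses.dataclass(frozen=True)
class HeartModel:
    """Main dipole plus an optional lesion set; fields add by superposition."""

    main_dipole: CurrentDipole = dataclasses.field(default_factory=main_dipole)
    lesions: LesionSet | None = None

    @property
    def dipoles(self) -> tuple[CurrentDipole, ...]:
        if self.lesions is None:
            return (self.main_dipole,)
        return (self.main_dipole, *self.lesions.dipoles)

    def positions_moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Stacked (M, 3) position and moment arrays over all dipoles."""
        dipoles = self.dipoles
        positions = np.array([d.position for d in dipoles])
        moments = np.array([d.moment for d in dipoles])
        return positions, moments


def dipole_field(
    dipole: CurrentDipole, field_point, k: float = DEFAULT_K
) -> np.ndarray:
    """Magnetic field of one dipole at one field point: k (rho x r) / |r|^3."""
    rf = _as_vec3(field_point, "field_point")
    r = rf - dipole.position
    r3 = float(np.linalg.norm(r)) ** 3
    if r3 == 0.0:
        raise SingularFieldError(
            f"field point {rf} coincides with the dipole position"
        )
    return k * np.cross(dipole.moment, r) / r3


def superposed_field(
    points: np.ndarray,
    positions: np.ndarray,
    moments: np.ndarray,
    k: float = DEFAULT_K,
) -> np.ndarray:
    """Total field (N, 3) of M dipoles at N points, summed by superposition."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    moments = np.atleast_2d(np.asarray(moments, dtype=float))
    r = points[:, None, :] - positions[None, :, :]  # (N, M, 3)
    r2 = np.einsum("nmi,nmi->nm", r, r)
    if np.any(r2 == 0.0):
        n_idx, m_idx = np.argwhere(r2 == 0.0)[0]
        raise SingularFieldError(
            f"field point {points[n_idx]} coincides with dipole {m_idx}"
        )
    inv_r3 = r2 ** -1.5
    cross = np.cross(np.broadcast_to(moments[None, :, :], r.shape), r)
    return k * np.einsum("nmi,nm->ni", cross, inv_r3)


def superposed_bz(
    points: np.ndarray,
    positions: np.ndarray,
    moments: np.ndarray,
    k: float = DEFAULT_K,
) -> np.ndarray:
    """z-component of the superposed field at N points; the sensor readout core.

    Computed component-wise without materialising the (N, M, 3) displacement
    tensor, so large point batches stay cheap.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    moments = np.atleast_2d(np.asarray(moments, dtype=float))
    rx = points[:, 0, None] - positions[None, :, 0]
    ry = points[:, 1, None] - positions[None, :, 1]
    rz = points[:, 2, None] - positions[None, :, 2]
    r2 = rx * rx
    r2 += ry * ry
    r2 += rz * rz
    if np.any(r2 == 0.0):
        n_idx, m_idx = np.argwhere(r2 == 0.0)[0]
        raise SingularFieldError(
            f"field point {points[n_idx]} coincides with dipole {m_idx}"
        )
    # Bz = (mx * ry - my * rx) / |r|^3
    bz = moments[None, :, 0] * ry
    bz -= moments[None, :, 1] * rx
    bz /= r2 * np.sqrt(r2)
    return k * bz.sum(axis=1)


def model_field(model: HeartModel, field_point, k: float = DEFAULT_K) -> np.ndarray:
    """Superposed field of the whole heart model at one point."""
    rf = _as_vec3(field_point, "field_point")
    positions, moments = model.positions_moments()
    return superposed_field(rf[None, :], positions, moments, k)[0]


def _coerce_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    # Normalised 3D Gaussian: uniform on the unit sphere.
    while True:
        v = rng.standard_normal(3)
        norm = np.linalg.norm(v)
        if norm > 1e-12:
            return v / norm


def sample_lesion_set(rng, seed: int | None = None) -> LesionSet:
    """Draw one lesion set.

    Count ~ uniform{1..10}; each position coordinate uniform on the lesion
    box; orientation uniform on the unit sphere; intensity uniform on (0, 1].
    A draw landing exactly on the main-dipole position is rejected and
    redrawn (probability zero, guarded anyway).
    """
    rng = _coerce_rng(rng)
    count = int(rng.integers(1, MAX_LESION_DIPOLES + 1))
    dipoles = []
    main_pos = np.asarray(_MAIN_POSITION)
    while len(dipoles) < count:
        position = np.array([rng.uniform(lo, hi) for lo, hi in LESION_BOX])
        if np.array_equal(position, main_pos):
            continue
        orientation = _random_unit_vector(rng)
        intensity = 1.0 - rng.random()  # uniform on (0, 1]
        dipoles.append(CurrentDipole(position, orientation, intensity))
    return LesionSet(tuple(dipoles), seed=seed)


def sample_lesion_sets(n: int, rng) -> list[LesionSet]:
    """Draw ``n`` independent lesion sets; reproducible for a fixed seed."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = _coerce_rng(rng)
    return [sample_lesion_set(rng) for _ in range(n)]


_CSV_COLUMNS = ["set_id", "dipole_id", "x_cm", "y_cm", "z_cm", "ox", "oy", "oz", "intensity"]


def lesion_sets_to_csv(sets: Sequence[LesionSet], path) -> None:
    """Serialize lesion sets to CSV; floats carry 17 significant digits."""
    rows = []
    for set_id, lesion_set in enumerate(sets):
        for dipole_id, d in enumerate(lesion_set.dipoles):
            rows.append(
                (set_id, dipole_id, *d.position, *d.orientation, d.intensity)
            )
    frame = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    frame.to_csv(path, index=False, float_format="%.17g")


def lesion_sets_from_csv(path) -> list[LesionSet]:
    """Inverse of :func:`lesion_sets_to_csv`; round-trips exactly."""
    frame = pd.read_csv(path, float_precision="round_trip")
    sets = []
    for _, group in frame.groupby("set_id", sort=True):
        group = group.sort_values("dipole_id")
        dipoles = tuple(
            CurrentDipole(
                (row.x_cm, row.y_cm, row.z_cm),
                (row.ox, row.oy, row.oz),
                row.intensity,
            )
            for row in group.itertuples()
        )
        sets.append(LesionSet(dipoles))
    return sets
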