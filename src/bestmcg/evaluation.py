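"""Geometry sweeps, accuracy surfaces, and slope regressions.

A sensor geometry's score is the best-epoch validation accuracy of a
classifier trained on its simulated readouts.  Sweeping geometry parameters
(bottom edge ``a``, height ``h``, distance ``d``) yields an accuracy table;
the table is upsampled to a dense surface for visualisation and each
one-parameter slice is summarised by an ordinary-least-squares slope with a
two-tailed t-test on H0: beta1 = 0 (significance stars at 0.05 / 0.01 /
0.001).

Sweep families
--------------
``cubic``           a = h, swept over the printed a and d sets.
``cuboid_h_fixed``  h fixed (0.5 cm), a and d swept.
``d4_grid``         d fixed (4 cm), a and h swept on the full grid.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import RectBivariateSpline, RegularGridInterpolator

from .classifier import ClassifierConfig, train_classifier
from .datasets import (
    assemble_final_measurements,
    calibrate_sigma,
    generate_noise_bank,
    split_dataset,
)
from .dipole import DEFAULT_K, HeartModel, LesionSet, sample_lesion_sets
from .sensors import ArrayConfig, SensorSpec, measure_models

__all__ = [
    "A_SET",
    "H_SET",
    "D_SET",
    "SweepPoint",
    "AccuracyTable",
    "SurfaceGrid",
    "RegressionResult",
    "PipelineConfig",
    "cubic_geometries",
    "cuboid_h_fixed_geometries",
    "d4_grid_geometries",
    "run_geometry",
    "run_sweep",
    "interpolate_surface",
    "ols_slope_test",
    "significance_label",
    "slope_regression_protocol",
    "regression_frame",
]

logger = logging.getLogger(__name__)

#: Swept parameter values (cm).
A_SET = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0)
H_SET = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0)
D_SET = (2.0, 2.5, 3.0, 4.0, 5.0)


@dataclasses.dataclass(frozen=True)
class SweepPoint:
    """One (geometry, replicate) -> accuracy observation."""

    a: float
    h: float
    d: float
    accuracy: float
    seed: int
    replicate: int = 0


@dataclasses.dataclass(frozen=True)
class AccuracyTable:
    points: tuple[SweepPoint, ...]
    family: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family": self.family,
                "a_cm": [p.a for p in self.points],
                "h_cm": [p.h for p in self.points],
                "d_cm": [p.d for p in self.points],
                "replicate": [p.replicate for p in self.points],
                "seed": [p.seed for p in self.points],
                "accuracy": [p.accuracy for p in self.points],
            }
        )


@dataclasses.dataclass(frozen=True)
class SurfaceGrid:
    """Dense interpolated accuracy surface over two geometry axes."""

    x_name: str
    y_name: str
    x: np.ndarray
    y: np.ndarray
    values: np.ndarray  # (len(x), len(y))
    mode: str


@dataclasses.dataclass(frozen=True)
class RegressionResult:
    """One summary row: OLS slope of accuracy on a geometry parameter."""

    regressor: str
    control: str
    slope: float
    intercept: float
    stderr: float
    t: float
    p: float
    label: str
    n: int
    degenerate: bool = False


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Everything one geometry evaluation needs besides the geometry itself."""

    n_per_class: int = 1000
    sigma: float | None = None  # None -> calibrate from the reference geometry
    sigma_fraction: float = 0.1
    classifier: ClassifierConfig = dataclasses.field(default_factory=ClassifierConfig)
    use_interpolated: bool = False
    k: float = DEFAULT_K

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


def cubic_geometries(
    a_set: Sequence[float] = A_SET, d_set: Sequence[float] = D_SET
) -> list[tuple[float, float, float]]:
    """(a, h, d) triples with a = h: 7 sizes x 5 distances by default."""
    return [(a, a, d) for a in a_set for d in d_set]


def cuboid_h_fixed_geometries(
    h: float = 0.5,
    a_set: Sequence[float] = A_SET,
    d_set: Sequence[float] = D_SET,
) -> list[tuple[float, float, float]]:
    return [(a, h, d) for a in a_set for d in d_set]


def d4_grid_geometries(
    d: float = 4.0,
    a_set: Sequence[float] = A_SET,
    h_set: Sequence[float] = H_SET,
) -> list[tuple[float, float, float]]:
    return [(a, h, d) for a in a_set for h in h_set]


def run_geometry(
    a: float,
    h: float,
    d: float,
    pipeline: PipelineConfig,
    lesion_sets: Sequence[LesionSet],
    noise_bank,
    classifier_seed: int,
) -> float:
    """Measure, assemble, split and train for one geometry; return the score."""
    spec = SensorSpec(a=a, h=h)
    config = ArrayConfig(d=d)
    normal, abnormal = measure_models(
        HeartModel(), lesion_sets, config, spec, k=pipeline.k
    )
    maps = assemble_final_measurements(normal, abnormal, noise_bank)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # scaled-down class counts are intentional
        dataset = split_dataset(
            maps,
            attrs={
                "a": a, "h": h, "d": d,
                "sigma": noise_bank.sigma,
                "interpolated": pipeline.use_interpolated,
            },
        )
    cls_config = dataclasses.replace(pipeline.classifier, seed=classifier_seed)
    result = train_classifier(dataset, cls_config)
    return result.best_accuracy


def run_sweep(
    family: str,
    geometries: Sequence[tuple[float, float, float]],
    pipeline: PipelineConfig,
    replicates: int = 1,
    master_seed: int = 0,
) -> AccuracyTable:
    """Evaluate every geometry (x replicate) and tabulate the accuracies.

    Within one replicate the same lesion-set collection and the same noise
    bank are shared by every geometry, mirroring a single deposited set of
    dipole combinations and noise matrices evaluated on all arrays.  All
    randomness descends from ``master_seed``.
    """
    if not geometries:
        raise ValueError("no geometries to sweep")
    sigma = pipeline.sigma
    if sigma is None:
        sigma = calibrate_sigma(pipeline.sigma_fraction, k=pipeline.k)
        logger.info("calibrated noise sigma = %.6g", sigma)
    root = np.random.SeedSequence(master_seed)
    replicate_seeds = root.spawn(replicates)
    points = []
    for rep, rep_seq in enumerate(replicate_seeds):
        lesion_seq, noise_seq, *geo_seqs = rep_seq.spawn(2 + len(geometries))
        lesion_sets = sample_lesion_sets(
            pipeline.n_per_class, np.random.default_rng(lesion_seq)
        )
        bank = generate_noise_bank(
            pipeline.n_per_class, sigma, np.random.default_rng(noise_seq)
        )
        for (a, h, d), geo_seq in zip(geometries, geo_seqs):
            cls_seed = int(geo_seq.generate_state(1)[0] % (2**31))
            accuracy = run_geometry(a, h, d, pipeline, lesion_sets, bank, cls_seed)
            logger.info(
                "family=%s rep=%d a=%.2f h=%.2f d=%.2f accuracy=%.4f",
                family, rep, a, h, d, accuracy,
            )
            points.append(
                SweepPoint(a=a, h=h, d=d, accuracy=accuracy, seed=cls_seed, replicate=rep)
            )
    return AccuracyTable(points=tuple(points), family=family)


def _grid_from_table(
    table: AccuracyTable, x_name: str, y_name: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    frame = table.to_frame()
    col = {"a": "a_cm", "h": "h_cm", "d": "d_cm"}
    mean = frame.groupby([col[x_name], col[y_name]])["accuracy"].mean()
    xs = np.array(sorted({i[0] for i in mean.index}))
    ys = np.array(sorted({i[1] for i in mean.index}))
    values = np.full((len(xs), len(ys)), np.nan)
    for (xv, yv), acc in mean.items():
        values[np.searchsorted(xs, xv), np.searchsorted(ys, yv)] = acc
    if np.isnan(values).any():
        raise ValueError(
            "accuracy table does not cover a full rectangular grid of "
            f"({x_name}, {y_name}) values"
        )
    return xs, ys, values


def interpolate_surface(
    table: AccuracyTable,
    mode: str,
    x_range: tuple[float, float, int] | None = None,
    y_range: tuple[float, float, int] | None = None,
) -> SurfaceGrid:
    """Dense accuracy surface for visualisation.

    For the a-d families the x axis is d on [2, 5] with 301 nodes (300
    intervals) and the y axis is a on [0, 4] with 401 nodes (400 intervals);
    the d=4 grid family maps h and a each onto [0, 4] with 401 nodes.
    ``mode`` is ``"cubic"`` (bicubic spline; used for the cubic family) or
    ``"linear"`` (used for the cuboid families, where cubic overshoots at
    the edges).  Replicates are averaged per geometry before interpolation.
    """
    if mode not in ("linear", "cubic"):
        raise ValueError(f"mode must be 'linear' or 'cubic', got {mode!r}")
    if table.family == "d4_grid":
        x_name, y_name = "h", "a"
        x_range = x_range or (0.0, 4.0, 401)
        y_range = y_range or (0.0, 4.0, 401)
    else:
        x_name, y_name = "d", "a"
        x_range = x_range or (2.0, 5.0, 301)
        y_range = y_range or (0.0, 4.0, 401)
    xs, ys, values = _grid_from_table(table, x_name, y_name)
    if len(xs) < 2 or len(ys) < 2:
        raise ValueError(
            f"surface interpolation needs at least 2 distinct values per axis; "
            f"got {len(xs)} x {len(ys)}"
        )
    x_out = np.linspace(x_range[0], x_range[1], x_range[2])
    y_out = np.linspace(y_range[0], y_range[1], y_range[2])
    if mode == "cubic":
        kx = min(3, len(xs) - 1)
        ky = min(3, len(ys) - 1)
        spline = RectBivariateSpline(xs, ys, values, kx=kx, ky=ky, s=0)
        out = spline(x_out, y_out)
    else:
        interp = RegularGridInterpolator(
            (xs, ys), values, method="linear", bounds_error=False, fill_value=None
        )
        mesh = np.stack(np.meshgrid(x_out, y_out, indexing="ij"), axis=-1)
        out = interp(mesh)
    return SurfaceGrid(
        x_name=x_name, y_name=y_name, x=x_out, y=y_out, values=out, mode=mode
    )


def significance_label(p: float) -> str:
    """Star label: *** p<0.001, ** p<0.01, * p<0.05, else n.s. (strict)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value must lie in [0, 1], got {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def ols_slope_test(
    x: Sequence[float],
    y: Sequence[float],
    regressor: str = "x",
    control: str = "",
) -> RegressionResult:
    """OLS fit y = beta0 + beta1 x with a two-tailed t-test on the slope.

    SE(beta1) = sqrt(SSE / (n - 2) / Sxx); t = beta1 / SE; p comes from the
    exact t distribution with n - 2 degrees of freedom (n can be as small
    as 3 here, so no normal approximation).  A perfect fit (SSE = 0) is
    flagged degenerate with SE = 0, |t| = inf, p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("regressor x is constant")
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    residuals = y - (intercept + slope * x)
    sse = float(residuals @ residuals)
    # Perfect fits leave SSE at rounding-noise scale; treat as degenerate.
    scale = float(np.sum((y - ym) ** 2)) or 1.0
    if sse <= 1e-12 * scale:
        t = np.inf if slope > 0 else (-np.inf if slope < 0 else 0.0)
        p = 0.0 if slope != 0 else 1.0
        return RegressionResult(
            regressor=regressor, control=control, slope=slope, intercept=intercept,
            stderr=0.0, t=float(t), p=p, label=significance_label(p), n=n,
            degenerate=True,
        )
    stderr = np.sqrt(sse / (n - 2) / sxx)
    t = slope / stderr
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return RegressionResult(
        regressor=regressor, control=control, slope=slope, intercept=intercept,
        stderr=float(stderr), t=float(t), p=p, label=significance_label(p), n=n,
    )


def _slices(frame: pd.DataFrame, regress: str, control: str) -> list[RegressionResult]:
    col = {"a": "a_cm", "h": "h_cm", "d": "d_cm"}
    results = []
    for level in sorted(frame[col[control]].unique()):
        part = frame[frame[col[control]] == level]
        if part.shape[0] < 3 or part[col[regress]].nunique() < 3:
            logger.warning(
                "skipping control level %s = %g with %d points",
                control, level, part.shape[0],
            )
            continue
        results.append(
            ols_slope_test(
                part[col[regress]].to_numpy(),
                part["accuracy"].to_numpy(),
                regressor=regress,
                control=f"{control} = {level:g}",
            )
        )
    return results


def slope_regression_protocol(table: AccuracyTable) -> list[RegressionResult]:
    """All one-parameter slope regressions of a sweep family, in table order.

    a-d families: regress accuracy on a at each fixed d, then on d at each
    fixed a (5 + 7 = 12 rows at the default sets).  The d = 4 grid family:
    regress on a at each fixed h, then on h at each fixed a (7 + 7 = 14
    rows).  Control levels with fewer than 3 points are skipped with a
    warning.
    """
    frame = table.to_frame()
    if table.family == "d4_grid":
        return _slices(frame, "a", "h") + _slices(frame, "h", "a")
    return _slices(frame, "a", "d") + _slices(frame, "d", "a")


def regression_frame(results: Sequence[RegressionResult], sensor_type: str = "") -> pd.DataFrame:
    """Tabulate regression rows (slope, SE, t, p, stars) for reporting."""
    if not results:
        return pd.DataFrame(
            columns=["sensor_type", "regressor", "control", "slope", "std_error",
                     "t", "p_value", "significance", "n", "degenerate"]
        )
    return pd.DataFrame(
        {
            "sensor_type": sensor_type,
            "regressor": [r.regressor for r in results],
            "control": [r.control for r in results],
            "slope": [r.slope for r in results],
            "std_error": [r.stderr for r in results],
            "t": [r.t for r in results],
            "p_value": [r.p for r in results],
            "significance": [r.label for r in results],
            "n": [r.n for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )
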