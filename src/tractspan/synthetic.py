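"""Synthetic study generators with known ground truth.

Emulates the statistical structure a four-cohort lifespan study of white
matter bundle features presents to the analysis: an age-partitioned feature
table (infant, development, young adult, aging cohorts with non-overlapping
age ranges), smooth nonlinear ground-truth trajectories per bundle and
feature, an additive acquisition offset confined to the young-adult cohort,
an additive sex effect, Gaussian residual noise, and optional repeated
(longitudinal) sessions for infant subjects. Geometric fixtures — parametric
streamline bundles with analytically known shape and simple scalar volumes —
exercise the shape-feature and sampling stages.

Everything is deterministic given a seed; ground truth travels alongside the
generated data so recovery can be tested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .geometry import StreamlineBundle, VoxelGrid
from .sampling import ScalarVolume

__all__ = [
    "TruthRecord",
    "CohortSpec",
    "COHORT_AGE_BOUNDS",
    "TABLE1_PASS_QA",
    "default_cohorts",
    "generate_feature_table",
    "generate_bundle",
    "generate_scalar_volume",
    "default_truth",
    "write_truth",
    "read_truth",
]

#: Age bounds (years) of the four cohorts.
COHORT_AGE_BOUNDS: dict[str, tuple[float, float]] = {
    "infant": (0.03, 6.1),
    "development": (5.5, 21.9),
    "young_adult": (22.0, 37.0),
    "aging": (36.0, 100.0),
}

#: Published per-cohort session counts after quality assurance.
TABLE1_PASS_QA: dict[str, int] = {
    "infant": 388,
    "development": 622,
    "young_adult": 1062,
    "aging": 717,
}

_COHORT_ORDER = ("infant", "development", "young_adult", "aging")


@dataclass
class TruthRecord:
    """Ground-truth generating model for one bundle x feature.

    curve_family is one of:

    * ``poisson_like`` — f(a) = c0 + c1 * a * exp(-c2 * a), the classic
      rise-then-decline lifespan shape; params = (c0, c1, c2).
    * ``quadratic`` — f(a) = c0 + c1 * a + c2 * a^2; params = (c0, c1, c2).
    * ``spline`` — smooth cubic interpolation through control points;
      params = ((age1, value1), (age2, value2), ...).

    ``ya_offset`` is an additive acquisition offset applied only to
    young-adult cohort rows; ``sex_effect`` is added for female rows;
    ``noise_sd`` is the residual Gaussian standard deviation.
    """

    bundle_id: str
    feature: str
    curve_family: str
    params: tuple
    ya_offset: float = 0.0
    noise_sd: float = 0.0
    sex_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.curve_family not in ("poisson_like", "quadratic", "spline"):
            raise ValueError(f"unknown curve_family {self.curve_family!r}")
        probe = self.curve(np.linspace(0.0, 100.0, 201))
        if not np.all(np.isfinite(probe)):
            raise ValueError(
                f"truth curve for {self.bundle_id}/{self.feature} is not "
                "finite on [0, 100] years"
            )

    def curve(self, ages: np.ndarray) -> np.ndarray:
        """Evaluate the noise-free truth curve at ages (years)."""
        a = np.asarray(ages, dtype=float)
        if self.curve_family == "poisson_like":
            c0, c1, c2 = self.params
            return c0 + c1 * a * np.exp(-c2 * a)
        if self.curve_family == "quadratic":
            c0, c1, c2 = self.params
            return c0 + c1 * a + c2 * a**2
        pts = np.asarray(self.params, dtype=float)
        spline = CubicSpline(pts[:, 0], pts[:, 1], bc_type="natural")
        return spline(a)


@dataclass
class CohortSpec:
    """Sampling plan for one cohort: age bounds and subject/session counts."""

    cohort: str
    age_low: float
    age_high: float
    n_subjects: int
    sessions_per_subject: tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        if self.age_low >= self.age_high:
            raise ValueError("age_low must be < age_high")
        lo, hi = self.sessions_per_subject
        if lo < 1 or hi < lo:
            raise ValueError("invalid sessions_per_subject range")
        if hi > 1 and self.cohort != "infant":
            raise ValueError("repeated sessions are only modelled for the infant cohort")


def default_cohorts(
    n_per_cohort: int = 100, infant_sessions: tuple[int, int] = (1, 3)
) -> list[CohortSpec]:
    """Desk-scale cohort plan using the study's age partition."""
    specs = []
    for cohort in _COHORT_ORDER:
        lo, hi = COHORT_AGE_BOUNDS[cohort]
        specs.append(
            CohortSpec(
                cohort=cohort,
                age_low=lo,
                age_high=hi,
                n_subjects=n_per_cohort,
                sessions_per_subject=infant_sessions if cohort == "infant" else (1, 1),
            )
        )
    return specs


def generate_feature_table(
    truth: list[TruthRecord],
    cohorts: list[CohortSpec],
    seed: int,
) -> tuple[pd.DataFrame, list[TruthRecord]]:
    """Draw a long-format session x bundle feature table from ground truth.

    One row per session x bundle with one column per feature:
    value = curve(age) + sex_effect*1[F] + ya_offset*1[young_adult] + noise.
    Ages are uniform within cohort bounds; sex is 50/50; infant subjects may
    carry several sessions at increasing ages (increments of 0.5-1.5 y).
    Identical inputs and seed reproduce the table exactly.
    """
    if not truth:
        raise ValueError("no truth records supplied")
    rng = np.random.default_rng(seed)
    bundles = sorted({t.bundle_id for t in truth})
    features = sorted({t.feature for t in truth})
    by_key = {(t.bundle_id, t.feature): t for t in truth}

    sessions: list[dict] = []
    for spec in cohorts:
        for i in range(spec.n_subjects):
            subject = f"{spec.cohort}_s{i:04d}"
            sex = "F" if rng.random() < 0.5 else "M"
            lo_s, hi_s = spec.sessions_per_subject
            n_sess = int(rng.integers(lo_s, hi_s + 1))
            increments = rng.uniform(0.5, 1.5, size=n_sess - 1)
            total = float(increments.sum())
            base_hi = max(spec.age_low, spec.age_high - total)
            age = float(rng.uniform(spec.age_low, base_hi))
            ages = age + np.concatenate([[0.0], np.cumsum(increments)])
            ages = np.clip(ages, spec.age_low, spec.age_high)
            for j, a in enumerate(ages):
                sessions.append(
                    {
                        "subject_id": subject,
                        "session_id": f"{subject}_ses{j + 1:02d}",
                        "age": float(a),
                        "sex": sex,
                        "cohort": spec.cohort,
                    }
                )

    rows: list[dict] = []
    for sess in sessions:
        for bundle in bundles:
            row = dict(sess, bundle=bundle)
            for feat in features:
                t = by_key.get((bundle, feat))
                if t is None:
                    row[feat] = np.nan
                    continue
                value = float(t.curve(sess["age"]))
                if sess["sex"] == "F":
                    value += t.sex_effect
                if sess["cohort"] == "young_adult":
                    value += t.ya_offset
                if t.noise_sd > 0:
                    value += float(rng.normal(0.0, t.noise_sd))
                row[feat] = value
            rows.append(row)
    columns = ["subject_id", "session_id", "age", "sex", "cohort", "bundle"] + features
    table = pd.DataFrame(rows, columns=columns)
    return table, truth


# ---------------------------------------------------------------------------
# geometric fixtures


def _fit_grid(points: np.ndarray, voxel_size: float, margin: float) -> VoxelGrid:
    lo = points.min(axis=0) - margin
    hi = points.max(axis=0) + margin
    shape = np.maximum(np.ceil((hi - lo) / voxel_size).astype(int) + 1, 1)
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size
    affine[:3, 3] = lo
    return VoxelGrid(shape=tuple(shape), affine=affine)


def generate_bundle(
    shape: str,
    n_streamlines: int = 1,
    seed: int = 0,
    length: float = 100.0,
    radius: float = 5.0,
    arc_radius: float = 50.0,
    arc_angle: float = np.pi,
    spread: float = 20.0,
    voxel_size: float = 1.0,
    grid: VoxelGrid | None = None,
    bundle_id: str | None = None,
) -> StreamlineBundle:
    """Parametric streamline bundle with analytically known geometry.

    * ``straight_tube`` — parallel lines of length ``length`` along +z within
      a cylinder of radius ``radius``.
    * ``arc`` — concentric circular arcs of radius ``arc_radius`` (+/- up to
      ``radius``) subtending ``arc_angle`` radians in the x-y plane.
    * ``fan`` — streamlines sharing one tight end region and spreading over a
      width of ``spread`` mm at the other end.

    Vertex spacing is kept below half the voxel size. If no grid is supplied
    one is fitted around the geometry; a supplied grid must contain it.
    """
    if n_streamlines < 1:
        raise ValueError("n_streamlines must be >= 1")
    if length <= 0 or radius <= 0 or arc_radius <= 0:
        raise ValueError("lengths and radii must be positive")
    rng = np.random.default_rng(seed)
    step = voxel_size / 2.0 * 0.9
    streamlines: list[np.ndarray] = []

    if shape == "straight_tube":
        n_pts = max(int(np.ceil(length / step)) + 1, 2)
        z = np.linspace(0.0, length, n_pts)
        for i in range(n_streamlines):
            if i == 0:
                x0 = y0 = 0.0
            else:
                r = radius * np.sqrt(rng.random())
                theta = rng.uniform(0.0, 2.0 * np.pi)
                x0, y0 = r * np.cos(theta), r * np.sin(theta)
            pts = np.column_stack([np.full(n_pts, x0), np.full(n_pts, y0), z])
            streamlines.append(pts)
    elif shape == "arc":
        if n_streamlines == 1:
            radii = np.array([arc_radius])
        else:
            radii = arc_radius + np.linspace(-radius, radius, n_streamlines)
        for r in radii:
            n_pts = max(int(np.ceil(r * arc_angle / step)) + 1, 2)
            t = np.linspace(0.0, arc_angle, n_pts)
            pts = np.column_stack([r * np.cos(t), r * np.sin(t), np.zeros(n_pts)])
            streamlines.append(pts)
    elif shape == "fan":
        n_pts = max(int(np.ceil((length + spread) / step)) + 1, 2)
        t = np.linspace(0.0, 1.0, n_pts)[:, None]
        for i in range(n_streamlines):
            start = np.array(
                [rng.uniform(-1.0, 1.0), rng.uniform(-1.0, 1.0), 0.0]
            )
            frac = i / max(n_streamlines - 1, 1)
            end = np.array(
                [(frac - 0.5) * 2.0 * spread, rng.uniform(-1.0, 1.0), length]
            )
            streamlines.append(start + t * (end - start))
    else:
        raise ValueError(f"unknown bundle shape {shape!r}")

    all_pts = np.vstack(streamlines)
    if grid is None:
        grid = _fit_grid(all_pts, voxel_size, margin=2.0 * voxel_size)
    else:
        if not np.all(grid.contains(all_pts)):
            raise ValueError("generated geometry exceeds the supplied grid extent")
    return StreamlineBundle(
        streamlines=streamlines, bundle_id=bundle_id or shape, grid=grid
    )


def generate_scalar_volume(
    grid: VoxelGrid,
    field: str,
    value: float = 0.0,
    axis: int = 0,
    v1: float = 0.0,
    v2: float = 0.0,
    threshold_mm: float = 0.0,
    feature: str = "scalar",
) -> ScalarVolume:
    """Deterministic scalar volume on a grid.

    * ``constant`` — every voxel holds ``value``.
    * ``gradient`` — each voxel holds its centre's world coordinate (mm)
      along ``axis``.
    * ``two_region`` — ``v1`` where the world coordinate along ``axis`` is
      below ``threshold_mm``, else ``v2``.
    """
    idx = np.indices(grid.shape).reshape(3, -1).T
    centres = grid.voxel_to_world(idx)
    coord = centres[:, axis].reshape(grid.shape)
    if field == "constant":
        values = np.full(grid.shape, float(value))
    elif field == "gradient":
        values = coord.copy()
    elif field == "two_region":
        values = np.where(coord < threshold_mm, float(v1), float(v2))
    else:
        raise ValueError(f"unknown field type {field!r}")
    return ScalarVolume(values=values, grid=grid, feature=feature)


# ---------------------------------------------------------------------------
# a default synthetic study


def default_truth(
    bundles: tuple[str, ...] = ("AF_left", "CST_left", "CC_2", "OR_left", "ILF_left"),
    features: tuple[str, ...] = ("FA", "MD", "volume", "cortical_thickness"),
    noise_scale: float = 1.0,
) -> list[TruthRecord]:
    """A small default study: plausible lifespan curves per bundle x feature.

    Bundles share each feature's curve family but differ in amplitude and
    timing (deterministic per-bundle perturbations), so per-pathway rates of
    change genuinely vary — which the rate-coupling analyses require.
    """
    base: dict[str, dict] = {
        "FA": dict(
            curve_family="poisson_like",
            params=(0.32, 0.015, 0.055),
            ya_offset=0.02,
            noise_sd=0.02,
            sex_effect=-0.005,
        ),
        "MD": dict(  # um^2/ms; falls in development, rises in aging
            curve_family="quadratic",
            params=(1.05, -0.009, 0.00011),
            ya_offset=-0.03,
            noise_sd=0.03,
            sex_effect=0.01,
        ),
        "volume": dict(  # cm^3; rises, peaks in the 20s, declines
            curve_family="spline",
            params=((0.0, 10.0), (5.0, 20.0), (25.0, 26.0), (60.0, 24.0), (100.0, 18.0)),
            ya_offset=1.5,
            noise_sd=1.5,
            sex_effect=-1.0,
        ),
        "cortical_thickness": dict(  # mm; infant rise then slow decline
            curve_family="spline",
            params=((0.0, 1.9), (2.0, 2.6), (10.0, 2.55), (40.0, 2.45), (100.0, 2.15)),
            ya_offset=0.05,
            noise_sd=0.08,
            sex_effect=0.02,
        ),
    }
    truth = []
    for b, bundle in enumerate(bundles):
        for feat in features:
            if feat not in base:
                raise ValueError(f"no default truth for feature {feat!r}")
            cfg = dict(base[feat])
            scale = 1.0 + 0.08 * (b - (len(bundles) - 1) / 2.0)
            if cfg["curve_family"] == "spline":
                pts = tuple((a, v * scale) for a, v in cfg["params"])
                cfg["params"] = pts
            else:
                c = list(cfg["params"])
                c[1] *= scale  # vary the age-dependent part across bundles
                cfg["params"] = tuple(c)
            cfg["noise_sd"] *= noise_scale
            truth.append(TruthRecord(bundle_id=bundle, feature=feat, **cfg))
    return truth


def write_truth(truth: list[TruthRecord], path: str | Path) -> None:
    payload = [asdict(t) for t in truth]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_truth(path: str | Path) -> list[TruthRecord]:
    payload = json.loads(Path(path).read_text())
    records = []
    for item in payload:
        params = item["params"]
        if item["curve_family"] == "spline":
            params = tuple(tuple(p) for p in params)
        else:
            params = tuple(params)
        item["params"] = params
        records.append(TruthRecord(**item))
    return records
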