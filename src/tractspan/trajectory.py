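"""Covariate-adjusted restricted cubic spline (C-RCS) lifespan trajectories.

Each bundle x feature series is modelled as

    value = b0 + b1 * B1(age) + ... + b_{k-1} * B_{k-1}(age)
            + g * 1[sex = F] + noise

where B1(age) = age and B2..B_{k-1} are Harrell's restricted cubic spline
basis functions over k fixed knots (default 2, 4, 22, 35, 75, 90 years):
truncated cubics combined so the fit is a natural cubic spline — twice
continuously differentiable, and exactly linear below the first and above
the last knot. The nonlinear terms are normalised by (t_k - t_1)^2 to keep
the design well conditioned.

From a fitted model the module derives the curve, its analytic derivative
(difference per year), the derivative as a percentage of the fitted value
(percent difference per year), the age at the curve's peak or minimum, and
subject-level bootstrap uncertainty: curves are refit on resamples of
subjects (all sessions of a drawn subject travel together, which respects
the longitudinal infant cohort), giving pointwise 95% bands and percentile
confidence intervals for the extremum age.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_KNOTS",
    "DEFAULT_BINS",
    "RCSBasisSpec",
    "PipelineConfig",
    "TrajectoryModel",
    "Extremum",
    "BootstrapResult",
    "rcs_basis",
    "rcs_basis_derivative",
    "fit_trajectory",
    "predict_curve",
    "difference_per_year",
    "percent_difference_per_year",
    "find_extremum",
    "bootstrap_trajectory",
    "bin_rates",
]

#: Default knot ages (years).
DEFAULT_KNOTS: tuple[float, ...] = (2.0, 4.0, 22.0, 35.0, 75.0, 90.0)

#: Default cohort bins (years) for rate summaries.
DEFAULT_BINS: dict[str, tuple[float, float]] = {
    "infant": (0.0, 5.0),
    "development": (5.0, 21.0),
    "young_adult": (22.0, 35.0),
    "aging": (36.0, 100.0),
}


@dataclass(frozen=True)
class RCSBasisSpec:
    """Restricted cubic spline basis over fixed knots."""

    knots: tuple[float, ...] = DEFAULT_KNOTS

    def __post_init__(self) -> None:
        knots = tuple(float(t) for t in self.knots)
        object.__setattr__(self, "knots", knots)
        if len(knots) < 3:
            raise ValueError("need at least 3 knots")
        if any(b <= a for a, b in zip(knots, knots[1:])):
            raise ValueError(f"knots must be strictly increasing, got {knots}")

    @property
    def n_columns(self) -> int:
        return len(self.knots) - 1

    @property
    def normalization(self) -> float:
        return (self.knots[-1] - self.knots[0]) ** 2


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable knobs shared across the trajectory and association stages."""

    B: int = 200  # bootstrap replicates (10_000 reproduces the full design)
    resample_unit: str = "subject"
    ci_level: float = 0.95
    grid_step: float = 0.1  # years, extremum scan and band grid
    fdr_q: float = 0.05
    seed: int = 0
    knots: tuple[float, ...] = DEFAULT_KNOTS
    max_dropped_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")


def _plus_cube(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, 0.0) ** 3


def _plus_square(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, 0.0) ** 2


def rcs_basis(ages: np.ndarray, spec: RCSBasisSpec = RCSBasisSpec()) -> np.ndarray:
    """Design columns of the restricted cubic spline: (n, k-1) array.

    Column 0 is age itself; column j (j = 1..k-2) is

        [ (a-t_j)+^3 - (a-t_{k-1})+^3 (t_k-t_j)/(t_k-t_{k-1})
          + (a-t_k)+^3 (t_{k-1}-t_j)/(t_k-t_{k-1}) ] / (t_k-t_1)^2

    which vanishes below the first knot and is linear above the last.
    """
    a = np.asarray(ages, dtype=float)
    t = np.asarray(spec.knots)
    k = len(t)
    cols = [a]
    denom = t[k - 1] - t[k - 2]
    for j in range(k - 2):
        col = (
            _plus_cube(a - t[j])
            - _plus_cube(a - t[k - 2]) * (t[k - 1] - t[j]) / denom
            + _plus_cube(a - t[k - 1]) * (t[k - 2] - t[j]) / denom
        ) / spec.normalization
        cols.append(col)
    return np.column_stack(cols)


def rcs_basis_derivative(
    ages: np.ndarray, spec: RCSBasisSpec = RCSBasisSpec()
) -> np.ndarray:
    """Analytic d/d(age) of every basis column: (n, k-1) array."""
    a = np.asarray(ages, dtype=float)
    t = np.asarray(spec.knots)
    k = len(t)
    cols = [np.ones_like(a)]
    denom = t[k - 1] - t[k - 2]
    for j in range(k - 2):
        col = (
            3.0 * _plus_square(a - t[j])
            - 3.0 * _plus_square(a - t[k - 2]) * (t[k - 1] - t[j]) / denom
            + 3.0 * _plus_square(a - t[k - 1]) * (t[k - 2] - t[j]) / denom
        ) / spec.normalization
        cols.append(col)
    return np.column_stack(cols)


@dataclass
class TrajectoryModel:
    """A fitted C-RCS model for one bundle x feature."""

    basis: RCSBasisSpec
    coefficients: np.ndarray  # intercept, k-1 basis terms, covariates
    column_names: tuple[str, ...]
    covariates: tuple[str, ...]
    sex_reference: float  # fraction female used as prediction reference
    residual_sd: float
    n: int
    age_range: tuple[float, float]

    @property
    def n_basis(self) -> int:
        return self.basis.n_columns


def _design(
    ages: np.ndarray,
    sex_female: np.ndarray | None,
    spec: RCSBasisSpec,
    covariates: tuple[str, ...],
) -> tuple[np.ndarray, tuple[str, ...]]:
    cols = [np.ones_like(np.asarray(ages, dtype=float))]
    names = ["intercept", "age"]
    basis = rcs_basis(ages, spec)
    cols.append(basis[:, :1])
    for j in range(1, basis.shape[1]):
        cols.append(basis[:, j : j + 1])
        names.append(f"rcs_{j}")
    cols[0] = cols[0][:, None]
    if "sex" in covariates:
        cols.append(np.asarray(sex_female, dtype=float)[:, None])
        names.append("sex_F")
    X = np.hstack(cols)
    return X, tuple(names)


def _collinear_columns(X: np.ndarray, names: tuple[str, ...]) -> list[str]:
    """Name columns that lie (numerically) in the span of earlier columns."""
    bad = []
    for j in range(1, X.shape[1]):
        prev = X[:, :j]
        col = X[:, j]
        resid = col - prev @ np.linalg.lstsq(prev, col, rcond=None)[0]
        if np.linalg.norm(resid) < 1e-8 * max(np.linalg.norm(col), 1.0):
            bad.append(names[j])
    return bad


def fit_trajectory(
    data: pd.DataFrame,
    feature: str,
    spec: RCSBasisSpec = RCSBasisSpec(),
    covariates: tuple[str, ...] = ("sex",),
) -> TrajectoryModel:
    """Least-squares C-RCS fit of one feature against age (plus covariates).

    Rows with missing feature values are dropped. Raises on rank deficiency,
    naming the collinear design columns.
    """
    rows = data.dropna(subset=[feature])
    ages = rows["age"].to_numpy(dtype=float)
    y = rows[feature].to_numpy(dtype=float)
    sex_female = (
        (rows["sex"] == "F").to_numpy(dtype=float) if "sex" in covariates else None
    )
    X, names = _design(ages, sex_female, spec, covariates)
    if len(y) <= X.shape[1]:
        raise ValueError(
            f"need more than {X.shape[1]} rows to fit, got {len(y)}"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise ValueError(
            f"rank-deficient design for feature {feature!r}; collinear "
            f"columns: {bad or 'undetermined'}"
        )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = max(len(y) - X.shape[1], 1)
    return TrajectoryModel(
        basis=spec,
        coefficients=coef,
        column_names=names,
        covariates=tuple(covariates),
        sex_reference=float(sex_female.mean()) if sex_female is not None else 0.0,
        residual_sd=float(np.sqrt(resid @ resid / dof)),
        n=len(y),
        age_range=(float(ages.min()), float(ages.max())),
    )


def _check_ages(ages: np.ndarray) -> np.ndarray:
    a = np.atleast_1d(np.asarray(ages, dtype=float))
    if np.any((a < 0.0) | (a > 120.0)):
        raise ValueError("ages outside [0, 120] years are not supported")
    return a


def predict_curve(
    model: TrajectoryModel, ages: np.ndarray, sex: str | float = "average"
) -> np.ndarray:
    """Evaluate the fitted curve at ages.

    ``sex`` sets the covariate reference: "average" uses the observed
    fraction female from the training data (the cohort-mean curve), "M"/"F"
    a single sex, or a numeric fraction female.
    """
    a = _check_ages(ages)
    if sex == "average":
        frac_f = model.sex_reference
    elif sex == "M":
        frac_f = 0.0
    elif sex == "F":
        frac_f = 1.0
    else:
        frac_f = float(sex)
    basis = rcs_basis(a, model.basis)
    n_b = basis.shape[1]
    value = model.coefficients[0] + basis @ model.coefficients[1 : 1 + n_b]
    if "sex" in model.covariates:
        value = value + model.coefficients[1 + n_b] * frac_f
    return value


def difference_per_year(model: TrajectoryModel, ages: np.ndarray) -> np.ndarray:
    """Analytic derivative of the fitted curve (feature units per year)."""
    a = _check_ages(ages)
    dbasis = rcs_basis_derivative(a, model.basis)
    n_b = dbasis.shape[1]
    return dbasis @ model.coefficients[1 : 1 + n_b]


def percent_difference_per_year(
    model: TrajectoryModel, ages: np.ndarray, sex: str | float = "average"
) -> np.ndarray:
    """100 * derivative / fitted value (%/yr); NaN where the curve is 0."""
    fitted = predict_curve(model, ages, sex=sex)
    deriv = difference_per_year(model, ages)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * deriv / fitted
    pct = np.where(np.isfinite(pct), pct, np.nan)
    return pct


@dataclass(frozen=True)
class Extremum:
    """Age and kind of a trajectory's interior extremum (if any)."""

    age: float | None
    kind: str  # "peak", "minimum", or "none"
    value: float | None
    ci_low: float | None = None
    ci_high: float | None = None


def find_extremum(
    model: TrajectoryModel,
    age_range: tuple[float, float] | None = None,
    step: float = 0.1,
) -> Extremum:
    """Locate the curve's global interior extremum by a dense grid scan.

    Returns a peak when the global maximum lies strictly inside the range, a
    minimum when the global minimum does and no interior maximum exists, and
    ``kind="none"`` for curves monotone over the range (extremes only at the
    boundaries) — trajectories with no single well-defined maximum.
    """
    lo, hi = age_range if age_range is not None else model.age_range
    if hi <= lo:
        raise ValueError("empty age range")
    grid = np.arange(lo, hi + step / 2.0, step)
    values = predict_curve(model, grid)
    imax = int(np.argmax(values))
    imin = int(np.argmin(values))
    last = len(grid) - 1
    if 0 < imax < last:
        return Extremum(age=float(grid[imax]), kind="peak", value=float(values[imax]))
    if 0 < imin < last:
        return Extremum(age=float(grid[imin]), kind="minimum", value=float(values[imin]))
    return Extremum(age=None, kind="none", value=None)


@dataclass
class BootstrapResult:
    """Subject-level bootstrap of a trajectory fit."""

    age_grid: np.ndarray
    point_curve: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    extremum: Extremum
    extremum_ages: np.ndarray  # replicate argmax/argmin ages (matching kind)
    n_replicates: int
    n_dropped: int


def bootstrap_trajectory(
    data: pd.DataFrame,
    feature: str,
    spec: RCSBasisSpec | None = None,
    covariates: tuple[str, ...] = ("sex",),
    config: PipelineConfig = PipelineConfig(),
) -> BootstrapResult:
    """Pointwise CI bands and extremum-age CI from a subject bootstrap.

    Subjects are resampled with replacement (every session of a drawn
    subject is included), the model refit per replicate, and curves and
    extremum ages collected. Bands are pointwise percentiles at
    ``config.ci_level``; the extremum CI is the same percentile interval of
    replicate extremum ages over replicates that found the same kind of
    extremum as the point fit. Rank-deficient replicates are dropped and
    counted; more than ``config.max_dropped_fraction`` dropped is an error.
    """
    spec = spec if spec is not None else RCSBasisSpec(knots=config.knots)
    rng = np.random.default_rng(config.seed)
    model = fit_trajectory(data, feature, spec, covariates)
    lo, hi = model.age_range
    grid = np.arange(lo, hi + config.grid_step / 2.0, config.grid_step)
    point_curve = predict_curve(model, grid)
    point_ext = find_extremum(model, step=config.grid_step)

    # the design of a resample is a row-selection of the full design, so
    # build it (and the evaluation-grid design) once
    rows = data.dropna(subset=[feature])
    ages = rows["age"].to_numpy(dtype=float)
    y = rows[feature].to_numpy(dtype=float)
    sex_female = (
        (rows["sex"] == "F").to_numpy(dtype=float) if "sex" in covariates else None
    )
    X, _ = _design(ages, sex_female, spec, covariates)
    n_params = X.shape[1]
    grid_design, _ = _design(
        grid,
        np.full(len(grid), model.sex_reference),
        spec,
        covariates,
    )
    subject_codes, subjects = pd.factorize(rows["subject_id"], sort=False)
    order = np.argsort(subject_codes, kind="stable")
    sorted_codes = subject_codes[order]
    starts = np.searchsorted(sorted_codes, np.arange(len(subjects)))
    ends = np.searchsorted(sorted_codes, np.arange(len(subjects)), side="right")
    subject_rows = [order[s:e] for s, e in zip(starts, ends)]

    curves = np.empty((config.B, len(grid)))
    ext_ages: list[float] = []
    n_dropped = 0
    kept = 0
    last = len(grid) - 1
    for _ in range(config.B):
        draw = rng.integers(0, len(subjects), size=len(subjects))
        idx = np.concatenate([subject_rows[s] for s in draw])
        Xb, yb = X[idx], y[idx]
        coef, _, rank, _ = np.linalg.lstsq(Xb, yb, rcond=None)
        if rank < n_params:
            n_dropped += 1
            continue
        curve = grid_design @ coef
        curves[kept] = curve
        kept += 1
        if point_ext.kind != "none":
            imax = int(np.argmax(curve))
            imin = int(np.argmin(curve))
            if 0 < imax < last:
                kind, age = "peak", float(grid[imax])
            elif 0 < imin < last:
                kind, age = "minimum", float(grid[imin])
            else:
                kind, age = "none", None
            if kind == point_ext.kind:
                ext_ages.append(age)
    if n_dropped > config.max_dropped_fraction * config.B:
        raise ValueError(
            f"{n_dropped}/{config.B} bootstrap replicates were rank deficient"
        )
    curves = curves[:kept]
    alpha = (1.0 - config.ci_level) / 2.0
    band_low = np.quantile(curves, alpha, axis=0)
    band_high = np.quantile(curves, 1.0 - alpha, axis=0)
    ext_arr = np.asarray(ext_ages, dtype=float)
    extremum = point_ext
    if point_ext.kind != "none" and ext_arr.size > 0:
        extremum = Extremum(
            age=point_ext.age,
            kind=point_ext.kind,
            value=point_ext.value,
            ci_low=float(np.quantile(ext_arr, alpha)),
            ci_high=float(np.quantile(ext_arr, 1.0 - alpha)),
        )
    return BootstrapResult(
        age_grid=grid,
        point_curve=point_curve,
        band_low=band_low,
        band_high=band_high,
        extremum=extremum,
        extremum_ages=ext_arr,
        n_replicates=kept,
        n_dropped=n_dropped,
    )


def bin_rates(
    model: TrajectoryModel,
    bins: dict[str, tuple[float, float]] = DEFAULT_BINS,
    step: float = 0.1,
    sex: str | float = "average",
) -> dict[str, float]:
    """Mean percent difference per year within each cohort age bin.

    Bins are clipped to the model's fitted age range; a bin with no grid
    point inside the fitted range yields NaN.
    """
    lo_fit, hi_fit = model.age_range
    out: dict[str, float] = {}
    for name, (lo, hi) in bins.items():
        lo_c, hi_c = max(lo, lo_fit), min(hi, hi_fit)
        if hi_c <= lo_c:
            out[name] = float("nan")
            continue
        grid = np.arange(lo_c, hi_c + step / 2.0, step)
        pct = percent_difference_per_year(model, grid, sex=sex)
        out[name] = float(np.nanmean(pct))
    return out
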