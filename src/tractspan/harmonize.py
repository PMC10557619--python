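"""Continuity-based cohort harmonization.

When cohorts partition the age axis with no overlap, site-effect methods
that need covariate overlap (ComBat and friends) cannot be applied. If the
underlying lifespan trajectory is smooth, however, an acquisition offset in
one cohort shows up as a jump at the age boundaries it shares with its
neighbours. The estimator here makes that continuity assumption operational:
at each boundary age b, fit value ~ age linearly to the target-cohort rows
on its side of b within a window of +/- `window` years, and to the
neighbour-cohort rows on the other side; the discrepancy at b is the
difference of the two predictions, and the cohort's additive offset is the
mean discrepancy over its boundaries. Subtracting it restores continuity.

The estimator is unbiased when the trajectory is locally linear within the
window; for a curved trajectory the bias is bounded by
max|f''| * window^2 / 8 on each side (second-order Taylor remainder of the
linear fit at the window edge).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["OffsetEstimate", "estimate_offset", "apply_offset", "METADATA_COLUMNS"]

#: Columns of the feature-table schema that are not feature values.
METADATA_COLUMNS = ("subject_id", "session_id", "age", "sex", "cohort", "bundle")


@dataclass(frozen=True)
class OffsetEstimate:
    """Additive offset of one cohort for one bundle x feature."""

    bundle_id: str
    feature: str
    target_cohort: str
    offset: float  # feature units; subtract from target rows to harmonize
    boundary_discrepancies: tuple[float, ...]
    boundaries: tuple[float, ...]
    window: float  # years used on each side of a boundary
    n_target: int
    n_neighbor: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.offset):
            raise ValueError("offset must be finite")
        if self.window <= 0:
            raise ValueError("window must be positive")


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def _linear_prediction(ages: np.ndarray, values: np.ndarray, at: float) -> float:
    slope, intercept = np.polyfit(ages, values, 1)
    return float(slope * at + intercept)


def estimate_offset(
    table: pd.DataFrame,
    target_cohort: str = "young_adult",
    boundaries: tuple[float, ...] = (22.0, 36.0),
    window: float = 5.0,
    min_n: int = 5,
    pool_bundles: bool = False,
) -> list[OffsetEstimate]:
    """Estimate the target cohort's additive offset per bundle x feature.

    At each boundary the side the target cohort occupies is decided from its
    median age relative to the boundary; the fit windows are then
    [b - window, b] and [b, b + window] for the two sides. Requires at least
    ``min_n`` rows in every window. With ``pool_bundles`` one offset is
    estimated per feature from all bundles jointly and replicated per bundle.
    """
    if target_cohort not in set(table["cohort"]):
        raise ValueError(f"table has no rows for target cohort {target_cohort!r}")
    if window <= 0:
        raise ValueError("window must be positive")
    features = feature_columns(table)
    if not features:
        raise ValueError("table has no feature columns")

    groups: list[tuple[str, pd.DataFrame]]
    if pool_bundles:
        groups = [("__pooled__", table)]
    else:
        groups = [(b, g) for b, g in table.groupby("bundle", sort=True)]

    estimates: list[OffsetEstimate] = []
    for bundle_id, sub in groups:
        target = sub[sub["cohort"] == target_cohort]
        neighbor = sub[sub["cohort"] != target_cohort]
        target_median_age = float(target["age"].median())
        for feat in features:
            discrepancies = []
            n_t = n_n = 0
            for b in boundaries:
                target_above = target_median_age >= b
                if target_above:
                    t_rows = target[(target["age"] >= b) & (target["age"] <= b + window)]
                    n_rows = neighbor[(neighbor["age"] >= b - window) & (neighbor["age"] <= b)]
                else:
                    t_rows = target[(target["age"] >= b - window) & (target["age"] <= b)]
                    n_rows = neighbor[(neighbor["age"] >= b) & (neighbor["age"] <= b + window)]
                t_rows = t_rows.dropna(subset=[feat])
                n_rows = n_rows.dropna(subset=[feat])
                if len(t_rows) < min_n or len(n_rows) < min_n:
                    raise ValueError(
                        f"insufficient rows for offset estimation at boundary "
                        f"{b} y (bundle {bundle_id!r}, feature {feat!r}): "
                        f"{len(t_rows)} target / {len(n_rows)} neighbour rows "
                        f"in a {window} y window, need >= {min_n}"
                    )
                pred_t = _linear_prediction(
                    t_rows["age"].to_numpy(), t_rows[feat].to_numpy(), b
                )
                pred_n = _linear_prediction(
                    n_rows["age"].to_numpy(), n_rows[feat].to_numpy(), b
                )
                discrepancies.append(pred_t - pred_n)
                n_t += len(t_rows)
                n_n += len(n_rows)
            target_bundles = (
                sorted(sub["bundle"].unique()) if pool_bundles else [bundle_id]
            )
            for out_bundle in target_bundles:
                estimates.append(
                    OffsetEstimate(
                        bundle_id=out_bundle,
                        feature=feat,
                        target_cohort=target_cohort,
                        offset=float(np.mean(discrepancies)),
                        boundary_discrepancies=tuple(discrepancies),
                        boundaries=tuple(boundaries),
                        window=window,
                        n_target=n_t,
                        n_neighbor=n_n,
                    )
                )
    return estimates


def apply_offset(table: pd.DataFrame, estimates: list[OffsetEstimate]) -> pd.DataFrame:
    """Return a harmonized copy: target-cohort values shifted by -offset.

    Every bundle x feature present in the table must be covered by an
    estimate; all non-target rows are left untouched.
    """
    out = table.copy()
    features = feature_columns(table)
    lookup = {(e.bundle_id, e.feature): e for e in estimates}
    targets = {e.target_cohort for e in estimates}
    if not estimates:
        raise ValueError("no offset estimate supplied for any bundle x feature")
    if len(targets) != 1:
        raise ValueError("estimates must all target the same cohort")
    target_cohort = targets.pop()
    for bundle_id in table["bundle"].unique():
        for feat in features:
            est = lookup.get((bundle_id, feat))
            if est is None:
                raise ValueError(
                    f"no offset estimate for bundle {bundle_id!r}, feature {feat!r}"
                )
            sel = (out["cohort"] == target_cohort) & (out["bundle"] == bundle_id)
            out.loc[sel, feat] = out.loc[sel, feat] - est.offset
    return out


def estimates_to_frame(estimates: list[OffsetEstimate]) -> pd.DataFrame:
    """Tidy audit table of offset estimates."""
    rows = []
    for e in estimates:
        row = {
            "bundle": e.bundle_id,
            "feature": e.feature,
            "target_cohort": e.target_cohort,
            "offset": e.offset,
            "window": e.window,
            "n_target": e.n_target,
            "n_neighbor": e.n_neighbor,
        }
        for b, d in zip(e.boundaries, e.boundary_discrepancies):
            row[f"discrepancy_at_{b:g}y"] = d
        rows.append(row)
    return pd.DataFrame(rows)
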