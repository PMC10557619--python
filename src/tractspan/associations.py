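"""Cross-feature correlation structure and rate coupling.

Three families of questions about how bundle features relate:

* Across a population (sessions): Pearson correlation between every pair of
  features within one pathway and cohort, optionally as partial correlation
  controlling age and sex, with Benjamini-Hochberg FDR over the matrix.
* Across pathways (rates): the correlation, over bundles, between the
  per-year rates of change of two features within a cohort — do pathways
  changing fast in one feature change fast in another?
* Across life stages: for one feature, the correlation over bundles between
  development-cohort rates and aging-cohort rates (the "gain predicts loss"
  question), and linear/quadratic trends of rates along the
  anterior-posterior (MNI y) axis.

Missing entries (e.g. cortical features of mid-brain pathways) are dropped
pairwise; correlation p-values use the t transform with n - 2 (partial:
n - 2 - #controls) degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "CouplingResult",
    "GradientFit",
    "feature_correlations",
    "bh_fdr",
    "rate_coupling",
    "dev_aging_coupling",
    "ap_gradient",
]


@dataclass
class AssociationResult:
    """Feature x feature correlation matrix with p-values and an FDR mask."""

    matrix: pd.DataFrame
    pvalues: pd.DataFrame
    significant: pd.DataFrame  # boolean, BH-FDR at fdr_q over the matrix
    method: str
    fdr_q: float
    n: pd.DataFrame  # pairwise complete observations

    def tidy(self) -> pd.DataFrame:
        """Long-format (feature1, feature2, r, p, n, significant) rows."""
        feats = list(self.matrix.index)
        rows = []
        for i, f1 in enumerate(feats):
            for f2 in feats[i + 1 :]:
                rows.append(
                    {
                        "feature1": f1,
                        "feature2": f2,
                        "r": self.matrix.loc[f1, f2],
                        "p": self.pvalues.loc[f1, f2],
                        "n": self.n.loc[f1, f2],
                        "significant": bool(self.significant.loc[f1, f2]),
                    }
                )
        return pd.DataFrame(rows)


def _corr_pvalue(r: float, n: int, n_controls: int = 0) -> float:
    df = n - 2 - n_controls
    if df <= 0 or not np.isfinite(r):
        return float("nan")
    r = min(max(r, -1.0), 1.0)
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df))


def _residualize(y: np.ndarray, controls: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(y)), controls])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _pairwise_corr(
    data: pd.DataFrame,
    features: list[str],
    controls: np.ndarray | None,
    min_n: int,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    k = len(features)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    n_controls = controls.shape[1] if controls is not None else 0
    values = data[features].to_numpy(dtype=float)
    for i in range(k):
        n[i, i] = int(np.isfinite(values[:, i]).sum())
        for j in range(i + 1, k):
            ok = np.isfinite(values[:, i]) & np.isfinite(values[:, j])
            if controls is not None:
                ok &= np.all(np.isfinite(controls), axis=1)
            n[i, j] = n[j, i] = int(ok.sum())
            if ok.sum() < min_n:
                continue
            x, y = values[ok, i], values[ok, j]
            if np.std(x) == 0 or np.std(y) == 0:
                continue  # zero variance: correlation undefined, stays NaN
            if controls is not None:
                c = controls[ok]
                x = _residualize(x, c)
                y = _residualize(y, c)
                if np.std(x) == 0 or np.std(y) == 0:
                    continue
            rij = float(np.corrcoef(x, y)[0, 1])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = _corr_pvalue(rij, int(ok.sum()), n_controls)
    idx = pd.Index(features)
    return (
        pd.DataFrame(r, index=idx, columns=idx),
        pd.DataFrame(p, index=idx, columns=idx),
        pd.DataFrame(n, index=idx, columns=idx),
    )


def bh_fdr(pvalues: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask.

    Rejects the m' smallest p-values where m' = max{i : p(i) <= i q / m},
    with m counting only the finite entries; NaN entries are never rejected.
    """
    p = np.asarray(pvalues, dtype=float)
    flat = p.ravel()
    mask = np.zeros(flat.shape, dtype=bool)
    finite = np.isfinite(flat)
    if np.any((flat[finite] < 0) | (flat[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if finite.sum() > 0:
        rej, _, _, _ = multipletests(flat[finite], alpha=q, method="fdr_bh")[:4]
        mask[finite] = rej
    return mask.reshape(p.shape)


def feature_correlations(
    data: pd.DataFrame,
    features: list[str] | None = None,
    method: str = "pearson",
    controls: tuple[str, ...] = ("age", "sex"),
    fdr_q: float = 0.05,
    min_n: int = 4,
) -> AssociationResult:
    """Feature x feature (partial) correlations over sessions.

    ``method="pearson"`` correlates raw values; ``method="partial"``
    residualizes both features on the control columns (age, sex) first. The
    FDR family is all upper-triangle pairs of the matrix.
    """
    from .harmonize import feature_columns

    if features is None:
        features = feature_columns(data)
    if method not in ("pearson", "partial"):
        raise ValueError(f"unknown method {method!r}")
    ctrl = None
    if method == "partial":
        cols = []
        for c in controls:
            if c == "sex":
                cols.append((data["sex"] == "F").to_numpy(dtype=float))
            else:
                cols.append(data[c].to_numpy(dtype=float))
        ctrl = np.column_stack(cols)
    r, p, n = _pairwise_corr(data, list(features), ctrl, min_n)
    sig = _fdr_mask_upper(p, fdr_q)
    return AssociationResult(
        matrix=r, pvalues=p, significant=sig, method=method, fdr_q=fdr_q, n=n
    )


def _fdr_mask_upper(p: pd.DataFrame, q: float) -> pd.DataFrame:
    """Apply BH-FDR to the upper triangle and mirror it."""
    k = p.shape[0]
    iu = np.triu_indices(k, 1)
    mask = np.zeros((k, k), dtype=bool)
    if iu[0].size:
        rej = bh_fdr(p.to_numpy()[iu], q)
        mask[iu] = rej
        mask = mask | mask.T
    return pd.DataFrame(mask, index=p.index, columns=p.columns)


def rate_coupling(
    rates: pd.DataFrame,
    fdr_q: float = 0.05,
    min_pathways: int = 3,
) -> AssociationResult:
    """Correlation, over pathways, between per-year rates of two features.

    ``rates`` is a pathways x features table (one row per bundle). Pathways
    with a missing value in either feature are dropped pairwise; a pair with
    fewer than ``min_pathways`` complete pathways stays NaN.
    """
    features = list(rates.columns)
    r, p, n = _pairwise_corr(rates, features, None, min_pathways)
    sig = _fdr_mask_upper(p, fdr_q)
    return AssociationResult(
        matrix=r, pvalues=p, significant=sig, method="pearson", fdr_q=fdr_q, n=n
    )


@dataclass(frozen=True)
class CouplingResult:
    """Correlation across pathways between two rate vectors."""

    r: float
    p: float
    n_pathways: int


def dev_aging_coupling(
    rates_dev: np.ndarray, rates_aging: np.ndarray
) -> CouplingResult:
    """Correlate one feature's per-pathway rates in development vs aging.

    Both vectors must share the bundle ordering; NaN pathways are dropped
    pairwise. Fewer than 3 complete pathways is an error.
    """
    x = np.asarray(rates_dev, dtype=float)
    y = np.asarray(rates_aging, dtype=float)
    if x.shape != y.shape:
        raise ValueError("rate vectors must share the bundle ordering and length")
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError(
            f"need >= 3 complete pathways, got {int(ok.sum())}"
        )
    r = float(np.corrcoef(x[ok], y[ok])[0, 1])
    return CouplingResult(r=r, p=_corr_pvalue(r, int(ok.sum())), n_pathways=int(ok.sum()))


@dataclass(frozen=True)
class GradientFit:
    """Linear and quadratic trends of per-pathway rates along MNI y."""

    slope: float
    slope_p: float
    quad_coefs: tuple[float, float, float]  # intercept, y, y^2
    quad_p: float  # p-value of the y^2 term
    n_bundles: int


def ap_gradient(rates: np.ndarray, coords_mm: np.ndarray) -> GradientFit:
    """Fit rate ~ y and rate ~ y + y^2 over bundles (y = MNI anterior axis).

    Returns the linear slope with its p-value and the quadratic fit with the
    p-value of its highest-order term.
    """
    import statsmodels.api as sm

    r = np.asarray(rates, dtype=float)
    y = np.asarray(coords_mm, dtype=float)
    ok = np.isfinite(r) & np.isfinite(y)
    r, y = r[ok], y[ok]
    if len(r) < 4:
        raise ValueError("need >= 4 complete bundles for linear + quadratic fits")
    if np.std(y) == 0:
        raise ValueError("anterior-posterior coordinates are collinear (constant)")
    lin = sm.OLS(r, sm.add_constant(y)).fit()
    Xq = sm.add_constant(np.column_stack([y, y**2]))
    quad = sm.OLS(r, Xq).fit()
    return GradientFit(
        slope=float(lin.params[1]),
        slope_p=float(lin.pvalues[1]),
        quad_coefs=tuple(float(c) for c in quad.params),
        quad_p=float(quad.pvalues[2]),
        n_bundles=len(r),
    )
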