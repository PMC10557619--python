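"""End-to-end orchestration: simulate -> harmonize -> fit -> associate.

The pipeline composes the stages in analysis order on a feature table
(generated synthetically or supplied as CSV), writing numeric outputs as
CSV/JSON plus a run manifest (config snapshot, output hashes, row counts,
timings) so a run is auditable and a rerun with the same config and seed is
hash-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import associations as assoc
from . import harmonize as harm
from . import synthetic
from . import trajectory as traj

__all__ = ["RunManifest", "run_pipeline", "summarize_table", "table_from_counts"]


@dataclass
class RunManifest:
    config: dict
    outputs: dict[str, dict]  # path -> {stage, sha256, rows}
    stage_seconds: dict[str, float]
    row_counts: dict[str, int]

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def summarize_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cohort subject/session counts and age ranges, plus pooled totals.

    Counts are over unique subjects and sessions (the table holds one row
    per session x bundle).
    """
    rows = []
    if len(table):
        for cohort, g in table.groupby("cohort", sort=True):
            rows.append(
                {
                    "cohort": cohort,
                    "n_subjects": g["subject_id"].nunique(),
                    "n_sessions": g["session_id"].nunique(),
                    "age_min": float(g["age"].min()),
                    "age_max": float(g["age"].max()),
                }
            )
    pooled = {
        "cohort": "pooled",
        "n_subjects": table["subject_id"].nunique() if len(table) else 0,
        "n_sessions": table["session_id"].nunique() if len(table) else 0,
        "age_min": float(table["age"].min()) if len(table) else float("nan"),
        "age_max": float(table["age"].max()) if len(table) else float("nan"),
    }
    rows.append(pooled)
    return pd.DataFrame(rows)


def table_from_counts(session_counts: dict[str, int]) -> pd.DataFrame:
    """Minimal feature table carrying given per-cohort session counts.

    Useful for reconciling published cohort tables: each session becomes one
    row (one subject per session, ages at the cohort bounds).
    """
    rows = []
    for cohort, n in session_counts.items():
        lo, hi = synthetic.COHORT_AGE_BOUNDS.get(cohort, (0.0, 100.0))
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"{cohort}_s{i:05d}",
                    "session_id": f"{cohort}_ses{i:05d}",
                    "age": lo if i == 0 else hi,
                    "sex": "M",
                    "cohort": cohort,
                    "bundle": "none",
                }
            )
    return pd.DataFrame(
        rows, columns=["subject_id", "session_id", "age", "sex", "cohort", "bundle"]
    )


def run_pipeline(
    out_dir: str | Path,
    config: traj.PipelineConfig = traj.PipelineConfig(),
    table: pd.DataFrame | None = None,
    truth: list[synthetic.TruthRecord] | None = None,
    n_per_cohort: int = 100,
    harmonize: bool = True,
    target_cohort: str = "young_adult",
    boundaries: tuple[float, ...] = (22.0, 36.0),
    window: float = 5.0,
    min_n: int = 3,
) -> RunManifest:
    """Run the full analysis and write outputs + manifest under ``out_dir``.

    With no ``table`` a synthetic study is generated from ``truth`` (default
    study if omitted). Stages: summary -> harmonization -> per bundle x
    feature C-RCS fits with bootstrap -> cohort-binned rates -> per-pathway
    feature correlations (raw and partial) -> rate coupling per cohort ->
    development vs aging coupling per feature.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, dict] = {}
    timings: dict[str, float] = {}
    row_counts: dict[str, int] = {}

    def register(path: Path, stage: str, rows: int | None = None) -> None:
        outputs[str(path.relative_to(out))] = {
            "stage": stage,
            "sha256": _sha256(path),
            "rows": rows,
        }

    # --- stage 1: input table -------------------------------------------
    t0 = time.perf_counter()
    if table is None:
        if truth is None:
            truth = synthetic.default_truth()
        cohorts = synthetic.default_cohorts(n_per_cohort=n_per_cohort)
        table, truth = synthetic.generate_feature_table(truth, cohorts, config.seed)
        truth_path = out / "truth.json"
        synthetic.write_truth(truth, truth_path)
        register(truth_path, "simulate")
    table_path = out / "feature_table.csv"
    table.to_csv(table_path, index=False)
    register(table_path, "simulate", len(table))
    row_counts["feature_table"] = len(table)

    summary = summarize_table(table)
    summary_path = out / "summary.csv"
    summary.to_csv(summary_path, index=False)
    register(summary_path, "summarize", len(summary))
    timings["simulate"] = time.perf_counter() - t0

    # --- stage 2: harmonization -----------------------------------------
    t0 = time.perf_counter()
    if harmonize and target_cohort in set(table["cohort"]):
        estimates = harm.estimate_offset(
            table, target_cohort=target_cohort, boundaries=boundaries,
            window=window, min_n=min_n,
        )
        offsets = harm.estimates_to_frame(estimates)
        offsets_path = out / "offsets.csv"
        offsets.to_csv(offsets_path, index=False)
        register(offsets_path, "harmonize", len(offsets))
        harmonized = harm.apply_offset(table, estimates)
    else:
        harmonized = table
    harmonized_path = out / "harmonized.csv"
    harmonized.to_csv(harmonized_path, index=False)
    register(harmonized_path, "harmonize", len(harmonized))
    row_counts["harmonized"] = len(harmonized)
    timings["harmonize"] = time.perf_counter() - t0

    # --- stage 3: trajectories ------------------------------------------
    t0 = time.perf_counter()
    spec = traj.RCSBasisSpec(knots=config.knots)
    features = harm.feature_columns(harmonized)
    curves_dir = out / "curves"
    curves_dir.mkdir(exist_ok=True)
    rate_rows = []
    model_meta = {}
    n_curve_rows = 0
    for bundle_id, g in harmonized.groupby("bundle", sort=True):
        for feat in features:
            boot = traj.bootstrap_trajectory(g, feat, spec, config=config)
            model = traj.fit_trajectory(g, feat, spec)
            pct = traj.percent_difference_per_year(model, boot.age_grid)
            curve_df = pd.DataFrame(
                {
                    "age": boot.age_grid,
                    "fitted": boot.point_curve,
                    "band_low": boot.band_low,
                    "band_high": boot.band_high,
                    "difference_per_year": traj.difference_per_year(model, boot.age_grid),
                    "percent_difference_per_year": pct,
                }
            )
            curve_path = curves_dir / f"{bundle_id}__{feat}.csv"
            curve_df.to_csv(curve_path, index=False, float_format="%.10g")
            register(curve_path, "fit", len(curve_df))
            n_curve_rows += len(curve_df)
            model_meta[f"{bundle_id}/{feat}"] = {
                "extremum_kind": boot.extremum.kind,
                "extremum_age": boot.extremum.age,
                "extremum_ci": [boot.extremum.ci_low, boot.extremum.ci_high],
                "n": model.n,
                "residual_sd": model.residual_sd,
            }
            rates = traj.bin_rates(model, step=config.grid_step)
            for cohort_bin, rate in rates.items():
                rate_rows.append(
                    {
                        "bundle": bundle_id,
                        "feature": feat,
                        "cohort_bin": cohort_bin,
                        "percent_difference_per_year": rate,
                    }
                )
    models_path = out / "models.json"
    models_path.write_text(json.dumps(model_meta, indent=2, sort_keys=True))
    register(models_path, "fit", len(model_meta))
    rates_df = pd.DataFrame(rate_rows)
    rates_path = out / "cohort_rates.csv"
    rates_df.to_csv(rates_path, index=False, float_format="%.10g")
    register(rates_path, "fit", len(rates_df))
    row_counts["curves"] = n_curve_rows
    row_counts["cohort_rates"] = len(rates_df)
    timings["fit"] = time.perf_counter() - t0

    # --- stage 4: associations ------------------------------------------
    t0 = time.perf_counter()
    assoc_dir = out / "associations"
    assoc_dir.mkdir(exist_ok=True)
    n_assoc_rows = 0
    for bundle_id, g in harmonized.groupby("bundle", sort=True):
        for cohort, gc in g.groupby("cohort", sort=True):
            for method in ("pearson", "partial"):
                res = assoc.feature_correlations(
                    gc, features, method=method, fdr_q=config.fdr_q
                )
                tidy = res.tidy()
                path = assoc_dir / f"{bundle_id}__{cohort}__{method}.csv"
                tidy.to_csv(path, index=False, float_format="%.10g")
                register(path, "associate", len(tidy))
                n_assoc_rows += len(tidy)
    row_counts["associations"] = n_assoc_rows

    # rate coupling within each cohort bin, and development vs aging
    wide = rates_df.pivot_table(
        index="bundle", columns=["feature", "cohort_bin"],
        values="percent_difference_per_year",
    )
    coupling_rows = []
    for cohort_bin in traj.DEFAULT_BINS:
        cols = [c for c in wide.columns if c[1] == cohort_bin]
        sub = wide[cols]
        sub.columns = [c[0] for c in cols]
        if sub.shape[1] >= 2 and len(sub) >= 3:
            res = assoc.rate_coupling(sub, fdr_q=config.fdr_q)
            tidy = res.tidy()
            tidy.insert(0, "cohort_bin", cohort_bin)
            coupling_rows.append(tidy)
    if coupling_rows:
        coupling_df = pd.concat(coupling_rows, ignore_index=True)
        coupling_path = out / "rate_coupling.csv"
        coupling_df.to_csv(coupling_path, index=False, float_format="%.10g")
        register(coupling_path, "couple-rates", len(coupling_df))

    dev_aging_rows = []
    for feat in features:
        try:
            dev = wide[(feat, "development")].to_numpy()
            aging = wide[(feat, "aging")].to_numpy()
            c = assoc.dev_aging_coupling(dev, aging)
            dev_aging_rows.append(
                {"feature": feat, "r": c.r, "p": c.p, "n_pathways": c.n_pathways}
            )
        except (KeyError, ValueError):
            dev_aging_rows.append(
                {"feature": feat, "r": float("nan"), "p": float("nan"), "n_pathways": 0}
            )
    dev_aging_df = pd.DataFrame(dev_aging_rows)
    dev_aging_path = out / "dev_aging_coupling.csv"
    dev_aging_df.to_csv(dev_aging_path, index=False, float_format="%.10g")
    register(dev_aging_path, "couple-rates", len(dev_aging_df))
    timings["associate"] = time.perf_counter() - t0

    manifest = RunManifest(
        config={
            "B": config.B,
            "seed": config.seed,
            "knots": list(config.knots),
            "ci_level": config.ci_level,
            "grid_step": config.grid_step,
            "fdr_q": config.fdr_q,
            "harmonize": harmonize,
            "target_cohort": target_cohort,
            "boundaries": list(boundaries),
            "window": window,
            "n_per_cohort": n_per_cohort if table is None else None,
        },
        outputs=outputs,
        stage_seconds=timings,
        row_counts=row_counts,
    )
    manifest.write(out / "manifest.json")
    return manifest
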