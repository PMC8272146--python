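"""High-level orchestration: config -> dataset -> features -> reports.

Thin glue used by both the command-line interface and scripted analyses;
all heavy lifting lives in the bench, features and regression modules.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .bench import BenchDataset, bench_scene_factory, run_protocol
from .config import RunConfig, config_hash
from .features import FeatureSpec, build_feature_matrix, feature_columns, write_feature_csv
from .regression import (
    CVReport,
    ablation,
    cross_validate,
    epsilon_ball_curve,
    error_map,
    feature_importance,
    fit,
)

__all__ = [
    "dataset_from_config",
    "features_from_config",
    "split_features",
    "train_and_report",
]


def dataset_from_config(cfg: RunConfig, fast: Optional[bool] = None) -> BenchDataset:
    """Emulate the gaze protocol described by a run config."""
    geom = cfg.geometry
    factory = bench_scene_factory(
        eye=geom.eye.build(),
        ring=geom.ring.build(),
        occluder=geom.occluder.build(),
        gaze_range_deg=geom.gaze_range_deg,
    )
    return run_protocol(
        cfg.protocol.build(geom.ring),
        factory,
        cfg.burst.build(),
        cfg.noise.build(),
        seed=cfg.seed,
        fast=cfg.fast if fast is None else fast,
    )


def features_from_config(cfg: RunConfig, dataset: Optional[BenchDataset] = None) -> pd.DataFrame:
    """Full feature table for a config (emulating the dataset if needed)."""
    dataset = dataset or dataset_from_config(cfg)
    spec = cfg.features.build(cfg.protocol.group_size)
    return build_feature_matrix(dataset, spec)


def split_features(features: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """(X, Y) split of a feature table: feature columns and gaze labels."""
    cols = [c for c in features.columns if c.startswith(("tof_us_", "amp_"))]
    return features[cols], features[["theta_deg", "phi_deg"]].to_numpy(dtype=float)


def train_and_report(
    features: pd.DataFrame,
    cfg: RunConfig,
    out_dir: str | Path,
    ablate: bool = False,
    permutation_shuffles: int = 0,
) -> dict[str, CVReport]:
    """Train gbrt + linear, cross-validate, and write the report bundle.

    Writes cv_report.csv (Table-style summary), epsilon_curve.csv,
    feature_importance.csv, error_map.csv and summary.txt under
    ``out_dir``; returns the CV reports keyed by row label.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X, Y = split_features(features)
    gconf = cfg.regression.build()
    k = cfg.regression.folds
    seed = cfg.seed

    reports: dict[str, CVReport] = {
        "gbrt": cross_validate(X, Y, gconf, kind="gbrt", k=k, seed=seed),
        "linear": cross_validate(X, Y, gconf, kind="linear", k=k, seed=seed),
    }
    if ablate:
        reports["gbrt_tof_only"] = ablation(X, Y, gconf, family="tof", k=k, seed=seed)
        reports["gbrt_amp_only"] = ablation(X, Y, gconf, family="amp", k=k, seed=seed)
    if permutation_shuffles:
        from .regression import permutation_null

        null = permutation_null(
            X, Y, gconf, kind="gbrt", k=k, n_shuffles=permutation_shuffles, seed=seed
        )
        null.to_csv(out / "permutation_null.csv", index=False)

    rows = []
    for name, rep in reports.items():
        rows.append(
            {
                "model": name,
                "adj_r2_pct_mean": rep.adj_r2_mean.mean(),
                "adj_r2_pct_std": rep.adj_r2_mean.std(ddof=0),
                "rmse_deg_mean": rep.rmse_pooled.mean(),
                "rmse_deg_std": rep.rmse_pooled.std(ddof=0),
                "rmse_theta_deg": rep.rmse_theta.mean(),
                "rmse_phi_deg": rep.rmse_phi.mean(),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(out / "cv_report.csv", index=False)

    gbrt = reports["gbrt"]
    radii = np.arange(0.0, 5.0 + 1e-9, 0.05)
    curve = epsilon_ball_curve(gbrt.oof_pred, gbrt.truth, radii)
    pd.DataFrame({"radius_deg": curve.radii_deg, "fraction": curve.fraction}).to_csv(
        out / "epsilon_curve.csv", index=False
    )
    error_map(gbrt.oof_pred, gbrt.truth).to_csv(out / "error_map.csv", index=False)

    est = fit(X, Y, gconf, kind="gbrt", seed=seed)
    feature_importance(est).rename_axis("feature").to_csv(out / "feature_importance.csv")

    lines = ["model                adj-R2 (%)        RMSE (deg)"]
    for r in rows:
        lines.append(
            f"{r['model']:<20} {r['adj_r2_pct_mean']:5.1f} +/- {r['adj_r2_pct_std']:<6.1f} "
            f"{r['rmse_deg_mean']:.3f} +/- {r['rmse_deg_std']:.3f}"
        )
    lines.append("")
    lines.append(f"50% of estimates within {curve.radius_at(0.5):.2f} deg")
    lines.append(f"90% of estimates within {curve.radius_at(0.9):.2f} deg")
    lines.append(f"config hash: {config_hash(cfg)}  seed: {cfg.seed}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return reports
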