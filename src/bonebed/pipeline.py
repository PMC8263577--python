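"""End-to-end orchestration: simulate or ingest, detect levels, per-level
spatial statistics, clusters, fabric, taphonomy, aggregate report.

``run_pipeline`` is a pure function of its configuration: every stochastic
stage draws from a seed recorded in the run manifest, so re-running a
config reproduces the report byte for byte (timestamps excluded by
design — none are embedded).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .levels import (
    apply_hitl,
    classify_specimens,
    consensus_report,
    propose_levels,
    train_consensus,
)
from .orientation import circular_mean, fabric_by_cluster, plunge_profile
from .pointpattern import (
    PointPattern2D,
    Window,
    centered_l,
    dbscan,
    fit_intensity,
    hopkins_skellam,
    k_function,
    quadrat_csr_test,
    select_eps,
)
from .specimens import SpecimenTable, read_specimen_table
from .synthetic import SyntheticSiteConfig, simulate_site
from .taphonomy import compute_profile

__all__ = ["PipelineConfig", "run_pipeline", "to_jsonable"]


@dataclass
class PipelineConfig:
    """Configuration for a full run; every stochastic stage keys off
    ``seed``."""

    input_csv: str | None = None  # None -> simulate
    simulation: SyntheticSiteConfig = field(default_factory=SyntheticSiteConfig)
    seed: int = 0
    # level detection
    detect_levels: bool = True
    confidence_threshold: float = 0.80
    cv_folds: int = 3
    n_estimators: int = 500
    curation_overrides: list[dict] = field(default_factory=list)
    # spatial statistics
    spatial_stats: bool = True
    quadrat_grid: tuple[int, int] = (8, 8)
    nsim: int = 999
    r_max: float | None = None
    n_r: int = 50
    bandwidth: float | None = None
    eps: float | None = None  # None -> k-distance knee
    min_pts: int = 5
    # orientation
    orientations: bool = True
    flat_threshold: float = 10.0
    steep_threshold: float = 45.0
    # taphonomy
    taphonomy: bool = True


def to_jsonable(obj):
    """Recursively convert report objects to JSON-serialisable values."""
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return to_jsonable(obj.reset_index().to_dict(orient="records"))
    if isinstance(obj, np.ndarray):
        return to_jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, float) and np.isnan(obj):
        return None
    if hasattr(obj, "__dataclass_fields__"):
        return to_jsonable(asdict(obj))
    return obj


def _window_for(df: pd.DataFrame, margin: float = 0.05) -> Window:
    x, y = df["x"].to_numpy(float), df["y"].to_numpy(float)
    return Window(
        float(x.min() - margin), float(x.max() + margin),
        float(y.min() - margin), float(y.max() + margin),
    )


def _spatial_for_level(df: pd.DataFrame, cfg: PipelineConfig, seed: int) -> dict:
    pts = df[["x", "y"]].dropna().to_numpy(float)
    window = _window_for(df)
    pattern = PointPattern2D(pts, window)
    out: dict = {"n": pattern.n, "window_area_m2": window.area}
    rng = np.random.default_rng(seed)
    q = quadrat_csr_test(pattern, *cfg.quadrat_grid, nsim=cfg.nsim, seed=rng)
    out["quadrat"] = {
        "grid": list(q.grid), "chi2": q.chi2, "p_value": q.p_value, "nsim": q.nsim,
    }
    r_max = cfg.r_max or 0.25 * min(window.x1 - window.x0, window.y1 - window.y0)
    r = np.linspace(0, r_max, cfg.n_r)
    lam = fit_intensity(pattern, cfg.bandwidth)
    k_res = k_function(pattern, r, lam=lam.at_points, correction="border")
    out["k_inhom"] = {
        "r": r, "k_hat": k_res.k_hat, "k_csr": k_res.k_theo, "centered_l": centered_l(k_res),
        "intensity_bandwidth": lam.bandwidth,
    }
    hs = hopkins_skellam(pattern, m=min(100, pattern.n), seed=rng)
    out["hopkins_skellam"] = {
        "A": hs.A, "m": hs.m, "p_value": hs.p_value, "interpretation": hs.interpretation,
    }
    eps = cfg.eps if cfg.eps is not None else select_eps(pts, k=cfg.min_pts)
    cl = dbscan(pts, eps=eps, min_pts=cfg.min_pts)
    out["clusters"] = {
        "n_clusters": cl.n_clusters, "eps": eps, "min_pts": cfg.min_pts,
        "n_noise": int((cl.labels == 0).sum()), "labels": cl.labels,
    }
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the aggregate report dict
    (``to_jsonable``-able).  Any stage failure propagates with the stage
    name prefixed."""
    cfg = config
    report: dict = {}
    # -- input -------------------------------------------------------------
    if cfg.input_csv:
        table = read_specimen_table(cfg.input_csv)
    else:
        table = simulate_site(cfg.simulation, seed=cfg.seed)
    report["manifest"] = {
        "version": __version__,
        "seed": cfg.seed,
        "n_specimens": len(table),
        "input": cfg.input_csv or "simulated",
        "config_hash": hashlib.sha256(
            json.dumps(to_jsonable(asdict(cfg)), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
    }

    df = table.df
    level_col = None
    # -- level detection ---------------------------------------------------
    if cfg.detect_levels:
        try:
            bands = propose_levels(table)
            bands = apply_hitl(bands, cfg.curation_overrides)
            model = train_consensus(
                table, bands, cv_folds=cfg.cv_folds, seed=cfg.seed,
                n_estimators=cfg.n_estimators,
            )
            assignments, skipped = classify_specimens(
                model, table, threshold=cfg.confidence_threshold
            )
            rep = consensus_report(assignments)
            rep.n_skipped = len(skipped)
            report["levels"] = {
                "bands": [vars(b) for b in bands],
                "cv_accuracy": model.cv_accuracy,
                "consensus": rep,
            }
            label_by_id = {a.specimen_id: a.final_label or "" for a in assignments}
            level_col = df["specimen_id"].map(label_by_id).fillna("")
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage 'detect-levels' failed: {exc}") from exc
    elif (df["level"] != "").any():
        level_col = df["level"]

    levels = sorted(v for v in (level_col.unique() if level_col is not None else []) if v)
    per_level = {lv: df[level_col == lv] for lv in levels} if levels else {"all": df}

    # -- spatial + orientation per level ------------------------------------
    if cfg.spatial_stats:
        report["spatial"] = {}
        for i, (lv, sub) in enumerate(per_level.items()):
            if sub[["x", "y"]].dropna().shape[0] < max(10, cfg.min_pts + 1):
                report["spatial"][lv] = {"skipped": "too few located specimens"}
                continue
            try:
                report["spatial"][lv] = _spatial_for_level(sub, cfg, seed=cfg.seed + 1000 + i)
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(f"stage 'spatial-stats' ({lv}) failed: {exc}") from exc

    if cfg.orientations:
        report["orientation"] = {}
        for lv, sub in per_level.items():
            trend = sub["trend_deg"].dropna().to_numpy()
            if len(trend) < 4:
                report["orientation"][lv] = {"skipped": "too few oriented specimens"}
                continue
            s = circular_mean(trend, axial=True)
            entry = {
                "n": s.n, "mean_axis_deg": s.mean_deg, "resultant_length": s.resultant_length,
                "rayleigh_z": s.rayleigh_z, "p_value": s.p_value,
            }
            plunges = sub["plunge_deg"].dropna()
            if len(plunges):
                entry["plunge"] = plunge_profile(
                    plunges.to_numpy(), cfg.flat_threshold, cfg.steep_threshold
                )
            spatial_lv = report.get("spatial", {}).get(lv, {})
            if "clusters" in spatial_lv:
                located = sub[["x", "y"]].dropna().index
                entry["by_cluster"] = fabric_by_cluster(
                    sub.loc[located, "trend_deg"].to_numpy(),
                    sub.loc[located, "plunge_deg"].to_numpy(),
                    np.asarray(spatial_lv["clusters"]["labels"]),
                    level_id=lv,
                )
            report["orientation"][lv] = entry

    # -- taphonomy -----------------------------------------------------------
    if cfg.taphonomy:
        report["taphonomy"] = compute_profile(table).to_dict()

    return report


def write_report(report: dict, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "report.json"
    path.write_text(json.dumps(to_jsonable(report), indent=2, sort_keys=True))
    return path
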