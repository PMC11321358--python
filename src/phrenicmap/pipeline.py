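"""Scenario orchestration: calibrated reproduction and geometric end-to-end runs.

Two reproducible scenarios:

``calibrated``
    Draw replicate cohorts from the truncated-normal generator calibrated to
    the published per-category summaries, run the full diagnostics on each,
    and aggregate replicate means — the statistical reproduction of the
    published correlation, ROC and sensitivity/specificity panel.

``geometric``
    Full physical analogue: synthetic anatomy -> nerve rasterized into an
    attenuation volume -> threshold segmentation -> centerline extraction ->
    landmark + ICP registration of the map frame (optionally perturbed to
    emulate merge error) -> site distances -> capture-model thresholds ->
    diagnostics, plus a misregistration sensitivity table.

Seeds are split per stage/replicate through ``numpy.random.SeedSequence`` so
stages are independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .capture import (CaptureModelParams, PacingProtocol, simulate_observed_category,
                      threshold_from_distance)
from .cohort import (AnatomyModel, generate_anatomy, generate_calibrated_cohort,
                     load_study_summary, sample_pacing_sites, REGION_LA_SEPTAL)
from .geometry import points_to_polyline_distances
from .registration import RigidTransform, icp_register, kabsch_align, perturb_transform
from .stats import build_table2, full_cohort_stats, roc_analysis
from .volume import HUVolume, extract_centerline, rasterize_nerve, segment_hu_threshold

__all__ = ["PipelineConfig", "RunReport", "run_calibrated_reproduction",
           "run_geometric_endtoend"]


@dataclass
class PipelineConfig:
    scenario: str = "calibrated"          # calibrated | geometric
    seed: int = 0
    n_replicates: int = 200               # calibrated scenario
    n_sites: int | None = None            # default: published cohort size
    voxel_spacing_mm: float = 1.0         # geometric scenario
    perturb_translation_mm: tuple = (0.0, 1.0, 2.0, 4.0)
    perturb_rotation_deg: float = 0.0
    capture_params: CaptureModelParams = field(default_factory=CaptureModelParams)
    distance_cutoff_mm: float = 10.0
    n_boot: int = 2000
    output_dir: str | None = None

    def __post_init__(self):
        if self.scenario not in ("calibrated", "geometric"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.seed < 0 or self.n_replicates < 1:
            raise ValueError("seed must be >= 0 and n_replicates >= 1")


@dataclass
class RunReport:
    scenario: str
    seed: int
    n_replicates: int
    aggregates: dict                       # replicate means/SDs of the key stats
    table2: pd.DataFrame                   # aggregate Se/Sp panel
    per_replicate: pd.DataFrame            # one row per replicate
    sensitivity: pd.DataFrame | None = None  # geometric: misregistration study
    provenance: dict = field(default_factory=dict)

    def save(self, outdir) -> None:
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.table2.to_csv(out / "table2.csv", index=False)
        self.per_replicate.to_csv(out / "per_replicate.csv", index=False)
        if self.sensitivity is not None:
            self.sensitivity.to_csv(out / "misregistration_sensitivity.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump({"scenario": self.scenario, "seed": self.seed,
                       "n_replicates": self.n_replicates,
                       "aggregates": self.aggregates,
                       "provenance": self.provenance}, fh, indent=1)


def _replicate_row(records: pd.DataFrame, cutoff: float) -> dict:
    cs = full_cohort_stats(records)
    tb = build_table2(records, cutoff)
    row = {"auc": tb.auc, "spearman_rho": cs.spearman_rho,
           "mean_mm_cat0": cs.categories[0].mean_mm,
           "p_adjacent_01": cs.adjacent_t_pvalues[0]}
    for r in tb.rows:
        key = r["cutoff"].split(" ")[0].replace(">", "gt")
        row[f"se_{key}"] = r["sensitivity"]
        row[f"sp_{key}"] = r["specificity"]
    return row


def _aggregate(per_rep: pd.DataFrame) -> dict:
    return {c: {"mean": float(per_rep[c].mean()), "sd": float(per_rep[c].std(ddof=1))
                if len(per_rep) > 1 else 0.0}
            for c in per_rep.columns}


def _aggregate_table2(per_rep: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    rows = []
    for k, lab in zip(("gt10", "gt20", "gt30", "gt50"),
                      (">10 mA", ">20 mA", ">30 mA", ">50 mA (no capture)")):
        rows.append({"cutoff": lab,
                     "sensitivity": round(per_rep[f"se_{k}"].mean(), 3),
                     "specificity": round(per_rep[f"sp_{k}"].mean(), 3)})
    return pd.DataFrame(rows)


def run_calibrated_reproduction(config: PipelineConfig) -> RunReport:
    """Replicate calibrated cohorts -> diagnostics -> replicate-mean aggregates."""
    study = load_study_summary()
    ss = np.random.SeedSequence(config.seed)
    rows = []
    first_records = None
    for child in ss.spawn(config.n_replicates):
        rng = np.random.default_rng(child)
        rec = generate_calibrated_cohort(study["categories"], seed=rng,
                                         n_patients=study["n_patients"],
                                         la_fraction=study["n_la_sites"] / study["n_sites"])
        if first_records is None:
            first_records = rec
        rows.append(_replicate_row(rec, config.distance_cutoff_mm))
    per_rep = pd.DataFrame(rows)
    agg = _aggregate(per_rep)
    # bootstrap AUC CI on one representative cohort
    roc = roc_analysis(first_records, config.distance_cutoff_mm,
                       n_boot=config.n_boot, seed=np.random.default_rng(ss.spawn(1)[0]))
    agg["auc_ci"] = {"low": roc.auc_ci_low, "high": roc.auc_ci_high}
    report = RunReport("calibrated", config.seed, config.n_replicates, agg,
                       _aggregate_table2(per_rep, config.distance_cutoff_mm), per_rep,
                       provenance={"version": __version__,
                                   "cohort_size": int(study["n_sites"])})
    if config.output_dir:
        report.save(config.output_dir)
    return report


def _build_volume_for(anatomy: AnatomyModel, spacing: float) -> HUVolume:
    pad = 12.0
    lo = np.minimum(anatomy.shell.vertices.min(axis=0),
                    anatomy.nerve_path.vertices.min(axis=0)) - pad
    hi = np.maximum(anatomy.shell.vertices.max(axis=0),
                    anatomy.nerve_path.vertices.max(axis=0)) + pad
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    return HUVolume.background(tuple(shape), (spacing,) * 3, lo)


def run_geometric_endtoend(config: PipelineConfig, n_sites: int | None = None) -> RunReport:
    """Anatomy -> volume -> segmentation -> registration -> distances -> capture -> stats.

    Also reports measured-vs-true distance agreement and a misregistration
    sensitivity table over the configured translation magnitudes. Any stage
    failure raises with the stage name.
    """
    n_sites = n_sites or config.n_sites or 1033
    ss = np.random.SeedSequence(config.seed)
    s_anat, s_sites, s_map, s_capture, s_perturb = ss.spawn(5)

    def stage(name, fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except Exception as e:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(f"geometric pipeline failed at stage '{name}': {e}") from e

    anatomy = stage("anatomy", generate_anatomy,
                    int(np.random.default_rng(s_anat).integers(2**31)))
    vol = stage("volume", _build_volume_for, anatomy, config.voxel_spacing_mm)
    marked = stage("rasterize", rasterize_nerve, anatomy.nerve_path, vol)
    voxels = stage("segment", segment_hu_threshold, marked)
    centerline = stage("centerline", extract_centerline, voxels,
                       5 * config.voxel_spacing_mm)

    sites = stage("sites", sample_pacing_sites, anatomy, n_sites,
                  REGION_LA_SEPTAL, np.random.default_rng(s_sites))
    site_xyz = sites[["x_mm", "y_mm", "z_mm"]].to_numpy()

    # map frame = CT frame moved by a hidden rigid motion; registration recovers it
    rng_map = np.random.default_rng(s_map)
    t_true = perturb_transform(RigidTransform.identity(), rotation_deg=8.0,
                               translation_mm=15.0, seed=rng_map)
    map_sites = t_true.inverse().apply(site_xyz)
    shell_pts = anatomy.shell.vertices
    map_shell = t_true.inverse().apply(
        shell_pts[rng_map.choice(len(shell_pts), size=min(500, len(shell_pts)),
                                 replace=False)])

    init = stage("landmark_align", kabsch_align,
                 t_true.inverse().apply(anatomy.fiducials()), anatomy.fiducials())
    reg = stage("icp", icp_register, map_shell, shell_pts, init)
    t_hat = reg.transform
    if config.perturb_rotation_deg > 0:
        t_hat = perturb_transform(t_hat, config.perturb_rotation_deg, 0.0,
                                  np.random.default_rng(s_perturb))

    fused = t_hat.apply(map_sites)
    measured = points_to_polyline_distances(fused, centerline)
    truth = sites["distance_mm"].to_numpy()

    # capture simulation driven by the true geometric distances
    protocol = PacingProtocol()
    thresholds = threshold_from_distance(truth, config.capture_params,
                                         protocol.pulse_width_ms)
    cats = simulate_observed_category(thresholds, protocol,
                                      config.capture_params.threshold_noise_sd_log,
                                      np.random.default_rng(s_capture))
    records = sites.assign(category=cats, distance_mm=measured,
                           true_distance_mm=truth)

    row = _replicate_row(records, config.distance_cutoff_mm)
    per_rep = pd.DataFrame([row])
    agg = _aggregate(per_rep)
    agg["distance_error_mm"] = {
        "max": float(np.max(np.abs(measured - truth))),
        "mean": float(np.mean(np.abs(measured - truth)))}
    agg["registration_rms_mm"] = {"value": reg.rms_residual}

    sens_rows = []
    rng_p = np.random.default_rng(s_perturb)
    for mag in config.perturb_translation_mm:
        tp = perturb_transform(t_hat, 0.0, float(mag), rng_p)
        dp = points_to_polyline_distances(tp.apply(map_sites), centerline)
        delta = np.abs(dp - measured)
        sens_rows.append({"translation_mm": float(mag),
                          "max_abs_ddist_mm": float(delta.max()),
                          "mean_abs_ddist_mm": float(delta.mean())})
    sens = pd.DataFrame(sens_rows)

    report = RunReport("geometric", config.seed, 1, agg,
                       build_table2(records, config.distance_cutoff_mm).to_frame(),
                       per_rep, sensitivity=sens,
                       provenance={"version": __version__, "n_sites": int(n_sites),
                                   "voxel_spacing_mm": config.voxel_spacing_mm,
                                   "capture_params": asdict(config.capture_params)})
    if config.output_dir:
        report.save(config.output_dir)
    report.records = records  # stage output retained for inspection
    return report
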