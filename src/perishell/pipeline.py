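"""End-to-end orchestration: phantom cohort -> shells -> catalog ->
ROI contrasts -> centrifugal trend -> cohort models, with every artifact
written to disk and the run replayable from its saved config + seed."""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster_metrics import (ClusterRecord, catalog_frame, catalog_summary,
                              classify_location, classify_shape, grade_cavitation,
                              volume_ml)
from .cohort import fit_logistic, fit_ordinal, screen_univariable
from .phantom import PhantomCase, PhantomConfig, cohort_frame, generate_cohort
from .roistats import stratified_contrasts, trend_table
from .trend import fit_trend

__all__ = ["RunConfig", "RunReport", "run_pipeline", "build_catalog"]

#: covariates always adjusted for in the multivariable models
PRESELECTED_TERMS = ["age", "male", "wmh_norm_log10", "lacune_count"]


@dataclass
class RunConfig:
    """Fully serialisable run configuration (YAML round-trip)."""

    out_dir: str = "perishell_run"
    seed: int = 0
    n_patients: int = 60      # cohort size for the per-patient layer
    n_imaging: int = 10       # patients with full volumes for the imaging layer
    # phantom settings
    grid_shape: tuple[int, int, int] = (72, 80, 48)
    n_clusters: int = 3
    cvr_deficit: float = 0.05
    gradient_slope: float = 0.015
    noise_sd: float = 0.02
    effect_spec: dict = field(default_factory=lambda: {"lacune_count": 0.26,
                                                       "wmh_norm_log10": 0.65})
    # shell / masking parameters
    n_shells: int = 3
    shell_thickness: float = 2.0
    erosion_mm: float = 2.5
    ventricle_dilation_mm: float = 2.5
    min_voxels: int = 5
    # statistics options
    t_mode: str = "paired"
    vif_threshold: float = 5.0
    collapse_at: int = 4

    def phantom_config(self) -> PhantomConfig:
        return PhantomConfig(grid_shape=tuple(self.grid_shape),
                             n_clusters=self.n_clusters,
                             cvr_deficit=self.cvr_deficit,
                             gradient_slope=self.gradient_slope,
                             noise_sd=self.noise_sd,
                             n_shells=self.n_shells,
                             shell_thickness=self.shell_thickness,
                             seed=self.seed)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["grid_shape"] = tuple(raw.get("grid_shape", (72, 80, 48)))
        return cls(**raw)


@dataclass
class RunReport:
    config: RunConfig
    n_patients: int
    n_clusters: int
    attrition: dict
    tables: dict[str, str]
    summary_text: str


def build_catalog(cases: list[PhantomCase]) -> list[ClusterRecord]:
    """Catalog records for every cluster of a cohort, with landmarks for
    the anterior/posterior location taken from each case's ventricles."""
    records = []
    for case in cases:
        if not case.has_volumes or not case.cluster_masks:
            continue
        vent = np.argwhere(case.ventricle_mask.require_binary())
        ant_y, post_y = float(vent[:, 1].max()), float(vent[:, 1].min())
        for ci, cm in enumerate(case.cluster_masks):
            truth = case.truth_clusters.iloc[ci]
            records.append(ClusterRecord(
                cluster_id=f"{case.case_id}:c{ci:02d}",
                patient_id=str(case.covariates.get("patient_id", case.case_id)),
                volume_ml=volume_ml(cm),
                shape=classify_shape(cm),
                location=classify_location(cm, ant_y, post_y),
                hemisphere=str(truth["hemisphere"]),
                n_vessels=int(truth["n_vessels"]),
                cavitation=grade_cavitation(cm, case.labels),
                rim=bool(truth["grade"] == "complete"),
            ))
    return records


def run_pipeline(config: RunConfig) -> RunReport:
    """Run every stage on a synthetic cohort and write all artifacts.

    Stages (each failure is reported with its stage name): phantom
    generation, shell geometry + ROI contrasts, catalog, centrifugal
    trend, per-patient cohort models.  Outputs: catalog.csv,
    roi_measures.csv, contrasts.csv, trend.csv, cohort_screen.csv,
    cohort_logistic.csv, cohort_ordinal.csv, patients.csv, run.json,
    summary.txt and the saved config.yaml.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    tables: dict[str, str] = {}
    attrition: dict = {}

    def _stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return deco

    @_stage("phantom")
    def cases():
        return generate_cohort(config.phantom_config(), config.n_patients,
                               effect_spec=config.effect_spec,
                               with_volumes=min(config.n_imaging, config.n_patients))

    imaging_cases = [c for c in cases if c.has_volumes]
    patients = cohort_frame(cases)
    patients.to_csv(out / "patients.csv")
    tables["patients"] = "patients.csv"

    @_stage("catalog")
    def catalog():
        return build_catalog(imaging_cases)

    cat_df = catalog_frame(catalog) if catalog else pd.DataFrame()
    cat_df.to_csv(out / "catalog.csv", index=False)
    tables["catalog"] = "catalog.csv"
    cat_summary = catalog_summary(catalog) if catalog else None

    @_stage("roistats")
    def ctab():
        return stratified_contrasts(imaging_cases, min_voxels=config.min_voxels,
                             erosion_mm=config.erosion_mm,
                             ventricle_dilation_mm=config.ventricle_dilation_mm,
                             n_shells=config.n_shells, thickness=config.shell_thickness,
                             mode=config.t_mode)

    ctab.measures.to_csv(out / "roi_measures.csv", index=False)
    ctab.contrasts.to_csv(out / "contrasts.csv", index=False)
    tables["roi_measures"] = "roi_measures.csv"
    tables["contrasts"] = "contrasts.csv"
    attrition["clusters_total"] = ctab.n_clusters_total
    attrition["clusters_mirror_flagged"] = ctab.n_excluded_mirror
    attrition["clusters_below_min_voxels"] = ctab.n_excluded_invalid

    @_stage("trend")
    def trend_res():
        tt = trend_table(ctab)
        # clusters must contribute >= 2 levels to the mixed model
        ok = tt.groupby("cluster_id")["level_idx"].transform("nunique") >= 2
        attrition["trend_rows_dropped"] = int((~ok).sum())
        return fit_trend(tt[ok])

    trend_df = trend_res.to_frame()
    trend_df.to_csv(out / "trend.csv", index=False)
    tables["trend"] = "trend.csv"

    @_stage("cohort")
    def cohort_out():
        pats = patients.copy()
        pats["cadasil"] = (pats["svd_type"] == "CADASIL").astype(int)
        screen_cols = ["age", "male", "cadasil", "hypertension", "diabetes",
                       "hyperlipidemia", "smoking", "alcohol", "lacune_count",
                       "microbleeds", "pvs_total_score", "wmh_norm_log10"]
        screen = screen_univariable(pats, outcome="has_cluster", covariates=screen_cols)
        extra = [t for t in screen[screen["flagged"]]["term"]
                 if t not in PRESELECTED_TERMS]
        terms = PRESELECTED_TERMS + extra
        logit = fit_logistic(pats, "has_cluster", terms,
                             vif_threshold=config.vif_threshold)
        ordin = fit_ordinal(pats, "n_vessel_clusters", terms,
                            collapse_at=config.collapse_at)
        return screen, logit, ordin

    screen, logit, ordin = cohort_out
    screen.to_csv(out / "cohort_screen.csv", index=False)
    logit.to_frame().to_csv(out / "cohort_logistic.csv", index=False)
    ordin.to_frame().to_csv(out / "cohort_ordinal.csv", index=False)
    tables.update(cohort_screen="cohort_screen.csv", cohort_logistic="cohort_logistic.csv",
                  cohort_ordinal="cohort_ordinal.csv")

    # ------------------------------------------------------------------
    lines = [
        f"perishell {__version__} run (seed={config.seed}, n_patients={config.n_patients})",
        f"clusters: {ctab.n_clusters_total} total, "
        f"{ctab.n_excluded_mirror} mirror-flagged, "
        f"{ctab.n_excluded_invalid} below the {config.min_voxels}-voxel validity rule",
        "",
    ]
    if cat_summary is not None:
        lines.append(f"catalog: {cat_summary.n_clusters} clusters in "
                     f"{cat_summary.n_patients_with_cluster} patients")
    if not ctab.contrasts.empty:
        lines.append("\nipsi - contra CVR magnitude contrasts (paired t):")
        sel = ctab.contrasts[ctab.contrasts["metric"] == "cvr_magnitude"]
        for _, r in sel.iterrows():
            lines.append(f"  {r['group']:<13}{r['level']:<14}"
                         f"diff={r['mean_diff']:+.4f} (SD {r['sd_diff']:.4f}) "
                         f"t={r['t_statistic']:+.2f} p={r['p_value']:.3f} "
                         f"n={int(r['n_clusters'])}")
    lines.append("\ncentrifugal trend:")
    lines.append(trend_res.summary())
    lines.append("\ncohort logistic model:")
    lines.append(logit.summary())
    summary_text = "\n".join(lines)
    (out / "summary.txt").write_text(summary_text)

    run_meta = {
        "version": __version__,
        "seed": config.seed,
        "python": platform.python_version(),
        "attrition": attrition,
        "tables": tables,
    }
    with open(out / "run.json", "w") as fh:
        json.dump(run_meta, fh, indent=2)

    return RunReport(config=config, n_patients=config.n_patients,
                     n_clusters=ctab.n_clusters_total, attrition=attrition,
                     tables=tables, summary_text=summary_text)
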