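"""ROI-level CVR statistics: ipsi- vs contralateral contrasts by level.

For every cluster the analysis extracts mean CVR magnitude and delay in
seven nested ROIs (the cluster, three concentric shells, three cumulative
expansions), in both the source hemisphere and the mirrored contralateral
position, and contrasts the two sides per cavitation stratum (complete
vs not complete).  The default contrast is the paired per-cluster
difference d_i = ipsi_i - contra_i with t = mean(d) * sqrt(n) / SD(d); a
classical two-sample t is available via ``mode="two_sample"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grid import VolumeGrid
from .maskops import ShellSet, dilate, erode, make_shells, resample_mask
from .phantom import PhantomCase

__all__ = [
    "RoiMeasure",
    "RoiContrast",
    "roi_mean",
    "paired_contrast",
    "stratified_contrasts",
    "ContrastTable",
    "LEVELS",
]

LEVELS = ("cluster", "shell1", "shell2", "shell3",
          "expansion0_2", "expansion0_4", "expansion0_6")


@dataclass
class RoiMeasure:
    """Mean CVR in one ROI on one side."""

    roi_id: str
    level: str
    side: str                      # "ipsi" or "contra"
    mean: float
    n_voxels: int
    n_nan: int = 0
    valid: bool = True
    metric: str = "cvr_magnitude"


@dataclass
class RoiContrast:
    """Per-stratum ipsi-vs-contra contrast at one level for one metric."""

    group: str
    level: str
    metric: str
    mean_diff: float
    sd_diff: float
    t_statistic: float
    p_value: float
    n_clusters: int
    mode: str = "paired"


def roi_mean(map_grid: VolumeGrid, mask: VolumeGrid, min_voxels: int = 5,
             roi_id: str = "", level: str = "", side: str = "ipsi",
             metric: str = "cvr_magnitude") -> RoiMeasure:
    """Arithmetic mean of the map over the mask, NaN voxels excluded.

    ``valid`` is false when fewer than ``min_voxels`` finite voxels
    contribute; the mean is still reported (NaN when empty).
    """
    if map_grid.shape != mask.shape:
        raise ValueError(f"map shape {map_grid.shape} != mask shape {mask.shape}; "
                         "resample the mask to the map grid first")
    m = mask.require_binary()
    vals = np.asarray(map_grid.values, dtype=float)[m]
    finite = np.isfinite(vals)
    n = int(finite.sum())
    mean = float(vals[finite].mean()) if n else float("nan")
    return RoiMeasure(roi_id=roi_id, level=level, side=side, mean=mean,
                      n_voxels=n, n_nan=int((~finite).sum()),
                      valid=n >= min_voxels, metric=metric)


def paired_contrast(pairs: list[tuple[RoiMeasure, RoiMeasure]], mode: str = "paired",
                    group: str = "", level: str = "", metric: str = "cvr_magnitude",
                    ) -> RoiContrast:
    """Contrast valid ipsi/contra ROI-mean pairs.

    paired (default): one-sample t on d_i = ipsi_i - contra_i with n-1 df;
    two_sample: pooled-variance Student t on the two sides' means.
    Degenerate all-zero differences give t = 0, p = 1.
    """
    if mode not in ("paired", "two_sample"):
        raise ValueError(f"mode must be 'paired' or 'two_sample', got {mode!r}")
    valid = [(a, b) for a, b in pairs if a.valid and b.valid
             and np.isfinite(a.mean) and np.isfinite(b.mean)]
    n = len(valid)
    if n < 2:
        raise ValueError(f"need >= 2 valid ipsi/contra pairs in stratum "
                         f"{group or '<unnamed>'} (level {level or '<any>'}), got {n}")
    ipsi = np.array([a.mean for a, _ in valid])
    contra = np.array([b.mean for _, b in valid])
    d = ipsi - contra
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    if mode == "paired":
        if sd_diff == 0.0:
            t = 0.0 if mean_diff == 0.0 else float(np.sign(mean_diff) * np.inf)
            p = 1.0 if mean_diff == 0.0 else 0.0
        else:
            t = mean_diff * np.sqrt(n) / sd_diff
            p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    else:
        if ipsi.std(ddof=1) == 0.0 and contra.std(ddof=1) == 0.0:
            t, p = (0.0, 1.0) if mean_diff == 0.0 else (float(np.sign(mean_diff) * np.inf), 0.0)
        else:
            t, p = stats.ttest_ind(ipsi, contra, equal_var=True)
            t, p = float(t), float(p)
    return RoiContrast(group=group, level=level, metric=metric, mean_diff=mean_diff,
                       sd_diff=sd_diff, t_statistic=float(t), p_value=float(p),
                       n_clusters=n, mode=mode)


@dataclass
class ContrastTable:
    """Cavitation-stratified per-cluster contrast table plus the raw
    measures and the attrition bookkeeping."""

    measures: pd.DataFrame        # one row per cluster x level x side x metric
    contrasts: pd.DataFrame       # one row per stratum x level x metric
    n_clusters_total: int
    n_excluded_invalid: int       # clusters lost to the min-voxel validity rule
    n_excluded_mirror: int        # clusters whose mirrored reference was flagged

    def contrast(self, group: str, level: str, metric: str = "cvr_magnitude") -> pd.Series:
        sel = self.contrasts[(self.contrasts["group"] == group)
                             & (self.contrasts["level"] == level)
                             & (self.contrasts["metric"] == metric)]
        if sel.empty:
            raise KeyError(f"no contrast for ({group}, {level}, {metric})")
        return sel.iloc[0]


def _measures_for_case(case: PhantomCase, grades: list[str], min_voxels: int,
                       erosion_mm: float, ventricle_dilation_mm: float,
                       n_shells: int, thickness: float, mode_space: str):
    """ROI measures for every cluster of one case; returns rows + flags."""
    wm = case.wm_mask
    analysis = erode(wm, erosion_mm, unit="mm")
    vent_d = dilate(case.ventricle_mask, ventricle_dilation_mm, unit="mm")
    analysis = analysis.with_values(analysis.require_binary() & ~vent_d.require_binary())

    all_sources = np.zeros(wm.shape, dtype=bool)
    for cm in case.cluster_masks:
        all_sources |= cm.require_binary()
    sources = wm.with_values(all_sources)

    if mode_space == "cvr":
        maps = {"cvr_magnitude": case.cvr_magnitude, "cvr_delay": case.cvr_delay}
        factor = case.config.cvr_downsample
    elif mode_space == "highres":
        maps = {"cvr_magnitude": case.cvr_magnitude_highres}
        factor = 1
    else:
        raise ValueError("mode_space must be 'cvr' or 'highres'")

    rows = []
    mirror_flags = []
    for ci, cm in enumerate(case.cluster_masks):
        ss: ShellSet = make_shells(cm, wm, n_shells=n_shells, thickness=thickness,
                                   analysis_mask=analysis, source_clusters=sources)
        mirror_flags.append(ss.mirror_flagged)
        for side, levels in (("ipsi", ss.levels()), ("contra", ss.mirrored_levels())):
            for level, roi in levels.items():
                if roi is None:
                    continue
                roi_cvr = resample_mask(roi, factor=factor) if factor > 1 else roi
                for metric, mp in maps.items():
                    meas = roi_mean(mp, roi_cvr, min_voxels=min_voxels,
                                    roi_id=f"{case.case_id}:c{ci:02d}", level=level,
                                    side=side, metric=metric)
                    rows.append({"case_id": case.case_id, "cluster": f"{case.case_id}:c{ci:02d}",
                                 "grade": grades[ci], "level": level, "side": side,
                                 "metric": metric, "mean": meas.mean,
                                 "n_voxels": meas.n_voxels, "valid": meas.valid,
                                 "mirror_flagged": ss.mirror_flagged})
    return rows, mirror_flags


def stratified_contrasts(cases: list[PhantomCase], catalog: pd.DataFrame | None = None,
                  min_voxels: int = 5, erosion_mm: float = 2.5,
                  ventricle_dilation_mm: float = 2.5, n_shells: int = 3,
                  thickness: float = 2.0, mode: str = "paired",
                  mode_space: str = "cvr") -> ContrastTable:
    """Cavitation-stratified ipsi/contra CVR contrasts at all 7 levels.

    Cavitation grades come from ``catalog`` (columns cluster, cavitation)
    when given, else from each case's generating truth.  Strata are
    ``complete`` and ``not_complete``; contrasts are computed for CVR
    magnitude and (in CVR space) delay.  Clusters whose mirrored
    reference is flagged (poor white-matter overlap or collision with a
    source cluster) are excluded, replacing the manual check a human rater would perform.
    """
    all_rows: list[dict] = []
    n_total = 0
    n_mirror = 0
    for case in cases:
        if not case.has_volumes or not case.cluster_masks:
            continue
        if catalog is not None:
            cat = catalog.set_index("cluster") if "cluster" in catalog.columns else catalog
            grades = [cat.loc[f"{case.case_id}:c{ci:02d}", "cavitation"]
                      for ci in range(len(case.cluster_masks))]
        else:
            grades = list(case.truth_clusters["grade"])
        n_total += len(case.cluster_masks)
        rows, mflags = _measures_for_case(case, grades, min_voxels, erosion_mm,
                                          ventricle_dilation_mm, n_shells, thickness,
                                          mode_space)
        n_mirror += sum(mflags)
        all_rows.extend(rows)

    measures = pd.DataFrame(all_rows)
    if measures.empty:
        raise ValueError("no clusters in the supplied cases")
    usable = measures[~measures["mirror_flagged"]]

    contrast_rows = []
    n_invalid = 0
    strata = {"complete": lambda g: g == "complete",
              "not_complete": lambda g: g != "complete"}
    for group, pred in strata.items():
        sub = usable[usable["grade"].map(pred)]
        for metric in sub["metric"].unique():
            for level in LEVELS:
                cell = sub[(sub["level"] == level) & (sub["metric"] == metric)]
                piv = cell.pivot_table(index="cluster", columns="side",
                                       values=["mean", "valid", "n_voxels"],
                                       aggfunc="first")
                pairs = []
                for _, r in piv.iterrows():
                    a = RoiMeasure(roi_id="", level=level, side="ipsi",
                                   mean=r[("mean", "ipsi")],
                                   n_voxels=int(r[("n_voxels", "ipsi")]),
                                   valid=bool(r[("valid", "ipsi")]), metric=metric)
                    b = RoiMeasure(roi_id="", level=level, side="contra",
                                   mean=r[("mean", "contra")],
                                   n_voxels=int(r[("n_voxels", "contra")]),
                                   valid=bool(r[("valid", "contra")]), metric=metric)
                    pairs.append((a, b))
                n_valid = sum(1 for a, b in pairs if a.valid and b.valid)
                if metric == "cvr_magnitude" and level == "cluster":
                    n_invalid += len(pairs) - n_valid
                if n_valid < 2:
                    continue
                c = paired_contrast(pairs, mode=mode, group=group, level=level,
                                    metric=metric)
                contrast_rows.append(vars(c))

    return ContrastTable(measures=measures, contrasts=pd.DataFrame(contrast_rows),
                      n_clusters_total=n_total, n_excluded_invalid=n_invalid,
                      n_excluded_mirror=n_mirror)


def trend_table(ctab: ContrastTable, metric: str = "cvr_magnitude",
                side: str = "ipsi") -> pd.DataFrame:
    """Long table (cluster, level 0..3, value, group) for the trend model.

    Levels are the cluster (0) and the three concentric shells (1..3),
    the centrifugal ordering the gradient analysis tests.
    """
    order = {"cluster": 0, "shell1": 1, "shell2": 2, "shell3": 3}
    m = ctab.measures
    sub = m[(m["metric"] == metric) & (m["side"] == side)
            & m["level"].isin(order) & m["valid"] & ~m["mirror_flagged"]].copy()
    sub["level_idx"] = sub["level"].map(order)
    sub["group"] = np.where(sub["grade"] == "complete", "complete", "not_complete")
    out = sub.rename(columns={"cluster": "cluster_id", "mean": "value"})
    return out[["cluster_id", "level_idx", "value", "group"]].reset_index(drop=True)
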