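"""Synthetic 3-D brain phantoms with known perilesional CVR structure.

The generator builds, per subject, a midline-symmetric head geometry
(intracranial, white-matter and ventricle masks on the structural grid),
a configurable number of white-matter lesion clusters with cavitation
grades {noncavitated, partial, complete}, and CVR magnitude/delay maps on
a coarser grid (block-averaged from a structural-resolution truth field,
emulating the lower resolution of BOLD-CVR acquisitions).

Completely cavitated clusters carry a CVR deficit at the core and a
linear centrifugal recovery through the three surrounding shells:

    CVR(shell k) = baseline - deficit + slope * k,   k = 1..3

so every downstream statistic (ROI means, ipsi/contra contrasts, the
mixed-model linear trend) has a known truth to recover.  Contralateral
mirror positions are left at baseline by construction, so the mirrored
reference assumption holds exactly.  Cohort generation adds per-patient
covariates and samples vessel-cluster counts from a proportional-odds
model, giving the regression layer a recoverable truth as well.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import VolumeGrid, from_nifti, to_nifti
from .maskops import block_mean, mirror

__all__ = [
    "PhantomConfig",
    "PhantomCase",
    "PlacementError",
    "generate_case",
    "generate_cohort",
    "cohort_frame",
    "write_case",
    "read_case",
]

GRADES = ("noncavitated", "partial", "complete")
# voxel label codes for the tissue-class volume used by cavitation grading
LABEL_NAWM, LABEL_WMH, LABEL_CAVITY = 0, 1, 2


class PlacementError(RuntimeError):
    """Raised when the requested clusters cannot be placed without overlap."""


def _bbox_slices(mask: np.ndarray, pad: int) -> tuple[slice, slice, slice]:
    """Bounding-box slices of a mask expanded by ``pad`` voxels (clipped)."""
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + pad, mask.shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


@dataclass
class PhantomConfig:
    """Study conditions for one synthetic subject.

    Defaults follow the cohort the analysis is designed for: structural
    voxels of 1.25 mm with a factor-2 coarser CVR grid (so a 2-voxel
    structural shell is one CVR voxel thick), a white-matter CVR baseline
    of 0.20 %/mm Hg, a 0.05 %/mm Hg deficit inside completely cavitated
    clusters recovering by 0.015 %/mm Hg per shell level, and a
    13/47/40% cavitation mix typical of severe-SVD cohorts.
    """

    grid_shape: tuple[int, int, int] = (72, 80, 48)
    spacing_t2: tuple[float, float, float] = (1.25, 1.25, 1.25)
    cvr_downsample: int = 2
    n_clusters: int = 4
    cavitation_mix: tuple[float, float, float] = (0.13, 0.47, 0.40)
    cvr_wm_baseline: float = 0.20      # %/mm Hg
    cvr_deficit: float = 0.05          # %/mm Hg, at complete-cavity core
    partial_deficit: float = 0.0       # optional flat deficit for partial grade
    gradient_slope: float = 0.015      # %/mm Hg per shell level
    noise_sd: float = 0.02             # %/mm Hg additive Gaussian
    delay_baseline: float = 10.0       # seconds
    delay_sd: float = 2.0              # seconds
    n_shells: int = 3
    shell_thickness: float = 2.0       # structural voxels
    midline_margin_vox: int = 3        # cluster keep-out around the midline
    seed: int = 0

    @property
    def spacing_cvr(self) -> tuple[float, float, float]:
        return tuple(s * self.cvr_downsample for s in self.spacing_t2)

    @property
    def midline_index(self) -> float:
        return (self.grid_shape[0] - 1) / 2.0

    def validate(self) -> None:
        if abs(sum(self.cavitation_mix) - 1.0) > 1e-9:
            raise ValueError("cavitation_mix must sum to 1 within 1e-9")
        if any(p < 0 for p in self.cavitation_mix):
            raise ValueError("cavitation_mix proportions must be >= 0")
        if any(s <= 0 for s in self.spacing_t2):
            raise ValueError("spacing values must be strictly positive")
        if self.cvr_downsample < 1:
            raise ValueError("cvr_downsample must be >= 1")
        if any(n % self.cvr_downsample for n in self.grid_shape):
            raise ValueError("grid_shape must be divisible by cvr_downsample")
        if self.n_clusters < 0:
            raise ValueError("n_clusters must be >= 0")
        if self.noise_sd < 0 or self.delay_sd < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass
class PhantomCase:
    """One synthetic subject: masks, CVR maps, and the generating truth."""

    config: PhantomConfig
    case_id: str = "case000"
    icv_mask: VolumeGrid | None = None
    wm_mask: VolumeGrid | None = None
    ventricle_mask: VolumeGrid | None = None
    cluster_masks: list[VolumeGrid] = field(default_factory=list)
    labels: VolumeGrid | None = None            # tissue classes for cavitation grading
    cvr_magnitude: VolumeGrid | None = None     # CVR grid, noisy
    cvr_delay: VolumeGrid | None = None         # CVR grid, noisy
    cvr_magnitude_highres: VolumeGrid | None = None  # structural grid, own noise draw
    cvr_magnitude_truth: VolumeGrid | None = None    # structural grid, noise-free
    truth_clusters: pd.DataFrame = field(default_factory=pd.DataFrame)
    covariates: dict = field(default_factory=dict)

    @property
    def has_volumes(self) -> bool:
        return self.wm_mask is not None

    def validate(self) -> None:
        """Assert the mask-nesting invariants."""
        icv = self.icv_mask.require_binary()
        wm = self.wm_mask.require_binary()
        vent = self.ventricle_mask.require_binary()
        assert not (vent & wm).any(), "ventricle mask intersects white matter"
        assert not (wm & ~icv).any(), "white matter leaves the intracranial mask"
        for i, cm in enumerate(self.cluster_masks):
            assert not (cm.require_binary() & ~wm).any(), f"cluster {i} leaves white matter"


# ----------------------------------------------------------------------
# geometry helpers
# ----------------------------------------------------------------------

def _ellipsoid(shape, center, semi) -> np.ndarray:
    ix, iy, iz = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (((ix - center[0]) / semi[0]) ** 2
            + ((iy - center[1]) / semi[1]) ** 2
            + ((iz - center[2]) / semi[2]) ** 2) <= 1.0


def _head_geometry(cfg: PhantomConfig):
    nx, ny, nz = cfg.grid_shape
    center = ((nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0)
    icv = _ellipsoid(cfg.grid_shape, center, (0.47 * nx, 0.47 * ny, 0.47 * nz))
    wm = _ellipsoid(cfg.grid_shape, center, (0.38 * nx, 0.38 * ny, 0.36 * nz))
    vent = np.zeros(cfg.grid_shape, dtype=bool)
    for sign in (-1.0, 1.0):
        c = (center[0] + sign * 0.09 * nx, center[1], center[2])
        vent |= _ellipsoid(cfg.grid_shape, c, (0.045 * nx, 0.17 * ny, 0.10 * nz))
    vent &= icv
    wm = wm & ~vent & icv
    mk = lambda v: VolumeGrid(v, cfg.spacing_t2, midline_index=cfg.midline_index)
    return mk(icv), mk(wm), mk(vent)


_SHAPE_CLASSES = ("round", "ovoid", "linear", "irregular")
_SHAPE_PROBS = (0.45, 0.35, 0.12, 0.08)


def _sample_cluster_mask(cfg: PhantomConfig, rng: np.random.Generator,
                         center: tuple[int, int, int]) -> tuple[np.ndarray, str]:
    """Random ellipsoid-based cluster mask of one of the four shape classes."""
    cls = _SHAPE_CLASSES[rng.choice(4, p=_SHAPE_PROBS)]
    r = rng.uniform(1.8, 2.6)  # round volumes ~25-75 voxels (~0.05-0.15 mL)
    if cls == "round":
        semi = r * rng.uniform(0.92, 1.08, size=3)
        m = _ellipsoid(cfg.grid_shape, center, semi)
    elif cls == "ovoid":
        semi = np.array([2.1 * r, r, 0.95 * r])
        rng.shuffle(semi)
        m = _ellipsoid(cfg.grid_shape, center, semi)
    elif cls == "linear":
        semi = np.array([3.4 * r, 0.75 * r, 0.7 * r])
        rng.shuffle(semi)
        m = _ellipsoid(cfg.grid_shape, center, semi)
    else:  # irregular: two offset lobes -> low solidity
        semi = (1.6 * r, 0.8 * r, 0.8 * r)
        off = rng.integers(-2, 3, size=3) + np.array([2.0 * r, 0, 0])
        m = _ellipsoid(cfg.grid_shape, center, semi)
        m |= _ellipsoid(cfg.grid_shape, tuple(np.add(center, off)), semi[::-1])
    return m, cls


def _grade_counts(cfg: PhantomConfig) -> list[str]:
    """Deterministic largest-remainder allocation of grades to clusters."""
    n = cfg.n_clusters
    raw = [p * n for p in cfg.cavitation_mix]
    counts = [int(np.floor(x)) for x in raw]
    rem = n - sum(counts)
    order = np.argsort([c - x for c, x in zip(counts, raw)])  # largest remainder first
    for idx in order[:rem]:
        counts[idx] += 1
    grades: list[str] = []
    for g, c in zip(GRADES, counts):
        grades.extend([g] * c)
    return grades


def _place_clusters(cfg: PhantomConfig, rng: np.random.Generator, wm: VolumeGrid,
                    grades: list[str], max_attempts: int = 500):
    """Place non-overlapping clusters inside WM, away from the midline.

    Keep-out rules keep every constructed quantity pure by design:

    * every cluster voxel stays >= midline_margin_vox + n_shells*thickness
      voxels from the midline, so neither the imposed deficit field nor
      the shells ever cross it;
    * completely cavitated clusters write a deficit field extending
      n_shells*thickness voxels outward, so they carry a keep-out halo of
      2*n_shells*thickness voxels around themselves *and* their mirror
      position: no other cluster's shells, and no mirrored reference,
      can touch a written region.  Completes are placed first;
    * non-complete clusters write nothing (tissue stays at baseline), so
      they only need a small 2-voxel disjointness halo.

    Returns masks aligned with ``grades`` plus the sampled shape classes.
    """
    from scipy import ndimage

    w = wm.require_binary()
    nx = cfg.grid_shape[0]
    mid = cfg.midline_index
    margin = cfg.midline_margin_vox + cfg.n_shells * cfg.shell_thickness
    sep_strict = 2 * cfg.n_shells * cfg.shell_thickness
    sep_light = 2.0

    ix = np.arange(nx).reshape(-1, 1, 1)
    away = np.broadcast_to(np.abs(ix - mid) >= margin, cfg.grid_shape)
    # candidate centres: WM interior so the sampled ellipsoids usually fit
    interior = ndimage.distance_transform_edt(w) > 3.0
    elig_mask = w & away & interior
    if not elig_mask.any() and grades:
        raise PlacementError("no eligible white-matter voxels for cluster placement")

    order = sorted(range(len(grades)), key=lambda i: grades[i] != "complete")
    forbidden = np.zeros(cfg.grid_shape, dtype=bool)
    masks: dict[int, np.ndarray] = {}
    shapes: dict[int, str] = {}
    for ci in order:
        sep = sep_strict if grades[ci] == "complete" else sep_light
        eligible = np.argwhere(elig_mask)
        placed = False
        if len(eligible):
            for _ in range(max_attempts):
                center = tuple(eligible[rng.integers(len(eligible))])
                m, cls = _sample_cluster_mask(cfg, rng, center)
                if not m.any() or (m & ~w).any():
                    continue
                ii = np.nonzero(m)[0]
                if np.abs(ii - mid).min() < margin:
                    continue
                if (m & forbidden).any():
                    continue
                masks[ci] = m
                shapes[ci] = cls
                mg = wm.with_values(m)
                occ = m | mirror(mg).require_binary()
                # keep-out halo grown in a local box (pad >= sep+1 keeps EDT exact)
                box = _bbox_slices(occ, int(sep) + 2)
                d = ndimage.distance_transform_edt(~occ[box])
                forbidden[box] |= d <= sep
                elig_mask &= ~forbidden
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place cluster {len(masks) + 1}/{len(grades)} after "
                f"{max_attempts} attempts; reduce n_clusters or enlarge the grid")
    return [masks[i] for i in range(len(grades))], [shapes[i] for i in range(len(grades))]


# ----------------------------------------------------------------------
# case generation
# ----------------------------------------------------------------------

def _impose_deficits(cfg: PhantomConfig, field_t2: np.ndarray,
                     masks: list[np.ndarray], grades: list[str]) -> list[dict]:
    """Write the deficit + centrifugal recovery pattern into the truth field."""
    from scipy import ndimage

    rows = []
    t = cfg.shell_thickness
    for m, g in zip(masks, grades):
        deficit = slope = 0.0
        if g == "complete":
            deficit, slope = cfg.cvr_deficit, cfg.gradient_slope
        elif g == "partial":
            deficit = cfg.partial_deficit
        if deficit or slope:
            field_t2[m] = cfg.cvr_wm_baseline - deficit
            if slope:
                box = _bbox_slices(m, int(cfg.n_shells * t) + 2)
                mb = m[box]
                d = ndimage.distance_transform_edt(~mb)
                sub = field_t2[box]
                for k in range(1, cfg.n_shells + 1):
                    band = (~mb) & (d > t * (k - 1)) & (d <= t * k)
                    sub[band] = cfg.cvr_wm_baseline - deficit + slope * k
        rows.append({"grade": g, "imposed_deficit": deficit, "imposed_slope": slope})
    return rows


def _label_volume(cfg: PhantomConfig, wm: np.ndarray,
                  masks: list[np.ndarray], grades: list[str]) -> np.ndarray:
    labels = np.full(cfg.grid_shape, LABEL_NAWM, dtype=np.int16)
    for m, g in zip(masks, grades):
        if g == "noncavitated":
            labels[m] = LABEL_WMH
        elif g == "complete":
            labels[m] = LABEL_CAVITY
        else:  # partial: checkerboard half cavity / half WMH
            ix, iy, iz = np.nonzero(m)
            parity = (ix + iy + iz) % 2 == 0
            labels[ix[parity], iy[parity], iz[parity]] = LABEL_CAVITY
            labels[ix[~parity], iy[~parity], iz[~parity]] = LABEL_WMH
    return labels


def _draw_covariates(rng: np.random.Generator) -> dict:
    """Per-patient covariates with the cohort-level structure the analysis
    assumes (severe-SVD study population)."""
    icv = float(rng.normal(1450.0, 120.0))
    wmh_norm_log10 = float(rng.normal(-1.9, 0.45))
    wmh_volume = icv * 10.0 ** wmh_norm_log10
    return {
        "age": float(rng.normal(57.0, 12.0)),
        "male": int(rng.random() < 0.46),
        "svd_type": "CADASIL" if rng.random() < 0.41 else "sporadic",
        "hypertension": int(rng.random() < 0.61),
        "diabetes": int(rng.random() < 0.15),
        "hyperlipidemia": int(rng.random() < 0.59),
        "smoking": int(rng.random() < 0.53),
        "alcohol": int(rng.random() < 0.71),
        "lacune_count": int(rng.poisson(3.0)),
        "microbleeds": int(rng.poisson(1.5)),
        "pvs_total_score": int(rng.integers(2, 9)),
        "icv": icv,
        "wmh_volume": wmh_volume,
        "wmh_norm_log10": wmh_norm_log10,
        "cvr_nawm": float(rng.normal(0.20, 0.05)),
        "cvr_wmh": float(rng.normal(0.12, 0.05)),
    }


def _case_rng(seed: int, case_index: int) -> np.random.Generator:
    # one stream per case keyed by (seed, case index): reproducible under
    # parallel generation
    return np.random.default_rng((int(seed), int(case_index)))


def generate_case(config: PhantomConfig, case_index: int = 0,
                  n_clusters: int | None = None,
                  covariates: dict | None = None,
                  rng: np.random.Generator | None = None) -> PhantomCase:
    """Generate one synthetic subject; deterministic given (seed, case_index)."""
    config.validate()
    if rng is None:
        rng = _case_rng(config.seed, case_index)
    if n_clusters is None:
        n_clusters = config.n_clusters
    cfg = replace(config, n_clusters=n_clusters)

    icv, wm, vent = _head_geometry(cfg)
    grades = _grade_counts(cfg)
    rng.shuffle(grades)
    masks, shape_classes = _place_clusters(cfg, rng, wm, grades)

    field_t2 = np.full(cfg.grid_shape, cfg.cvr_wm_baseline, dtype=float)
    rows = _impose_deficits(cfg, field_t2, masks, grades)
    labels = _label_volume(cfg, wm.require_binary(), masks, grades)

    mid = cfg.midline_index
    for i, (row, m, cls) in enumerate(zip(rows, masks, shape_classes)):
        ii, jj, kk = np.nonzero(m)
        multi_p = [0.10, 0.25, 0.30, 0.20, 0.15] if row["grade"] == "complete" \
            else [0.40, 0.30, 0.15, 0.10, 0.05]
        row.update({
            "cluster_id": f"c{i:02d}",
            "shape_class": cls,
            "hemisphere": "left" if ii.mean() < mid else "right",
            "n_vessels": int(rng.choice([1, 2, 3, 4, 5], p=multi_p)),
            "center_x": float(ii.mean()), "center_y": float(jj.mean()),
            "center_z": float(kk.mean()),
            "n_voxels": int(m.sum()),
        })

    # noise draws: CVR-grid maps carry noise_sd directly; the structural-grid
    # copy carries its own independent draw at the same SD
    f = cfg.cvr_downsample
    truth_grid = VolumeGrid(field_t2, cfg.spacing_t2, midline_index=mid)
    cvr_mag = block_mean(truth_grid, f)
    cvr_mag.values = cvr_mag.values + rng.normal(0.0, 1.0, cvr_mag.shape) * cfg.noise_sd
    delay = VolumeGrid(
        cfg.delay_baseline + rng.normal(0.0, 1.0, cvr_mag.shape) * cfg.delay_sd,
        cfg.spacing_cvr, midline_index=cvr_mag.midline_index)
    highres = truth_grid.with_values(
        field_t2 + rng.normal(0.0, 1.0, cfg.grid_shape) * cfg.noise_sd)

    cov = covariates if covariates is not None else _draw_covariates(rng)
    cov = dict(cov)
    cov.setdefault("patient_id", f"p{case_index:04d}")
    cov["n_vessel_clusters"] = cov.get("n_vessel_clusters", n_clusters)
    cov["has_cluster"] = int(cov["n_vessel_clusters"] >= 1)

    case = PhantomCase(
        config=cfg,
        case_id=f"case{case_index:03d}",
        icv_mask=icv, wm_mask=wm, ventricle_mask=vent,
        cluster_masks=[wm.with_values(m) for m in masks],
        labels=VolumeGrid(labels, cfg.spacing_t2, midline_index=mid),
        cvr_magnitude=cvr_mag, cvr_delay=delay,
        cvr_magnitude_highres=highres, cvr_magnitude_truth=truth_grid,
        truth_clusters=pd.DataFrame(rows),
        covariates=cov,
    )
    case.validate()
    return case


# ----------------------------------------------------------------------
# cohort generation
# ----------------------------------------------------------------------

#: proportional-odds thresholds (relative to -intercept) for counts 0..4
_PO_THRESHOLD_STEPS = (0.0, 1.1, 2.2, 3.3)


def _sample_count(rng: np.random.Generator, eta: float, intercept: float) -> int:
    u = eta + rng.logistic()
    return int(sum(u > (-intercept + s) for s in _PO_THRESHOLD_STEPS))


#: generative means used to centre covariates in the latent predictor
_COVARIATE_CENTERS = {
    "age": 57.0, "male": 0.46, "wmh_norm_log10": -1.9, "lacune_count": 3.0,
    "microbleeds": 1.5, "pvs_total_score": 5.0, "cvr_nawm": 0.20, "cvr_wmh": 0.12,
}


def generate_cohort(config: PhantomConfig, n_patients: int,
                    effect_spec: dict[str, float] | None = None,
                    with_volumes: bool | int = True,
                    max_clusters_per_case: int = 4) -> list[PhantomCase]:
    """Generate a cohort of synthetic patients.

    Vessel-cluster counts (0..4, the top category standing for "4 or
    more") are sampled from a proportional-odds model whose latent linear
    predictor is ``intercept + sum_k beta_k * (x_k - mean_k)`` with
    coefficients taken from ``effect_spec`` (log-odds per unit covariate;
    the ``"intercept"`` entry sets the presence log-odds at covariate
    means, default 0 i.e. 50% prevalence).  The cumulative split at
    count >= 1 is then exactly a logistic model with the same
    coefficients, so both the logistic and the ordinal analysis layers
    have a recoverable truth.

    ``with_volumes=False`` skips volume rasterisation (covariate and
    count truth only), which makes large-n cohorts cheap; an integer N
    rasterises volumes for the first N patients only.
    """
    config.validate()
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    effect_spec = dict(effect_spec or {})
    intercept = float(effect_spec.pop("intercept", 0.0))
    if with_volumes is True:
        n_vol = n_patients
    elif with_volumes is False:
        n_vol = 0
    else:
        n_vol = int(with_volumes)

    cases: list[PhantomCase] = []
    for idx in range(n_patients):
        rng = _case_rng(config.seed, idx)
        cov = _draw_covariates(rng)
        eta = 0.0
        for term, beta in effect_spec.items():
            if term not in cov:
                raise KeyError(f"effect_spec term {term!r} is not a generated covariate")
            eta += float(beta) * (float(cov[term]) - _COVARIATE_CENTERS.get(term, 0.0))
        count = _sample_count(rng, eta, intercept)
        cov["patient_id"] = f"p{idx:04d}"
        cov["n_vessel_clusters"] = count
        cov["has_cluster"] = int(count >= 1)
        if idx < n_vol:
            case = generate_case(config, case_index=idx,
                                 n_clusters=min(count, max_clusters_per_case),
                                 covariates=cov, rng=rng)
        else:
            case = PhantomCase(config=config, case_id=f"case{idx:03d}", covariates=cov)
        cases.append(case)
    return cases


def cohort_frame(cases: list[PhantomCase]) -> pd.DataFrame:
    """Per-patient covariate table for the cohort analysis layer."""
    return pd.DataFrame([c.covariates for c in cases]).set_index("patient_id")


# ----------------------------------------------------------------------
# on-disk representation
# ----------------------------------------------------------------------

def write_case(case: PhantomCase, directory: str | Path) -> dict:
    """Write a case to disk (NIfTI volumes + CSV truth tables + manifest).

    The manifest's ``volumes`` entry lists exactly the analysis inputs:
    3 masks, the per-cluster masks, and the 2 CVR maps.  Auxiliary truth
    volumes (tissue labels, structural-resolution CVR copies) go under
    ``extras``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if not case.has_volumes:
        raise ValueError("case has no volumes to write (generated with with_volumes=False)")

    volumes: dict[str, str] = {}

    def _save(name: str, grid: VolumeGrid, registry: dict) -> None:
        path = directory / f"{name}.nii.gz"
        to_nifti(grid, path)
        registry[name] = path.name

    _save("icv_mask", case.icv_mask, volumes)
    _save("wm_mask", case.wm_mask, volumes)
    _save("ventricle_mask", case.ventricle_mask, volumes)
    for i, cm in enumerate(case.cluster_masks):
        _save(f"cluster_{i:02d}", cm, volumes)
    _save("cvr_magnitude", case.cvr_magnitude, volumes)
    _save("cvr_delay", case.cvr_delay, volumes)

    extras: dict[str, str] = {}
    if case.labels is not None:
        _save("labels", case.labels, extras)
    if case.cvr_magnitude_highres is not None:
        _save("cvr_magnitude_highres", case.cvr_magnitude_highres, extras)
    if case.cvr_magnitude_truth is not None:
        _save("cvr_magnitude_truth", case.cvr_magnitude_truth, extras)

    tables: dict[str, str] = {}
    truth_path = directory / "truth_clusters.csv"
    case.truth_clusters.to_csv(truth_path, index=False)
    tables["truth_clusters"] = truth_path.name
    cov_path = directory / "covariates.csv"
    pd.DataFrame([case.covariates]).to_csv(cov_path, index=False)
    tables["covariates"] = cov_path.name

    manifest = {
        "case_id": case.case_id,
        "seed": case.config.seed,
        "n_clusters": len(case.cluster_masks),
        "midline_index": case.config.midline_index,
        "volumes": volumes,
        "extras": extras,
        "tables": tables,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_case(directory: str | Path) -> PhantomCase:
    """Round-trip loader for :func:`write_case` output."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    mid = manifest["midline_index"]

    def _load(name: str, registry: dict) -> VolumeGrid | None:
        if name not in registry:
            return None
        return from_nifti(directory / registry[name], midline_index=mid)

    vols, extras = manifest["volumes"], manifest["extras"]
    cluster_names = sorted(n for n in vols if n.startswith("cluster_"))
    truth = pd.read_csv(directory / manifest["tables"]["truth_clusters"]) \
        if (directory / manifest["tables"]["truth_clusters"]).exists() else pd.DataFrame()
    cov_df = pd.read_csv(directory / manifest["tables"]["covariates"])
    case = PhantomCase(
        config=PhantomConfig(seed=manifest["seed"]),
        case_id=manifest["case_id"],
        icv_mask=_load("icv_mask", vols).astype_binary(),
        wm_mask=_load("wm_mask", vols).astype_binary(),
        ventricle_mask=_load("ventricle_mask", vols).astype_binary(),
        cluster_masks=[_load(n, vols).astype_binary() for n in cluster_names],
        labels=_load("labels", extras),
        cvr_magnitude=_load("cvr_magnitude", vols),
        cvr_delay=_load("cvr_delay", vols),
        cvr_magnitude_highres=_load("cvr_magnitude_highres", extras),
        cvr_magnitude_truth=_load("cvr_magnitude_truth", extras),
        truth_clusters=truth,
        covariates=cov_df.iloc[0].to_dict() if len(cov_df) else {},
    )
    return case
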