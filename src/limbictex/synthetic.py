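"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a longitudinal two-group psychosis cohort (ECT +
medication vs. medication only, both scanned at baseline and follow-up)
plus a cross-sectional healthy-control (HC) reference group, on a grid of
disjoint ellipsoidal limbic ROIs.

Intra-ROI texture is a Gaussian random field: white noise smoothed with an
isotropic Gaussian kernel of width σ (voxels). σ is the single coarseness
knob — larger σ produces larger same-level zones after discretization and
hence larger GLSZM large area emphasis (LAE). Patients start with a σ
deficit relative to HC; at follow-up the ECT group's σ moves back toward
the HC value (its normalized texture "approaches zero") while the
medication-only group is unchanged in expectation. ROI volumes carry an
analogous planted group×time effect in mm³. Clinical score changes are
linearly coupled to the planted texture change in the ECT group only;
in the MED group they are independent noise.

A fast outcome-level simulator (`simulate_feature_table`) draws values
directly from the mixed model the statistics stage assumes, for Monte
Carlo calibration studies (type-I error, power, bias) where rendering
images would add nothing but runtime.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .image_io import (
    DEFAULT_ROI_REGISTRY,
    IntensityVolume,
    SegmentationMap,
    write_segmentation,
    write_volume,
)

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "DEFAULT_ROI_SEMI_AXES",
    "ellipsoid_mask",
    "make_textured_roi",
    "simulate_cohort",
    "simulate_feature_table",
]

logger = logging.getLogger(__name__)

#: Ellipsoid semi-axes (voxels) per ROI family. Relative sizes loosely follow
#: limbic anatomy (hippocampus largest, accumbens smallest); absolute brain
#: realism is out of scope.
DEFAULT_ROI_SEMI_AXES: dict[str, tuple[float, float, float]] = {
    "Hippocampus": (7.0, 6.0, 5.0),
    "Amygdala": (5.0, 4.5, 4.0),
    "Accumbens-area": (4.0, 3.5, 3.0),
    "VentralDC": (6.0, 5.0, 4.5),
    "caudalanteriorcingulate": (5.5, 5.0, 4.0),
    "rostralanteriorcingulate": (6.0, 5.0, 4.0),
    "parahippocampal": (6.0, 5.5, 4.5),
}

# Target cohort demographics: (mean, sd) by group.
_AGE = {"ECT": (32.94, 6.89), "MED": (34.00, 9.20), "HC": (25.49, 8.12)}
_MALE_FRAC = {"ECT": 19 / 36, "MED": 17 / 27, "HC": 39 / 70}
_OZ_DOSE = {"ECT": (44.27, 21.91), "MED": (19.94, 8.59)}
_PANSS_BASE = {  # (mean, sd) at baseline per group
    "ECT": {"panss_total": (77.25, 20.56), "panss_pos": (20.56, 6.45),
            "panss_neg": (19.25, 6.48), "panss_gen": (37.61, 10.69), "cgi_s": (5.22, 0.72)},
    "MED": {"panss_total": (61.33, 12.00), "panss_pos": (16.93, 4.51),
            "panss_neg": (16.00, 6.46), "panss_gen": (28.41, 6.46), "cgi_s": (4.52, 0.80)},
}
# Mean change baseline -> follow-up per group (from the follow-up severity above).
_PANSS_DELTA_MEAN = {
    "ECT": {"panss_total": -16.94, "panss_pos": -5.75, "panss_neg": -2.89,
            "panss_gen": -7.94, "cgi_s": -1.00},
    "MED": {"panss_total": -3.22, "panss_pos": 2.14, "panss_neg": 0.07,
            "panss_gen": -1.22, "cgi_s": -0.15},
}
_PANSS_DELTA_SD = {"panss_total": 9.0, "panss_pos": 3.5, "panss_neg": 3.0,
                   "panss_gen": 4.5, "cgi_s": 0.55}
# Coupling slope per 1-sd planted texture change, ECT group only. Negative:
# texture normalizing toward HC accompanies symptom improvement.
_COUPLING = {"panss_total": -8.0, "panss_pos": -2.5, "panss_neg": -1.8,
             "panss_gen": -4.0, "cgi_s": -0.40}
_SCORE_BOUNDS = {"panss_total": (30, 210), "panss_pos": (7, 49), "panss_neg": (7, 49),
                 "panss_gen": (16, 112), "cgi_s": (1, 7)}


def _roi_family(name: str) -> str:
    for fam in DEFAULT_ROI_SEMI_AXES:
        if fam in name:
            return fam
    raise KeyError(f"no semi-axis entry matches ROI {name!r}")


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Texture parameters are Gaussian-field smoothing widths in voxels; the
    planted group×time texture effect is the mean increment of σ in the ECT
    group at follow-up. Volume effects are in mm³ of analytic ellipsoid
    volume. Group sizes default to the 36/27/70 cohort the pipeline targets.
    """

    n_ect: int = 36
    n_med: int = 27
    n_hc: int = 70
    rois: tuple[str, ...] = tuple(DEFAULT_ROI_REGISTRY.values())
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: tuple[float, float, float] = (1.0, 0.98, 0.98)
    sigma_hc: float = 1.6          # HC texture correlation length (voxels)
    sigma_patient: float = 1.25    # patient baseline correlation length
    sigma_subject_sd: float = 0.07  # between-subject spread of sigma
    texture_effect: float = 0.22   # ECT follow-up increment of sigma (toward HC)
    texture_change_sd: float = 0.06  # subject-level spread of the sigma change
    volume_effect: float = 45.0    # ECT follow-up volume increment (mm³)
    volume_subject_sd: float = 0.06  # between-subject fractional volume spread
    volume_change_sd: float = 12.0   # subject-level spread of the volume change (mm³)
    coupling_roi: str = "Left-Hippocampus"
    clinical_coupling: dict = field(default_factory=lambda: dict(_COUPLING))
    seed: int = 0

    def __post_init__(self) -> None:
        for name, n in (("n_ect", self.n_ect), ("n_med", self.n_med), ("n_hc", self.n_hc)):
            if n < 3:
                raise ValueError(f"{name} must be >= 3, got {n}")
        if self.sigma_hc <= 0 or self.sigma_patient <= 0:
            raise ValueError("texture correlation lengths must be positive")
        unknown = [r for r in self.rois if r not in DEFAULT_ROI_REGISTRY.values()]
        if unknown:
            raise ValueError(f"unknown ROIs: {unknown}")
        if self.coupling_roi not in self.rois:
            raise ValueError(f"coupling_roi {self.coupling_roi!r} not among rois")


@dataclass
class SyntheticCohort:
    """Manifest + ground truth; volumes on disk (paths) or in memory."""

    manifest: pd.DataFrame
    ground_truth: dict
    registry: dict[int, str]
    images: dict | None = None  # (subject_id, timepoint) -> (IntensityVolume, SegmentationMap)


def ellipsoid_mask(semi_axes, box_shape=None) -> np.ndarray:
    """Boolean voxel mask of an ellipsoid centered in its box."""
    a, b, c = semi_axes
    if box_shape is None:
        box_shape = tuple(2 * int(math.ceil(s)) + 1 for s in (a, b, c))
    center = [(n - 1) / 2 for n in box_shape]
    zi, yi, xi = np.ogrid[: box_shape[0], : box_shape[1], : box_shape[2]]
    return ((zi - center[0]) / a) ** 2 + ((yi - center[1]) / b) ** 2 + (
        (xi - center[2]) / c
    ) ** 2 <= 1.0


def make_textured_roi(
    semi_axes, sigma: float, rng: np.random.Generator, box_shape=None
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-random-field patch masked to an ROI ellipsoid.

    White standard-normal noise is smoothed with an isotropic Gaussian
    kernel of width ``sigma`` voxels; larger sigma yields larger
    same-level zones after discretization (coarser texture, higher LAE).

    Returns
    -------
    (patch, mask) : the smoothed field over the box and the ellipsoid mask.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    mask = ellipsoid_mask(semi_axes, box_shape)
    noise = rng.standard_normal(mask.shape)
    return gaussian_filter(noise, sigma), mask


#: Lattice cell edge (voxels) hosting one ROI ellipsoid; large enough for the
#: biggest default ellipsoid after subject- and effect-level volume scaling.
ROI_CELL = 18


def _lattice_centers(grid_shape, n_rois: int, cell: int = ROI_CELL) -> list[tuple[int, int, int]]:
    per_axis = [g // cell for g in grid_shape]
    slots = per_axis[0] * per_axis[1] * per_axis[2]
    if slots < n_rois:
        raise ValueError(
            f"grid {grid_shape} holds only {slots} ROI cells of size {cell}; need {n_rois}"
        )
    centers = []
    for i in range(per_axis[0]):
        for j in range(per_axis[1]):
            for k in range(per_axis[2]):
                centers.append((i * cell + cell // 2, j * cell + cell // 2, k * cell + cell // 2))
    return centers[:n_rois]


def _analytic_volume(semi_axes, voxel_volume: float) -> float:
    a, b, c = semi_axes
    return 4.0 / 3.0 * math.pi * a * b * c * voxel_volume


def simulate_cohort(
    spec: CohortSpec, out_dir: str | os.PathLike | None = None
) -> SyntheticCohort:
    """Generate a full image cohort per ``spec``.

    HC subjects are scanned once (baseline); patients twice. If ``out_dir``
    is given, NIfTI volumes/segmentations, the manifest CSV and a
    ground-truth JSON are written there; otherwise images stay in memory.
    Identical spec (including seed) reproduces bit-identical images.
    """
    rng = np.random.default_rng(spec.seed)
    name_to_code = {v: k for k, v in DEFAULT_ROI_REGISTRY.items()}
    registry = {name_to_code[r]: r for r in spec.rois}
    centers = _lattice_centers(spec.grid_shape, len(spec.rois))
    voxvol = float(np.prod(spec.voxel_size))

    subjects = (
        [(f"ECT{i:03d}", "ECT") for i in range(spec.n_ect)]
        + [(f"MED{i:03d}", "MED") for i in range(spec.n_med)]
        + [(f"HC{i:03d}", "HC") for i in range(spec.n_hc)]
    )

    manifest_rows = []
    images: dict = {}
    truth_subjects = {}
    clip_events = 0
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)

    for sid, grp in subjects:
        timepoints = ("baseline",) if grp == "HC" else ("baseline", "followup")
        age = rng.normal(*_AGE[grp])
        sex = "M" if rng.random() < _MALE_FRAC[grp] else "F"
        dose = max(0.0, rng.normal(*_OZ_DOSE[grp])) if grp != "HC" else 0.0
        etiv = rng.normal(1.5e6, 1.5e5)

        # per-ROI planted parameters
        roi_truth = {}
        for roi in spec.rois:
            base_sigma = spec.sigma_hc if grp == "HC" else spec.sigma_patient
            sig_b = max(0.2, base_sigma + rng.normal(0.0, spec.sigma_subject_sd))
            semi = DEFAULT_ROI_SEMI_AXES[_roi_family(roi)]
            vol_mult = max(0.5, rng.normal(1.0, spec.volume_subject_sd))
            vol_b = _analytic_volume(semi, voxvol) * vol_mult
            if grp == "ECT":
                d_sig = spec.texture_effect + rng.normal(0.0, spec.texture_change_sd)
                d_vol = spec.volume_effect + rng.normal(0.0, spec.volume_change_sd)
            elif grp == "MED":
                d_sig = rng.normal(0.0, spec.texture_change_sd)
                d_vol = rng.normal(0.0, spec.volume_change_sd)
            else:
                d_sig, d_vol = 0.0, 0.0
            roi_truth[roi] = {
                "sigma_baseline": sig_b, "sigma_change": d_sig,
                "volume_baseline": vol_b, "volume_change": d_vol,
                "base_scale": vol_mult,
            }

        # clinical scores
        scores = {}
        if grp == "HC":
            for cv in _PANSS_BASE["ECT"]:
                scores[cv] = {"baseline": np.nan}
        else:
            u = roi_truth[spec.coupling_roi]["sigma_change"]
            u_std = (u - (spec.texture_effect if grp == "ECT" else 0.0)) / spec.texture_change_sd
            for cv, (m, s) in _PANSS_BASE[grp].items():
                base = rng.normal(m, s)
                if grp == "ECT":
                    delta = (
                        _PANSS_DELTA_MEAN[grp][cv]
                        + spec.clinical_coupling[cv] * u_std
                        + rng.normal(0.0, _PANSS_DELTA_SD[cv] / 2)
                    )
                else:
                    delta = _PANSS_DELTA_MEAN[grp][cv] + rng.normal(0.0, _PANSS_DELTA_SD[cv])
                lo, hi = _SCORE_BOUNDS[cv]
                vals = {"baseline": base, "followup": base + delta}
                for tp, v in vals.items():
                    if v < lo or v > hi:
                        clip_events += 1
                        vals[tp] = float(np.clip(v, lo, hi))
                scores[cv] = vals

        for tp in timepoints:
            vol_data = np.zeros(spec.grid_shape, dtype=np.float64)
            seg_data = np.zeros(spec.grid_shape, dtype=np.int32)
            for roi, center in zip(spec.rois, centers):
                t = roi_truth[roi]
                sig = t["sigma_baseline"] + (t["sigma_change"] if tp == "followup" else 0.0)
                v_target = t["volume_baseline"] + (
                    t["volume_change"] if tp == "followup" else 0.0
                )
                semi0 = DEFAULT_ROI_SEMI_AXES[_roi_family(roi)]
                scale = (v_target / _analytic_volume(semi0, voxvol)) ** (1.0 / 3.0)
                scale = min(scale, (ROI_CELL - 2) / (2.0 * max(semi0)))  # stay inside the cell
                semi = tuple(s * scale for s in semi0)
                box = tuple(2 * int(math.ceil(s)) + 2 for s in semi)
                patch, mask = make_textured_roi(semi, max(0.2, sig), rng, box_shape=box)
                sl = tuple(
                    slice(c - n // 2, c - n // 2 + n) for c, n in zip(center, box)
                )
                vol_data[sl][mask] = patch[mask]
                seg_data[sl][mask] = name_to_code[roi]
            iv = IntensityVolume(vol_data, spec.voxel_size)
            sm_ = SegmentationMap(seg_data, spec.voxel_size, registry=registry)
            row = {
                "subject_id": sid, "group": grp, "timepoint": tp,
                "age": age, "sex": sex, "oz_dose": dose, "etiv": etiv,
            }
            for cv in scores:
                row[cv] = scores[cv].get(tp, np.nan)
            if out_dir is not None:
                ipath = os.path.join(str(out_dir), f"{sid}_{tp}_T1.nii")
                spath = os.path.join(str(out_dir), f"{sid}_{tp}_seg.nii")
                write_volume(iv, ipath)
                write_segmentation(sm_, spath)
                row["image_path"], row["seg_path"] = ipath, spath
            else:
                images[(sid, tp)] = (iv, sm_)
            manifest_rows.append(row)

        truth_subjects[sid] = {"group": grp, "rois": roi_truth}

    if clip_events:
        logger.info("clipped %d clinical scores to their valid ranges", clip_events)

    manifest = pd.DataFrame(manifest_rows)
    truth = {
        "spec": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(spec).items()},
        "subjects": truth_subjects,
        "n_clipped_scores": clip_events,
    }
    cohort = SyntheticCohort(
        manifest=manifest,
        ground_truth=truth,
        registry=registry,
        images=images if out_dir is None else None,
    )
    if out_dir is not None:
        from .image_io import write_registry

        write_registry(registry, os.path.join(str(out_dir), "registry.tsv"))
        manifest.to_csv(os.path.join(str(out_dir), "manifest.csv"), index=False)
        with open(os.path.join(str(out_dir), "ground_truth.json"), "w") as fh:
            json.dump(truth, fh, indent=1)
    return cohort


def simulate_feature_table(
    n_ect: int = 36,
    n_med: int = 27,
    delta: float = 0.0,
    rng: np.random.Generator | int | None = None,
    subject_sd: float = 1.0,
    noise_sd: float = 0.7,
    roi: str = "sim-roi",
    feature: str = "sim-feature",
) -> tuple[pd.DataFrame, float]:
    """Outcome-level simulator for mixed-model calibration studies.

    Draws two-timepoint outcomes directly from the model the statistics
    stage assumes — subject random intercept (sd ``subject_sd``), residual
    sd ``noise_sd``, small nonzero covariate effects, and a group×time
    interaction of ``delta`` change-score standard deviations
    (sd_change = √2·noise_sd).

    Returns
    -------
    (table, true_beta) : the long feature table (with covariates) and the
    planted interaction coefficient on the outcome scale.
    """
    rng = np.random.default_rng(rng)
    sd_change = math.sqrt(2.0) * noise_sd
    true_beta = delta * sd_change
    rows = []
    for grp, n in (("ECT", n_ect), ("MED", n_med)):
        age = rng.normal(*_AGE[grp], size=n)
        sex = (rng.random(n) < _MALE_FRAC[grp]).astype(float)
        dose = np.maximum(0.0, rng.normal(*_OZ_DOSE[grp], size=n))
        intercept = rng.normal(0.0, subject_sd, size=n)
        g = 1.0 if grp == "ECT" else 0.0
        for i in range(n):
            base_fix = 0.02 * (age[i] - 30) + 0.3 * sex[i] + 0.01 * (dose[i] - 30) - 0.4 * g
            for t, tp in enumerate(("baseline", "followup")):
                y = (
                    base_fix + intercept[i] + 0.15 * t + true_beta * g * t
                    + rng.normal(0.0, noise_sd)
                )
                rows.append({
                    "subject_id": f"{grp}{i:03d}", "group": grp, "timepoint": tp,
                    "roi": roi, "feature": feature, "value": y,
                    "age": age[i], "sex": sex[i], "oz_dose": dose[i],
                })
    return pd.DataFrame(rows), true_beta
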