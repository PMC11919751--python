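"""Gray level size zone matrices (GLSZM) and the 16 derived texture features.

A *zone* is a maximal 3D-connected set of voxels that share one discretized
gray level. The size-zone matrix P(i, j) counts the zones of gray level i
and voxel size j inside an ROI; p(i, j) = P(i, j) / Nz is its normalized
form, where Nz is the total zone count. Because zones are defined purely by
connectivity, every GLSZM feature is invariant under rotations and axis
permutations of the image grid — the property that makes the family suited
to neuroimaging data which may be rotated during processing.

Coarse texture (large same-level zones) drives large area emphasis (LAE)
up; fine, noise-like texture drives small area emphasis (SAE) up. The
remaining features summarize the gray-level and size marginals of P.

Feature definitions follow the standard radiomics conventions:

======================================  =============================================
small_area_emphasis                     Σ P(i,j)/j² / Nz
large_area_emphasis                     Σ P(i,j)·j² / Nz
gray_level_nonuniformity                Σ_i (Σ_j P)² / Nz
gray_level_nonuniformity_normalized     Σ_i (Σ_j P)² / Nz²
size_zone_nonuniformity                 Σ_j (Σ_i P)² / Nz
size_zone_nonuniformity_normalized      Σ_j (Σ_i P)² / Nz²
zone_percentage                         Nz / Np  (Np = ROI voxel count)
gray_level_variance                     Σ p(i,j)·(i − μ)²,  μ = Σ p(i,j)·i
zone_variance                           Σ p(i,j)·(j − ν)²,  ν = Σ p(i,j)·j
zone_entropy                            −Σ p(i,j)·log2 p(i,j)
low_gray_level_zone_emphasis            Σ P(i,j)/i² / Nz
high_gray_level_zone_emphasis           Σ P(i,j)·i² / Nz
small_area_low_gray_level_emphasis      Σ P(i,j)/(i²·j²) / Nz
small_area_high_gray_level_emphasis     Σ P(i,j)·i²/j² / Nz
large_area_low_gray_level_emphasis      Σ P(i,j)·j²/i² / Nz
large_area_high_gray_level_emphasis     Σ P(i,j)·i²·j² / Nz
======================================  =============================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .image_io import ROISample

__all__ = [
    "FEATURE_NAMES",
    "DiscretizedROI",
    "Zone",
    "GLSZMatrix",
    "discretize",
    "label_zones",
    "build_glszm",
    "compute_features",
    "glszm_features",
    "GLSZMFeatureExtractor",
]

#: Canonical order of the 16 GLSZM features (also the tie-break order for
#: feature selection downstream).
FEATURE_NAMES: tuple[str, ...] = (
    "small_area_emphasis",
    "large_area_emphasis",
    "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized",
    "size_zone_nonuniformity",
    "size_zone_nonuniformity_normalized",
    "zone_percentage",
    "gray_level_variance",
    "zone_variance",
    "zone_entropy",
    "low_gray_level_zone_emphasis",
    "high_gray_level_zone_emphasis",
    "small_area_low_gray_level_emphasis",
    "small_area_high_gray_level_emphasis",
    "large_area_low_gray_level_emphasis",
    "large_area_high_gray_level_emphasis",
)


@dataclass
class DiscretizedROI:
    """ROI voxels mapped to integer gray levels 1..n_levels."""

    levels: np.ndarray  # 1D int, values in 1..n_levels
    coords: np.ndarray  # (n, 3) int
    n_levels: int  # Ng

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64).ravel()
        self.coords = np.asarray(self.coords, dtype=np.int64)
        if len(self.levels) != len(self.coords):
            raise ValueError("levels and coords length mismatch")
        if len(self.levels) == 0:
            raise ValueError("empty discretized ROI")
        if self.levels.min() < 1 or self.levels.max() > self.n_levels:
            raise ValueError("levels must lie in 1..n_levels")


@dataclass(frozen=True)
class Zone:
    """One maximal connected component of equal-level voxels."""

    level: int
    size: int


@dataclass
class GLSZMatrix:
    """Size-zone matrix with its counts and normalization.

    ``P[a, b]`` counts zones of gray level ``gray_levels[a]`` and size
    ``zone_sizes[b]``; only observed levels and sizes are stored (sparse in
    the size axis — a dense axis of length Np would be wasteful and every
    feature formula only touches observed (i, j) pairs).
    """

    P: np.ndarray  # (n_gray, n_sizes) int zone counts
    gray_levels: np.ndarray  # observed levels i (ascending)
    zone_sizes: np.ndarray  # observed sizes j (ascending)
    n_gray: int  # Ng, number of discrete gray levels in the ROI
    n_sizes: int  # Ns, number of distinct zone sizes
    n_zones: int  # Nz

    @property
    def p(self) -> np.ndarray:
        """Normalized matrix p(i, j) = P(i, j) / Nz."""
        return self.P / self.n_zones

    @property
    def mu(self) -> float:
        """Zone-weighted mean gray level μ = Σ p(i,j)·i."""
        return float((self.p * self.gray_levels[:, None]).sum())

    @property
    def n_voxels(self) -> int:
        """Total ROI voxel count Σ P(i,j)·j."""
        return int((self.P * self.zone_sizes[None, :]).sum())


def discretize(sample: ROISample, n_bins: int = 16) -> DiscretizedROI:
    """Equal-width binning of the within-ROI intensity range into n_bins levels.

    A constant ROI maps entirely to level 1 with Ng = 1. Binning with a
    fixed bin *count* (rather than width) makes the levels invariant to any
    positive affine rescaling of the intensities.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    x = sample.intensities
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return DiscretizedROI(np.ones(len(x), dtype=np.int64), sample.coords, 1)
    # floor onto n_bins equal-width bins; the max maps into the top bin
    levels = np.minimum((n_bins * (x - lo) / (hi - lo)).astype(np.int64) + 1, n_bins)
    return DiscretizedROI(levels, sample.coords, n_bins)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def _level_grid(d: DiscretizedROI) -> np.ndarray:
    """Embed the ROI in its bounding box; 0 marks outside-ROI voxels."""
    lo = d.coords.min(axis=0)
    hi = d.coords.max(axis=0)
    grid = np.zeros(tuple(hi - lo + 1), dtype=np.int64)
    idx = d.coords - lo
    grid[idx[:, 0], idx[:, 1], idx[:, 2]] = d.levels
    return grid


def zones_from_grid(grid: np.ndarray, connectivity: int = 26) -> list[Zone]:
    """Zones of a 3D integer level grid (0 = outside the ROI)."""
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of 6, 18, 26, got {connectivity}")
    structure = _STRUCTURES[connectivity]
    zones: list[Zone] = []
    for level in np.unique(grid):
        if level == 0:
            continue
        labeled, n_comp = ndimage.label(grid == level, structure=structure)
        sizes = np.bincount(labeled.ravel())[1:]  # skip background count
        zones.extend(Zone(int(level), int(s)) for s in sizes)
    return zones


def label_zones(d: DiscretizedROI, connectivity: int = 26) -> list[Zone]:
    """Maximal connected components of equal-level voxels.

    Every ROI voxel belongs to exactly one zone; Σ size over zones equals
    the ROI voxel count.
    """
    return zones_from_grid(_level_grid(d), connectivity)


def build_glszm(zones: list[Zone]) -> GLSZMatrix:
    """Accumulate a zone list into the size-zone matrix P(i, j)."""
    if not zones:
        raise ValueError("cannot build a GLSZM from an empty zone list")
    levels = np.array([z.level for z in zones])
    sizes = np.array([z.size for z in zones])
    gray_levels, li = np.unique(levels, return_inverse=True)
    zone_sizes, si = np.unique(sizes, return_inverse=True)
    P = np.zeros((len(gray_levels), len(zone_sizes)), dtype=np.int64)
    np.add.at(P, (li, si), 1)
    return GLSZMatrix(
        P=P,
        gray_levels=gray_levels,
        zone_sizes=zone_sizes,
        n_gray=len(gray_levels),
        n_sizes=len(zone_sizes),
        n_zones=len(zones),
    )


def compute_features(m: GLSZMatrix) -> dict[str, float]:
    """Evaluate all 16 GLSZM features; finite for any valid matrix."""
    P = m.P.astype(float)
    i = m.gray_levels.astype(float)[:, None]
    j = m.zone_sizes.astype(float)[None, :]
    Nz = float(m.n_zones)
    Np = float(m.n_voxels)
    p = P / Nz

    row = P.sum(axis=1)  # Σ_j P(i,j), per gray level
    col = P.sum(axis=0)  # Σ_i P(i,j), per zone size
    mu = float((p * i).sum())
    nu = float((p * j).sum())
    p_pos = p[p > 0]

    return {
        "small_area_emphasis": float((P / j**2).sum() / Nz),
        "large_area_emphasis": float((P * j**2).sum() / Nz),
        "gray_level_nonuniformity": float((row**2).sum() / Nz),
        "gray_level_nonuniformity_normalized": float((row**2).sum() / Nz**2),
        "size_zone_nonuniformity": float((col**2).sum() / Nz),
        "size_zone_nonuniformity_normalized": float((col**2).sum() / Nz**2),
        "zone_percentage": float(Nz / Np),
        "gray_level_variance": float((p * (i - mu) ** 2).sum()),
        "zone_variance": float((p * (j - nu) ** 2).sum()),
        "zone_entropy": float(-(p_pos * np.log2(p_pos)).sum()),
        "low_gray_level_zone_emphasis": float((P / i**2).sum() / Nz),
        "high_gray_level_zone_emphasis": float((P * i**2).sum() / Nz),
        "small_area_low_gray_level_emphasis": float((P / (i**2 * j**2)).sum() / Nz),
        "small_area_high_gray_level_emphasis": float((P * i**2 / j**2).sum() / Nz),
        "large_area_low_gray_level_emphasis": float((P * j**2 / i**2).sum() / Nz),
        "large_area_high_gray_level_emphasis": float((P * i**2 * j**2).sum() / Nz),
    }


def glszm_features(
    sample: ROISample, n_bins: int = 16, connectivity: int = 26
) -> dict[str, float]:
    """Discretize → label zones → build GLSZM → all 16 features."""
    zones = label_zones(discretize(sample, n_bins=n_bins), connectivity=connectivity)
    return compute_features(build_glszm(zones))


class GLSZMFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping ROI samples to a 16-column GLSZM feature frame.

    Parameters
    ----------
    n_bins : int, default 16
        Number of discrete gray levels for the equal-width binning.
    connectivity : {6, 18, 26}, default 26
        3D neighborhood defining zone connectedness.
    """

    def __init__(self, n_bins: int = 16, connectivity: int = 26):
        self.n_bins = n_bins
        self.connectivity = connectivity

    def fit(self, X, y=None):
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")
        if self.connectivity not in (6, 18, 26):
            raise ValueError(f"connectivity must be 6, 18 or 26, got {self.connectivity}")
        self.feature_names_out_ = list(FEATURE_NAMES)
        return self

    def transform(self, X: list[ROISample]) -> pd.DataFrame:
        """Compute features for a list of ROISample objects."""
        if not hasattr(self, "feature_names_out_"):
            self.fit(X)
        rows = [
            glszm_features(s, n_bins=self.n_bins, connectivity=self.connectivity)
            for s in X
        ]
        return pd.DataFrame(rows, columns=list(FEATURE_NAMES))

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
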