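"""Topological voxel analysis (TVA) of nuclear chromatin textures.

Each segmented nucleus is partitioned into cubes of constant physical size
(default 500 nm per side, set by the resolution limit of the imaging system:
at 120 x 120 x 250 nm pixel pitch one cube spans 5 x 5 x 2 pixels).  Per cube
three texture parameters are computed:

``cond``
    Chromatin condensation: the cube's mean DAPI intensity divided by a
    robust per-image intensity scale (99.5th percentile of within-ROI DAPI),
    clipped to [0, 1].  DAPI intensity proxies local genomic-DNA density.
``meth``
    Relative DNA methylation: the analogous scale-normalized mean of the MeC
    channel.
``assoc``
    Spatial association of the two signals: the fraction of the cube's pixels
    whose channels agree in thresholded state (both below or both at/above
    their image-inherent low-intensity thresholds).  A cube that is entirely
    low (or entirely high) in both channels is in perfect agreement and scores
    1 — the degenerate case is continuous with the generic one.

Per-nucleus scalars are the occupancy-weighted (volume-weighted) means of the
per-cube values, so partial cubes at the ROI boundary contribute in
proportion to the ROI volume they actually contain.  Cube lattices are
anchored at each ROI's bounding-box corner, which makes the features
translation invariant for identical nuclei.

Topology is captured by the normalized radial position r of each cube: the
physical distance from the ROI centroid to the cube center, divided by the
distance from the centroid to the ROI surface *along the same direction* (so
an ellipsoidal nucleus is not conflated with a topological gradient), clipped
to [0, 1].  Radial profiles are occupancy-weighted shell means of the
per-cube parameters from center (r=0) to periphery (r=1).

Also computed per nucleus: LID% and LIM%, the percentages of ROI pixels below
the image-inherent low-intensity threshold of the DAPI and MeC channel, and
the raw mean channel intensities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skimage.filters import threshold_otsu

from .errors import ConfigurationError, SegmentationError
from .image_io import ImageStack
from .segmentation import NucleusROI

logger = logging.getLogger(__name__)

DEFAULT_CUBE_SIZE_NM = 500.0
DEFAULT_SCALE_PERCENTILE = 99.5
FEATURE_NAMES = ("cond", "meth", "assoc")


@dataclass
class VoxelGrid:
    """Partition of one nuclear ROI into fixed-size physical cubes.

    ``cube_ids`` maps every ROI pixel (aligned with ``roi.coords``) to a cube
    index in ``[0, n_cubes)``; ``occupancy`` counts ROI pixels per cube and
    sums exactly to the ROI volume; ``r`` is the normalized radial position of
    each cube center.
    """

    cube_size_nm: float
    cube_ids: np.ndarray
    occupancy: np.ndarray
    r: np.ndarray
    centers_nm: np.ndarray

    @property
    def n_cubes(self) -> int:
        return len(self.occupancy)


@dataclass
class TVAFeatures:
    """Per-nucleus scalar chromatin-texture features."""

    label: int
    cond: float
    meth: float
    assoc: float
    lid_pct: float
    lim_pct: float
    volume_px: int
    mean_dapi: float
    mean_mec: float
    radial_profile: dict[str, np.ndarray] | None = None

    def as_record(self) -> dict:
        """Flat mapping for the per-cell CSV (radial profile omitted)."""
        return {
            "label": self.label,
            "volume_px": self.volume_px,
            "mean_dapi": self.mean_dapi,
            "mean_mec": self.mean_mec,
            "lid_pct": self.lid_pct,
            "lim_pct": self.lim_pct,
            "cond": self.cond,
            "meth": self.meth,
            "assoc": self.assoc,
        }


def low_intensity_threshold(intensities: np.ndarray, method: str = "otsu") -> float:
    """Image-inherent low-intensity threshold for one channel.

    Otsu's method on the pooled within-ROI intensity sample.  Computed once
    per image and shared by all ROIs of that image, so per-nucleus LID%/LIM%
    values are comparable within a field.
    """
    intensities = np.asarray(intensities).ravel()
    if intensities.size == 0 or intensities.min() == intensities.max():
        raise SegmentationError("constant or empty intensity sample: no threshold separable")
    if method != "otsu":
        raise ValueError(f"unknown threshold method {method!r}")
    from .segmentation import _between_classes

    return _between_classes(intensities, threshold_otsu(intensities))


def image_thresholds(
    stack: ImageStack,
    rois: Sequence[NucleusROI],
    method: str = "otsu",
) -> dict[str, float]:
    """Per-channel low-intensity thresholds pooled over all ROIs of a stack."""
    out = {}
    for name in ("DAPI", "MeC"):
        chan = stack.channel(name)
        pooled = np.concatenate([chan[roi.pixel_index] for roi in rois])
        out[name] = low_intensity_threshold(pooled, method=method)
    return out


def channel_scales(
    stack: ImageStack,
    rois: Sequence[NucleusROI],
    percentile: float = DEFAULT_SCALE_PERCENTILE,
) -> dict[str, float]:
    """Robust per-image intensity scales (upper percentile of within-ROI pixels).

    The percentile (default 99.5) stands in for the image maximum, which is
    fragile to hot pixels at 12-bit dynamic range.
    """
    out = {}
    for name in ("DAPI", "MeC"):
        chan = stack.channel(name)
        pooled = np.concatenate([chan[roi.pixel_index] for roi in rois])
        out[name] = float(np.percentile(pooled, percentile))
    return out


def lid_lim_percent(
    stack: ImageStack,
    roi: NucleusROI,
    thresholds: Mapping[str, float],
) -> tuple[float, float]:
    """(LID%, LIM%): percentage of ROI pixels strictly below each threshold."""
    if roi.volume_px == 0:
        raise ValueError(f"ROI {roi.label} is empty")
    dapi = stack.channel("DAPI")[roi.pixel_index]
    mec = stack.channel("MeC")[roi.pixel_index]
    lid = 100.0 * float(np.count_nonzero(dapi < thresholds["DAPI"])) / roi.volume_px
    lim = 100.0 * float(np.count_nonzero(mec < thresholds["MeC"])) / roi.volume_px
    return lid, lim


def voxelize(
    roi: NucleusROI,
    stack: ImageStack,
    cube_size_nm: float = DEFAULT_CUBE_SIZE_NM,
) -> VoxelGrid:
    """Partition a nuclear ROI into cubes of ``cube_size_nm`` per side.

    The cube lattice is anchored at the ROI bounding-box corner.  Partial
    cubes at the boundary are retained with their actual occupancy.  Every ROI
    pixel belongs to exactly one cube.
    """
    pitch = np.array(stack.voxel_size_zyx)  # (z, y, x) nm
    if cube_size_nm < pitch.max():
        raise ConfigurationError(
            f"cube size {cube_size_nm} nm below the largest pixel pitch {pitch.max()} nm"
        )
    origin = np.asarray(roi.bbox[0])
    local = roi.coords - origin
    # Pixel i occupies [i*pitch, (i+1)*pitch); classify by its start position.
    cube_idx = np.floor(local * pitch / cube_size_nm).astype(np.int64)
    n_per_axis = cube_idx.max(axis=0) + 1
    flat = np.ravel_multi_index(tuple(cube_idx.T), tuple(n_per_axis))
    unique, cube_ids = np.unique(flat, return_inverse=True)
    occupancy = np.bincount(cube_ids)

    # cube "center" = mean physical position of its occupied pixels, so a
    # cube's radial position reflects the ROI volume it actually holds
    phys = (roi.coords + 0.5) * pitch
    centers_nm = np.stack([
        np.bincount(cube_ids, weights=phys[:, axis]) / occupancy for axis in range(3)
    ], axis=1)
    r = _radial_positions(roi, centers_nm, pitch)
    return VoxelGrid(
        cube_size_nm=float(cube_size_nm),
        cube_ids=cube_ids,
        occupancy=occupancy,
        r=r,
        centers_nm=centers_nm,
    )


def _radial_positions(roi: NucleusROI, centers_nm: np.ndarray, pitch: np.ndarray) -> np.ndarray:
    """Normalized center-to-periphery position of each cube center.

    Marches a ray from the ROI centroid through each cube center until it
    leaves the ROI mask; r = (centroid-to-center distance) / (centroid-to-
    surface distance along that ray), clipped to [0, 1].
    """
    mask, origin = roi.local_mask()
    centroid_nm = (np.asarray(roi.centroid) + 0.5) * pitch
    delta = centers_nm - centroid_nm
    dist = np.linalg.norm(delta, axis=1)
    r = np.zeros(len(centers_nm))
    moving = dist > 1e-9
    if not moving.any():
        return r

    dirs = delta[moving] / dist[moving, None]
    step = 0.5 * pitch.min()
    max_extent = np.linalg.norm(np.array(mask.shape) * pitch) + 2 * step
    ts = np.arange(1, int(np.ceil(max_extent / step)) + 1) * step
    pts = centroid_nm[None, None, :] + dirs[:, None, :] * ts[None, :, None]
    px = np.floor(pts / pitch).astype(np.int64) - origin
    inside = np.ones(px.shape[:2], dtype=bool)
    for axis in range(3):
        inside &= (px[:, :, axis] >= 0) & (px[:, :, axis] < mask.shape[axis])
    inb = inside.copy()
    coords = np.clip(px, 0, np.array(mask.shape) - 1)
    inb &= mask[coords[:, :, 0], coords[:, :, 1], coords[:, :, 2]]
    first_out = np.argmax(~inb, axis=1)  # rays always exit the bbox, so this exists
    boundary = ts[first_out] - 0.5 * step
    r[moving] = np.clip(dist[moving] / np.maximum(boundary, step), 0.0, 1.0)
    return r


def voxel_features(
    stack: ImageStack,
    roi: NucleusROI,
    grid: VoxelGrid,
    thresholds: Mapping[str, float],
    scales: Mapping[str, float],
) -> dict[str, np.ndarray]:
    """Per-cube ``cond``, ``meth`` and ``assoc`` arrays for one nucleus."""
    dapi = stack.channel("DAPI")[roi.pixel_index].astype(np.float64)
    mec = stack.channel("MeC")[roi.pixel_index].astype(np.float64)
    occ = grid.occupancy.astype(np.float64)
    mean_d = np.bincount(grid.cube_ids, weights=dapi, minlength=grid.n_cubes) / occ
    mean_m = np.bincount(grid.cube_ids, weights=mec, minlength=grid.n_cubes) / occ
    agree = (dapi < thresholds["DAPI"]) == (mec < thresholds["MeC"])
    assoc = np.bincount(grid.cube_ids, weights=agree.astype(np.float64), minlength=grid.n_cubes) / occ
    return {
        "cond": np.clip(mean_d / scales["DAPI"], 0.0, 1.0),
        "meth": np.clip(mean_m / scales["MeC"], 0.0, 1.0),
        "assoc": assoc,
    }


def aggregate(grid: VoxelGrid, features: Mapping[str, np.ndarray]) -> dict[str, float]:
    """Volume-weighted mean of each per-cube parameter over the whole ROI."""
    occ = grid.occupancy.astype(np.float64)
    total = occ.sum()
    return {name: float(np.sum(occ * np.asarray(vals)) / total) for name, vals in features.items()}


def radial_profile(
    grid: VoxelGrid,
    features: Mapping[str, np.ndarray],
    n_shells: int,
) -> dict[str, np.ndarray]:
    """Occupancy-weighted shell means of each parameter from center to periphery.

    Cubes are binned by r into ``n_shells`` equal-width shells over [0, 1];
    empty shells are NaN.
    """
    if n_shells < 1:
        raise ValueError("n_shells must be >= 1")
    shell = np.minimum((grid.r * n_shells).astype(int), n_shells - 1)
    occ = grid.occupancy.astype(np.float64)
    weight = np.bincount(shell, weights=occ, minlength=n_shells)
    out = {}
    for name, vals in features.items():
        num = np.bincount(shell, weights=occ * np.asarray(vals), minlength=n_shells)
        with np.errstate(invalid="ignore"):
            out[name] = np.where(weight > 0, num / np.where(weight > 0, weight, 1.0), np.nan)
    return out


def profile_dispersion(profiles: np.ndarray) -> dict[str, np.ndarray]:
    """Across-nucleus per-shell mean, SD and coefficient of variation.

    ``profiles`` is ``(n_nuclei, n_shells)`` for one parameter; missing
    (NaN) shells are ignored per shell.  Requires >= 2 profiles.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] < 2:
        raise ValueError("need a (n_nuclei >= 2, n_shells) profile array")
    mean = np.nanmean(profiles, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.nanstd(profiles, axis=0, ddof=1)
        cv = np.where(np.abs(mean) > 0, sd / np.abs(mean), np.nan)
    return {"mean": mean, "sd": sd, "cv": cv}


def compute_tva_features(
    stack: ImageStack,
    roi: NucleusROI,
    thresholds: Mapping[str, float],
    scales: Mapping[str, float],
    cube_size_nm: float = DEFAULT_CUBE_SIZE_NM,
    n_shells: int = 0,
) -> TVAFeatures:
    """All per-nucleus features: voxelize, per-cube parameters, aggregation.

    ``n_shells > 0`` additionally attaches the radial profile.
    """
    grid = voxelize(roi, stack, cube_size_nm=cube_size_nm)
    feats = voxel_features(stack, roi, grid, thresholds, scales)
    agg = aggregate(grid, feats)
    lid, lim = lid_lim_percent(stack, roi, thresholds)
    dapi = stack.channel("DAPI")[roi.pixel_index]
    mec = stack.channel("MeC")[roi.pixel_index]
    profile = radial_profile(grid, feats, n_shells) if n_shells > 0 else None
    return TVAFeatures(
        label=roi.label,
        cond=agg["cond"],
        meth=agg["meth"],
        assoc=agg["assoc"],
        lid_pct=lid,
        lim_pct=lim,
        volume_px=roi.volume_px,
        mean_dapi=float(dapi.mean()),
        mean_mec=float(mec.mean()),
        radial_profile=profile,
    )
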