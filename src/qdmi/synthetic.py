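"""Ground-truthed two-channel 3D phantoms of interphase nucleus populations.

The generator emulates the specimens this pipeline was designed for: fields of
non-overlapping ellipsoidal nuclei counterstained with DAPI (chromatin density)
and immunostained for 5-methylcytosine (MeC), degraded by confocal-like
anisotropic blur and Poisson-Gaussian noise, quantized to 12 bits.

Chromatin texture model
-----------------------
Within each nucleus a latent smooth random field (a Gaussian random field plus
``n_foci`` dense heterochromatin bumps) is rank-transformed to uniform
quantiles.  Each channel thresholds a noisy copy of that shared field at its
own quantile: the top ``cond_level`` fraction of DAPI-field quantiles becomes
condensed (high-DAPI) chromatin and the top ``mec_level`` fraction of the
MeC-field quantiles becomes methylated (high-MeC) chromatin.  Sharing the
latent field couples the two channels spatially (the basis of the *assoc*
feature) while the per-channel noise keeps the coupling imperfect, so jointly
lowering both levels concentrates pixels in the both-low state and raises
*assoc*, as observed in senescent populations.

Phenotype presets encode the scheme relating growth behavior to global
methylation/condensation: *meth* and *cond* order as
senescent < cancer < proliferating, and senescent nuclei are enlarged.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .errors import PlacementError
from .image_io import ImageStack

logger = logging.getLogger(__name__)

#: Baseline intensity levels (12-bit ADU). Background is dim but nonzero, as
#: in real confocal records; the high:low chromatin contrast is 2:1 so that a
#: global image-inherent threshold separates background from nuclei rather
#: than splitting the intra-nuclear bimodal histogram.
BACKGROUND = 50.0
DAPI_LO, DAPI_HI = 1400.0, 2800.0
MEC_LO, MEC_HI = 1200.0, 2400.0
MAX_INTENSITY = 4095


@dataclass
class PhenotypeSpec:
    """Programmable growth-behavior phenotype of a phantom population.

    Parameters
    ----------
    name
        Label, e.g. ``"proliferating"``, ``"cancer"``, ``"senescent"``.
    nuclear_radius_nm
        Mean and spread (SD) of the ellipsoid semi-axes, nm.
    mec_level
        Target fraction of high-MeC (methylated) chromatin, in [0, 1].
    cond_level
        Target fraction of high-DAPI (condensed) chromatin, in [0, 1].
    n_foci
        Number of dense heterochromatin bumps added to the latent field.
    noise_sigma
        Gaussian read-noise SD (ADU).
    photon_scale
        Photons per ADU for Poisson shot noise; 0 disables shot noise.
    blur_sigma_nm
        Anisotropic Gaussian blur SD, ``(x, y, z)`` nm, approximating the
        confocal point-spread function.
    channel_corr
        Latent-field correlation between the DAPI and MeC textures.  High by
        default: methylated DNA is a subset of the DNA that DAPI stains, so
        the two signals colocalize strongly.
    """

    name: str = "custom"
    nuclear_radius_nm: tuple[float, float] = (4200.0, 350.0)
    mec_level: float = 0.5
    cond_level: float = 0.5
    n_foci: int = 8
    noise_sigma: float = 30.0
    photon_scale: float = 0.1
    blur_sigma_nm: tuple[float, float, float] = (200.0, 200.0, 350.0)
    channel_corr: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 <= self.mec_level <= 1.0:
            raise ValueError(f"mec_level must be in [0, 1], got {self.mec_level}")
        if not 0.0 <= self.cond_level <= 1.0:
            raise ValueError(f"cond_level must be in [0, 1], got {self.cond_level}")
        if self.nuclear_radius_nm[0] <= 0:
            raise ValueError("nuclear radius must be positive")
        if self.n_foci < 0:
            raise ValueError("n_foci must be >= 0")

    @classmethod
    def preset(cls, name: str, **overrides) -> "PhenotypeSpec":
        """Return one of the built-in phenotypes, optionally customized."""
        try:
            params = dict(_PRESETS[name])
        except KeyError:
            raise KeyError(f"unknown phenotype {name!r}; available: {sorted(_PRESETS)}") from None
        params.update(overrides)
        return cls(name=name, **params)


_PRESETS = {
    # meth/cond levels order senescent < cancer < proliferating; senescent
    # nuclei are enlarged (volume ratio ~1.7x over proliferating).
    "proliferating": dict(nuclear_radius_nm=(4200.0, 350.0), mec_level=0.55, cond_level=0.50, n_foci=10),
    "cancer": dict(nuclear_radius_nm=(4100.0, 350.0), mec_level=0.30, cond_level=0.38, n_foci=8),
    "senescent": dict(nuclear_radius_nm=(5000.0, 450.0), mec_level=0.12, cond_level=0.22, n_foci=4),
}


@dataclass
class GroundTruth:
    """Planted truth for one phantom field.

    ``label_volume`` assigns a nucleus ID (0 = background) to every pixel;
    ``table`` has one row per nucleus with its true volume, texture levels and
    outlier flag.
    """

    label_volume: np.ndarray
    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=_TRUTH_COLUMNS))

    def copy(self) -> "GroundTruth":
        return GroundTruth(self.label_volume.copy(), self.table.copy())


_TRUTH_COLUMNS = [
    "label", "volume_px", "true_mec_level", "true_cond_level",
    "is_outlier", "centroid_z", "centroid_y", "centroid_x",
]


def generate_population(
    n_nuclei: int,
    spec: PhenotypeSpec,
    field_shape: Sequence[int],
    voxel_size: Sequence[float] = (120.0, 120.0, 250.0),
    seed: int = 0,
    max_tries: int = 200,
) -> tuple[ImageStack, GroundTruth]:
    """Generate a two-channel phantom field of ``n_nuclei`` nuclei.

    Nuclei are ellipsoids placed by rejection sampling (non-overlapping, clear
    of the field border); textures follow the module's latent-field model;
    both channels are blurred anisotropically, degraded by Poisson-Gaussian
    noise and quantized to 12 bits.  Deterministic given ``seed``.

    Returns the degraded :class:`~qdmi.image_io.ImageStack` and the pre-noise
    :class:`GroundTruth`.

    Raises
    ------
    PlacementError
        If the requested nuclei cannot be packed after bounded retries.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in field_shape)
    pitch = np.array([voxel_size[2], voxel_size[1], voxel_size[0]], dtype=float)  # (z, y, x)

    labels = np.zeros(shape, dtype=np.int32)
    dapi = np.full(shape, BACKGROUND, dtype=np.float64)
    mec = np.full(shape, BACKGROUND, dtype=np.float64)
    rows = []

    semi_axes, centers = _place_nuclei(n_nuclei, spec, shape, pitch, rng, max_tries)

    for i in range(n_nuclei):
        lab = i + 1
        mask, origin = _rasterize_ellipsoid(centers[i], semi_axes[i], shape, pitch)
        if not mask.any():
            raise PlacementError(f"nucleus {lab} rasterized to zero pixels; field or radii too small")
        sl = tuple(slice(o, o + s) for o, s in zip(origin, mask.shape))
        labels[sl][mask] = lab

        hi_d, hi_m = _texture(mask, semi_axes[i], pitch, spec, rng)
        dapi[sl][mask] = np.where(hi_d, DAPI_HI, DAPI_LO)
        mec[sl][mask] = np.where(hi_m, MEC_HI, MEC_LO)

        coords = np.argwhere(mask) + origin
        rows.append({
            "label": lab,
            "volume_px": int(mask.sum()),
            "true_mec_level": float(hi_m.mean()),
            "true_cond_level": float(hi_d.mean()),
            "is_outlier": False,
            "centroid_z": float(coords[:, 0].mean()),
            "centroid_y": float(coords[:, 1].mean()),
            "centroid_x": float(coords[:, 2].mean()),
        })

    data = np.stack([
        _degrade(dapi, spec, pitch, rng),
        _degrade(mec, spec, pitch, rng),
    ])
    stack = ImageStack(data=data, voxel_size=tuple(voxel_size), channel_names=("DAPI", "MeC"))
    table = pd.DataFrame(rows, columns=_TRUTH_COLUMNS) if rows else pd.DataFrame(columns=_TRUTH_COLUMNS)
    return stack, GroundTruth(label_volume=labels, table=table)


def _place_nuclei(n_nuclei, spec, shape, pitch, rng, max_tries):
    """Rejection-sample non-overlapping ellipsoid centers; physical units."""
    extent = np.array(shape) * pitch
    mean_r, sd_r = spec.nuclear_radius_nm
    margin = 2.0 * max(spec.blur_sigma_nm) + 300.0

    semi_axes = []
    for _ in range(n_nuclei):
        base = max(rng.normal(mean_r, sd_r), 0.3 * mean_r)
        factors = np.clip(rng.normal(1.0, 0.06, size=3), 0.8, 1.2)
        semi_axes.append(base * factors)  # (z, y, x) nm

    centers = []
    budget = max_tries * max(n_nuclei, 1)
    for i in range(n_nuclei):
        semi = semi_axes[i]
        lo = semi + margin
        hi = extent - semi - margin
        if np.any(lo >= hi):
            raise PlacementError(
                f"field {shape} (pitch {tuple(pitch)} nm) too small for radius {semi.max():.0f} nm"
            )
        placed = False
        while budget > 0:
            budget -= 1
            c = rng.uniform(lo, hi)
            ok = all(
                np.linalg.norm(c - cj) >= semi.max() + sj.max() + margin
                for cj, sj in zip(centers, semi_axes[:i])
            )
            if ok:
                centers.append(c)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place nucleus {i + 1}/{n_nuclei} after bounded retries; "
                "enlarge the field or reduce radii"
            )
    return semi_axes, centers


def _rasterize_ellipsoid(center_nm, semi_nm, shape, pitch):
    """Binary ellipsoid mask over its bounding box; returns (mask, origin_px)."""
    lo_px = np.maximum(np.floor((center_nm - semi_nm) / pitch).astype(int) - 1, 0)
    hi_px = np.minimum(np.ceil((center_nm + semi_nm) / pitch).astype(int) + 2, np.array(shape))
    grids = np.meshgrid(
        *[(np.arange(lo, hi) + 0.5) * p for lo, hi, p in zip(lo_px, hi_px, pitch)],
        indexing="ij",
    )
    q = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center_nm, semi_nm))
    return q <= 1.0, lo_px


def _texture(mask, semi_nm, pitch, spec, rng):
    """High-intensity pixel assignment for both channels of one nucleus."""
    n = int(mask.sum())
    if n == 1:
        hi = np.ones(1, dtype=bool)
        return (hi if spec.cond_level >= 0.5 else ~hi), (hi if spec.mec_level >= 0.5 else ~hi)

    sigma_px = np.maximum(semi_nm / 3.0 / pitch, 0.5)
    shared = ndi.gaussian_filter(rng.standard_normal(mask.shape), sigma_px)
    shared = _standardize(shared, mask)

    if spec.n_foci > 0:
        foci_sigma = np.maximum(400.0 / pitch, 0.5)
        grids = np.meshgrid(*[np.arange(s, dtype=float) for s in mask.shape], indexing="ij")
        center_px = np.array(ndi.center_of_mass(mask))
        semi_px = semi_nm / pitch
        for _ in range(spec.n_foci):
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            radius = rng.uniform(0.0, 0.75)
            pos = center_px + radius * u * semi_px
            d2 = sum(((g - p) / s) ** 2 for g, p, s in zip(grids, pos, foci_sigma))
            shared = shared + 3.0 * np.exp(-0.5 * d2)
        shared = _standardize(shared, mask)

    rho = spec.channel_corr
    out = []
    for level in (spec.cond_level, spec.mec_level):
        noise = _standardize(ndi.gaussian_filter(rng.standard_normal(mask.shape), sigma_px), mask)
        u = rho * shared + np.sqrt(max(1.0 - rho**2, 0.0)) * noise
        vals = u[mask]
        ranks = np.empty(n, dtype=float)
        ranks[np.argsort(vals, kind="stable")] = np.arange(n)
        quantile = ranks / max(n - 1, 1)
        out.append(quantile >= 1.0 - level if level > 0 else np.zeros(n, dtype=bool))
    return out[0], out[1]


def _standardize(fieldvol, mask):
    vals = fieldvol[mask]
    sd = vals.std()
    return (fieldvol - vals.mean()) / (sd if sd > 0 else 1.0)


def _degrade(img, spec, pitch, rng):
    """Confocal-like degradation: anisotropic blur, shot + read noise, 12-bit."""
    sigma_px = np.array([spec.blur_sigma_nm[2], spec.blur_sigma_nm[1], spec.blur_sigma_nm[0]]) / pitch
    if np.any(sigma_px > 0):
        img = ndi.gaussian_filter(img, sigma_px)
    if spec.photon_scale > 0:
        img = rng.poisson(np.maximum(img, 0.0) * spec.photon_scale) / spec.photon_scale
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    clipped = int(np.count_nonzero(img > MAX_INTENSITY))
    if clipped:
        logger.info("quantization clipped %d pixels at %d", clipped, MAX_INTENSITY)
    return np.clip(np.rint(img), 0, MAX_INTENSITY).astype(np.uint16)


def g2_mimic(spec: PhenotypeSpec, volume_factor: float = 1.8) -> PhenotypeSpec:
    """A G2-phase mimic: enlarged nuclear volume at identical texture statistics.

    G2 nuclei hold twice the genomic DNA but pack it into less than twice the
    volume (imaging cytometry of synchronized populations reports volume
    ratios around 1.6-1.8x), hence the default ``volume_factor`` of 1.8.
    """
    mean_r, sd_r = spec.nuclear_radius_nm
    factor = volume_factor ** (1.0 / 3.0)
    return replace(spec, name=f"{spec.name}-G2", nuclear_radius_nm=(mean_r * factor, sd_r * factor))


def plant_outlier(
    stack: ImageStack,
    truth: GroundTruth,
    mode: str = "inverted-texture",
    seed: int = 0,
) -> tuple[ImageStack, GroundTruth]:
    """Replace one nucleus with an aberrant texture and flag it in the truth.

    Modes
    -----
    ``"mitotic-compact"``
        Mimics an M-phase figure: the nucleus is replaced by a compact
        (~45% volume), uniformly bright-DAPI body, the sort of object the
        joint-distribution filter is expected to reject automatically.
    ``"inverted-texture"``
        The MeC intensities inside the nucleus are inverted about their local
        midrange, flipping the MeC/DAPI joint histogram onto the anti-diagonal
        so it shares almost no mass with the population reference.

    Returns new ``(stack, truth)`` objects; inputs are not mutated.
    """
    if len(truth.table) == 0:
        raise PlacementError("no nucleus present to replace")
    if mode not in ("mitotic-compact", "inverted-texture"):
        raise ValueError(f"unknown outlier mode {mode!r}")

    rng = np.random.default_rng(seed)
    stack = ImageStack(
        data=stack.data.copy(),
        voxel_size=stack.voxel_size,
        channel_names=stack.channel_names,
        bit_depth=stack.bit_depth,
    )
    truth = truth.copy()
    row = int(rng.integers(len(truth.table)))
    lab = int(truth.table.iloc[row]["label"])
    region = truth.label_volume == lab

    dapi = stack.channel("DAPI")
    mec = stack.channel("MeC")

    if mode == "inverted-texture":
        vals = mec[region].astype(np.int64)
        inverted = (int(vals.min()) + int(vals.max())) - vals
        mec[region] = inverted.astype(mec.dtype)
    else:  # mitotic-compact
        coords = np.argwhere(region)
        centroid = coords.mean(axis=0)
        old_volume = int(region.sum())
        hi_dapi = float(np.percentile(dapi[region], 99.0))
        mid_mec = float(np.median(mec[region]))
        bg_d = float(np.median(dapi[truth.label_volume == 0]))
        bg_m = float(np.median(mec[truth.label_volume == 0]))

        pitch = np.array(stack.voxel_size_zyx)
        target_nm = (0.45 * old_volume * np.prod(pitch) * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        for chan, fill in ((dapi, bg_d), (mec, bg_m)):
            noise = rng.normal(0.0, 15.0, size=old_volume)
            chan[region] = np.clip(np.rint(fill + noise), 0, MAX_INTENSITY).astype(chan.dtype)
        truth.label_volume[region] = 0

        ball, origin = _rasterize_ellipsoid(
            (centroid + 0.5) * pitch, np.full(3, target_nm), stack.spatial_shape, pitch
        )
        sl = tuple(slice(o, o + s) for o, s in zip(origin, ball.shape))
        ball &= truth.label_volume[sl] == 0  # never overwrite neighbours
        n_ball = int(ball.sum())
        truth.label_volume[sl][ball] = lab
        dapi[sl][ball] = np.clip(
            np.rint(min(1.3 * hi_dapi, MAX_INTENSITY) + rng.normal(0, 30.0, n_ball)), 0, MAX_INTENSITY
        ).astype(dapi.dtype)
        mec[sl][ball] = np.clip(
            np.rint(mid_mec + rng.normal(0, 30.0, n_ball)), 0, MAX_INTENSITY
        ).astype(mec.dtype)
        new_coords = np.argwhere(truth.label_volume == lab)
        truth.table.iloc[row, truth.table.columns.get_loc("volume_px")] = n_ball
        for axis, col in enumerate(["centroid_z", "centroid_y", "centroid_x"]):
            truth.table.iloc[row, truth.table.columns.get_loc(col)] = float(new_coords[:, axis].mean())

    truth.table.iloc[row, truth.table.columns.get_loc("is_outlier")] = True
    logger.info("planted %s outlier at label %d", mode, lab)
    return stack, truth
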