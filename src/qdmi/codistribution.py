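"""Per-nucleus MeC/DAPI codistributions and Kullback-Leibler outlier filtering.

Each nucleus is summarized by the normalized 2D joint histogram of its
(DAPI, MeC) pixel intensities over population-level bin edges.  Population
homogeneity is assessed by scoring each cell's histogram against the
population mean ("reference") with the K-L divergence (base 2); nuclei whose
divergence exceeds a dissimilarity cut are excluded from feature statistics.
M-phase-like figures (compact, uniformly bright) need no dedicated detector:
their codistribution departs far enough from the reference to be flagged.

The dissimilarity cut of 4.5 bits is the published operating point for
populations of more than a thousand nuclei.  Against an *inclusive* mean
reference the divergence of any single cell is bounded by log2(n), so for
small populations :func:`calibrate_threshold` rescales the cut accordingly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .image_io import ImageStack
from .segmentation import NucleusROI

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 64
#: Dissimilarity cut in bits; published operating point for n > 1000 cells.
DEFAULT_KL_THRESHOLD = 4.5
#: Population size at which the 4.5-bit cut was established.
REFERENCE_POPULATION = 1000


@dataclass
class Codistribution:
    """Normalized 2D joint histogram over (DAPI bin, MeC bin).

    ``counts`` keeps the raw per-bin pixel counts (their sum equals the ROI
    volume); ``hist`` is the probability table.  ``kld`` is unset until the
    nucleus has been scored against a population reference.
    """

    hist: np.ndarray
    counts: np.ndarray
    bin_edges: tuple[np.ndarray, np.ndarray]
    kld: float | None = None

    @property
    def n_bins(self) -> int:
        return self.hist.shape[0]


def population_bin_edges(
    stack: ImageStack,
    rois: Sequence[NucleusROI],
    n_bins: int = DEFAULT_N_BINS,
) -> tuple[np.ndarray, np.ndarray]:
    """Shared bin edges spanning [0, max] of the pooled within-ROI intensities."""
    if not rois:
        raise ValueError("need at least one ROI to derive bin edges")
    dapi = stack.channel("DAPI")
    mec = stack.channel("MeC")
    hi_d = max(int(dapi[roi.pixel_index].max()) for roi in rois)
    hi_m = max(int(mec[roi.pixel_index].max()) for roi in rois)
    edges_d = np.linspace(0.0, hi_d + 1.0, n_bins + 1)
    edges_m = np.linspace(0.0, hi_m + 1.0, n_bins + 1)
    return edges_d, edges_m


def joint_histogram(
    stack: ImageStack,
    roi: NucleusROI,
    bin_edges: tuple[np.ndarray, np.ndarray],
) -> Codistribution:
    """Joint (DAPI, MeC) histogram of one nucleus, normalized to probabilities."""
    if roi.volume_px == 0:
        raise ValueError(f"ROI {roi.label} is empty")
    dapi = stack.channel("DAPI")[roi.pixel_index]
    mec = stack.channel("MeC")[roi.pixel_index]
    counts, _, _ = np.histogram2d(dapi, mec, bins=bin_edges)
    total = counts.sum()
    if total == 0:
        raise ValueError(f"ROI {roi.label}: all pixels fall outside the bin range")
    return Codistribution(hist=counts / total, counts=counts, bin_edges=(bin_edges[0], bin_edges[1]))


def default_epsilon(n_total_bins: int) -> float:
    """Default per-bin pseudocount: 1 / (total bins)^2.

    Small enough to leave the histograms essentially undistorted (total added
    mass 1/B) while keeping every log ratio finite.
    """
    return 1.0 / float(n_total_bins) ** 2


def kl_divergence(p: Codistribution, q: Codistribution, epsilon: float | None = None) -> float:
    """K-L divergence D(p || q) in bits over epsilon-smoothed, renormalized tables.

    Both tables receive the per-bin pseudocount ``epsilon`` (default
    :func:`default_epsilon`) and are renormalized before the sum
    ``sum_b p_b * log2(p_b / q_b)``.  Nonnegative by Gibbs' inequality, up to
    floating-point round-off.
    """
    if p.hist.shape != q.hist.shape or not all(
        np.array_equal(pe, qe) for pe, qe in zip(p.bin_edges, q.bin_edges)
    ):
        raise ValueError("codistributions have mismatched binning")
    if epsilon is None:
        epsilon = default_epsilon(p.hist.size)
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    ps = p.hist + epsilon
    qs = q.hist + epsilon
    ps = ps / ps.sum()
    qs = qs / qs.sum()
    return float(np.sum(ps * np.log2(ps / qs)))


def population_reference(cods: Sequence[Codistribution]) -> Codistribution:
    """Element-wise mean of the population's histograms, renormalized."""
    if len(cods) < 2:
        raise ValueError(f"need >= 2 nuclei for a population reference, got {len(cods)}")
    first = cods[0]
    for c in cods[1:]:
        if c.hist.shape != first.hist.shape or not all(
            np.array_equal(a, b) for a, b in zip(c.bin_edges, first.bin_edges)
        ):
            raise ValueError("codistributions have mismatched binning")
    mean = np.mean([c.hist for c in cods], axis=0)
    mean = mean / mean.sum()
    return Codistribution(hist=mean, counts=np.sum([c.counts for c in cods], axis=0), bin_edges=first.bin_edges)


def score_population(
    cods: Sequence[Codistribution],
    reference: Codistribution | None = None,
    epsilon: float | None = None,
) -> np.ndarray:
    """Score every nucleus against the (inclusive mean) population reference.

    Sets ``cod.kld`` in place and returns the divergence array.
    """
    if reference is None:
        reference = population_reference(cods)
    klds = np.array([kl_divergence(c, reference, epsilon=epsilon) for c in cods])
    for c, k in zip(cods, klds):
        c.kld = float(k)
    return klds


def flag_outliers(
    cods: Sequence[Codistribution],
    threshold: float = DEFAULT_KL_THRESHOLD,
) -> tuple[list[int], list[int]]:
    """Split scored nuclei into (kept, dissimilar) index lists.

    A nucleus is dissimilar iff its divergence exceeds ``threshold``.  All
    nuclei must have been scored (see :func:`score_population`) against the
    same reference.
    """
    kept, dissimilar = [], []
    for i, c in enumerate(cods):
        if c.kld is None:
            raise ValueError(f"codistribution {i} has not been scored")
        (dissimilar if c.kld > threshold else kept).append(i)
    if cods:
        logger.info(
            "flag_outliers: %d/%d nuclei dissimilar (%.2f%%) at K-L > %.3g",
            len(dissimilar), len(cods), 100.0 * len(dissimilar) / len(cods), threshold,
        )
    return kept, dissimilar


def calibrate_threshold(
    n_cells: int,
    base: float = DEFAULT_KL_THRESHOLD,
    base_population: int = REFERENCE_POPULATION,
) -> float:
    """Small-population equivalent of the dissimilarity cut.

    A cell scored against the inclusive mean of ``n`` histograms can diverge by
    at most log2(n) bits, so the published cut (``base`` at ``base_population``
    cells) is rescaled proportionally to that ceiling.
    """
    if n_cells < 2:
        raise ValueError("need >= 2 cells")
    return base * np.log2(n_cells) / np.log2(base_population)


def export_scatter(
    stack: ImageStack,
    roi: NucleusROI,
    max_points: int = 5000,
    seed: int = 0,
) -> "np.ndarray":
    """Per-pixel (DAPI, MeC) sample of one nucleus for scatter plotting.

    Returns an ``(n, 2)`` array subsampled to ``max_points`` pixels.
    """
    dapi = stack.channel("DAPI")[roi.pixel_index]
    mec = stack.channel("MeC")[roi.pixel_index]
    pairs = np.column_stack([dapi, mec])
    if len(pairs) > max_points:
        rng = np.random.default_rng(seed)
        pairs = pairs[rng.choice(len(pairs), size=max_points, replace=False)]
    return pairs
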