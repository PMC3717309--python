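"""Shared helpers for the test suite: scaled-down phantom geometry.

Tests run at a 2x-binned geometry (voxel 240 x 240 x 500 nm, nuclear radii
~1.8-2.8 um) so whole-population checks stay fast; the orderings and
invariants under test are scale-free.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from qdmi.segmentation import collect_rois
from qdmi.synthetic import PhenotypeSpec, generate_population
from qdmi import tva

VOXEL = (240.0, 240.0, 500.0)  # (x, y, z) nm


def small_spec(preset: str = "proliferating", radius=(2100.0, 150.0), **overrides) -> PhenotypeSpec:
    return PhenotypeSpec.preset(preset, nuclear_radius_nm=radius, **overrides)


def phantom(n, spec, seed, shape=(20, 224, 224)):
    """Generate a phantom field and its ground-truth ROIs (no segmentation)."""
    stack, truth = generate_population(n, spec, field_shape=shape, voxel_size=VOXEL, seed=seed)
    rois, _ = collect_rois(truth.label_volume)
    return stack, truth, rois


def population_features(stack, rois, n_shells: int = 0) -> pd.DataFrame:
    """TVA feature table for all ROIs of one stack (shared thresholds/scales)."""
    thresholds = tva.image_thresholds(stack, rois)
    scales = tva.channel_scales(stack, rois)
    records = [
        tva.compute_tva_features(stack, roi, thresholds, scales, n_shells=n_shells).as_record()
        for roi in rois
    ]
    return pd.DataFrame(records)


def match_to_truth(roi, truth):
    """Ground-truth label with maximal overlap with a segmented ROI (0 = background)."""
    vals, cnts = np.unique(truth.label_volume[roi.pixel_index], return_counts=True)
    return int(vals[np.argmax(cnts)])
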