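"""Reading and writing of 3D multi-channel image stacks and per-cell tables.

All stacks are held in memory as a 4D integer array with axis order
``(channel, z, y, x)``; coordinates are 0-based and bounding boxes half-open.
Physical voxel size is carried as an ``(x, y, z)`` triple in nanometers and
propagates unchanged to every downstream record.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigurationError, FormatError

logger = logging.getLogger(__name__)

#: Acquisition constants of the confocal setup this pipeline targets:
#: 120 nm lateral and 250 nm axial sampling, 12-bit dynamic range.
DEFAULT_VOXEL_SIZE_NM = (120.0, 120.0, 250.0)
DEFAULT_BIT_DEPTH = 12

REQUIRED_CHANNELS = ("DAPI", "MeC")


@dataclass
class ImageStack:
    """A 3D multi-channel intensity volume plus physical metadata.

    Parameters
    ----------
    data
        Integer array of shape ``(channel, z, y, x)``.
    voxel_size
        Physical edge lengths ``(x, y, z)`` in nanometers.
    channel_names
        Ordered channel labels; must include ``"DAPI"`` and ``"MeC"``.
    bit_depth
        Dynamic range of the detector (intensities in ``[0, 2**bit_depth - 1]``).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_names: tuple[str, ...]
    bit_depth: int = DEFAULT_BIT_DEPTH

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise FormatError(f"stack data must be 4D (c, z, y, x), got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise FormatError(f"stack data must be integer-valued, got {self.data.dtype}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ConfigurationError(f"voxel_size must be 3 strictly positive values, got {self.voxel_size}")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ConfigurationError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} channels"
            )
        for required in REQUIRED_CHANNELS:
            if required not in self.channel_names:
                raise ConfigurationError(f"required channel {required!r} missing from {self.channel_names}")
        lo, hi = int(self.data.min(initial=0)), int(self.data.max(initial=0))
        if lo < 0 or hi > 2**self.bit_depth - 1:
            raise FormatError(
                f"intensities [{lo}, {hi}] outside the {self.bit_depth}-bit range"
            )

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        """Shape of one channel, ``(z, y, x)``."""
        return self.data.shape[1:]

    @property
    def voxel_size_zyx(self) -> tuple[float, float, float]:
        """Voxel pitch reordered to match array axes ``(z, y, x)``."""
        x, y, z = self.voxel_size
        return (z, y, x)

    def channel(self, name: str) -> np.ndarray:
        """Return the 3D volume of the named channel (a view)."""
        try:
            return self.data[self.channel_names.index(name)]
        except ValueError:
            raise ConfigurationError(f"no channel named {name!r} in {self.channel_names}") from None


def read_stack(
    path,
    channel_map: Mapping[str, int] | None = None,
    voxel_size: Sequence[float] | None = None,
) -> ImageStack:
    """Read a multi-page TIFF (or one file per channel) into an :class:`ImageStack`.

    ``channel_map`` maps channel names to channel indices in the stored array
    and must cover ``DAPI`` and ``MeC``; if omitted, channel names embedded at
    write time by :func:`write_stack` are used.  ``voxel_size`` is ``(x, y, z)``
    in nm; when absent both here and in the file metadata, the acquisition
    default of 120 x 120 x 250 nm is assumed with a warning.  Intensities are
    preserved bit-exactly.
    """
    if isinstance(path, (list, tuple)):
        volumes = [_read_single(p)[0] for p in path]
        shapes = {v.shape for v in volumes}
        if len(shapes) != 1:
            raise FormatError(f"per-channel files disagree in shape: {sorted(shapes)}")
        data = np.stack([v if v.ndim == 3 else v[0] for v in volumes])
        meta = {}
    else:
        data, meta = _read_single(path)
        if data.ndim == 3:
            data = data[None]
        elif data.ndim != 4:
            raise FormatError(f"cannot interpret TIFF with ndim={data.ndim} as (c, z, y, x)")

    if channel_map is None:
        names = meta.get("channel_names")
        if names is None:
            raise ConfigurationError("no channel_map given and no channel names stored in the file")
        channel_map = {name: i for i, name in enumerate(names)}
    for required in REQUIRED_CHANNELS:
        if required not in channel_map:
            raise ConfigurationError(f"channel_map must include {required!r}")
    n_chan = data.shape[0]
    for name, idx in channel_map.items():
        if not 0 <= idx < n_chan:
            raise ConfigurationError(f"channel {name!r} mapped to index {idx} but file has {n_chan} channels")

    order = sorted(channel_map.items(), key=lambda kv: kv[1])
    names = tuple(name for name, _ in order)
    data = data[[idx for _, idx in order]]

    if voxel_size is None:
        voxel_size = meta.get("voxel_size_nm")
    if voxel_size is None:
        voxel_size = DEFAULT_VOXEL_SIZE_NM
        logger.warning(
            "no voxel size provided or stored; assuming acquisition default %s nm", voxel_size
        )
    bit_depth = int(meta.get("bit_depth", 0)) or _infer_bit_depth(data)
    return ImageStack(data=data, voxel_size=tuple(voxel_size), channel_names=names, bit_depth=bit_depth)


def _read_single(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            meta = {}
            if tif.shaped_metadata:
                meta = dict(tif.shaped_metadata[0])
    except (ValueError, tifffile.TiffFileError) as exc:  # e.g. ragged page shapes
        raise FormatError(f"cannot read {path} as a TIFF stack: {exc}") from exc
    return data, meta


def _infer_bit_depth(data: np.ndarray) -> int:
    hi = int(data.max(initial=0))
    return DEFAULT_BIT_DEPTH if hi < 2**DEFAULT_BIT_DEPTH else 16


def write_stack(stack: ImageStack, path) -> None:
    """Write an :class:`ImageStack` as a shaped multi-page TIFF.

    Voxel size, channel names and bit depth are embedded in the TIFF's JSON
    description so that :func:`read_stack` can restore the stack without
    external metadata; the round trip is bit-exact.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path,
        stack.data,
        photometric="minisblack",
        metadata={
            "axes": "CZYX",
            "voxel_size_nm": list(stack.voxel_size),
            "channel_names": list(stack.channel_names),
            "bit_depth": stack.bit_depth,
        },
    )


def write_labels(labels: np.ndarray, path) -> None:
    """Write an integer label volume (z, y, x) as TIFF."""
    tifffile.imwrite(Path(path), np.asarray(labels, dtype=np.int32))


def read_labels(path) -> np.ndarray:
    return tifffile.imread(Path(path))


def write_cell_table(records, path) -> None:
    """Write one row per nucleus to CSV with >= 6 significant digits.

    ``records`` is a sequence of mappings (or a DataFrame) sharing a common
    schema; an empty sequence produces a header-only file when the schema can
    be inferred, otherwise an empty file with no rows.
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = pd.DataFrame(list(records))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.8g")


def read_cell_table(path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
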