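"""Reading and writing images and measurement tables.

Images travel as OME-TIFF with voxel-size metadata (``PhysicalSizeX/Y/Z`` in
μm); measurement tables as comma-separated UTF-8 text with a header row and
'.' decimal separator, via pandas.
"""

from __future__ import annotations

import logging
import os
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile

from .stack import ImageStack

log = logging.getLogger(__name__)

DEFAULT_VOXEL_SIZE = (1.0, 1.0, 1.0)


def write_stack(stack: ImageStack, path: str | os.PathLike) -> None:
    """Write a stack as OME-TIFF, embedding voxel size and channel names."""
    dz, dy, dx = stack.voxel_size
    data = stack.voxels
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": dx,
            "PhysicalSizeXUnit": "µm",
            "Channel": {"Name": list(stack.channel_names)},
        },
    )


def read_stack(path: str | os.PathLike) -> ImageStack:
    """Read an (OME-)TIFF z-stack.

    Voxel-size metadata is recovered from the OME header when present;
    otherwise (plain TIFF) it defaults to (1, 1, 1) μm with a logged warning.
    Round trips through :func:`write_stack` preserve voxels and voxel size
    exactly.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            ome = tf.ome_metadata
    except (tifffile.TiffFileError, ValueError) as exc:
        raise OSError(f"could not read TIFF image {path}: {exc}") from exc

    voxel_size = DEFAULT_VOXEL_SIZE
    channel_names: list[str] = []
    if ome:
        meta = tifffile.xml2dict(ome)
        try:
            image = meta["OME"]["Image"]
            if isinstance(image, list):
                image = image[0]
            pixels = image["Pixels"]
            voxel_size = (
                float(pixels.get("PhysicalSizeZ", 1.0)),
                float(pixels.get("PhysicalSizeY", 1.0)),
                float(pixels.get("PhysicalSizeX", 1.0)),
            )
            chans = pixels.get("Channel", [])
            if isinstance(chans, Mapping):
                chans = [chans]
            channel_names = [
                str(c.get("Name", f"channel{i}")) for i, c in enumerate(chans)
            ]
        except (KeyError, TypeError):
            log.warning("OME metadata in %s lacks pixel sizes; assuming 1 µm voxels", path)
    else:
        log.warning("%s carries no OME voxel-size metadata; assuming (1, 1, 1) µm", path)

    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None, None]
    elif data.ndim == 3:
        data = data[None]
    elif data.ndim != 4:
        raise OSError(f"unsupported TIFF dimensionality {data.ndim} in {path}")
    if channel_names and len(channel_names) != data.shape[0]:
        channel_names = []
    return ImageStack(voxels=data, voxel_size=voxel_size, channel_names=channel_names)


def write_image2d(image: np.ndarray, path: str | os.PathLike, pixel_size: float) -> None:
    """Write a single-plane image (e.g. a well montage) with pixel size metadata."""
    tifffile.imwrite(
        path,
        np.asarray(image),
        ome=True,
        metadata={
            "axes": "YX",
            "PhysicalSizeY": pixel_size,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": pixel_size,
            "PhysicalSizeXUnit": "µm",
        },
    )


def read_image2d(path: str | os.PathLike) -> tuple[np.ndarray, float]:
    """Read a 2D TIFF, returning (image, pixel_size_um)."""
    stack = read_stack(path)
    if stack.voxels.shape[:2] != (1, 1):
        raise OSError(f"{path} is not a single-plane image")
    return stack.voxels[0, 0], stack.voxel_size[2]


def write_measurements(rows: Iterable[Mapping] | pd.DataFrame, path: str | os.PathLike) -> None:
    """Write measurement rows as CSV (UTF-8, header row, '.' decimal).

    All rows must share one schema; otherwise a ``ValueError`` names the
    offending columns. An empty row list produces a header-only file only if
    a DataFrame (which carries its schema) is supplied; an empty plain list
    has no schema and yields an empty table.
    """
    if isinstance(rows, pd.DataFrame):
        frame = rows
    else:
        rows = list(rows)
        if rows:
            schema = list(rows[0].keys())
            for i, row in enumerate(rows):
                if list(row.keys()) != schema:
                    missing = sorted(set(schema) ^ set(row.keys()))
                    raise ValueError(
                        f"row {i} does not match the first row's schema; "
                        f"mismatched columns: {missing}"
                    )
        frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False, encoding="utf-8")


def read_measurements(path: str | os.PathLike) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such measurement table: {path}")
    return pd.read_csv(path, encoding="utf-8")
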