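"""Raster mask I/O and the coordinate contract used by every downstream module.

All pixel coordinates in this package are 0-based ``(row, col)`` with row 0 at
the image top.  Disc-center sidecar files written in ``(x, y)`` order must be
loaded with ``xy_order=True``, which swaps the two columns on load; nothing
downstream ever sees x/y.

Masks are binary by construction (the upstream manual segmentations are
painted binary), so any pixel at or above ``threshold`` (default 1) counts as
vessel.  ``pixel_size_um`` is optional metadata only: every metric in scope is
either dimensionless or reported in pixel units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError, ValidationError

__all__ = [
    "BinaryMask",
    "DiscCenter",
    "load_mask",
    "save_mask",
    "load_disc_centers",
    "load_group_table",
    "write_results_table",
]


@dataclass(frozen=True)
class BinaryMask:
    """A 2-D boolean vessel raster with identification metadata.

    Parameters
    ----------
    pixels
        Boolean raster, shape ``(rows, cols)``; ``True`` = vessel.
    image_id
        Identifier used to join masks with disc centers and group tables.
    pixel_size_um
        Physical edge length of one pixel in micrometres, or 1.0 when the
        calibration is unknown (all in-scope metrics stay in pixel units).
    """

    pixels: np.ndarray
    image_id: str = ""
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.size == 0:
            raise ValidationError(
                f"mask must be a non-empty 2-D raster, got shape {arr.shape}"
            )
        if arr.dtype != bool:
            arr = arr.astype(bool)
        object.__setattr__(self, "pixels", arr)
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def n_vessel_pixels(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class DiscCenter:
    """Optic-disc center in (row, col) pixel coordinates."""

    row: float
    col: float
    image_id: str = ""

    def __post_init__(self) -> None:
        if self.row < 0 or self.col < 0:
            raise ValidationError(
                f"disc center must be non-negative, got ({self.row}, {self.col})"
            )

    def validate_against(self, mask: BinaryMask) -> None:
        rows, cols = mask.shape
        if not (self.row < rows and self.col < cols):
            raise ValidationError(
                f"disc center ({self.row}, {self.col}) outside raster bounds "
                f"{rows}x{cols} for image {mask.image_id!r}"
            )


def _collapse_channels(arr: np.ndarray, path: Path) -> np.ndarray:
    """Collapse a trivially multi-channel raster to one channel."""
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[-1] in (2, 3, 4):
        color = arr[..., :3] if arr.shape[-1] == 4 else arr
        first = color[..., 0]
        if all(np.array_equal(color[..., k], first) for k in range(1, color.shape[-1])):
            return first
        raise FormatError(
            f"{path}: multi-channel image with differing channels; "
            "expected a single-channel binary mask"
        )
    raise FormatError(f"{path}: cannot interpret array of shape {arr.shape} as a mask")


def load_mask(
    path: str | Path,
    threshold: int = 1,
    image_id: str | None = None,
    pixel_size_um: float = 1.0,
) -> BinaryMask:
    """Load a TIFF/PNG raster as a :class:`BinaryMask`.

    Pixels with intensity ``>= threshold`` become vessel. A 3/4-channel image
    is accepted only when its color channels are identical (alpha ignored).
    """
    path = Path(path)
    if threshold < 1:
        raise ValidationError("threshold must be >= 1")
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # unreadable / corrupt file
        raise OSError(f"cannot read raster file {path}: {exc}") from exc
    arr = _collapse_channels(np.asarray(arr), path)
    return BinaryMask(
        pixels=np.asarray(arr) >= threshold,
        image_id=image_id if image_id is not None else path.stem,
        pixel_size_um=pixel_size_um,
    )


def save_mask(mask: BinaryMask, path: str | Path) -> Path:
    """Write a mask losslessly as 8-bit (0/255) PNG or TIFF."""
    path = Path(path)
    iio.imwrite(path, (mask.pixels.astype(np.uint8) * 255))
    return path


_DISC_KEYS = ("image_id", "row", "col")


def load_disc_centers(path: str | Path, xy_order: bool = False) -> list[DiscCenter]:
    """Load disc centers from CSV (header ``image_id,row,col``) or JSON.

    With ``xy_order=True`` the two coordinate columns are interpreted as
    ``(x, y)`` = ``(col, row)`` and swapped on load.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        frame = pd.DataFrame.from_records(records)
        if frame.empty:
            frame = pd.DataFrame(columns=list(_DISC_KEYS))
    else:
        frame = pd.read_csv(path)
    missing = [k for k in _DISC_KEYS if k not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns/keys {missing}")
    dupes = frame["image_id"][frame["image_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValidationError(f"{path}: duplicate image_id entries {dupes}")
    centers = []
    for rec in frame.itertuples(index=False):
        row, col = float(rec.row), float(rec.col)
        if xy_order:
            row, col = col, row
        centers.append(DiscCenter(row=row, col=col, image_id=str(rec.image_id)))
    return centers


_GROUP_KEYS = ("image_id", "condition")


def load_group_table(path: str | Path) -> pd.DataFrame:
    """Load the grouping table mapping image_id → condition (+ optional
    ``timepoint`` and paired-eye key)."""
    frame = pd.read_csv(path, dtype=str)
    missing = [k for k in _GROUP_KEYS if k not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    dupes = frame["image_id"][frame["image_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValidationError(f"{path}: duplicate image_id entries {dupes}")
    return frame


def write_results_table(records: list[dict], path: str | Path) -> Path:
    """Write homogeneous records to CSV with ``image_id`` as first column.

    Column order is stable (first-record order, ``image_id`` promoted to the
    front) so reruns produce byte-identical files.
    """
    if not records:
        raise ValidationError("cannot write an empty results table")
    keys = list(records[0].keys())
    for rec in records[1:]:
        extra = set(rec.keys()) ^ set(keys)
        if extra:
            raise ValidationError(f"records have mixed keys: {sorted(extra)}")
    if "image_id" in keys:
        keys = ["image_id"] + [k for k in keys if k != "image_id"]
    frame = pd.DataFrame.from_records(records, columns=keys)
    path = Path(path)
    frame.to_csv(path, index=False)
    return path
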