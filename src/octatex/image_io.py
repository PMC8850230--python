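"""Reading, validation and quality filtering of en-face OCTA images.

An en-face image is a single 8-bit grayscale slab (superficial/deep plexus or
choriocapillaris) exported from the OCTA device, accompanied by cohort
metadata carried in a manifest CSV.  Multi-channel and high-bit-depth inputs
are converted to 8-bit grayscale on load; analysis-ready images are centred
crops of a fixed size (512 px by default, 5 um/px).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = [
    "subject_id",
    "eye",
    "group",
    "layer",
    "signal_strength",
    "image_path",
    "pixel_scale_um",
]

VALID_EYES = {"OD", "OS", "NA"}
VALID_GROUPS = {"case", "control"}
VALID_LAYERS = {"SCP", "DCP", "ORL", "CCL"}

#: ITU-R BT.601 luminance weights used to collapse RGB exports to grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class EnFaceImage:
    """One 8-bit grayscale en-face OCTA slab with its cohort metadata."""

    pixels: np.ndarray
    pixel_scale_um: float = 5.0
    subject_id: str = ""
    eye: str = "NA"
    group: str = ""
    layer: str = ""
    signal_strength: Optional[int] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2D array")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            if not np.array_equal(self.pixels, np.round(self.pixels)):
                raise ValueError("intensities must be integers")
            self.pixels = self.pixels.astype(np.uint8)
        if not self.pixel_scale_um > 0:
            raise ValueError("pixel_scale_um must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    """Collapse channels by luminance and min-max rescale non-8-bit data."""
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            arr = arr.astype(float) @ _LUMA
        elif arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ValueError(f"unsupported channel count {arr.shape[2]}")
    if arr.dtype == np.uint8:
        return arr
    arr = arr.astype(float)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.full(arr.shape, np.clip(round(lo), 0, 255), dtype=np.uint8)
    scaled = (arr - lo) / (hi - lo) * 255.0
    return np.round(scaled).astype(np.uint8)


def load_image(path: str | Path, **metadata) -> EnFaceImage:
    """Load a PNG/TIFF en-face export as an :class:`EnFaceImage`.

    RGB inputs are collapsed by luminance; 16-bit or float rasters are
    min-max rescaled to the 8-bit range (logged, since the native export is
    8-bit).  ``metadata`` keywords are forwarded to the dataclass.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - decoding errors vary by plugin
        raise IOError(f"could not read image {path}: {exc}") from exc
    if raw.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    if raw.ndim not in (2, 3):
        raise ValueError(f"expected a 2D raster, got shape {raw.shape}: {path}")
    if raw.dtype != np.uint8:
        logger.info("rescaling %s from %s to 8-bit", path, raw.dtype)
    return EnFaceImage(pixels=_to_uint8(raw), **metadata)


def save_image(img: EnFaceImage, path: str | Path) -> None:
    """Write the pixel matrix as an 8-bit grayscale PNG/TIFF."""
    iio.imwrite(Path(path), img.pixels)


def crop_center(img: EnFaceImage, size: int) -> EnFaceImage:
    """Return the centred ``size`` x ``size`` window; metadata preserved.

    Offsets are floor((dim - size)/2), so a 600x600 image cropped to 512
    starts at (44, 44).
    """
    if size > min(img.height, img.width):
        raise ValueError(
            f"crop size {size} exceeds image dimensions {img.height}x{img.width}"
        )
    r0 = (img.height - size) // 2
    c0 = (img.width - size) // 2
    return replace(img, pixels=img.pixels[r0 : r0 + size, c0 : c0 + size])


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort manifest CSV.

    Columns: ``subject_id,eye,group,layer,signal_strength,image_path,
    pixel_scale_um``; missing signal strength as an empty field.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    return validate_manifest(df)


def validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest is missing columns: {missing}")
    df = df[MANIFEST_COLUMNS].copy()
    bad_group = set(df["group"]) - VALID_GROUPS
    if bad_group:
        raise ValueError(f"invalid group values: {sorted(bad_group)}")
    key = df[["subject_id", "eye", "layer"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0].tolist()
        raise ValueError(f"duplicate subject/eye/layer entry: {dup}")
    df["signal_strength"] = pd.to_numeric(df["signal_strength"], errors="coerce")
    df["pixel_scale_um"] = pd.to_numeric(df["pixel_scale_um"]).fillna(5.0)
    return df


def filter_quality(manifest: pd.DataFrame, min_signal: int = 6) -> pd.DataFrame:
    """Drop rows whose device signal strength is below ``min_signal``.

    Rows with a missing strength are retained with a warning: the strength
    is device-reported and its absence in a manifest usually means the
    export lost the field, not that the scan was poor.
    """
    if min_signal < 0:
        raise ValueError("min_signal must be non-negative")
    strength = manifest["signal_strength"]
    missing = strength.isna()
    if missing.any():
        for sid in manifest.loc[missing, "subject_id"]:
            logger.warning("subject %s has no signal strength; retained", sid)
    keep = missing | (strength >= min_signal)
    return manifest[keep].reset_index(drop=True)
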