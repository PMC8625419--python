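"""On-disk conventions: channel images, label maps, and summary tables.

Images are single-plane grayscale TIFF (8/16-bit); label maps may also be
PNG.  Loading never rescales intensities — a 12-bit image keeps its 0..4095
range as floats — so any standardization downstream is explicit.  Class
maps use the fixed code set 0=Background, 1=StriatedMyocyte, 2=Other,
3=Foreground-unresolved and are serialized as 8-bit images.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

CHANNELS = ("actin", "alpha_actinin", "nuclei")

CLASS_BACKGROUND = 0
CLASS_STRIATED = 1
CLASS_OTHER = 2
CLASS_FOREGROUND = 3  # foreground not yet resolved into striated vs other
CLASS_CODES = frozenset({CLASS_BACKGROUND, CLASS_STRIATED, CLASS_OTHER, CLASS_FOREGROUND})

CLASS_NAMES = {
    CLASS_BACKGROUND: "Background",
    CLASS_STRIATED: "StriatedMyocyte",
    CLASS_OTHER: "Other",
    CLASS_FOREGROUND: "Foreground",
}

MIN_IMAGE_SIDE = 64

SUMMARY_COLUMNS = [
    "well",
    "cell_type",
    "oop",
    "director_deg",
    "angle_to_stretch_deg",
    "n_vectors",
    "actin_fraction",
]


@dataclass
class ChannelImage:
    """A single fluorescence channel held as floats.

    ``pixel_size_um`` is inert metadata carried through for provenance; no
    computation in the package uses physical units.
    """

    pixels: np.ndarray
    channel: str
    pixel_size_um: float | None = None
    source_dtype: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("expected single-channel image: a 2-D intensity grid")
        h, w = self.pixels.shape
        if h < MIN_IMAGE_SIDE or w < MIN_IMAGE_SIDE:
            raise ValueError(f"image too small: {h}x{w}, need >= {MIN_IMAGE_SIDE} per side")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel tag {self.channel!r}; expected one of {CHANNELS}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite intensities")
        if self.pixels.min() < 0:
            raise ValueError("image contains negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LabelMap:
    """Integer label grid: nucleus instances or semantic class codes."""

    labels: np.ndarray
    semantics: str  # "instance" or "class"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label map must hold integers")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        if self.semantics not in ("instance", "class"):
            raise ValueError("semantics must be 'instance' or 'class'")
        if self.semantics == "class":
            bad = set(np.unique(self.labels)) - CLASS_CODES
            if bad:
                raise ValueError(f"unknown class codes present: {sorted(bad)}")


def _read_gray(path: str) -> np.ndarray:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(
            f"expected single-channel image, got shape {arr.shape}: "
            "supply one grayscale plane per channel file"
        )
    return arr


def load_channel(path: str, channel_tag: str, pixel_size_um: float | None = None) -> ChannelImage:
    """Load one grayscale channel; intensities kept on their original scale."""
    arr = _read_gray(path)
    return ChannelImage(
        pixels=arr.astype(float),
        channel=channel_tag,
        pixel_size_um=pixel_size_um,
        source_dtype=str(arr.dtype),
    )


def save_channel(image: ChannelImage, path: str) -> None:
    """Write a channel as 16-bit TIFF (values rounded, clipped to uint16)."""
    arr = np.clip(np.round(image.pixels), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, arr)


def save_class_map(label_map: LabelMap, path: str) -> None:
    if label_map.semantics != "class":
        raise ValueError("save_class_map expects class semantics")
    arr = label_map.labels.astype(np.uint8)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def load_class_map(path: str) -> LabelMap:
    return LabelMap(labels=_read_gray(path).astype(np.int64), semantics="class")


def save_instance_map(label_map: LabelMap, path: str) -> None:
    if label_map.semantics != "instance":
        raise ValueError("save_instance_map expects instance semantics")
    arr = label_map.labels
    if arr.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many instances for 16-bit serialization")
    arr = arr.astype(np.uint16)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def load_instance_map(path: str) -> LabelMap:
    return LabelMap(labels=_read_gray(path).astype(np.int64), semantics="instance")


def _format_float(x) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return ""
    return f"{x:.6g}"


def write_well_summary(records: list[dict], path: str) -> None:
    """Write per-well/cell-type organization rows as CSV, floats at 6 sig digits."""
    df = pd.DataFrame(records, columns=SUMMARY_COLUMNS)
    for col in ("oop", "director_deg", "angle_to_stretch_deg", "actin_fraction"):
        df[col] = df[col].map(_format_float)
    df.to_csv(path, index=False)


def read_well_summary(path: str) -> pd.DataFrame:
    return pd.read_csv(path)
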