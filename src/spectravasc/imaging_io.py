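"""Readers and writers for spectral libraries, masks, and result tables.

A spectral library on disk is a directory of grayscale TIFFs, one per
excitation/emission channel, named by the channel label
(``ex488_em550.tif``, ``ex635_emnone.tif``, ...), plus a ``library.json``
sidecar carrying the pixel pitch, bit depth and free-form provenance.
Intensities are normalized to [0, 1] at load so downstream contrast and
thresholding are bit-depth independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .spectral_model import ChannelSpec

__all__ = [
    "SpectralLibrary",
    "SIDECAR_NAME",
    "RESULT_COLUMNS",
    "read_library",
    "write_library",
    "read_mask",
    "write_mask",
    "write_results",
]

SIDECAR_NAME = "library.json"
TRUTH_MASK_NAME = "truth_mask.tif"

RESULT_COLUMNS = [
    "sample_id",
    "group",
    "vessel_area_mm2",
    "roi_area_mm2",
    "area_fraction",
    "mvd_analog",
]


@dataclass
class SpectralLibrary:
    """Co-registered per-channel images with the shared pixel pitch."""

    channels: dict[ChannelSpec, np.ndarray]
    pixel_pitch_mm: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("library needs at least one channel")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel_pitch_mm must be > 0")
        shapes = {img.shape for img in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel images disagree on shape: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, channel: ChannelSpec) -> np.ndarray:
        return self.channels[channel]


def write_library(
    lib: SpectralLibrary, path: str | Path, bit_depth: int = 16
) -> Path:
    """Write one TIFF per channel plus the JSON sidecar; returns the directory."""
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scale = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    for channel, img in lib.channels.items():
        quantized = np.round(np.clip(img, 0.0, 1.0) * scale).astype(dtype)
        tifffile.imwrite(path / f"{channel.label}.tif", quantized)
    sidecar = {
        "pixel_pitch_mm": lib.pixel_pitch_mm,
        "bit_depth": bit_depth,
        "channels": [ch.label for ch in lib.channels],
        "meta": _jsonable(lib.meta),
    }
    (path / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=2) + "\n")
    return path


def read_library(path: str | Path) -> SpectralLibrary:
    """Load a channel directory written by :func:`write_library`.

    Channel specs are parsed from the filenames; intensities are divided by
    the sidecar's full-scale value.  Missing sidecar, unparseable filenames,
    or shape mismatches raise.
    """
    path = Path(path)
    sidecar_path = path / SIDECAR_NAME
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    scale = 2 ** int(sidecar["bit_depth"]) - 1
    channels: dict[ChannelSpec, np.ndarray] = {}
    names = sidecar.get("channels") or sorted(
        p.stem for p in path.glob("ex*_em*.tif")
    )
    for name in names:
        stem = name[:-4] if name.endswith(".tif") else name
        try:
            spec = ChannelSpec.parse(stem)
        except ValueError as err:
            raise ValueError(f"unparseable channel filename {stem!r}.tif") from err
        img = tifffile.imread(path / f"{stem}.tif").astype(float) / scale
        channels[spec] = img
    return SpectralLibrary(
        channels=channels,
        pixel_pitch_mm=float(sidecar["pixel_pitch_mm"]),
        meta=sidecar.get("meta", {}),
    )


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a binary mask as an 8-bit TIFF (vessel = 255)."""
    path = Path(path)
    tifffile.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    """Read a TIFF mask; any nonzero pixel is vessel."""
    return tifffile.imread(Path(path)) > 0


def write_results(rows: list[dict], path: str | Path) -> Path:
    """Write per-sample records to CSV with a fixed header.

    The area fraction is recomputed as vessel_area_mm2 / roi_area_mm2 on
    write, so the emitted table is always internally consistent.
    """
    path = Path(path)
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if len(df):
        df["area_fraction"] = df["vessel_area_mm2"] / df["roi_area_mm2"]
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
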