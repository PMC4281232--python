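"""Disk interchange: multichannel TIFFs, ladder CSVs, masks, metric tables.

Images travel as multi-page TIFF (one page per channel, order declared in
a YAML sidecar or assumed LW, MW, SW, UV); ROI masks as single-channel
TIFF; the grey-standard ladder as a CSV with columns
``channel, reflectance, measured_value``; all tabular results as CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .calibration import GreyStandardLadder, RawMultispectralImage
from .colour import CHANNELS

__all__ = [
    "write_multispectral_tiff",
    "read_multispectral_tiff",
    "write_mask_tiff",
    "read_mask_tiff",
    "write_ladder_csv",
    "read_ladder_csv",
]


def write_multispectral_tiff(
    path: str | Path,
    image: RawMultispectralImage,
    channel_order: tuple[str, ...] = CHANNELS,
) -> None:
    stack = np.stack([image.rasters[ch] for ch in channel_order]).astype(np.float32)
    tifffile.imwrite(str(path), stack, photometric="minisblack")


def read_multispectral_tiff(
    path: str | Path,
    standard_roi: np.ndarray,
    ruler_scale: float,
    channel_order: tuple[str, ...] = CHANNELS,
) -> RawMultispectralImage:
    stack = tifffile.imread(str(path)).astype(float)
    if stack.ndim != 3 or stack.shape[0] != len(channel_order):
        raise ValueError(
            f"{path}: expected {len(channel_order)} channel pages, got shape {stack.shape}"
        )
    rasters = {ch: stack[i] for i, ch in enumerate(channel_order)}
    return RawMultispectralImage(
        rasters=rasters, standard_roi=standard_roi, ruler_scale=ruler_scale
    )


def write_mask_tiff(path: str | Path, mask: np.ndarray) -> None:
    tifffile.imwrite(str(path), mask.astype(np.uint8) * 255)


def read_mask_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)) > 0


def write_ladder_csv(path: str | Path, ladder: GreyStandardLadder) -> None:
    rows = [
        {"channel": ch, "reflectance": r, "measured_value": v}
        for ch, vals in ladder.measured.items()
        for r, v in zip(ladder.reflectances, vals)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ladder_csv(path: str | Path) -> GreyStandardLadder:
    df = pd.read_csv(path)
    required = {"channel", "reflectance", "measured_value"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: ladder CSV needs columns {sorted(required)}")
    refl = np.sort(df["reflectance"].unique())
    measured = {}
    for ch, sub in df.groupby("channel"):
        sub = sub.sort_values("reflectance")
        if not np.allclose(sub["reflectance"].to_numpy(), refl):
            raise ValueError(f"{path}: channel {ch!r} reflectances differ across channels")
        measured[str(ch)] = sub["measured_value"].to_numpy(dtype=float)
    return GreyStandardLadder(reflectances=refl, measured=measured)
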