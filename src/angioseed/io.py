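"""Image and seed-table I/O.

Images are read from PNG/TIFF (8- or 16-bit grayscale) and converted to
float intensities without rescaling; multi-channel inputs are reduced to
their first channel.  Seed sets round-trip through CSV with columns
x, y, response, status.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .ridge_detect import SeedSet

__all__ = [
    "read_image",
    "write_image",
    "seeds_to_dataframe",
    "write_seeds_csv",
    "read_seeds_csv",
    "render_overlay",
    "write_overlay_png",
]


def read_image(path: str | Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:  # drop color/alpha channels
        arr = arr[..., 0]
    return arr.astype(float)


def write_image(path: str | Path, values: np.ndarray) -> None:
    """Write a float image as 16-bit TIFF / PNG (linearly scaled to range)."""
    values = np.asarray(values, dtype=float)
    vmax = values.max()
    scaled = values / vmax * 65535.0 if vmax > 0 else values
    iio.imwrite(path, scaled.astype(np.uint16))


def seeds_to_dataframe(seeds: SeedSet) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x": seeds.x.astype(int),
            "y": seeds.y.astype(int),
            "response": seeds.response,
            "status": seeds.status,
        }
    )


def write_seeds_csv(path: str | Path, seeds: SeedSet) -> None:
    seeds_to_dataframe(seeds).to_csv(path, index=False, float_format="%.6f")


def read_seeds_csv(path: str | Path) -> SeedSet:
    df = pd.read_csv(path)
    return SeedSet(
        x=df["x"].to_numpy(np.intp),
        y=df["y"].to_numpy(np.intp),
        response=df["response"].to_numpy(float),
        status=df["status"].to_numpy("<U9"),
    )


def render_overlay(image: np.ndarray, seeds: SeedSet) -> np.ndarray:
    """RGB rendering: refined seeds green, rejected red, candidates yellow."""
    image = np.asarray(image, dtype=float)
    vmax = image.max()
    gray = (image / vmax * 255.0 if vmax > 0 else image).astype(np.uint8)
    rgb = np.stack([gray, gray, gray], axis=-1)
    colors = {"refined": (0, 255, 0), "rejected": (255, 0, 0), "candidate": (255, 255, 0)}
    for status, color in colors.items():
        sel = seeds.status == status
        rgb[seeds.y[sel], seeds.x[sel]] = color
    return rgb


def write_overlay_png(path: str | Path, image: np.ndarray, seeds: SeedSet) -> None:
    iio.imwrite(path, render_overlay(image, seeds))
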