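"""Sine-wave colormap test image and colormap overlays.

The test pattern is a horizontal ramp with a superimposed sine wave
whose amplitude grows linearly from zero at the bottom edge to a
maximum at the top edge.  Regions of a colormap with too little local
contrast make the wave vanish; uneven contrast shows as uneven wave
visibility across the image.
"""

from __future__ import annotations

import numpy as np

from . import colorspace as cs
from .cmap_io import RGBColormap
from .cvd import CVDSpec, simulate

__all__ = ["make_test_image", "overlay", "save_png"]


def make_test_image(
    width: int = 512,
    height: int = 128,
    wavelength_px: float = 8.0,
    max_amplitude: float = 0.05,
) -> np.ndarray:
    """Scalar test image in [0, 1], shape (height, width); row 0 is the top.

    value(x, y) = clip01( x/(width-1) + A(y) * sin(2*pi*x / wavelength) )
    with A growing linearly from 0 at the bottom row to
    ``max_amplitude`` at the top row.
    """
    if width < 2 or height < 1:
        raise ValueError("image must be at least 2x1 pixels")
    if wavelength_px < 2:
        raise ValueError("wavelength must be >= 2 px")
    if not (0.0 <= max_amplitude <= 0.5):
        raise ValueError("max_amplitude must lie in [0, 0.5]")
    x = np.arange(width)
    ramp = x / (width - 1)
    # row index grows downward; amplitude grows toward the top edge
    frac_from_bottom = (
        np.ones(height) if height == 1
        else (height - 1 - np.arange(height)) / (height - 1)
    )
    amp = max_amplitude * frac_from_bottom
    img = ramp[None, :] + amp[:, None] * np.sin(2.0 * np.pi * x / wavelength_px)[None, :]
    return np.clip(img, 0.0, 1.0)


def overlay(
    image: np.ndarray,
    cmap: RGBColormap,
    spec: CVDSpec | None = None,
) -> np.ndarray:
    """Render a scalar image through a colormap; shape (H, W, 3).

    Uses the same nearest-index lookup as the CDPS machinery.  If
    ``spec`` is given, the rendered colors are CVD-simulated.
    """
    image = np.asarray(image, dtype=float)
    if image.min() < 0 or image.max() > 1 or not np.all(np.isfinite(image)):
        raise ValueError("scalar image values must be finite and in [0, 1]")
    rgb = cmap.lookup(image)
    if spec is not None:
        rgb = simulate(rgb, spec)
    return rgb


def save_png(raster: np.ndarray, path) -> None:
    """Write an (H, W, 3) float raster in [0, 1] as an 8-bit PNG."""
    from PIL import Image

    arr = np.rint(np.clip(raster, 0.0, 1.0) * 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)
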