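"""Colormap containers, file formats, bundled fixtures, synthetic generators.

Supported formats:

* plain-text RGB tables (whitespace- or comma-separated, three numeric
  columns), in a ``float01`` (values in [0,1]) or ``int255`` (0-255)
  dialect — the dialect is an explicit flag, never sniffed, because a
  value like "1" is ambiguous between the two;
* JSON ``{"name": ..., "colors": [[r,g,b], ...]}``;
* raw binary ImageJ ``.lut`` files: 256 red bytes, then 256 green, then
  256 blue (768 bytes), drop-in compatible with ``ImageJ/luts``.

Bundled fixtures (256-entry public-domain standard tables): ``viridis``,
``jet``, ``gray``, plus a two-entry degenerate map for edge-case tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import colorspace

__all__ = [
    "RGBColormap",
    "ColormapFormatError",
    "read_table",
    "write_table",
    "read_json",
    "write_json",
    "read_imagej_lut",
    "write_imagej_lut",
    "fixture",
    "fixture_names",
    "synth_trajectory",
]

FIXTURE_NAMES = ("viridis", "jet", "gray", "two_point_degenerate")


class ColormapFormatError(ValueError):
    """A colormap file violates its format contract."""


@dataclass(frozen=True)
class RGBColormap:
    """An ordered table of display colors; the package's external currency.

    ``colors`` is an (N, 3) float array of encoded sRGB values in [0, 1].
    """

    colors: np.ndarray
    name: str = "colormap"

    def __post_init__(self) -> None:
        colors = np.atleast_2d(np.asarray(self.colors, dtype=float))
        object.__setattr__(self, "colors", colors)
        if colors.ndim != 2 or colors.shape[1] != 3:
            raise ValueError("colors must be an (N, 3) array")
        if len(colors) < 2:
            raise ValueError("a colormap needs at least 2 entries")
        if not np.all(np.isfinite(colors)):
            raise ValueError("non-finite color values")
        if not colorspace.in_gamut(colors).all():
            raise ValueError("colormap entries must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.colors)

    def lookup(self, values) -> np.ndarray:
        """Map data values in [0, 1] to colors by nearest-index lookup.

        A value v picks entry ``round(v * (N - 1))``.
        """
        values = np.asarray(values, dtype=float)
        idx = np.rint(values * (len(self) - 1)).astype(int)
        return self.colors[np.clip(idx, 0, len(self) - 1)]


# ---------------------------------------------------------------------------
# text tables

def _load_numeric_table(path) -> np.ndarray:
    try:
        df = pd.read_csv(
            path, sep=None, engine="python", header=None, comment="#",
            skip_blank_lines=True,
        )
    except Exception as exc:  # malformed text
        raise ColormapFormatError(f"{path}: cannot parse table ({exc})") from exc
    if df.shape[1] != 3:
        raise ColormapFormatError(
            f"{path}: expected 3 columns, found {df.shape[1]}"
        )
    try:
        return df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ColormapFormatError(f"{path}: non-numeric entries") from exc


def read_table(path, dialect: str = "float01", name: str | None = None) -> RGBColormap:
    """Read an RGB table; ``dialect`` is 'float01' or 'int255'."""
    if dialect not in ("float01", "int255"):
        raise ValueError("dialect must be 'float01' or 'int255'")
    arr = _load_numeric_table(path)
    hi = 1.0 if dialect == "float01" else 255.0
    bad = np.where((arr < 0) | (arr > hi))[0]
    if bad.size:
        raise ColormapFormatError(
            f"{path}: value out of {dialect} range at row {bad[0] + 1}"
        )
    if dialect == "int255":
        arr = arr / 255.0
    return RGBColormap(arr, name=name or Path(str(path)).stem)


def write_table(cmap: RGBColormap, path, dialect: str = "float01") -> None:
    if dialect == "float01":
        np.savetxt(path, cmap.colors, fmt="%.8f", delimiter=",")
    elif dialect == "int255":
        np.savetxt(
            path, np.rint(cmap.colors * 255).astype(int), fmt="%d", delimiter=","
        )
    else:
        raise ValueError("dialect must be 'float01' or 'int255'")


def read_json(path) -> RGBColormap:
    with open(path) as fh:
        obj = json.load(fh)
    try:
        return RGBColormap(np.asarray(obj["colors"], dtype=float),
                           name=obj.get("name", Path(str(path)).stem))
    except (KeyError, TypeError, ValueError) as exc:
        raise ColormapFormatError(f"{path}: invalid colormap JSON") from exc


def write_json(cmap: RGBColormap, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"name": cmap.name, "colors": cmap.colors.tolist()}, fh, indent=1
        )


# ---------------------------------------------------------------------------
# ImageJ LUT (raw 768-byte binary: 256 R, 256 G, 256 B)

def write_imagej_lut(cmap: RGBColormap, path) -> None:
    if len(cmap) != 256:
        raise ValueError("ImageJ LUTs require exactly 256 entries")
    planes = np.rint(cmap.colors.T * 255).astype(np.uint8)  # (3, 256)
    Path(path).write_bytes(planes.tobytes())


def read_imagej_lut(path, name: str | None = None) -> RGBColormap:
    raw = Path(path).read_bytes()
    if len(raw) != 768:
        raise ColormapFormatError(
            f"{path}: ImageJ LUT must be 768 bytes, got {len(raw)}"
        )
    planes = np.frombuffer(raw, dtype=np.uint8).reshape(3, 256)
    return RGBColormap(planes.T / 255.0, name=name or Path(str(path)).stem)


# ---------------------------------------------------------------------------
# fixtures

def fixture_names() -> tuple[str, ...]:
    return FIXTURE_NAMES


def uniform_gray(n: int = 256) -> RGBColormap:
    """Perceptually uniform grayscale: equal-RGB colors, J' linear.

    Gray levels are chosen (by inverting a dense lightness-vs-level
    table) so that J' runs linearly from 0 at black to 100 at white.
    This is the grayscale reference of the CDPS statistic.
    """
    if n < 2:
        raise ValueError("gray ramp needs at least 2 entries")
    levels = np.linspace(0.0, 1.0, 4096)
    jp = colorspace.srgb_to_ucs(np.stack([levels] * 3, axis=1))[:, 0]
    g = np.interp(np.linspace(0.0, 100.0, n), jp, levels)
    g[0], g[-1] = 0.0, 1.0
    return RGBColormap(np.stack([g] * 3, axis=1), name="gray")


def fixture(name: str) -> RGBColormap:
    """Return a bundled fixture colormap by name.

    ``gray`` is the perceptually uniform (lightness-linear) grayscale,
    not an RGB-linear ramp.
    """
    if name == "gray":
        return uniform_gray(256)
    if name == "two_point_degenerate":
        return RGBColormap(np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]]),
                           name="two_point_degenerate")
    if name in ("viridis", "jet"):
        ref = resources.files("cvdcmap.data").joinpath(f"{name}.csv")
        with resources.as_file(ref) as p:
            return read_table(p, dialect="float01", name=name)
    raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")


# ---------------------------------------------------------------------------
# synthetic generator for property tests

def synth_trajectory(
    seed: int,
    n: int = 256,
    chroma_radius: float = 15.0,
    jp_range: tuple[float, float] = (25.0, 75.0),
) -> RGBColormap:
    """Generate a smooth in-gamut colormap from a UCS-space arc.

    The path is a circular arc of the given radius in the (a', b')
    plane (random center angle and sweep drawn from ``seed``) with J'
    linear over ``jp_range``, converted to sRGB.  Raises RuntimeError
    if the requested geometry leaves the display gamut.
    """
    rng = np.random.default_rng(seed)
    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    sweep = rng.uniform(0.5 * np.pi, 1.5 * np.pi) * rng.choice([-1.0, 1.0])
    theta = theta0 + sweep * np.linspace(0.0, 1.0, n)
    jp = np.linspace(jp_range[0], jp_range[1], n)
    jab = np.stack(
        [jp, chroma_radius * np.cos(theta), chroma_radius * np.sin(theta)],
        axis=1,
    )
    rgb = colorspace.ucs_to_srgb(jab)
    if not np.all(np.isfinite(rgb)) or not colorspace.in_gamut(rgb, atol=1e-9).all():
        raise RuntimeError(
            "synthetic trajectory leaves the sRGB gamut; reduce chroma_radius "
            "or narrow jp_range"
        )
    return RGBColormap(np.clip(rgb, 0.0, 1.0), name=f"synth-{seed}")
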