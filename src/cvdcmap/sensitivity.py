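"""Colormap-data perceptual sensitivity (CDPS).

For a 1-D data transect (values normalized to [0, 1]) rendered through
a colormap, CDPS compares *perceptual* differences to *data*
differences over all unordered pairs of transect points:

* data delta      = |v_i - v_j|
* perceptual delta = Euclidean CAM02-UCS distance between the two
  rendered colors, normalized by the regression slope of the grayscale
  case on the same transect (so grayscale always scores slope 1).

An ordinary least-squares fit of normalized perceptual delta against
data delta summarizes the scatter: the slope ``m`` measures sensitivity
(how much perceived change per unit of data change, relative to
grayscale) and ``r^2`` measures uniformity (1 = perceptually uniform).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import colorspace as cs
from .cmap_io import RGBColormap
from .cvd import CVDSpec, simulate

__all__ = [
    "CDPSResult",
    "DegenerateRegressionError",
    "uniform_transect",
    "data_deltas",
    "perceptual_deltas",
    "cdps",
    "adjacent_delta_profile",
    "gray_ramp",
]


class DegenerateRegressionError(ValueError):
    """The transect carries no data variation; the fit is undefined."""


@dataclass(frozen=True)
class CDPSResult:
    m: float
    r2: float
    pairs: np.ndarray  # (n_pairs, 2): data delta, normalized perceptual delta
    gray_slope: float


def uniform_transect(n: int = 64) -> np.ndarray:
    """n evenly spaced data values spanning [0, 1]."""
    if n < 2:
        raise ValueError("transect needs at least 2 points")
    return np.linspace(0.0, 1.0, n)


def gray_ramp(n: int = 256) -> RGBColormap:
    """Perceptually uniform gray ramp: equal-RGB colors with J' linear.

    Same construction as the bundled ``gray`` fixture; an RGB-linear
    ramp is NOT perceptually uniform (its J' is curved against the
    encoded value).
    """
    from .cmap_io import uniform_gray

    return uniform_gray(n)


def _validate_transect(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("transect must be 1-D with length >= 2")
    if not np.all(np.isfinite(t)) or t.min() < 0 or t.max() > 1:
        raise ValueError("transect values must be finite and in [0, 1]")
    return t


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    # all unordered pairs i < j in (i, j)-lexicographic order
    return np.triu_indices(n, k=1)


def data_deltas(transect) -> np.ndarray:
    """|v_i - v_j| over all unordered pairs, lexicographic order."""
    t = _validate_transect(transect)
    i, j = _pair_indices(len(t))
    return np.abs(t[i] - t[j])


def perceptual_deltas(
    transect,
    cmap: RGBColormap,
    vc: cs.ViewingConditions = cs.SRGB_AVERAGE,
) -> np.ndarray:
    """Pairwise UCS distances of the rendered transect, same pair order."""
    t = _validate_transect(transect)
    ucs = cs.srgb_to_ucs(cmap.lookup(t), vc)
    i, j = _pair_indices(len(t))
    return cs.delta(ucs[i], ucs[j])


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(slope, r^2) of a simple with-intercept least-squares fit."""
    if np.ptp(x) == 0:
        raise DegenerateRegressionError("all data deltas are equal")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.rvalue**2)


def cdps(
    transect,
    cmap: RGBColormap,
    vc: cs.ViewingConditions = cs.SRGB_AVERAGE,
    gray_reference: RGBColormap | None = None,
) -> CDPSResult:
    """CDPS slope m and r^2 for a colormap on a transect.

    ``gray_reference`` defaults to a linear gray ramp of the colormap's
    length; its regression slope on the same transect is the
    normalization constant, so the grayscale case itself scores m = 1.
    """
    t = _validate_transect(transect)
    if gray_reference is None:
        gray_reference = gray_ramp(len(cmap))
    dd = data_deltas(t)
    gray_slope, _ = _ols(dd, perceptual_deltas(t, gray_reference, vc))
    if not gray_slope > 0:
        raise ValueError("invalid gray reference: non-positive slope")
    pdeltas = perceptual_deltas(t, cmap, vc) / gray_slope
    m, r2 = _ols(dd, pdeltas)
    return CDPSResult(
        m=m, r2=r2, pairs=np.stack([dd, pdeltas], axis=1), gray_slope=gray_slope
    )


def adjacent_delta_profile(
    cmap: RGBColormap,
    spec: CVDSpec | None = None,
    vc: cs.ViewingConditions = cs.SRGB_AVERAGE,
) -> tuple[np.ndarray, float]:
    """Consecutive-entry UCS deltas and the 'imperfection' scalar.

    Returns (deltas, max |delta - mean delta|); the scalar is 0 for a
    perfectly uniform map.  If ``spec`` is given the colormap is CVD-
    simulated first.
    """
    rgb = cmap.colors if spec is None else simulate(cmap.colors, spec)
    ucs = cs.srgb_to_ucs(rgb, vc)
    deltas = cs.delta(ucs[1:], ucs[:-1])
    return deltas, float(np.abs(deltas - deltas.mean()).max())
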