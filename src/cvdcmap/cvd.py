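"""Color vision deficiency simulation (Machado physiological matrix model).

A deficiency is described by its type (deuteranomaly, protanomaly,
tritanomaly) and a severity on a 0-100 scale, where 0 is normal
trichromatic vision and 100 is complete dichromacy.  Simulation is a
3x3 matrix applied in *linear* RGB: encoded sRGB is decoded, multiplied,
re-encoded, and finally clamped to [0, 1].

The anchor matrices shipped here are the identity (severity 0) and the
published full-dichromacy matrices of the physiologically-based
two-stage opponent model (severity 100); intermediate severities are
element-wise linear interpolations between the bracketing anchors,
which keeps the dial continuous and exact at both endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colorspace import srgb_decode, srgb_encode

__all__ = ["CVDSpec", "simulation_matrix", "simulate", "CVD_KINDS"]

CVD_KINDS = ("deuteranomaly", "protanomaly", "tritanomaly")

# Published full-dichromacy matrices (linear-RGB domain) of the
# physiologically-based CVD model; rows sum to ~1 (grays preserved).
_DICHROMACY = {
    "protanomaly": np.array(
        [
            [0.152286, 1.052583, -0.204868],
            [0.114503, 0.786281, 0.099216],
            [-0.003882, -0.048116, 1.051998],
        ]
    ),
    "deuteranomaly": np.array(
        [
            [0.367322, 0.860646, -0.227968],
            [0.280085, 0.672501, 0.047413],
            [-0.011820, 0.042940, 0.968881],
        ]
    ),
    "tritanomaly": np.array(
        [
            [1.255528, -0.076749, -0.178779],
            [-0.078411, 0.930809, 0.147602],
            [0.004733, 0.691367, 0.303900],
        ]
    ),
}

# severity -> matrix anchors, interpolated element-wise between.
_ANCHOR_SEVERITIES = np.array([0.0, 100.0])


@dataclass(frozen=True)
class CVDSpec:
    """Deficiency type + severity parameterizing the simulation matrix."""

    kind: str = "deuteranomaly"
    severity: float = 100.0

    def __post_init__(self) -> None:
        if self.kind not in CVD_KINDS:
            raise ValueError(
                f"unknown CVD kind {self.kind!r}; expected one of {CVD_KINDS}"
            )
        if not (0.0 <= self.severity <= 100.0):
            raise ValueError("severity must lie in [0, 100]")


def _anchors(kind: str) -> np.ndarray:
    return np.stack([np.eye(3), _DICHROMACY[kind]])


def simulation_matrix(spec: CVDSpec) -> np.ndarray:
    """3x3 linear-RGB transform for the given deficiency spec.

    Severity 0 is the identity; severities between anchors interpolate
    the anchor matrices element-wise.
    """
    anchors = _anchors(spec.kind)
    sev = spec.severity
    hi = int(np.searchsorted(_ANCHOR_SEVERITIES, sev, side="left"))
    if hi == 0:
        return anchors[0].copy()
    lo = hi - 1
    s0, s1 = _ANCHOR_SEVERITIES[lo], _ANCHOR_SEVERITIES[hi]
    w = (sev - s0) / (s1 - s0)
    return (1.0 - w) * anchors[lo] + w * anchors[hi]


def simulate(rgb, spec: CVDSpec) -> np.ndarray:
    """Render colors as seen with the given deficiency.

    `rgb` is a single encoded-sRGB triple or an (..., 3) array with all
    colors in gamut.  The matrix is applied in linear RGB; the result is
    re-encoded and clamped to [0, 1].
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.size == 0:
        raise ValueError("empty colormap")
    if rgb.shape[-1] != 3:
        raise ValueError("expected (..., 3) RGB input")
    m = simulation_matrix(spec)
    out = srgb_encode(srgb_decode(rgb) @ m.T)
    return np.clip(out, 0.0, 1.0)
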