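"""sRGB <-> CIECAM02-UCS conversion under fixed viewing conditions.

The forward path is sRGB (IEC 61966-2-1 encoded) -> linear RGB -> CIE XYZ
(D65) -> CIECAM02 appearance correlates (J, M, h) -> the Luo et al.
"large and small differences" uniform space J'a'b' (CAM02-UCS, K_L = 1,
c1 = 0.007, c2 = 0.0228).  The inverse path runs the appearance model
backwards and deliberately does NOT clamp: out-of-gamut J'a'b' points
return raw channel values outside [0, 1] so callers can measure how far
outside the display gamut a requested color lies.  Clamping is the
explicit, separate :func:`clamp_gamut` step (absolute colorimetric
rendering intent).

Euclidean distance in J'a'b' approximates perceived color difference;
:func:`delta` is that metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "ViewingConditions",
    "SRGB_AVERAGE",
    "srgb_to_ucs",
    "ucs_to_srgb",
    "clamp_gamut",
    "delta",
    "in_gamut",
]

# sRGB (linear) -> XYZ, D65 white, 2-degree observer; derived from the
# IEC 61966-2-1 primaries at full precision so that white maps exactly
# to the adapting white below.
M_XYZ_FROM_RGB = np.array(
    [
        [0.41239079926595934, 0.357584339383878, 0.1804807884018343],
        [0.21263900587151027, 0.715168678767756, 0.07219231536073371],
        [0.01933081871559182, 0.11919477979462598, 0.9505321522496607],
    ]
)
M_RGB_FROM_XYZ = np.linalg.inv(M_XYZ_FROM_RGB)

# CAT02 chromatic adaptation and Hunt-Pointer-Estevez cone matrices.
M_CAT02 = np.array(
    [
        [0.7328, 0.4296, -0.1624],
        [-0.7036, 1.6975, 0.0061],
        [0.0030, 0.0136, 0.9834],
    ]
)
M_HPE = np.array(
    [
        [0.38971, 0.68898, -0.07868],
        [-0.22981, 1.18340, 0.04641],
        [0.00000, 0.00000, 1.00000],
    ]
)
_M_HPE_FROM_CAT02 = M_HPE @ np.linalg.inv(M_CAT02)
_M_CAT02_FROM_HPE = np.linalg.inv(_M_HPE_FROM_CAT02)

# CAM02-UCS constants (Luo, Cui & Li 2006, the version for both large
# and small color differences).
_UCS_C1 = 0.007
_UCS_C2 = 0.0228

_SURROUNDS = {
    # surround: (F, c, N_c)
    "average": (1.0, 0.69, 1.0),
    "dim": (0.9, 0.59, 0.9),
    "dark": (0.8, 0.525, 0.8),
}

# D65 white of the sRGB matrix, on the 0-100 XYZ scale.
_D65_WHITE_100 = tuple(100.0 * M_XYZ_FROM_RGB.sum(axis=1))


@dataclass(frozen=True)
class ViewingConditions:
    """CIECAM02 viewing-condition parameters.

    Defaults are the standard-dynamic-range sRGB convention: D65
    adapting white, average surround, 20% background luminance factor,
    and an adapting luminance of 64/(5*pi) ~ 4.07 cd/m^2 (a 64 lux
    ambient on a 20% gray background).
    """

    whitepoint: tuple[float, float, float] = _D65_WHITE_100
    adapting_luminance: float = 64.0 / (5.0 * np.pi)
    background_luminance_factor: float = 20.0
    surround: str = "average"

    def __post_init__(self) -> None:
        if self.surround not in _SURROUNDS:
            raise ValueError(f"unknown surround {self.surround!r}")
        if not (self.adapting_luminance > 0):
            raise ValueError("adapting_luminance must be positive")
        if not (self.background_luminance_factor > 0):
            raise ValueError("background_luminance_factor must be positive")


SRGB_AVERAGE = ViewingConditions()


@dataclass(frozen=True)
class _DerivedVC:
    """Quantities of the appearance model that depend only on the VC."""

    D_RGB: np.ndarray
    F_L: float
    n: float
    z: float
    N_bb: float
    N_c: float
    c: float
    A_w: float

    @classmethod
    def from_vc(cls, vc: ViewingConditions) -> "_DerivedVC":
        F, c, N_c = _SURROUNDS[vc.surround]
        XYZ_w = np.asarray(vc.whitepoint, dtype=float)
        Y_w = XYZ_w[1]
        L_A = vc.adapting_luminance

        RGB_w = M_CAT02 @ XYZ_w
        D = F * (1.0 - (1.0 / 3.6) * np.exp((-L_A - 42.0) / 92.0))
        D = float(np.clip(D, 0.0, 1.0))
        D_RGB = D * Y_w / RGB_w + 1.0 - D

        k = 1.0 / (5.0 * L_A + 1.0)
        F_L = (
            0.2 * k**4 * (5.0 * L_A)
            + 0.1 * (1.0 - k**4) ** 2 * (5.0 * L_A) ** (1.0 / 3.0)
        )
        n = vc.background_luminance_factor / Y_w
        z = 1.48 + np.sqrt(n)
        N_bb = 0.725 * n**-0.2

        RGBp_w = _M_HPE_FROM_CAT02 @ (D_RGB * RGB_w)
        RGBp_aw = _adapt(RGBp_w, F_L)
        A_w = (2.0 * RGBp_aw[0] + RGBp_aw[1] + RGBp_aw[2] / 20.0 - 0.305) * N_bb
        return cls(D_RGB=D_RGB, F_L=F_L, n=n, z=z, N_bb=N_bb, N_c=N_c, c=c, A_w=A_w)


@lru_cache(maxsize=8)
def _derived(vc: ViewingConditions) -> _DerivedVC:
    return _DerivedVC.from_vc(vc)


def _adapt(x: np.ndarray, F_L: float) -> np.ndarray:
    # Post-adaptation cone response compression; odd extension for
    # negative cone signals as in the CIE formulation.
    t = (F_L * np.abs(x) / 100.0) ** 0.42
    return np.sign(x) * 400.0 * t / (27.13 + t) + 0.1


def _unadapt(xa: np.ndarray, F_L: float) -> np.ndarray:
    # Inverse of _adapt.  |xa - 0.1| >= 400 has no preimage; return NaN.
    s = xa - 0.1
    mag = np.abs(s)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = 27.13 * mag / (400.0 - mag)
        out = np.sign(s) * (100.0 / F_L) * t ** (1.0 / 0.42)
    return np.where(mag < 400.0, out, np.nan)


# ---------------------------------------------------------------------------
# sRGB transfer function (IEC 61966-2-1 piecewise curve)

def srgb_encode(linear: np.ndarray) -> np.ndarray:
    linear = np.asarray(linear, dtype=float)
    a = np.abs(linear)
    enc = np.where(a <= 0.0031308, 12.92 * a, 1.055 * a ** (1.0 / 2.4) - 0.055)
    return np.sign(linear) * enc


def srgb_decode(encoded: np.ndarray) -> np.ndarray:
    encoded = np.asarray(encoded, dtype=float)
    a = np.abs(encoded)
    lin = np.where(a <= 0.04045, a / 12.92, ((a + 0.055) / 1.055) ** 2.4)
    return np.sign(encoded) * lin


# ---------------------------------------------------------------------------
# CIECAM02 core (XYZ on the 0-100 scale)

def xyz_to_jmh(xyz: np.ndarray, vc: ViewingConditions) -> np.ndarray:
    """XYZ100 -> (J, M, h) with h in radians."""
    d = _derived(vc)
    xyz = np.asarray(xyz, dtype=float)
    rgb_c = (xyz @ M_CAT02.T) * d.D_RGB
    rgbp_a = _adapt(rgb_c @ _M_HPE_FROM_CAT02.T, d.F_L)
    Ra, Ga, Ba = rgbp_a[..., 0], rgbp_a[..., 1], rgbp_a[..., 2]

    a = Ra - 12.0 * Ga / 11.0 + Ba / 11.0
    b = (Ra + Ga - 2.0 * Ba) / 9.0
    h = np.arctan2(b, a)
    e_t = (np.cos(h + 2.0) + 3.8) / 4.0

    A = (2.0 * Ra + Ga + Ba / 20.0 - 0.305) * d.N_bb
    # A < 0 (possible for strongly out-of-gamut intermediates) has no
    # lightness; keep NaN rather than a complex power.
    with np.errstate(invalid="ignore"):
        J = 100.0 * np.where(A >= 0, A / d.A_w, np.nan) ** (d.c * d.z)
        t = (
            (50000.0 / 13.0)
            * d.N_c
            * d.N_bb
            * e_t
            * np.hypot(a, b)
            / (Ra + Ga + 21.0 / 20.0 * Ba)
        )
        C = t**0.9 * np.sqrt(J / 100.0) * (1.64 - 0.29**d.n) ** 0.73
    M = C * d.F_L**0.25
    return np.stack([J, M, h], axis=-1)


def jmh_to_xyz(jmh: np.ndarray, vc: ViewingConditions) -> np.ndarray:
    """(J, M, h) -> XYZ100; NaN rows where the inverse model is undefined."""
    d = _derived(vc)
    jmh = np.asarray(jmh, dtype=float)
    J, M, h = jmh[..., 0], jmh[..., 1], jmh[..., 2]

    with np.errstate(invalid="ignore", divide="ignore"):
        C = M / d.F_L**0.25
        J_ok = J > 0
        Jsafe = np.where(J_ok, J, np.nan)
        t = (C / (np.sqrt(Jsafe / 100.0) * (1.64 - 0.29**d.n) ** 0.73)) ** (
            1.0 / 0.9
        )
        e_t = (np.cos(h + 2.0) + 3.8) / 4.0
        A = d.A_w * (Jsafe / 100.0) ** (1.0 / (d.c * d.z))
        p2 = A / d.N_bb + 0.305

        p1 = (50000.0 / 13.0) * d.N_c * d.N_bb * e_t / t
        sin_h, cos_h = np.sin(h), np.cos(h)
        num = p2 * (2.0 + 21.0 / 20.0) * (460.0 / 1403.0)
        sin_dom = np.abs(sin_h) >= np.abs(cos_h)
        # branch on the dominant trig component for numerical stability
        with np.errstate(invalid="ignore", divide="ignore"):
            b_s = num / (
                p1 / sin_h
                + (2.0 + 21.0 / 20.0) * (220.0 / 1403.0) * (cos_h / sin_h)
                - 27.0 / 1403.0
                + (21.0 / 20.0) * (6300.0 / 1403.0)
            )
            a_s = b_s * cos_h / sin_h
            a_c = num / (
                p1 / cos_h
                + (2.0 + 21.0 / 20.0) * (220.0 / 1403.0)
                - (27.0 / 1403.0 - (21.0 / 20.0) * (6300.0 / 1403.0))
                * (sin_h / cos_h)
            )
            b_c = a_c * sin_h / cos_h
        a = np.where(sin_dom, a_s, a_c)
        b = np.where(sin_dom, b_s, b_c)
        zero_chroma = ~(t > 0)  # t == 0 or NaN from C == 0
        a = np.where(zero_chroma, 0.0, a)
        b = np.where(zero_chroma, 0.0, b)

        Ra = (460.0 * p2 + 451.0 * a + 288.0 * b) / 1403.0
        Ga = (460.0 * p2 - 891.0 * a - 261.0 * b) / 1403.0
        Ba = (460.0 * p2 - 220.0 * a - 6300.0 * b) / 1403.0
        rgbp = _unadapt(np.stack([Ra, Ga, Ba], axis=-1), d.F_L)
        rgb_c = rgbp @ _M_CAT02_FROM_HPE.T
        xyz = (rgb_c / d.D_RGB) @ np.linalg.inv(M_CAT02).T

    # J == 0 is exactly black only when it carries no chroma.
    black = (~J_ok) & (J >= -1e-12) & (np.abs(M) < 1e-9)
    xyz = np.where(black[..., None], 0.0, xyz)
    return xyz


# ---------------------------------------------------------------------------
# CAM02-UCS

def jmh_to_ucs(jmh: np.ndarray) -> np.ndarray:
    jmh = np.asarray(jmh, dtype=float)
    J, M, h = jmh[..., 0], jmh[..., 1], jmh[..., 2]
    jp = (1.0 + 100.0 * _UCS_C1) * J / (1.0 + _UCS_C1 * J)
    Mp = np.log1p(_UCS_C2 * M) / _UCS_C2
    return np.stack([jp, Mp * np.cos(h), Mp * np.sin(h)], axis=-1)


def ucs_to_jmh(jab: np.ndarray) -> np.ndarray:
    jab = np.asarray(jab, dtype=float)
    jp, ap, bp = jab[..., 0], jab[..., 1], jab[..., 2]
    J = jp / (1.0 + 100.0 * _UCS_C1 - _UCS_C1 * jp)
    Mp = np.hypot(ap, bp)
    M = np.expm1(_UCS_C2 * Mp) / _UCS_C2
    h = np.arctan2(bp, ap)
    return np.stack([J, M, h], axis=-1)


# ---------------------------------------------------------------------------
# public API

def srgb_to_ucs(rgb, vc: ViewingConditions = SRGB_AVERAGE) -> np.ndarray:
    """Encoded sRGB in [0,1] -> CAM02-UCS (J', a', b').

    Accepts a single triple or an (..., 3) array.  Input must be finite;
    the in-gamut precondition is the caller's contract (mildly
    out-of-range values are converted on the model's analytic extension).
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape[-1] != 3:
        raise ValueError("expected (..., 3) RGB input")
    if not np.all(np.isfinite(rgb)):
        raise ValueError("non-finite RGB input")
    xyz = 100.0 * (srgb_decode(rgb) @ M_XYZ_FROM_RGB.T)
    return jmh_to_ucs(xyz_to_jmh(xyz, vc))


def ucs_to_srgb(jab, vc: ViewingConditions = SRGB_AVERAGE) -> np.ndarray:
    """CAM02-UCS -> encoded sRGB, WITHOUT gamut clamping.

    Out-of-gamut points return channel values outside [0, 1]; points
    whose inverse appearance model is undefined return NaN.
    """
    jab = np.asarray(jab, dtype=float)
    if jab.shape[-1] != 3:
        raise ValueError("expected (..., 3) J'a'b' input")
    if not np.all(np.isfinite(jab)):
        raise ValueError("non-finite J'a'b' input")
    xyz = jmh_to_xyz(ucs_to_jmh(jab), vc)
    return srgb_encode((xyz / 100.0) @ M_RGB_FROM_XYZ.T)


def clamp_gamut(rgb) -> np.ndarray:
    """Absolute colorimetric gamut mapping: clip each channel to [0, 1]."""
    rgb = np.asarray(rgb, dtype=float)
    if not np.all(np.isfinite(rgb)):
        raise ValueError("non-finite RGB input")
    return np.clip(rgb, 0.0, 1.0)


def in_gamut(rgb, atol: float = 0.0) -> np.ndarray:
    """Per-color boolean: all channels within [0 - atol, 1 + atol]."""
    rgb = np.asarray(rgb, dtype=float)
    ok = np.isfinite(rgb) & (rgb >= -atol) & (rgb <= 1.0 + atol)
    return ok.all(axis=-1)


def delta(p, q) -> np.ndarray:
    """Euclidean color difference in CAM02-UCS (perceptual delta)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return np.linalg.norm(p - q, axis=-1)
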