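"""CVD-aware colormap optimization pipeline.

Stages, in order:

1. **lift** — simulate the input colormap as seen with the chosen
   deficiency and convert it to CAM02-UCS, giving a (J', a', b') path.
2. **equalize** — resample the path so consecutive points are
   equidistant along the (a', b') polyline: a' and b' are interpolated
   against the original parameterization at ``n_interp`` points, the
   total arc length is divided by ``n_out - 1``, and points are picked
   that distance apart.  Hues and the a'b' path are preserved; only the
   spacing changes.
3. **linearize** — replace J' by a straight line against entry index:
   its least-squares fit ("fit"); the endpoint-anchored line of
   maximal lightness range, which runs from the lowest displayable J'
   at the first entry to the highest at the last and may clamp at
   interior entries ("maxrange"); or the steepest line that stays
   inside the per-entry [J'min, J'max] displayable corridor
   everywhere, solved as an exact linear program ("steepest").
4. **finalize** — convert back to sRGB, clamp to the display gamut
   (absolute colorimetric intent), re-convert the clamped colors to UCS
   and report the per-entry clamp error so the departure from the
   intended path is quantified rather than hidden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from . import colorspace as cs
from .cmap_io import RGBColormap
from .cvd import CVDSpec, simulate

__all__ = [
    "UCSTrajectory",
    "JBounds",
    "OptimizationReport",
    "DegenerateTrajectoryError",
    "InfeasibleLinearizationError",
    "OptimizationError",
    "lift_to_ucs",
    "equalize_ab",
    "gamut_jbounds",
    "linearize_jp_fit",
    "linearize_jp_maxrange",
    "linearize_jp_steepest",
    "finalize",
    "optimize",
]

# Total a'b' arc length (UCS units) below which a path is treated as
# achromatic: under one just-noticeable difference across the whole
# map, equal spacing is meaningless and equalization is skipped.
ACHROMATIC_ARC_LENGTH = 1.0


class DegenerateTrajectoryError(ValueError):
    """The a'b' path has (near-)zero arc length; nothing to equalize."""


class InfeasibleLinearizationError(RuntimeError):
    """No straight J' line fits inside the gamut corridor."""

    def __init__(self, msg: str, tightest_index: int):
        super().__init__(msg)
        self.tightest_index = tightest_index


class OptimizationError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, msg: str):
        super().__init__(f"[{stage}] {msg}")
        self.stage = stage


@dataclass(frozen=True)
class UCSTrajectory:
    """An ordered (J', a', b') path with a provenance tag."""

    points: np.ndarray
    provenance: str = "raw"

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("trajectory must be an (N, 3) array")
        if len(pts) < 2:
            raise ValueError("trajectory needs at least 2 points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("non-finite trajectory coordinates")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def jp(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def ab(self) -> np.ndarray:
        return self.points[:, 1:]

    def adjacent_deltas(self) -> np.ndarray:
        return cs.delta(self.points[1:], self.points[:-1])


@dataclass(frozen=True)
class JBounds:
    """Per-entry displayable-lightness intervals for fixed (a', b').

    Empty intervals (no displayable J' at all) are stored as NaN pairs.
    """

    jp_min: np.ndarray
    jp_max: np.ndarray
    jp_step: float

    def __len__(self) -> int:
        return len(self.jp_min)

    @property
    def empty(self) -> np.ndarray:
        return ~np.isfinite(self.jp_min)


@dataclass(frozen=True)
class OptimizationReport:
    """Final colormap plus everything needed to audit the gamut clamp.

    ``clamp_error_pct`` is the per-entry relative error
    100 * ||intended - reconverted|| / ||intended|| in UCS coordinates;
    ``clamp_delta_e`` is the same difference as an absolute UCS
    distance (a percentage of the 0-100 J'a'b' scale for near-unit
    vectors).  Both are zero wherever the intended color was
    displayable.
    """

    final: RGBColormap
    pre_clamp_rgb: np.ndarray
    intended: UCSTrajectory
    reconverted: UCSTrajectory
    clamp_error_pct: np.ndarray
    mean_clamp_error_pct: float
    clamp_delta_e: np.ndarray
    method: str
    spec: CVDSpec | None

    @property
    def clamp_affected(self) -> np.ndarray:
        """Entries whose pre-clamp RGB fell outside [0, 1]."""
        return ~cs.in_gamut(self.pre_clamp_rgb, atol=1e-9)

    @property
    def affected_mean_delta_e(self) -> float:
        """Mean UCS distance intended->final over clamp-affected entries."""
        aff = self.clamp_affected
        return float(self.clamp_delta_e[aff].mean()) if aff.any() else 0.0

    @property
    def affected_mean_error_pct(self) -> float:
        """Mean relative clamp error over clamp-affected entries."""
        aff = self.clamp_affected
        return float(self.clamp_error_pct[aff].mean()) if aff.any() else 0.0

    @property
    def min_pre_clamp_channel(self) -> tuple[float, int]:
        """(value, entry index) of the smallest raw channel value."""
        flat = int(np.argmin(self.pre_clamp_rgb))
        return float(self.pre_clamp_rgb.flat[flat]), flat // 3


# ---------------------------------------------------------------------------

def lift_to_ucs(
    cmap: RGBColormap,
    spec: CVDSpec | None = None,
    vc: cs.ViewingConditions = cs.SRGB_AVERAGE,
) -> UCSTrajectory:
    """CVD-simulate a colormap (optionally) and lift it to CAM02-UCS."""
    rgb = cmap.colors
    provenance = "raw"
    if spec is not None:
        rgb = simulate(rgb, spec)
        provenance = "cvd-simulated"
    return UCSTrajectory(cs.srgb_to_ucs(rgb, vc), provenance=provenance)


def equalize_ab(
    trajectory: UCSTrajectory, n_out: int = 256, n_interp: int = 10000
) -> UCSTrajectory:
    """Resample so consecutive points are equidistant in the a'b' plane.

    The a' and b' arrays are piecewise-linearly interpolated at
    ``n_interp`` points, the polyline arc length is accumulated, and
    ``n_out`` points are selected at multiples of
    (total arc length) / (n_out - 1).  J' is carried along by
    interpolation at the same positions so the trajectory remains a
    single coherent path.  Endpoints are preserved exactly.
    """
    if n_out < 2 or n_interp < len(trajectory):
        raise ValueError("need n_out >= 2 and n_interp >= input length")
    t_in = np.linspace(0.0, 1.0, len(trajectory))
    t_fine = np.linspace(0.0, 1.0, n_interp)
    jp_f = np.interp(t_fine, t_in, trajectory.jp)
    a_f = np.interp(t_fine, t_in, trajectory.points[:, 1])
    b_f = np.interp(t_fine, t_in, trajectory.points[:, 2])

    seg = np.hypot(np.diff(a_f), np.diff(b_f))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total < ACHROMATIC_ARC_LENGTH:
        raise DegenerateTrajectoryError(
            f"a'b' arc length {total:.3g} below achromatic threshold "
            f"{ACHROMATIC_ARC_LENGTH}"
        )
    targets = np.linspace(0.0, total, n_out)
    # position along the fine parameterization at each target arc length;
    # linear interpolation inside the crossing segment (no snapping)
    t_sel = np.interp(targets, cum, t_fine)
    out = np.stack(
        [
            np.interp(t_sel, t_fine, jp_f),
            np.interp(t_sel, t_fine, a_f),
            np.interp(t_sel, t_fine, b_f),
        ],
        axis=1,
    )
    # endpoints must coincide with the input's exactly
    out[0, 1:] = trajectory.points[0, 1:]
    out[-1, 1:] = trajectory.points[-1, 1:]
    return UCSTrajectory(out, provenance="equalized")


def _resample_plain(trajectory: UCSTrajectory, n_out: int) -> UCSTrajectory:
    """Index-linear resampling (used when equalization is degenerate)."""
    t_in = np.linspace(0.0, 1.0, len(trajectory))
    t_out = np.linspace(0.0, 1.0, n_out)
    out = np.stack(
        [np.interp(t_out, t_in, trajectory.points[:, k]) for k in range(3)],
        axis=1,
    )
    return UCSTrajectory(out, provenance="equalized")


def gamut_jbounds(
    trajectory: UCSTrajectory,
    vc: cs.ViewingConditions = cs.SRGB_AVERAGE,
    jp_step: float = 0.1,
) -> JBounds:
    """Displayable J' interval for each (a', b') of the trajectory.

    Scans J' over [0, 100] at ``jp_step`` resolution and keeps, per
    entry, the extreme values whose (J', a', b') maps into [0, 1]^3
    (tolerance 1e-6 per channel).  Entries with no displayable J' get
    an empty (NaN) interval.
    """
    ab = trajectory.ab
    jps = np.arange(0.0, 100.0 + jp_step / 2, jp_step)
    # grid: (n_jp, n_entries, 3)
    jab = np.empty((len(jps), len(ab), 3))
    jab[:, :, 0] = jps[:, None]
    jab[:, :, 1:] = ab[None, :, :]
    rgb = cs.ucs_to_srgb(jab.reshape(-1, 3), vc).reshape(len(jps), len(ab), 3)
    ok = cs.in_gamut(rgb, atol=1e-6)
    any_ok = ok.any(axis=0)
    first = np.argmax(ok, axis=0)
    last = len(jps) - 1 - np.argmax(ok[::-1], axis=0)
    jp_min = np.where(any_ok, jps[first], np.nan)
    jp_max = np.where(any_ok, jps[last], np.nan)
    return JBounds(jp_min=jp_min, jp_max=jp_max, jp_step=jp_step)


def linearize_jp_fit(trajectory: UCSTrajectory) -> UCSTrajectory:
    """Replace J' by its least-squares line against entry index."""
    idx = np.arange(len(trajectory), dtype=float)
    slope, intercept = np.polyfit(idx, trajectory.jp, 1)
    out = trajectory.points.copy()
    out[:, 0] = slope * idx + intercept
    return UCSTrajectory(out, provenance="linearized")


def linearize_jp_maxrange(
    trajectory: UCSTrajectory, bounds: JBounds
) -> UCSTrajectory:
    """Replace J' by the straight line of maximal lightness range.

    For an increasing map the line runs from the *lowest* displayable
    J' at the first entry to the *highest* displayable J' at the last
    entry (mirrored for decreasing maps), putting the ends of the
    colormap as far apart in lightness as the display gamut allows.
    The line may dip outside the displayable corridor at interior
    entries; those entries are clamped at finalization and show up in
    the clamp-error report.  Use :func:`linearize_jp_steepest` for the
    conservative variant that never leaves the corridor.
    """
    if len(bounds) != len(trajectory):
        raise ValueError("bounds length must match trajectory length")
    if bounds.empty.any():
        idx_bad = int(np.argmax(bounds.empty))
        raise InfeasibleLinearizationError(
            f"no displayable J' at entry {idx_bad}", idx_bad
        )
    n = len(trajectory)
    idx = np.arange(n, dtype=float)
    increasing = trajectory.jp[-1] >= trajectory.jp[0]
    if increasing:
        lo, hi = bounds.jp_min[0], bounds.jp_max[-1]
        if hi <= lo:
            raise InfeasibleLinearizationError(
                "no increasing line spans the corridor endpoints",
                int(np.argmin(bounds.jp_max - bounds.jp_min)),
            )
        line = lo + (hi - lo) * idx / (n - 1)
    else:
        hi, lo = bounds.jp_max[0], bounds.jp_min[-1]
        if hi <= lo:
            raise InfeasibleLinearizationError(
                "no decreasing line spans the corridor endpoints",
                int(np.argmin(bounds.jp_max - bounds.jp_min)),
            )
        line = hi + (lo - hi) * idx / (n - 1)
    out = trajectory.points.copy()
    out[:, 0] = line
    return UCSTrajectory(out, provenance="linearized")


def linearize_jp_steepest(
    trajectory: UCSTrajectory, bounds: JBounds
) -> UCSTrajectory:
    """Replace J' by the steepest straight line inside the gamut corridor.

    Solves  max |s|  s.t.  jp_min[i] <= s*i + c <= jp_max[i]  exactly as
    a linear program, taking the slope-sign branch that matches the
    input's net J' direction; among equally steep lines the one with
    the largest uniform margin to the corridor walls is returned.
    Unlike :func:`linearize_jp_maxrange` the result is displayable at
    every entry, so the final colormap needs no clamping.
    """
    if len(bounds) != len(trajectory):
        raise ValueError("bounds length must match trajectory length")
    if bounds.empty.any():
        idx_bad = int(np.argmax(bounds.empty))
        raise InfeasibleLinearizationError(
            f"no displayable J' at entry {idx_bad}", idx_bad
        )
    n = len(trajectory)
    idx = np.arange(n, dtype=float)
    increasing = trajectory.jp[-1] >= trajectory.jp[0]

    # variables x = (s, c)
    a_ub = np.vstack(
        [np.stack([idx, np.ones(n)], axis=1),
         np.stack([-idx, -np.ones(n)], axis=1)]
    )
    b_ub = np.concatenate([bounds.jp_max, -bounds.jp_min])
    sign = 1.0 if increasing else -1.0
    res = linprog(
        c=[-sign, 0.0],
        A_ub=a_ub,
        b_ub=b_ub,
        bounds=[(0.0, None) if increasing else (None, 0.0), (None, None)],
        method="highs",
    )
    if not res.success:
        tightest = int(np.argmin(bounds.jp_max - bounds.jp_min))
        raise InfeasibleLinearizationError(
            f"no {'increasing' if increasing else 'decreasing'} line fits the "
            f"gamut corridor (tightest at entry {tightest})",
            tightest,
        )
    s_opt = res.x[0]
    # tie-break: fix the slope, center the line by maximizing the margin
    a_ub2 = np.vstack(
        [np.stack([np.ones(n), np.ones(n)], axis=1),
         np.stack([-np.ones(n), np.ones(n)], axis=1)]
    )
    b_ub2 = np.concatenate([bounds.jp_max - s_opt * idx, s_opt * idx - bounds.jp_min])
    res2 = linprog(
        c=[0.0, -1.0],
        A_ub=a_ub2,
        b_ub=b_ub2,
        bounds=[(None, None), (0.0, None)],
        method="highs",
    )
    c_opt = res2.x[0] if res2.success else res.x[1]
    out = trajectory.points.copy()
    out[:, 0] = s_opt * idx + c_opt
    return UCSTrajectory(out, provenance="linearized")


def finalize(
    trajectory: UCSTrajectory,
    vc: cs.ViewingConditions = cs.SRGB_AVERAGE,
    name: str = "optimized",
    method: str = "",
    spec: CVDSpec | None = None,
) -> OptimizationReport:
    """Convert to sRGB, clamp, re-convert, and report clamp errors.

    The per-entry clamp error is 100 * ||intended - reconverted|| /
    ||intended|| in UCS coordinates; it is zero wherever the intended
    color was displayable.
    """
    pre_clamp = cs.ucs_to_srgb(trajectory.points, vc)
    if not np.all(np.isfinite(pre_clamp)):
        bad = int(np.argmax(~np.isfinite(pre_clamp).all(axis=1)))
        raise OptimizationError(
            "finalize", f"inverse appearance model undefined at entry {bad}"
        )
    final_rgb = cs.clamp_gamut(pre_clamp)
    recon = cs.srgb_to_ucs(final_rgb, vc)
    diff = cs.delta(trajectory.points, recon)
    norm = np.linalg.norm(trajectory.points, axis=1)
    err = 100.0 * diff / np.where(norm > 0, norm, np.inf)
    return OptimizationReport(
        final=RGBColormap(final_rgb, name=name),
        pre_clamp_rgb=pre_clamp,
        intended=UCSTrajectory(trajectory.points, provenance="linearized"),
        reconverted=UCSTrajectory(recon.copy(), provenance="final-reconverted"),
        clamp_error_pct=err,
        mean_clamp_error_pct=float(err.mean()),
        clamp_delta_e=diff,
        method=method,
        spec=spec,
    )


def optimize(
    cmap: RGBColormap,
    spec: CVDSpec | None = CVDSpec("deuteranomaly", 100.0),
    method: str = "maxrange",
    vc: cs.ViewingConditions = cs.SRGB_AVERAGE,
    n_out: int = 256,
    n_interp: int = 10000,
    jp_step: float = 0.1,
) -> OptimizationReport:
    """Run the full pipeline; deterministic for fixed inputs.

    ``method`` is "fit" (follow the original J' trend), "maxrange"
    (endpoint-anchored maximal lightness range; interior entries may
    clamp), or "steepest" (steepest line that stays displayable at
    every entry).  If a gamut-bounded method cannot fit a straight
    line it falls back to "fit" (recorded in the report's ``method``
    field).
    """
    if method not in ("fit", "maxrange", "steepest"):
        raise ValueError("method must be 'fit', 'maxrange' or 'steepest'")
    traj = lift_to_ucs(cmap, spec, vc)
    try:
        traj = equalize_ab(traj, n_out=n_out, n_interp=n_interp)
    except DegenerateTrajectoryError:
        traj = _resample_plain(traj, n_out)

    used = method
    if method in ("maxrange", "steepest"):
        linearizer = (
            linearize_jp_maxrange if method == "maxrange" else linearize_jp_steepest
        )
        try:
            bounds = gamut_jbounds(traj, vc, jp_step=jp_step)
            traj = linearizer(traj, bounds)
        except InfeasibleLinearizationError:
            traj = linearize_jp_fit(traj)
            used = f"{method}->fit-fallback"
    else:
        traj = linearize_jp_fit(traj)

    return finalize(
        traj, vc, name=f"{cmap.name}-optimized", method=used, spec=spec
    )
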