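"""Synthetic strip imaging: frame rendering, meniscus tracking, velocities.

This module stands in for the camera + manual image analysis stage of the
bench workflow.  Trajectories are rendered into grayscale time-lapse
frames (liquid columns dark on a light background, meniscus edge
anti-aliased by partial-pixel coverage), and heights are re-detected per
frame by scanning each registered capillary column upward from the
reservoir baseline for the sub-pixel crossing of the midpoint between the
calibrated wet and dry intensity levels.  Instantaneous velocity is then
estimated from pairs of height samples, with the pair spacing widened at
later times where the meniscus moves slowly and timing noise would
otherwise dominate.

Coordinate convention: pixel row 0 is the image top; heights are physical
millimetres above the registered reservoir baseline row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    DomainError,
    InsufficientDataError,
    RenderError,
)
from .flow_simulator import RiseTrajectory, StripLayout

__all__ = [
    "FrameStack",
    "VelocitySeries",
    "DEFAULT_OPTICS",
    "render_frames",
    "track_meniscus",
    "estimate_velocity",
]

#: Rendering defaults; the physical pixel scale of the bench camera is not
#: fixed by the hardware description, so it is fully configurable.
DEFAULT_OPTICS: dict = {
    "scale_mm_per_px": 0.1,
    "capillary_width_px": 5,
    "gap_px": 3,
    "strip_gap_px": 12,
    "margin_px": 6,
    "baseline_offset_px": 10,  # rows between image bottom and reservoir baseline
    "background_level": 230,
    "liquid_level": 60,
    "noise_sigma": 0.0,  # additive Gaussian pixel noise, intensity levels
    "headroom_px": 8,  # rows kept clear above the highest rise
    "image_height_px": None,  # None -> sized from the trajectories
    "seed": 0,
}


@dataclass
class FrameStack:
    """Grayscale time-lapse frames plus the registration needed to read them."""

    frames: np.ndarray  # (n_frames, rows, cols) uint8
    timestamps: np.ndarray  # s, strictly increasing
    scale: float  # mm per pixel
    columns: dict[tuple[int, int], tuple[int, int]]  # (strip, cap) -> [c0, c1)
    baseline_row: int

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3 or self.frames.dtype != np.uint8:
            raise ConfigurationError("frames must be a (n, rows, cols) uint8 array")
        if len(self.timestamps) != len(self.frames):
            raise ConfigurationError("one timestamp per frame required")
        if self.timestamps.size > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise DomainError("timestamps must be strictly increasing")
        if not self.scale > 0:
            raise ConfigurationError("pixel scale must be positive")


@dataclass
class VelocitySeries:
    """Finite-difference velocity estimates paired with reciprocal heights."""

    times: np.ndarray  # s, midpoints of the sample pairs
    velocities: np.ndarray  # m/s, clamped >= 0
    reciprocal_heights: np.ndarray  # 1/m at the midpoint height
    heights: np.ndarray  # m, midpoint heights
    clamped: np.ndarray  # bool, True where a negative difference was clamped
    signed_velocities: np.ndarray | None = None  # m/s, raw differences (fitting)
    strip_id: int = 0
    capillary_id: int = 0


def render_frames(
    trajectories: Sequence[RiseTrajectory],
    layout: StripLayout,
    optics: Mapping | None = None,
) -> FrameStack:
    """Render trajectories into a synthetic grayscale frame stack.

    Every trajectory must share one time grid (they come from one imaging
    run).  Each capillary occupies a fixed pixel-column range; rows from
    the reservoir baseline up to H(t)/scale are set to the liquid level,
    with the top partial pixel linearly blended for sub-pixel meniscus
    position.  Optional additive Gaussian pixel noise is seeded.
    """
    opt = {**DEFAULT_OPTICS, **(optics or {})}
    if not trajectories:
        raise ConfigurationError("no trajectories to render")
    times = trajectories[0].times
    for tr in trajectories[1:]:
        if tr.times.shape != times.shape or not np.allclose(tr.times, times):
            raise ConfigurationError("all trajectories must share one time grid")
    want = {(s, c) for s in range(layout.n_strips)
            for c in range(layout.capillaries_per_strip)}
    have = {(tr.strip_id, tr.capillary_id) for tr in trajectories}
    if want - have:
        raise ConfigurationError(f"trajectories missing for capillaries {sorted(want - have)[:5]}")

    scale = float(opt["scale_mm_per_px"])
    w_cap, gap, sgap, margin = (int(opt[k]) for k in
                                ("capillary_width_px", "gap_px", "strip_gap_px", "margin_px"))
    columns: dict[tuple[int, int], tuple[int, int]] = {}
    col = margin
    for s in range(layout.n_strips):
        for c in range(layout.capillaries_per_strip):
            columns[(s, c)] = (col, col + w_cap)
            col += w_cap + gap
        col += sgap - gap
    width = col - sgap + gap + margin

    max_h_px = max(float(np.max(tr.heights)) for tr in trajectories) * 1e3 / scale
    base_off = int(opt["baseline_offset_px"])
    if opt["image_height_px"] is None:
        rows = int(math.ceil(max_h_px)) + base_off + int(opt["headroom_px"]) + 1
    else:
        rows = int(opt["image_height_px"])
    baseline_row = rows - 1 - base_off

    bg = float(opt["background_level"])
    liq = float(opt["liquid_level"])
    rng = np.random.default_rng(opt["seed"])
    n_frames = len(times)
    frames = np.empty((n_frames, rows, width), dtype=np.uint8)

    # per-row coverage template: pixel j above the baseline spans [j, j+1) px
    j_grid = np.arange(baseline_row + 1, dtype=float)
    traj_map = {(tr.strip_id, tr.capillary_id): tr for tr in trajectories}
    for k in range(n_frames):
        img = np.full((rows, width), bg)
        img[baseline_row + 1:, :] = liq  # submerged reservoir below the baseline
        for (s, c), (c0, c1) in columns.items():
            h_px = traj_map[(s, c)].heights[k] * 1e3 / scale
            if h_px > baseline_row + 0.5:
                raise RenderError(
                    f"strip {s} capillary {c}: height {h_px:.1f} px exceeds the "
                    f"image extent ({baseline_row} px above baseline)"
                )
            if h_px <= 0:
                continue
            frac = np.clip(h_px - j_grid, 0.0, 1.0)
            column_rows = baseline_row - np.arange(baseline_row + 1)
            img[column_rows, c0:c1] = (bg + (liq - bg) * frac)[:, None]
        if opt["noise_sigma"] > 0:
            img = img + rng.normal(0.0, opt["noise_sigma"], size=img.shape)
        frames[k] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    return FrameStack(frames=frames, timestamps=np.asarray(times, float),
                      scale=scale, columns=dict(columns), baseline_row=baseline_row)


#: Minimum wet/dry contrast (intensity levels) to declare a column wetted.
MIN_CONTRAST = 40.0


def _profile_height_px(profile: np.ndarray) -> float | None:
    """Sub-pixel meniscus position from a baseline-up intensity profile.

    ``profile[j]`` is the mean intensity of pixel row j above the
    baseline.  Returns the meniscus position in pixels above the baseline,
    or None if the column shows no wet/dry transition.  The wet and dry
    levels are calibrated from the profile itself, which makes the
    detection invariant to global intensity offsets.  The meniscus is
    located at the crossing of the wet/dry midpoint level, then its
    sub-pixel position is read from the anti-aliased coverage of the two
    bracketing pixels (linear in the meniscus position by construction of
    a partial-pixel edge).
    """
    n = profile.size
    if n < 8:
        return None
    # the renderer keeps a dry headroom at the image top; calibrate the dry
    # level there so a nearly full column cannot contaminate it
    dry = float(np.median(profile[-5:]))
    wet = float(np.median(profile[:3]))
    if dry - wet < MIN_CONTRAST:
        return None
    mid = 0.5 * (wet + dry)
    above = profile >= mid
    idx = np.nonzero(above)[0]
    j = int(idx[0])

    def coverage(jp: int) -> float:
        # fractional liquid coverage of pixel jp from its intensity; the
        # anti-aliased meniscus pixel encodes the sub-pixel position linearly
        return float(np.clip((dry - profile[jp]) / (dry - wet), 0.0, 1.0))

    if j == 0:
        return coverage(0)  # meniscus inside the first pixel above baseline
    # pixels below j-1 are fully wet; the meniscus lies in pixel j-1 or j
    return (j - 1) + coverage(j - 1) + coverage(j)


def track_meniscus(stack: FrameStack) -> list[RiseTrajectory]:
    """Recover per-capillary height–time series from a frame stack.

    For each registered capillary and frame the column-mean intensity
    profile is scanned upward from the reservoir baseline; the meniscus is
    the sub-pixel crossing of the midpoint between the calibrated wet and
    dry levels.  A capillary with no detectable wet/dry transition reports
    height 0 (not yet wetted); once wetted, a frame with no crossing
    carries the previous height forward.
    """
    if not stack.columns:
        raise ConfigurationError("frame stack has no registered capillary columns")
    out = []
    row_order = stack.baseline_row - np.arange(stack.baseline_row + 1)
    for (s, c), (c0, c1) in sorted(stack.columns.items()):
        heights = np.zeros(len(stack.frames))
        quality = np.zeros(len(stack.frames), dtype=int)
        wetted = False
        last = 0.0
        for k, frame in enumerate(stack.frames):
            profile = frame[row_order, c0:c1].mean(axis=1)
            h_px = _profile_height_px(profile)
            if h_px is None:
                heights[k] = last if wetted else 0.0
                quality[k] = 2 if wetted else 1
            else:
                wetted = True
                last = h_px * stack.scale * 1e-3
                heights[k] = last
        out.append(
            RiseTrajectory(times=stack.timestamps.copy(), heights=heights,
                           strip_id=s, capillary_id=c, quality=quality)
        )
    return out


#: Default adaptive pair-spacing parameters for velocity estimation.
DEFAULT_SCHEME: dict = {
    "mode": "adaptive",
    "fast_window_s": 3.0,  # consecutive frames while the meniscus is fast
    "max_spacing_s": 2.0,  # spacing reached by t approx 30 s
    "reference_time_s": 30.0,
    "spacing": 1,  # frames, for mode="fixed"
}


def _pair_spacing(t: float, frame_dt: float, scheme: Mapping) -> int:
    if scheme["mode"] == "fixed":
        return max(1, int(scheme["spacing"]))
    t_fast = scheme["fast_window_s"]
    if t < t_fast:
        return 1
    p = math.log(scheme["max_spacing_s"] / frame_dt) / math.log(
        scheme["reference_time_s"] / t_fast
    )
    target = min(scheme["max_spacing_s"], frame_dt * (t / t_fast) ** p)
    return max(1, int(round(target / frame_dt)))


def estimate_velocity(
    traj: RiseTrajectory, scheme: Mapping | None = None
) -> VelocitySeries:
    """Instantaneous velocity from pairs of height samples.

    u_i = (H(t_i+k) - H(t_i)) / (t_i+k - t_i), assigned to the pair's time
    midpoint with the reciprocal height evaluated at the midpoint height.
    The spacing k grows with time (consecutive frames early, up to ~2 s by
    30 s) so that at late times, where the meniscus creeps, timing noise
    does not swamp the signal.  Negative differences (measurement noise)
    are clamped to zero and flagged in ``velocities``; the raw signed
    differences are kept in ``signed_velocities`` so that downstream
    least-squares fits can use them without the rectification bias the
    clamp would introduce near equilibrium.
    """
    sch = {**DEFAULT_SCHEME, **(scheme or {})}
    t, h = traj.times, traj.heights
    if t.size < 2:
        raise InsufficientDataError("need at least two samples to difference")
    if np.any(np.diff(t) <= 0):
        raise DomainError("timestamps must be strictly increasing")
    frame_dt = float(np.median(np.diff(t)))
    times, u, raw, inv_h, h_mid, clamped = [], [], [], [], [], []
    i = 0
    n = t.size
    while i < n - 1:
        k = _pair_spacing(float(t[i]), frame_dt, sch)
        if i + k > n - 1:
            break  # no truncated tail pair: a shortened spacing would
            # amplify height noise exactly where the meniscus creeps
        du = (h[i + k] - h[i]) / (t[i + k] - t[i])
        hm = 0.5 * (h[i] + h[i + k])
        times.append(0.5 * (t[i] + t[i + k]))
        clamped.append(du < 0)
        u.append(max(du, 0.0))
        raw.append(du)
        h_mid.append(hm)
        inv_h.append(1.0 / hm if hm > 0 else np.inf)
        i += k
    return VelocitySeries(
        times=np.asarray(times),
        velocities=np.asarray(u),
        reciprocal_heights=np.asarray(inv_h),
        heights=np.asarray(h_mid),
        clamped=np.asarray(clamped, dtype=bool),
        signed_velocities=np.asarray(raw),
        strip_id=traj.strip_id,
        capillary_id=traj.capillary_id,
    )
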