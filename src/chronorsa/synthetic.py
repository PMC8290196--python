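"""Seeded generator of growing root systems and rendered image sequences.

Emulates near-infrared plate imagery of a seedling: one main root (MR)
growing downward from the seed, lateral roots (LRs) emerging from it over
time, sensor noise, per-frame illumination (gamma) jitter and transient
water-droplet occlusions.  Every frame comes with exact ground-truth
polylines and lengths, so segmentation, graph reconstruction and trait
extraction can all be validated against known truth.

Conventions: image coordinates are (row, col), 0-based, origin at the
top-left; the seed sits at the top and the MR grows toward larger rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from skimage.draw import disk as _disk
from skimage.draw import line as _line
from skimage.morphology import dilation, footprint_rectangle

__all__ = [
    "RootSystemSpec",
    "GroundTruthFrame",
    "GroundTruthSystem",
    "simulate_root_system",
    "render_mask",
    "render_image",
    "simulate_growth_signal",
    "write_sequence",
]


@dataclass
class RootSystemSpec:
    """Parameters of a simulated root system and its imaging conditions.

    ``mr_speed`` may be a constant (mm/h) or a function of time in hours;
    sinusoidal speed profiles model circadian (24 h) and ultradian (12 h)
    growth-rate oscillations.
    """

    seed_position: tuple[float, float] = (10.0, 150.0)
    mr_speed: float | Callable[[float], float] = 0.35
    lr_emergence_times: Sequence[float] = ()
    lr_angles: Sequence[float] = ()  # degrees from vertical; sign = side
    lr_speeds: Sequence[float] = ()
    # LRs emerge in the mature zone, a fixed arc distance above the MR
    # tip's position at emergence time, already lr_initial_length_mm long
    # (emergence = the primordium becoming visible at image scale)
    lr_attach_offset_mm: float = 1.0
    lr_initial_length_mm: float = 0.6
    duration_h: float = 96.0
    frame_interval_h: float = 0.25
    image_size: tuple[int, int] = (300, 300)
    mm_per_px: float = 0.04
    stroke_px: int = 3
    root_level: int = 180
    background_level: int = 50
    noise_sigma: float = 6.0
    gamma_range: tuple[float, float] = (0.9, 1.1)
    # droplets: explicit (frame_index, (row, col), radius_px) occluders,
    # or a count to place randomly on the root in isolated frames
    droplets: Sequence[tuple[int, tuple[float, float], float]] = ()
    droplet_count: int = 0
    droplet_radius_px: float = 6.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval_h <= 0:
            raise ValueError("frame_interval_h must be > 0")
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be > 0")
        n = len(self.lr_emergence_times)
        if len(self.lr_angles) != n or len(self.lr_speeds) != n:
            raise ValueError("lr_emergence_times, lr_angles and lr_speeds "
                             "must have equal lengths")
        if any(t >= self.duration_h for t in self.lr_emergence_times):
            raise ValueError("LR emergence times must lie within duration_h")

    def speed_at(self, t: float) -> float:
        return self.mr_speed(t) if callable(self.mr_speed) else float(self.mr_speed)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_h / self.frame_interval_h)) + 1

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_h


@dataclass
class GroundTruthFrame:
    """Exact root state at one time point."""

    time_h: float
    mr_polyline: np.ndarray  # (n, 2) float (row, col) pixel coordinates
    lr_polylines: list[np.ndarray]
    mr_length_mm: float
    lr_lengths_mm: list[float]

    @property
    def lr_count(self) -> int:
        return sum(1 for v in self.lr_lengths_mm if v > 0)

    @property
    def tr_length_mm(self) -> float:
        return self.mr_length_mm + float(sum(self.lr_lengths_mm))


@dataclass
class GroundTruthSystem:
    """Per-frame ground truth for a whole simulated sequence."""

    spec: RootSystemSpec
    frames: list[GroundTruthFrame] = field(default_factory=list)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time_h for f in self.frames])

    @property
    def mr_lengths_mm(self) -> np.ndarray:
        return np.array([f.mr_length_mm for f in self.frames])

    @property
    def lr_total_lengths_mm(self) -> np.ndarray:
        return np.array([sum(f.lr_lengths_mm) for f in self.frames])

    @property
    def lr_counts(self) -> np.ndarray:
        return np.array([f.lr_count for f in self.frames])


def _polyline_px(start: np.ndarray, direction: np.ndarray,
                 length_px: float, step_px: float = 1.0) -> np.ndarray:
    """Straight polyline from ``start`` along unit ``direction``."""
    if length_px <= 0:
        return start[None, :].copy()
    n = max(int(np.ceil(length_px / step_px)), 1)
    s = np.linspace(0.0, length_px, n + 1)
    return start[None, :] + s[:, None] * direction[None, :]


def simulate_root_system(spec: RootSystemSpec) -> GroundTruthSystem:
    """Grow a root system frame by frame.

    The MR grows straight downward from the seed; its length at time t is
    the integral of the speed profile.  Each LR appears at its emergence
    time at the point the MR tip has then reached, and grows as a straight
    segment at its angle from vertical.  Output is fully determined by the
    spec (the rng seed only affects rendering noise, not geometry).
    """
    times = spec.times
    speeds = np.array([spec.speed_at(t) for t in times])
    if np.any(speeds < 0):
        raise ValueError("mr_speed must be non-negative at all sampled times")
    # cumulative trapezoid integral of speed -> MR length in mm
    mr_len = np.concatenate(
        ([0.0], np.cumsum(0.5 * (speeds[1:] + speeds[:-1]) * np.diff(times))))

    seed = np.asarray(spec.seed_position, dtype=float)
    down = np.array([1.0, 0.0])
    h, w = spec.image_size

    # precompute LR attach points (MR tip position at emergence time)
    attach: list[np.ndarray] = []
    dirs: list[np.ndarray] = []
    for te, ang in zip(spec.lr_emergence_times, spec.lr_angles):
        l_at = max(0.0, float(np.interp(te, times, mr_len))
                   - spec.lr_attach_offset_mm) / spec.mm_per_px
        p = seed + l_at * down
        if not (0 <= p[0] < h and 0 <= p[1] < w):
            raise ValueError(
                f"LR emergence at t={te} h lies outside the plate bounds")
        attach.append(p)
        a = np.deg2rad(ang)
        dirs.append(np.array([np.cos(a), np.sin(a)]))

    system = GroundTruthSystem(spec=spec)
    for i, t in enumerate(times):
        mr_poly = _polyline_px(seed, down, mr_len[i] / spec.mm_per_px)
        lr_polys: list[np.ndarray] = []
        lr_lengths: list[float] = []
        for (te, v), p, d in zip(
                zip(spec.lr_emergence_times, spec.lr_speeds), attach, dirs):
            if t >= te:
                lmm = spec.lr_initial_length_mm + (t - te) * v
                lr_polys.append(_polyline_px(p, d, lmm / spec.mm_per_px))
            else:
                lmm = 0.0
            lr_lengths.append(lmm)
        system.frames.append(GroundTruthFrame(
            time_h=float(t), mr_polyline=mr_poly, lr_polylines=lr_polys,
            mr_length_mm=float(mr_len[i]), lr_lengths_mm=lr_lengths))
    return system


def _rasterize(polylines: Sequence[np.ndarray], shape: tuple[int, int],
               stroke_px: int) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    h, w = shape
    for poly in polylines:
        pts = np.clip(np.rint(np.asarray(poly)), 0,
                      [h - 1, w - 1]).astype(int)
        if len(pts) == 1:
            mask[pts[0, 0], pts[0, 1]] = True
            continue
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            rr, cc = _line(r0, c0, r1, c1)
            mask[rr, cc] = True
    if stroke_px > 1:
        mask = dilation(mask, footprint_rectangle((stroke_px, stroke_px)))
    return mask


def render_mask(gt_frame: GroundTruthFrame, spec: RootSystemSpec) -> np.ndarray:
    """Rasterize the frame's polylines into a binary mask.

    Each polyline is drawn as an 8-connected 1-px line and thickened to the
    spec's stroke width; an empty frame yields an all-background mask.
    """
    polys = [gt_frame.mr_polyline] + list(gt_frame.lr_polylines)
    polys = [p for p in polys if len(p) > 1]
    return _rasterize(polys, spec.image_size, spec.stroke_px)


def _frame_rng(spec: RootSystemSpec, frame_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([spec.rng_seed, frame_index]))


def _droplet_schedule(spec: RootSystemSpec,
                      system: GroundTruthSystem | None = None):
    """Explicit droplets, plus randomly placed ones on the root in
    isolated frames (never in adjacent frames, so occlusions are
    transient by construction)."""
    sched = list(spec.droplets)
    if spec.droplet_count and system is not None:
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.rng_seed, 0xD20]))
        n_frames = len(system.frames)
        candidates = [i for i in range(2, n_frames - 1, 2)
                      if len(system.frames[i].mr_polyline) > 5]
        rng.shuffle(candidates)
        for i in candidates[:spec.droplet_count]:
            poly = system.frames[i].mr_polyline
            pt = poly[rng.integers(1, len(poly))]
            sched.append((i, (float(pt[0]), float(pt[1])),
                          spec.droplet_radius_px))
    return sched


def render_image(mask: np.ndarray, spec: RootSystemSpec, frame_index: int,
                 droplets: Sequence[tuple[int, tuple[float, float], float]]
                 | None = None) -> np.ndarray:
    """Render a grayscale uint8 frame from a binary mask.

    Root pixels are brighter than the background; additive Gaussian noise
    and a per-frame random gamma emulate the sensor; droplet occluders
    erase root pixels (back to background level) in their own frame only.
    """
    rng = _frame_rng(spec, frame_index)
    img = np.full(mask.shape, float(spec.background_level))
    img[mask] = float(spec.root_level)
    if droplets is None:
        droplets = spec.droplets
    for fi, center, radius in droplets:
        if fi == frame_index:
            rr, cc = _disk(center, radius, shape=mask.shape)
            img[rr, cc] = float(spec.background_level)
    lo, hi = spec.gamma_range
    gamma = rng.uniform(lo, hi)
    img = 255.0 * (img / 255.0) ** gamma
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def simulate_growth_signal(amp24: float, amp12: float, trend: float,
                           noise_sd: float, duration_h: float,
                           interval_h: float = 0.25,
                           rng_seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Growth-speed series with circadian/ultradian components.

    speed(t) = trend + amp24*sin(2*pi*t/24) + amp12*sin(2*pi*t/12) + noise.
    Returns (times_h, speed_mm_per_h).
    """
    t = np.arange(0.0, duration_h + 0.5 * interval_h, interval_h)
    s = (trend + amp24 * np.sin(2 * np.pi * t / 24.0)
         + amp12 * np.sin(2 * np.pi * t / 12.0))
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        s = s + rng.normal(0.0, noise_sd, size=t.shape)
    return t, s


def write_sequence(spec: RootSystemSpec, out_dir: str | Path,
                   system: GroundTruthSystem | None = None) -> GroundTruthSystem:
    """Render a full sequence to zero-padded PNGs + JSON ground truth.

    The sidecar ``ground_truth.json`` stores per-frame true lengths and the
    acquisition metadata (frame interval, mm/px) so rendered sequences are
    self-describing inputs for the pipeline.
    """
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if system is None:
        system = simulate_root_system(spec)
    droplets = _droplet_schedule(spec, system)
    for i, frame in enumerate(system.frames):
        mask = render_mask(frame, spec)
        img = render_image(mask, spec, i, droplets=droplets)
        iio.imwrite(out / f"frame_{i:05d}.png", img)
    gt = {
        "frame_interval_h": spec.frame_interval_h,
        "mm_per_px": spec.mm_per_px,
        "seed_position": list(spec.seed_position),
        "times_h": [f.time_h for f in system.frames],
        "mr_length_mm": [f.mr_length_mm for f in system.frames],
        "lr_lengths_mm": [f.lr_lengths_mm for f in system.frames],
        "lr_count": [int(f.lr_count) for f in system.frames],
        "droplet_frames": sorted({int(d[0]) for d in droplets}),
    }
    (out / "ground_truth.json").write_text(json.dumps(gt, indent=1))
    return system
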