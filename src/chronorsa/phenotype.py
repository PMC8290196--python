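"""Temporal root phenotypes from labelled graph sequences.

Classic architectural traits per frame (MR/LR/TR lengths, LR count and
density, MR fraction, convex-hull area) plus the temporal/spectral
parameters: the MR-vs-LR crossing time and the slope/derivative of the
aligned difference curve, growth speed, Fourier energy of the speed
signal at the circadian (1/24 h) and ultradian (1/12 h) frequencies,
and the 7-day sliding-window energy series.

All lengths are mm, times are hours since sowing, frequencies 1/h.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "SpectralFeatures", "measure_frame", "measure_sequence",
    "convex_hull_area", "lr_density_over_hull", "intersection_time",
    "aligned_difference_curve", "derivative_at_crossing", "slope_fit",
    "growth_speed", "spectral_energy", "windowed_energy_series",
]

FRAME_INTERVAL_H = 0.25
WINDOW_7D_H = 168.0


def measure_frame(labelled_graph) -> dict:
    """One TraitSeries row from a labelled graph.

    lr_density = LR count / MR length (1/mm); mr_fraction = MR/TR.
    Ratios whose denominator is zero are reported as missing (NaN).
    """
    if not labelled_graph.labelled:
        raise ValueError("graph must be labelled first")
    mr = labelled_graph.mr_length_mm
    lrs = labelled_graph.lr_lengths_mm
    lr_total = float(sum(lrs.values()))
    tr = mr + lr_total
    return {
        "time_h": labelled_graph.timestamp_h,
        "mr_length_mm": mr,
        "lr_total_length_mm": lr_total,
        "tr_length_mm": tr,
        "lr_count": len(lrs),
        "lr_density_per_mm": len(lrs) / mr if mr > 0 else np.nan,
        "mr_fraction": mr / tr if tr > 0 else np.nan,
        "tracking_failure": labelled_graph.tracking_failure,
    }


def measure_sequence(graphs, masks=None, mm_per_px: float | None = None,
                     plant_id: str = "plant1") -> pd.DataFrame:
    """Tidy per-frame trait table for one plant.

    When per-frame binary masks are supplied, the dynamic convex-hull
    area (mm^2) and the LR-length-over-hull density (mm/mm^2) are
    included as well.
    """
    rows = [measure_frame(g) for g in graphs]
    df = pd.DataFrame(rows)
    df.insert(0, "plant", plant_id)
    if masks is not None:
        scale = mm_per_px if mm_per_px is not None else graphs[0].mm_per_px
        hull = [convex_hull_area(m, scale) for m in masks]
        df["hull_area_mm2"] = hull
        df["lr_density_over_hull_per_mm"] = [
            lr_density_over_hull(l, h)
            for l, h in zip(df["lr_total_length_mm"], hull)]
    return df


def convex_hull_area(pixels: np.ndarray, mm_per_px: float = 1.0) -> float:
    """Area (mm^2) of the convex hull of root pixel centers.

    Accepts a binary mask or an (n, 2) array of pixel coordinates.
    Fewer than 3 points, or collinear points, span no area and return 0.
    """
    pts = np.asarray(pixels)
    if pts.ndim == 2 and pts.shape[1] != 2:
        pts = np.argwhere(pts)
    elif pts.ndim != 2:
        raise ValueError("expected a mask or an (n, 2) coordinate array")
    if len(pts) < 3:
        return 0.0
    try:
        hull = ConvexHull(pts.astype(float))
    except QhullError:        # degenerate (collinear) input
        return 0.0
    return float(hull.volume) * mm_per_px ** 2     # 2-D: volume is area


def lr_density_over_hull(lr_total_length_mm: float,
                         hull_area_mm2: float) -> float:
    """Total LR length over explored area (mm/mm^2); NaN for zero area."""
    if hull_area_mm2 <= 0:
        return float("nan")
    return lr_total_length_mm / hull_area_mm2


def _series(values, times):
    if isinstance(values, pd.Series):
        return np.asarray(values.index, dtype=float), values.to_numpy(float)
    if times is None:
        raise ValueError("times required for plain arrays")
    return np.asarray(times, dtype=float), np.asarray(values, dtype=float)


def intersection_time(mr_series, lr_total_series, times=None) -> float | None:
    """First time the summed LR length reaches the MR length.

    The crossing is bracketed on the sampling grid and refined by
    linear interpolation.  Returns None when the curves never cross
    (the LR sum must start below the MR).
    """
    t, mr = _series(mr_series, times)
    _, lr = _series(lr_total_series, times)
    if len(mr) != len(lr):
        raise ValueError("series must share one time grid")
    d = mr - lr
    above = np.nonzero(d <= 0)[0]
    if len(above) == 0:
        return None
    i = above[0]
    if i == 0 or d[i] == 0:
        return float(t[i])
    # linear interpolation between the bracketing samples
    return float(t[i - 1] + (t[i] - t[i - 1]) * d[i - 1] / (d[i - 1] - d[i]))


def aligned_difference_curve(mr_series, lr_total_series, t_star: float,
                             times=None, half_window_h: float = 24.0,
                             interval_h: float = FRAME_INTERVAL_H):
    """d(tau) = MR(t*+tau) - sum LR(t*+tau), tau in [-24, +24] h.

    Sampled on the native acquisition grid (2 * 96 + 1 = 193 points at
    15-min cadence); d(0) = 0 by construction of t*.  If the window
    leaves the record, the curve is truncated and flagged.

    Returns (tau_h, d, truncated).
    """
    t, mr = _series(mr_series, times)
    _, lr = _series(lr_total_series, times)
    n = int(round(half_window_h / interval_h))
    tau = np.arange(-n, n + 1) * interval_h
    want = t_star + tau
    ok = (want >= t[0]) & (want <= t[-1])
    truncated = not ok.all()
    tau = tau[ok]
    diff = np.interp(want[ok], t, mr - lr)
    return tau, diff, truncated


def derivative_at_crossing(tau: np.ndarray, d: np.ndarray,
                           interval_h: float = FRAME_INTERVAL_H):
    """Finite-difference derivative of the aligned curve at tau = 0.

    Central difference over one acquisition step when both neighbours
    exist (exact for linear curves), otherwise a one-sided difference,
    flagged.  Returns (slope_mm_per_h, one_sided).
    """
    tau = np.asarray(tau, dtype=float)
    d = np.asarray(d, dtype=float)

    def at(x):
        i = np.argmin(np.abs(tau - x))
        if abs(tau[i] - x) > 1e-9:
            return None
        return d[i]

    prev_, next_ = at(-interval_h), at(interval_h)
    if prev_ is not None and next_ is not None:
        return (next_ - prev_) / (2 * interval_h), False
    mid = at(0.0)
    if next_ is not None and mid is not None:
        return (next_ - mid) / interval_h, True
    if prev_ is not None and mid is not None:
        return (mid - prev_) / interval_h, True
    raise ValueError("curve does not cover tau = 0 and a neighbour")


def slope_fit(tau: np.ndarray, d: np.ndarray) -> float:
    """Least-squares slope of d over the full +-24 h window (mm/h)."""
    tau = np.asarray(tau, dtype=float)
    d = np.asarray(d, dtype=float)
    if len(np.unique(tau)) < 2:
        return float("nan")
    return float(np.polyfit(tau, d, 1)[0])


def growth_speed(length_series, times=None,
                 interval_h: float = FRAME_INTERVAL_H,
                 smooth_window_h: float = 1.0):
    """Growth speed (mm/h) from a uniformly sampled length series.

    First differences over the sampling interval, assigned to interval
    midpoints, optionally smoothed by a centered moving average
    (default 1 h) to tame quantization noise from pixel-level length
    measurements.  Returns (mid_times_h, speed).
    """
    if isinstance(length_series, pd.Series):
        times = np.asarray(length_series.index, dtype=float)
        length = length_series.to_numpy(float)
    else:
        length = np.asarray(length_series, dtype=float)
        if times is None:
            times = np.arange(len(length)) * interval_h
        times = np.asarray(times, dtype=float)
    if len(length) < 2:
        return np.empty(0), np.empty(0)
    dt = np.diff(times)
    speed = np.diff(length) / dt
    mid = times[:-1] + dt / 2
    if smooth_window_h and smooth_window_h > 0:
        w = max(int(round(smooth_window_h / np.median(dt))), 1)
        if w > 1:
            kernel = np.ones(w) / w
            pad = np.pad(speed, (w // 2, w - 1 - w // 2), mode="edge")
            speed = np.convolve(pad, kernel, mode="valid")
    return mid, speed


@dataclass
class SpectralFeatures:
    """DFT energy spectrum of a growth-speed signal.

    ``energy`` is |X_k|^2 / n with one-sided bins doubled, so the total
    energy equals the sum of squared (preprocessed) samples (Parseval).
    ``norm_scale`` is the standard deviation divided out during
    preprocessing; amplitude estimates multiply it back in.
    """

    frequencies_per_h: np.ndarray
    energy: np.ndarray
    energy_24: float
    energy_12: float
    n_samples: int
    norm_scale: float = 1.0

    def amplitude(self, energy: float) -> float:
        """Sinusoid amplitude implied by the energy in one exact bin."""
        return float(np.sqrt(2.0 * energy / self.n_samples) * self.norm_scale)


def _highpass_24h(x: np.ndarray, interval_h: float) -> np.ndarray:
    # centered 24 h moving average; periodic padding matches the DFT's
    # periodicity assumption and is exact for integer-cycle records
    w = max(int(round(24.0 / interval_h)), 1)
    pad = np.pad(x, (w // 2, w - 1 - w // 2), mode="wrap")
    baseline = np.convolve(pad, np.ones(w) / w, mode="valid")
    return x - baseline


def spectral_energy(speed_series, interval_h: float = FRAME_INTERVAL_H,
                    preprocess: bool = True) -> SpectralFeatures:
    """Fourier energy spectrum of the growth-speed signal.

    Preprocessing (on by default): high-pass by subtracting a centered
    24 h moving average, then normalization to unit variance.  Energies
    are reported on the one-sided DFT grid; the circadian and ultradian
    values are read at the bins nearest 1/24 and 1/12 per hour.
    """
    x = np.asarray(speed_series, dtype=float)
    if np.isnan(x).any():
        raise ValueError("speed series contains gaps; resample upstream")
    scale = 1.0
    if preprocess:
        x = _highpass_24h(x, interval_h)
        sd = x.std()
        if sd > 0:
            x = x / sd
            scale = float(sd)
    n = len(x)
    spec = np.fft.rfft(x)
    energy = np.abs(spec) ** 2 / n
    mult = np.full(len(energy), 2.0)
    mult[0] = 1.0
    if n % 2 == 0:
        mult[-1] = 1.0
    energy = energy * mult
    freqs = np.fft.rfftfreq(n, d=interval_h)
    e24 = float(energy[np.argmin(np.abs(freqs - 1.0 / 24.0))])
    e12 = float(energy[np.argmin(np.abs(freqs - 1.0 / 12.0))])
    return SpectralFeatures(freqs, energy, e24, e12, n, scale)


def windowed_energy_series(speed_series, target_freq_per_h: float,
                           window_h: float = WINDOW_7D_H,
                           interval_h: float = FRAME_INTERVAL_H,
                           preprocess: bool = True):
    """Sliding-window energy at one frequency (7-day window default).

    A 7-day window holds exactly 7 circadian and 14 ultradian cycles,
    so 1/24 and 1/12 per hour fall on exact DFT bins and leak nowhere.
    The window slides one sample at a time; each window is preprocessed
    independently.  Returns (center_times_h, energies).
    """
    x = np.asarray(speed_series, dtype=float)
    w = int(round(window_h / interval_h))
    if len(x) < w:
        raise ValueError(
            f"record ({len(x)} samples) shorter than the {window_h} h "
            f"window ({w} samples)")
    freqs = np.fft.rfftfreq(w, d=interval_h)
    k = int(np.argmin(np.abs(freqs - target_freq_per_h)))
    centers = (np.arange(len(x) - w + 1) + (w - 1) / 2.0) * interval_h
    energies = np.empty(len(centers))
    phase = np.exp(-2j * np.pi * k * np.arange(w) / w)
    for i in range(len(centers)):
        seg = x[i:i + w]
        if preprocess:
            seg = _highpass_24h(seg, interval_h)
            sd = seg.std()
            if sd > 0:
                seg = seg / sd
        coef = (seg * phase).sum()
        e = np.abs(coef) ** 2 / w
        if 0 < k < w / 2:
            e *= 2.0
        energies[i] = e
    return centers, energies
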