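"""Post-segmentation refinement.

Three stages sit between the network's probability maps and the graph
reconstruction:

1. a fully connected CRF with a Potts compatibility and a bilateral
   appearance kernel (spatial std ``theta_alpha`` = 5 px, intensity std
   ``theta_beta`` = 3 grey levels) homogenizes labels of contiguous,
   similar-intensity pixels (mean-field inference, message passing
   approximated on a bilateral grid);
2. a trailing-average recursion a^t = s^t + alpha * a^{t-1}
   (alpha = 0.9) lets past segmentations vote on the present frame, so
   a root segment hidden by a water droplet for a frame or two is not
   lost;
3. per-plant mask extraction: crop to the plant ROI, threshold the
   accumulated map, morphological closing/opening, keep the largest
   8-connected component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.measure import label as cc_label
from skimage.morphology import closing, footprint_rectangle, opening

__all__ = [
    "CRFParams", "TemporalAccumulator", "crf_refine",
    "accumulate_temporal", "extract_plant_mask",
]


@dataclass(frozen=True)
class CRFParams:
    """Dense-CRF inference parameters (Potts model, appearance kernel)."""

    theta_alpha: float = 5.0    # spatial std of the appearance kernel, px
    theta_beta: float = 3.0     # intensity std, grey levels
    compat: float = 3.0         # Potts penalty for differing labels
    iterations: int = 5
    soft: bool = False          # return probabilities instead of labels

    def __post_init__(self):
        if self.theta_alpha <= 0 or self.theta_beta <= 0:
            raise ValueError("kernel standard deviations must be positive")


def _bilateral_message(q: np.ndarray, image: np.ndarray,
                       theta_alpha: float, theta_beta: float) -> np.ndarray:
    """Gaussian message passing under the appearance kernel.

    Computes, for every pixel i and label l, sum_j k(f_i, f_j) Q_j(l)
    with k = exp(-|p_i-p_j|^2 / 2 theta_alpha^2
                 - |I_i-I_j|^2 / 2 theta_beta^2),
    approximated by splatting Q onto a (row, col, intensity) bilateral
    grid sampled at the kernel's standard deviations, blurring with a
    unit-sigma Gaussian and slicing back (nearest-bin interpolation).
    """
    L = q.shape[0]
    h, w = image.shape
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    ri = np.rint(rows / theta_alpha).astype(int)
    ci = np.rint(cols / theta_alpha).astype(int)
    ii = np.rint(image / theta_beta).astype(int)
    ii -= ii.min()
    grid = np.zeros((L, ri.max() + 1, ci.max() + 1, ii.max() + 1),
                    dtype=np.float64)
    flat = (ri * grid.shape[2] + ci) * grid.shape[3] + ii
    for l in range(L):
        np.add.at(grid[l].reshape(-1), flat.reshape(-1), q[l].reshape(-1))
    grid = gaussian_filter(grid, sigma=(0, 1.0, 1.0, 1.0), mode="constant")
    return grid[:, ri, ci, ii]


def crf_refine(prob_map: np.ndarray, image: np.ndarray,
               params: CRFParams | None = None) -> np.ndarray:
    """Mean-field inference in a fully connected binary CRF.

    The unary term is the negative log of (background, root)
    probabilities; the pairwise term couples every pixel pair through
    the appearance kernel with a Potts compatibility, so contiguous
    pixels of similar intensity are pushed toward a common label.
    Degenerate inputs (all-0 or all-1 probability) are returned
    unchanged.
    """
    params = params or CRFParams()
    p = np.asarray(prob_map, dtype=np.float64)
    image = np.asarray(image, dtype=np.float64)
    if p.shape != image.shape:
        raise ValueError("prob_map and image must share a shape")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("prob_map must lie in [0, 1]")
    if np.all(p == 0) or np.all(p == 1):
        return p > 0.5 if not params.soft else p.copy()

    eps = 1e-8
    unary = -np.log(np.clip(np.stack([1.0 - p, p]), eps, None))
    q = np.stack([1.0 - p, p])
    for _ in range(params.iterations):
        msg = _bilateral_message(q, image, params.theta_alpha,
                                 params.theta_beta)
        # Potts: each label is penalized by the mass of the *other* label
        pairwise = params.compat * (msg.sum(axis=0, keepdims=True) - msg)
        logit = -unary - pairwise
        logit -= logit.max(axis=0, keepdims=True)
        q = np.exp(logit)
        q /= q.sum(axis=0, keepdims=True)
    return q[1] > 0.5 if not params.soft else q[1]


@dataclass
class TemporalAccumulator:
    """State of the trailing-average recursion a^t = s^t + alpha a^{t-1}.

    The accumulator is not a probability: for a persistently segmented
    pixel it converges to 1/(1-alpha) (10 for the default alpha = 0.9),
    while a single-frame artifact never exceeds 1 + alpha.
    """

    alpha: float = 0.9
    a: np.ndarray | None = None

    def __post_init__(self):
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must lie in [0, 1)")


def accumulate_temporal(s_t: np.ndarray,
                        accumulator: TemporalAccumulator) -> TemporalAccumulator:
    """Fold the current segmentation into the accumulator.

    First frame: a^1 = s^1.  Later: a^t = s^t + alpha * a^{t-1}.
    """
    s_t = np.asarray(s_t, dtype=np.float64)
    if s_t.min() < 0 or s_t.max() > 1:
        raise ValueError("segmentation map must lie in [0, 1]")
    if accumulator.a is None:
        accumulator.a = s_t.copy()
        return accumulator
    if accumulator.a.shape != s_t.shape:
        raise ValueError("shape mismatch between frame and accumulator")
    accumulator.a = s_t + accumulator.alpha * accumulator.a
    return accumulator


def extract_plant_mask(accumulator: TemporalAccumulator | np.ndarray,
                       roi: tuple[int, int, int, int] | None = None,
                       threshold: float = 1.0) -> np.ndarray | None:
    """Binary root mask of one plant from the accumulated map.

    ``roi`` is (row_min, col_min, row_max, col_max), 0-based half-open.
    Pipeline: crop -> threshold -> morphological closing then opening
    (3x3 square) -> largest 8-connected component.  Returns ``None``
    when no plant is detected (nothing above threshold, or nothing
    survives morphology).
    """
    a = accumulator.a if isinstance(accumulator, TemporalAccumulator) else accumulator
    if a is None:
        return None
    a = np.asarray(a)
    if roi is not None:
        r0, c0, r1, c1 = roi
        if not (0 <= r0 < r1 <= a.shape[0] and 0 <= c0 < c1 <= a.shape[1]):
            raise ValueError(f"ROI {roi} outside frame bounds {a.shape}")
        a = a[r0:r1, c0:c1]
    binary = a >= threshold
    if not binary.any():
        return None
    foot = footprint_rectangle((3, 3))
    binary = opening(closing(binary, foot), foot)
    if not binary.any():
        return None
    labels = cc_label(binary, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()
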