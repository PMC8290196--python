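"""Root-segmentation networks: lightweight UNet, ResUNet, deeply
supervised ResUNet (DSResUNet), training, ensembling and evaluation.

The three architectures share one encoder-decoder plan: a lightweight
UNet with the feature maps of the standard UNet reduced by a factor 4
(16/32/64 encoder channels, 128 bottleneck), summation skip
connections, average pooling, ELU activations, bias-free convolutions
followed by batch normalization, stride-2 transposed-convolution
upsampling and a two-channel softmax output.  This plan has exactly
488,212 trainable parameters.  ResUNet replaces each two-convolution
block with a residual block (1x1 projection shortcut + batch norm).
DSResUNet appends a cascade: the ResUNet's probability map is
concatenated with the input image and refined by two further
convolutional layers; both outputs are exposed so training can sum two
cross-entropy terms (deep supervision).

Inference is fully convolutional: models train on patches and predict
full-resolution frames of arbitrary size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import directed_hausdorff

from . import nn
from .nn import (Adam, BatchNorm2d, Conv2d, ConvTranspose2d, Module, Tensor,
                 add, avg_pool2, concat, elu, softmax, softmax_cross_entropy,
                 softmax_op)

__all__ = [
    "ArchitectureConfig", "TrainingConfig", "ProbabilityMap",
    "build_unet", "build_resunet", "build_dsresunet", "count_parameters",
    "sample_training_patch", "augment_patch", "train_model", "predict",
    "ensemble_predict", "evaluate_segmentation",
]


@dataclass(frozen=True)
class ArchitectureConfig:
    """Structural hyperparameters of the encoder-decoder plan.

    The defaults reproduce the published trainable-parameter budget of
    the lightweight UNet family; the parameter count of a built model
    is a pure function of this config.
    """

    base_feature_maps: int = 16
    depth: int = 3                      # number of pooling stages
    skip_mode: str = "summation"
    pool_mode: str = "average"
    activation: str = "ELU"
    block_type: str = "plain"           # or "residual"
    deep_supervision: bool = False
    input_channels: int = 1
    output_channels: int = 1            # probability channels (root)
    head_width: int = 580               # deep-supervision refinement width
    min_input_px: int = 8
    rng_seed: int = 0

    def __post_init__(self):
        if self.skip_mode != "summation":
            raise ValueError("only summation skip connections are supported")
        if self.pool_mode != "average":
            raise ValueError("only average pooling is supported")
        if self.input_channels != 1 or self.output_channels != 1:
            raise ValueError("single-channel input/probability output only")
        if self.min_input_px // (2 ** self.depth) < 1:
            raise ValueError(
                f"depth {self.depth} shrinks a {self.min_input_px}-px input "
                "below 1 px at the bottleneck")

    @property
    def encoder_channels(self) -> list[int]:
        return [self.base_feature_maps * 2 ** i for i in range(self.depth)]

    @property
    def bottleneck_channels(self) -> int:
        return self.base_feature_maps * 2 ** self.depth

    @property
    def n_classes(self) -> int:
        return self.output_channels + 1   # softmax over {background, root}


@dataclass
class TrainingConfig:
    """Patch-based training protocol defaults."""

    learning_rate: float = 1e-4
    weight_decay: float = 1e-8
    patch_size: int = 256
    batch_size: int = 8
    root_center_prob: float = 0.5
    steps: int = 200
    noise_sd: float = 0.03
    gamma_range: tuple[float, float] = (0.7, 1.4)
    blur_sigma_max: float = 1.0
    flip_prob: float = 0.5
    rng_seed: int = 0


@dataclass
class ProbabilityMap:
    """Per-pixel root probability for one frame."""

    values: np.ndarray
    timestamp_h: float | None = None

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.min() < 0 or v.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        self.values = v


# ----------------------------------------------------------- blocks

class _PlainBlock(Module):
    def __init__(self, cin, cout, rng):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, 3, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, 3, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(cout)

    def __call__(self, x):
        y = elu(self.bn1(self.conv1(x)))
        return elu(self.bn2(self.conv2(y)))


class _ResidualBlock(Module):
    """Two conv-BN layers plus a projected identity shortcut."""

    def __init__(self, cin, cout, rng):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, 3, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, 3, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(cout)
        self.proj = Conv2d(cin, cout, 1, bias=False, rng=rng)
        self.bn_proj = BatchNorm2d(cout)

    def __call__(self, x):
        y = elu(self.bn1(self.conv1(x)))
        y = self.bn2(self.conv2(y))
        return elu(add(y, self.bn_proj(self.proj(x))))


class _UpLayer(Module):
    def __init__(self, cin, cout, rng):
        super().__init__()
        self.up = ConvTranspose2d(cin, cout, 3, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)

    def __call__(self, x):
        return elu(self.bn(self.up(x)))


class SegmentationNet(Module):
    """Shared encoder-decoder body (UNet when plain, ResUNet when
    residual).  ``forward`` returns 2-channel logits."""

    def __init__(self, config: ArchitectureConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.rng_seed)
        Block = _ResidualBlock if config.block_type == "residual" else _PlainBlock
        chans = config.encoder_channels
        self.enc = []
        cin = config.input_channels
        for c in chans:
            self.enc.append(Block(cin, c, rng))
            cin = c
        self.bottleneck = Block(cin, config.bottleneck_channels, rng)
        self.ups, self.dec = [], []
        cin = config.bottleneck_channels
        for c in reversed(chans):
            self.ups.append(_UpLayer(cin, c, rng))
            self.dec.append(Block(c, c, rng))
            cin = c
        self.out_conv = Conv2d(cin, config.n_classes, 3, bias=False, rng=rng)
        self.out_bn = BatchNorm2d(config.n_classes)

    def forward(self, x: Tensor) -> Tensor:
        skips = []
        for block in self.enc:
            x = block(x)
            skips.append(x)
            x = avg_pool2(x)
        x = self.bottleneck(x)
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            x = add(up(x), skip)      # summation skip connection
            x = block(x)
        return self.out_bn(self.out_conv(x))

    __call__ = forward


class DeepSupervisedNet(Module):
    """ResUNet cascade with a refinement head.

    The body's softmax output is concatenated with the input image and
    passed through two further convolutional layers; ``forward``
    returns (stage1_logits, refined_logits) so the training loss can
    sum two cross-entropy terms.
    """

    def __init__(self, config: ArchitectureConfig):
        super().__init__()
        self.config = config
        self.body = SegmentationNet(config)
        rng = np.random.default_rng(config.rng_seed + 1)
        a = config.head_width
        self.head_conv1 = Conv2d(config.n_classes + config.input_channels,
                                 a, 3, bias=False, rng=rng)
        self.head_bn1 = BatchNorm2d(a)
        self.head_conv2 = Conv2d(a, config.n_classes, 3, bias=False, rng=rng)
        self.head_bn2 = BatchNorm2d(config.n_classes)

    def forward(self, x: Tensor):
        logits1 = self.body(x)
        h = concat([x, softmax_op(logits1, axis=1)], axis=1)
        h = elu(self.head_bn1(self.head_conv1(h)))
        logits2 = self.head_bn2(self.head_conv2(h))
        return logits1, logits2

    __call__ = forward


# --------------------------------------------------------- builders

def build_unet(config: ArchitectureConfig | None = None) -> SegmentationNet:
    config = config or ArchitectureConfig()
    if config.block_type != "plain":
        raise ValueError("build_unet requires block_type='plain'")
    return SegmentationNet(config)


def build_resunet(config: ArchitectureConfig | None = None) -> SegmentationNet:
    config = config or ArchitectureConfig(block_type="residual")
    if config.block_type != "residual":
        raise ValueError("build_resunet requires block_type='residual'")
    return SegmentationNet(config)


def build_dsresunet(config: ArchitectureConfig | None = None) -> DeepSupervisedNet:
    config = config or ArchitectureConfig(block_type="residual",
                                          deep_supervision=True)
    if not config.deep_supervision:
        raise ValueError("build_dsresunet requires deep_supervision=True")
    if config.block_type != "residual":
        raise ValueError("build_dsresunet requires block_type='residual'")
    return DeepSupervisedNet(config)


def count_parameters(model: Module) -> int:
    """Number of trainable scalars (conv weights, biases, BN scale/shift)."""
    return int(sum(p.data.size for p in model.parameters()))


# --------------------------------------------------- patch sampling

def sample_training_patch(image: np.ndarray, mask: np.ndarray,
                          rng: np.random.Generator, patch_size: int = 256,
                          root_center_prob: float = 0.5):
    """Draw one training patch, root-centered with probability 0.5.

    Roots cover a tiny fraction of a plate image, so unbiased patch
    sampling would starve the loss of root pixels; centering half the
    patches on root pixels balances the classes.  Patches near the
    border are completed by reflection padding.
    """
    if image.shape != mask.shape:
        raise ValueError("image and mask must have the same shape")
    mask = mask.astype(bool)
    want_root = rng.random() < root_center_prob
    if want_root and not mask.any():
        warnings.warn("mask has no root pixels; sampling background patch")
        want_root = False
    elif not want_root and mask.all():
        want_root = True
    pool = np.argwhere(mask if want_root else ~mask)
    r, c = pool[rng.integers(len(pool))]
    half = patch_size // 2
    pad = ((half, patch_size - half), (half, patch_size - half))
    img_p = np.pad(image, pad, mode="reflect")
    mask_p = np.pad(mask, pad, mode="reflect")
    patch = img_p[r:r + patch_size, c:c + patch_size]
    patch_mask = mask_p[r:r + patch_size, c:c + patch_size]
    return patch.copy(), patch_mask.copy()


def augment_patch(patch: np.ndarray, patch_mask: np.ndarray,
                  rng: np.random.Generator, noise_sd: float = 0.03,
                  gamma_range: tuple[float, float] = (0.7, 1.4),
                  blur_sigma_max: float = 1.0, flip_prob: float = 0.5):
    """Online augmentation: horizontal flip (applied to patch and mask
    alike), then Gaussian noise, random gamma and blur on the patch
    only.  The patch is expected in [0, 1]."""
    patch = np.asarray(patch, dtype=np.float32)
    patch_mask = patch_mask.astype(bool)
    if rng.random() < flip_prob:
        patch = patch[:, ::-1].copy()
        patch_mask = patch_mask[:, ::-1].copy()
    lo, hi = gamma_range
    if (lo, hi) != (1.0, 1.0):
        gamma = rng.uniform(lo, hi)
        patch = np.clip(patch, 0.0, 1.0) ** gamma
    if blur_sigma_max > 0:
        sigma = rng.uniform(0.0, blur_sigma_max)
        if sigma > 1e-3:
            patch = gaussian_filter(patch, sigma)
    if noise_sd > 0:
        patch = patch + rng.normal(0.0, noise_sd, patch.shape).astype(np.float32)
    return patch.astype(np.float32), patch_mask


# ----------------------------------------------------------- training

def _as_float(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.dtype == np.uint8:
        return image.astype(np.float32) / 255.0
    return image.astype(np.float32)


def train_model(model: Module, dataset, config: TrainingConfig | None = None):
    """Patch-based training with cross-entropy loss and Adam.

    ``dataset`` is a sequence of (image, binary mask) pairs.  For
    deeply supervised models the loss is the sum of the two stages'
    cross-entropy terms.  Returns (model, loss_history); sampling and
    augmentation are driven by one seeded generator, so a fixed seed
    gives a reproducible trajectory on a fixed machine.
    """
    cfg = config or TrainingConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    images = [_as_float(im) for im, _ in dataset]
    masks = [np.asarray(mk).astype(bool) for _, mk in dataset]
    opt = Adam(model.parameters(), lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)
    model.train(True)
    history = []
    for step in range(cfg.steps):
        xb = np.empty((cfg.batch_size, 1, cfg.patch_size, cfg.patch_size),
                      dtype=np.float32)
        yb = np.empty((cfg.batch_size, cfg.patch_size, cfg.patch_size),
                      dtype=np.float32)
        for i in range(cfg.batch_size):
            j = rng.integers(len(images))
            p, m = sample_training_patch(images[j], masks[j], rng,
                                         cfg.patch_size, cfg.root_center_prob)
            p, m = augment_patch(p, m, rng, cfg.noise_sd, cfg.gamma_range,
                                 cfg.blur_sigma_max, cfg.flip_prob)
            xb[i, 0], yb[i] = p, m
        x = Tensor(xb)
        out = model(x)
        if isinstance(out, tuple):      # deep supervision: sum of two terms
            loss = add(softmax_cross_entropy(out[0], yb),
                       softmax_cross_entropy(out[1], yb))
        else:
            loss = softmax_cross_entropy(out, yb)
        if not np.isfinite(loss.data):
            raise RuntimeError(
                f"non-finite loss {loss.data!r} at step {step}; "
                "check learning rate and input scaling")
        model.zero_grad()
        loss.backward()
        opt.step()
        history.append(float(loss.data))
    model.eval()
    return model, history


# ---------------------------------------------------------- inference

def predict(model: Module, image: np.ndarray) -> np.ndarray:
    """Full-resolution root-probability map for a single-channel image.

    The input is reflect-padded to a multiple of the pooling footprint,
    run through the network in eval mode, and cropped back, so the
    output shape always equals the input shape.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("predict expects a single-channel 2D image")
    cfg = model.config
    f = 2 ** cfg.depth
    h, w = image.shape
    ph, pw = (-h) % f, (-w) % f
    x = _as_float(image)
    x = np.pad(x, ((0, ph), (0, pw)), mode="reflect")
    model.eval()
    out = model(Tensor(x[None, None]))
    logits = out[1] if isinstance(out, tuple) else out
    prob = softmax(logits.data, axis=1)[0, 1, :h, :w]
    return np.ascontiguousarray(prob, dtype=np.float32)


def ensemble_predict(models, image: np.ndarray) -> np.ndarray:
    """Unweighted average of member probability maps.

    Approximates the posterior P(y|x) by (1/M) sum_m P(y|x, theta_m);
    the member count M is whatever is passed in.
    """
    models = list(models)
    if not models:
        raise ValueError("ensemble requires at least one model")
    maps = [predict(m, image) for m in models]
    shapes = {m.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError(f"member map shapes differ: {sorted(shapes)}")
    return np.mean(maps, axis=0, dtype=np.float64).astype(np.float32)


# --------------------------------------------------------- evaluation

def evaluate_segmentation(pred_mask: np.ndarray, gt_mask: np.ndarray,
                          mm_per_px: float = 1.0) -> dict:
    """Dice, recall and symmetric Hausdorff distance (in mm).

    Dice = 2|A∩B|/(|A|+|B|); recall is the fraction of ground-truth
    root pixels retrieved.  Conventions: two empty masks are a perfect
    match (Dice 1, Hausdorff 0); exactly one empty mask gives Dice 0
    and an infinite Hausdorff distance.
    """
    a = np.asarray(pred_mask).astype(bool)
    b = np.asarray(gt_mask).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks must have the same shape")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return {"dice": 1.0, "recall": 1.0, "hausdorff_mm": 0.0}
    if na == 0 or nb == 0:
        return {"dice": 0.0, "recall": 0.0 if nb else np.nan,
                "hausdorff_mm": np.inf}
    inter = int(np.logical_and(a, b).sum())
    pa = np.argwhere(a).astype(float)
    pb = np.argwhere(b).astype(float)
    hd = max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])
    return {"dice": 2.0 * inter / (na + nb),
            "recall": inter / nb,
            "hausdorff_mm": hd * mm_per_px}
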