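"""Heart-region and LV localization.

Two-step mask-regression localizer: a small convolutional network first
finds the heart in the zero-padded, 64 x 64-downsampled frame, then the
same architecture, trained on 64 x 64 heart-region crops at the original
resolution, outputs the LV binary mask whose white-region centroid is the
LV seed point.

Architecture (asserted at build time): one convolution layer of 50 filters
of size 9 x 9 ("valid" boundary, so 64 - 9 + 1 = 56), ReLU, max pooling of
size 8 x 8 with stride 8 (56 / 8 = 7), and a fully connected layer mapping
the 7 x 7 x 50 feature block to 4096 sigmoid outputs reshaped into a
64 x 64 mask.  Weights are initialized from a zero-mean Gaussian with
standard deviation 0.01.  Training minimizes per-pixel binary
cross-entropy with momentum SGD; this is a deliberate toy-scale
implementation in numpy — large-scale training on real data is out of
scope.

A deterministic, non-learned **fallback localizer** (Otsu threshold +
brightest compact blob) is the pipeline default so the rest of the chain
does not depend on training.

Localization failures are signalled by returning ``None``, never by
raising, so callers can fall back or record a per-frame failure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._util import centroid, extract_patch, largest_component
from .errors import ConfigError, ParameterError

ROI_SIZE = 64


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

@dataclass
class LocalizerInput:
    """A frame padded to square with zeros and downsampled to 64 x 64.

    ``scale`` and ``pad`` record the affine map back to original
    coordinates: ``orig = (down + 0.5) * scale - 0.5 - pad``.
    """

    image: np.ndarray                 # (64, 64)
    scale: float
    pad: Tuple[int, int]              # zeros added at (top, left)
    orig_shape: Tuple[int, int]

    def to_original(self, points):
        pts = np.asarray(points, dtype=float)
        return (pts + 0.5) * self.scale - 0.5 - np.asarray(self.pad)

    def to_downsampled(self, points):
        pts = np.asarray(points, dtype=float) + np.asarray(self.pad)
        return (pts + 0.5) / self.scale - 0.5


def preprocess(image: np.ndarray) -> LocalizerInput:
    """Zero-pad a frame to square and downsample it to 64 x 64."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ParameterError("localizer input must be a nonempty 2-D image")
    rows, cols = image.shape
    side = max(rows, cols)
    pad_top = (side - rows) // 2
    pad_left = (side - cols) // 2
    padded = np.zeros((side, side), dtype=float)
    padded[pad_top:pad_top + rows, pad_left:pad_left + cols] = image
    if side == ROI_SIZE:
        small = padded
    else:
        from skimage.transform import resize

        small = resize(padded, (ROI_SIZE, ROI_SIZE), anti_aliasing=True,
                       preserve_range=True)
    return LocalizerInput(small, side / ROI_SIZE, (pad_top, pad_left), (rows, cols))


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

@dataclass
class NetConfig:
    n_filters: int = 50
    kernel: int = 9
    init_sd: float = 0.01
    pool: int = 8
    pool_stride: int = 8
    fc_outputs: int = 4096
    input_side: int = ROI_SIZE
    seed: int = 0

    def validate(self) -> None:
        if self.fc_outputs != self.input_side ** 2:
            raise ConfigError(
                f"fc_outputs must equal input_side^2 ({self.input_side ** 2}); "
                f"got {self.fc_outputs}"
            )
        conv_side = self.input_side - self.kernel + 1
        if conv_side <= 0 or conv_side % self.pool_stride != 0:
            raise ConfigError(
                f"conv output side {conv_side} not divisible by pool stride {self.pool_stride}"
            )
        if self.pool != self.pool_stride:
            raise ConfigError("non-overlapping pooling expected (pool == stride)")

    @property
    def conv_side(self) -> int:
        return self.input_side - self.kernel + 1

    @property
    def pooled_side(self) -> int:
        return self.conv_side // self.pool_stride


class MaskNet:
    """conv(9x9, 50) -> ReLU -> maxpool(8/8) -> FC -> sigmoid mask."""

    def __init__(self, config: NetConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        k, f = config.kernel, config.n_filters
        self.w_conv = rng.normal(0.0, config.init_sd, size=(f, k, k))
        self.b_conv = np.zeros(f)
        n_feat = config.pooled_side ** 2 * f
        self.w_fc = rng.normal(0.0, config.init_sd, size=(n_feat, config.fc_outputs))
        self.b_fc = np.zeros(config.fc_outputs)
        self._vel = [np.zeros_like(p) for p in self.parameters()]

    def parameters(self):
        return [self.w_conv, self.b_conv, self.w_fc, self.b_fc]

    # -- forward ------------------------------------------------------------

    def forward(self, x: np.ndarray):
        cfg = self.config
        if x.shape != (cfg.input_side, cfg.input_side):
            raise ParameterError(f"network input must be {cfg.input_side}x{cfg.input_side}")
        k, f, s = cfg.kernel, cfg.n_filters, cfg.pool_stride
        cs, ps = cfg.conv_side, cfg.pooled_side
        patches = sliding_window_view(x, (k, k)).reshape(cs * cs, k * k)
        conv = patches @ self.w_conv.reshape(f, k * k).T + self.b_conv   # (cs*cs, f)
        relu = np.maximum(conv, 0.0)
        blocks = relu.reshape(cs, cs, f).reshape(ps, s, ps, s, f)
        pooled = blocks.max(axis=(1, 3))                                  # (ps, ps, f)
        flat = pooled.reshape(-1)
        logits = flat @ self.w_fc + self.b_fc
        probs = 1.0 / (1.0 + np.exp(-logits))
        return probs.reshape(cfg.input_side, cfg.input_side)

    def predict_mask(self, x: np.ndarray) -> np.ndarray:
        """Binary 64 x 64 mask: sigmoid outputs binarized at 0.5."""
        return (self.forward(x) >= 0.5).astype(np.uint8)

    # -- training -----------------------------------------------------------

    def _step(self, x: np.ndarray, y: np.ndarray, lr: float, momentum: float = 0.9):
        """One SGD step on per-pixel BCE; returns the sample loss."""
        cfg = self.config
        k, f, s = cfg.kernel, cfg.n_filters, cfg.pool_stride
        cs, ps = cfg.conv_side, cfg.pooled_side
        patches = sliding_window_view(x, (k, k)).reshape(cs * cs, k * k)
        conv = patches @ self.w_conv.reshape(f, k * k).T + self.b_conv
        relu = np.maximum(conv, 0.0)
        blocks = relu.reshape(cs, cs, f).reshape(ps, s, ps, s, f)
        pooled = blocks.max(axis=(1, 3))
        flat = pooled.reshape(-1)
        logits = flat @ self.w_fc + self.b_fc
        probs = 1.0 / (1.0 + np.exp(-logits))
        t = y.reshape(-1).astype(float)
        eps = 1e-12
        loss = -np.mean(t * np.log(probs + eps) + (1 - t) * np.log(1 - probs + eps))

        dlogits = (probs - t) / logits.size
        dw_fc = np.outer(flat, dlogits)
        db_fc = dlogits
        dflat = self.w_fc @ dlogits
        dpooled = dflat.reshape(ps, ps, f)
        # route gradient to the argmax position of each pooling block
        is_max = blocks == pooled[:, None, :, None, :]
        counts = is_max.sum(axis=(1, 3), keepdims=True)
        drelu = (is_max * (dpooled[:, None, :, None, :] / counts)).reshape(cs * cs, f)
        dconv = drelu * (conv > 0)
        dw_conv = (dconv.T @ patches).reshape(f, k, k)
        db_conv = dconv.sum(axis=0)

        grads = [dw_conv, db_conv, dw_fc, db_fc]
        for p, g, v in zip(self.parameters(), grads, self._vel):
            v *= momentum
            v -= lr * g
            p += v
        return float(loss)

    def fit(self, pairs: Sequence[Tuple[np.ndarray, np.ndarray]],
            epochs: int = 10, lr: float = 0.5) -> List[float]:
        """Train on (image, binary mask) pairs; returns per-epoch mean loss."""
        losses = []
        for _ in range(epochs):
            epoch = [self._step(x, y, lr) for x, y in pairs]
            losses.append(float(np.mean(epoch)))
        return losses


def build_network(config: NetConfig = None) -> MaskNet:
    """Build (and architecture-check) the mask-regression network."""
    return MaskNet(config or NetConfig())


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(net: MaskNet, path) -> None:
    header = json.dumps(net.config.__dict__)
    np.savez(
        path,
        config_json=np.str_(header),
        w_conv=net.w_conv, b_conv=net.b_conv, w_fc=net.w_fc, b_fc=net.b_fc,
    )


def load_checkpoint(path) -> MaskNet:
    with np.load(path, allow_pickle=False) as z:
        config = NetConfig(**json.loads(str(z["config_json"])))
        net = MaskNet(config)
        net.w_conv = z["w_conv"].copy()
        net.b_conv = z["b_conv"].copy()
        net.w_fc = z["w_fc"].copy()
        net.b_fc = z["b_fc"].copy()
    return net


# ---------------------------------------------------------------------------
# training data handling
# ---------------------------------------------------------------------------

def _check_pairs(pairs) -> None:
    if len(pairs) == 0:
        raise ParameterError("training set is empty")
    for _, mask in pairs:
        vals = np.unique(np.asarray(mask))
        if not np.all(np.isin(vals, (0, 1))):
            raise ParameterError("training masks must be binary (values in {0, 1})")


def augment_pairs(pairs, factor: int, seed: int = 0):
    """Expand the training set by translation, rotation and intensity changes.

    Returns the originals plus ``factor - 1`` transformed copies of each,
    so the dataset grows by exactly ``factor``.
    """
    from scipy.ndimage import rotate, shift

    if factor < 1:
        raise ParameterError("augmentation factor must be >= 1")
    rng = np.random.default_rng(seed)
    out = list(pairs)
    for img, mask in pairs:
        for _ in range(factor - 1):
            dr, dc = rng.uniform(-5, 5, size=2)
            ang = rng.uniform(-15, 15)
            gain = rng.uniform(0.8, 1.2)
            offset = rng.uniform(-0.05, 0.05)
            a_img = shift(img.astype(float), (dr, dc), order=1, mode="constant")
            a_img = rotate(a_img, ang, reshape=False, order=1, mode="constant")
            a_img = np.clip(gain * a_img + offset, 0.0, 1.0)
            a_mask = shift(mask.astype(float), (dr, dc), order=0, mode="constant")
            a_mask = rotate(a_mask, ang, reshape=False, order=0, mode="constant")
            out.append((a_img, (a_mask >= 0.5).astype(np.uint8)))
    return out


def _to_net_pairs(pairs):
    """Preprocess full-resolution (image, mask) pairs to 64 x 64."""
    net_pairs = []
    for img, mask in pairs:
        pi = preprocess(img)
        pm = preprocess(mask.astype(float))
        net_pairs.append((pi.image, (pm.image >= 0.5).astype(np.uint8)))
    return net_pairs


def train_step1_heart(pairs, config: NetConfig = None, epochs: int = 10,
                      lr: float = 0.5, checkpoint_path=None):
    """Train the heart-region localizer on (frame, heart-mask) pairs.

    Returns ``(network, per-epoch losses)``.
    """
    _check_pairs(pairs)
    net = build_network(config)
    losses = net.fit(_to_net_pairs(pairs), epochs=epochs, lr=lr)
    if checkpoint_path is not None:
        save_checkpoint(net, checkpoint_path)
    return net, losses


def train_step2_lv(pairs, config: NetConfig = None, epochs: int = 10,
                   lr: float = 0.5, checkpoint_path=None):
    """Train the LV localizer on (64 x 64 heart-ROI crop, LV-mask) pairs."""
    return train_step1_heart(pairs, config=config, epochs=epochs, lr=lr,
                             checkpoint_path=checkpoint_path)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

@dataclass
class MaskPrediction:
    """A predicted binary mask plus its white-region centroid.

    ``center`` is in original-image coordinates; ``mask`` is in the
    predictor's native grid (64 x 64 for the network, full frame resolution
    for the fallback localizer).
    """

    mask: np.ndarray
    center: Tuple[float, float]


@dataclass
class RoiCrop:
    """A 64 x 64 original-resolution crop centered on the predicted heart."""

    image: np.ndarray
    center: Tuple[float, float]       # heart center, full-frame coordinates
    origin: Tuple[int, int]           # full-frame (row, col) of crop pixel (0, 0)


def predict_heart_roi(network: Optional[MaskNet], frame: np.ndarray) -> Optional[RoiCrop]:
    """Step-1 inference: heart center -> 64 x 64 crop of the original frame.

    With ``network=None`` the fallback localizer supplies the center.
    Returns ``None`` (a localization failure, not an exception) when no
    heart region is found.
    """
    if network is None:
        pred = fallback_localize(frame)
        if pred is None:
            return None
        center = pred.center
    else:
        pre = preprocess(frame)
        mask = network.predict_mask(pre.image)
        comp = largest_component(mask)
        if comp is None:
            return None
        center = tuple(pre.to_original(centroid(comp)))
    crop, origin = extract_patch(np.asarray(frame, dtype=float), center, ROI_SIZE)
    return RoiCrop(crop, center, origin)


def predict_lv_mask(network: Optional[MaskNet], roi: RoiCrop) -> Optional[MaskPrediction]:
    """Step-2 inference: LV mask and endocardial-contour center from a heart ROI."""
    if network is None:
        pred = fallback_localize(roi.image)
        if pred is None:
            return None
        mask, (r, c) = pred.mask, pred.center
    else:
        mask = network.predict_mask(roi.image)
        comp = largest_component(mask)
        if comp is None:
            return None
        mask, (r, c) = mask, centroid(comp)
    return MaskPrediction(mask, (r + roi.origin[0], c + roi.origin[1]))


# ---------------------------------------------------------------------------
# fallback localizer
# ---------------------------------------------------------------------------

def fallback_localize(frame: np.ndarray, min_area: int = 30,
                      min_solidity: float = 0.75) -> Optional[MaskPrediction]:
    """Deterministic non-learned localizer.

    Thresholds the frame at the blood-pool cut (upper threshold of a
    three-class Otsu partition, see :func:`fbcine.lvcenter.pool_threshold`)
    and keeps the brightest (highest mean intensity) connected blob that
    is large (``>= min_area`` px) and compact (solidity
    ``>= min_solidity`` — the blood pool is convex-ish, while thresholded
    noise percolates into ragged regions).  Ties on mean intensity break
    topmost-then-leftmost by bounding box.  Returns ``None`` when no
    acceptable blob exists.
    """
    from skimage.measure import label, regionprops

    from .errors import DegenerateInputError
    from .lvcenter import pool_threshold

    frame = np.asarray(frame, dtype=float)
    try:
        thr = pool_threshold(frame)
    except DegenerateInputError:
        return None
    binary = frame > thr
    labels = label(binary, connectivity=1)
    best = None
    for prop in regionprops(labels, intensity_image=frame):
        if prop.area < min_area or prop.solidity < min_solidity:
            continue
        key = (-prop.intensity_mean, prop.bbox[0], prop.bbox[1])
        if best is None or key < best[0]:
            best = (key, prop)
    if best is None:
        return None
    prop = best[1]
    mask = (labels == prop.label).astype(np.uint8)
    return MaskPrediction(mask, centroid(mask))
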