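"""Synthetic free-breathing short-axis cine phantom.

Renders a cine stack in which a bright elliptical blood pool sits inside a
darker myocardial annulus over a textured thorax background.  Two motions
are superposed, mimicking a real-time acquisition without breath-hold:

* a **cardiac** oscillation of the pool area (smooth interpolation between
  an end-diastolic and an end-systolic radius, period ``cardiac_period_frames``);
* a slower **respiratory** vertical translation of the whole heart with a
  long dwell near end-expiration, where the heart sits highest (smallest
  image row), as it does when the diaphragm relaxes after exhalation.

Two papillary-muscle-like dark blobs are drawn inside the pool, placed
symmetrically about the center so they bias segmentation but not the true
centroid.  Every stack comes with a :class:`PhantomTruth` record (true
center per frame, ED/ES frame indices, end-expiration window) so each
downstream stage can be tested against ground truth.

All public frame indices are 1-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ParameterError, RangeError
from .io import CineSlice

# fixed phantom geometry (not exposed: downstream stages must not depend on them)
_POOL_ELONG = (1.12, 0.90)    # pool semi-axis factors (major, minor) on the radius
_POOL_ANGLE = 0.35            # pool orientation, radians
_WALL_PX = 5.5                # myocardial wall thickness, pixels
_PAPILLARY_RADIUS = 1.4       # papillary blob radius, pixels
_PAPILLARY_OFFSET = 0.45      # blob offset along the major axis, fraction of it
_DWELL_FRAC = 0.30            # fraction of the respiratory period spent at end-expiration
_DWELL_START_FRAME = 18       # 1-based frame at which the first full dwell begins
_DWELL_CURVE = 0.03           # shallow rounding of the dwell, fraction of amplitude


@dataclass
class PhantomConfig:
    """Study conditions for one synthetic slice.

    Defaults follow the acquisition regime the pipeline targets: 84 frames
    of a 128 x 160 matrix at ~60 ms temporal resolution, a cardiac cycle of
    14 frames and a respiratory period of ~60 frames (~3.5 s breathing
    period), with a few pixels of superior-inferior respiratory excursion.
    """

    n_frames: int = 84
    frame_shape: Tuple[int, int] = (128, 160)   # (rows, cols)
    cardiac_period_frames: int = 14
    resp_period_frames: int = 60
    resp_amplitude_px: float = 6.0
    pool_radius_ed_px: float = 11.0
    pool_radius_es_px: float = 6.5
    pool_intensity: float = 0.9
    myo_intensity: float = 0.35
    bg_intensity: float = 0.15
    noise_sd: float = 0.02
    n_papillary: int = 2
    seed: int = 0

    def validate(self) -> None:
        if not self.pool_radius_ed_px > self.pool_radius_es_px > 0:
            raise ParameterError(
                "invariant violated: pool_radius_ed_px > pool_radius_es_px > 0 "
                f"(got {self.pool_radius_ed_px}, {self.pool_radius_es_px})"
            )
        if not self.cardiac_period_frames < self.resp_period_frames:
            raise ParameterError(
                "invariant violated: cardiac_period_frames < resp_period_frames "
                f"(got {self.cardiac_period_frames}, {self.resp_period_frames})"
            )
        if not self.n_frames >= 2 * self.cardiac_period_frames:
            raise ParameterError(
                "invariant violated: n_frames >= 2*cardiac_period_frames "
                f"(got {self.n_frames}, {self.cardiac_period_frames})"
            )
        if len(self.frame_shape) != 2 or min(self.frame_shape) < 32:
            raise ParameterError(f"invariant violated: frame_shape too small {self.frame_shape}")
        if self.resp_amplitude_px < 0:
            raise ParameterError("invariant violated: resp_amplitude_px >= 0")
        if self.noise_sd < 0:
            raise ParameterError("invariant violated: noise_sd >= 0")


@dataclass
class PhantomTruth:
    """Ground truth for one rendered stack (frame indices 1-based)."""

    center_trace: np.ndarray          # (n_frames, 2) true (row, col) of the LV center
    ed_frames: List[int]
    es_frames: List[int]
    expiration_window: Tuple[int, int]
    n_f: int
    area_trace: np.ndarray = field(default=None)  # analytic pool area per frame, px^2

    def to_json(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(
                {
                    "center_trace": np.round(self.center_trace, 4).tolist(),
                    "ed_frames": list(self.ed_frames),
                    "es_frames": list(self.es_frames),
                    "expiration_window": list(self.expiration_window),
                    "n_f": self.n_f,
                    "area_trace": np.round(self.area_trace, 3).tolist(),
                },
                fh,
            )
        return path


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _respiratory_displacement(config: PhantomConfig) -> np.ndarray:
    """Downward displacement d(t) >= 0 of the heart; d = 0 at end-expiration.

    Within each respiratory period a fraction ``_DWELL_FRAC`` is spent in a
    near-flat end-expiratory dwell (rounded by a shallow parabola so the
    best end-expiratory window is unique); the remainder is a raised-cosine
    excursion to end-inspiration and back.
    """
    t = np.arange(1, config.n_frames + 1)
    period = config.resp_period_frames
    phase = ((t - _DWELL_START_FRAME) % period) / period
    d = np.where(
        phase < _DWELL_FRAC,
        _DWELL_CURVE * (2 * phase / _DWELL_FRAC - 1.0) ** 2,
        0.5 - 0.5 * np.cos(2 * np.pi * (phase - _DWELL_FRAC) / (1.0 - _DWELL_FRAC)),
    )
    return config.resp_amplitude_px * d


def _pool_radius(config: PhantomConfig) -> np.ndarray:
    """Effective pool radius per frame; ED at cardiac phase 0 (frame 1)."""
    t = np.arange(1, config.n_frames + 1)
    phase = 2 * np.pi * (t - 1) / config.cardiac_period_frames
    w = 0.5 + 0.5 * np.cos(phase)
    return config.pool_radius_es_px + (config.pool_radius_ed_px - config.pool_radius_es_px) * w


def _geometry(config: PhantomConfig):
    rows, cols = config.frame_shape
    base = np.array([0.45 * rows, 0.5 * cols])
    d = _respiratory_displacement(config)
    centers = np.column_stack([base[0] + d, np.full(config.n_frames, base[1])])
    radii = _pool_radius(config)
    return centers, radii


def _truth(config: PhantomConfig) -> PhantomTruth:
    centers, radii = _geometry(config)
    nf = config.cardiac_period_frames
    ed = [t for t in range(1, config.n_frames + 1) if (t - 1) % nf == 0]
    es = [t for t in range(1, config.n_frames + 1) if (t - 1) % nf == nf // 2]
    h = config.frame_shape[0] - centers[:, 0]
    sums = np.convolve(h, np.ones(nf), mode="valid")
    a = int(np.argmax(sums)) + 1            # earliest maximizing start, 1-based
    areas = np.pi * (_POOL_ELONG[0] * radii) * (_POOL_ELONG[1] * radii)
    return PhantomTruth(
        center_trace=centers,
        ed_frames=ed,
        es_frames=es,
        expiration_window=(a, a + nf - 1),
        n_f=nf,
        area_trace=areas,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _ellipse_coverage(rr, cc, center, semi_axes, angle) -> np.ndarray:
    """Approximate per-pixel coverage of an ellipse with a ~1 px soft edge."""
    a, b = semi_axes
    dr = rr - center[0]
    dc = cc - center[1]
    u = (dr * np.cos(angle) + dc * np.sin(angle)) / a
    v = (-dr * np.sin(angle) + dc * np.cos(angle)) / b
    rho = np.sqrt(u * u + v * v)
    dist = (rho - 1.0) * min(a, b)          # approximate signed distance in px
    return np.clip(0.5 - dist, 0.0, 1.0)


def _pool_params(center, radius):
    return center, (_POOL_ELONG[0] * radius, _POOL_ELONG[1] * radius), _POOL_ANGLE


def _render_frame(bg, rr, cc, center, radius, config: PhantomConfig) -> np.ndarray:
    _, pool_axes, ang = _pool_params(center, radius)
    outer_axes = (pool_axes[0] + _WALL_PX, pool_axes[1] + _WALL_PX)
    img = bg.copy()
    cov_myo = _ellipse_coverage(rr, cc, center, outer_axes, ang)
    img = img * (1 - cov_myo) + config.myo_intensity * cov_myo
    cov_pool = _ellipse_coverage(rr, cc, center, pool_axes, ang)
    img = img * (1 - cov_pool) + config.pool_intensity * cov_pool
    if config.n_papillary > 0:
        offs = _PAPILLARY_OFFSET * pool_axes[0]
        direction = np.array([np.cos(ang), np.sin(ang)])
        signs = [1, -1] * (config.n_papillary // 2) + [1] * (config.n_papillary % 2)
        for k, s in enumerate(signs[: config.n_papillary]):
            pc = center + s * offs * direction * (1.0 + 0.1 * (k // 2))
            cov_p = _ellipse_coverage(
                rr, cc, pc, (_PAPILLARY_RADIUS, _PAPILLARY_RADIUS), 0.0
            )
            cov_p = cov_p * cov_pool
            img = img * (1 - cov_p) + config.myo_intensity * cov_p
    return img


def _pool_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    _, pool_axes, ang = _pool_params(center, radius)
    cov = _ellipse_coverage(rr, cc, center, pool_axes, ang)
    return (cov >= 0.5).astype(np.uint8)


def generate_cine(config: PhantomConfig = None) -> Tuple[CineSlice, PhantomTruth]:
    """Render a synthetic cine slice and its ground truth.

    Deterministic for a fixed ``config.seed`` (bit-identical stacks).
    """
    config = config or PhantomConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows, cols = config.frame_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")

    texture = gaussian_filter(rng.standard_normal((rows, cols)), sigma=6.0)
    texture *= 0.04 / max(texture.std(), 1e-12)
    bg = np.clip(config.bg_intensity + texture, 0.0, 1.0)

    centers, radii = _geometry(config)
    frames = np.empty((config.n_frames, rows, cols))
    for i in range(config.n_frames):
        img = _render_frame(bg, rr, cc, centers[i], radii[i], config)
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
        np.clip(img, 0.0, 1.0, out=frames[i])

    slc = CineSlice(
        frames,
        pixel_spacing=(2.24, 2.125),
        frame_interval=59.5,
        slice_id=f"phantom-seed{config.seed}",
    )
    return slc, _truth(config)


def generate_labeled_pair(config: PhantomConfig, frame_index: int):
    """Return ``(image, binary LV-pool mask)`` for one frame (1-based index).

    The image is bit-identical to the corresponding frame of
    :func:`generate_cine` under the same config.
    """
    config.validate()
    if not 1 <= frame_index <= config.n_frames:
        raise RangeError(f"frame {frame_index} out of range 1..{config.n_frames}")
    slc, _ = generate_cine(config)
    centers, radii = _geometry(config)
    mask = _pool_mask(config.frame_shape, centers[frame_index - 1], radii[frame_index - 1])
    return slc.frames[frame_index - 1], mask


def write_phantom(config: PhantomConfig, out_dir) -> dict:
    """Write NIfTI + NPZ stacks and the truth JSON sidecar; return the paths."""
    from . import io as fio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    slc, truth = generate_cine(config)
    paths = {
        "nifti": fio.write_nifti(slc, out / "cine.nii.gz"),
        "npz": fio.write_npz(slc, out / "cine.npz"),
        "truth": truth.to_json(out / "truth.json"),
    }
    return paths
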