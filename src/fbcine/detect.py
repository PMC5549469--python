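"""End-expiration windowing and NCC-based ED/ES identification.

The N frames of a slice are scanned with a sliding window of one cardiac
cycle (N_f frames); the window maximizing the summed relative position
H(t) is the end-expiration interval [A, B], because the heart dwells
highest there.  Within that window, every pair of 40 x 40 patches
centered on the LV is compared by normalized cross-correlation (NCC); the
most *dissimilar* pair — the minimum of the NCC matrix — is the
(ED, ES) pair, since maximal filling and maximal contraction look most
different.  Which member is ED is decided by the larger fitted ellipse
area.

NCC here is the mean-subtracted, variance-normalized (Pearson) similarity
and lives in [-1, 1]; values are kept signed, which leaves the argmin
well-defined and strictly more discriminative than clamping to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from . import localize, lvcenter, motion
from ._util import extract_patch
from .errors import DetectionError, ParameterError, RangeError, SignalError
from .io import CineSlice, RunConfig
from .lvcenter import EllipseFit, StageFailure


@dataclass
class ExpirationWindow:
    """Frame interval [first, last] of length n_f at end-expiration (1-based)."""

    first: int
    last: int
    n_f: int
    score: float                       # sum of H(t) over the window


@dataclass
class NccMatrix:
    """Pairwise NCC over the end-expiration frames."""

    c: np.ndarray                      # (n, n), diagonal 1, symmetric
    frames: List[int]                  # 1-based frame indices, ascending
    window_size: int
    anchors: List[Tuple[int, int]]     # integer LV-center pixel per frame
    valid: np.ndarray                  # (n, n) bool; False where NCC undefined


@dataclass
class EdEsResult:
    ed: int
    es: int
    ed_area: float
    es_area: float
    window: ExpirationWindow
    ncc_min: float
    area_tiebreak: bool = False        # True when areas tied and the low-pass
                                       # corrected area (then frame order) decided


@dataclass
class SliceReport:
    """Everything detect_slice computed, successful or not."""

    result: Optional[EdEsResult]
    fits: list
    trace: Optional[motion.MotionTrace]
    n_f: Optional[int]
    window: Optional[ExpirationWindow]
    ncc: Optional[NccMatrix]
    failures: List[StageFailure] = field(default_factory=list)
    error: Optional[str] = None


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def find_end_expiration(h: np.ndarray, n_f: int) -> ExpirationWindow:
    """Window of ``n_f`` frames maximizing the summed relative position.

    All ``N - n_f + 1`` start positions are scored; ties break to the
    earliest start.  Indices are 1-based.
    """
    h = np.asarray(h, dtype=float)
    n = len(h)
    if not 1 <= n_f <= n:
        raise RangeError(f"window length {n_f} out of range 1..{n}")
    if not np.all(np.isfinite(h)):
        raise ParameterError("H(t) must be finite")
    sums = np.convolve(h, np.ones(n_f), mode="valid")
    start = int(np.argmax(sums))       # np.argmax returns the first maximum
    return ExpirationWindow(start + 1, start + n_f, int(n_f), float(sums[start]))


def ncc(f1: np.ndarray, f2: np.ndarray) -> float:
    """Mean-subtracted normalized cross-correlation of two equal-shape windows.

    Returns a value in [-1, 1], or ``nan`` when either window is constant
    (similarity undefined).
    """
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    if f1.shape != f2.shape:
        raise ParameterError(f"window shapes differ: {f1.shape} vs {f2.shape}")
    a = f1 - f1.mean()
    b = f2 - f2.mean()
    denom = np.sqrt(np.sum(a * a) * np.sum(b * b))
    if denom == 0.0:
        return float("nan")
    return float(np.sum(a * b) / denom)


def build_ncc_matrix(slc: CineSlice, fits, window: ExpirationWindow,
                     window_size: int = 40) -> NccMatrix:
    """NCC over all frame pairs in [A, B], patches anchored at the LV center.

    Each patch is ``window_size`` square, centered at the rounded per-frame
    LV center (zero-padded at image edges).  Pairs whose NCC is undefined
    (a constant patch, e.g. fully outside the image) are marked invalid.
    """
    frames = list(range(window.first, window.last + 1))
    patches, anchors = [], []
    for t in frames:
        fit = fits[t - 1]
        if fit is None or not hasattr(fit, "center"):
            raise DetectionError(f"no LV-center fit for frame {t} in the window")
        patch, _ = extract_patch(slc.frames[t - 1], fit.center, window_size)
        patches.append(patch)
        anchors.append((int(np.rint(fit.center[0])), int(np.rint(fit.center[1]))))
    n = len(frames)
    c = np.eye(n)
    valid = np.ones((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            v = ncc(patches[i], patches[j])
            if np.isnan(v):
                valid[i, j] = valid[j, i] = False
                c[i, j] = c[j, i] = np.nan
            else:
                c[i, j] = c[j, i] = v
    return NccMatrix(c, frames, int(window_size), anchors, valid)


def identify_ed_es(cmat: NccMatrix, fits) -> EdEsResult:
    """ED/ES = the most dissimilar valid frame pair, ordered by ellipse area.

    The argmin runs over valid off-diagonal entries; ties break to the
    lexicographically earliest (i, j).  The pair member with the larger
    fitted area is ED.  If areas tie exactly, the areas corrected for the
    slow (respiratory-scale) trend decide, then the earlier frame is ED.
    """
    n = len(cmat.frames)
    if n < 2:
        raise DetectionError("need at least 2 frames in the end-expiration window")
    best = None
    for i in range(n):
        for j in range(i + 1, n):
            if not cmat.valid[i, j]:
                continue
            if best is None or cmat.c[i, j] < best[0]:
                best = (cmat.c[i, j], i, j)
    if best is None:
        raise DetectionError("every frame pair in the window had undefined NCC")
    cmin, i, j = best
    ti, tj = cmat.frames[i], cmat.frames[j]
    area_i, area_j = fits[ti - 1].area, fits[tj - 1].area
    tiebreak = False
    if area_i == area_j:
        tiebreak = True
        areas = np.array([
            f.area if (f is not None and hasattr(f, "area")) else np.nan
            for f in fits
        ])
        idx = np.arange(len(areas))
        good = ~np.isnan(areas)
        areas[~good] = np.interp(idx[~good], idx[good], areas[good])
        try:
            trend = motion.hanning_smooth(areas, 2 * n + 1)
            corr = areas - trend
            area_i, area_j = corr[ti - 1], corr[tj - 1]
        except SignalError:
            pass
    if area_i > area_j or (area_i == area_j and ti < tj):
        ed, es = ti, tj
        ed_area, es_area = fits[ti - 1].area, fits[tj - 1].area
    else:
        ed, es = tj, ti
        ed_area, es_area = fits[tj - 1].area, fits[ti - 1].area
    window = ExpirationWindow(cmat.frames[0], cmat.frames[-1], n,
                              float("nan"))
    return EdEsResult(ed, es, float(ed_area), float(es_area), window,
                      float(cmin), area_tiebreak=tiebreak)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _interpolated_fit(fits, t, image_shape):
    """Placeholder fit for a failed frame: center and area interpolated."""
    idx = np.arange(len(fits))
    good = np.array([f is not None and hasattr(f, "center") for f in fits])
    rows = np.array([f.center[0] if g else np.nan for f, g in zip(fits, good)])
    cols = np.array([f.center[1] if g else np.nan for f, g in zip(fits, good)])
    areas = np.array([f.area if g else np.nan for f, g in zip(fits, good)])
    gi = idx[good]
    r = float(np.interp(t - 1, gi, rows[good]))
    c = float(np.interp(t - 1, gi, cols[good]))
    ar = float(np.interp(t - 1, gi, areas[good]))
    radius = float(np.sqrt(max(ar, 1e-6) / np.pi))
    return EllipseFit((r, c), (radius, radius), 0.0, ar)


def detect_slice(slc: CineSlice, localizer: str = "fallback",
                 config: Optional[RunConfig] = None,
                 networks=None) -> SliceReport:
    """Run the full chain: localize -> LV center -> motion -> window -> ED/ES.

    ``localizer="cnn"`` uses ``networks=(heart_net, lv_net)`` for seeding
    and falls back to the deterministic localizer on per-frame failure.
    Soft failures (too many bad frames, no periodicity, no valid NCC pair)
    are reported in the returned :class:`SliceReport` with ``result=None``;
    contract violations (e.g. a slice shorter than two requested cardiac
    cycles) raise.
    """
    cfg = config or RunConfig(localizer=localizer)
    if isinstance(cfg.nf, int) and slc.n_frames < 2 * cfg.nf:
        raise SignalError(
            f"slice has {slc.n_frames} frames; need >= 2*n_f = {2 * cfg.nf}"
        )
    use_cnn = cfg.localizer == "cnn" or localizer == "cnn"
    if use_cnn and (networks is None or len(networks) != 2):
        raise ParameterError("cnn localizer needs networks=(heart_net, lv_net)")

    fits: list = []
    failures: List[StageFailure] = []
    for t in range(1, slc.n_frames + 1):
        frame = slc.frames[t - 1]
        seed = None
        if use_cnn:
            roi = localize.predict_heart_roi(networks[0], frame)
            if roi is not None:
                pred = localize.predict_lv_mask(networks[1], roi)
                if pred is not None:
                    seed = pred.center
        if seed is None:
            pred = localize.fallback_localize(frame)
            if pred is None:
                failures.append(StageFailure("localize", "no acceptable blob", t))
                fits.append(None)
                continue
            seed = pred.center
        fit = lvcenter.locate_center(frame, seed)
        if isinstance(fit, StageFailure):
            fit.frame = t
            failures.append(fit)
            fits.append(None)
        else:
            fits.append(fit)

    def _soft_fail(stage, exc, trace=None, n_f=None, window=None):
        return SliceReport(None, fits, trace, n_f, window, None, failures,
                           error=f"{stage}: {exc}")

    try:
        h = motion.relative_position(fits, slc.frame_shape)
    except Exception as exc:
        return _soft_fail("motion.relative_position", exc)

    if isinstance(cfg.nf, int):
        n_f = cfg.nf
    else:
        areas = np.array([
            f.area if (f is not None and hasattr(f, "area")) else np.nan
            for f in fits
        ])
        idx = np.arange(len(areas))
        good = ~np.isnan(areas)
        areas[~good] = np.interp(idx[~good], idx[good], areas[good])
        try:
            n_f = motion.estimate_cardiac_period(areas)
        except Exception as exc:
            return _soft_fail("motion.estimate_cardiac_period", exc)

    if cfg.hanning_length != "auto":
        kernel = cfg.hanning_length
    else:
        # default 2*n_f+1, clamped so short slices can still be decomposed
        kernel = min(2 * n_f + 1, (slc.n_frames // 2 - 1) | 1)
    try:
        respiratory, cardiac = motion.lowpass_respiratory(h, n_f, kernel_length=kernel)
    except Exception as exc:
        return _soft_fail("motion.lowpass_respiratory", exc, n_f=n_f)
    trace = motion.MotionTrace(h, respiratory, cardiac, slc.n_frames)

    window = find_end_expiration(h, n_f)
    full_fits = [
        f if (f is not None and hasattr(f, "center")) else
        _interpolated_fit(fits, t, slc.frame_shape)
        for t, f in enumerate(fits, start=1)
    ]
    try:
        cmat = build_ncc_matrix(slc, full_fits, window, cfg.window_size)
        result = identify_ed_es(cmat, full_fits)
    except DetectionError as exc:
        return _soft_fail("detect", exc, trace=trace, n_f=n_f, window=window)
    result.window = window
    return SliceReport(result, fits, trace, n_f, window, cmat, failures)
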