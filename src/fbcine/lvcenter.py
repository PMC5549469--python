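"""LV-center refinement: region growing, convex hull, ellipse fit.

The localizer's seed is only guaranteed to be inside the blood pool, not
at its center.  This stage refines it per frame: an Otsu threshold on the
64 x 64 heart ROI separates the bright pool from myocardium/background,
4-connected region growing from the seed segments the pool, the convex
hull removes the bites that papillary muscles and trabeculations take out
of it, and a direct least-squares ellipse fit to the hull gives a
sub-pixel center plus the pool area used later to order ED before ES.

Per-frame failures (seed outside the pool, degenerate geometry) are
returned as :class:`StageFailure` records, never raised, so a single bad
frame does not abort the slice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from ._util import extract_patch
from .errors import DegenerateInputError, EllipseFitError, RangeError


@dataclass
class BloodPool:
    """A connected above-threshold region grown from a seed."""

    mask: np.ndarray                  # 2-D bool
    seed: Tuple[int, int]
    threshold: float

    @property
    def pixels(self) -> np.ndarray:
        return np.argwhere(self.mask)

    @property
    def boundary(self) -> np.ndarray:
        """Region pixels 4-adjacent to a sub-threshold or out-of-image pixel."""
        from scipy.ndimage import binary_erosion

        cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
        interior = binary_erosion(self.mask, structure=cross, border_value=0)
        return np.argwhere(self.mask & ~interior)

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class EllipseFit:
    """A fitted LV ellipse; ``center`` is sub-pixel (row, col)."""

    center: Tuple[float, float]
    semi_axes: Tuple[float, float]    # (a, b), a >= b, pixels
    angle: float                      # major-axis angle in the (row, col) plane, [0, pi)
    area: float                       # pi * a * b, pixels^2


@dataclass
class StageFailure:
    """Why a pipeline stage failed on one frame."""

    stage: str
    reason: str
    frame: Optional[int] = None


def otsu_threshold(image: np.ndarray) -> float:
    """Threshold maximizing between-class variance of the 256-bin histogram."""
    from skimage.filters import threshold_otsu

    image = np.asarray(image, dtype=float)   # force the 256-bin histogram path
    if image.size == 0 or np.unique(image).size < 2:
        raise DegenerateInputError("Otsu threshold undefined for a constant image")
    return float(threshold_otsu(image, nbins=256))


def pool_threshold(image: np.ndarray) -> float:
    """Blood-pool threshold: upper cut of a three-class Otsu partition.

    Short-axis frames hold three intensity classes — background/lung,
    myocardium, bright blood — with the blood pool by far the smallest.
    A binary Otsu split on such class-imbalanced histograms can land
    between background and myocardium, merging muscle with blood; the
    three-class generalization of the Otsu criterion separates all three,
    and its upper threshold isolates the pool.  Falls back to the binary
    threshold when the histogram cannot support three classes.
    """
    from skimage.filters import threshold_multiotsu

    image = np.asarray(image, dtype=float)
    if image.size == 0 or np.unique(image).size < 2:
        raise DegenerateInputError("threshold undefined for a constant image")
    if np.unique(image).size < 3:
        return otsu_threshold(image)
    try:
        return float(threshold_multiotsu(image, classes=3, nbins=256)[-1])
    except ValueError:
        return otsu_threshold(image)


def region_grow(image: np.ndarray, seed: Tuple[int, int],
                threshold: float) -> Optional[BloodPool]:
    """Maximal 4-connected set of pixels above ``threshold`` containing ``seed``.

    Returns ``None`` (a seed failure, not an exception) when the seed pixel
    itself is not above the threshold; the caller may re-seed.
    """
    from scipy.ndimage import label

    image = np.asarray(image, dtype=float)
    r, c = int(seed[0]), int(seed[1])
    if not (0 <= r < image.shape[0] and 0 <= c < image.shape[1]):
        raise RangeError(f"seed {seed} outside image {image.shape}")
    if image[r, c] <= threshold:
        return None
    above = image > threshold
    labels, _ = label(above, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    return BloodPool(labels == labels[r, c], (r, c), float(threshold))


def convex_hull(pool: BloodPool) -> np.ndarray:
    """Vertices (row, col) of the convex hull of the pool's pixel centers.

    Ordered counterclockwise in the (x=col, y=row) plane.  Raises
    :class:`DegenerateInputError` for fewer than 3 or collinear points.
    """
    from scipy.spatial import ConvexHull, QhullError

    pts = pool.pixels
    if len(pts) < 3:
        raise DegenerateInputError(f"hull needs >= 3 pixels; pool has {len(pts)}")
    xy = pts[:, ::-1].astype(float)          # (col, row) as (x, y)
    try:
        hull = ConvexHull(xy)
    except QhullError as exc:
        raise DegenerateInputError(f"degenerate (collinear) pool: {exc}") from exc
    return xy[hull.vertices][:, ::-1]        # back to (row, col), order kept


def hull_area_pixels(vertices: np.ndarray, pool: BloodPool) -> int:
    """Rasterized hull area: pixels whose centers fall inside the hull polygon.

    The continuous hull contains every pool pixel center by construction;
    the union with the pool mask keeps that guarantee after rasterization.
    """
    from skimage.draw import polygon2mask

    mask = polygon2mask(pool.mask.shape, vertices)
    return int((mask | pool.mask).sum())


def fit_ellipse(points: np.ndarray) -> EllipseFit:
    """Direct algebraic least-squares conic fit constrained to an ellipse."""
    from skimage.measure import EllipseModel

    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or len(points) < 5:
        raise EllipseFitError("ellipse fit needs >= 5 (row, col) points")
    model = EllipseModel.from_estimate(points[:, ::-1])   # (x=col, y=row)
    if not model:
        raise EllipseFitError("degenerate point set: conic fit failed")
    xc, yc = model.center
    a, b = model.axis_lengths
    theta = float(model.theta)
    if b > a:
        a, b = b, a
        theta += np.pi / 2
    theta = float(np.mod(theta, np.pi))
    if not (np.isfinite([xc, yc, a, b]).all() and a >= b > 0):
        raise EllipseFitError("fit did not yield a proper ellipse")
    return EllipseFit(
        center=(float(yc), float(xc)),
        semi_axes=(float(a), float(b)),
        angle=theta,
        area=float(np.pi * a * b),
    )


def locate_center(frame: np.ndarray, seed: Tuple[float, float],
                  roi_size: int = 64):
    """Refine one frame's LV center from a localizer seed.

    Runs Otsu -> region growing -> convex hull -> ellipse fit on a
    ``roi_size`` crop around the seed.  Returns an :class:`EllipseFit` in
    full-frame coordinates, or a :class:`StageFailure` naming the stage
    that failed.
    """
    frame = np.asarray(frame, dtype=float)
    roi, origin = extract_patch(frame, seed, roi_size)
    seed_roi = (
        int(np.rint(seed[0])) - origin[0],
        int(np.rint(seed[1])) - origin[1],
    )
    try:
        thr = pool_threshold(roi)
    except DegenerateInputError as exc:
        return StageFailure("otsu", str(exc))
    pool = region_grow(roi, seed_roi, thr)
    if pool is None:
        return StageFailure("region_grow", "seed pixel below Otsu threshold")
    if pool.area < 5:
        return StageFailure("region_grow", f"pool too small ({pool.area} px)")
    try:
        hull = convex_hull(pool)
    except DegenerateInputError as exc:
        return StageFailure("convex_hull", str(exc))
    try:
        fit = fit_ellipse(hull)
    except EllipseFitError as exc:
        return StageFailure("fit_ellipse", str(exc))
    return EllipseFit(
        center=(fit.center[0] + origin[0], fit.center[1] + origin[1]),
        semi_axes=fit.semi_axes,
        angle=fit.angle,
        area=fit.area,
    )


def fits_to_csv(fits, path) -> None:
    """Per-frame CSV export: frame, center, axes, angle, area, status."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame", "center_row", "center_col", "a", "b", "angle", "area", "status"])
        for i, fit in enumerate(fits, start=1):
            if isinstance(fit, EllipseFit):
                w.writerow([
                    i, f"{fit.center[0]:.4f}", f"{fit.center[1]:.4f}",
                    f"{fit.semi_axes[0]:.4f}", f"{fit.semi_axes[1]:.4f}",
                    f"{fit.angle:.4f}", f"{fit.area:.4f}", "ok",
                ])
            else:
                reason = fit.reason if isinstance(fit, StageFailure) else "missing"
                w.writerow([i, "", "", "", "", "", "", f"failed:{reason}"])
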