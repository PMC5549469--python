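"""Shared pixel-level helpers."""

from __future__ import annotations

import numpy as np


def extract_patch(frame: np.ndarray, center, size: int):
    """Crop a ``size x size`` patch anchored at the rounded ``center``.

    For even sizes the center pixel sits at patch position
    ``(size//2 - 1, size//2 - 1)`` (0-based), i.e. at (20, 20) 1-based for a
    40 x 40 window.  Out-of-image regions are zero-filled.  Returns
    ``(patch, origin)`` where ``origin`` is the full-frame (row, col) of the
    patch's top-left pixel.
    """
    r0 = int(np.rint(center[0]))
    c0 = int(np.rint(center[1]))
    lo_off = size // 2 - 1 if size % 2 == 0 else size // 2
    top, left = r0 - lo_off, c0 - lo_off
    patch = np.zeros((size, size), dtype=float)
    rows, cols = frame.shape
    src_r0, src_r1 = max(top, 0), min(top + size, rows)
    src_c0, src_c1 = max(left, 0), min(left + size, cols)
    if src_r0 < src_r1 and src_c0 < src_c1:
        patch[src_r0 - top:src_r1 - top, src_c0 - left:src_c1 - left] = \
            frame[src_r0:src_r1, src_c0:src_c1]
    return patch, (top, left)


def largest_component(mask: np.ndarray):
    """Largest 4-connected foreground component of a binary mask, or None.

    Ties on size are broken by topmost-then-leftmost bounding box.
    """
    from scipy import ndimage

    labels, n = ndimage.label(mask, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    if n == 0:
        return None
    best = None
    for lab in range(1, n + 1):
        comp = labels == lab
        size = int(comp.sum())
        rs, cs = np.nonzero(comp)
        key = (-size, rs.min(), cs.min())
        if best is None or key < best[0]:
            best = (key, comp)
    return best[1]


def centroid(mask: np.ndarray):
    """Area centroid (row, col) of a binary mask."""
    rs, cs = np.nonzero(mask)
    return float(rs.mean()), float(cs.mean())
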