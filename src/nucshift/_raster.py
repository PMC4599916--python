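"""Pixel rasterization helpers shared by the renderer and the segmenter.

Convention: images are indexed (row, col), 0-based; a pixel belongs to a
shape when its *center* satisfies the shape inequality (``<=`` on the
boundary). All helpers return ``(rows, cols)`` integer index arrays clipped
to the frame.
"""

from __future__ import annotations

import numpy as np


def _bbox(shape: tuple[int, int], center: tuple[float, float], extent: float):
    r0 = max(int(np.floor(center[0] - extent)), 0)
    r1 = min(int(np.ceil(center[0] + extent)) + 1, shape[0])
    c0 = max(int(np.floor(center[1] - extent)), 0)
    c1 = min(int(np.ceil(center[1] + extent)) + 1, shape[1])
    return r0, r1, c0, c1


def disk_pixels(shape, center, radius):
    """Pixels whose centers lie within ``radius`` of ``center``."""
    r0, r1, c0, c1 = _bbox(shape, center, radius)
    if r0 >= r1 or c0 >= c1:
        return np.empty(0, int), np.empty(0, int)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    inside = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return rr[inside], cc[inside]


def annulus_pixels(shape, center, r_inner, r_outer):
    """Pixels with ``r_inner < dist(center) <= r_outer``."""
    r0, r1, c0, c1 = _bbox(shape, center, r_outer)
    if r0 >= r1 or c0 >= c1:
        return np.empty(0, int), np.empty(0, int)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    inside = (d2 > r_inner**2) & (d2 <= r_outer**2)
    return rr[inside], cc[inside]


def ellipse_pixels(shape, center, semi_major, semi_minor, orientation):
    """Pixels inside a rotated ellipse; ``orientation`` in radians from the row axis."""
    extent = max(semi_major, semi_minor)
    r0, r1, c0, c1 = _bbox(shape, center, extent)
    if r0 >= r1 or c0 >= c1:
        return np.empty(0, int), np.empty(0, int)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr = rr - center[0]
    dc = cc - center[1]
    u = dr * np.cos(orientation) + dc * np.sin(orientation)
    v = -dr * np.sin(orientation) + dc * np.cos(orientation)
    inside = (u / semi_major) ** 2 + (v / semi_minor) ** 2 <= 1.0
    return rr[inside], cc[inside]


def disk_area(shape, center, radius) -> int:
    """Rasterized pixel count of a disk (same convention as :func:`disk_pixels`)."""
    return disk_pixels(shape, center, radius)[0].size
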