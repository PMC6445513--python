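"""Gradient-voting search-space reduction.

Fringe edges of a radially symmetric pattern have gradients pointing along
the radius, so straight lines drawn through each edge pixel along its
gradient orientation intersect at the pattern center.  Accumulating those
lines into a "line image" turns center detection into finding bright
accumulator peaks; keeping only the brightest c% of pixels shrinks the
template-matching search space by roughly a factor 100/c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "GradientField",
    "LineImage",
    "CandidateSet",
    "sobel_gradient",
    "draw_line_image",
    "select_candidates",
]


@dataclass(frozen=True)
class GradientField:
    """Horizontal (gx) and vertical (gy) Sobel responses of an image."""

    gx: np.ndarray
    gy: np.ndarray


@dataclass(frozen=True)
class LineImage:
    """Non-negative accumulator of rasterized gradient-orientation lines."""

    accumulator: np.ndarray


@dataclass(frozen=True)
class CandidateSet:
    """Pixel positions surviving pre-selection.

    ``positions`` is an (N, 2) int array of (x, y) = (column, row)
    coordinates; ``c`` the retained percentage.  Ties at the selection
    threshold are all kept, so N may slightly exceed c% of the image area.
    """

    positions: np.ndarray
    c: float

    def __len__(self) -> int:
        return len(self.positions)


def sobel_gradient(image: np.ndarray) -> GradientField:
    """Image gradient via the standard 3x3 Sobel kernels.

    Borders are handled by edge replication.  ``gx`` differentiates along
    x (columns), ``gy`` along y (rows).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {image.shape}")
    if min(image.shape) < 3:
        raise ValueError("image must be at least 3x3")
    gx = ndimage.sobel(image, axis=1, mode="nearest")
    gy = ndimage.sobel(image, axis=0, mode="nearest")
    return GradientField(gx=gx, gy=gy)


def draw_line_image(
    field: GradientField, r_max: int, magnitude_floor: float = 0.05
) -> LineImage:
    """Rasterize a line along the gradient orientation of every edge pixel.

    For every pixel whose gradient magnitude exceeds
    ``magnitude_floor * max(magnitude)``, a straight segment through the
    pixel center is drawn ``r_max`` pixels in *both* directions along the
    gradient orientation (fringe-edge gradients alternate sign between
    rings, so a one-sided line would miss the center for half the edges).
    Each covered pixel increments the accumulator by 1 per line;
    out-of-bounds portions are clipped.

    The rasterization steps along the dominant axis of the direction
    vector (Bresenham-equivalent), so a line never counts a pixel twice.
    """
    if r_max < 1:
        raise ValueError("r_max must be >= 1")
    gx, gy = field.gx, field.gy
    h, w = gx.shape
    mag = np.hypot(gx, gy)
    mmax = mag.max()
    acc = np.zeros(h * w, dtype=np.int64)
    if mmax == 0:
        return LineImage(accumulator=acc.reshape(h, w).astype(float))

    mask = mag > magnitude_floor * mmax
    if not mask.any():
        return LineImage(accumulator=acc.reshape(h, w).astype(float))
    ys, xs = np.nonzero(mask)
    m = mag[mask]
    ux = gx[mask] / m
    uy = gy[mask] / m
    major = np.maximum(np.abs(ux), np.abs(uy))
    sx = ux / major  # step vector with dominant component +-1
    sy = uy / major
    k_lim = np.floor(r_max * major).astype(np.int64)  # Euclidean half-length r_max

    acc = np.zeros(h * w, dtype=np.int64)
    kk = np.arange(-r_max, r_max + 1)
    block = max(1, int(4e6 // (2 * r_max + 1)))  # bound peak memory
    for start in range(0, len(xs), block):
        sl = slice(start, start + block)
        px = np.rint(xs[sl] + kk[:, None] * sx[sl]).astype(np.int64)
        py = np.rint(ys[sl] + kk[:, None] * sy[sl]).astype(np.int64)
        ok = (
            (np.abs(kk)[:, None] <= k_lim[sl])
            & (px >= 0)
            & (px < w)
            & (py >= 0)
            & (py < h)
        )
        acc += np.bincount((py * w + px)[ok], minlength=h * w)
    return LineImage(accumulator=acc.reshape(h, w).astype(float))


def select_candidates(line_image: LineImage, c: float) -> CandidateSet:
    """Keep the brightest ``c`` percent of accumulator pixels.

    Positions at or above the (100 - c)th percentile of accumulator values
    are retained, excluding zero-valued pixels; threshold ties are all
    included.  An all-zero accumulator yields an empty (valid) set.
    """
    if not (0 < c <= 100):
        raise ValueError("c must be in (0, 100]")
    acc = line_image.accumulator
    if acc.max() == 0:
        return CandidateSet(positions=np.empty((0, 2), dtype=np.int64), c=c)
    threshold = np.percentile(acc, 100.0 - c)
    keep = (acc >= threshold) & (acc > 0)
    ys, xs = np.nonzero(keep)
    return CandidateSet(positions=np.column_stack([xs, ys]), c=c)
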