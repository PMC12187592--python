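"""Fixed per-proposal pixel descriptors — the test-scale backbone front end.

The backbone contract is any map from an image to an R x d feature matrix
aligned with the proposal grid. At test scale we pool raw pixels per box
(integral-image box means are exact and fast), yielding for each proposal:
per-channel means, gray-level variance, a 4 x 4 grid of gray block means
(coarse shape of the region), and the normalized box geometry. A trainable
MLP feature extractor (see `wsmial.model`) then maps these descriptors to
the region features the scoring heads consume. Descriptors depend only on
(pixels, grid), never on labels or ground-truth boxes.
"""

from __future__ import annotations

import numpy as np

from .proposals import ProposalGrid

N_BLOCKS = 4  # 4x4 block means per box, for gray and for redness
DESCRIPTOR_DIM = 3 + 1 + 2 * N_BLOCKS * N_BLOCKS + 2 + 4


def _integral(img: np.ndarray) -> np.ndarray:
    """Zero-padded 2-D integral image: I[y, x] = sum of img[:y, :x]."""
    out = np.zeros((img.shape[0] + 1, img.shape[1] + 1), dtype=np.float64)
    np.cumsum(np.cumsum(img, axis=0), axis=1, out=out[1:, 1:])
    return out


def _box_sums(I: np.ndarray, x0, y0, x1, y1) -> np.ndarray:
    return I[y1, x1] - I[y0, x1] - I[y1, x0] + I[y0, x0]


def region_descriptors(pixels: np.ndarray, grid: ProposalGrid) -> np.ndarray:
    """Compute the (R, DESCRIPTOR_DIM) descriptor matrix for one image."""
    if pixels.shape[0] != grid.image_size or pixels.shape[1] != grid.image_size:
        raise ValueError("pixel array does not match the grid's image size")
    img = pixels.astype(np.float64) / 255.0
    gray = img.mean(axis=2)
    red = img[:, :, 0] - img[:, :, 1]   # tongue tissue is strongly red-green
    integrals = [_integral(img[:, :, c]) for c in range(3)]
    ig = _integral(gray)
    ig2 = _integral(gray * gray)
    ir = _integral(red)

    boxes = grid.proposals
    x0, y0, x1, y1 = boxes[:, 0], boxes[:, 1], boxes[:, 2], boxes[:, 3]
    area = ((x1 - x0) * (y1 - y0)).astype(np.float64)

    feats = np.empty((grid.R, DESCRIPTOR_DIM), dtype=np.float64)
    col = 0
    for I in integrals:                       # per-channel means
        feats[:, col] = _box_sums(I, x0, y0, x1, y1) / area - 0.5
        col += 1
    mean_g = _box_sums(ig, x0, y0, x1, y1) / area
    mean_g2 = _box_sums(ig2, x0, y0, x1, y1) / area
    feats[:, col] = np.maximum(mean_g2 - mean_g ** 2, 0.0)  # gray variance
    col += 1

    # 4x4 block means of gray and redness inside each box
    kx = np.round(x0[:, None] + (x1 - x0)[:, None]
                  * np.arange(N_BLOCKS + 1) / N_BLOCKS).astype(np.int64)
    ky = np.round(y0[:, None] + (y1 - y0)[:, None]
                  * np.arange(N_BLOCKS + 1) / N_BLOCKS).astype(np.int64)
    for I, shift in ((ig, 0.5), (ir, 0.0)):
        for bi in range(N_BLOCKS):
            for bj in range(N_BLOCKS):
                bx0, bx1 = kx[:, bj], kx[:, bj + 1]
                by0, by1 = ky[:, bi], ky[:, bi + 1]
                barea = ((bx1 - bx0) * (by1 - by0)).astype(np.float64)
                s = _box_sums(I, bx0, by0, bx1, by1)
                feats[:, col] = np.where(
                    barea > 0, s / np.maximum(barea, 1), 0.0) - shift
                col += 1

    # box-vs-surround contrast: mean inside minus mean of a 3 px margin ring
    m = 3
    sx0 = np.maximum(x0 - m, 0)
    sy0 = np.maximum(y0 - m, 0)
    sx1 = np.minimum(x1 + m, grid.image_size)
    sy1 = np.minimum(y1 + m, grid.image_size)
    sarea = ((sx1 - sx0) * (sy1 - sy0)).astype(np.float64)
    ring_area = np.maximum(sarea - area, 1.0)
    for I in (ig, ir):
        inner = _box_sums(I, x0, y0, x1, y1)
        outer = _box_sums(I, sx0, sy0, sx1, sy1)
        feats[:, col] = inner / area - (outer - inner) / ring_area
        col += 1

    n = float(grid.image_size)
    feats[:, col] = (x0 + x1) / (2 * n) - 0.5   # center x
    feats[:, col + 1] = (y0 + y1) / (2 * n) - 0.5
    feats[:, col + 2] = (x1 - x0) / n
    feats[:, col + 3] = (y1 - y0) / n
    return feats


def descriptor_batch(samples, grid: ProposalGrid) -> np.ndarray:
    """Stack descriptors for a list of samples into (B, R, D)."""
    return np.stack([region_descriptors(s.pixels, grid) for s in samples])
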