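"""One-stage, segmentation-free instance proposal generation.

The image is divided into an S x S grid (S = image size / downsampling
factor); every cell contributes one candidate box per anchor, centered on
the cell center with the anchor's width and height and clipped to the
image. Anchor dimensions come from k-means clustering of box widths and
heights. No objectness pre-filtering is applied: without ground-truth
boxes a proper IoU-based confidence is undefined, so all grid proposals
flow to the scoring heads, which learn the confidence weakly from
image-level labels.

Boxes are 0-based half-open pixel rectangles ``(x0, y0, x1, y1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

# Nine-cluster anchor preset for full-size clinical photographs,
# three scales with three anchors each (area-ascending).
PUBLISHED_ANCHORS: tuple[tuple[int, int], ...] = (
    (37, 19), (20, 41), (25, 36), (37, 35), (27, 52),
    (21, 69), (34, 47), (37, 64), (32, 90),
)

ANCHOR_PRESETS: dict[str, tuple[tuple[int, int], ...]] = {
    "published9": PUBLISHED_ANCHORS,
    # single shallow scale for 64 px synthetic images; spans the default
    # synthetic notch diameter range of 6-14 px
    "tiny64": ((8, 8), (12, 10), (10, 14)),
}


@dataclass(frozen=True)
class AnchorSet:
    """K-means anchor dimensions, assigned evenly to scales."""

    anchors: tuple[tuple[int, int], ...]
    n_scales: int = 1

    def __post_init__(self):
        if not self.anchors:
            raise ValueError("anchor set must not be empty")
        for w, h in self.anchors:
            if w <= 0 or h <= 0:
                raise ValueError("anchor dimensions must be positive")
        if len(self.anchors) % self.n_scales != 0:
            raise ValueError("anchors must distribute evenly across scales")

    @property
    def n_clusters(self) -> int:
        return len(self.anchors)

    def at_scale(self, scale: int = 0) -> tuple[tuple[int, int], ...]:
        """Anchors of one scale; scale 0 is the shallow (smallest-area) one."""
        per = len(self.anchors) // self.n_scales
        if not 0 <= scale < self.n_scales:
            raise ValueError("scale index out of range")
        ordered = sorted(self.anchors, key=lambda wh: (wh[0] * wh[1], wh))
        return tuple(ordered[scale * per:(scale + 1) * per])

    @classmethod
    def preset(cls, name: str) -> "AnchorSet":
        if name not in ANCHOR_PRESETS:
            raise KeyError(f"unknown anchor preset {name!r}")
        anchors = ANCHOR_PRESETS[name]
        return cls(anchors=anchors, n_scales=3 if name == "published9" else 1)


def kmeans_anchors(box_dims, n_clusters: int, seed: int) -> AnchorSet:
    """Cluster (w, h) box dimensions into anchor centroids.

    Uses Lloyd's algorithm with a seeded sample of the data as the initial
    centroids; centroids are rounded to integer pixels and sorted by area
    ascending.
    """
    dims = np.asarray(box_dims, dtype=np.float64)
    if dims.ndim != 2 or dims.shape[1] != 2:
        raise ValueError("box_dims must be a list of (w, h) pairs")
    if len(dims) < n_clusters:
        raise ValueError("need at least n_clusters box dimensions")
    rng = np.random.default_rng(seed)
    unique = np.unique(dims, axis=0)
    if len(unique) < n_clusters:
        raise ValueError("need at least n_clusters distinct box dimensions")
    init = unique[rng.choice(len(unique), size=n_clusters, replace=False)]
    km = KMeans(n_clusters=n_clusters, init=init, n_init=1, max_iter=300,
                tol=0.0, algorithm="lloyd")
    km.fit(dims)
    centroids = np.rint(km.cluster_centers_).astype(int)
    centroids = np.maximum(centroids, 1)
    order = np.lexsort((centroids[:, 1], centroids[:, 0],
                        centroids[:, 0] * centroids[:, 1]))
    anchors = tuple((int(w), int(h)) for w, h in centroids[order])
    return AnchorSet(anchors=anchors, n_scales=1)


@dataclass(frozen=True)
class ProposalGrid:
    """All candidate boxes for one image geometry.

    ``proposals`` is an (R, 4) int array in deterministic row-major cell
    order, anchors varying fastest within a cell.
    """

    image_size: int
    S: int
    proposals: np.ndarray
    cell_index: np.ndarray
    anchor_index: np.ndarray
    anchors: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    @property
    def R(self) -> int:
        return self.proposals.shape[0]


def build_grid(image_size: int, downsample: int, anchors: AnchorSet,
               scale: int = 0) -> ProposalGrid:
    """Lay anchor boxes on every grid-cell center and clip to the image."""
    if image_size <= 0 or downsample <= 0:
        raise ValueError("image_size and downsample must be positive")
    if image_size % downsample != 0:
        raise ValueError(
            f"image_size {image_size} is not divisible by downsample {downsample}")
    S = image_size // downsample
    scale_anchors = anchors.at_scale(scale)
    boxes = []
    cells = []
    anchor_ids = []
    for i in range(S):          # row-major cells
        for j in range(S):
            cx = (j + 0.5) * downsample
            cy = (i + 0.5) * downsample
            for a, (w, h) in enumerate(scale_anchors):
                x0 = int(np.clip(round(cx - w / 2), 0, image_size - 1))
                y0 = int(np.clip(round(cy - h / 2), 0, image_size - 1))
                x1 = int(np.clip(round(cx + w / 2), x0 + 1, image_size))
                y1 = int(np.clip(round(cy + h / 2), y0 + 1, image_size))
                boxes.append((x0, y0, x1, y1))
                cells.append(i * S + j)
                anchor_ids.append(a)
    return ProposalGrid(
        image_size=image_size,
        S=S,
        proposals=np.asarray(boxes, dtype=np.int64),
        cell_index=np.asarray(cells, dtype=np.int64),
        anchor_index=np.asarray(anchor_ids, dtype=np.int64),
        anchors=scale_anchors,
    )


def proposals_to_coco(grid: ProposalGrid, image_id: int = 0) -> dict:
    """Export the proposal boxes as a COCO-style annotation dictionary."""
    annotations = []
    for k, (x0, y0, x1, y1) in enumerate(grid.proposals.tolist()):
        annotations.append({
            "id": k,
            "image_id": image_id,
            "category_id": 1,
            "bbox": [x0, y0, x1 - x0, y1 - y0],
            "area": (x1 - x0) * (y1 - y0),
            "iscrowd": 0,
        })
    return {
        "images": [{"id": image_id, "width": grid.image_size,
                    "height": grid.image_size}],
        "categories": [{"id": 1, "name": "proposal"}],
        "annotations": annotations,
    }
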