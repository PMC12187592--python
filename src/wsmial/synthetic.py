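"""Seeded generator of synthetic tongue-like images.

Real tooth-marked-tongue photographs show an elliptical tongue body on a
cluttered face/background, with tooth pressure leaving concave notches —
accompanied by a local color change — along the lateral edges of the
tongue. Clinically most marks sit on the two sides rather than the tip.
This module emulates exactly that phenomenology at small scale: a pinkish
ellipse over background clutter, circular "bites" subtracted from the
ellipse boundary with a darkened halo (positives), and distractor
structures that appear in *both* classes — a band of teeth above the
tongue, lip arcs around it, dark cracks and ecchymosis-like spots inside
it — so that a classifier cannot shortcut around instance-level evidence.

Every image-level label is positive iff at least one notch was drawn, and
each notch's bounding box is recorded for evaluation-only use. All
randomness flows from the single spec seed; identical spec + seed yields a
byte-identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .data import DataPools, ImageSample, LABELED, UNLABELED

DEFAULT_POSITIVE_FRACTION = 401 / 1108  # clinical class balance


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study population.

    The default positive fraction mirrors the clinical screening balance of
    401 tooth-marked among 1,108 tongues. Notch diameters default to
    6–14 px on a 64 px image, i.e. roughly 10–20% of the tongue width —
    small lateral marks, matching the shallow-scale detection regime.
    """

    image_size: int = 64
    positive_fraction: float = DEFAULT_POSITIVE_FRACTION
    notch_count_range: tuple[int, int] = (1, 5)
    notch_size_range: tuple[int, int] = (6, 14)
    distractor_kinds: tuple[str, ...] = ("teeth", "lips", "cracks", "spots")
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ConfigurationError("image_size must be >= 32")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ConfigurationError("positive_fraction must lie in [0, 1]")
        lo, hi = self.notch_count_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("notch_count_range must be 1 <= lo <= hi")
        slo, shi = self.notch_size_range
        if not (2 <= slo <= shi <= self.image_size // 2):
            raise ConfigurationError("notch_size_range out of bounds")
        unknown = set(self.distractor_kinds) - {"teeth", "lips", "cracks", "spots"}
        if unknown:
            raise ConfigurationError(f"unknown distractor kinds: {sorted(unknown)}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")


def _render_image(rng: np.random.Generator, spec: SyntheticSpec,
                  positive: bool) -> tuple[np.ndarray, list[tuple[int, int, int, int]]]:
    n = spec.image_size
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)

    # -- background clutter (muted skin tones + low-frequency texture)
    img = np.empty((n, n, 3))
    base = np.array([0.52, 0.42, 0.38])
    tex = gaussian_filter(rng.normal(0.0, 1.0, (n, n)), sigma=n / 16)
    for c in range(3):
        img[:, :, c] = base[c] + 0.10 * tex
    for _ in range(rng.integers(2, 5)):
        bx, by = rng.uniform(0, n, 2)
        br = rng.uniform(n / 12, n / 5)
        blob = ((xx - bx) ** 2 + (yy - by) ** 2) <= br ** 2
        color = base + rng.uniform(-0.12, 0.12, 3)
        img[blob] = color

    background = img.copy()

    # -- tongue ellipse
    cx = n / 2 + rng.uniform(-0.03, 0.03) * n
    cy = 0.56 * n + rng.uniform(-0.03, 0.03) * n
    ax = (0.27 + rng.uniform(-0.02, 0.02)) * n   # horizontal semi-axis
    by_ = (0.34 + rng.uniform(-0.02, 0.02)) * n  # vertical semi-axis
    e = ((xx - cx) / ax) ** 2 + ((yy - cy) / by_) ** 2
    tongue = e <= 1.0
    tongue_color = np.array([0.78, 0.45, 0.47]) + rng.uniform(-0.03, 0.03, 3)
    grad = 1.0 - 0.12 * (yy - (cy - by_)) / (2 * by_)  # brighter tip
    for c in range(3):
        img[:, :, c] = np.where(tongue, tongue_color[c] * grad, img[:, :, c])

    # -- distractors (drawn for positives and negatives alike)
    kinds = spec.distractor_kinds
    if "lips" in kinds:
        ring = (e > 1.0) & (e <= 1.28) & (yy < cy)
        lip_color = np.array([0.48, 0.24, 0.26])
        img[ring] = lip_color + rng.uniform(-0.03, 0.03, 3)
    if "teeth" in kinds:
        ty = cy - by_ - rng.uniform(0.04, 0.08) * n
        tooth_w = max(2, int(0.05 * n))
        for k in range(int(rng.integers(4, 7))):
            tx = cx + (k - 2.5) * (tooth_w + 1) + rng.uniform(-1, 1)
            box = (xx >= tx) & (xx < tx + tooth_w) & \
                  (yy >= ty) & (yy < ty + 0.06 * n)
            img[box & ~tongue] = np.array([0.9, 0.88, 0.84])
    if "cracks" in kinds and rng.random() < 0.7:
        px = cx + rng.uniform(-0.05, 0.05) * n
        crack = np.zeros((n, n), dtype=bool)
        for t in np.linspace(-0.5, 0.6, 40):
            qy = cy + t * by_
            qx = px + 0.04 * n * np.sin(t * 9 + rng.uniform(0, 6))
            crack |= (np.abs(xx - qx) < 0.8) & (np.abs(yy - qy) < 1.2)
        img[crack & tongue] *= 0.55
    if "spots" in kinds:
        for _ in range(int(rng.integers(1, 4))):
            t = rng.uniform(0, 2 * np.pi)
            rr = rng.uniform(0, 0.55)
            sx = cx + np.sqrt(rr) * ax * np.cos(t)
            sy = cy + np.sqrt(rr) * by_ * np.sin(t)
            sr = rng.uniform(1.0, 2.0)
            spot = ((xx - sx) ** 2 + (yy - sy) ** 2) <= sr ** 2
            img[spot & tongue] *= 0.5

    # -- notches: circular bites out of the lateral boundary + dark halo
    boxes: list[tuple[int, int, int, int]] = []
    if positive:
        count = int(rng.integers(spec.notch_count_range[0],
                                 spec.notch_count_range[1] + 1))
        for _ in range(count):
            # lateral bias: sample the ellipse parameter near the left or
            # right edge (most clinical marks sit on the two sides)
            if rng.random() < 0.9:
                center = 0.0 if rng.random() < 0.5 else np.pi
                t = center + rng.uniform(-0.8, 0.8)
            else:
                t = rng.uniform(0, 2 * np.pi)
            px = cx + ax * np.cos(t)
            py = cy + by_ * np.sin(t)
            rho = rng.uniform(*spec.notch_size_range) / 2.0
            d2 = (xx - px) ** 2 + (yy - py) ** 2
            bite = (d2 <= rho ** 2) & tongue
            halo = (d2 <= (rho + 2.0) ** 2) & ~(d2 <= rho ** 2) & tongue
            img[bite] = background[bite]          # tongue matter removed
            img[halo] *= 0.55                     # local color change
            x0 = int(np.clip(np.floor(px - rho), 0, n - 1))
            y0 = int(np.clip(np.floor(py - rho), 0, n - 1))
            x1 = int(np.clip(np.ceil(px + rho), x0 + 1, n))
            y1 = int(np.clip(np.ceil(py + rho), y0 + 1, n))
            boxes.append((x0, y0, x1, y1))

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    pixels = (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)
    return pixels, boxes


def generate_dataset(spec: SyntheticSpec, n_images: int) -> list[ImageSample]:
    """Draw ``n_images`` seeded samples; each image is positive with
    probability ``spec.positive_fraction`` and positives carry >= 1 notch
    with its ground-truth box (evaluation only).
    """
    if n_images < 1:
        raise ConfigurationError("n_images must be >= 1")
    rng = np.random.default_rng(spec.seed)
    samples: list[ImageSample] = []
    width = max(4, len(str(n_images)))
    for i in range(n_images):
        positive = bool(rng.random() < spec.positive_fraction)
        pixels, boxes = _render_image(rng, spec, positive)
        samples.append(ImageSample(
            id=f"syn{i:0{width}d}",
            pixels=pixels,
            label_state=LABELED,
            y=int(positive),
            gt_boxes=boxes,
        ))
    return samples


def split_pools(samples: list[ImageSample], test_n: int,
                initial_labeled_frac: float, seed: int) -> DataPools:
    """Partition samples into a held-out test set D_t, an initial labeled
    pool D_l, and an unlabeled pool D_u whose labels move into the hidden
    vault. D_pl starts empty.
    """
    if test_n >= len(samples):
        raise ValueError("test_n must be smaller than the number of samples")
    if not 0.0 <= initial_labeled_frac <= 1.0:
        raise ValueError("initial_labeled_frac must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    pools = DataPools()
    test_idx = set(order[:test_n].tolist())
    train_idx = [int(i) for i in order[test_n:]]
    n_init = int(initial_labeled_frac * len(train_idx))
    labeled_idx = set(train_idx[:n_init])
    for i, sample in enumerate(samples):
        if i in test_idx:
            pools.test[sample.id] = sample
        elif i in labeled_idx:
            pools.labeled[sample.id] = sample
        else:
            truth = sample.y
            sample.y = None
            sample.label_state = UNLABELED
            pools.unlabeled[sample.id] = sample
            pools._vault[sample.id] = int(truth)
    pools.check_invariants()
    return pools
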