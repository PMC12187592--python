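"""Dataset manifests, YAML configuration, and model checkpoints.

A dataset on disk is a directory of PNG images plus a CSV manifest with
columns ``id, image_path, label, split`` (label in {0, 1, NA}; NA rows
seed the unlabeled pool) and an optional COCO JSON of evaluation-only
boxes. These formats interoperate with standard annotation tools.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .config import ConfigError, WSMIALConfig
from .data import DataPools, ImageSample, LABELED, UNLABELED

CHECKPOINT_VERSION = 1


class ManifestError(ValueError):
    pass


# --------------------------------------------------------------------- #
# dataset writing                                                       #
# --------------------------------------------------------------------- #
def save_dataset(samples: list[ImageSample], out_dir: str | Path,
                 splits: dict[str, str] | None = None) -> Path:
    """Write PNG images, a CSV manifest and a COCO box file; returns the
    manifest path. ``splits`` maps sample id -> {train, test} (default all
    train)."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    coco_images = []
    coco_annotations = []
    ann_id = 0
    for sample in samples:
        rel = f"images/{sample.id}.png"
        Image.fromarray(sample.pixels).save(out / rel)
        label = "NA" if sample.y is None else str(int(sample.y))
        split = (splits or {}).get(sample.id, "train")
        rows.append({"id": sample.id, "image_path": rel,
                     "label": label, "split": split})
        coco_images.append({"id": sample.id,
                            "width": sample.pixels.shape[1],
                            "height": sample.pixels.shape[0]})
        for (x0, y0, x1, y1) in sample.gt_boxes:
            coco_annotations.append({
                "id": ann_id, "image_id": sample.id, "category_id": 1,
                "bbox": [x0, y0, x1 - x0, y1 - y0],
                "area": (x1 - x0) * (y1 - y0), "iscrowd": 0,
            })
            ann_id += 1
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    with open(out / "boxes.json", "w") as fh:
        json.dump({"images": coco_images,
                   "categories": [{"id": 1, "name": "tooth_mark"}],
                   "annotations": coco_annotations}, fh)
    return manifest


# --------------------------------------------------------------------- #
# manifest loading                                                      #
# --------------------------------------------------------------------- #
def load_manifest(path: str | Path, load_boxes: bool = True) -> DataPools:
    """Read a manifest into a DataPools skeleton.

    Labeled train rows seed D_l, NA train rows seed D_u (with no hidden
    truth — only interactive annotation could label them), test rows seed
    D_t. All validation problems are reported together with row numbers.
    """
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"id", "image_path", "label", "split"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ManifestError(f"manifest missing columns: {sorted(missing_cols)}")

    errors: list[str] = []
    seen: set[str] = set()
    root = path.parent
    pools = DataPools()
    boxes: dict[str, list] = {}
    box_file = root / "boxes.json"
    if load_boxes and box_file.exists():
        with open(box_file) as fh:
            coco = json.load(fh)
        for ann in coco.get("annotations", []):
            x, y, w, h = ann["bbox"]
            boxes.setdefault(str(ann["image_id"]), []).append(
                (int(x), int(y), int(x + w), int(y + h)))

    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        sid = row.id
        if sid in seen:
            errors.append(f"row {row_no}: duplicate id {sid!r}")
            continue
        seen.add(sid)
        if row.label not in ("0", "1", "NA"):
            errors.append(f"row {row_no}: label {row.label!r} not in {{0,1,NA}}")
            continue
        if row.split not in ("train", "test"):
            errors.append(f"row {row_no}: split {row.split!r} not in "
                          "{train,test}")
            continue
        img_path = root / row.image_path
        if not img_path.exists():
            errors.append(f"row {row_no}: missing image file {row.image_path}")
            continue
        if row.split == "test" and row.label == "NA":
            errors.append(f"row {row_no}: test rows need a label")
            continue
        pixels = np.asarray(Image.open(img_path).convert("RGB"))
        sample = ImageSample(
            id=sid, pixels=pixels,
            label_state=UNLABELED if row.label == "NA" else LABELED,
            y=None if row.label == "NA" else int(row.label),
            gt_boxes=boxes.get(sid, []),
        )
        if row.split == "test":
            pools.test[sid] = sample
        elif row.label == "NA":
            pools.unlabeled[sid] = sample
        else:
            pools.labeled[sid] = sample
    if errors:
        raise ManifestError("; ".join(errors))
    return pools


# --------------------------------------------------------------------- #
# configuration                                                         #
# --------------------------------------------------------------------- #
def load_config(path: str | Path) -> WSMIALConfig:
    """Read a YAML config; unset keys fall back to the published defaults,
    unknown keys are rejected."""
    with open(path) as fh:
        values = yaml.safe_load(fh)
    if values is None:
        values = {}
    if not isinstance(values, dict):
        raise ConfigError("config file must contain a mapping")
    return WSMIALConfig.from_dict(values)


def config_hash(config: WSMIALConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


# --------------------------------------------------------------------- #
# checkpoints                                                           #
# --------------------------------------------------------------------- #
def save_checkpoint(model, config: WSMIALConfig, path: str | Path) -> None:
    """Serialize model parameters with an embedded version and config hash.

    Works for a single detector or an ensemble; the member count is stored
    so loading can rebuild the same structure.
    """
    n_members = len(getattr(model, "members", [model]))
    arrays = {f"param_{i}": a for i, a in enumerate(model.state_arrays())}
    meta = json.dumps({"version": CHECKPOINT_VERSION,
                       "config_hash": config_hash(config),
                       "n_members": n_members,
                       "config": config.to_dict()})
    np.savez(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path, model, config: WSMIALConfig | None = None):
    """Load parameters into `model`; returns the checkpoint's config dict."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError("unsupported checkpoint version")
        if config is not None and meta["config_hash"] != config_hash(config):
            raise ValueError("checkpoint was written with a different config")
        n = len([k for k in data.files if k.startswith("param_")])
        model.load_state_arrays([data[f"param_{i}"] for i in range(n)])
    return meta


def checkpoint_meta(path: str | Path) -> dict:
    """Read a checkpoint's metadata without loading parameters."""
    with np.load(path) as data:
        return json.loads(bytes(data["_meta"]).decode())
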