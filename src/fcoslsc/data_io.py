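"""COCO-format detection I/O, LabelMe conversion, splitting and preprocessing.

Boxes are continuous corner coordinates ``(x_min, y_min, x_max, y_max)``,
0-based, with exclusive-edge semantics for area and IoU; the COCO
``[x, y, width, height]`` convention appears only at the serialization
boundary.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from PIL import Image

from .config import PreprocessConfig

logger = logging.getLogger("fcoslsc")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Box:
    """Axis-aligned box in continuous pixel corner coordinates."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self):
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(f"degenerate box {self}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> Tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def to_xywh(self) -> List[float]:
        return [self.x_min, self.y_min, self.width, self.height]

    @classmethod
    def from_xywh(cls, xywh: Sequence[float]) -> "Box":
        x, y, w, h = xywh
        return cls(x, y, x + w, y + h)

    def clip(self, width: float, height: float) -> "Box":
        return Box(max(0.0, self.x_min), max(0.0, self.y_min),
                   min(float(width), self.x_max), min(float(height), self.y_max))

    def as_array(self) -> np.ndarray:
        return np.array([self.x_min, self.y_min, self.x_max, self.y_max])


def box_iou(a: Box, b: Box) -> float:
    iw = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    ih = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (a.area + b.area - inter)


@dataclass
class ImageSample:
    image_id: int
    filename: str
    width: int
    height: int
    boxes: List[Box] = field(default_factory=list)
    labels: List[int] = field(default_factory=list)
    image: Optional[np.ndarray] = None  # HxWx3, uint8 on disk / float in pipeline

    def load_image(self, root: Path) -> np.ndarray:
        if self.image is None:
            with Image.open(Path(root) / self.filename) as im:
                self.image = np.asarray(im.convert("RGB"))
        return self.image


@dataclass
class DatasetSplit:
    train: List[ImageSample]
    val: List[ImageSample]
    ratio: Tuple[float, float]


# ---------------------------------------------------------------------------
# COCO read / write
# ---------------------------------------------------------------------------

def read_coco(path) -> Tuple[List[ImageSample], Dict[int, str]]:
    """Read a COCO detection JSON into samples plus a category table.

    Annotations are converted from ``[x, y, w, h]`` to corner boxes and
    keyed by ``image_id``; an annotation referencing an unknown image is
    a validation error naming the offending id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"COCO file not found: {path}")
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("images", "annotations", "categories"):
        if key not in doc:
            raise ValueError(f"not a COCO detection file (missing '{key}'): {path}")
    categories = {int(c["id"]): c["name"] for c in doc["categories"]}
    samples: Dict[int, ImageSample] = {}
    for im in doc["images"]:
        sid = int(im["id"])
        samples[sid] = ImageSample(
            image_id=sid, filename=im["file_name"],
            width=int(im["width"]), height=int(im["height"]))
    for ann in doc["annotations"]:
        iid = int(ann["image_id"])
        if iid not in samples:
            raise ValueError(f"annotation {ann.get('id')} references unknown image_id {iid}")
        cid = int(ann["category_id"])
        if cid not in categories:
            raise ValueError(f"annotation {ann.get('id')} references unknown category_id {cid}")
        box = Box.from_xywh(ann["bbox"]).clip(samples[iid].width, samples[iid].height)
        samples[iid].boxes.append(box)
        samples[iid].labels.append(cid)
    return [samples[k] for k in sorted(samples)], categories


def write_coco(samples: Sequence[ImageSample], categories: Dict[int, str], path) -> dict:
    doc = {
        "images": [
            {"id": s.image_id, "file_name": s.filename,
             "width": s.width, "height": s.height}
            for s in samples
        ],
        "annotations": [],
        "categories": [{"id": cid, "name": name} for cid, name in sorted(categories.items())],
    }
    ann_id = 1
    for s in samples:
        for box, label in zip(s.boxes, s.labels):
            doc["annotations"].append({
                "id": ann_id, "image_id": s.image_id, "category_id": int(label),
                "bbox": [round(v, 6) for v in box.to_xywh()],
                "area": round(box.area, 6), "iscrowd": 0,
            })
            ann_id += 1
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
    return doc


def write_coco_results(detections: Sequence[dict], path):
    """Write a standard COCO results list (image_id, category_id, bbox, score)."""
    with open(path, "w") as fh:
        json.dump(list(detections), fh, indent=1)


# ---------------------------------------------------------------------------
# LabelMe conversion
# ---------------------------------------------------------------------------

def convert_labelme(directory, category_map: Dict[str, int]) -> Tuple[dict, dict]:
    """Convert a directory of LabelMe per-image JSON files to one COCO document.

    Every polygon/rectangle shape becomes one annotation whose bbox is the
    tight axis-aligned bound of its points.  Ids are assigned sequentially
    and deterministically: files sorted by name, shapes in file order.
    Shapes with fewer than two points are skipped with a warning and
    counted in the returned summary.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix == ".json")
    doc = {"images": [], "annotations": [],
           "categories": [{"id": cid, "name": name}
                          for name, cid in sorted(category_map.items(), key=lambda kv: kv[1])]}
    summary = {"files": 0, "annotations": 0, "skipped_shapes": 0}
    ann_id = 1
    for img_id, path in enumerate(files, start=1):
        with open(path) as fh:
            lm = json.load(fh)
        width = int(lm.get("imageWidth", 0))
        height = int(lm.get("imageHeight", 0))
        doc["images"].append({
            "id": img_id,
            "file_name": lm.get("imagePath", path.with_suffix(".png").name),
            "width": width, "height": height,
        })
        summary["files"] += 1
        for shape in lm.get("shapes", []):
            pts = shape.get("points", [])
            if len(pts) < 2:
                logger.warning("skipping shape with <2 points in %s", path.name)
                summary["skipped_shapes"] += 1
                continue
            xs = [p[0] for p in pts]
            ys = [p[1] for p in pts]
            x0, y0, x1, y1 = min(xs), min(ys), max(xs), max(ys)
            label = shape.get("label", "")
            if label not in category_map:
                raise KeyError(f"label '{label}' in {path.name} missing from category_map")
            doc["annotations"].append({
                "id": ann_id, "image_id": img_id,
                "category_id": category_map[label],
                "bbox": [x0, y0, x1 - x0, y1 - y0],
                "area": (x1 - x0) * (y1 - y0), "iscrowd": 0,
            })
            ann_id += 1
            summary["annotations"] += 1
    return doc, summary


# ---------------------------------------------------------------------------
# Dataset split
# ---------------------------------------------------------------------------

def split_dataset(samples: Sequence[ImageSample], ratio=(0.7, 0.3), seed=0) -> DatasetSplit:
    """Seeded random 7:3-style split; |train| = round-half-up(ratio_train * N)."""
    n = len(samples)
    if n < 2:
        raise ValueError("need at least 2 samples to form two non-empty splits")
    r_train = ratio[0] / (ratio[0] + ratio[1])
    if not 0.0 < r_train < 1.0:
        raise ValueError("train ratio must lie strictly between 0 and 1")
    n_train = int(math.floor(r_train * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    order = np.random.default_rng(seed).permutation(n)
    train = [samples[i] for i in order[:n_train]]
    val = [samples[i] for i in order[n_train:]]
    return DatasetSplit(train=train, val=val, ratio=(r_train, 1.0 - r_train))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def _pad_to_divisor(n: int, d: int) -> int:
    return ((n + d - 1) // d) * d


def flip_box(box: Box, width: float) -> Box:
    return Box(width - box.x_max, box.y_min, width - box.x_min, box.y_max)


def preprocess(sample: ImageSample, train_mode: bool, cfg: PreprocessConfig = None,
               rng: Optional[np.random.Generator] = None):
    """Resize, (seeded) random horizontal flip, normalize, pad to /32.

    Returns a new ImageSample whose ``image`` is a float32 CHW-able HxWx3
    array, plus a record of the applied operations (scales, flip, pad) so
    the transform can be inverted for visualization.  Boxes that collapse
    to zero area after resizing are dropped with a warning.
    """
    cfg = cfg or PreprocessConfig()
    if rng is None:
        rng = np.random.default_rng(0)
    tw, th = cfg.target_size
    if tw <= 0 or th <= 0:
        raise ValueError("target_size must be positive")
    img = sample.image
    if img is None:
        raise ValueError("sample has no image loaded")
    h0, w0 = img.shape[:2]
    sx, sy = tw / w0, th / h0
    if (w0, h0) != (tw, th):
        pil = Image.fromarray(img.astype(np.uint8)) if img.dtype != np.uint8 else Image.fromarray(img)
        img = np.asarray(pil.resize((tw, th), Image.BILINEAR))
    boxes, labels = [], []
    for box, label in zip(sample.boxes, sample.labels):
        sb = Box(box.x_min * sx, box.y_min * sy,
                 max(box.x_max * sx, box.x_min * sx + 1e-9),
                 max(box.y_max * sy, box.y_min * sy + 1e-9)).clip(tw, th)
        if sb.area <= 1e-6:
            logger.warning("dropping zero-area box after resize in %s", sample.filename)
            continue
        boxes.append(sb)
        labels.append(label)

    flipped = bool(train_mode and rng.random() < cfg.flip_prob)
    if flipped:
        img = img[:, ::-1]
        boxes = [flip_box(b, tw) for b in boxes]

    arr = img.astype(np.float32)
    mean = np.asarray(cfg.mean, dtype=np.float32)
    std = np.asarray(cfg.std, dtype=np.float32)
    arr = (arr - mean) / std

    ph = _pad_to_divisor(th, cfg.pad_divisor)
    pw = _pad_to_divisor(tw, cfg.pad_divisor)
    if (ph, pw) != (th, tw):
        padded = np.zeros((ph, pw, 3), dtype=np.float32)
        padded[:th, :tw] = arr
        arr = padded

    record = {
        "scale": (sx, sy), "flipped": flipped,
        "resized_to": (tw, th), "padded_to": (pw, ph),
        "mean": tuple(cfg.mean), "std": tuple(cfg.std),
    }
    out = replace(sample, image=arr, boxes=boxes, labels=labels,
                  width=pw, height=ph)
    return out, record
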