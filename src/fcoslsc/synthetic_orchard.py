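"""Seeded synthetic green-on-green orchard scenes with COCO ground truth.

The generator emulates the conditions a green-fruit detector faces in a
real orchard: fruits whose hue differs from the foliage background by
only a configurable offset, fruit-fruit overlap, elongated branch/leaf
occluders drawn over the fruit, global lighting changes (soft, strong,
backlight, low light) and distance blur.  Scenes are rendered in HSV so
"green-on-green" hardness is a single hue knob, then converted to RGB.

Ground-truth boxes annotate the *visible* extent of each fruit (what a
human annotator could draw); fruits whose visible fraction falls below
``min_visible_fraction`` are omitted from the annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
from matplotlib.colors import hsv_to_rgb
from PIL import Image
from scipy.ndimage import gaussian_filter

from .data_io import Box, ImageSample, write_coco

LIGHTING_MODES = ("soft", "strong", "backlight", "low_light")

# background foliage hue, degrees on the 360 wheel
_BG_HUE_DEG = 100.0


@dataclass
class SceneConfig:
    image_size: Tuple[int, int] = (256, 192)        # (W, H) pixels
    fruit_count_range: Tuple[int, int] = (2, 6)
    fruit_radius_range: Tuple[float, float] = (12.0, 30.0)
    fruit_hue_offset: float = 18.0                   # degrees from background
    occluder_count_range: Tuple[int, int] = (1, 4)
    overlap_probability: float = 0.3
    lighting_mode: str = "soft"
    blur_sigma_range: Tuple[float, float] = (0.0, 1.2)
    min_visible_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self):
        for name in ("fruit_count_range", "fruit_radius_range",
                     "occluder_count_range", "blur_sigma_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be an ordered pair")
        if not 0.0 < self.min_visible_fraction <= 1.0:
            raise ValueError("min_visible_fraction must lie in (0, 1]")
        if not 0.0 <= self.overlap_probability <= 1.0:
            raise ValueError("overlap_probability must lie in [0, 1]")
        if self.lighting_mode not in LIGHTING_MODES:
            raise ValueError(f"lighting_mode must be one of {LIGHTING_MODES}")


def _noise_field(rng, h, w, scale, sigma):
    f = rng.standard_normal((h, w))
    f = gaussian_filter(f, sigma)
    f /= max(np.abs(f).max(), 1e-8)
    return f * scale


def render_scene(config: SceneConfig, index: int):
    """Render one scene.

    Returns ``(sample, info)`` where ``sample`` is an ImageSample with a
    uint8 RGB image and visible-extent boxes, and ``info`` carries the
    per-fruit visibility fractions, full/visible masks and amodal boxes
    so every annotation rule is recomputable.
    """
    W, H = config.image_size
    r_lo, r_hi = config.fruit_radius_range
    if r_hi > min(W, H) / 2:
        raise ValueError("fruit radius exceeds half the image size")
    rng = np.random.default_rng(config.seed + index)

    # --- background: textured green field (seeded noise + gradient) -------
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    hue = np.full((H, W), _BG_HUE_DEG / 360.0)
    hue += _noise_field(rng, H, W, 0.015, 12)
    sat = 0.55 + _noise_field(rng, H, W, 0.12, 8)
    val = 0.42 + 0.12 * (yy / H) + _noise_field(rng, H, W, 0.10, 6)

    # --- fruits: shaded ellipses, hue = background + offset ---------------
    n_fruit = int(rng.integers(config.fruit_count_range[0],
                               config.fruit_count_range[1] + 1))
    owner = np.full((H, W), -1, dtype=np.int64)   # topmost fruit per pixel
    full_masks: List[np.ndarray] = []
    amodal_boxes: List[Box] = []
    centers: List[Tuple[float, float]] = []
    for i in range(n_fruit):
        rx = rng.uniform(r_lo, r_hi)
        ry = rx * rng.uniform(0.85, 1.15)
        placed_overlapping = (len(centers) > 0
                              and rng.random() < config.overlap_probability)
        if placed_overlapping:
            j = int(rng.integers(len(centers)))
            ang = rng.uniform(0, 2 * np.pi)
            dist = rng.uniform(0.4, 0.9) * (rx + ry)
            cx = float(np.clip(centers[j][0] + dist * np.cos(ang), rx, W - rx))
            cy = float(np.clip(centers[j][1] + dist * np.sin(ang), ry, H - ry))
        else:
            cx = rng.uniform(rx, W - rx)
            cy = rng.uniform(ry, H - ry)
        centers.append((cx, cy))
        d2 = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2
        mask = d2 <= 1.0
        full_masks.append(mask)
        ys, xs = np.nonzero(mask)
        amodal_boxes.append(Box(xs.min(), ys.min(), xs.max() + 1.0, ys.max() + 1.0))
        owner[mask] = i
        # lambertian-ish shading with an off-center highlight
        shade = np.clip(1.0 - 0.55 * d2, 0.0, 1.0)
        hl = np.exp(-(((xx - (cx - 0.35 * rx)) / (0.5 * rx)) ** 2
                      + ((yy - (cy - 0.35 * ry)) / (0.5 * ry)) ** 2))
        hue[mask] = (_BG_HUE_DEG + config.fruit_hue_offset) / 360.0
        sat[mask] = 0.60 + 0.1 * rng.standard_normal()
        val[mask] = (0.35 + 0.45 * shade + 0.25 * hl)[mask]

    # --- occluders: elongated darker-green strokes above the fruit --------
    n_occ = int(rng.integers(config.occluder_count_range[0],
                             config.occluder_count_range[1] + 1))
    occluded = np.zeros((H, W), dtype=bool)
    for _ in range(n_occ):
        x0, y0 = rng.uniform(0, W), rng.uniform(0, H)
        ang = rng.uniform(0, np.pi)
        length = rng.uniform(0.3, 0.9) * max(W, H)
        thick = rng.uniform(3.0, 9.0)
        dx, dy = np.cos(ang), np.sin(ang)
        # distance from pixel to the stroke's center line, clipped to length
        t = (xx - x0) * dx + (yy - y0) * dy
        t = np.clip(t, -length / 2, length / 2)
        px, py = x0 + t * dx, y0 + t * dy
        dist = np.hypot(xx - px, yy - py)
        stroke = dist <= thick / 2
        occluded |= stroke
        hue[stroke] = (_BG_HUE_DEG - 8.0) / 360.0
        sat[stroke] = 0.5
        val[stroke] = 0.22 + 0.08 * rng.random()

    # --- lighting ----------------------------------------------------------
    if config.lighting_mode == "strong":
        val = np.clip(val * 1.35, 0, 1) ** 0.85
    elif config.lighting_mode == "low_light":
        val = val * 0.45
    elif config.lighting_mode == "backlight":
        ramp = 1.25 - 0.9 * (yy / H)
        val = np.clip(val * ramp, 0, 1)
        sat = sat * 0.7

    hsv = np.stack([np.mod(hue, 1.0), np.clip(sat, 0, 1), np.clip(val, 0, 1)], axis=-1)
    rgb = hsv_to_rgb(hsv)

    # --- distance blur ------------------------------------------------------
    sigma = rng.uniform(*config.blur_sigma_range)
    if sigma > 0.05:
        rgb = np.stack([gaussian_filter(rgb[..., c], sigma) for c in range(3)], axis=-1)
    img = (np.clip(rgb, 0, 1) * 255).round().astype(np.uint8)

    # --- annotations: tight bounds of visible pixels ------------------------
    boxes, labels, fractions, visible_masks, kept = [], [], [], [], []
    for i, mask in enumerate(full_masks):
        visible = mask & (owner == i) & ~occluded
        frac = float(visible.sum()) / float(mask.sum())
        fractions.append(frac)
        visible_masks.append(visible)
        if frac < config.min_visible_fraction or not visible.any():
            continue
        ys, xs = np.nonzero(visible)
        boxes.append(Box(float(xs.min()), float(ys.min()),
                         float(xs.max()) + 1.0, float(ys.max()) + 1.0))
        labels.append(1)
        kept.append(i)

    sample = ImageSample(image_id=index, filename=f"scene_{index:05d}.png",
                         width=W, height=H, boxes=boxes, labels=labels, image=img)
    info = {
        "visibility": fractions,
        "full_masks": full_masks,
        "visible_masks": visible_masks,
        "amodal_boxes": amodal_boxes,
        "kept": kept,
        "blur_sigma": sigma,
    }
    return sample, info


CATEGORIES = {1: "fruit"}


def generate_dataset(config: SceneConfig, n_images: int, out_dir) -> Path:
    """Render ``n_images`` scenes to ``out_dir`` with a COCO annotation file.

    Image ids run 1..n; the per-image seed is ``config.seed + id`` so a
    dataset can be extended without reshuffling existing images.  Returns
    the path of the written COCO JSON.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = []
    for idx in range(1, n_images + 1):
        sample, _ = render_scene(config, idx)
        Image.fromarray(sample.image).save(out_dir / sample.filename)
        samples.append(sample)
    ann_path = out_dir / "annotations.json"
    write_coco(samples, CATEGORIES, ann_path)
    return ann_path


def render_in_memory(config: SceneConfig, n_images: int) -> List[ImageSample]:
    """Render scenes without touching disk (training/eval convenience)."""
    return [render_scene(config, idx)[0] for idx in range(1, n_images + 1)]
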