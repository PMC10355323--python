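import json

import numpy as np
import pytest

from fcoslsc import SceneConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240615)


@pytest.fixture
def tiny_scene_config():
    """Small fast scenes used by pipeline-level tests."""
    return SceneConfig(image_size=(64, 64), fruit_count_range=(1, 3),
                       fruit_radius_range=(6.0, 12.0), fruit_hue_offset=35.0,
                       occluder_count_range=(0, 1), overlap_probability=0.2,
                       blur_sigma_range=(0.0, 0.4), seed=7)


@pytest.fixture
def coco_fixture_path(tmp_path):
    """Hand-authored 3-image / 5-annotation COCO file."""
    doc = {
        "images": [
            {"id": 1, "file_name": "a.png", "width": 100, "height": 80},
            {"id": 2, "file_name": "b.png", "width": 64, "height": 64},
            {"id": 3, "file_name": "c.png", "width": 50, "height": 40},
        ],
        "annotations": [
            {"id": 1, "image_id": 1, "category_id": 1, "bbox": [10, 20, 30, 40],
             "area": 1200, "iscrowd": 0},
            {"id": 2, "image_id": 1, "category_id": 1, "bbox": [5, 5, 10, 10],
             "area": 100, "iscrowd": 0},
            {"id": 3, "image_id": 2, "category_id": 1, "bbox": [0, 0, 32, 16],
             "area": 512, "iscrowd": 0},
            {"id": 4, "image_id": 2, "category_id": 1, "bbox": [8, 8, 8, 8],
             "area": 64, "iscrowd": 0},
            {"id": 5, "image_id": 3, "category_id": 1, "bbox": [1, 2, 3, 4],
             "area": 12, "iscrowd": 0},
        ],
        "categories": [{"id": 1, "name": "fruit"}],
    }
    path = tmp_path / "tiny_coco.json"
    path.write_text(json.dumps(doc))
    return path


def numeric_gradient(f, arrays, idx, eps=1e-6):
    """Central-difference gradient of scalar f() w.r.t. arrays[idx]."""
    a = arrays[idx]
    g = np.zeros_like(a)
    it = np.nditer(a, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = a[i]
        a[i] = orig + eps
        fp = f()
        a[i] = orig - eps
        fm = f()
        a[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
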