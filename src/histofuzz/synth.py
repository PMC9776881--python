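"""Deterministic synthetic histology-like tile generator.

Emulates a three-class osteosarcoma tile set — viable tumor (VT),
non-viable/necrotic tumor (NVT), and non-tumor (NT) — so every pipeline
stage can be exercised without the external benchmark dataset.  Class
signal is carried by several independent channels: nucleus density and
size (elliptical blobs), stain color (hematoxylin-like purple vs. eosin
pink vs. pale background), background brightness, and texture.  Tiles are
contrast-compressed toward mid-gray (to give CLAHE something to restore)
and finished with additive Gaussian noise.

The generator is its own oracle: the class-conditional parameters below
define the study conditions, and tests verify that the emitted statistics
match them.  The same seed always yields a byte-identical image set.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "ClassParams",
    "SyntheticImageSpec",
    "DatasetManifest",
    "CLASS_NAMES",
    "generate_tile",
    "generate_arrays",
    "generate_dataset",
    "default_benchmark_manifest",
    "load_manifest_images",
]

CLASS_NAMES = ("VT", "NVT", "NT")

#: class counts matching the benchmark's 1144-image imbalance
BENCHMARK_COUNTS = {"VT": 345, "NVT": 263, "NT": 536}


@dataclasses.dataclass(frozen=True)
class ClassParams:
    """Generative parameters for one tile class."""

    nucleus_count: tuple[int, int]  # inclusive range
    nucleus_radius: tuple[float, float]
    stain_rgb: tuple[float, float, float]
    background_rgb: tuple[float, float, float]
    noise_sigma: float
    contrast_compression: float  # in (0, 1]; 1 = no compression

    def __post_init__(self) -> None:
        if not 0.0 < self.contrast_compression <= 1.0:
            raise ValueError("contrast_compression must be in (0, 1]")


# Densely packed dark-purple nuclei for viable tumor; sparse, larger, pale
# pink-brown nuclei on an eosinophilic background for necrotic tissue; few
# small nuclei on a bright background for non-tumor tissue.
DEFAULT_CLASS_PARAMS: dict[str, ClassParams] = {
    "VT": ClassParams(
        nucleus_count=(26, 40),
        nucleus_radius=(2.0, 4.0),
        stain_rgb=(0.32, 0.12, 0.45),
        background_rgb=(0.82, 0.66, 0.80),
        noise_sigma=0.03,
        contrast_compression=0.45,
    ),
    "NVT": ClassParams(
        nucleus_count=(8, 16),
        nucleus_radius=(3.0, 6.0),
        stain_rgb=(0.62, 0.34, 0.36),
        background_rgb=(0.93, 0.78, 0.72),
        noise_sigma=0.04,
        contrast_compression=0.40,
    ),
    "NT": ClassParams(
        nucleus_count=(2, 7),
        nucleus_radius=(1.5, 3.0),
        stain_rgb=(0.48, 0.30, 0.55),
        background_rgb=(0.96, 0.90, 0.94),
        noise_sigma=0.02,
        contrast_compression=0.55,
    ),
}


@dataclasses.dataclass(frozen=True)
class SyntheticImageSpec:
    """Tile geometry, per-class generative parameters, and the master seed."""

    tile_size: int = 64
    class_params: dict[str, ClassParams] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CLASS_PARAMS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tile_size < 8:
            raise ValueError("tile_size must be >= 8")
        if set(self.class_params) != set(CLASS_NAMES):
            raise ValueError(f"class_params must cover exactly {CLASS_NAMES}")
        seen = set()
        for name, params in self.class_params.items():
            key = dataclasses.astuple(params)
            if key in seen:
                raise ValueError("class parameter sets must be pairwise distinct")
            seen.add(key)


@dataclasses.dataclass
class DatasetManifest:
    """Labeled image index: rows of (image_path, class_label)."""

    frame: pd.DataFrame  # columns: path, label

    def __post_init__(self) -> None:
        required = {"path", "label"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"manifest needs columns {required}")
        bad = set(self.frame["label"]) - set(CLASS_NAMES)
        if bad:
            raise ValueError(f"unknown labels {bad}; expected {CLASS_NAMES}")
        if self.frame["path"].duplicated().any():
            raise ValueError("duplicate paths in manifest")

    @property
    def class_counts(self) -> dict[str, int]:
        counts = self.frame["label"].value_counts()
        return {name: int(counts.get(name, 0)) for name in CLASS_NAMES}

    def __len__(self) -> int:
        return len(self.frame)

    def save(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        return cls(pd.read_csv(path))


def generate_tile(params: ClassParams, tile_size: int,
                  rng: np.random.Generator) -> np.ndarray:
    """One (tile_size, tile_size, 3) uint8 tile drawn from ``params``."""
    n = tile_size
    # textured background: low-frequency multiplicative field
    texture = gaussian_filter(rng.normal(0.0, 1.0, (n, n)), sigma=6.0)
    peak = np.abs(texture).max()
    if peak > 0:
        texture /= peak
    img = np.empty((n, n, 3))
    for ch in range(3):
        img[..., ch] = params.background_rgb[ch] * (1.0 + 0.08 * texture)

    yy, xx = np.mgrid[0:n, 0:n]
    count = int(rng.integers(params.nucleus_count[0], params.nucleus_count[1] + 1))
    for _ in range(count):
        cy, cx = rng.uniform(0, n, size=2)
        ry = rng.uniform(*params.nucleus_radius)
        rx = rng.uniform(*params.nucleus_radius)
        angle = rng.uniform(0, np.pi)
        ca, sa = np.cos(angle), np.sin(angle)
        u = (xx - cx) * ca + (yy - cy) * sa
        v = -(xx - cx) * sa + (yy - cy) * ca
        # soft-edged ellipse mask
        dist = (u / rx) ** 2 + (v / ry) ** 2
        alpha = np.clip(1.2 - dist, 0.0, 1.0)
        shade = rng.uniform(0.75, 1.0)
        for ch in range(3):
            img[..., ch] = (1 - alpha) * img[..., ch] + alpha * (
                params.stain_rgb[ch] * shade)

    # squash contrast toward mid-gray, then add sensor-like noise
    img = 0.5 + (img - 0.5) * params.contrast_compression
    img = img + rng.normal(0.0, params.noise_sigma, img.shape)
    return np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)


def generate_arrays(
    spec: SyntheticImageSpec, n_per_class: dict[str, int]
) -> tuple[np.ndarray, np.ndarray]:
    """In-memory dataset: (N, H, W, 3) uint8 images and int labels.

    Label ``i`` corresponds to ``CLASS_NAMES[i]``.  Tile order is grouped
    by class in CLASS_NAMES order; deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    images, labels = [], []
    for idx, name in enumerate(CLASS_NAMES):
        count = n_per_class.get(name, 0)
        if count < 1:
            raise ValueError(f"need at least 1 tile for class {name}")
        params = spec.class_params[name]
        for _ in range(count):
            images.append(generate_tile(params, spec.tile_size, rng))
            labels.append(idx)
    return np.stack(images), np.array(labels)


def generate_dataset(
    spec: SyntheticImageSpec, n_per_class: dict[str, int], out_dir
) -> DatasetManifest:
    """Write PNG tiles plus a CSV manifest under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images, labels = generate_arrays(spec, n_per_class)
    rows = []
    counters = {name: 0 for name in CLASS_NAMES}
    for img, label_idx in zip(images, labels):
        name = CLASS_NAMES[label_idx]
        class_dir = out_dir / name
        class_dir.mkdir(exist_ok=True)
        path = class_dir / f"{name}_{counters[name]:04d}.png"
        iio.imwrite(path, img)
        counters[name] += 1
        rows.append({"path": str(path), "label": name})
    manifest = DatasetManifest(pd.DataFrame(rows))
    manifest.save(out_dir / "manifest.csv")
    return manifest


def default_benchmark_manifest(out_dir, seed: int = 0) -> DatasetManifest:
    """Synthetic dataset with the benchmark's class imbalance (345/263/536)."""
    spec = SyntheticImageSpec(seed=seed)
    return generate_dataset(spec, BENCHMARK_COUNTS, out_dir)


def load_manifest_images(manifest: DatasetManifest) -> tuple[np.ndarray, np.ndarray]:
    """Load manifest images as (N, H, W, 3) uint8 plus integer labels."""
    images = np.stack([iio.imread(p) for p in manifest.frame["path"]])
    labels = np.array([CLASS_NAMES.index(lbl) for lbl in manifest.frame["label"]])
    return images, labels
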