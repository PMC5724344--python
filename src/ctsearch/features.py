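"""Bag-of-visual-words front end: descriptors, vocabulary, quantization.

Each CT slice is represented as a bag of "visual words". Local descriptors
are computed on a dense grid of square patches over the brain-windowed
image: each patch is divided into a grid of cells and described by
per-cell, magnitude-weighted gradient-orientation histograms (4x4 cells x 8
orientations = 128 dimensions by default), L2-normalized. Near-constant
patches (background air, uniform tissue) are discarded by a variance
threshold. A k-means clustering of descriptors sampled from the corpus
forms the visual vocabulary; quantizing a descriptor means assigning it to
its nearest centroid (Euclidean distance, ties to the lower centroid index).

Regions of interest select descriptors from the *full-image* grid whose
patch centers fall inside the rectangle, so an ROI bag is always a subset
of the whole-image bag. Rectangles are 0-based half-open
(row_start, row_stop, col_start, col_stop).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

__all__ = [
    "DescriptorConfig",
    "Descriptor",
    "VisualVocabulary",
    "VisualWordBag",
    "extract_descriptors",
    "build_vocabulary",
    "quantize",
    "save_vocabulary",
    "load_vocabulary",
]


@dataclass(frozen=True)
class DescriptorConfig:
    """Parameters of the dense-patch descriptor extractor.

    patch/stride are in pixels; window_center/window_width are the CT
    display window in HU applied before gradients (default: brain window,
    center 40, width 80 — raw HU dynamic range would otherwise swamp
    soft-tissue texture). variance_threshold is applied to the [0, 1]-scaled
    patch intensities.
    """

    patch: int = 16
    stride: int = 8
    cells: int = 4
    orientations: int = 8
    variance_threshold: float = 1e-4
    window_center: float = 40.0
    window_width: float = 80.0

    def __post_init__(self) -> None:
        if self.patch < self.cells or self.patch % self.cells:
            raise ValueError("patch must be a positive multiple of cells")
        if self.stride < 1 or self.orientations < 1:
            raise ValueError("stride and orientations must be >= 1")
        if self.window_width <= 0:
            raise ValueError("window_width must be positive")

    @property
    def length(self) -> int:
        return self.cells * self.cells * self.orientations


@dataclass(frozen=True)
class Descriptor:
    vector: np.ndarray  # fixed-length, L2-normalized unless all-zero
    location: tuple[int, int]  # patch-center pixel (row, col)
    scale: int  # patch side length in pixels


@dataclass
class VisualVocabulary:
    """k centroids in descriptor space; centroid index = visual-word id."""

    centroids: np.ndarray
    training_seed: int
    descriptor_config: DescriptorConfig = field(default_factory=DescriptorConfig)

    def __post_init__(self) -> None:
        self.centroids = np.ascontiguousarray(self.centroids, dtype=np.float64)
        if self.centroids.ndim != 2 or self.centroids.shape[0] < 1:
            raise ValueError("centroids must be a non-empty 2-D array")

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    @property
    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(str(self.centroids.shape).encode())
        h.update(self.centroids.tobytes())
        return h.hexdigest()


@dataclass
class VisualWordBag:
    """Visual-word id → occurrence count for one image (or ROI)."""

    counts: dict[int, int] = field(default_factory=dict)
    image_id: int | None = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _window(image: np.ndarray, config: DescriptorConfig) -> np.ndarray:
    lo = config.window_center - config.window_width / 2.0
    return np.clip((image.astype(np.float64) - lo) / config.window_width, 0.0, 1.0)


def _validate_roi(roi: tuple[int, int, int, int], shape: tuple[int, int]) -> None:
    r0, r1, c0, c1 = roi
    if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
        raise ValueError(f"roi {roi} is not a valid sub-rectangle of image {shape}")


def extract_descriptors(
    image: np.ndarray,
    roi: tuple[int, int, int, int] | None = None,
    config: DescriptorConfig | None = None,
) -> list[Descriptor]:
    """Dense-grid gradient-histogram descriptors of a 2-D HU image.

    When `roi` is given, exactly those descriptors of the full-image grid
    whose patch centers lie inside the (half-open) rectangle are returned.
    """
    config = config or DescriptorConfig()
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"image must be 2-D, got shape {image.shape}")
    if roi is not None:
        _validate_roi(roi, image.shape)

    win = _window(image, config)
    gy, gx = np.gradient(win)
    magnitude = np.hypot(gx, gy)
    # orientation bin per pixel in [0, orientations)
    angle = np.arctan2(gy, gx)  # [-pi, pi]
    bins = np.floor((angle + np.pi) / (2 * np.pi) * config.orientations).astype(int)
    bins = np.clip(bins, 0, config.orientations - 1)

    p, s = config.patch, config.stride
    cell = p // config.cells
    half = p // 2
    descriptors: list[Descriptor] = []
    for r0 in range(0, image.shape[0] - p + 1, s):
        for c0 in range(0, image.shape[1] - p + 1, s):
            center = (r0 + half, c0 + half)
            if roi is not None:
                if not (roi[0] <= center[0] < roi[1] and roi[2] <= center[1] < roi[3]):
                    continue
            patch = win[r0 : r0 + p, c0 : c0 + p]
            if patch.var() < config.variance_threshold:
                continue
            vec = np.zeros(config.length, dtype=np.float64)
            idx = 0
            for cr in range(config.cells):
                for cc in range(config.cells):
                    sl = (
                        slice(r0 + cr * cell, r0 + (cr + 1) * cell),
                        slice(c0 + cc * cell, c0 + (cc + 1) * cell),
                    )
                    vec[idx : idx + config.orientations] = np.bincount(
                        bins[sl].ravel(),
                        weights=magnitude[sl].ravel(),
                        minlength=config.orientations,
                    )
                    idx += config.orientations
            norm = np.linalg.norm(vec)
            if norm > 0:
                vec /= norm
            descriptors.append(Descriptor(vector=vec, location=center, scale=p))
    return descriptors


def build_vocabulary(
    descriptors: list[Descriptor] | np.ndarray,
    k: int,
    seed: int,
    config: DescriptorConfig | None = None,
    max_iter: int = 300,
) -> VisualVocabulary:
    """Cluster a descriptor sample into a k-word visual vocabulary.

    Uses k-means with k-means++ initialization and a fixed seed, so the
    result is deterministic given (sample order, k, seed).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(descriptors, np.ndarray):
        X = np.asarray(descriptors, dtype=np.float64)
    else:
        if len(descriptors) == 0:
            raise ValueError("descriptor sample must be non-empty")
        X = np.stack([d.vector for d in descriptors]).astype(np.float64)
    if X.size == 0:
        raise ValueError("descriptor sample must be non-empty")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds sample size {X.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=max_iter,
                random_state=seed)
    km.fit(X)
    centroids = km.cluster_centers_[np.lexsort(km.cluster_centers_.T[::-1])]
    return VisualVocabulary(
        centroids=centroids,
        training_seed=seed,
        descriptor_config=config or DescriptorConfig(),
    )


def quantize(
    descriptors: list[Descriptor],
    vocab: VisualVocabulary,
    image_id: int | None = None,
) -> VisualWordBag:
    """Assign each descriptor to its nearest centroid and aggregate counts.

    Euclidean distance; exact ties break to the lowest centroid index, so
    quantization is a pure deterministic function of (descriptor, centroids).
    """
    if not descriptors:
        return VisualWordBag(counts={}, image_id=image_id)
    X = np.stack([d.vector for d in descriptors]).astype(np.float64)
    if X.shape[1] != vocab.centroids.shape[1]:
        raise ValueError(
            f"descriptor length {X.shape[1]} != vocabulary length "
            f"{vocab.centroids.shape[1]}"
        )
    words = np.argmin(cdist(X, vocab.centroids, metric="sqeuclidean"), axis=1)
    counts: dict[int, int] = {}
    for w in words:
        w = int(w)
        counts[w] = counts.get(w, 0) + 1
    return VisualWordBag(counts=counts, image_id=image_id)


# ---------------------------------------------------------------------------
# Persistence: JSON manifest + plain-text centroid matrix.

_VOCAB_FORMAT = 1


def save_vocabulary(vocab: VisualVocabulary, directory: str | Path) -> list[Path]:
    """Write `vocab` as vocab.json (manifest) + vocab_centroids.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    csv_path = directory / "vocab_centroids.csv"
    np.savetxt(csv_path, vocab.centroids, fmt="%.17g", delimiter=",")
    manifest = {
        "format": _VOCAB_FORMAT,
        "k": vocab.k,
        "dim": int(vocab.centroids.shape[1]),
        "training_seed": vocab.training_seed,
        "descriptor_config": asdict(vocab.descriptor_config),
        "checksum": vocab.checksum,
    }
    json_path = directory / "vocab.json"
    json_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return [json_path, csv_path]


def load_vocabulary(directory: str | Path) -> VisualVocabulary:
    directory = Path(directory)
    manifest = json.loads((directory / "vocab.json").read_text())
    if manifest.get("format") != _VOCAB_FORMAT:
        raise ValueError(
            f"unsupported vocabulary format {manifest.get('format')}; "
            f"expected {_VOCAB_FORMAT}"
        )
    centroids = np.loadtxt(
        directory / "vocab_centroids.csv", delimiter=",", ndmin=2, dtype=np.float64
    )
    vocab = VisualVocabulary(
        centroids=centroids,
        training_seed=manifest["training_seed"],
        descriptor_config=DescriptorConfig(**manifest["descriptor_config"]),
    )
    if vocab.checksum != manifest["checksum"]:
        raise ValueError("vocabulary checksum mismatch: centroid file corrupted")
    if vocab.k != manifest["k"]:
        raise ValueError("vocabulary k mismatch with manifest")
    return vocab
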