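"""From mammogram-like images to labelled, vectorized m x m patch datasets.

Window convention (used everywhere, tested by round-trip): 0-based indices,
half-open windows [r, r+m) x [c, c+m), row-major vectorization.  With the
default 43.5 um pixel pitch, an m = 115 window spans 5.0025 mm — the size of
region over which >= 3 microcalcifications count as a cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, uniform_filter

from .seeding import child_seed
from .sparse_coding import FeatureTransform, Vocabulary, apply_transform, normalize_columns

__all__ = [
    "MammogramImage",
    "PatchSet",
    "PreprocessSettings",
    "preprocess",
    "enhance_spots",
    "extract_patches",
    "label_patches",
    "assemble_vocabulary",
    "WINDOW_MM",
]

# physical window side at the default pitch: 115 px * 43.5 um = 5.0025 mm
WINDOW_MM = 115 * 43.5 / 1000.0


@dataclass
class MammogramImage:
    """2-D nonnegative intensity grid with physical pixel pitch and bit depth."""

    pixels: np.ndarray
    pixel_pitch_um: float = 43.5
    bit_depth: int = 12

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2-D")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError("bit_depth must be one of 8, 12, 16")
        if not self.pixel_pitch_um > 0:
            raise ValueError("pixel pitch must be positive")

    @property
    def max_value(self) -> float:
        return float(2**self.bit_depth - 1)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class PatchSet:
    """Vectorized patches as columns, with source coordinates and labels."""

    vectors: np.ndarray
    coords: np.ndarray  # (n, 2) 0-based top-left (row, col)
    m: int
    labels: Optional[np.ndarray] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.coords = np.asarray(self.coords, dtype=int)
        if self.vectors.shape[0] != self.m * self.m:
            raise ValueError(f"vectors length {self.vectors.shape[0]} != m^2 = {self.m * self.m}")
        if self.coords.shape != (self.vectors.shape[1], 2):
            raise ValueError("coords must be (n_patches, 2)")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.vectors.shape[1],):
                raise ValueError("labels must align with patch columns")

    @property
    def n_patches(self) -> int:
        return self.vectors.shape[1]

    def save(self, path: Union[str, Path]) -> None:
        from ._io import save_arrays

        path = Path(path)
        save_arrays(
            path,
            vectors=self.vectors,
            coords=self.coords,
            m=np.array(self.m),
            labels=self.labels if self.labels is not None else np.array([]),
            source_id=np.array(self.source_id),
        )
        manifest = pd.DataFrame(
            {
                "patch_id": np.arange(self.n_patches),
                "row": self.coords[:, 0],
                "col": self.coords[:, 1],
                "label": self.labels if self.labels is not None else np.full(self.n_patches, 0),
            }
        )
        manifest.to_csv(path.with_suffix(".manifest.csv"), index=False)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "PatchSet":
        with np.load(path, allow_pickle=False) as f:
            labels = f["labels"]
            return cls(
                vectors=f["vectors"],
                coords=f["coords"],
                m=int(f["m"]),
                labels=labels if labels.size else None,
                source_id=str(f["source_id"]),
            )


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------


@dataclass
class PreprocessSettings:
    """Stages of the simplified enhancement chain; each individually toggleable."""

    clip: bool = True
    flatten: bool = True
    rescale: bool = True
    flatten_window_px: int = 460  # >= 4 * m at the default window size


def preprocess(image: MammogramImage, settings: Optional[PreprocessSettings] = None) -> MammogramImage:
    """Clip to the valid range, subtract a large-window moving-average
    background estimate, and rescale the detail to [0, max]."""
    settings = settings or PreprocessSettings()
    px = image.pixels.copy()
    if settings.flatten and settings.flatten_window_px > min(image.shape):
        raise ValueError(
            f"flatten window {settings.flatten_window_px} exceeds image size {image.shape}"
        )
    if settings.clip:
        px = np.clip(px, 0.0, image.max_value)
    if settings.flatten:
        px = px - uniform_filter(px, size=settings.flatten_window_px, mode="reflect")
    if settings.rescale:
        lo, hi = px.min(), px.max()
        px = np.zeros_like(px) if hi - lo <= 0 else (px - lo) / (hi - lo) * image.max_value
    return MammogramImage(px, image.pixel_pitch_um, image.bit_depth)


def enhance_spots(pixels: np.ndarray, sigma_spot: float = 1.0, sigma_background: float = 6.0) -> np.ndarray:
    """Difference-of-Gaussians band-pass tuned to microcalcification scale.

    Suppresses both the low-frequency tissue background and pixel noise while
    keeping 0.1-1 mm bright spots; applied per patch before feature coding.
    """
    px = np.asarray(pixels, dtype=float)
    return gaussian_filter(px, sigma_spot) - gaussian_filter(px, sigma_background)


def enhance_patch_vectors(vectors: np.ndarray, m: int, sigma_spot: float = 1.0, sigma_background: float = 6.0) -> np.ndarray:
    """Apply `enhance_spots` to each column of vectorized m x m patches."""
    vectors = np.asarray(vectors, dtype=float)
    out = np.empty_like(vectors)
    for j in range(vectors.shape[1]):
        out[:, j] = enhance_spots(vectors[:, j].reshape(m, m), sigma_spot, sigma_background).ravel()
    return out


def spot_density(pixels: np.ndarray, sigma_spot: float = 1.0, sigma_background: float = 6.0,
                 sigma_density: float = 16.0) -> np.ndarray:
    """Half-wave rectified band-pass response smoothed to a spot-density map.

    Rectification keeps only bright (calcification-like) band-pass responses;
    the wide second smoothing turns the discrete spot pattern into a spatial
    density, so patches whose clusters roughly coincide become close in
    Euclidean distance even when individual spot positions differ.
    """
    return gaussian_filter(
        np.maximum(enhance_spots(pixels, sigma_spot, sigma_background), 0.0), sigma_density
    )


# --------------------------------------------------------------------------
# patches
# --------------------------------------------------------------------------


def extract_patches(image: MammogramImage, m: int, stride: int = 1) -> PatchSet:
    """Row-major scan of all m x m windows at the given stride."""
    H, W = image.shape
    if m > H or m > W:
        raise ValueError(f"window m={m} exceeds image size {image.shape}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    win = np.lib.stride_tricks.sliding_window_view(image.pixels, (m, m))[::stride, ::stride]
    nr, nc = win.shape[:2]
    vectors = win.reshape(nr * nc, m * m).T.copy()
    rows, cols = np.meshgrid(np.arange(nr) * stride, np.arange(nc) * stride, indexing="ij")
    coords = np.stack([rows.ravel(), cols.ravel()], axis=1)
    return PatchSet(vectors=vectors, coords=coords, m=m)


def label_patches(patchset: PatchSet, truth, min_spots: int = 3) -> np.ndarray:
    """Label a patch +1 iff >= ``min_spots`` truth spot centers fall inside
    its half-open window, else -1.

    ``truth`` needs ``centers_px`` (n, 2) in (row, col) pixels and, if
    available, ``image_shape`` for bounds checking; out-of-bounds spots are
    ignored with a warning.
    """
    centers = np.atleast_2d(np.asarray(truth.centers_px, dtype=float))
    if centers.size == 0:
        centers = centers.reshape(0, 2)
    shape = getattr(truth, "image_shape", None)
    if shape is not None and centers.shape[0]:
        inside = (
            (centers[:, 0] >= 0)
            & (centers[:, 0] < shape[0])
            & (centers[:, 1] >= 0)
            & (centers[:, 1] < shape[1])
        )
        if not inside.all():
            warnings.warn(
                f"{int((~inside).sum())} truth spot(s) outside image bounds ignored",
                RuntimeWarning,
                stacklevel=2,
            )
            centers = centers[inside]
    labels = np.empty(patchset.n_patches, dtype=int)
    m = patchset.m
    for j, (r0, c0) in enumerate(patchset.coords):
        hit = (
            (centers[:, 0] >= r0)
            & (centers[:, 0] < r0 + m)
            & (centers[:, 1] >= c0)
            & (centers[:, 1] < c0 + m)
        )
        labels[j] = 1 if int(hit.sum()) >= min_spots else -1
    return labels


def assemble_vocabulary(
    patchset: PatchSet,
    transform: Optional[FeatureTransform] = None,
    balance: bool = False,
    seed: int = 0,
) -> Vocabulary:
    """Transform, normalize and (optionally) class-balance labelled patches
    into a sparse-coding vocabulary."""
    if patchset.labels is None:
        raise ValueError("patchset must be labelled")
    labels = patchset.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("vocabulary requires both classes")
    transform = transform or FeatureTransform.identity()
    keep = np.arange(patchset.n_patches)
    if balance:
        rng = np.random.default_rng(child_seed(seed, "vocab-balance"))
        pos = np.flatnonzero(labels == 1)
        neg = np.flatnonzero(labels == -1)
        k = min(pos.size, neg.size)
        keep = np.sort(
            np.concatenate(
                [rng.choice(pos, k, replace=False), rng.choice(neg, k, replace=False)]
            )
        )
    feats = apply_transform(transform, patchset.vectors[:, keep])
    cols, scales = normalize_columns(feats)
    return Vocabulary(
        columns=cols,
        labels=labels[keep],
        normalized=True,
        transform_id=transform.id_string,
        scales=scales,
    )
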