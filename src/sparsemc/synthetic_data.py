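"""Synthetic mammogram-phantom generator and low-dimensional test fixtures.

The phantom emulates screening-mammogram patches: a textured background
(stationary correlated noise plus a low-frequency planar gradient, the
minimal structure that makes background flattening meaningful) with clusters
of small Gaussian-profile bright spots standing in for microcalcifications.
Spot diameters span 0.1-1 mm; at the default 43.5 um pitch that is about
2.3-23 px.  A positive patch contains one cluster of >= 3 spots inside a
<= 5 mm box; every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import qr
from scipy.ndimage import gaussian_filter

from .patch_pipeline import MammogramImage, PatchSet, label_patches
from .seeding import child_seed
from .sparse_coding import Vocabulary, normalize_columns

__all__ = [
    "BackgroundSpec",
    "SpotSpec",
    "ClusterSpec",
    "PhantomSpec",
    "GroundTruth",
    "generate_background",
    "add_mc_cluster",
    "generate_dataset",
    "generate_subspace_fixture",
    "generate_cluster_fixture",
]


@dataclass
class BackgroundSpec:
    """base grey level, texture correlation length (px), texture sd, and
    peak-to-trough amplitude of a random planar gradient."""

    base: float = 800.0
    texture_corr_px: float = 8.0
    texture_amp: float = 40.0
    gradient_amp: float = 30.0


@dataclass
class SpotSpec:
    """Gaussian-profile bright spots; FWHM = physical diameter.

    ``contrast_rel_sd`` sets the peak amplitude as a multiple of the
    background texture standard deviation (default 8, a clearly visible
    calcification).
    """

    diameter_range_mm: tuple[float, float] = (0.1, 1.0)
    contrast_rel_sd: float = 8.0

    def __post_init__(self) -> None:
        lo, hi = self.diameter_range_mm
        if not (0.05 <= lo <= hi <= 2.0):
            raise ValueError("diameter range must lie within [0.05, 2.0] mm")
        if self.contrast_rel_sd < 0:
            raise ValueError("contrast must be >= 0")


@dataclass
class ClusterSpec:
    """Number of spots per cluster (uniform in range) and cluster box extent."""

    spots_range: tuple[int, int] = (3, 6)
    extent_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.spots_range[0] < 1:
            raise ValueError("at least one spot per cluster")
        if not 0 < self.extent_mm <= 5.0:
            raise ValueError("cluster extent must be in (0, 5] mm")


@dataclass
class PhantomSpec:
    image_size_px: tuple[int, int] = (256, 256)
    pixel_pitch_um: float = 43.5
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    spots: SpotSpec = field(default_factory=SpotSpec)
    cluster: ClusterSpec = field(default_factory=ClusterSpec)
    bit_depth: int = 12

    def px_per_mm(self) -> float:
        return 1000.0 / self.pixel_pitch_um

    def spot_amplitude(self) -> float:
        return self.spots.contrast_rel_sd * self.background.texture_amp


@dataclass
class GroundTruth:
    """Per-image spot annotations: centers (px), diameters (mm), cluster box."""

    centers_px: np.ndarray
    diameters_mm: np.ndarray
    cluster_box: Optional[tuple[int, int, int, int]] = None  # (r0, c0, r1, c1) half-open
    image_shape: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        self.centers_px = np.atleast_2d(np.asarray(self.centers_px, dtype=float))
        if self.centers_px.size == 0:
            self.centers_px = self.centers_px.reshape(0, 2)
        self.diameters_mm = np.asarray(self.diameters_mm, dtype=float)


def generate_background(spec: PhantomSpec, seed: int) -> MammogramImage:
    """base + correlated texture + random planar gradient, deterministic per seed.

    The smoothed white noise is rescaled to the configured texture standard
    deviation (Gaussian smoothing alone would shrink it by an
    aperture-dependent factor).
    """
    rng = np.random.default_rng(seed)
    H, W = spec.image_size_px
    bg = spec.background
    px = np.full((H, W), bg.base)
    if bg.texture_amp > 0:
        tex = gaussian_filter(rng.standard_normal((H, W)), bg.texture_corr_px, mode="reflect")
        sd = tex.std()
        if sd > 0:
            px += tex * (bg.texture_amp / sd)
    if bg.gradient_amp > 0:
        theta = rng.uniform(0, 2 * np.pi)
        rr, cc = np.meshgrid(np.linspace(-0.5, 0.5, H), np.linspace(-0.5, 0.5, W), indexing="ij")
        px += bg.gradient_amp * (np.cos(theta) * rr + np.sin(theta) * cc)
    px = np.clip(px, 0.0, 2**spec.bit_depth - 1)
    return MammogramImage(px, spec.pixel_pitch_um, spec.bit_depth)


def _place_spots(rng, k, box, sigmas_px):
    """Integer-pixel spot centers inside the half-open box, rejection-sampled
    for pairwise separation so each peak reads back its own amplitude."""
    r0, c0, r1, c1 = box
    centers = []
    for i in range(k):
        best, best_d = None, -1.0
        for _ in range(200):
            cand = (int(rng.integers(r0, r1)), int(rng.integers(c0, c1)))
            if not centers:
                best = cand
                break
            d = min(np.hypot(cand[0] - p[0], cand[1] - p[1]) for p in centers)
            need = max(
                2.8 * max(sigmas_px[i], sigmas_px[j]) + 1.0 for j, p in enumerate(centers)
            )
            if d >= need:
                best = cand
                break
            if d > best_d:
                best, best_d = cand, d
        centers.append(best)
    return np.array(centers, dtype=float)


def add_mc_cluster(
    image: MammogramImage,
    spec: PhantomSpec,
    seed: int,
    box_center: Optional[tuple[float, float]] = None,
) -> tuple[MammogramImage, GroundTruth]:
    """Place one cluster of Gaussian-profile spots; additive intensity.

    Spot count is uniform in ``spec.cluster.spots_range``, diameters
    log-uniform in the configured range (small calcifications dominate real
    clusters), positions uniform inside the cluster box.  Centers are snapped
    to pixel centers so the peak pixel carries the full configured amplitude.
    """
    rng = np.random.default_rng(seed)
    H, W = image.shape
    ext_px = int(round(spec.cluster.extent_mm * spec.px_per_mm()))
    if ext_px > H or ext_px > W:
        raise ValueError(f"cluster box of {ext_px} px does not fit image {image.shape}")
    if box_center is None:
        r0 = int(rng.integers(0, H - ext_px + 1))
        c0 = int(rng.integers(0, W - ext_px + 1))
    else:
        r0 = int(round(box_center[0] - ext_px / 2))
        c0 = int(round(box_center[1] - ext_px / 2))
        if r0 < 0 or c0 < 0 or r0 + ext_px > H or c0 + ext_px > W:
            raise ValueError("cluster box does not fit image at the requested center")
    box = (r0, c0, r0 + ext_px, c0 + ext_px)

    lo, hi = spec.spots.diameter_range_mm
    k = int(rng.integers(spec.cluster.spots_range[0], spec.cluster.spots_range[1] + 1))
    diameters = np.exp(rng.uniform(np.log(lo), np.log(hi), size=k))
    sigmas = diameters * spec.px_per_mm() / 2.3548  # FWHM -> sigma
    centers = _place_spots(rng, k, box, sigmas)

    px = image.pixels.copy()
    amp = spec.spot_amplitude()
    for (cr, cc), s in zip(centers, sigmas):
        half = int(np.ceil(4 * s))
        rr = np.arange(max(0, int(cr) - half), min(H, int(cr) + half + 1))
        ccols = np.arange(max(0, int(cc) - half), min(W, int(cc) + half + 1))
        RR, CC = np.meshgrid(rr, ccols, indexing="ij")
        px[np.ix_(rr, ccols)] += amp * np.exp(-((RR - cr) ** 2 + (CC - cc) ** 2) / (2 * s**2))
    px = np.clip(px, 0.0, image.max_value)
    truth = GroundTruth(
        centers_px=centers,
        diameters_mm=diameters,
        cluster_box=box,
        image_shape=(H, W),
    )
    return MammogramImage(px, image.pixel_pitch_um, image.bit_depth), truth


def generate_dataset(
    spec: PhantomSpec,
    n_pos: int = 3000,
    n_neg: int = 3000,
    m: int = 115,
    seed: int = 0,
) -> tuple[PatchSet, list[GroundTruth]]:
    """Labelled phantom patch dataset: ``n_pos`` patches each holding one
    cluster (centered with uniform jitter so the cluster never clips) and
    ``n_neg`` background-only patches.

    Labels are re-derived through the cluster counting rule rather than
    trusted from construction.  Returns the patch set and per-patch truth
    (empty truth for negatives).
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one patch per class")
    pspec = PhantomSpec(
        image_size_px=(m, m),
        pixel_pitch_um=spec.pixel_pitch_um,
        background=spec.background,
        spots=spec.spots,
        cluster=spec.cluster,
        bit_depth=spec.bit_depth,
    )
    ext_px = int(round(spec.cluster.extent_mm * pspec.px_per_mm()))
    max_jitter = min(m // 4, max((m - ext_px) // 2 - 1, 0))

    vectors = np.empty((m * m, n_pos + n_neg))
    truths: list[GroundTruth] = []
    labels = np.empty(n_pos + n_neg, dtype=int)
    for i in range(n_pos):
        s = child_seed(seed, f"pos{i}")
        img = generate_background(pspec, s)
        rng = np.random.default_rng(child_seed(seed, f"pos{i}-jitter"))
        jr, jc = rng.integers(-max_jitter, max_jitter + 1, size=2) if max_jitter else (0, 0)
        img, truth = add_mc_cluster(img, pspec, child_seed(seed, f"pos{i}-cluster"),
                                    box_center=(m / 2 + jr, m / 2 + jc))
        vectors[:, i] = img.pixels.ravel()
        truths.append(truth)
    for i in range(n_neg):
        s = child_seed(seed, f"neg{i}")
        img = generate_background(pspec, s)
        vectors[:, n_pos + i] = img.pixels.ravel()
        truths.append(GroundTruth(centers_px=np.zeros((0, 2)), diameters_mm=np.zeros(0),
                                  image_shape=(m, m)))

    coords = np.zeros((n_pos + n_neg, 2), dtype=int)
    patchset = PatchSet(vectors=vectors, coords=coords, m=m, source_id=f"phantom-seed{seed}")
    single = PatchSet(vectors=np.zeros((m * m, 1)), coords=np.zeros((1, 2), dtype=int), m=m)
    for i, truth in enumerate(truths):
        labels[i] = label_patches(single, truth)[0]
    patchset.labels = labels
    return patchset, truths


# --------------------------------------------------------------------------
# low-dimensional classifier fixtures
# --------------------------------------------------------------------------


def generate_subspace_fixture(
    dim: int,
    rank_per_class: int,
    n_train: int,
    n_test: int,
    noise_sd: float,
    seed: int,
) -> tuple[Vocabulary, np.ndarray, np.ndarray]:
    """Two classes supported on mutually orthogonal random subspaces.

    This is the structural assumption sparse-representation classification
    relies on: samples of a class lie (near) the span of that class's
    training columns.  Returns (vocabulary, test columns, test labels).
    """
    if 2 * rank_per_class > dim:
        raise ValueError("need 2 * rank_per_class <= dim")
    rng = np.random.default_rng(seed)
    Q, _ = qr(rng.standard_normal((dim, 2 * rank_per_class)), mode="economic")
    bases = {1: Q[:, :rank_per_class], -1: Q[:, rank_per_class:]}

    def sample(cls, n):
        coef = rng.standard_normal((rank_per_class, n))
        pts = bases[cls] @ coef
        if noise_sd > 0:
            pts = pts + noise_sd * rng.standard_normal(pts.shape)
        return pts

    train = np.hstack([sample(1, n_train), sample(-1, n_train)])
    train_labels = np.concatenate([np.ones(n_train, int), -np.ones(n_train, int)])
    test = np.hstack([sample(1, n_test), sample(-1, n_test)])
    test_labels = np.concatenate([np.ones(n_test, int), -np.ones(n_test, int)])
    cols, scales = normalize_columns(train)
    vocab = Vocabulary(cols, train_labels, normalized=True, transform_id="identity", scales=scales)
    return vocab, test, test_labels


def generate_cluster_fixture(
    means: tuple, sd: float, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two isotropic Gaussian clouds (rows = points) with labels +1 / -1."""
    if len(means) != 2:
        raise ValueError("exactly two class means required")
    rng = np.random.default_rng(seed)
    m1 = np.asarray(means[0], dtype=float)
    m2 = np.asarray(means[1], dtype=float)
    X1 = m1 + sd * rng.standard_normal((n, m1.size))
    X2 = m2 + sd * rng.standard_normal((n, m2.size))
    X = np.vstack([X1, X2])
    labels = np.concatenate([np.ones(n, int), -np.ones(n, int)])
    return X, labels
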