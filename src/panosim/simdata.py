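"""Synthetic scenes, illumination patterns, and mosaic tile stacks.

This module provides a complete forward model for a patterned-illumination
tiling microscope: a large ground-truth scene is cropped into an overlapping
grid of tiles; each tile is imaged N times under a shifting binary line
pattern, blurred by a Gaussian PSF, shaded by a smooth multiplicative
vignette common to all tiles, and corrupted by Poisson-Gaussian noise.
Every downstream stage (reconstruction, devignetting, stitching, metrics)
can therefore be exercised against known ground truth without any
acquisition hardware or downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "PatternSet",
    "SceneGroundTruth",
    "MosaicLayout",
    "TileStack",
    "make_line_patterns",
    "make_scene",
    "make_vignette",
    "simulate_mosaic",
]


@dataclass(frozen=True)
class PatternSet:
    """A set of N phase-shifted binary line-illumination masks.

    The masks emulate patterns rendered on a binary (on/off) microdisplay:
    parallel stripes of width ``period_px * duty`` that advance by one phase
    step between consecutive masks.  Because the phase windows partition one
    full period, the pixelwise sum of the N masks is exactly constant -- the
    property that makes the plain average of the phase images a valid
    wide-field reconstruction.
    """

    period_px: int
    n_phases: int
    orientation_deg: float
    duty: float
    masks: np.ndarray  # (N, H, W) float array with values in {0, 1}

    @property
    def tile_px(self) -> int:
        return self.masks.shape[-1]


@dataclass(frozen=True)
class SceneGroundTruth:
    """Ground-truth description of a simulated acquisition.

    Parameters
    ----------
    scene
        Large 2-D nonnegative intensity image (the whole-slide "sample").
    psf_sigma_px
        Standard deviation of the isotropic Gaussian PSF, in pixels.
    vignette_truth
        Smooth multiplicative shading field in (0, 1], one tile in size,
        identical for every tile of the mosaic.
    poisson_scale
        Expected photon count per unit intensity.  0 disables shot noise.
    read_sigma
        Additive Gaussian read-noise standard deviation.  0 disables it.
    seed
        Seed for all simulation randomness.
    """

    scene: np.ndarray
    psf_sigma_px: float = 0.0
    vignette_truth: np.ndarray | None = None
    poisson_scale: float = 0.0
    read_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if np.min(self.scene) < 0:
            raise ValueError("scene intensities must be nonnegative")
        if self.vignette_truth is not None:
            v = self.vignette_truth
            if np.min(v) <= 0 or np.max(v) > 1 + 1e-12:
                raise ValueError("vignette_truth values must lie in (0, 1]")


@dataclass(frozen=True)
class MosaicLayout:
    """Regular grid of square tiles with proportional overlap.

    Tiles are ordered row-major from the top-left; y increases downward and
    pixel indices are 0-based with half-open crops.  The step between
    adjacent nominal offsets is ``round(tile_px * (1 - overlap_frac))`` in
    both axes.
    """

    rows: int
    cols: int
    tile_px: int
    overlap_frac: float = 0.2
    pixel_size_nm: float = 100.0

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_frac < 0.5):
            raise ValueError("overlap_frac must lie in [0, 0.5)")
        if self.rows < 1 or self.cols < 1 or self.tile_px < 1:
            raise ValueError("rows, cols and tile_px must be positive")

    @property
    def step_px(self) -> int:
        return int(round(self.tile_px * (1.0 - self.overlap_frac)))

    @property
    def offsets(self) -> np.ndarray:
        """Nominal (y, x) top-left positions, row-major, shape (rows*cols, 2)."""
        s = self.step_px
        grid = [(r * s, c * s) for r in range(self.rows) for c in range(self.cols)]
        return np.asarray(grid, dtype=int)

    @property
    def mosaic_shape(self) -> tuple[int, int]:
        s = self.step_px
        return ((self.rows - 1) * s + self.tile_px, (self.cols - 1) * s + self.tile_px)


@dataclass(frozen=True)
class TileStack:
    """The N phase-shifted raw images acquired at one mosaic position."""

    data: np.ndarray  # (N, H, W)
    pattern: PatternSet
    position: tuple[int, int]
    pixel_size_nm: float = 100.0

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("TileStack data must be (phases, H, W)")
        if self.data.shape[0] != self.pattern.n_phases:
            raise ValueError(
                f"stack has {self.data.shape[0]} pages but the pattern set "
                f"has {self.pattern.n_phases} phases"
            )
        if np.min(self.data) < 0:
            raise ValueError("intensities must be nonnegative")

    @property
    def n_phases(self) -> int:
        return self.data.shape[0]


def make_line_patterns(
    tile_px: int, period_px: int, n_phases: int, orientation_deg: float = 0.0
) -> PatternSet:
    """Generate N phase-shifted binary line patterns of one tile in size.

    Each mask switches a pixel on when the coordinate along the pattern
    normal, modulo the period, falls inside that phase's window.  The N
    windows of width ``period_px / n_phases`` partition the period, so the
    pixelwise sum over phases is exactly 1 everywhere regardless of
    orientation, and the duty cycle is ``1 / n_phases``.

    Raises
    ------
    ValueError
        If ``period_px`` is not divisible by ``n_phases`` (integer phase
        steps could not tile the period, breaking homogeneity) or
        ``n_phases < 2``.
    """
    if n_phases < 2:
        raise ValueError("need at least 2 phases")
    if period_px < 2:
        raise ValueError("period_px must be > 1")
    if period_px % n_phases != 0:
        raise ValueError(
            f"period_px={period_px} is not divisible by n_phases={n_phases}; "
            "integer phase steps cannot sum to homogeneous illumination"
        )
    step = period_px // n_phases
    theta = np.deg2rad(orientation_deg)
    yy, xx = np.mgrid[0:tile_px, 0:tile_px]
    # coordinate along the pattern normal: orientation 0 -> stripes vary by row
    u = np.cos(theta) * yy + np.sin(theta) * xx
    masks = np.empty((n_phases, tile_px, tile_px), dtype=np.float64)
    for n in range(n_phases):
        phase = np.mod(u - n * step, period_px)
        masks[n] = (phase < step).astype(np.float64)
    return PatternSet(
        period_px=period_px,
        n_phases=n_phases,
        orientation_deg=orientation_deg,
        duty=step / period_px,
        masks=masks,
    )


def make_scene(kind: str, size_px: int, seed: int = 0) -> np.ndarray:
    """Deterministic synthetic test scene.

    ``beads``   -- sparse Gaussian spots on a dark background.
    ``star``    -- a Siemens-star radial target (for resolution tests).
    ``texture`` -- band-limited filtered noise mimicking dense tissue.
    """
    rng = np.random.default_rng(seed)
    if kind == "beads":
        img = np.zeros((size_px, size_px))
        n_beads = max(10, size_px**2 // 400)
        ys = rng.integers(0, size_px, n_beads)
        xs = rng.integers(0, size_px, n_beads)
        amps = rng.uniform(0.5, 1.0, n_beads)
        img[ys, xs] = amps
        img = ndimage.gaussian_filter(img, 1.5)
        img = 100.0 * img / max(img.max(), 1e-12) + 1.0
    elif kind == "star":
        c = (size_px - 1) / 2.0
        yy, xx = np.mgrid[0:size_px, 0:size_px]
        theta = np.arctan2(yy - c, xx - c)
        n_spokes = 36
        img = 50.0 * (1.0 + np.cos(n_spokes * theta)) + 5.0
        # fade the hub so the spoke period never aliases at the center
        rr = np.hypot(yy - c, xx - c)
        img = img * (rr > 0.02 * size_px) + 55.0 * (rr <= 0.02 * size_px)
    elif kind == "texture":
        # dense tissue: band-limited variation on a bright, fully stained
        # background (every pixel carries signal; contrast is modest)
        noise = rng.standard_normal((size_px, size_px))
        img = ndimage.gaussian_filter(noise, 1.0) - ndimage.gaussian_filter(noise, 6.0)
        img = img - img.min()
        img = 100.0 * img / max(img.max(), 1e-12) + 200.0
    else:
        raise ValueError(f"unknown scene kind: {kind!r}")
    return img.astype(np.float64)


def make_vignette(tile_px: int, strength: float) -> np.ndarray:
    """Smooth radial shading field: 1.0 at the tile center, ``1 - strength``
    at the corners, strictly positive everywhere.

    Raises
    ------
    ValueError
        If ``strength >= 1`` (corners would reach zero, making division by
        the profile ill-posed).
    """
    if not (0 <= strength < 1):
        raise ValueError("strength must lie in [0, 1)")
    c = (tile_px - 1) / 2.0
    yy, xx = np.mgrid[0:tile_px, 0:tile_px]
    r2 = ((yy - c) ** 2 + (xx - c) ** 2) / (2 * c**2) if tile_px > 1 else np.zeros((1, 1))
    return 1.0 - strength * r2


def _crop(scene: np.ndarray, top: int, left: int, size: int) -> np.ndarray:
    if top < 0 or left < 0 or top + size > scene.shape[0] or left + size > scene.shape[1]:
        raise ValueError(
            f"tile crop [{top}:{top + size}, {left}:{left + size}] exceeds "
            f"scene bounds {scene.shape}"
        )
    return scene[top : top + size, left : left + size]


def simulate_mosaic(
    truth: SceneGroundTruth,
    layout: MosaicLayout,
    pattern: PatternSet,
    jitter_px: np.ndarray | None = None,
) -> list[TileStack]:
    """Simulate the full grid acquisition: one TileStack per mosaic position.

    For each tile the forward model is: crop scene -> multiply by each phase
    mask -> convolve with the Gaussian PSF -> multiply by the common
    vignette -> Poisson shot noise scaled by ``poisson_scale`` -> additive
    Gaussian read noise.  With all noise parameters zero the model is exact,
    so the mean over phases equals ``duty * vignette * blurred crop``.

    Parameters
    ----------
    jitter_px
        Optional (rows*cols, 2) integer array of per-tile stage-position
        errors: tile i is cropped at ``nominal_offset[i] + jitter_px[i]``.
        Used as a stitching-refinement test fixture.
    """
    if pattern.tile_px != layout.tile_px:
        raise ValueError("pattern mask size must match layout tile size")
    offsets = layout.offsets
    if jitter_px is not None:
        jitter_px = np.asarray(jitter_px, dtype=int)
        if jitter_px.shape != offsets.shape:
            raise ValueError("jitter_px must have shape (rows*cols, 2)")
        offsets = offsets + jitter_px
    vignette = (
        truth.vignette_truth
        if truth.vignette_truth is not None
        else np.ones((layout.tile_px, layout.tile_px))
    )
    rng = np.random.default_rng(truth.seed)
    stacks: list[TileStack] = []
    for i, (top, left) in enumerate(offsets):
        crop = _crop(truth.scene, int(top), int(left), layout.tile_px)
        pages = np.empty((pattern.n_phases, layout.tile_px, layout.tile_px))
        for n in range(pattern.n_phases):
            img = crop * pattern.masks[n]
            if truth.psf_sigma_px > 0:
                img = ndimage.gaussian_filter(img, truth.psf_sigma_px)
            img = img * vignette
            if truth.poisson_scale > 0:
                img = rng.poisson(np.maximum(img, 0) * truth.poisson_scale) / truth.poisson_scale
            if truth.read_sigma > 0:
                img = img + rng.normal(0.0, truth.read_sigma, img.shape)
            pages[n] = np.maximum(img, 0.0)
        stacks.append(
            TileStack(
                data=pages,
                pattern=pattern,
                position=(i // layout.cols, i % layout.cols),
                pixel_size_nm=layout.pixel_size_nm,
            )
        )
    return stacks
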