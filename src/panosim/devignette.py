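"""Estimation and removal of the vignetting profile common to mosaic tiles.

Patterned-illumination reconstruction leaves a smooth shading (vignette) in
every tile that a pre-acquisition calibration slide cannot capture, because
the reconstruction itself contributes to it.  The profile is therefore
estimated from the reconstructed tiles: an average intensity projection
across all tiles averages away the (tile-varying) foreground while
preserving the (tile-constant) vignette, and a border-limited mean blur
removes the residual foreground texture without the edge-brightening glow
that padded or mirrored blurs introduce.  Dividing each tile by the
unit-mean profile flattens the mosaic; for bright-field color tiles the
correction is instead additive, using an empty-field reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "VignetteProfile",
    "average_projection",
    "border_limited_mean",
    "estimate_vignette",
    "apply_devignette",
    "devignette_brightfield",
]

#: Blur half-width in pixels used when none is given.  Chosen for full-size
#: (~2048 px) camera frames; scale proportionally for smaller tiles.
DEFAULT_RADIUS = 200


@dataclass(frozen=True)
class VignetteProfile:
    """Estimated multiplicative shading field shared by all tiles.

    ``profile`` is strictly positive with mean exactly 1, so dividing by it
    preserves the overall intensity scale of the mosaic.  ``normalization``
    keeps the mean of the raw blurred projection for provenance.
    """

    profile: np.ndarray
    normalization: float

    def __post_init__(self) -> None:
        if np.min(self.profile) <= 0:
            raise ValueError("vignette profile must be strictly positive")


def average_projection(tiles: list[np.ndarray]) -> np.ndarray:
    """Pixelwise arithmetic mean across tiles."""
    if len(tiles) == 0:
        raise ValueError("need at least one tile")
    shape = tiles[0].shape
    for i, t in enumerate(tiles):
        if t.shape != shape:
            raise ValueError(f"tile {i} shape {t.shape} != {shape}")
    return np.mean(np.stack(tiles), axis=0)


def border_limited_mean(img: np.ndarray, radius: int) -> np.ndarray:
    """Mean filter over a square window clipped at the image border.

    The (2*radius+1)^2 window is intersected with the image domain and the
    mean taken over in-bounds pixels only -- no padding or mirroring -- so a
    constant image stays exactly constant out to its corners instead of
    acquiring the bright edge glow of zero-padded blurs.  ``radius=0`` is
    the identity.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return img.astype(np.float64, copy=True)
    size = 2 * radius + 1
    num = ndimage.uniform_filter(img.astype(np.float64), size, mode="constant", cval=0.0)
    den = ndimage.uniform_filter(np.ones_like(img, dtype=np.float64), size, mode="constant", cval=0.0)
    return num / den


def estimate_vignette(tiles: list[np.ndarray], radius: int = DEFAULT_RADIUS) -> VignetteProfile:
    """Estimate the common vignette: blurred average projection, unit-mean.

    Accuracy improves with more tiles (the projection retains foreground
    coarseness for small mosaics, which only the blur can remove).

    Raises
    ------
    ValueError
        If the blurred projection has any nonpositive pixel (unusable as a
        divisor).
    """
    proj = average_projection(tiles)
    blurred = border_limited_mean(proj, radius)
    if np.min(blurred) <= 0:
        raise ValueError("blurred projection has nonpositive pixels; cannot divide")
    norm = float(blurred.mean())
    return VignetteProfile(profile=blurred / norm, normalization=norm)


def apply_devignette(tile: np.ndarray, profile: VignetteProfile) -> np.ndarray:
    """Divide one tile by the unit-mean vignette profile."""
    if tile.shape != profile.profile.shape:
        raise ValueError(f"tile shape {tile.shape} != profile {profile.profile.shape}")
    return tile / profile.profile


def devignette_brightfield(
    tile: np.ndarray, empty: np.ndarray, white_level: float | None = None
) -> np.ndarray:
    """Additive empty-field correction for bright-field color tiles.

    Per channel: ``out = clip(tile + (white_level - empty), 0, white_level)``.
    Adding the photographic inverse of an empty-field acquisition (taken
    under conditions identical to the tiles) maps the empty background to
    uniform white, removing vignetting and color-balance gradients in one
    step.  ``white_level`` defaults to the dtype maximum for integer tiles
    and 1.0 for floats.
    """
    if tile.shape != empty.shape:
        raise ValueError(f"tile shape {tile.shape} != empty shape {empty.shape}")
    if white_level is None:
        white_level = (
            float(np.iinfo(tile.dtype).max) if np.issubdtype(tile.dtype, np.integer) else 1.0
        )
    out = tile.astype(np.float64) + (white_level - empty.astype(np.float64))
    return np.clip(out, 0.0, white_level)
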