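"""Grid stitching of devignetted tiles into a seamless panoramic mosaic.

Tiles are placed at their nominal grid offsets (step ``round(l*(1-r))`` for
tile side l and overlap fraction r).  Optionally each tile's position is
refined by phase-correlating its overlap strips against the already-placed
left/top neighbors, recovering small stage-position errors.  Overlapping
pixels are resolved by feathering (linear distance-to-edge weights,
normalized to a partition of unity), plain averaging, or overwrite.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from skimage.registration import phase_cross_correlation

from .simdata import MosaicLayout

__all__ = ["StitchResult", "phase_correlate", "stitch_grid"]


@dataclass(frozen=True)
class StitchResult:
    """A stitched mosaic plus the per-tile placements that produced it."""

    mosaic: np.ndarray
    offsets_used: np.ndarray  # (n_tiles, 2) int (y, x)
    refinement_shifts: np.ndarray  # (n_tiles, 2) float (dy, dx) vs nominal


def phase_correlate(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Estimate the translation of ``b`` relative to ``a``.

    Returns ``(dy, dx)`` such that ``b(y, x) ~= a(y - dy, x - dx)`` -- i.e.,
    features of ``a`` appear in ``b`` displaced by ``(dy, dx)``.  Sub-pixel
    precision via upsampled cross-correlation.  Identical images give (0, 0).
    """
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if float(np.var(a)) == 0.0 or float(np.var(b)) == 0.0:
        raise ValueError("zero-variance input: no texture to correlate")
    shift, _, _ = phase_cross_correlation(a, b, upsample_factor=20, normalization=None)
    # skimage returns the shift registering b onto a (a ~= roll(b, shift))
    return (-float(shift[0]), -float(shift[1]))


def _feather_weight(tile_shape: tuple[int, int]) -> np.ndarray:
    """Linear distance-to-nearest-edge weight, minimum 1 at the border."""
    h, w = tile_shape
    y = np.minimum(np.arange(h), np.arange(h)[::-1]) + 1.0
    x = np.minimum(np.arange(w), np.arange(w)[::-1]) + 1.0
    return np.minimum(y[:, None], x[None, :])


def stitch_grid(
    tiles: list[np.ndarray],
    layout: MosaicLayout,
    refine: bool = False,
    blend: str = "feather",
    max_shift_frac: float = 0.1,
) -> StitchResult:
    """Assemble a rows x cols grid of tiles into one mosaic.

    Parameters
    ----------
    tiles
        Row-major list of rows*cols same-shape 2-D tiles.
    refine
        If True, adjust each tile's placement (row-major order) by phase
        correlation of its overlap strips against the already-placed left
        and top neighbors.  Shifts are clamped to
        ``max_shift_frac * tile_px``; a shift exceeding the clamp is
        discarded with a warning and the nominal position used.
    blend
        ``feather`` (linear edge-distance weights), ``average`` (unweighted
        mean of covering tiles), or ``overwrite`` (later tile wins).
    """
    if len(tiles) != layout.rows * layout.cols:
        raise ValueError(
            f"expected {layout.rows * layout.cols} tiles, got {len(tiles)}"
        )
    if blend not in ("feather", "average", "overwrite"):
        raise ValueError(f"unknown blend mode: {blend!r}")
    l = layout.tile_px
    for i, t in enumerate(tiles):
        if t.shape != (l, l):
            raise ValueError(f"tile {i} shape {t.shape} != ({l}, {l})")

    nominal = layout.offsets
    shifts = np.zeros((len(tiles), 2), dtype=float)
    clamp = max_shift_frac * l
    overlap_px = l - layout.step_px

    if refine and overlap_px > 0:
        for i in range(len(tiles)):
            r, c = i // layout.cols, i % layout.cols
            estimates = []
            for (nr, nc) in ((r, c - 1), (r - 1, c)):
                if nr < 0 or nc < 0:
                    continue
                j = nr * layout.cols + nc
                if nc == c - 1:  # left neighbor: vertical overlap strips
                    strip_n = tiles[j][:, l - overlap_px :]
                    strip_i = tiles[i][:, :overlap_px]
                else:  # top neighbor: horizontal strips
                    strip_n = tiles[j][l - overlap_px :, :]
                    strip_i = tiles[i][: overlap_px, :]
                try:
                    m = phase_correlate(strip_n, strip_i)
                except ValueError:
                    continue
                # measured m = shift_of_neighbor - shift_of_this_tile
                estimates.append(shifts[j] - np.asarray(m))
            if estimates:
                est = np.mean(estimates, axis=0)
                if np.max(np.abs(est)) > clamp:
                    warnings.warn(
                        f"tile ({r},{c}): refinement shift {tuple(est)} exceeds "
                        f"clamp {clamp:.1f} px; using nominal position"
                    )
                else:
                    shifts[i] = est

    used = nominal + np.round(shifts).astype(int)
    top_left = used.min(axis=0)
    used_rel = used - top_left
    extent = used_rel.max(axis=0) + l
    mosaic = np.zeros(tuple(extent), dtype=np.float64)

    if blend == "overwrite":
        for t, (y, x) in zip(tiles, used_rel):
            mosaic[y : y + l, x : x + l] = t
    else:
        weights = np.zeros_like(mosaic)
        w_tile = _feather_weight((l, l)) if blend == "feather" else np.ones((l, l))
        for t, (y, x) in zip(tiles, used_rel):
            mosaic[y : y + l, x : x + l] += w_tile * t
            weights[y : y + l, x : x + l] += w_tile
        covered = weights > 0
        mosaic[covered] /= weights[covered]

    return StitchResult(mosaic=mosaic, offsets_used=used, refinement_shifts=shifts)
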