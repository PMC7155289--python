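"""TIFF and YAML I/O for tile stacks, layouts and reconstruction products.

Each mosaic position is stored as one multi-page TIFF (one page per
illumination phase) named ``tile_r{row}_c{col}.tif``, with a YAML sidecar
(``mosaic.yaml``) recording the grid layout, pattern parameters and, for
simulated data, the ground-truth parameters.  Reconstructed products are
written as 32-bit float TIFFs with ``_WF`` / ``_OS`` / ``_MAPSIM`` suffixes.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .simdata import MosaicLayout, PatternSet, TileStack, make_line_patterns

__all__ = [
    "write_tile_dir",
    "read_tile_dir",
    "write_image",
    "read_image",
    "SIDECAR_NAME",
]

SIDECAR_NAME = "mosaic.yaml"
_TILE_RE = re.compile(r"tile_r(\d+)_c(\d+)\.tif{1,2}$")


def write_image(path: str | Path, img: np.ndarray) -> None:
    """Write a single image as a 32-bit float TIFF."""
    tifffile.imwrite(str(path), np.asarray(img, dtype=np.float32))


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=np.float64)


def write_tile_dir(
    path: str | Path,
    stacks: list[TileStack],
    layout: MosaicLayout,
    pattern: PatternSet,
    extra_meta: dict | None = None,
) -> Path:
    """Write a full mosaic acquisition: per-tile multi-page TIFFs + sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for stack in stacks:
        r, c = stack.position
        tifffile.imwrite(
            str(path / f"tile_r{r}_c{c}.tif"),
            np.asarray(stack.data, dtype=np.float32),
            photometric="minisblack",
        )
    meta = {
        "layout": {
            "rows": layout.rows,
            "cols": layout.cols,
            "tile_px": layout.tile_px,
            "overlap_frac": float(layout.overlap_frac),
            "pixel_size_nm": float(layout.pixel_size_nm),
        },
        "pattern": {
            "period_px": pattern.period_px,
            "n_phases": pattern.n_phases,
            "orientation_deg": float(pattern.orientation_deg),
        },
    }
    if extra_meta:
        meta.update(extra_meta)
    (path / SIDECAR_NAME).write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_tile_dir(
    path: str | Path, overlap_frac: float | None = None
) -> tuple[list[TileStack], MosaicLayout, PatternSet]:
    """Read a tile directory back into stacks + layout + pattern.

    The layout and pattern come from the YAML sidecar when present;
    otherwise the grid is inferred from the filenames and ``overlap_frac``
    must be supplied.  Stacks are returned row-major.

    Raises
    ------
    FileNotFoundError
        If a grid position implied by the filenames is missing (the error
        names the missing (row, col)).
    ValueError
        If tiles disagree on the number of phases (offenders are listed).
    """
    path = Path(path)
    found: dict[tuple[int, int], Path] = {}
    for f in sorted(path.iterdir()):
        m = _TILE_RE.match(f.name)
        if m:
            found[(int(m.group(1)), int(m.group(2)))] = f
    if not found:
        raise FileNotFoundError(f"no tile_r*_c*.tif files in {path}")
    rows = max(r for r, _ in found) + 1
    cols = max(c for _, c in found) + 1
    missing = [(r, c) for r in range(rows) for c in range(cols) if (r, c) not in found]
    if missing:
        raise FileNotFoundError(f"missing tile positions: {missing}")

    sidecar = path / SIDECAR_NAME
    meta = yaml.safe_load(sidecar.read_text()) if sidecar.exists() else {}

    arrays: dict[tuple[int, int], np.ndarray] = {}
    for pos, f in found.items():
        arr = np.asarray(tifffile.imread(str(f)), dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[None]
        arrays[pos] = arr
    counts = {pos: a.shape[0] for pos, a in arrays.items()}
    n_phases = counts[(0, 0)]
    bad = [pos for pos, n in counts.items() if n != n_phases]
    if bad:
        raise ValueError(
            f"inconsistent phase counts: expected {n_phases}, offenders {sorted(bad)}"
        )

    tile_px = arrays[(0, 0)].shape[-1]
    lay_meta = meta.get("layout", {})
    layout = MosaicLayout(
        rows=lay_meta.get("rows", rows),
        cols=lay_meta.get("cols", cols),
        tile_px=lay_meta.get("tile_px", tile_px),
        overlap_frac=lay_meta.get(
            "overlap_frac", overlap_frac if overlap_frac is not None else 0.2
        ),
        pixel_size_nm=lay_meta.get("pixel_size_nm", 100.0),
    )
    pat_meta = meta.get("pattern")
    if pat_meta:
        pattern = make_line_patterns(
            tile_px=layout.tile_px,
            period_px=pat_meta["period_px"],
            n_phases=pat_meta["n_phases"],
            orientation_deg=pat_meta.get("orientation_deg", 0.0),
        )
    else:
        # no sidecar: a homogeneous all-on "pattern" so WF reconstruction works
        pattern = PatternSet(
            period_px=n_phases,
            n_phases=n_phases,
            orientation_deg=0.0,
            duty=1.0,
            masks=np.ones((n_phases, tile_px, tile_px)),
        )
    stacks = [
        TileStack(
            data=arrays[(r, c)],
            pattern=pattern,
            position=(r, c),
            pixel_size_nm=layout.pixel_size_nm,
        )
        for r in range(rows)
        for c in range(cols)
    ]
    return stacks, layout, pattern
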