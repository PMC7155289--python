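"""Remove the shared vignette from a tile grid and stitch it seamlessly.

Simulates a 4x4 mosaic of dense-tissue tiles that all carry the same
radial shading, estimates the vignette from the blurred average intensity
projection of the tiles, divides it out, and compares the grid-artifact
spectra of the uncorrected and corrected stitches.
"""

import panosim as ps

layout = ps.MosaicLayout(rows=4, cols=4, tile_px=128, overlap_frac=0.2)
pattern = ps.make_line_patterns(128, period_px=10, n_phases=5)
mh, mw = layout.mosaic_shape
truth = ps.SceneGroundTruth(
    scene=ps.make_scene("texture", max(mh, mw) + 8, seed=7),
    psf_sigma_px=1.0,
    vignette_truth=ps.make_vignette(128, strength=0.4),
    poisson_scale=50.0,
    read_sigma=0.5,
    seed=7,
)
stacks = ps.simulate_mosaic(truth, layout, pattern)
tiles = [ps.reconstruct_widefield(s) for s in stacks]

profile = ps.estimate_vignette(tiles, radius=8)
corrected = [ps.apply_devignette(t, profile) for t in tiles]

raw_mosaic = ps.stitch_grid(tiles, layout).mosaic
fixed_mosaic = ps.stitch_grid(corrected, layout).mosaic

for name, mosaic in (("uncorrected", raw_mosaic), ("devignetted", fixed_mosaic)):
    rep = ps.grid_artifact_spectrum(mosaic, layout)
    print(f"{name:12s}: grid peak/background = {rep.peak_ratio:8.1f} "
          f"(T_stitch = {rep.t_stitch_px:.1f} px)")
# The uncorrected stitch shows bright FFT peaks at 1/T_stitch; after
# dividing each tile by the estimated profile the peaks collapse into the
# spectral background (a ratio smaller by >= 10x).
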