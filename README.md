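# panosim

Panoramic structured-illumination microscopy (SIM) processing: from
phase-stepped tile acquisitions to a seamless, quantitatively scored
whole-slide mosaic.

Tiled SIM imaging of large samples (e.g., H&E-stained histology slides)
produces, for every mosaic position, a stack of N images acquired under a
shifting binary line-illumination pattern. Turning those stacks into one
clean panorama requires four computational stages, all provided here as a
library (with a thin `panosim` CLI on top):

1. **Reconstruction** (`panosim.recon`). Because the N pattern positions
   sum to homogeneous illumination, the wide-field image is the average
   intensity projection, I_WF = (1/N) Σₙ Iₙ. The optically sectioned
   (OS-SIM) image is the homodyne demodulation amplitude at the phase
   stepping frequency, OS(x) = (2/N) |Σₙ Iₙ(x) e^(−2πin/N)|, which keeps
   only pattern-modulated (in-focus) signal. MAP-SIM computes a maximum a
   posteriori estimate of the scene — argmin_{x≥0} Σₙ ‖P(mₙ∘x) − Iₙ‖² +
   λ‖∇x‖², with mₙ the known illumination masks and P the PSF-blur +
   downsample operator — and merges its high frequencies with the OS-SIM
   low frequencies in the Fourier domain.
2. **Devignetting** (`panosim.devignette`). SIM reconstruction leaves a
   smooth shading common to all tiles that calibration slides cannot
   capture. The profile is estimated as the border-limited-mean blur of the
   average intensity projection of the tiles, normalized to unit mean, and
   divided out. Bright-field color tiles are corrected additively with an
   empty-field reference.
3. **Stitching** (`panosim.stitch`). Tiles are placed on the nominal grid
   (step `round(l·(1−r))` for tile width l, overlap fraction r), optionally
   refined by phase correlation against placed neighbors, and blended
   (feather / average / overwrite).
4. **Metrics** (`panosim.metrics`). Resolution is the real-space period of
   the cut-off frequency where the noise-corrected, normalized radially
   averaged power spectral density (PSD) reaches zero. Residual vignetting
   repeats with period T_stitch = l·(1−r) and is scored by the FFT
   peak-to-background ratio at 1/T_stitch.

A full synthetic forward model (`panosim.simdata`) — scene, binary
shifting patterns whose per-set sum is exactly homogeneous, Gaussian PSF,
shared vignette, Poisson–Gaussian noise, overlapping tile grid — makes
every stage testable against ground truth without any microscope data.

## Worked example

`examples/devignette_and_stitch.py` simulates a 4×4 mosaic of dense-tissue
tiles (128 px tiles, 20% overlap, 5-phase pattern, vignette strength 0.4),
estimates and removes the vignette, and scores both stitches:

```
uncorrected : grid peak/background = 157504.6 (T_stitch = 102.4 px)
devignetted : grid peak/background =    224.8 (T_stitch = 102.4 px)
```

The uncorrected stitch's spectrum has bright peaks at the grid fundamental
1/T_stitch ≈ 1/102.4 cycles/px — the signature of tile-periodic shading.
Dividing each tile by the estimated profile suppresses the peak ratio by
~700×, i.e., the grid pattern disappears into the spectral background.

`examples/simulate_and_reconstruct.py` reconstructs a Siemens-star tile
(100 nm pixels) and measures both reconstructions:

```
wide-field resolution :  311.3 nm
MAP-SIM resolution    :  104.9 nm
```

MAP-SIM resolves a finer cut-off than wide-field because the patterned
acquisition plus deconvolution recovers frequencies the PSF attenuated.

Other examples: `measure_resolution.py` (PSD cut-off vs PSF width),
`full_pipeline.py` (one-call workflow with a hashed run manifest). The same
stages are available from the shell: `panosim simulate | reconstruct |
devignette | stitch | measure | run`.

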