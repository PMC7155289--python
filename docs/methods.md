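# Methods

This note records the models, estimators, parameter choices, and numerical
conventions behind `panosim`, and what the synthetic tests do and do not
demonstrate about real microscope data.

## Acquisition model (simdata)

A tile acquisition is modeled per phase n as

    I_n = Noise( PSF * (m_n · S_crop) · V )

where `S_crop` is a half-open, 0-based crop of the ground-truth scene at
the tile's nominal grid offset (optionally plus an integer stage-jitter),
`m_n` the n-th binary illumination mask, `PSF` an isotropic Gaussian of
sigma `psf_sigma_px`, `V` a multiplicative vignette common to all tiles,
and `Noise` Poisson shot noise (scaled by `poisson_scale`, the expected
photon count per intensity unit) followed by additive Gaussian read noise
(`read_sigma`) — the standard sCMOS noise model. All randomness derives
from one `numpy` Generator seeded by `SceneGroundTruth.seed`, so mosaics
are bit-reproducible.

**Patterns.** Masks are binary shifting line patterns, as produced by a
ferroelectric on/off microdisplay; sinusoidal illumination is out of scope.
A pixel is "on" in phase n when its coordinate along the pattern normal,
modulo `period_px`, falls in the n-th of N equal windows. Because the
windows partition the period, the pixelwise sum over phases is exactly
constant for any orientation — the property that makes the phase average a
true wide-field image — and the duty cycle is 1/N. `period_px` must be
divisible by `n_phases`; other combinations cannot sum homogeneously with
integer shifts and are rejected.

**Scenes.** Three deterministic generators: `beads` (sparse Gaussian
spots), `star` (36-spoke Siemens star with a faded hub, for resolution
measurements), and `texture` (difference-of-Gaussians filtered noise on a
bright baseline of 200 with ~100 units of variation). The texture baseline
emulates dense, fully stained tissue — the regime tiled-SIM devignetting
is designed for, where every pixel carries signal and foreground contrast
is modest relative to the mean. Sparse or high-contrast samples average
away less cleanly; see "Limitations".

**Vignette.** A parabolic radial falloff, 1 at the tile center and
`1 − strength` at the corners; default strength 0.4 gives the projection a
coefficient of variation of ~0.1, a visually obvious shading.

## Reconstruction (recon)

**Wide-field** is the exact arithmetic mean over phases — no scaling.

**OS-SIM.** The paper class of N-phase systems (5/6/8 phases) needs a
demodulator that is uniform in N, so the optical section is the homodyne
amplitude at the phase-stepping fundamental,
`OS(x) = (2/N) |Σ_n I_n(x) exp(−2πi n/N)|` — the N-phase generalization of
the classic three-phase square-root rule. A constant (unmodulated)
sequence gives exactly zero; a cosine-modulated sequence `c + a·cos`
returns `a`.

**MAP estimate.** Projected gradient descent on
`Σ_n ‖P(m_n ∘ x) − I_n‖² + λ‖∇x‖²` over x ≥ 0, with P = Gaussian blur at
the (upsampled) PSF width followed by block-mean downsampling; the adjoint
is block replication (scaled) followed by the same blur. The iteration is
initialized from the Fourier-upsampled wide-field image, uses a step
normalized to `max|x| / max|gradient|` with up to 12 halvings of
backtracking, tracks the best iterate, and warns (returning the best
iterate) if the objective rises on two consecutive iterations. Defaults:
20 iterations, λ = 0.01, upsample factor 2 (by Fourier zero-padding, which
preserves the image mean). These favor robustness over convergence speed;
the merge only needs the estimate's high-frequency band.

**Spectral merge.** `F_out = w·s·F_low + (1−w)·F_high`, with w a radially
symmetric raised-cosine low-pass of transition width 0.1×Nyquist centered
at `merge_cutoff_frac`×Nyquist (default 0.4), and s the ratio of mean
spectral magnitudes in the crossover annulus (matching the low spectrum to
the high one). The output is the real part of the inverse FFT, clipped at
zero — intensities are nonnegative. Because the OS and MAP images can sit
on different intensity scales (the demodulation amplitude is roughly a
duty-cycle fraction of the scene scale), `reconstruct_mapsim` first
rescales the MAP estimate to the OS image's mean; the merge then operates
between matched spectra (s ≈ 1) and the final image stays on the OS-SIM
intensity scale, within the 20% the merge contract tolerates.

## Devignetting (devignette)

The profile estimator is `border_limited_mean(average_projection(tiles),
radius)`, normalized to unit mean. Averaging across tiles cancels the
(tile-varying) foreground while preserving the (tile-constant) shading;
the blur removes the residual foreground coarseness. The border-limited
mean intersects its square window with the image domain and averages only
in-bounds pixels — no padding or mirroring — so a constant image is
preserved exactly out to its corners, avoiding the bright edge glow that
padded Gaussian blurs produce. It is computed exactly (to float rounding)
as the ratio of two zero-padded uniform filters.

Unit-mean normalization (rather than unit-max) makes division
scale-preserving: the corrected mosaic's mean stays within float tolerance
of the uncorrected mean. The module-level default radius of 200 px suits
full-size (~2048 px) camera frames; for smaller synthetic tiles the radius
should scale roughly proportionally. The profile-recovery tests use radius
≈ 4% of the tile width: large enough to suppress foreground residue of a
few-pixel correlation length, small enough that the window-clipping bias
near borders (the mean of a sloped profile over an asymmetric window)
stays well under 1%. Profiles are estimated separately per reconstruction
method — the shading left by WF averaging and by MAP-SIM differ.

Bright-field color tiles are corrected additively: `out = clip(tile +
(white_level − empty), 0, white_level)`, the photographic inverse of an
empty-field acquisition; a pixel identical to the empty reference maps to
pure white. This is the only reading under which adding the "inverse"
flattens the background.

## Stitching (stitch)

Nominal placement uses step `round(l·(1−r))`. Refinement phase-correlates
each tile's overlap strips against its already-placed left/top neighbors
(row-major), chaining the neighbors' accepted corrections so the estimates
compose across the grid; shifts beyond `0.1 × tile_px` (configurable) are
treated as spurious low-texture correlations and dropped with a warning.
Sub-pixel estimates come from upsampled cross-correlation; placement
rounds to integer pixels. Blending: `feather` weights each tile by its
linear distance to the nearest edge (+1, so border pixels keep nonzero
weight) and normalizes by the accumulated weight — a partition of unity
wherever at least one tile covers; `average` is the unweighted mean;
`overwrite` lets the later tile win. When overlapping data are consistent,
all three produce identical mosaics.

## Metrics (metrics)

**PSD cut-off resolution.** Power spectra are windowed (Hann by default;
`window=None` gives a leakage-free raw FFT for synthetic band-limited
inputs), circularly averaged into `side/2` radial bins up to Nyquist, and
normalized to maximum 1. The noise floor is the mean over the top decile
of radial frequencies; the cut-off is the first frequency at which the
noise-corrected curve falls to zero, linearly interpolated between the
straddling bins, with a 1e−12 relative tolerance so machine-precision
dust in clean synthetic tails cannot postpone the crossing. Resolution is
`pixel_size / cutoff_freq`. The estimator is scale-invariant and monotone
in PSF width; constant images (no spectrum beyond DC) are rejected.

**Grid artifact.** The artifact period is `T_stitch = l·(1−r)`; its
fundamental is sampled on both frequency axes at the nearest FFT bin with
a 3×3-neighborhood maximum (one-bin discretization tolerance), against a
background taken as the median of a surrounding annulus of radii 2–8 bins
that excludes the peak neighborhood and the DC core. The report carries
the mean peak-to-background ratio and the two 1-D axis profiles through
the spectrum center. A peak over an exactly zero background (a pure tone)
reports infinity; spectra whose "peak" is FFT round-off dust (≤1e−18 of
total power) report zero.

## Pipeline (cli_io / pipeline)

`run_pipeline` executes simulate-or-read → per-tile reconstruction →
per-method devignette → stitch (both uncorrected and corrected, so the
suppression is measurable) → metrics, writing every product as 32-bit
float TIFF and a YAML manifest with the resolved configuration, per-stage
timings, metric values, and SHA-256 hashes of all outputs. Identical
configurations and seeds reproduce identical hashes. Tile directories use
one multi-page TIFF per mosaic position (`tile_r{row}_c{col}.tif`) plus a
YAML sidecar holding layout and pattern parameters.

## Problem sizes in the test suite

Synthetic checks run on 96–128 px tiles in grids from 1×1 to 7×7, 4–5
phase patterns of period 8–10 px, and 8–20 MAP iterations — large enough
that every spectral quantity has well-separated bins, small enough that
the whole suite completes in well under a minute.

## Limitations

- The vignette estimator assumes dense scenes and many tiles; for sparse
  samples or small grids the average projection retains foreground and
  the profile estimate degrades (the coarseness grows noticeably below a
  few dozen tiles).
- The MAP solver is a plain first-order method with a quadratic prior; it
  demonstrates the objective contract and the resolution gain on synthetic
  data but is not tuned for speed or for edge-preserving regularization.
- The synthetic PSF is an isotropic Gaussian and patterns are assumed
  known exactly (as on a microdisplay system); pattern-phase estimation
  from data, measured PSFs, 3-D stacks, and sub-pixel stage jitter are not
  modeled, so the tests say nothing about robustness to those effects.
- Stitching is translation-only on a known grid; rotation, affine error,
  and illumination-aware seam placement are out of scope.
- Resolution values measured on synthetic star tiles depend on the chosen
  PSF, pattern period, and noise levels; only orderings and invariances
  (MAP-SIM finer than WF; scale invariance; blur monotonicity) transfer
  beyond the simulation.
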