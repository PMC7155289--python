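"""Reconstruction of wide-field, optically sectioned, and MAP-SIM images.

Three estimates are produced from one phase-stepped tile stack:

* **Wide-field (WF)** -- the average intensity projection ``(1/N) sum_n I_n``.
  Because the illumination pattern set sums to homogeneous illumination,
  this equals a conventional unpatterned exposure.
* **OS-SIM** -- homodyne demodulation at the phase-stepping frequency,
  ``OS(x) = (2/N) | sum_n I_n(x) exp(-2 pi i n / N) |``.  Only structures
  modulated by the illumination (i.e., in focus) survive; constant
  background is rejected.  This generalizes the classic three-phase
  square-root rule to the 5/6/8-phase sets used on binary microdisplays.
* **MAP-SIM** -- a maximum a posteriori estimate of the underlying scene
  obtained by projected gradient descent on a least-squares data term with
  a Tikhonov-on-gradient prior, then merged in the Fourier domain with the
  OS-SIM image: the OS spectrum supplies the low frequencies, the MAP
  spectrum the high frequencies, with a raised-cosine radial crossover.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import warnings

import numpy as np
from scipy import ndimage

from .simdata import PatternSet, TileStack

__all__ = [
    "ReconParams",
    "ReconResult",
    "reconstruct_widefield",
    "reconstruct_ossim",
    "map_estimate",
    "spectral_merge",
    "reconstruct_mapsim",
    "fourier_upsample",
]


@dataclass(frozen=True)
class ReconParams:
    """Tunable parameters of the MAP-SIM reconstruction.

    Attributes
    ----------
    map_iterations
        Gradient-descent iterations (default 20; the objective decrease is
        steep early and the merge only needs the high-frequency content).
    map_step
        Initial step size; adapted by backtracking, so the default is safe.
    map_lambda
        Weight of the squared-gradient (Tikhonov) prior relative to the
        data term.  0 disables regularization.
    psf_sigma_px
        Gaussian PSF sigma assumed by the imaging operator, in raw-data
        pixels.
    merge_cutoff_frac
        Spectral crossover of the OS/MAP merge, as a fraction of the
        Nyquist frequency.
    upsample_factor
        Integer grid refinement of the MAP estimate (2 for super-resolution
        output, 1 for speed).
    """

    map_iterations: int = 20
    map_step: float = 1.0
    map_lambda: float = 0.01
    psf_sigma_px: float = 1.0
    merge_cutoff_frac: float = 0.4
    upsample_factor: int = 2

    def __post_init__(self) -> None:
        if self.map_iterations < 1:
            raise ValueError("map_iterations must be >= 1")
        if not (0 < self.merge_cutoff_frac < 1):
            raise ValueError("merge_cutoff_frac must lie in (0, 1)")
        if self.upsample_factor < 1:
            raise ValueError("upsample_factor must be >= 1")


@dataclass(frozen=True)
class ReconResult:
    """Bundle of the three reconstructions of one tile."""

    wf: np.ndarray
    os: np.ndarray
    mapsim: np.ndarray
    params: ReconParams


def reconstruct_widefield(stack: TileStack) -> np.ndarray:
    """Average intensity projection of the phase images: ``(1/N) sum_n I_n``."""
    if stack.data.shape[0] < 1:
        raise ValueError("empty stack")
    return stack.data.mean(axis=0)


def reconstruct_ossim(stack: TileStack) -> np.ndarray:
    """Per-pixel demodulation amplitude at the phase-stepping frequency.

    Computes ``(2/N) | sum_n I_n exp(-2 pi i n / N) |`` -- the magnitude of
    the first DFT coefficient of the per-pixel phase sequence, scaled so
    that a pure cosine modulation ``c + a cos(2 pi n / N)`` returns ``a``.
    Unmodulated (out-of-focus or constant) signal vanishes identically.
    """
    n = stack.data.shape[0]
    if n < 3:
        raise ValueError("OS-SIM demodulation needs >= 3 phases")
    phases = np.exp(-2j * np.pi * np.arange(n) / n)
    acc = np.tensordot(phases, stack.data.astype(np.float64), axes=(0, 0))
    return (2.0 / n) * np.abs(acc)


def fourier_upsample(img: np.ndarray, factor: int) -> np.ndarray:
    """Upsample by zero-padding the centered spectrum; preserves the mean."""
    if factor == 1:
        return img.astype(np.float64, copy=True)
    h, w = img.shape
    spec = np.fft.fftshift(np.fft.fft2(img))
    padded = np.zeros((h * factor, w * factor), dtype=complex)
    top, left = (h * factor - h) // 2, (w * factor - w) // 2
    padded[top : top + h, left : left + w] = spec
    out = np.fft.ifft2(np.fft.ifftshift(padded)).real * factor**2
    return out


def _block_mean(img: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return img
    h, w = img.shape
    return img.reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))


def _block_repeat(img: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return img
    return np.repeat(np.repeat(img, factor, axis=0), factor, axis=1)


class MapDiagnostics(UserWarning):
    """Raised as a warning when the MAP objective fails to keep decreasing."""


def map_estimate(
    stack: TileStack, pattern: PatternSet, params: ReconParams
) -> np.ndarray:
    """MAP estimate of the scene on a (possibly upsampled) grid.

    Minimizes, over nonnegative images ``x`` on the fine grid,

        ``sum_n || P(m_n * x) - I_n ||^2 + lambda ||grad x||^2``

    where ``m_n`` is the n-th illumination mask (block-replicated to the
    fine grid), and ``P`` is Gaussian blurring by the assumed PSF followed
    by block-mean downsampling to the camera grid.  Solved by projected
    gradient descent with backtracking line search, initialized from the
    upsampled wide-field image.  Deterministic.

    If the objective increases on two consecutive iterations despite
    backtracking, a :class:`MapDiagnostics` warning is emitted and the best
    iterate found is returned.
    """
    if pattern.masks.shape[1:] != stack.data.shape[1:]:
        raise ValueError("pattern masks must match the stack geometry")
    f = params.upsample_factor
    data = stack.data.astype(np.float64)
    masks_hi = np.stack([_block_repeat(m, f) for m in pattern.masks])
    sigma_hi = params.psf_sigma_px * f

    def forward(x: np.ndarray, m: np.ndarray) -> np.ndarray:
        y = m * x
        if sigma_hi > 0:
            y = ndimage.gaussian_filter(y, sigma_hi)
        return _block_mean(y, f)

    def adjoint(r: np.ndarray, m: np.ndarray) -> np.ndarray:
        y = _block_repeat(r, f) / f**2
        if sigma_hi > 0:
            y = ndimage.gaussian_filter(y, sigma_hi)
        return m * y

    lam = params.map_lambda

    def objective(x: np.ndarray) -> float:
        val = 0.0
        for n in range(data.shape[0]):
            resid = forward(x, masks_hi[n]) - data[n]
            val += float(np.sum(resid**2))
        if lam > 0:
            gy, gx = np.gradient(x)
            val += lam * float(np.sum(gy**2) + np.sum(gx**2))
        return val

    def gradient(x: np.ndarray) -> np.ndarray:
        g = np.zeros_like(x)
        for n in range(data.shape[0]):
            resid = forward(x, masks_hi[n]) - data[n]
            g += 2.0 * adjoint(resid, masks_hi[n])
        if lam > 0:
            g += -2.0 * lam * ndimage.laplace(x)
        return g

    x = np.maximum(fourier_upsample(reconstruct_widefield(stack), f), 0.0)
    best_x, best_obj = x, objective(x)
    obj = best_obj
    step = params.map_step
    bad_streak = 0
    for _ in range(params.map_iterations):
        g = gradient(x)
        # normalize the step to the problem scale once per iterate
        gnorm = float(np.max(np.abs(g)))
        if gnorm == 0:
            break
        trial_step = step * float(np.max(np.abs(x)) + 1e-12) / gnorm
        new_x = np.maximum(x - trial_step * g, 0.0)
        new_obj = objective(new_x)
        n_back = 0
        while new_obj > obj and n_back < 12:
            trial_step *= 0.5
            new_x = np.maximum(x - trial_step * g, 0.0)
            new_obj = objective(new_x)
            n_back += 1
        if new_obj > obj:
            bad_streak += 1
            if bad_streak >= 2:
                warnings.warn(
                    f"MAP objective stalled at {best_obj:.6g}; returning best iterate",
                    MapDiagnostics,
                )
                return best_x
        else:
            bad_streak = 0
        x, obj = new_x, new_obj
        if obj < best_obj:
            best_x, best_obj = x, obj
    return best_x


def _radial_freq_grid(shape: tuple[int, int]) -> np.ndarray:
    fy = np.fft.fftfreq(shape[0])
    fx = np.fft.fftfreq(shape[1])
    return np.hypot(fy[:, None], fx[None, :])


def spectral_merge(
    low_img: np.ndarray, high_img: np.ndarray, merge_cutoff_frac: float
) -> np.ndarray:
    """Fuse two images in the Fourier domain: low frequencies from
    ``low_img``, high frequencies from ``high_img``.

    The merge is ``F_out = w * s * F_low + (1 - w) * F_high`` where ``w`` is
    a radially symmetric raised-cosine low-pass with transition width
    0.1 x Nyquist centered at ``merge_cutoff_frac`` x Nyquist, and ``s``
    matches the mean spectral magnitude of the low image to the high image
    inside the crossover annulus.  The output is the real part of the
    inverse transform, clipped at zero.
    """
    if low_img.shape != high_img.shape:
        raise ValueError(
            f"shape mismatch: low {low_img.shape} vs high {high_img.shape}"
        )
    nyquist = 0.5
    f0 = merge_cutoff_frac * nyquist
    width = 0.1 * nyquist
    fr = _radial_freq_grid(low_img.shape)
    w = np.where(
        fr <= f0 - width / 2,
        1.0,
        np.where(
            fr >= f0 + width / 2,
            0.0,
            0.5 * (1.0 + np.cos(np.pi * (fr - (f0 - width / 2)) / width)),
        ),
    )
    f_low = np.fft.fft2(low_img)
    f_high = np.fft.fft2(high_img)
    annulus = (fr >= f0 - width / 2) & (fr <= f0 + width / 2)
    mean_low = float(np.mean(np.abs(f_low[annulus]))) if annulus.any() else 0.0
    mean_high = float(np.mean(np.abs(f_high[annulus]))) if annulus.any() else 0.0
    s = mean_high / mean_low if mean_low > 0 else 1.0
    out = np.fft.ifft2(w * s * f_low + (1.0 - w) * f_high).real
    return np.maximum(out, 0.0)


def reconstruct_mapsim(
    stack: TileStack, pattern: PatternSet, params: ReconParams | None = None
) -> ReconResult:
    """Full per-tile reconstruction pipeline.

    Computes the WF and OS-SIM images, the MAP estimate on the upsampled
    grid, rescales the MAP estimate to the OS image's mean intensity (so
    the merged spectra share a common scale and the output stays on the
    OS-SIM intensity scale), and merges the two in the Fourier domain.
    Deterministic for fixed parameters.
    """
    if params is None:
        params = ReconParams()
    wf = reconstruct_widefield(stack)
    os_img = reconstruct_ossim(stack)
    hi = map_estimate(stack, pattern, params)
    os_up = np.maximum(fourier_upsample(os_img, params.upsample_factor), 0.0)
    mean_hi = float(hi.mean())
    if mean_hi > 0 and os_up.mean() > 0:
        hi = hi * (float(os_up.mean()) / mean_hi)
    mapsim = spectral_merge(os_up, hi, params.merge_cutoff_frac)
    return ReconResult(wf=wf, os=os_img, mapsim=mapsim, params=params)
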