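"""Feature-similarity (FSIM) index.

FSIM scores a reconstruction against its reference by combining two
low-level feature maps: phase congruency (PC), which marks perceptually
significant structure independent of contrast, and gradient magnitude (G).
Pointwise similarity maps

    S_PC = (2 PC1 PC2 + T1) / (PC1^2 + PC2^2 + T1)
    S_G  = (2 G1 G2 + T2) / (G1^2 + G2^2 + T2)

are pooled with phase-congruency weights PCm = max(PC1, PC2):

    FSIM = sum(S_PC * S_G * PCm) / sum(PCm)

Phase congruency is computed with a bank of log-Gabor filters (4 scales x 4
orientations by default) following the standard monogenic-free formulation:
per orientation, the local energy along the summed filter responses is
noise-thresholded using a Rayleigh estimate from the smallest-scale
amplitudes, then normalized by the total amplitude sum.  The gradient is a
Scharr 3x3 operator.  T2 is defined on a 0-255 dynamic range; inputs in
[0, 1] are scaled by 255 internally so the published constants keep their
meaning.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import DomainError

_SCHARR_X = np.array([[3, 0, -3], [10, 0, -10], [3, 0, -3]]) / 16.0
_SCHARR_Y = _SCHARR_X.T


def _lowpass_filter(shape: tuple[int, int], cutoff: float = 0.45,
                    n: int = 15) -> np.ndarray:
    """Butterworth low-pass in the frequency domain (origin at [0, 0])."""
    rows, cols = shape
    radius = _radial_grid(shape)[0]
    return 1.0 / (1.0 + (radius / cutoff) ** (2 * n))


def _freq_axis(n: int) -> np.ndarray:
    if n % 2:
        return np.arange(-(n - 1) // 2, (n - 1) // 2 + 1) / (n - 1)
    return np.arange(-n // 2, n // 2) / n


def _radial_grid(shape: tuple[int, int]):
    rows, cols = shape
    x, y = np.meshgrid(_freq_axis(cols), _freq_axis(rows))
    radius = np.fft.ifftshift(np.sqrt(x * x + y * y))
    theta = np.fft.ifftshift(np.arctan2(-y, x))
    radius[0, 0] = 1.0  # avoid log(0) at DC; DC response is zeroed anyway
    return radius, theta


#: cached log-Gabor banks keyed by (shape, scales, orients, wavelength,
#: mult, sigma_on_f, d_theta_on_sigma); building the bank dominates a
#: single phase-congruency call, and evaluation scores hundreds of
#: same-sized images
_BANKS: dict[tuple, list] = {}


def _filter_bank(shape, nscale, norient, min_wavelength, mult, sigma_on_f,
                 d_theta_on_sigma):
    """Per-orientation list of (filters, ifft_filters, EM_n, noise sums)."""
    key = (shape, nscale, norient, min_wavelength, mult, sigma_on_f,
           d_theta_on_sigma)
    if key in _BANKS:
        return _BANKS[key]
    rows, cols = shape
    radius, theta = _radial_grid(shape)
    sintheta, costheta = np.sin(theta), np.cos(theta)
    lp = _lowpass_filter(shape)

    log_gabor = []
    for s in range(nscale):
        fo = 1.0 / (min_wavelength * mult ** s)
        g = np.exp(-(np.log(radius / fo)) ** 2
                   / (2.0 * np.log(sigma_on_f) ** 2)) * lp
        g[0, 0] = 0.0
        log_gabor.append(g)

    theta_sigma = np.pi / norient / d_theta_on_sigma
    bank = []
    for o in range(norient):
        angl = o * np.pi / norient
        ds = sintheta * np.cos(angl) - costheta * np.sin(angl)
        dc = costheta * np.cos(angl) + sintheta * np.sin(angl)
        dtheta = np.abs(np.arctan2(ds, dc))
        spread = np.exp(-dtheta ** 2 / (2.0 * theta_sigma ** 2))
        filters = [g * spread for g in log_gabor]
        ifft_filters = [np.real(np.fft.ifft2(f)) * np.sqrt(rows * cols)
                        for f in filters]
        em_n = float(np.sum(filters[0] ** 2))
        sum_an2 = float(np.sum(sum(f ** 2 for f in ifft_filters)))
        sum_aiaj = 0.0
        for si in range(nscale - 1):
            for sj in range(si + 1, nscale):
                sum_aiaj += float(np.sum(ifft_filters[si] * ifft_filters[sj]))
        bank.append((filters, ifft_filters, em_n, (sum_an2, sum_aiaj)))
    if len(_BANKS) > 8:  # bound memory across many distinct sizes
        _BANKS.clear()
    _BANKS[key] = bank
    return bank


def phase_congruency(img: np.ndarray, nscale: int = 4, norient: int = 4,
                     min_wavelength: float = 6.0, mult: float = 2.0,
                     sigma_on_f: float = 0.55, d_theta_on_sigma: float = 1.2,
                     k: float = 2.0, epsilon: float = 1e-4) -> np.ndarray:
    """Phase-congruency map in [0, 1] via a log-Gabor filter bank.

    Per orientation the filter responses are summed over scales; local
    energy is projected on the mean phase vector, reduced by an estimated
    noise floor (Rayleigh statistics of the smallest-scale amplitude), and
    normalized by the summed amplitudes.  Orientation energies are pooled
    by summation.
    """
    img = np.asarray(img, dtype=np.float64)
    imagefft = np.fft.fft2(img)

    bank = _filter_bank(img.shape, nscale, norient, min_wavelength, mult,
                        sigma_on_f, d_theta_on_sigma)

    energy_all = np.zeros_like(img)
    an_all = np.zeros_like(img)

    for o in range(norient):
        eo = []
        sum_e = np.zeros_like(img)
        sum_o = np.zeros_like(img)
        sum_an = np.zeros_like(img)
        filters, _, em_n, noise_consts = bank[o]
        for s in range(nscale):
            response = np.fft.ifft2(imagefft * filters[s])
            eo.append(response)
            an = np.abs(response)
            sum_an += an
            sum_e += np.real(response)
            sum_o += np.imag(response)

        x_energy = np.sqrt(sum_e ** 2 + sum_o ** 2) + epsilon
        mean_e, mean_o = sum_e / x_energy, sum_o / x_energy
        energy = np.zeros_like(img)
        for response in eo:
            e, od = np.real(response), np.imag(response)
            energy += e * mean_e + od * mean_o - np.abs(e * mean_o - od * mean_e)

        # Rayleigh noise floor from the smallest-scale amplitude median
        median_e2n = np.median(np.abs(eo[0]) ** 2)
        mean_e2n = -median_e2n / np.log(0.5)
        noise_power = mean_e2n / em_n
        sum_an2, sum_aiaj = noise_consts
        est_noise_energy2 = (2.0 * noise_power * sum_an2
                             + 4.0 * noise_power * sum_aiaj)
        tau = np.sqrt(est_noise_energy2 / 2.0)
        est_noise_energy = tau * np.sqrt(np.pi / 2.0)
        est_noise_sigma = np.sqrt((2.0 - np.pi / 2.0) * tau ** 2)
        t = (est_noise_energy + k * est_noise_sigma) / 1.7

        energy_all += np.maximum(energy - t, 0.0)
        an_all += sum_an

    return energy_all / (an_all + epsilon)


def _gradient_magnitude(img: np.ndarray) -> np.ndarray:
    gx = ndimage.convolve(img, _SCHARR_X, mode="constant")
    gy = ndimage.convolve(img, _SCHARR_Y, mode="constant")
    return np.sqrt(gx * gx + gy * gy)


def fsim(x: np.ndarray, x_hat: np.ndarray, scales: int = 4, orientations: int = 4,
         t1: float = 0.85, t2: float = 160.0,
         min_wavelength: float = 6.0, mult: float = 2.0,
         sigma_on_f: float = 0.55) -> float:
    """Feature-similarity index between two images in [0, 1].

    Symmetric in its arguments and equal to 1 for identical images.  Images
    are rescaled to 0-255 internally so the published stabilizing constants
    T1 (phase congruency) and T2 (gradient, 0-255 scale) apply unchanged.
    Images are downsampled by ``round(min(H, W) / 256)`` (when > 1) with
    block averaging first, as the published procedure prescribes.
    """
    x = np.asarray(x, dtype=np.float64) * 255.0
    x_hat = np.asarray(x_hat, dtype=np.float64) * 255.0
    if x.shape != x_hat.shape:
        raise DomainError(f"shape mismatch {x.shape} vs {x_hat.shape}")
    if min(x.shape) < 32:
        raise DomainError("images must be at least 32 pixels per side")

    f = max(1, int(round(min(x.shape) / 256.0)))
    if f > 1:
        kern = np.ones((f, f)) / (f * f)
        x = ndimage.convolve(x, kern, mode="nearest")[::f, ::f]
        x_hat = ndimage.convolve(x_hat, kern, mode="nearest")[::f, ::f]

    pc1 = phase_congruency(x, nscale=scales, norient=orientations,
                           min_wavelength=min_wavelength, mult=mult,
                           sigma_on_f=sigma_on_f)
    pc2 = phase_congruency(x_hat, nscale=scales, norient=orientations,
                           min_wavelength=min_wavelength, mult=mult,
                           sigma_on_f=sigma_on_f)
    g1 = _gradient_magnitude(x)
    g2 = _gradient_magnitude(x_hat)

    s_pc = (2.0 * pc1 * pc2 + t1) / (pc1 ** 2 + pc2 ** 2 + t1)
    s_g = (2.0 * g1 * g2 + t2) / (g1 ** 2 + g2 ** 2 + t2)
    pcm = np.maximum(pc1, pc2)
    denom = float(np.sum(pcm))
    if denom == 0.0:  # featureless pair (e.g. two constants)
        return 1.0 if np.array_equal(x, x_hat) else 0.0
    return float(np.sum(s_pc * s_g * pcm) / denom)
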