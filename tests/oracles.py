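"""Independent reference implementations used only as test oracles.

These deliberately re-derive the metrics from their published definitions
with a different code organization than the package (direct valid-region
convolutions, MATLAB-style filter construction with explicit fftshift
grids), so that agreement is a meaningful cross-check rather than a
tautology.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import convolve2d


# ---------------------------------------------------------------- SSIM --
def ssim_reference(img1: np.ndarray, img2: np.ndarray, data_range: float = 1.0,
                   sigma: float = 1.5, win: int = 11,
                   k1: float = 0.01, k2: float = 0.03) -> float:
    """Windowed SSIM exactly as in the original publication: Gaussian
    window, valid region only, population statistics."""
    ax = np.arange(win) - (win - 1) / 2.0
    g = np.exp(-(ax ** 2) / (2.0 * sigma ** 2))
    w = np.outer(g, g)
    w /= w.sum()

    x = np.asarray(img1, dtype=np.float64)
    y = np.asarray(img2, dtype=np.float64)
    mu1 = convolve2d(x, w, mode="valid")
    mu2 = convolve2d(y, w, mode="valid")
    s11 = convolve2d(x * x, w, mode="valid") - mu1 ** 2
    s22 = convolve2d(y * y, w, mode="valid") - mu2 ** 2
    s12 = convolve2d(x * y, w, mode="valid") - mu1 * mu2

    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    num = (2 * mu1 * mu2 + c1) * (2 * s12 + c2)
    den = (mu1 ** 2 + mu2 ** 2 + c1) * (s11 + s22 + c2)
    return float(np.mean(num / den))


# ---------------------------------------------------------------- FSIM --
def _lowpassfilter(rows: int, cols: int, cutoff: float, n: int) -> np.ndarray:
    if cols % 2:
        xr = np.arange(-(cols - 1) / 2, (cols - 1) / 2 + 1) / (cols - 1)
    else:
        xr = np.arange(-cols / 2, cols / 2) / cols
    if rows % 2:
        yr = np.arange(-(rows - 1) / 2, (rows - 1) / 2 + 1) / (rows - 1)
    else:
        yr = np.arange(-rows / 2, rows / 2) / rows
    xg, yg = np.meshgrid(xr, yr)
    radius = np.sqrt(xg ** 2 + yg ** 2)
    f = np.fft.ifftshift(1.0 / (1.0 + (radius / cutoff) ** (2 * n)))
    return f


def phasecong_reference(im: np.ndarray, nscale=4, norient=4, min_wave=6,
                        mult=2, sigma_onf=0.55, d_theta_sigma=1.2, k=2.0,
                        eps=1e-4) -> np.ndarray:
    """Phase congruency map, a direct transcription of the published
    log-Gabor local-energy algorithm with Rayleigh noise compensation."""
    rows, cols = im.shape
    imfft = np.fft.fft2(im)

    if cols % 2:
        xr = np.arange(-(cols - 1) / 2, (cols - 1) / 2 + 1) / (cols - 1)
    else:
        xr = np.arange(-cols / 2, cols / 2) / cols
    if rows % 2:
        yr = np.arange(-(rows - 1) / 2, (rows - 1) / 2 + 1) / (rows - 1)
    else:
        yr = np.arange(-rows / 2, rows / 2) / rows
    xg, yg = np.meshgrid(xr, yr)
    radius = np.fft.ifftshift(np.sqrt(xg ** 2 + yg ** 2))
    theta = np.fft.ifftshift(np.arctan2(-yg, xg))
    radius[0, 0] = 1.0
    sintheta, costheta = np.sin(theta), np.cos(theta)
    lp = _lowpassfilter(rows, cols, 0.45, 15)

    theta_sigma = np.pi / norient / d_theta_sigma
    energy_all = np.zeros((rows, cols))
    an_all = np.zeros((rows, cols))

    for o in range(norient):
        angl = o * np.pi / norient
        ds = sintheta * np.cos(angl) - costheta * np.sin(angl)
        dc = costheta * np.cos(angl) + sintheta * np.sin(angl)
        dtheta = np.abs(np.arctan2(ds, dc))
        spread = np.exp(-dtheta ** 2 / (2 * theta_sigma ** 2))

        eo_list, ifft_list = [], []
        sum_an = np.zeros((rows, cols))
        sum_e = np.zeros((rows, cols))
        sum_o = np.zeros((rows, cols))
        em_n = 0.0
        for s in range(nscale):
            fo = 1.0 / (min_wave * mult ** s)
            log_gabor = np.exp(
                -(np.log(radius / fo)) ** 2 / (2 * np.log(sigma_onf) ** 2))
            log_gabor *= lp
            log_gabor[0, 0] = 0.0
            filt = log_gabor * spread
            if s == 0:
                em_n = float(np.sum(filt ** 2))
            eo = np.fft.ifft2(imfft * filt)
            eo_list.append(eo)
            ifft_list.append(np.real(np.fft.ifft2(filt)) * np.sqrt(rows * cols))
            sum_an += np.abs(eo)
            sum_e += np.real(eo)
            sum_o += np.imag(eo)

        x_energy = np.sqrt(sum_e ** 2 + sum_o ** 2) + eps
        mean_e = sum_e / x_energy
        mean_o = sum_o / x_energy
        energy = np.zeros((rows, cols))
        for eo in eo_list:
            e, od = np.real(eo), np.imag(eo)
            energy += e * mean_e + od * mean_o - np.abs(e * mean_o - od * mean_e)

        median_e2n = np.median(np.abs(eo_list[0]) ** 2)
        mean_e2n = -median_e2n / np.log(0.5)
        noise_power = mean_e2n / em_n
        est_sum_an2 = sum(f ** 2 for f in ifft_list)
        est_sum_aiaj = np.zeros((rows, cols))
        for si in range(nscale - 1):
            for sj in range(si + 1, nscale):
                est_sum_aiaj += ifft_list[si] * ifft_list[sj]
        est_noise_energy2 = 2 * noise_power * np.sum(est_sum_an2) \
            + 4 * noise_power * np.sum(est_sum_aiaj)
        tau = np.sqrt(est_noise_energy2 / 2)
        est_noise_energy = tau * np.sqrt(np.pi / 2)
        est_noise_sigma = np.sqrt((2 - np.pi / 2) * tau ** 2)
        t = (est_noise_energy + k * est_noise_sigma) / 1.7

        energy_all += np.maximum(energy - t, 0)
        an_all += sum_an

    return energy_all / (an_all + eps)


def fsim_reference(img1: np.ndarray, img2: np.ndarray) -> float:
    """FSIM on images in [0, 1], transcribed from the published procedure
    (0-255 scale, optional block-average downsampling, Scharr gradients,
    T1 = 0.85, T2 = 160)."""
    im1 = np.asarray(img1, dtype=np.float64) * 255.0
    im2 = np.asarray(img2, dtype=np.float64) * 255.0
    rows, cols = im1.shape
    f = max(1, round(min(rows, cols) / 256))
    if f > 1:
        ave = np.ones((f, f)) / f ** 2
        im1 = convolve2d(im1, ave, mode="same")[::f, ::f]
        im2 = convolve2d(im2, ave, mode="same")[::f, ::f]

    pc1 = phasecong_reference(im1)
    pc2 = phasecong_reference(im2)

    dx = np.array([[3, 0, -3], [10, 0, -10], [3, 0, -3]]) / 16.0
    dy = dx.T
    g1 = np.sqrt(convolve2d(im1, dx, mode="same") ** 2
                 + convolve2d(im1, dy, mode="same") ** 2)
    g2 = np.sqrt(convolve2d(im2, dx, mode="same") ** 2
                 + convolve2d(im2, dy, mode="same") ** 2)

    t1, t2 = 0.85, 160.0
    pc_sim = (2 * pc1 * pc2 + t1) / (pc1 ** 2 + pc2 ** 2 + t1)
    g_sim = (2 * g1 * g2 + t2) / (g1 ** 2 + g2 ** 2 + t2)
    pcm = np.maximum(pc1, pc2)
    return float(np.sum(pc_sim * g_sim * pcm) / np.sum(pcm))
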