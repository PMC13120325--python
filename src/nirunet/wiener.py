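"""Adaptive (local linear MMSE) Wiener-filter baseline.

Per pixel, with local mean mu and local variance s^2 over a sliding window
and noise power v^2 (estimated as the image-mean local variance when not
given):

    out = mu + max(s^2 - v^2, 0) / max(s^2, v^2) * (x - mu)

which suppresses the signal toward the local mean wherever the local
variance is at or below the noise level.  Local statistics use reflective
boundary handling so a constant image passes through unchanged (zero-padded
windows would see spurious variance at the borders).  Because captured
images are darker where the hidden pattern lies, an optional normalization
step inverts polarity and min-max rescales the output so it is directly
comparable to the bright-on-dark targets.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import DomainError


def wiener_reconstruct(captured: np.ndarray, window: int = 5,
                       noise_power: float | None = None,
                       normalize: bool = False) -> np.ndarray:
    """Filter a captured image; optionally invert/rescale toward target
    polarity.

    Parameters
    ----------
    captured
        2-D image in [0, 1].
    window
        Odd sliding-window size (>= 3) for the local statistics.
    noise_power
        Noise variance v^2; estimated as the mean local variance if None.
    normalize
        If True, invert polarity (hidden structure becomes bright) and
        min-max normalize to [0, 1].
    """
    if window % 2 == 0 or window < 3:
        raise DomainError(f"window must be odd and >= 3, got {window}")
    captured = np.asarray(captured, dtype=np.float64)
    if captured.ndim != 2:
        raise DomainError("captured must be a 2-D image")

    mu = ndimage.uniform_filter(captured, window, mode="reflect")
    s2 = ndimage.uniform_filter(captured * captured, window,
                                mode="reflect") - mu * mu
    s2 = np.maximum(s2, 0.0)  # guard tiny negative round-off
    v2 = float(s2.mean()) if noise_power is None else float(noise_power)
    denom = np.maximum(s2, v2)
    with np.errstate(invalid="ignore", divide="ignore"):
        gain = np.where(denom > 0, np.maximum(s2 - v2, 0.0) / denom, 0.0)
    out = np.clip(mu + gain * (captured - mu), 0.0, 1.0)

    if normalize:
        out = 1.0 - out
        lo, hi = out.min(), out.max()
        if hi > lo:
            out = (out - lo) / (hi - lo)
    return out
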