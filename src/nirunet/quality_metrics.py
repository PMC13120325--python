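"""Full-reference image-quality metrics and batch evaluation reports.

The four metrics used throughout the package:

* ``mse``  — mean squared error, (1/(H*W)) * sum (x_ij - xhat_ij)^2; this one
  definition is shared with the trainer's loss.
* ``psnr`` — 10 * log10(max_val^2 / MSE) in dB; ``inf`` when MSE is zero.
* ``ssim`` — windowed luminance/contrast/structure similarity with the
  original publication's settings (11x11 Gaussian window, sigma 1.5,
  K1 = 0.01, K2 = 0.03), delegated to scikit-image.
* ``fsim`` — phase-congruency / gradient feature similarity (see
  :mod:`nirunet.fsim`).

``evaluate_methods`` scores a set of (target, captured) pairs under several
named reconstruction methods and produces a mean-and-std report row per
method, plus a row for the raw captured images themselves.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from skimage.metrics import structural_similarity

from . import fsim as _fsim_mod
from .errors import DomainError, EvaluationError

log = logging.getLogger(__name__)

METRIC_NAMES = ("psnr", "ssim", "fsim")


@dataclass(frozen=True)
class MetricParams:
    """Constants for the four metrics; defaults follow the metrics'
    original publications (T2 is defined on a 0-255 dynamic range)."""

    psnr_max: float = 1.0
    ssim_window: int = 11
    ssim_sigma: float = 1.5
    ssim_k1: float = 0.01
    ssim_k2: float = 0.03
    fsim_scales: int = 4
    fsim_orientations: int = 4
    fsim_t1: float = 0.85
    fsim_t2: float = 160.0

    def __post_init__(self):
        if self.ssim_window % 2 == 0 or self.ssim_window < 3:
            raise DomainError("ssim_window must be odd and >= 3")
        for name in ("psnr_max", "ssim_sigma", "ssim_k1", "ssim_k2",
                     "fsim_t1", "fsim_t2"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0")


def _check_shapes(x: np.ndarray, x_hat: np.ndarray) -> None:
    if x.shape != x_hat.shape:
        raise DomainError(f"shape mismatch: {x.shape} vs {x_hat.shape}")


def mse(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Mean squared error over all elements (any matching shapes)."""
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    _check_shapes(x, x_hat)
    return float(np.mean((x - x_hat) ** 2))


def psnr(x: np.ndarray, x_hat: np.ndarray, max_val: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` for identical images."""
    if max_val <= 0:
        raise DomainError("max_val must be > 0")
    err = mse(x, x_hat)
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(max_val ** 2 / err)


def ssim(x: np.ndarray, x_hat: np.ndarray,
         params: MetricParams = MetricParams()) -> float:
    """Structural similarity index in [-1, 1]; symmetric; 1 iff identical."""
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    _check_shapes(x, x_hat)
    if min(x.shape) < params.ssim_window:
        raise DomainError("image smaller than the SSIM window")
    return float(structural_similarity(
        x, x_hat, data_range=params.psnr_max, gaussian_weights=True,
        sigma=params.ssim_sigma, win_size=params.ssim_window,
        use_sample_covariance=False, K1=params.ssim_k1, K2=params.ssim_k2))


def fsim(x: np.ndarray, x_hat: np.ndarray,
         params: MetricParams = MetricParams()) -> float:
    """Feature similarity index in (0, 1]; see :mod:`nirunet.fsim`."""
    return _fsim_mod.fsim(
        x, x_hat, scales=params.fsim_scales,
        orientations=params.fsim_orientations,
        t1=params.fsim_t1, t2=params.fsim_t2)


@dataclass
class MetricsReport:
    """Per-method mean +/- std of PSNR/SSIM/FSIM over an evaluation set."""

    rows: dict[str, dict[str, float]] = field(default_factory=dict)
    per_pair: dict[str, dict[str, list[float]]] = field(default_factory=dict)

    COLUMNS = ("method", "n", "psnr_mean", "psnr_std", "ssim_mean",
               "ssim_std", "fsim_mean", "fsim_std")

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(self.COLUMNS)
            for method, row in self.rows.items():
                w.writerow([method] + [row[c] for c in self.COLUMNS[1:]])

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.rows, indent=1))

    def __str__(self) -> str:
        lines = [f"{'method':<12} {'n':>5} {'PSNR (dB)':>16} "
                 f"{'SSIM':>14} {'FSIM':>14}"]
        for m, r in self.rows.items():
            lines.append(
                f"{m:<12} {r['n']:>5} "
                f"{r['psnr_mean']:>8.2f} ± {r['psnr_std']:<5.2f} "
                f"{r['ssim_mean']:>7.3f} ± {r['ssim_std']:<5.3f} "
                f"{r['fsim_mean']:>7.3f} ± {r['fsim_std']:<5.3f}")
        return "\n".join(lines)


def _mean_std(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=np.float64)
    if arr.size == 0:
        return math.nan, math.nan
    std = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), std


def evaluate_methods(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    methods: dict[str, Callable[[np.ndarray], np.ndarray]],
    params: MetricParams = MetricParams(),
) -> MetricsReport:
    """Score reconstruction methods over (target, captured) pairs.

    Each method maps a captured image to a reconstruction, which is scored
    against the paired target.  A ``captured`` row scores the raw captured
    images themselves.  Pairs with infinite PSNR (zero MSE) are excluded
    from the PSNR aggregation with a logged count; SSIM/FSIM keep all pairs.
    """
    if len(pairs) < 1:
        raise DomainError("need at least one pair")

    report = MetricsReport()
    all_methods: dict[str, Callable] = {"captured": lambda c: c}
    all_methods.update(methods)

    for name, fn in all_methods.items():
        scores: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
        for target, captured in pairs:
            recon = np.asarray(fn(captured))
            if recon.shape != np.asarray(target).shape:
                raise EvaluationError(
                    f"method {name!r} returned shape {recon.shape} for "
                    f"target shape {np.asarray(target).shape}")
            scores["psnr"].append(psnr(target, recon, params.psnr_max))
            scores["ssim"].append(ssim(target, recon, params))
            scores["fsim"].append(fsim(target, recon, params))
        finite = [v for v in scores["psnr"] if math.isfinite(v)]
        n_inf = len(scores["psnr"]) - len(finite)
        if n_inf:
            log.info("method %r: excluded %d infinite-PSNR pairs from "
                     "PSNR aggregation", name, n_inf)
        psnr_mean, psnr_std = _mean_std(finite)
        ssim_mean, ssim_std = _mean_std(scores["ssim"])
        fsim_mean, fsim_std = _mean_std(scores["fsim"])
        report.rows[name] = {
            "n": len(pairs),
            "psnr_mean": psnr_mean, "psnr_std": psnr_std,
            "ssim_mean": ssim_mean, "ssim_std": ssim_std,
            "fsim_mean": fsim_mean, "fsim_std": fsim_std,
            "psnr_excluded": n_inf,
        }
        report.per_pair[name] = scores
    return report


def intensity_profile(image: np.ndarray, row_index: int) -> np.ndarray:
    """Horizontal cross-section: the W intensities of one image row."""
    image = np.asarray(image)
    if not 0 <= row_index < image.shape[0]:
        raise DomainError(
            f"row {row_index} out of range for height {image.shape[0]}")
    return image[row_index].copy()


def plot_profiles(original: np.ndarray, reconstruction: np.ndarray,
                  row_index: int, out_path) -> None:
    """Overlay original and reconstructed intensity profiles for one row."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(intensity_profile(original, row_index), label="original")
    ax.plot(intensity_profile(reconstruction, row_index),
            label="reconstruction", linestyle="--")
    ax.set_xlabel("column")
    ax.set_ylabel("intensity")
    ax.set_title(f"row {row_index}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def failure_rate(scores: Sequence[float],
                 threshold: float = 0.5) -> tuple[int, float]:
    """Count reconstructions whose SSIM falls below ``threshold``.

    Returns (count, fraction of the set).  A failed reconstruction is one
    in which the hidden structure is not recovered; SSIM below the
    threshold is the operational definition.
    """
    if len(scores) == 0:
        raise DomainError("scores must be non-empty")
    if not 0.0 < threshold < 1.0:
        raise DomainError("threshold must be in (0, 1)")
    count = int(sum(1 for s in scores if s < threshold))
    return count, count / len(scores)
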