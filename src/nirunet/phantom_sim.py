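"""Tissue-phantom forward simulation and paired-dataset generation.

Emulates an acquisition rig in which high-contrast flat patterns (displayed
beneath a ~5 mm scattering tissue phantom) are imaged in the near infrared:
the hidden pattern darkens the transmitted radiance, which is then degraded
by an oblique-illumination glare gradient, a thickness-dependent Gaussian
point-spread function, multiplicative speckle, additive sensor noise, and
8-bit quantization.  Every degradation stage has one parameter and can be
switched off independently, which the tests rely on.

Images are plain ``float`` arrays with values in [0, 1]; the hidden pattern
(*target*) is bright-on-dark, the simulated surface capture is dark where the
pattern lies.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw

from .errors import ConfigurationError, DomainError

GLYPH_KINDS = ("stroke-digit", "rectangle", "ring", "random-polyline")

#: seven-segment encodings for digits 0-9; segments are
#: (top, top-left, top-right, middle, bottom-left, bottom-right, bottom)
_SEGMENTS = {
    0: (1, 1, 1, 0, 1, 1, 1),
    1: (0, 0, 1, 0, 0, 1, 0),
    2: (1, 0, 1, 1, 1, 0, 1),
    3: (1, 0, 1, 1, 0, 1, 1),
    4: (0, 1, 1, 1, 0, 1, 0),
    5: (1, 1, 0, 1, 0, 1, 1),
    6: (1, 1, 0, 1, 1, 1, 1),
    7: (1, 0, 1, 0, 0, 1, 0),
    8: (1, 1, 1, 1, 1, 1, 1),
    9: (1, 1, 1, 1, 0, 1, 1),
}


@dataclass(frozen=True)
class PhantomParams:
    """Parameters of the six-stage scattering forward model.

    The blur standard deviation is ``blur_sigma_px_per_mm * thickness_mm``
    pixels, so thicker tissue produces a stronger low-pass point-spread
    function.  ``attenuation`` is the contrast factor alpha in the radiance
    map ``background_level * (1 - alpha * target)``.
    """

    thickness_mm: float = 5.0
    blur_sigma_px_per_mm: float = 1.6
    attenuation: float = 0.55
    glare_amplitude: float = 0.25
    glare_angle_deg: float = 45.0
    speckle_std: float = 0.08
    sensor_noise_std: float = 0.02
    background_level: float = 0.65
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.thickness_mm <= 0:
            raise ConfigurationError("thickness_mm must be > 0")
        if self.speckle_std < 0 or self.sensor_noise_std < 0:
            raise ConfigurationError("noise stds must be >= 0")
        for name in ("attenuation", "glare_amplitude", "background_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.bit_depth < 1:
            raise ConfigurationError("bit_depth must be >= 1")

    @property
    def blur_sigma_px(self) -> float:
        return self.blur_sigma_px_per_mm * self.thickness_mm

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomParams":
        return cls(**d)


@dataclass
class DatasetManifest:
    """Index of a paired target/captured dataset and the splits over it."""

    records: list[dict]  # {"target": str, "captured": str, "split": str}
    fractions: tuple[float, float, float]
    seed: int
    params: PhantomParams
    root: Path = field(default_factory=Path)

    SPLITS = ("train", "val", "test")

    def paths(self, split: str) -> list[tuple[Path, Path]]:
        if split not in self.SPLITS:
            raise DomainError(f"unknown split {split!r}")
        return [
            (self.root / r["target"], self.root / r["captured"])
            for r in self.records
            if r["split"] == split
        ]

    def split_sizes(self) -> dict[str, int]:
        sizes = {s: 0 for s in self.SPLITS}
        for r in self.records:
            sizes[r["split"]] += 1
        return sizes

    def save(self, path: Path) -> None:
        payload = {
            "records": self.records,
            "fractions": list(self.fractions),
            "seed": self.seed,
            "params": self.params.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: Path) -> "DatasetManifest":
        path = Path(path)
        d = json.loads(path.read_text())
        return cls(
            records=d["records"],
            fractions=tuple(d["fractions"]),
            seed=d["seed"],
            params=PhantomParams.from_dict(d["params"]),
            root=path.parent,
        )


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _thick_lines(size: int, lines: list[tuple[float, float, float, float]],
                 thickness: float) -> np.ndarray:
    """Rasterize line segments (r0, c0, r1, c1) with a disk brush."""
    img = np.zeros((size, size), dtype=bool)
    for r0, c0, r1, c1 in lines:
        rr, cc = skdraw.line(int(round(r0)), int(round(c0)),
                             int(round(r1)), int(round(c1)))
        ok = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
        img[rr[ok], cc[ok]] = True
    radius = max(1, int(round(thickness / 2)))
    footprint = skdraw.disk((radius, radius), radius + 0.5,
                            shape=(2 * radius + 1, 2 * radius + 1))
    fp = np.zeros((2 * radius + 1, 2 * radius + 1), dtype=bool)
    fp[footprint] = True
    return ndimage.binary_dilation(img, structure=fp)


def _glyph_stroke_digit(size: int, rng: np.random.Generator) -> np.ndarray:
    digit = int(rng.integers(0, 10))
    height = rng.uniform(0.55, 0.75) * size
    width = 0.55 * height
    thickness = rng.uniform(0.07, 0.10) * size
    margin = thickness
    r0 = rng.uniform(margin, size - height - margin)
    c0 = rng.uniform(margin, size - width - margin)
    top, mid, bot = r0, r0 + height / 2, r0 + height
    left, right = c0, c0 + width
    segs = [
        (top, left, top, right),        # top
        (top, left, mid, left),         # top-left
        (top, right, mid, right),       # top-right
        (mid, left, mid, right),        # middle
        (mid, left, bot, left),         # bottom-left
        (mid, right, bot, right),       # bottom-right
        (bot, left, bot, right),        # bottom
    ]
    lines = [s for s, on in zip(segs, _SEGMENTS[digit]) if on]
    return _thick_lines(size, lines, thickness)


def _glyph_rectangle(size: int, rng: np.random.Generator) -> np.ndarray:
    h = rng.uniform(0.22, 0.60) * size
    w = rng.uniform(0.22, 0.60) * size
    r0 = rng.uniform(0, size - h)
    c0 = rng.uniform(0, size - w)
    img = np.zeros((size, size), dtype=bool)
    rr, cc = skdraw.rectangle((int(r0), int(c0)),
                              extent=(int(h), int(w)), shape=(size, size))
    img[rr.astype(int), cc.astype(int)] = True
    return img


def _glyph_ring(size: int, rng: np.random.Generator) -> np.ndarray:
    outer = rng.uniform(0.16, 0.34) * size
    inner = outer * rng.uniform(0.40, 0.68)
    cr = rng.uniform(outer, size - outer)
    cc_ = rng.uniform(outer, size - outer)
    img = np.zeros((size, size), dtype=bool)
    rr, cc = skdraw.disk((cr, cc_), outer, shape=(size, size))
    img[rr, cc] = True
    rr, cc = skdraw.disk((cr, cc_), inner, shape=(size, size))
    img[rr, cc] = False
    return img


def _glyph_polyline(size: int, rng: np.random.Generator) -> np.ndarray:
    n_pts = int(rng.integers(4, 8))
    margin = 0.12 * size
    pts = [np.array([rng.uniform(margin, size - margin),
                     rng.uniform(margin, size - margin)])]
    while len(pts) < n_pts:
        cand = np.array([rng.uniform(margin, size - margin),
                         rng.uniform(margin, size - margin)])
        if np.linalg.norm(cand - pts[-1]) >= 0.28 * size:
            pts.append(cand)
    thickness = rng.uniform(0.07, 0.10) * size
    lines = [(pts[i][0], pts[i][1], pts[i + 1][0], pts[i + 1][1])
             for i in range(len(pts) - 1)]
    return _thick_lines(size, lines, thickness)


_GLYPH_FNS = {
    "stroke-digit": _glyph_stroke_digit,
    "rectangle": _glyph_rectangle,
    "ring": _glyph_ring,
    "random-polyline": _glyph_polyline,
}

# foreground-fraction band every generated glyph must fall in
_FG_BOUNDS = (0.03, 0.45)


def generate_glyph(kind: str, size: int, rng, antialias: bool = True) -> np.ndarray:
    """Draw one clean high-contrast target pattern.

    Parameters
    ----------
    kind
        One of ``GLYPH_KINDS``.  ``stroke-digit`` draws a seven-segment
        digit; the other families provide shape variety.
    size
        Output is ``size x size``; must be >= 32.
    rng
        A seeded :class:`numpy.random.Generator` (or an int seed).
    antialias
        Smooth the binary rasterization slightly (Gaussian, sigma 0.7) so
        edges carry sub-pixel information, as a physical display would.

    Returns
    -------
    ndarray
        Float image in [0, 1]; foreground (pattern) is 1, background 0.
        Foreground fraction of the underlying binary image lies in
        [0.03, 0.45].
    """
    if kind not in _GLYPH_FNS:
        raise ConfigurationError(
            f"unknown glyph kind {kind!r}; expected one of {GLYPH_KINDS}")
    if size < 32:
        raise DomainError(f"size must be >= 32, got {size}")
    rng = _as_rng(rng)
    lo, hi = _FG_BOUNDS
    for _ in range(16):
        binary = _GLYPH_FNS[kind](size, rng)
        if lo <= binary.mean() <= hi:
            break
    else:  # pragma: no cover - generators are constructed to stay in band
        raise RuntimeError("glyph generator failed to hit foreground band")
    img = binary.astype(np.float64)
    if antialias:
        img = ndimage.gaussian_filter(img, 0.7)
        img = np.clip(img, 0.0, 1.0)
    return img


def glare_field(shape: tuple[int, int], amplitude: float,
                angle_deg: float) -> np.ndarray:
    """Zero-mean planar illumination ramp, ``1 + amplitude * g``.

    ``g`` is a unit-gradient plane (in coordinates normalized by the larger
    image dimension) oriented along ``angle_deg``, recentred to zero mean so
    glare changes shading but not total flux.
    """
    h, w = shape
    scale = max(h, w)
    rr, cc = np.meshgrid(np.arange(h) / scale, np.arange(w) / scale,
                         indexing="ij")
    theta = np.deg2rad(angle_deg)
    g = cc * np.cos(theta) + rr * np.sin(theta)
    g = g - g.mean()
    return 1.0 + amplitude * g


def quantize(img: np.ndarray, bit_depth: int) -> np.ndarray:
    """Quantize values in [0, 1] to ``2**bit_depth`` levels and renormalize."""
    levels = 2 ** bit_depth - 1
    return np.round(img * levels) / levels


def tissue_forward(target: np.ndarray, params: PhantomParams,
                   rng=None) -> np.ndarray:
    """Degrade a clean target through the scattering phantom model.

    Stages, each independently disabled by its zero parameter:

    1. radiance map ``r = background_level * (1 - attenuation * target)``
       (the hidden pattern absorbs, so captures are darker over it);
    2. multiplicative planar glare ramp at ``glare_angle_deg``;
    3. isotropic Gaussian PSF, sigma = ``blur_sigma_px_per_mm * thickness_mm``
       pixels, reflective boundaries;
    4. multiplicative speckle ``1 + N(0, speckle_std^2)`` per pixel;
    5. additive sensor noise ``N(0, sensor_noise_std^2)``;
    6. clip to [0, 1] and quantize to ``bit_depth``.

    Deterministic given (``target``, ``params``, seed): when ``rng`` is
    omitted, ``params.seed`` is used.
    """
    target = np.asarray(target, dtype=np.float64)
    if target.ndim != 2:
        raise DomainError("target must be a 2-D image")
    if target.min() < 0 or target.max() > 1:
        raise DomainError("target values must lie in [0, 1]")
    rng = _as_rng(params.seed if rng is None else rng)

    img = params.background_level * (1.0 - params.attenuation * target)
    if params.glare_amplitude > 0:
        img = img * glare_field(img.shape, params.glare_amplitude,
                                params.glare_angle_deg)
    if params.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, params.blur_sigma_px,
                                      mode="reflect")
    if params.speckle_std > 0:
        img = img * (1.0 + rng.normal(0.0, params.speckle_std, img.shape))
    if params.sensor_noise_std > 0:
        img = img + rng.normal(0.0, params.sensor_noise_std, img.shape)
    img = np.clip(img, 0.0, 1.0)
    return quantize(img, params.bit_depth)


def split_sizes(n: int, fractions: Sequence[float]) -> tuple[int, int, int]:
    """Split counts: val/test get ``round(n*f)``, the remainder trains."""
    if abs(sum(fractions) - 1.0) > 1e-9 or any(f <= 0 for f in fractions):
        raise ConfigurationError("fractions must be positive and sum to 1")
    n_val = int(round(n * fractions[1]))
    n_test = int(round(n * fractions[2]))
    n_train = n - n_val - n_test
    if n_train <= 0:
        raise ConfigurationError("fractions leave no training records")
    return n_train, n_val, n_test


def split_labels(n: int, fractions: Sequence[float],
                 rng: np.random.Generator) -> np.ndarray:
    """Assign each of ``n`` records to a split by a seeded permutation."""
    n_train, n_val, n_test = split_sizes(n, fractions)
    order = rng.permutation(n)
    labels = np.empty(n, dtype=object)
    labels[order[:n_train]] = "train"
    labels[order[n_train:n_train + n_val]] = "val"
    labels[order[n_train + n_val:]] = "test"
    return labels


def build_dataset(n: int, params: PhantomParams, seed: int, out_dir,
                  fractions: Sequence[float] = (0.70, 0.15, 0.15),
                  size: int = 200,
                  glyph_kinds: Sequence[str] = GLYPH_KINDS) -> DatasetManifest:
    """Simulate ``n`` paired target/captured images and write them to disk.

    Pairs are stored as 8-bit grayscale PNGs (``target_%06d.png`` /
    ``captured_%06d.png``) with a JSON manifest.  Records are assigned to
    train/val/test splits by a seeded permutation; val and test sizes are
    ``round(n * fraction)`` and the remainder goes to training.
    """
    from . import io_utils  # local import to avoid a cycle at import time

    if n < 10:
        raise DomainError("n must be >= 10")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(seed)
    perm_rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = ss.spawn(n)
    labels = split_labels(n, fractions, perm_rng)

    records = []
    for i in range(n):
        rng = np.random.default_rng(child_seeds[i])
        kind = glyph_kinds[int(rng.integers(0, len(glyph_kinds)))]
        target = generate_glyph(kind, size, rng)
        captured = tissue_forward(target, params, rng)
        t_name, c_name = f"target_{i:06d}.png", f"captured_{i:06d}.png"
        io_utils.write_image(target, out_dir / t_name)
        io_utils.write_image(captured, out_dir / c_name)
        records.append({"target": t_name, "captured": c_name,
                        "split": str(labels[i])})

    manifest = DatasetManifest(records=records, fractions=tuple(fractions),
                               seed=seed, params=params, root=out_dir)
    manifest.save(out_dir / "manifest.json")
    return manifest
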