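"""Image and IDX file I/O.

Grayscale PNG/TIFF images are mapped to float arrays in [0, 1] by dividing
by the format's maximum value; writing is the exact inverse for 8-bit data.
The IDX reader provides optional access to MNIST-style digit archives as an
alternative source of target patterns.
"""

from __future__ import annotations

import struct
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize

from .errors import FormatError


def read_image(path) -> np.ndarray:
    """Read an 8- or 16-bit grayscale PNG/TIFF as a float image in [0, 1]."""
    path = Path(path)
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected grayscale, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    raise FormatError(f"{path}: unsupported dtype {arr.dtype}")


def write_image(img: np.ndarray, path) -> None:
    """Write a float image in [0, 1] as an 8-bit grayscale PNG/TIFF."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise FormatError(f"cannot write non-2D array of shape {img.shape}")
    data = np.round(np.clip(img, 0.0, 1.0) * 255.0).astype(np.uint8)
    iio.imwrite(Path(path), data)


# IDX magic: two zero bytes, a dtype code, then the number of dimensions.
_IDX_DTYPES = {0x08: np.uint8, 0x09: np.int8, 0x0B: np.int16,
               0x0C: np.int32, 0x0D: np.float32, 0x0E: np.float64}


def read_idx(path, target_size: int | None = None,
             binarize: bool = False) -> list[np.ndarray]:
    """Read an IDX (MNIST-container) image archive.

    Values are scaled to [0, 1] (``/255`` for unsigned bytes).  If
    ``target_size`` is given, each record is resized with bilinear
    interpolation; with ``binarize`` the resized image is re-thresholded at
    0.5 to restore two-level targets.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 4:
        raise FormatError(f"{path}: truncated header at offset {len(raw)}")
    zero, dtype_code, ndim = raw[0] << 8 | raw[1], raw[2], raw[3]
    if zero != 0 or dtype_code not in _IDX_DTYPES:
        raise FormatError(f"{path}: bad magic {raw[:4].hex()} at offset 0")
    header_len = 4 + 4 * ndim
    if len(raw) < header_len:
        raise FormatError(f"{path}: truncated header at offset {len(raw)}")
    dims = struct.unpack(f">{ndim}i", raw[4:header_len])
    dtype = _IDX_DTYPES[dtype_code]
    expected = int(np.prod(dims)) * np.dtype(dtype).itemsize
    if len(raw) - header_len != expected:
        raise FormatError(
            f"{path}: payload length {len(raw) - header_len} != {expected} "
            f"expected from header (offset {header_len})")
    data = np.frombuffer(raw, dtype=np.dtype(dtype).newbyteorder(">"),
                         offset=header_len).reshape(dims)
    if ndim == 2:
        data = data[None]
    elif ndim != 3:
        raise FormatError(f"{path}: expected rank 2 or 3, got {ndim}")

    images = []
    for rec in data:
        img = rec.astype(np.float64)
        if dtype_code == 0x08:
            img /= 255.0
        if target_size is not None and img.shape != (target_size, target_size):
            img = resize(img, (target_size, target_size), order=1,
                         anti_aliasing=False)
        if binarize:
            img = (img >= 0.5).astype(np.float64)
        images.append(np.clip(img, 0.0, 1.0))
    return images
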