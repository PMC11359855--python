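"""Raster I/O, grayscale transformation, and inverse-binary thresholding.

Images are plain ``numpy`` arrays: a grayscale image is a 2-D ``uint8``
array indexed ``(row, col)``; an RGB raster is ``(row, col, 3)``.  A binary
mask is a 2-D ``uint8`` array over ``{0, 255}`` with 255 = foreground.

The threshold follows the chemiluminescence display convention where
luminescent signal appears *dark* on a light background: pixels **below**
the cutoff become foreground (255) and pixels **at or above** the cutoff
become background (0), simultaneously reversing the roles of black and
white.  Pixels exactly at the cutoff are background.
"""

from __future__ import annotations

import os

import numpy as np
from PIL import Image

__all__ = [
    "DEFAULT_CUTOFF",
    "to_grayscale",
    "threshold_binary_inv",
    "read_image",
    "write_image",
]

#: Default intensity cutoff of the inverse-binary threshold.
DEFAULT_CUTOFF = 32

# Rec. 601 luma weights, the de facto default for grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


def _round_half_up(a: np.ndarray) -> np.ndarray:
    return np.floor(a + 0.5)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an RGB raster to 8-bit grayscale using Rec. 601 luma weights.

    Per pixel: ``round(0.299 R + 0.587 G + 0.114 B)`` with half-up
    rounding.  An already-grayscale (2-D) input passes through unchanged.

    Raises
    ------
    ValueError
        If the input is neither 2-D nor a 3-channel raster.
    """
    a = np.asarray(image)
    if a.ndim == 2:
        return a.astype(np.uint8, copy=False)
    if a.ndim == 3 and a.shape[2] == 1:
        return a[:, :, 0].astype(np.uint8, copy=False)
    if a.ndim != 3 or a.shape[2] != 3:
        raise ValueError(
            f"unsupported raster shape {a.shape}: expected 2-D grayscale "
            "or a 3-channel RGB image"
        )
    gray = _round_half_up(a.astype(np.float64) @ _LUMA)
    return np.clip(gray, 0, 255).astype(np.uint8)


def threshold_binary_inv(
    img: np.ndarray, cutoff: int = DEFAULT_CUTOFF, maxval: int = 255
) -> np.ndarray:
    """Inverse-binary threshold: dark pixels become foreground.

    Pixels with intensity strictly below ``cutoff`` are set to ``maxval``
    (foreground); pixels at or above ``cutoff`` are set to 0.

    Parameters
    ----------
    img
        2-D grayscale image.
    cutoff
        Intensity cutoff in [0, 255]; the default of 32 targets the dark
        luminescent signal of chemiluminescence-mode CCD captures.
    maxval
        Value assigned to foreground pixels (255 by convention).
    """
    if not 0 <= cutoff <= 255:
        raise ValueError(f"cutoff must be in [0, 255], got {cutoff}")
    a = np.asarray(img)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {a.shape}")
    return np.where(a < cutoff, maxval, 0).astype(np.uint8)


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG or TIFF raster as ``uint8`` grayscale or RGB.

    8-bit data is returned verbatim.  16-bit grayscale is linearly mapped
    from [0, 65535] to [0, 255] with half-up rounding, so both endpoints
    are exact.  Palette images are expanded to RGB; an alpha channel is
    stripped.
    """
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode == "P":
                im = im.convert("RGB")
            if im.mode in ("RGBA", "LA"):
                im = im.convert(im.mode[:-1])
            arr = np.asarray(im)
    except (OSError, SyntaxError) as exc:
        raise OSError(f"cannot read image file {os.fspath(path)!r}: {exc}") from exc
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        return _round_half_up(arr.astype(np.float64) * (255.0 / 65535.0)).astype(np.uint8)
    if arr.dtype == np.int32 and arr.ndim == 2:  # PIL mode "I"
        return _round_half_up(
            np.clip(arr, 0, 65535).astype(np.float64) * (255.0 / 65535.0)
        ).astype(np.uint8)
    raise OSError(
        f"unsupported pixel type {arr.dtype} in {os.fspath(path)!r}; "
        "expected 8-bit or 16-bit PNG/TIFF"
    )


def write_image(img: np.ndarray, path: str | os.PathLike) -> None:
    """Write an 8-bit grayscale or RGB image losslessly as PNG or TIFF.

    The format follows the file extension (``.png``, ``.tif``, ``.tiff``).
    """
    a = np.asarray(img)
    if a.dtype != np.uint8:
        raise ValueError(f"expected uint8 pixel data, got {a.dtype}")
    if a.ndim not in (2, 3):
        raise ValueError(f"expected a 2-D or 3-channel image, got shape {a.shape}")
    try:
        Image.fromarray(a).save(path)
    except OSError as exc:
        raise OSError(f"cannot write image file {os.fspath(path)!r}: {exc}") from exc
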