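"""Grey/pseudocolor display and merge overlays.

CCD captures are conventionally displayed in grey scale and in a
pseudocolor scale, and ex vivo captures additionally as a merge of the
luminescent signal over an unexposed photograph of the specimen.  The
pseudocolor mapping of acquisition software is vendor-defined, so this
module ships its own explicit 256-entry lookup tables (LUTs).

Shipped LUTs
------------
``grey``
    Identity: every intensity ``v`` maps to ``(v, v, v)``.
``fire``
    Piecewise-linear black -> red -> orange -> white ramp with anchors
    ``0 -> (0, 0, 0)``, ``96 -> (255, 64, 0)``, ``192 -> (255, 200, 0)``,
    ``255 -> (255, 255, 255)`` (half-up rounding between anchors).
    Reference entries: intensity 0 -> (0, 0, 0), 128 -> (255, 109, 0),
    255 -> (255, 255, 255).
"""

from __future__ import annotations

import numpy as np

from .image import threshold_binary_inv
from .pipeline import QuantConfig

__all__ = ["available_luts", "get_lut", "render_pseudocolor", "overlay_merge"]


def _interp_lut(anchors: list[tuple[int, tuple[int, int, int]]]) -> np.ndarray:
    xs = [a[0] for a in anchors]
    table = np.empty((256, 3), dtype=np.uint8)
    for ch in range(3):
        ys = [a[1][ch] for a in anchors]
        table[:, ch] = np.floor(np.interp(np.arange(256), xs, ys) + 0.5).astype(np.uint8)
    return table


_LUTS: dict[str, np.ndarray] = {
    "grey": np.repeat(np.arange(256, dtype=np.uint8)[:, None], 3, axis=1),
    "fire": _interp_lut(
        [(0, (0, 0, 0)), (96, (255, 64, 0)), (192, (255, 200, 0)), (255, (255, 255, 255))]
    ),
}


def available_luts() -> list[str]:
    return sorted(_LUTS)


def get_lut(name: str) -> np.ndarray:
    """The 256x3 uint8 color table of a named LUT."""
    try:
        return _LUTS[name].copy()
    except KeyError:
        raise ValueError(
            f"unknown LUT {name!r}; available LUTs: {', '.join(available_luts())}"
        ) from None


def render_pseudocolor(img: np.ndarray, lut: str = "fire") -> np.ndarray:
    """Map a grayscale image through a 256-entry LUT to an RGB raster."""
    table = get_lut(lut)
    a = np.asarray(img)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {a.shape}")
    return table[a.astype(np.intp)]


def overlay_merge(
    photo: np.ndarray,
    signal: np.ndarray,
    config: QuantConfig | None = None,
    alpha: float = 0.5,
    lut: str = "fire",
) -> np.ndarray:
    """Blend the pseudocolored thresholded signal onto a photograph.

    Foreground pixels of the inverse-binary threshold of ``signal`` show
    ``(1 - alpha) * photo + alpha * pseudocolor(signal)`` (half-up
    rounded); background pixels show the photograph unchanged.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    config = config or QuantConfig()
    photo_arr = np.asarray(photo)
    sig = np.asarray(signal)
    if photo_arr.ndim == 2:
        photo_arr = np.repeat(photo_arr[:, :, None], 3, axis=2)
    if photo_arr.shape[:2] != sig.shape:
        raise ValueError(
            f"photo {photo_arr.shape[:2]} and signal {sig.shape} dimensions differ"
        )
    colored = render_pseudocolor(sig, lut)
    fg = threshold_binary_inv(sig, cutoff=config.cutoff, maxval=255) > 0
    blended = np.floor(
        (1.0 - alpha) * photo_arr.astype(np.float64)
        + alpha * colored.astype(np.float64)
        + 0.5
    ).astype(np.uint8)
    out = photo_arr.astype(np.uint8).copy()
    out[fg] = blended[fg]
    return out
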