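"""End-to-end quantification: grayscale -> threshold -> contours -> psq area.

The per-image procedure mirrors the reporter-assay workflow: the capture
is grayscale-transformed if needed, binarized with the inverse-binary
threshold (cutoff 32 by default), the outer border of every top-level
dark region is traced and chain-compressed, and the combined shoelace
area of all contours — the approximation of bioluminescence intensity —
is reported in pixel-squared (psq) units.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contours import compress_chain_simple, polygon_area, trace_external_contours
from .image import DEFAULT_CUTOFF, read_image, threshold_binary_inv, to_grayscale

__all__ = ["QuantConfig", "QuantResult", "quantify_image", "quantify_batch"]


@dataclass(frozen=True)
class QuantConfig:
    """Quantification parameters.

    ``cutoff`` is the inverse-binary threshold intensity, ``maxval`` the
    foreground mask value, and ``min_area`` a minimum contour area in psq
    below which contours are discarded (0 keeps everything, reproducing
    the unfiltered procedure; a small positive value suppresses hot
    pixels in real captures).
    """

    cutoff: int = DEFAULT_CUTOFF
    maxval: int = 255
    min_area: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.cutoff <= 255:
            raise ValueError(f"cutoff must be in [0, 255], got {self.cutoff}")
        if self.min_area < 0:
            raise ValueError(f"min_area must be >= 0, got {self.min_area}")


@dataclass(frozen=True)
class QuantResult:
    """Per-image outcome: contour areas and their psq total."""

    image_id: str
    contour_areas: tuple[float, ...] = field(default_factory=tuple)

    @property
    def n_contours(self) -> int:
        return len(self.contour_areas)

    @property
    def total_area(self) -> float:
        """Combined contour area in psq (exact sum of ``contour_areas``)."""
        return float(sum(self.contour_areas))


def quantify_image(
    image: np.ndarray,
    config: QuantConfig | None = None,
    image_id: str = "image",
) -> QuantResult:
    """Quantify one capture (grayscale or RGB array) to a :class:`QuantResult`."""
    config = config or QuantConfig()
    gray = to_grayscale(image)
    mask = threshold_binary_inv(gray, cutoff=config.cutoff, maxval=config.maxval)
    areas = []
    for contour in trace_external_contours(mask):
        area = polygon_area(compress_chain_simple(contour))
        if area >= config.min_area:
            areas.append(area)
    return QuantResult(image_id=image_id, contour_areas=tuple(areas))


def _dedupe_ids(ids: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for i in ids:
        if i in seen:
            seen[i] += 1
            out.append(f"{i}_{seen[i]}")
        else:
            seen[i] = 0
            out.append(i)
    return out


def quantify_batch(
    inputs,
    config: QuantConfig | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Quantify a batch of image files into a tidy results table.

    Parameters
    ----------
    inputs
        Either an iterable of image paths, a path to a manifest CSV (with
        columns ``image_path`` and optionally ``group``; relative image
        paths resolve against the manifest's directory), or a manifest
        ``DataFrame``.
    config
        Quantification parameters (defaults reproduce the standard
        procedure: cutoff 32, no area filter).
    strict
        When true (default), the first unreadable file aborts the batch;
        when false, unreadable files are skipped with a warning printed to
        standard error.

    Returns
    -------
    DataFrame with columns ``image_id``, ``group`` (if supplied),
    ``n_contours``, ``total_area_psq``, in stable input order.
    """
    import sys

    config = config or QuantConfig()
    groups = None
    if isinstance(inputs, pd.DataFrame):
        paths = list(inputs["image_path"])
        groups = list(inputs["group"]) if "group" in inputs.columns else None
    elif isinstance(inputs, (str, os.PathLike)) and os.fspath(inputs).endswith(".csv"):
        manifest = pd.read_csv(inputs)
        base = os.path.dirname(os.fspath(inputs))
        paths = [
            p if os.path.isabs(p) else os.path.join(base, p)
            for p in manifest["image_path"]
        ]
        groups = list(manifest["group"]) if "group" in manifest.columns else None
    else:
        paths = [os.fspath(p) for p in inputs]

    ids = _dedupe_ids([os.path.splitext(os.path.basename(p))[0] for p in paths])
    rows = []
    for idx, (path, image_id) in enumerate(zip(paths, ids)):
        try:
            img = read_image(path)
        except OSError as exc:
            if strict:
                raise
            print(f"warning: skipping {path}: {exc}", file=sys.stderr)
            continue
        res = quantify_image(img, config, image_id=image_id)
        row = {"image_id": res.image_id}
        if groups is not None:
            row["group"] = groups[idx]
        row["n_contours"] = res.n_contours
        row["total_area_psq"] = res.total_area
        rows.append(row)
    cols = ["image_id"] + (["group"] if groups is not None else []) + [
        "n_contours",
        "total_area_psq",
    ]
    return pd.DataFrame(rows, columns=cols)
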