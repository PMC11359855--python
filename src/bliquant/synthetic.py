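"""Synthetic CCD luminescence captures with analytic ground truth.

Chemiluminescence-mode CCD displays show luminescent signal as *dark*
regions on a light background.  The generator emulates that: a uniform
light background, dark blobs with either a flat ``disk`` or a Gaussian
``bell`` radial profile, additive Gaussian read noise, and quantization to
8-bit.  A scene without blobs models the untransduced negative control.

Every scene carries a closed-form ground truth: the continuous area (in
pixel-squared units, psq) of the region where the noiseless intensity
falls below a given cutoff.  Quantification pipelines can therefore be
validated against known answers, which real captures never provide.

The noiseless field is ``S(x, y) = clamp(B - sum_b c_b(x, y), 0, 255)``
with background level ``B`` and per-blob contribution

* disk: ``depth`` inside ``r <= extent``, 0 outside;
* bell: ``depth * exp(-r^2 / (2 sigma^2))`` with ``sigma = extent``;

``r`` being the distance from the blob centre.  The rendered image is
``round(clamp(S + eps, 0, 255))`` with ``eps ~ N(0, noise_sd^2)`` i.i.d.
per pixel, drawn from the scene's seed: identical scene specs produce
bit-identical images.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .image import DEFAULT_CUTOFF, write_image

__all__ = [
    "BlobSpec",
    "SceneSpec",
    "GroundTruth",
    "UnsupportedSceneError",
    "render_scene",
    "expected_foreground_area",
    "make_dataset",
    "scene_from_dict",
    "scene_to_dict",
    "load_scene_config",
    "default_signal_scene",
    "default_control_scene",
]

_PROFILES = ("disk", "bell")


class UnsupportedSceneError(ValueError):
    """A scene outside the closed-form ground-truth regime (e.g. overlap)."""


@dataclass(frozen=True)
class BlobSpec:
    """One dark luminescent focus.

    ``center_x``/``center_y`` are 0-based pixel coordinates (x = column);
    ``extent`` is the disk radius or the bell scale sigma, in pixels;
    ``depth`` is the intensity subtracted from the background at the blob
    centre, in [0, 255].
    """

    center_x: float
    center_y: float
    extent: float
    depth: float
    profile: str = "disk"

    def __post_init__(self) -> None:
        if self.profile not in _PROFILES:
            raise ValueError(f"profile must be one of {_PROFILES}, got {self.profile!r}")
        if not self.extent > 0:
            raise ValueError(f"extent must be > 0, got {self.extent}")
        if not 0 <= self.depth <= 255:
            raise ValueError(f"depth must be in [0, 255], got {self.depth}")


@dataclass(frozen=True)
class SceneSpec:
    """A full synthetic capture: canvas, noise, blobs, and a seed."""

    width: int
    height: int
    background_level: float = 200.0
    noise_sd: float = 0.0
    blobs: tuple[BlobSpec, ...] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError(
                f"width and height must be >= 1, got {self.width}x{self.height}"
            )
        if not 0 <= self.background_level <= 255:
            raise ValueError(
                f"background_level must be in [0, 255], got {self.background_level}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        object.__setattr__(self, "blobs", tuple(self.blobs))
        for i, b in enumerate(self.blobs):
            if not (0 <= b.center_x < self.width and 0 <= b.center_y < self.height):
                raise ValueError(
                    f"blob {i} center ({b.center_x}, {b.center_y}) lies outside "
                    f"the {self.width}x{self.height} image"
                )


@dataclass(frozen=True)
class GroundTruth:
    """Analytic truth attached to a rendered scene."""

    spec: SceneSpec
    noiseless_field: np.ndarray  # continuous, pre-rounding

    @property
    def noiseless_image(self) -> np.ndarray:
        """The noiseless field quantized to uint8 (half-up rounding)."""
        return np.floor(self.noiseless_field + 0.5).astype(np.uint8)

    def foreground_mask(self, cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
        """Exact pixel set where the noiseless intensity is below ``cutoff``."""
        return self.noiseless_field < cutoff

    def foreground_area(self, cutoff: float = DEFAULT_CUTOFF) -> float:
        """Closed-form continuous area of the sub-cutoff region, in psq."""
        return expected_foreground_area(self.spec, cutoff)


def _noiseless_field(spec: SceneSpec) -> np.ndarray:
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width].astype(np.float64)
    s = np.full((spec.height, spec.width), float(spec.background_level))
    for b in spec.blobs:
        r2 = (xx - b.center_x) ** 2 + (yy - b.center_y) ** 2
        if b.profile == "disk":
            s -= np.where(r2 <= b.extent**2, b.depth, 0.0)
        else:
            s -= b.depth * np.exp(-r2 / (2.0 * b.extent**2))
    return np.clip(s, 0.0, 255.0)


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a scene to an 8-bit grayscale image plus its ground truth."""
    s = _noiseless_field(spec)
    noisy = s
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noisy = s + rng.normal(0.0, spec.noise_sd, size=s.shape)
    img = np.floor(np.clip(noisy, 0.0, 255.0) + 0.5).astype(np.uint8)
    return img, GroundTruth(spec=spec, noiseless_field=s)


def _threshold_radius(b: BlobSpec, background: float, cutoff: float) -> float:
    """Radius of the sub-cutoff region carved out by one blob (0 if none)."""
    if b.profile == "disk":
        return b.extent if background - b.depth < cutoff else 0.0
    # bell: depth * exp(-r^2 / 2 sigma^2) > background - cutoff
    arg = b.depth / (background - cutoff)
    if arg <= 1.0:
        return 0.0
    return b.extent * math.sqrt(2.0 * math.log(arg))


def expected_foreground_area(spec: SceneSpec, cutoff: float = DEFAULT_CUTOFF) -> float:
    """Analytic area (psq) of the region where noiseless intensity < cutoff.

    Per disk blob the region is the full disk, area ``pi * extent**2``,
    whenever ``background - depth < cutoff``; per bell blob it is a disk of
    radius ``rho`` with ``rho^2 = 2 sigma^2 ln(depth / (background -
    cutoff))`` when that log argument exceeds 1.  A background below the
    cutoff makes the whole frame foreground, in which case the frame area
    ``width * height`` is returned.

    The closed form requires the per-blob regions to be disjoint and fully
    inside the frame; scenes violating this raise
    :class:`UnsupportedSceneError`.  Bell tails reach beyond the reported
    radius, so disjointness is checked against ``max(rho, 3 sigma)`` for
    bell blobs.
    """
    bg = float(spec.background_level)
    if bg < cutoff:
        return float(spec.width * spec.height)
    if bg == cutoff and any(b.profile == "bell" and b.depth > 0 for b in spec.blobs):
        # every pixel with any bell contribution dips below the cutoff
        return float(spec.width * spec.height)

    radii = [_threshold_radius(b, bg, cutoff) for b in spec.blobs]
    guards = [
        max(r, 3.0 * b.extent) if b.profile == "bell" else b.extent
        for b, r in zip(spec.blobs, radii)
    ]
    for i in range(len(spec.blobs)):
        for j in range(i + 1, len(spec.blobs)):
            bi, bj = spec.blobs[i], spec.blobs[j]
            d = math.hypot(bi.center_x - bj.center_x, bi.center_y - bj.center_y)
            if d < guards[i] + guards[j]:
                raise UnsupportedSceneError(
                    f"blobs {i} and {j} overlap (centre distance {d:.2f} < "
                    f"{guards[i]:.2f} + {guards[j]:.2f}); the closed-form "
                    "ground truth requires disjoint blobs"
                )
    for i, (b, r) in enumerate(zip(spec.blobs, radii)):
        if r > 0 and not (
            r <= b.center_x <= spec.width - 1 - r
            and r <= b.center_y <= spec.height - 1 - r
        ):
            raise UnsupportedSceneError(
                f"blob {i} sub-cutoff region (radius {r:.2f}) is clipped by "
                "the frame; the closed-form ground truth requires it inside"
            )
    return float(sum(math.pi * r**2 for r in radii))


# ---------------------------------------------------------------------------
# dataset generation


def make_dataset(
    signal_spec: SceneSpec,
    control_spec: SceneSpec,
    n_per_group: int,
    seed: int,
    out_dir: str | os.PathLike,
    cutoff: float = DEFAULT_CUTOFF,
    image_format: str = "png",
) -> pd.DataFrame:
    """Write a labelled signal-vs-control image set plus a manifest.

    ``n_per_group`` images are rendered per group (the default of the study
    design is triplicates).  Per-image seeds are derived deterministically
    from the master ``seed`` as ``seed + index`` (signal images first), so a
    fixed master seed reproduces the dataset byte for byte.  The manifest
    (``manifest.csv`` in ``out_dir``) lists image_path, group,
    true_area_psq (the analytic sub-``cutoff`` area) and seed.
    """
    if n_per_group < 1:
        raise ValueError(f"n_per_group must be >= 1, got {n_per_group}")
    if image_format not in ("png", "tif", "tiff"):
        raise ValueError(f"image_format must be png or tif(f), got {image_format!r}")
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for g_idx, (label, spec) in enumerate(
        [("signal", signal_spec), ("control", control_spec)]
    ):
        true_area = expected_foreground_area(spec, cutoff)
        for i in range(n_per_group):
            img_seed = seed + g_idx * n_per_group + i
            img, _ = render_scene(replace(spec, seed=img_seed))
            name = f"{label}_{i:02d}.{image_format}"
            path = os.path.join(os.fspath(out_dir), name)
            write_image(img, path)
            rows.append((name, label, true_area, img_seed))
    manifest = pd.DataFrame(
        rows, columns=["image_path", "group", "true_area_psq", "seed"]
    )
    manifest.to_csv(os.path.join(os.fspath(out_dir), "manifest.csv"), index=False)
    return manifest


# ---------------------------------------------------------------------------
# configuration round-trip


def scene_to_dict(spec: SceneSpec) -> dict:
    """Serialize a scene to plain types suitable for YAML/JSON."""
    return {
        "width": spec.width,
        "height": spec.height,
        "background_level": spec.background_level,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "blobs": [
            {
                "center_x": b.center_x,
                "center_y": b.center_y,
                "extent": b.extent,
                "depth": b.depth,
                "profile": b.profile,
            }
            for b in spec.blobs
        ],
    }


def scene_from_dict(d: dict) -> SceneSpec:
    """Build a scene from a YAML/JSON-style mapping."""
    blobs = tuple(BlobSpec(**b) for b in d.get("blobs", []))
    known = {k: d[k] for k in ("width", "height", "background_level", "noise_sd", "seed") if k in d}
    return SceneSpec(blobs=blobs, **known)


def load_scene_config(path: str | os.PathLike) -> dict[str, SceneSpec]:
    """Load ``signal``/``control`` scenes from a YAML config file.

    The file holds either a single scene mapping (the control is then the
    same scene with its blobs removed) or a mapping with ``signal`` and
    ``control`` keys.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"scene config {os.fspath(path)!r} must be a mapping")
    if "signal" in cfg:
        signal = scene_from_dict(cfg["signal"])
        control = (
            scene_from_dict(cfg["control"])
            if "control" in cfg
            else replace(signal, blobs=())
        )
    else:
        signal = scene_from_dict(cfg)
        control = replace(signal, blobs=())
    return {"signal": signal, "control": control}


def default_signal_scene(seed: int = 0) -> SceneSpec:
    """The study-design fixture: one dark disk focus on a light background.

    64x64 canvas, background level 200, read-noise sd 3, a centred disk of
    radius 12 and depth 200 (i.e. the focus bottoms out at intensity 0,
    far below the default cutoff of 32).
    """
    return SceneSpec(
        width=64,
        height=64,
        background_level=200.0,
        noise_sd=3.0,
        blobs=(BlobSpec(center_x=32.0, center_y=32.0, extent=12.0, depth=200.0),),
        seed=seed,
    )


def default_control_scene(seed: int = 0) -> SceneSpec:
    """Matched blob-free negative control for :func:`default_signal_scene`."""
    return replace(default_signal_scene(seed), blobs=())
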