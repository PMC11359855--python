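import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240851)


def random_mask(rng, shape=(64, 64), density=0.3):
    """Seeded random binary mask with foreground value 255."""
    return (rng.random(shape) < density).astype(np.uint8) * 255


def brute_force_border_pixels(mask):
    """Outer-border oracle: foreground pixels with a background 4-neighbor
    or frame contact (independent of the tracing route)."""
    fg = np.asarray(mask) > 0
    h, w = fg.shape
    border = set()
    for r in range(h):
        for c in range(w):
            if not fg[r, c]:
                continue
            for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if not (0 <= rr < h and 0 <= cc < w) or not fg[rr, cc]:
                    border.add((c, r))  # (x, y)
                    break
    return border


def fan_triangulation_area(points):
    """Independent polygon-area oracle: sum of signed triangle areas fanned
    from the first vertex."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        return 0.0
    x0, y0 = pts[0]
    total = 0.0
    for (x1, y1), (x2, y2) in zip(pts[1:-1], pts[2:]):
        total += (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)
    return abs(total) / 2.0
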