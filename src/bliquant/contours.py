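"""External-contour tracing, chain-code compression, and polygon area.

This module is the computational core of the quantification procedure: a
binary mask (foreground 255 = luminescent signal) is decomposed into
8-connected foreground components, the outer border of every *top-level*
component is traced as a closed polygon of pixel-center coordinates, the
polygon is compressed by keeping only endpoints of straight (horizontal,
vertical or diagonal) runs, and its area is computed with the shoelace
formula in pixel-squared (psq) units.

Conventions
-----------
* Foreground is 8-connected, background is 4-connected; this is the
  standard pairing under which outer borders are well defined.
* Only outermost borders are traced: hole borders, and foreground
  components nested inside holes of other components, are not reported.
* Contour points are ``(x, y)`` pairs with ``x`` = column and ``y`` = row,
  both 0-based; the closing edge from the last point back to the first is
  implicit.
* Contours are discovered in raster-scan order (top-to-bottom, then
  left-to-right) and each trace starts at the component's first-scanned
  pixel, so identical masks always yield identical contour lists.
* Traversal orientation is fixed: clockwise as displayed (y increasing
  downward), which is counter-clockwise in right-handed coordinates; the
  signed shoelace sum of an outer contour is therefore non-negative.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "CHAIN_OFFSETS",
    "trace_external_contours",
    "compress_chain_simple",
    "polygon_area",
    "component_pixel_counts",
    "boundary_step_count",
    "contours_to_table",
]

# Freeman chain directions: code 0 points along +x, successive codes
# proceed counter-clockwise in image coordinates (y down), so code 2 is
# "up" on screen.  Offsets are (dx, dy).
CHAIN_OFFSETS: tuple[tuple[int, int], ...] = (
    (1, 0),    # 0: E
    (1, -1),   # 1: NE
    (0, -1),   # 2: N
    (-1, -1),  # 3: NW
    (-1, 0),   # 4: W
    (-1, 1),   # 5: SW
    (0, 1),    # 6: S
    (1, 1),    # 7: SE
)

_OFFSET_TO_CODE = {off: code for code, off in enumerate(CHAIN_OFFSETS)}

_EIGHT = np.ones((3, 3), dtype=int)
_FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


def _as_bool_mask(mask: np.ndarray) -> np.ndarray:
    a = np.asarray(mask)
    if a.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {a.shape}")
    return a > 0


def _top_level_labels(fg: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Label 8-connected foreground and list labels of top-level components.

    A component is top-level when it touches the background region that is
    connected (4-connectivity) to the image frame; components living inside
    a hole of another component touch only that hole and are excluded.
    Labels are renumbered nowhere: the returned list preserves raster-scan
    discovery order, which is the order ``scipy.ndimage.label`` assigns.
    """
    labels, n = ndimage.label(fg, structure=_EIGHT)
    if n == 0:
        return labels, []
    bg = np.pad(~fg, 1, constant_values=True)
    bg_labels, _ = ndimage.label(bg, structure=_FOUR)
    outer = bg_labels == bg_labels[0, 0]
    # grow the outer background by one 4-step and see which labels it hits
    reach = ndimage.binary_dilation(outer, structure=_FOUR)[1:-1, 1:-1]
    touched = np.unique(labels[reach & fg])
    order = sorted(int(t) for t in touched if t > 0)
    return labels, order


def _trace_border(fg: np.ndarray, start_rc: tuple[int, int]) -> np.ndarray:
    """Follow the outer border of the component containing ``start_rc``.

    ``start_rc`` must be the component's first pixel in raster order, so its
    west and north neighbours are background.  Border following in the
    Suzuki–Abe style: from the direction of the previous border pixel the
    neighbourhood of the current pixel is searched in a fixed rotation
    (clockwise as displayed, y down) for the next foreground pixel, which
    keeps the background on the trace's left and hugs the outer boundary.
    Every outer-border pixel is emitted once per passage; one-pixel wide
    arms therefore appear twice (out and back), which is what makes the
    traced cycle a faithful closed polygon.

    Termination uses the classic criterion: an initial opposite-rotation
    search identifies the pixel from which the trace will finally re-enter
    the start, and the loop stops when it is about to take that step.
    """
    h, w = fg.shape
    r0, c0 = start_rc

    def neighbor(r: int, c: int, code: int) -> tuple[int, int]:
        dx, dy = CHAIN_OFFSETS[code]
        return r + dy, c + dx

    def is_fg(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and fg[r, c]

    # re-entry pixel: first foreground neighbour counter-clockwise
    # (as displayed) from the west neighbour, which is background
    reentry = None
    for k in range(1, 9):
        code = (4 + k) % 8  # SW, S, SE, E, NE, N, NW, W
        rr, cc = neighbor(r0, c0, code)
        if is_fg(rr, cc):
            reentry = (rr, cc)
            break
    if reentry is None:  # isolated pixel
        return np.array([[c0, r0]], dtype=np.int64)

    points: list[tuple[int, int]] = []
    cur = (r0, c0)
    back = 4  # direction towards the (virtual) previous pixel, initially W
    limit = 4 * int(fg.sum()) + 8
    while True:
        # next border pixel: rotate clockwise as displayed, starting just
        # past the previous pixel
        next_code = None
        for k in range(1, 9):
            code = (back - k) % 8
            rr, cc = neighbor(*cur, code)
            if is_fg(rr, cc):
                next_code = code
                break
        points.append((cur[1], cur[0]))  # (x, y)
        nxt = neighbor(*cur, next_code)
        if nxt == (r0, c0) and cur == reentry:
            break
        back = (next_code + 4) % 8
        cur = nxt
        if len(points) > limit:  # pragma: no cover - defensive
            raise RuntimeError("border following failed to close")
    return np.asarray(points, dtype=np.int64)


def trace_external_contours(mask: np.ndarray) -> list[np.ndarray]:
    """Trace the outer border of every top-level foreground component.

    Parameters
    ----------
    mask
        2-D array; any value > 0 is foreground (a thresholded mask uses
        255).

    Returns
    -------
    list of ``(n, 2)`` int arrays of ``(x, y)`` pixel-center coordinates,
    one closed contour per top-level 8-connected component, in raster-scan
    discovery order.  An all-background mask yields an empty list.
    """
    fg = _as_bool_mask(mask)
    labels, order = _top_level_labels(fg)
    contours: list[np.ndarray] = []
    for lab in order:
        comp = labels == lab
        rows, cols = np.nonzero(comp)
        # first raster pixel: np.nonzero returns row-major order already
        start = (int(rows[0]), int(cols[0]))
        contours.append(_trace_border(comp, start))
    return contours


def _chain_codes(points: np.ndarray) -> np.ndarray:
    """Per-edge Freeman codes of a closed contour, validating 8-adjacency."""
    nxt = np.roll(points, -1, axis=0)
    steps = nxt - points
    codes = np.empty(len(points), dtype=np.int64)
    for i, (dx, dy) in enumerate(steps):
        key = (int(dx), int(dy))
        if key not in _OFFSET_TO_CODE:
            raise ValueError(
                f"consecutive contour points must be 8-neighbors; "
                f"step {key} at index {i} is not a unit chain move"
            )
        codes[i] = _OFFSET_TO_CODE[key]
    return codes


def compress_chain_simple(contour: np.ndarray) -> np.ndarray:
    """Keep only the endpoints of maximal straight runs of a contour.

    Horizontal, vertical and diagonal segments are compressed: a vertex is
    retained exactly when the chain direction of its incoming edge differs
    from that of its outgoing edge.  A single-point contour is returned
    unchanged.  The cyclic order of retained points is preserved.
    """
    points = np.asarray(contour, dtype=np.int64)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("contour must be an (n, 2) array of (x, y) points")
    n = len(points)
    if n <= 1:
        return points.copy()
    out_codes = _chain_codes(points)
    in_codes = np.roll(out_codes, 1)
    keep = in_codes != out_codes
    if not keep.any():  # cannot happen for a genuinely closed cycle
        raise ValueError("contour has a single chain direction and cannot close")
    return points[keep]


def polygon_area(contour: np.ndarray) -> float:
    """Shoelace area of a closed contour in pixel-squared units.

    ``|sum(x_i * y_{i+1} - x_{i+1} * y_i)| / 2`` over the implicit closed
    cycle.  Degenerate contours of one or two points have zero area.
    """
    points = np.asarray(contour, dtype=np.float64)
    if len(points) < 3:
        return 0.0
    x = points[:, 0]
    y = points[:, 1]
    return float(abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)) / 2.0)


def boundary_step_count(contour: np.ndarray) -> int:
    """Number of unit chain steps in the closed traversal of a contour.

    Equals the number of contour points for cycles of two or more points
    (each point starts exactly one step) and zero for a single-point
    contour.  This is the boundary count ``B`` in the lattice-polygon
    identity ``pixels = area + B/2 + 1`` for hole-free components, where
    border pixels traversed twice contribute two steps.
    """
    n = len(np.asarray(contour))
    return n if n >= 2 else 0


def component_pixel_counts(mask: np.ndarray) -> list[int]:
    """Pixel counts of top-level 8-connected components (test oracle).

    Independent of the tracing route: components are found with a
    hand-written breadth-first flood fill in raster discovery order, and
    top-level status is decided by a second flood fill of the background
    from the frame (4-connectivity).  Order matches
    :func:`trace_external_contours`.
    """
    fg = _as_bool_mask(mask)
    h, w = fg.shape

    # flood-fill the frame-connected background (4-connectivity)
    outer = np.zeros((h, w), dtype=bool)
    stack = [(r, c) for r in (0, h - 1) for c in range(w) if not fg[r, c]]
    stack += [(r, c) for c in (0, w - 1) for r in range(h) if not fg[r, c]]
    for r, c in stack:
        outer[r, c] = True
    while stack:
        r, c = stack.pop()
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < h and 0 <= cc < w and not fg[rr, cc] and not outer[rr, cc]:
                outer[rr, cc] = True
                stack.append((rr, cc))

    seen = np.zeros((h, w), dtype=bool)
    counts: list[int] = []
    for r in range(h):
        for c in range(w):
            if not fg[r, c] or seen[r, c]:
                continue
            # flood-fill this component (8-connectivity)
            comp = [(r, c)]
            seen[r, c] = True
            top_level = False
            size = 0
            while comp:
                cr, cc = comp.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, ccc = cr + dr, cc + dc
                        if not (0 <= rr < h and 0 <= ccc < w):
                            continue
                        if fg[rr, ccc] and not seen[rr, ccc]:
                            seen[rr, ccc] = True
                            comp.append((rr, ccc))
                if not top_level:
                    for rr, ccc in ((cr - 1, cc), (cr + 1, cc), (cr, cc - 1), (cr, cc + 1)):
                        if not (0 <= rr < h and 0 <= ccc < w) or outer[rr, ccc]:
                            top_level = True
                            break
            if top_level:
                counts.append(size)
    return counts


def contours_to_table(contours: list[np.ndarray]):
    """Flatten contours to a table with columns contour_id, vertex_index, x, y."""
    import pandas as pd

    rows = []
    for cid, contour in enumerate(contours):
        for vidx, (x, y) in enumerate(np.asarray(contour)):
            rows.append((cid, vidx, int(x), int(y)))
    return pd.DataFrame(rows, columns=["contour_id", "vertex_index", "x", "y"])
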