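"""Tumor-cluster labels -> cleaned mask -> initial contour -> signed
distance field.

Sign convention: phi is negative inside the contour, positive outside.
Multiple tumor lumps are kept as separate components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

__all__ = [
    "ContourPointSet",
    "tumor_mask",
    "mask_to_contour",
    "signed_distance_init",
]

#: phi value assigned to an all-background field (no contour anywhere)
_EMPTY_PHI = 1e3


@dataclass
class ContourPointSet:
    """Ordered (row, col) boundary points of a tumor mask, per component."""

    points: list[tuple[int, int]]
    slice_index: int = 0


def tumor_mask(
    labels: np.ndarray,
    tumor_idx: int,
    shape: tuple[int, int] | None = None,
    min_area: int = 20,
    max_area: int | None = None,
    cleanup: bool = True,
) -> tuple[np.ndarray, bool]:
    """Boolean mask of the tumor cluster, cleaned of clustering speckle.

    Cleaning = morphological opening (disk radius 1) followed by removal of
    connected components smaller than ``min_area`` pixels.  When
    ``max_area`` is given, components larger than it are dropped as well:
    on tumor-free slices the brightest cluster degenerates to a whole
    normal-tissue class, which dwarfs any plausible tumor cross-section.
    Multiple lumps are retained.  Returns ``(mask, empty_flag)``; an empty
    result is a warning, not an error (the slice simply has no tumor).
    """
    labels = np.asarray(labels)
    if shape is not None:
        labels = labels.reshape(shape)
    mask = labels == tumor_idx
    if cleanup and mask.any():
        # opening with foreground border so a full-frame mask is untouched
        eroded = ndimage.binary_erosion(mask, structure=disk(1), border_value=1)
        mask = ndimage.binary_dilation(eroded, structure=disk(1))
        lab, n = ndimage.label(mask)
        if n:
            sizes = np.asarray(
                ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
            )
            ok = sizes >= min_area
            if max_area is not None:
                ok &= sizes <= max_area
            mask = np.isin(lab, 1 + np.flatnonzero(ok))
    return mask, not mask.any()


# Moore neighborhood in clockwise order starting from the west neighbor
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def _trace_component(mask: np.ndarray) -> list[tuple[int, int]]:
    """Moore-neighbor boundary tracing (Jacob's stopping criterion) of a
    single 8-connected component."""
    rows, cols = np.nonzero(mask)
    start = (int(rows[0]), int(cols[0]))  # lexicographically smallest pixel

    def at(p: tuple[int, int]) -> bool:
        r, c = p
        return 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c]

    contour = [start]
    # backtrack starts west of the start pixel (known background by scan order)
    prev_dir = 0
    cur = start
    first_move: tuple[int, int] | None = None
    while True:
        found = None
        for k in range(8):
            d = (prev_dir + k) % 8
            cand = (cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1])
            if at(cand):
                found = (cand, d)
                break
        if found is None:  # isolated single pixel
            break
        nxt, d = found
        move = (cur, nxt)
        if nxt == start and first_move is not None and move == first_move:
            break
        if first_move is None:
            first_move = move
        if nxt != start or len(contour) == 1:
            if nxt != contour[-1]:
                contour.append(nxt)
        cur = nxt
        # resume search from the neighbor after the one we came from
        prev_dir = (d + 5) % 8
        if len(contour) > 4 * mask.size:  # pragma: no cover - safety net
            break
    # keep boundary pixels only, ordered, without duplicates
    seen = set()
    ordered = []
    for p in contour:
        if p not in seen:
            seen.add(p)
            ordered.append(p)
    return ordered


def mask_to_contour(mask: np.ndarray, slice_index: int = 0) -> ContourPointSet:
    """Ordered boundary points of every connected component of the mask.

    Every returned point lies on the mask's 4-connected boundary (has at
    least one non-tumor 4-neighbor).  Raises ``ValueError`` on an empty
    mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("degenerate input: empty mask has no contour")
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    cross = ndimage.generate_binary_structure(2, 1)
    points: list[tuple[int, int]] = []
    for comp in range(1, n + 1):
        comp_mask = lab == comp
        points.extend(_trace_component(comp_mask))
        # inner boundaries: rings of mask pixels 4-adjacent to each hole
        holes = ndimage.binary_fill_holes(comp_mask) & ~comp_mask
        if holes.any():
            hole_lab, hn = ndimage.label(holes, structure=np.ones((3, 3), dtype=int))
            for h in range(1, hn + 1):
                ring = comp_mask & ndimage.binary_dilation(
                    hole_lab == h, structure=cross
                )
                rlab, rn = ndimage.label(ring, structure=np.ones((3, 3), dtype=int))
                for rc in range(1, rn + 1):
                    points.extend(_trace_component(rlab == rc))
    # deduplicate while keeping order (a pixel can sit on two boundaries)
    seen: set[tuple[int, int]] = set()
    unique = [p for p in points if not (p in seen or seen.add(p))]
    return ContourPointSet(points=unique, slice_index=slice_index)


def boundary_4(mask: np.ndarray) -> np.ndarray:
    """Pixels of the mask with at least one non-mask 4-neighbor."""
    mask = np.asarray(mask, dtype=bool)
    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return mask & ~interior


def signed_distance_init(mask: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance field of a mask (negative inside).

    phi = dist-to-mask outside, -dist-to-background inside; the zero level
    set lies on the mask boundary and |grad phi| ~ 1 near it.  An empty
    mask yields a uniformly positive field.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.full(mask.shape, _EMPTY_PHI, dtype=np.float64)
    if mask.all():
        return np.full(mask.shape, -_EMPTY_PHI, dtype=np.float64)
    outside = ndimage.distance_transform_edt(~mask)
    inside = ndimage.distance_transform_edt(mask)
    return np.asarray(outside - inside, dtype=np.float64)
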