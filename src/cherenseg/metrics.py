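"""Binary segmentation metrics: Dice, IoU, boundary IoU, and
largest-connected-component extraction.

Boundary IoU follows the published definition: each mask is intersected
with the band of its own pixels lying within distance d of the mask
contour (image borders count as contour), and the plain IoU of the two
bands is returned.  As d grows past the image diagonal the band covers the
whole mask and the value converges to the ordinary IoU.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def _check(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a, b = np.asarray(a).astype(bool), np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def dice_score(a: np.ndarray, b: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|); two empty masks agree perfectly (1.0)."""
    a, b = _check(a, b)
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def iou_score(a: np.ndarray, b: np.ndarray) -> float:
    """|A∩B| / |A∪B|; two empty masks agree perfectly (1.0)."""
    a, b = _check(a, b)
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def boundary_band(mask: np.ndarray, d: float) -> np.ndarray:
    """Pixels of the mask within Euclidean distance d of its contour
    (background or the image border)."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return mask
    padded = np.pad(mask, 1)  # outside the image counts as background
    dist = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
    return mask & (dist <= d)


def boundary_iou(a: np.ndarray, b: np.ndarray, d: float = 2.0) -> float:
    """IoU of the two boundary bands; sensitive to contour placement."""
    if d < 1:
        raise ValueError("boundary width d must be >= 1 pixel")
    a, b = _check(a, b)
    return iou_score(boundary_band(a, d), boundary_band(b, d))


_STRUCTS = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def largest_component(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Largest connected foreground component; size ties broken by the
    smallest row-major top-left pixel.  Thin diagonal vessels stay joined
    under the default 8-connectivity."""
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask).astype(bool)
    labels, n = ndimage.label(mask, structure=_STRUCTS[connectivity])
    if n == 0:
        return np.zeros_like(mask, dtype=np.uint8)
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    best_size = sizes.max()
    candidates = np.flatnonzero(sizes == best_size) + 1
    if len(candidates) == 1:
        keep = candidates[0]
    else:
        flat = labels.ravel()
        keep = min(candidates, key=lambda lab: np.argmax(flat == lab))
    return (labels == keep).astype(np.uint8)


def report(
    pred: np.ndarray, ref: np.ndarray, d: float = 2.0, connectivity: int = 8
) -> dict[str, float]:
    """All metrics for one mask pair (the per-image CSV report row)."""
    return {
        "dice": dice_score(pred, ref),
        "iou": iou_score(pred, ref),
        "boundary_iou": boundary_iou(pred, ref, d),
        "boundary_d": float(d),
        "connectivity": connectivity,
    }
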