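"""Patch-based dataset construction.

Annotated images are cropped to a square region of interest whose side is
an exact multiple of the patch size (N x 224; Cherenkov beam ROIs use
N <= 4), tiled into non-overlapping 224 x 224 patches, filtered so that
only patches whose labeled vessel area exceeds 5 % of the patch are kept,
and randomly split 90/10 into training and validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import AnnotatedImage

PATCH_SIZE = 224
RETENTION_THRESHOLD = 0.05
TRAIN_FRACTION = 0.9
MAX_TARGET_GRID = 4

TRAIN = "train"
VAL = "val"


@dataclass
class Patch:
    """One image/mask tile with provenance back to its parent image."""

    image: np.ndarray
    mask: np.ndarray
    origin: tuple[int, int]           # (row, col) of top-left in parent ROI
    parent: str = ""

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape or self.image.ndim != 2:
            raise ValueError("patch image and mask must be equal-shaped 2-D")
        if self.image.shape[0] != self.image.shape[1]:
            raise ValueError("patches must be square")

    @property
    def size(self) -> int:
        return self.image.shape[0]

    @property
    def labeled_fraction(self) -> float:
        return float(self.mask.sum()) / self.mask.size


@dataclass
class PatchSet:
    """An ordered patch collection with optional train/val assignment."""

    patches: list[Patch]
    splits: list[str] = field(default_factory=list)
    split_seed: int | None = None

    def __post_init__(self) -> None:
        if self.splits and len(self.splits) != len(self.patches):
            raise ValueError("one split label per patch required")
        seen = set()
        for p in self.patches:
            key = (p.parent, p.origin)
            if key in seen:
                raise ValueError(f"duplicate patch {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.patches)

    def subset(self, label: str) -> list[Patch]:
        return [p for p, s in zip(self.patches, self.splits) if s == label]

    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "parent": p.parent,
                "origin_row": p.origin[0],
                "origin_col": p.origin[1],
                "labeled_fraction": p.labeled_fraction,
                "split": self.splits[i] if self.splits else "",
            }
            for i, p in enumerate(self.patches)
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def select_roi(
    img: AnnotatedImage,
    grid: int,
    center: tuple[int, int] | None = None,
    patch_size: int = PATCH_SIZE,
) -> AnnotatedImage:
    """Crop a centered (grid*patch_size)-square region of interest.

    Cherenkov beam ROIs are small (grid <= 4); fundus images use larger
    grids (6 x 6 yields the canonical 36 patches).  The crop is centered on
    the image unless an explicit center is given.
    """
    if grid < 1:
        raise ValueError("grid must be >= 1")
    if img.domain == "target" and grid > MAX_TARGET_GRID:
        raise ValueError(
            f"target-domain ROIs use at most {MAX_TARGET_GRID}x{MAX_TARGET_GRID} patches"
        )
    side = grid * patch_size
    h, w = img.shape
    if center is None:
        center = (h // 2, w // 2)
    r0 = int(center[0]) - side // 2
    c0 = int(center[1]) - side // 2
    for name, lo, extent in (("rows", r0, h), ("cols", c0, w)):
        if lo < 0 or lo + side > extent:
            raise ValueError(
                f"ROI of side {side} exceeds image bounds along {name} "
                f"(extent {extent})"
            )
    return AnnotatedImage(
        img.image[r0 : r0 + side, c0 : c0 + side],
        img.mask[r0 : r0 + side, c0 : c0 + side],
        domain=img.domain,
        identifier=f"{img.identifier}@({r0},{c0})" if img.identifier else f"@({r0},{c0})",
    )


def extract_patches(img: AnnotatedImage, patch_size: int = PATCH_SIZE) -> PatchSet:
    """Non-overlapping row-major tiling; dimensions must be exact multiples."""
    h, w = img.shape
    if h % patch_size or w % patch_size:
        raise ValueError(
            f"image shape {(h, w)} is not a multiple of patch size {patch_size}"
        )
    patches = []
    for r in range(0, h, patch_size):
        for c in range(0, w, patch_size):
            patches.append(
                Patch(
                    img.image[r : r + patch_size, c : c + patch_size],
                    img.mask[r : r + patch_size, c : c + patch_size],
                    origin=(r, c),
                    parent=img.identifier,
                )
            )
    return PatchSet(patches)


def retention_filter(ps: PatchSet, threshold: float = RETENTION_THRESHOLD) -> PatchSet:
    """Keep patches whose labeled area strictly exceeds the threshold
    fraction of the patch; order is preserved.  Idempotent."""
    if not (0.0 <= threshold < 1.0):
        raise ValueError("threshold must be in [0, 1)")
    kept = [p for p in ps.patches if p.labeled_fraction > threshold]
    return PatchSet(kept)


def split_patches(
    ps: PatchSet, train_fraction: float = TRAIN_FRACTION, seed: int = 0
) -> PatchSet:
    """Random 90/10 train/validation assignment, deterministic per seed.

    The train count is round-half-up of train_fraction * n (the clinical
    patch counts are not multiples of 10, so the rounding rule matters).
    """
    n = len(ps)
    if n == 0:
        raise ValueError("cannot split an empty patch set")
    if n < 2:
        raise ValueError("need at least 2 patches to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(train_fraction * n + 0.5))
    labels = [""] * n
    for rank, idx in enumerate(perm):
        labels[idx] = TRAIN if rank < n_train else VAL
    if n_train == n:
        warnings.warn(
            "validation split is empty at this set size; training-stage "
            "model selection needs a non-empty validation split",
            stacklevel=2,
        )
    return PatchSet(list(ps.patches), labels, split_seed=seed)


def reassemble(ps: PatchSet, shape: tuple[int, int]) -> AnnotatedImage:
    """Place every patch back at its origin; inverse of extract_patches."""
    img = np.zeros(shape)
    mask = np.zeros(shape, dtype=np.uint8)
    for p in ps.patches:
        r, c = p.origin
        img[r : r + p.size, c : c + p.size] = p.image
        mask[r : r + p.size, c : c + p.size] = p.mask
    return AnnotatedImage(img, mask)


def build_patchset(
    images: list[AnnotatedImage],
    grid: int,
    threshold: float = RETENTION_THRESHOLD,
    train_fraction: float = TRAIN_FRACTION,
    seed: int = 0,
    patch_size: int = PATCH_SIZE,
    centers: dict[str, tuple[int, int]] | None = None,
) -> PatchSet:
    """Full pipeline over a batch of images: ROI -> tiles -> retention ->
    split.  Per-image ROI centers may be supplied (Cherenkov ROIs are
    chosen by vessel location); default is the image center."""
    all_patches: list[Patch] = []
    for img in images:
        center = centers.get(img.identifier) if centers else None
        roi = select_roi(img, grid, center=center, patch_size=patch_size)
        tiled = extract_patches(roi, patch_size=patch_size)
        for p in tiled.patches:
            p.parent = img.identifier
        all_patches.extend(retention_filter(tiled, threshold).patches)
    return split_patches(PatchSet(all_patches), train_fraction, seed)


# ---------------------------------------------------------------------------
# archive I/O
# ---------------------------------------------------------------------------


def save_patchset(ps: PatchSet, array_path: str, manifest_path: str) -> None:
    """Single array container (.npz) plus a CSV manifest."""
    np.savez_compressed(
        array_path,
        images=np.stack([p.image for p in ps.patches]),
        masks=np.stack([p.mask for p in ps.patches]),
    )
    ps.manifest().to_csv(manifest_path, index=False)


def load_patchset(array_path: str, manifest_path: str) -> PatchSet:
    arrays = np.load(array_path)
    man = pd.read_csv(manifest_path, keep_default_na=False)
    patches = [
        Patch(
            arrays["images"][i],
            arrays["masks"][i],
            origin=(int(row.origin_row), int(row.origin_col)),
            parent=str(row.parent),
        )
        for i, row in enumerate(man.itertuples())
    ]
    splits = [str(s) for s in man["split"]] if man["split"].astype(bool).any() else []
    return PatchSet(patches, splits)
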