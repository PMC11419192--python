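"""Synthetic vascular phantoms for the two imaging domains.

Real vasculature appears as dark branching curves on a bright background in
both fundus photographs (the high-contrast transfer-learning source domain)
and Cherenkov images acquired during radiotherapy (the low-SNR target
domain, where signal exists only inside the bright treatment-beam
footprint).  This module grows random branching vessel trees, rasterizes
them into image/mask pairs for either domain, and renders video streams
with per-frame noise and optional sinusoidal breathing displacement.

Everything here is a pure function of ``(spec, seed)``: the same spec and
seed always produce bitwise-identical output.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

DEFAULT_FPS = 19.6  # Cherenkov camera acquisition rate, frames per second

SOURCE = "source"
TARGET = "target"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class VesselTree:
    """A connected branching tree of vessel centerlines.

    segments are (n_i, 2) float arrays of (row, col) pixel coordinates;
    widths are the stroke width of each segment in pixels.  Every non-root
    segment starts at the end point of its parent.
    """

    segments: list[np.ndarray]
    widths: list[float]
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        for s in self.segments:
            if s.ndim != 2 or s.shape[0] < 2 or s.shape[1] != 2:
                raise ValueError("each segment needs >= 2 (row, col) points")
        if any(w <= 0 for w in self.widths):
            raise ValueError("all stroke widths must be positive")
        if len(self.widths) != len(self.segments):
            raise ValueError("one width per segment required")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def displaced(self, drow: float, dcol: float = 0.0) -> "VesselTree":
        """Rigidly shift all centerlines; used for breathing motion."""
        segs = [s + np.array([drow, dcol]) for s in self.segments]
        return VesselTree(segs, list(self.widths), self.shape)


@dataclass
class PhantomSpec:
    """Parameters of the vessel-tree generator and its two renderers.

    The source domain emulates high-contrast fundus photographs; the target
    domain emulates low-SNR Cherenkov images where intensity is confined to
    a bright, superelliptic beam footprint.
    """

    shape: tuple[int, int] = (448, 448)
    domain: str = SOURCE
    # tree growth; defaults give ~8 % vessel-pixel density at 448 px, the
    # regime where the 5 % patch-retention filter keeps most central patches
    branch_prob: float = 0.9        # probability a finished segment bifurcates
    depth: int = 7                  # maximum number of branching generations
    step: float = 6.0               # walk step length, px
    n_steps: int = 16               # walk steps per segment
    width_range: tuple[float, float] = (4.0, 8.0)
    # rendering
    contrast: float = 0.7           # vessel darkening, fraction of range
    background: float = 0.85        # background level in [0, 1]
    noise_sigma: float = 0.02       # Gaussian noise sd, fraction of range
    # beam footprint (target domain only): axis-aligned superellipse
    beam_semiaxes: tuple[float, float] | None = None  # default 0.42 * shape
    beam_exponent: float = 4.0
    # video
    fps: float = DEFAULT_FPS
    motion_amplitude: float = 0.0   # px, 0 reproduces breath-hold (DIBH)
    motion_period: float = 4.0      # s, typical breathing cycle
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.branch_prob <= 1.0):
            raise ValueError("branch_prob must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if min(self.shape) < 1:
            raise ValueError("image shape must be positive")
        if not (0.0 < self.contrast <= 1.0):
            raise ValueError("contrast must be in (0, 1]")
        if not (0.0 <= self.background <= 1.0):
            raise ValueError("background must be in [0, 1]")
        if self.domain not in (SOURCE, TARGET):
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.width_range[0] <= 0 or self.width_range[1] < self.width_range[0]:
            raise ValueError("width_range must be positive and ordered")
        if self.fps <= 0:
            raise ValueError("fps must be positive")


def source_spec(**kw) -> PhantomSpec:
    """High-contrast, low-noise fundus-like rendering."""
    return PhantomSpec(domain=SOURCE, **kw)


def target_spec(**kw) -> PhantomSpec:
    """Low-SNR Cherenkov-like rendering with a beam footprint."""
    kw.setdefault("contrast", 0.35)
    kw.setdefault("background", 0.75)
    kw.setdefault("noise_sigma", 0.12)
    return PhantomSpec(domain=TARGET, **kw)


@dataclass
class AnnotatedImage:
    """A grayscale image in [0, 1] with its binary vasculature mask."""

    image: np.ndarray
    mask: np.ndarray
    domain: str = SOURCE
    identifier: str = ""

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        self.mask = np.asarray(self.mask)
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image shape {self.image.shape} != mask shape {self.mask.shape}"
            )
        if not np.isfinite(self.image).all():
            raise ValueError("image contains non-finite values")
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError("image values must lie in [0, 1]")
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask must be binary (0/1)")
        self.mask = self.mask.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape


@dataclass
class FrameStack:
    """An ordered video stream with a frame rate and a rest-position mask."""

    frames: np.ndarray            # (T, H, W) intensities in [0, 1]
    fps: float = DEFAULT_FPS
    reference_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty (T, H, W) stack")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.reference_mask is not None:
            self.reference_mask = np.asarray(self.reference_mask, dtype=np.uint8)
            if self.reference_mask.shape != self.frames.shape[1:]:
                raise ValueError("reference mask shape must match frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


# ---------------------------------------------------------------------------
# tree growth
# ---------------------------------------------------------------------------


def _grow_segment(
    start: np.ndarray, angle: float, spec: PhantomSpec, rng: np.random.Generator
) -> np.ndarray:
    """A biased random walk: gentle heading jitter, steered back off borders."""
    h, w = spec.shape
    pts = [start.copy()]
    pos = start.copy()
    for _ in range(spec.n_steps):
        angle += rng.normal(0.0, 0.22)
        step = np.array([np.sin(angle), np.cos(angle)]) * spec.step
        nxt = pos + step
        # steer back toward the image center when leaving a 6 % margin
        margin = 0.06 * min(h, w)
        if not (margin <= nxt[0] <= h - margin and margin <= nxt[1] <= w - margin):
            center = np.array([h / 2.0, w / 2.0])
            angle = float(np.arctan2(*(center - pos))) + rng.normal(0.0, 0.3)
            step = np.array([np.sin(angle), np.cos(angle)]) * spec.step
            nxt = pos + step
        nxt[0] = np.clip(nxt[0], 0.0, h - 1.0)
        nxt[1] = np.clip(nxt[1], 0.0, w - 1.0)
        pts.append(nxt)
        pos = nxt
    return np.array(pts)


def sample_vessel_tree(spec: PhantomSpec, seed: int | None = None) -> VesselTree:
    """Grow a connected branching vessel tree within the spec's extent.

    Each segment is a biased random walk of ``n_steps`` steps; when a
    segment of generation g < ``depth`` finishes, it bifurcates into two
    children with probability ``branch_prob`` (otherwise it terminates).
    With branch_prob = 1 the tree is the full binary expansion over
    ``depth`` generations: 2**(depth+1) - 1 segments.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    h, w = spec.shape
    root_start = np.array(
        [h * rng.uniform(0.35, 0.65), w * rng.uniform(0.35, 0.65)]
    )
    root_angle = rng.uniform(0.0, 2.0 * np.pi)
    root_width = rng.uniform(*spec.width_range)

    segments: list[np.ndarray] = []
    widths: list[float] = []
    # (start point, heading, width, generation) — grown breadth-first so the
    # segment order (and hence the rng stream) is deterministic
    frontier = [(root_start, root_angle, root_width, 0)]
    while frontier:
        nxt_frontier = []
        for start, angle, width, gen in frontier:
            pts = _grow_segment(start, angle, spec, rng)
            segments.append(pts)
            widths.append(width)
            if gen < spec.depth and rng.random() < spec.branch_prob:
                end = pts[-1]
                heading = float(
                    np.arctan2(*(pts[-1] - pts[-2]))
                ) if spec.n_steps > 0 else angle
                spread = rng.uniform(0.35, 0.8)
                child_w = max(width * 0.78, 1.0)
                nxt_frontier.append((end, heading - spread, child_w, gen + 1))
                nxt_frontier.append((end, heading + spread, child_w, gen + 1))
        frontier = nxt_frontier
    return VesselTree(segments, widths, spec.shape)


# ---------------------------------------------------------------------------
# rasterization and rendering
# ---------------------------------------------------------------------------


def _disk_offsets(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dr**2 + dc**2 <= radius**2
    return np.stack([dr[keep], dc[keep]], axis=1)


def rasterize(tree: VesselTree, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Binary mask of the tree: a disk of diameter ``width`` stamped along
    each centerline, resampled at sub-pixel spacing."""
    if shape is None:
        shape = tree.shape
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    for pts, width in zip(tree.segments, tree.widths):
        # resample the polyline at ~0.5 px spacing
        d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        total = d.sum()
        if total == 0:
            samples = pts[:1]
        else:
            t = np.concatenate([[0.0], np.cumsum(d)])
            s = np.arange(0.0, total + 0.25, 0.5)
            samples = np.stack(
                [np.interp(s, t, pts[:, 0]), np.interp(s, t, pts[:, 1])], axis=1
            )
        offs = _disk_offsets(width / 2.0)
        pix = np.rint(samples).astype(int)[:, None, :] + offs[None, :, :]
        pix = pix.reshape(-1, 2)
        ok = (
            (pix[:, 0] >= 0) & (pix[:, 0] < h) & (pix[:, 1] >= 0) & (pix[:, 1] < w)
        )
        mask[pix[ok, 0], pix[ok, 1]] = True
    return mask.astype(np.uint8)


def beam_region(spec: PhantomSpec) -> np.ndarray:
    """Axis-aligned superellipse marking the bright treatment-beam footprint."""
    h, w = spec.shape
    if spec.beam_semiaxes is None:
        a, b = 0.42 * h, 0.42 * w
    else:
        a, b = spec.beam_semiaxes
    r, c = np.mgrid[0:h, 0:w]
    p = spec.beam_exponent
    val = (np.abs(r - (h - 1) / 2.0) / a) ** p + (np.abs(c - (w - 1) / 2.0) / b) ** p
    return val <= 1.0


def render_annotated(
    tree: VesselTree,
    spec: PhantomSpec,
    seed: int | None = None,
    identifier: str = "",
) -> AnnotatedImage:
    """Render an image/mask pair in the spec's domain.

    The image is ``background`` with vessels darkened by ``contrast`` plus
    additive Gaussian noise, clipped to [0, 1].  Target-domain images are
    additionally zeroed outside the beam footprint, and the ground-truth
    mask is restricted to the beam (only vasculature that is actually
    visible in the Cherenkov signal is labeled).
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    mask = rasterize(tree, spec.shape)
    img = np.full(spec.shape, spec.background, dtype=np.float64)
    img -= spec.contrast * mask
    if spec.domain == TARGET:
        beam = beam_region(spec)
        img = np.where(beam, img, 0.0)
        mask = (mask.astype(bool) & beam).astype(np.uint8)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, spec.shape)
    img = np.clip(img, 0.0, 1.0)
    if not identifier:
        identifier = f"{spec.domain}-{seed}"
    return AnnotatedImage(img, mask, domain=spec.domain, identifier=identifier)


def motion_displacement(spec: PhantomSpec, frame_index: int) -> float:
    """Row displacement (px) of the tree at a given frame: a sinusoid of the
    configured amplitude/period sampled at the frame rate; 0 at frame 0."""
    if spec.motion_amplitude == 0:
        return 0.0
    t = frame_index / spec.fps
    return spec.motion_amplitude * float(np.sin(2.0 * np.pi * t / spec.motion_period))


def render_video(
    tree: VesselTree, spec: PhantomSpec, n_frames: int, seed: int | None = None
) -> FrameStack:
    """Render an ordered frame stream of the (possibly breathing) phantom.

    Each frame is an independent-noise rendering; with motion amplitude 0
    the stack reproduces the static breath-hold (DIBH) regime.  The
    displacement is applied to the centerlines before rasterization, so
    there are no interpolation artifacts.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    rest_mask = None
    frames = np.empty((n_frames, *spec.shape), dtype=np.float64)
    beam = beam_region(spec) if spec.domain == TARGET else None
    for t in range(n_frames):
        disp = motion_displacement(spec, t)
        m = rasterize(tree.displaced(disp) if disp else tree, spec.shape)
        if disp == 0.0 and rest_mask is None:
            rest_mask = m if beam is None else (m.astype(bool) & beam).astype(np.uint8)
        img = np.full(spec.shape, spec.background, dtype=np.float64)
        img -= spec.contrast * m
        if beam is not None:
            img = np.where(beam, img, 0.0)
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, spec.shape)
        frames[t] = np.clip(img, 0.0, 1.0)
    if rest_mask is None:  # no frame happened to sit at rest position
        m = rasterize(tree, spec.shape)
        rest_mask = m if beam is None else (m.astype(bool) & beam).astype(np.uint8)
    return FrameStack(frames, fps=spec.fps, reference_mask=rest_mask)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _to_uint8(img: np.ndarray) -> np.ndarray:
    return np.rint(np.clip(img, 0.0, 1.0) * 255).astype(np.uint8)


def save_annotated(ann: AnnotatedImage, out_dir: str | os.PathLike) -> tuple[str, str]:
    """Write image and mask as 8-bit PNG (mask as 0/255)."""
    import imageio.v3 as iio

    os.makedirs(out_dir, exist_ok=True)
    img_path = os.path.join(out_dir, f"{ann.identifier}_img.png")
    mask_path = os.path.join(out_dir, f"{ann.identifier}_mask.png")
    iio.imwrite(img_path, _to_uint8(ann.image))
    iio.imwrite(mask_path, (ann.mask * 255).astype(np.uint8))
    return img_path, mask_path


def load_annotated(
    img_path: str, mask_path: str, domain: str = SOURCE, identifier: str = ""
) -> AnnotatedImage:
    """Read an image/mask pair (PNG or TIFF); RGB input is converted to
    luminance, masks are thresholded at half range."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(img_path), dtype=np.float64)
    if img.ndim == 3:  # luminance conversion for color input
        img = img[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
    if img.max() > 1.0:
        img = img / 255.0
    mask = np.asarray(iio.imread(mask_path))
    if mask.ndim == 3:
        mask = mask[..., 0]
    mask = (mask > mask.max() / 2.0).astype(np.uint8) if mask.max() > 0 else mask
    if not identifier:
        identifier = os.path.splitext(os.path.basename(img_path))[0]
    return AnnotatedImage(np.clip(img, 0, 1), mask, domain=domain, identifier=identifier)


def save_framestack(fs: FrameStack, path: str | os.PathLike) -> str:
    """Write a stream as a multi-page TIFF (frames as 8-bit pages)."""
    import tifffile

    path = str(path)
    tifffile.imwrite(path, _to_uint8(fs.frames), photometric="minisblack")
    return path


def load_framestack(path: str, fps: float = DEFAULT_FPS) -> FrameStack:
    import tifffile

    frames = np.asarray(tifffile.imread(path), dtype=np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.max() > 1.0:
        frames = frames / 255.0
    return FrameStack(frames, fps=fps)


def save_sidecar(spec: PhantomSpec, seed: int, path: str | os.PathLike) -> str:
    """YAML sidecar recording the generator parameters and the seed."""
    doc = {"spec": dataclasses.asdict(spec), "seed": int(seed)}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return str(path)


def load_sidecar(path: str) -> tuple[PhantomSpec, int]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    d = doc["spec"]
    for key in ("shape", "width_range", "beam_semiaxes"):
        if d.get(key) is not None:
            d[key] = tuple(d[key])
    return PhantomSpec(**d), int(doc["seed"])
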