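"""Automated evaluation protocols.

Two protocols mirror how a deployed Cherenkov segmentation model is
stress-tested:

* **Robustness**: the model's prediction on the original image is the
  reference; the image is then rotated (90/180 degrees) or corrupted with
  Gaussian noise (10 % of range), re-segmented, mapped back to the
  reference frame (rotations are inverted), optionally reduced to the
  largest connected vessel component, and compared to the reference by
  Dice.

* **Sub-cumulative gate sweep**: a video stream is summed over time gates
  of k frames (k / 19.6 seconds).  The prediction on the full cumulation
  serves as the reference; disjoint consecutive k-frame windows are each
  cumulated, segmented and scored against it, giving mean Dice and
  standard error per gate size.  Short gates are noisy, so Dice rises with
  the gate; respiratory motion blurs long gates and caps the gain.

A *segmenter* here is any callable mapping a 2-D image in [0, 1] to a
same-shaped probability map — a trained ``SegModel.predict`` or a simple
intensity-thresholding baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import boundary_iou, dice_score, largest_component
from .phantom import DEFAULT_FPS, FrameStack
from .segnet import binarize

ROTATE90 = "rotate90"
ROTATE180 = "rotate180"
NOISE = "noise"
IDENTITY = "identity"


@dataclass
class PerturbationSpec:
    kind: str = NOISE
    magnitude: float = 0.10   # noise sd, fraction of dynamic range
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in (ROTATE90, ROTATE180, NOISE, IDENTITY):
            raise ValueError(f"unknown perturbation {self.kind!r}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")


def apply_perturbation(
    img: np.ndarray, spec: PerturbationSpec, rng: np.random.Generator
) -> np.ndarray:
    if spec.kind == ROTATE90:
        return np.rot90(img, 1)
    if spec.kind == ROTATE180:
        return np.rot90(img, 2)
    if spec.kind == NOISE:
        return np.clip(img + rng.normal(0.0, spec.magnitude, img.shape), 0.0, 1.0)
    return img


def invert_geometric(mask: np.ndarray, spec: PerturbationSpec) -> np.ndarray:
    """Map a prediction on a perturbed image back to the reference frame;
    only rotations change the frame."""
    if spec.kind == ROTATE90:
        return np.rot90(mask, -1)
    if spec.kind == ROTATE180:
        return np.rot90(mask, -2)
    return mask


def robustness_suite(
    segmenter,
    images: list[np.ndarray],
    specs: list[PerturbationSpec],
    threshold: float = 0.5,
    reduce_largest: bool = True,
) -> pd.DataFrame:
    """Per-image, per-perturbation Dice against the unperturbed prediction.

    Returns a tidy frame (image, perturbation, dice); aggregate with
    ``summarize_robustness``.
    """
    rows = []
    for i, img in enumerate(images):
        ref = binarize(segmenter(np.ascontiguousarray(img)), threshold)
        if reduce_largest:
            ref = largest_component(ref)
        for spec in specs:
            rng = np.random.default_rng(spec.seed + i)
            pert = apply_perturbation(img, spec, rng)
            pred = binarize(segmenter(np.ascontiguousarray(pert)), threshold)
            pred = invert_geometric(pred, spec)
            if reduce_largest:
                pred = largest_component(pred)
            rows.append(
                {"image": i, "perturbation": spec.kind,
                 "dice": dice_score(pred, ref)}
            )
    return pd.DataFrame(rows)


def summarize_robustness(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd Dice per perturbation kind."""
    return table.groupby("perturbation")["dice"].agg(["mean", "std"]).reset_index()


# ---------------------------------------------------------------------------
# video streams
# ---------------------------------------------------------------------------


def cumulate_frames(fs: FrameStack, gate: int, start: int = 0) -> np.ndarray:
    """Time-gated cumulative image: pixelwise mean of frames
    [start, start + gate), min-max rescaled to [0, 1].

    Averaging (rather than summing) keeps the intensity scale
    gate-invariant before rescaling; a pure sum followed by the same
    rescaling is equivalent.
    """
    if gate < 1 or start < 0 or start + gate > fs.n_frames:
        raise ValueError(
            f"gate [{start}, {start + gate}) outside the {fs.n_frames}-frame stack"
        )
    img = fs.frames[start : start + gate].mean(axis=0)
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    else:
        img = np.zeros_like(img)
    return img


def gate_to_seconds(k: int, fps: float = DEFAULT_FPS) -> float:
    """Gate duration in seconds, rounded to one decimal for reporting
    (10 frames -> 0.5 s, 120 frames -> 6.1 s at 19.6 fps)."""
    if k < 1 or fps <= 0:
        raise ValueError("need k >= 1 and fps > 0")
    return round(k / fps, 1)


@dataclass
class GateSweep:
    """Per-gate Dice statistics of the sub-cumulative analysis."""

    gates: list[int]
    mean_dice: list[float]
    stderr: list[float]
    per_window: dict[int, list[float]]
    fps: float = DEFAULT_FPS
    reference: str = "prediction"   # provenance of the reference mask

    @property
    def seconds(self) -> list[float]:
        return [gate_to_seconds(k, self.fps) for k in self.gates]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gate_frames": self.gates, "gate_seconds": self.seconds,
             "mean_dice": self.mean_dice, "stderr": self.stderr}
        )

    def spearman_trend(self) -> float:
        """Rank correlation of gate size vs mean Dice (positive when
        cumulating more frames helps)."""
        return float(stats.spearmanr(self.gates, self.mean_dice).statistic)


def subcumulative_analysis(
    segmenter,
    fs: FrameStack,
    gates: list[int],
    threshold: float = 0.5,
    reference: str = "prediction",
) -> GateSweep:
    """Segment disjoint k-frame cumulations and score them against the
    reference mask.

    ``reference="prediction"`` (the deployment protocol) uses the
    segmentation of the full cumulation; ``reference="truth"`` scores
    against the stack's ground-truth rest mask instead, which is the right
    comparison when contrasting breathing vs breath-hold accuracy (with a
    prediction reference, the full-gate window is compared to itself).
    """
    gates = sorted(set(int(g) for g in gates))
    if any(g < 1 or g > fs.n_frames for g in gates):
        raise ValueError("gate sizes must be within the stack length")
    if reference == "prediction":
        full = cumulate_frames(fs, fs.n_frames, 0)
        ref = binarize(segmenter(full), threshold)
    elif reference == "truth":
        if fs.reference_mask is None:
            raise ValueError("stack has no ground-truth reference mask")
        ref = fs.reference_mask
    else:
        raise ValueError("reference must be 'prediction' or 'truth'")
    mean_dice, stderr, per_window = [], [], {}
    for k in gates:
        scores = []
        for start in range(0, fs.n_frames - k + 1, k):
            img = cumulate_frames(fs, k, start)
            pred = binarize(segmenter(img), threshold)
            scores.append(dice_score(pred, ref))
        per_window[k] = scores
        mean_dice.append(float(np.mean(scores)))
        stderr.append(
            float(np.std(scores, ddof=1) / np.sqrt(len(scores)))
            if len(scores) > 1 else 0.0
        )
    return GateSweep(gates, mean_dice, stderr, per_window, fps=fs.fps,
                     reference=reference)


def plot_gatesweep(sweep: GateSweep, path: str) -> str:
    """Mean Dice +/- SE vs cumulation time; requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    sec = np.array(sweep.seconds)
    mu = np.array(sweep.mean_dice)
    se = np.array(sweep.stderr)
    ax.plot(sec, mu, "o-")
    ax.fill_between(sec, mu - se, mu + se, alpha=0.3)
    ax.set_xlabel("cumulation time (s)")
    ax.set_ylabel("Dice vs reference")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


# ---------------------------------------------------------------------------
# baselines and rater-consistency scoring
# ---------------------------------------------------------------------------


class ThresholdSegmenter:
    """Classical baseline: vessels are pixels darker than a threshold.

    Returns 1 - image shifted so that ``binarize(..., 0.5)`` selects
    pixels below ``dark_level``.  Exactly equivariant to 90-degree
    rotations (a pure pixel permutation), which makes it the natural stub
    for validating the robustness harness.
    """

    def __init__(self, dark_level: float = 0.5):
        self.dark_level = dark_level

    def __call__(self, img: np.ndarray) -> np.ndarray:
        return np.clip(1.0 - np.asarray(img) + (self.dark_level - 0.5), 0.0, 1.0)


def pairwise_consistency(masks: list[np.ndarray], d: float = 2.0) -> pd.DataFrame:
    """Dice and boundary IoU over all unordered pairs of repeated masks
    (the scoring used to compare repeated manual segmentations)."""
    rows = []
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            rows.append(
                {"pair": (i, j),
                 "dice": dice_score(masks[i], masks[j]),
                 "boundary_iou": boundary_iou(masks[i], masks[j], d)}
            )
    return pd.DataFrame(rows)
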