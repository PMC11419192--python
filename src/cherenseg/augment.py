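"""Stochastic training-time augmentation.

Three independent events per patch: horizontal flip (p = 0.33), rotation by
90/180/270 degrees (p = 0.33), and additive Gaussian noise on the image
only (p = 0.50) with sigma drawn uniformly up to 25 % of the dynamic range.
Geometric transforms are exact pixel permutations applied identically to
image and mask; noise never touches the mask, and the image is clipped back
to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .patchify import Patch


@dataclass
class AugmentPolicy:
    flip_prob: float = 0.33
    rot_prob: float = 0.33
    angles: tuple[int, ...] = (90, 180, 270)
    noise_prob: float = 0.50
    noise_max: float = 0.25   # sigma upper bound, fraction of dynamic range

    def __post_init__(self) -> None:
        for p in (self.flip_prob, self.rot_prob, self.noise_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if not set(self.angles) <= {90, 180, 270}:
            raise ValueError("angles must be a subset of {90, 180, 270}")
        if self.noise_max < 0:
            raise ValueError("noise_max must be >= 0")


IDENTITY_POLICY = AugmentPolicy(flip_prob=0.0, rot_prob=0.0, noise_prob=0.0)


def augment_arrays(
    image: np.ndarray,
    mask: np.ndarray,
    policy: AugmentPolicy,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one independent draw of the augmentation policy.

    The three transforms are independent events, so a patch may receive
    any combination of them.
    """
    if rng.random() < policy.flip_prob:
        image = image[:, ::-1]
        mask = mask[:, ::-1]
    if rng.random() < policy.rot_prob:
        angle = policy.angles[rng.integers(len(policy.angles))]
        k = angle // 90
        image = np.rot90(image, k)
        mask = np.rot90(mask, k)
    if rng.random() < policy.noise_prob:
        sigma = rng.uniform(0.0, policy.noise_max)
        image = np.clip(image + rng.normal(0.0, sigma, image.shape), 0.0, 1.0)
    return np.ascontiguousarray(image), np.ascontiguousarray(mask)


def augment_patch(p: Patch, policy: AugmentPolicy, rng: np.random.Generator) -> Patch:
    img, mask = augment_arrays(p.image, p.mask, policy, rng)
    return Patch(img, mask, origin=p.origin, parent=p.parent)
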