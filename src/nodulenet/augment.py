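"""Online training-time augmentation and class rebalancing.

Three geometric augmentations, each applied to the nodule cube and its mask
with identical geometry so the pair stays voxel aligned:

* integer translation with per-axis step drawn from [0, 5] voxels (sign
  drawn separately), zero fill at exposed faces;
* rotation: a random permutation of the three axes followed by an in-plane
  rotation by one of {45, 135, 225} degrees (linear interpolation for the
  intensity cube, nearest neighbour for the mask);
* independent per-axis flips with probability 0.5.

Malignant cases additionally get replicated (with fresh augmentation draws)
until the class counts balance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .data import Sample
from .preprocess import ROIPair


@dataclass(frozen=True)
class AugmentConfig:
    max_translate: int = 5
    rotation_angles: tuple[float, ...] = (45.0, 135.0, 225.0)
    flip_axes: tuple[int, ...] = (0, 1, 2)
    apply_prob: float = 0.5      # chance each augmentation fires per sample
    balance_by: str = "individual"
    seed: int = 0

    def validate(self):
        if not 0 <= self.max_translate <= 5:
            raise ValueError("translation step must lie in [0, 5] voxels")
        if not set(self.rotation_angles) <= {45.0, 135.0, 225.0}:
            raise ValueError("rotation angles restricted to {45, 135, 225}")
        return self


def random_translate(pair: ROIPair, rng: np.random.Generator,
                     max_step: int = 5) -> ROIPair:
    shifts = [int(rng.integers(0, max_step + 1))
              * (1 if rng.random() < 0.5 else -1) for _ in range(3)]

    def shift(a):
        out = np.zeros_like(a)
        src, dst = [], []
        for s, n in zip(shifts, a.shape):
            src.append(slice(max(-s, 0), n - max(s, 0)))
            dst.append(slice(max(s, 0), n - max(-s, 0)))
        out[tuple(dst)] = a[tuple(src)]
        return out

    return ROIPair(shift(pair.nodule_cube), shift(pair.mask_cube))


def random_rotate(pair: ROIPair, rng: np.random.Generator,
                  angles=(45.0, 135.0, 225.0)) -> ROIPair:
    perm = tuple(rng.permutation(3))
    angle = float(angles[rng.integers(0, len(angles))])
    cube = np.transpose(pair.nodule_cube, perm)
    mask = np.transpose(pair.mask_cube, perm)
    cube = ndimage.rotate(cube, angle, axes=(0, 1), reshape=False,
                          order=1, mode="constant", cval=0.0)
    mask = ndimage.rotate(mask, angle, axes=(0, 1), reshape=False,
                          order=0, mode="constant", cval=0)
    return ROIPair(np.clip(cube, 0.0, 1.0), mask.astype(pair.mask_cube.dtype))


def random_flip(pair: ROIPair, rng: np.random.Generator,
                axes=(0, 1, 2)) -> ROIPair:
    cube, mask = pair.nodule_cube, pair.mask_cube
    for ax in axes:
        if rng.random() < 0.5:
            cube = np.flip(cube, axis=ax)
            mask = np.flip(mask, axis=ax)
    return ROIPair(cube.copy(), mask.copy())


def augment_pair(pair: ROIPair, cfg: AugmentConfig,
                 rng: np.random.Generator) -> ROIPair:
    """Each augmentation fires independently with ``cfg.apply_prob``."""
    cfg.validate()
    if rng.random() < cfg.apply_prob:
        pair = random_translate(pair, rng, cfg.max_translate)
    if rng.random() < cfg.apply_prob:
        pair = random_rotate(pair, rng, cfg.rotation_angles)
    if rng.random() < cfg.apply_prob:
        pair = random_flip(pair, rng, cfg.flip_axes)
    return pair


def rebalance(samples: list[Sample], cfg: AugmentConfig,
              rng: np.random.Generator | None = None) -> list[Sample]:
    """Replicate malignant samples (flagged for fresh augmentation draws)
    until the class counts are equal within one; benign samples appear once.
    """
    cfg.validate()
    if not samples:
        return []
    key = cfg.balance_by
    benign = [s for s in samples if s.labels[key] == 0]
    malignant = [s for s in samples if s.labels[key] == 1]
    if not malignant or not benign or len(malignant) >= len(benign):
        return list(samples)
    rng = rng or np.random.default_rng(cfg.seed)
    out = list(samples)
    deficit = len(benign) - len(malignant)
    idx = rng.permutation(len(malignant))
    for j in range(deficit):
        out.append(malignant[idx[j % len(malignant)]])
    return out
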