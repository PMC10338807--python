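"""Synthetic 3D nodule phantoms with multi-reader annotations.

The generator produces the statistical structure the diagnosis network is
built around, with no external data:

* a nodule (ellipsoid, optional surface lobes, optional radial spikes,
  optional bright calcification core, Gaussian margin blur) on a smoothed
  noise background;
* a latent malignancy score on the 1-5 rating scale that increases
  monotonically with spike amplitude and lobe count (spiculated and lobed
  nodules read as more suspicious);
* R readers, each with a morphologically perturbed copy of the true mask
  (observer-specific segmentations) and ordinal ratings formed by adding
  Gaussian noise to the latent score and rounding onto 1-5;
* eight semantic-feature scores derived from the shape parameters by
  documented monotone maps, plus +/-1 reader noise.

Everything is reproducible from ``(config, seed)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .annotations import (
    EXCLUDED,
    FEATURE_RANGES,
    ReaderAnnotation,
    individual_label,
    panel_label,
    semantic_labels,
)
from .data import Sample
from .network import SEMANTIC_FEATURES
from .preprocess import HU_WINDOW, TARGET_SPACING

TEXTURES = ("ggo", "part_solid", "solid")


@dataclass(frozen=True)
class PhantomConfig:
    n_nodules: int = 100
    readers: int = 4
    cube_side: int = 80
    malignant_fraction: float = 0.36
    rating_noise_sd: float = 0.7
    mask_jitter: int = 2
    semantic_noise: bool = True
    seed: int = 0

    def validate(self):
        if self.readers < 1:
            raise ValueError("at least one reader required")
        if not 0.0 < self.malignant_fraction < 1.0:
            raise ValueError("malignant fraction must lie in (0, 1)")
        if self.cube_side < 16:
            raise ValueError("cube side must be >= 16 voxels")
        return self


@dataclass
class PhantomTruth:
    latent_malignancy: float
    radii: tuple[float, float, float]
    spike_count: int
    spike_amp: float
    lobe_count: int
    calcified: bool
    margin_blur: float
    texture: str
    true_mask: np.ndarray = None
    center: tuple[int, int, int] = (0, 0, 0)


def latent_malignancy(spike_amp: float, lobe_count: int) -> float:
    """Monotone map from shape irregularity to the 1-5 latent score."""
    return float(np.clip(1.0 + 3.2 * spike_amp + 0.45 * lobe_count, 1.0, 5.0))


def _nodule_rng(cfg: PhantomConfig, index: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, index])


def _class_sequence(cfg: PhantomConfig) -> np.ndarray:
    """Deterministic benign/malignant assignment hitting the target fraction
    exactly (to rounding), shuffled by the config seed."""
    n_mal = int(round(cfg.malignant_fraction * cfg.n_nodules))
    seq = np.array([1] * n_mal + [0] * (cfg.n_nodules - n_mal))
    np.random.default_rng([cfg.seed, 10**6]).shuffle(seq)
    return seq


def generate_truth(cfg: PhantomConfig, index: int,
                   malignant: bool | None = None
                   ) -> tuple[np.ndarray, PhantomTruth]:
    """Build one phantom cube (values in [0, 1]) and its ground truth."""
    cfg.validate()
    rng = _nodule_rng(cfg, index)
    if malignant is None:
        malignant = bool(_class_sequence(cfg)[index])
    S = cfg.cube_side
    if malignant:
        spike_amp = rng.uniform(0.75, 1.0)
        lobe_count = int(rng.integers(2, 5))
    else:
        spike_amp = rng.uniform(0.0, 0.25)
        lobe_count = int(rng.integers(0, 2))
    latent = latent_malignancy(spike_amp, lobe_count)
    size_scale = 1.0 + 0.25 * (latent - 1.0) / 4.0
    radii = tuple(S * (0.11 + 0.035 * rng.random()) * size_scale
                  for _ in range(3))
    center = tuple(int(S // 2 + rng.integers(-2, 3)) for _ in range(3))
    spike_count = 0 if spike_amp < 0.05 else int(rng.integers(4, 9))
    calcified = bool(rng.random() < 0.15)
    margin_blur = 0.4 + 0.22 * (latent - 1.0) + 0.1 * rng.random()
    texture = TEXTURES[int(rng.integers(0, 3))] if not malignant else "solid"

    # normalised radial coordinate of every voxel
    grid = np.indices((S, S, S), dtype=np.float32)
    delta = np.stack([grid[i] - center[i] for i in range(3)])
    rho = np.sqrt(sum((delta[i] / radii[i]) ** 2 for i in range(3)))
    threshold = np.ones_like(rho)
    if spike_count:
        norm = np.sqrt((delta ** 2).sum(axis=0)) + 1e-6
        d = delta / norm
        bump = np.zeros_like(rho)
        for _ in range(spike_count):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            cosang = np.clip(np.tensordot(u, d, axes=1), 0.0, 1.0)
            np.maximum(bump, cosang ** 8, out=bump)
        threshold += 1.8 * spike_amp * bump
    mask = rho <= threshold
    mean_r = float(np.mean(radii))
    for _ in range(lobe_count):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        lc = np.asarray(center) + 0.9 * np.asarray(radii) * u
        lr = 0.45 * mean_r
        dist = np.sqrt(sum((grid[i] - lc[i]) ** 2 for i in range(3)))
        mask |= dist <= lr

    intensity = {"solid": 0.7, "part_solid": 0.55, "ggo": 0.42}[texture]
    nodule_map = mask.astype(np.float32) * intensity
    if calcified:
        dist = np.sqrt(sum((grid[i] - center[i]) ** 2 for i in range(3)))
        nodule_map[dist <= 0.25 * mean_r] = 0.95
    nodule_map = ndimage.gaussian_filter(nodule_map, margin_blur)
    background = ndimage.gaussian_filter(
        rng.random((S, S, S), dtype=np.float32), 2.0)
    lo, hi = background.min(), background.max()
    background = 0.3 * (background - lo) / max(hi - lo, 1e-6)
    cube = np.clip(np.maximum(background, nodule_map), 0.0, 1.0)
    truth = PhantomTruth(
        latent_malignancy=latent, radii=radii, spike_count=spike_count,
        spike_amp=spike_amp, lobe_count=lobe_count, calcified=calcified,
        margin_blur=margin_blur, texture=texture,
        true_mask=mask.astype(np.uint8), center=center)
    return cube.astype(np.float32), truth


# ---------------------------------------------------------------------------
# semantic ground truth
# ---------------------------------------------------------------------------

def semantic_truth(truth: PhantomTruth, cube_side: int) -> dict[str, int]:
    """Documented monotone maps from shape parameters to semantic scores."""
    radii = np.asarray(truth.radii)
    aniso = float(radii.min() / radii.max())
    mean_r = float(radii.mean())
    scores = {
        "subtlety": int(np.clip(round(12 * mean_r / cube_side), 1, 5)),
        "internalStructure": 1,
        "calcification": int(np.clip(1 + truth.spike_count % 5, 1, 5))
        if truth.calcified else 6,
        "sphericity": int(np.clip(round(5 * aniso), 1, 5)),
        "margin": int(np.clip(round(5 - 2.2 * (truth.margin_blur - 0.4)),
                              1, 5)),
        "lobulation": int(np.clip(1 + truth.lobe_count, 1, 5)),
        "spiculation": int(np.clip(round(1 + 4.5 * truth.spike_amp), 1, 5)),
        "texture": {"ggo": 1, "part_solid": 3, "solid": 5}[truth.texture],
    }
    return scores


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _ball(radius: int) -> np.ndarray:
    if radius <= 0:
        return np.ones((1, 1, 1), dtype=bool)
    g = np.indices((2 * radius + 1,) * 3) - radius
    return (g ** 2).sum(axis=0) <= radius ** 2


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    denom = a.sum() + b.sum()
    return 2.0 * inter / denom if denom else 1.0


def perturb_mask(mask: np.ndarray, jitter: int,
                 rng: np.random.Generator,
                 radius: int | None = None,
                 dilate: bool | None = None) -> np.ndarray:
    """Random dilation/erosion of radius <= jitter with Dice >= 0.7 against
    the truth enforced by shrinking the radius."""
    if jitter <= 0:
        return mask.copy()
    if radius is None:
        radius = int(rng.integers(0, jitter + 1))
    radius = min(int(radius), jitter)
    if dilate is None:
        dilate = bool(rng.random() < 0.5)
    while radius > 0:
        op = ndimage.binary_dilation if dilate else ndimage.binary_erosion
        new = op(mask.astype(bool), structure=_ball(radius))
        if new.sum() > 0 and _dice(new, mask.astype(bool)) >= 0.7:
            return new.astype(np.uint8)
        radius -= 1
    return mask.copy()


def simulate_readers(truth: PhantomTruth, cfg: PhantomConfig,
                     rng: np.random.Generator,
                     scan_id: str = "scan", nodule_key: str = "n0"
                     ) -> list[ReaderAnnotation]:
    """One annotation per reader: perturbed mask, noisy malignancy rating,
    noisy semantic scores.

    A reader's rating bias and mask perturbation are coupled: a reader who
    over-segments (dilated mask) also rates higher, so the observer-specific
    mask channel carries information about that reader's own opinion.
    """
    base_scores = semantic_truth(truth, truth.true_mask.shape[0])
    out = []
    for r in range(cfg.readers):
        bias = (rng.normal(0.0, cfg.rating_noise_sd)
                if cfg.rating_noise_sd > 0 else 0.0)
        rating = int(np.clip(round(truth.latent_malignancy + bias), 1, 5))
        scores = {}
        for feat, s in base_scores.items():
            lo, hi = FEATURE_RANGES[feat]
            noise = int(rng.integers(-1, 2)) if cfg.semantic_noise else 0
            scores[feat] = int(np.clip(s + noise, lo, hi))
        mask = perturb_mask(truth.true_mask, cfg.mask_jitter, rng,
                            radius=int(round(abs(bias))),
                            dilate=bias > 0)
        out.append(ReaderAnnotation(
            reader_id=f"r{r}", nodule_key=nodule_key, scan_id=scan_id,
            center=truth.center, mask=mask, malignancy=rating,
            semantic_scores=scores).validate())
    return out


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def make_samples(cfg: PhantomConfig,
                 drop_panel_excluded: bool = False
                 ) -> list[Sample]:
    """In-memory dataset: one Sample per (nodule, reader)."""
    cfg.validate()
    samples = []
    for i in range(cfg.n_nodules):
        cube, truth = generate_truth(cfg, i)
        rng = np.random.default_rng([cfg.seed, i, 1])
        anns = simulate_readers(truth, cfg, rng, scan_id=f"s{i}",
                                nodule_key=f"n{i}")
        plabel = panel_label([a.malignancy for a in anns])
        if drop_panel_excluded and plabel == EXCLUDED:
            continue
        for ann in anns:
            samples.append(Sample(
                nodule_cube=cube, mask_cube=ann.mask,
                labels={
                    "individual": individual_label(ann.malignancy),
                    "panel": plabel,
                    "semantic": semantic_labels(ann.semantic_scores),
                },
                nodule_id=f"n{i}", reader_id=ann.reader_id))
    return samples


def build_dataset(cfg: PhantomConfig, out_dir: str | Path) -> Path:
    """Write cubes, per-reader masks and a JSON manifest consumable by
    :func:`nodulenet.annotations.parse_annotations`.

    Volumes are stored on the Hounsfield scale (the inverse of the [0, 1]
    windowing), at the target voxel spacing, so the preprocessing pipeline
    recovers the generated cubes.  Returns the manifest path.
    """
    import nibabel as nib

    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lo, hi = HU_WINDOW
    affine = np.diag(list(TARGET_SPACING) + [1.0])
    manifest = {"version": 1, "spacing": list(TARGET_SPACING),
                "cube_side": cfg.cube_side, "seed": cfg.seed,
                "scans": [], "annotations": [], "labels": {}}
    nodule_ids = []
    for i in range(cfg.n_nodules):
        cube, truth = generate_truth(cfg, i)
        rng = np.random.default_rng([cfg.seed, i, 1])
        anns = simulate_readers(truth, cfg, rng, scan_id=f"s{i}",
                                nodule_key=f"n{i}")
        hu = (cube * (hi - lo) + lo).astype(np.float32)
        vol_name = f"s{i}.nii"
        nib.save(nib.Nifti1Image(hu, affine), str(out_dir / vol_name))
        manifest["scans"].append({"scan_id": f"s{i}", "volume": vol_name,
                                  "slice_thickness": TARGET_SPACING[2]})
        plabel = panel_label([a.malignancy for a in anns])
        nodule_ids.append((f"n{i}", plabel))
        for ann in anns:
            mask_name = f"s{i}_n{i}_{ann.reader_id}.nii"
            nib.save(nib.Nifti1Image(ann.mask.astype(np.uint8), affine),
                     str(out_dir / mask_name))
            manifest["annotations"].append({
                "reader_id": ann.reader_id, "nodule_key": ann.nodule_key,
                "scan_id": ann.scan_id,
                "center": [int(c) for c in ann.center],
                "mask": mask_name, "malignancy": ann.malignancy,
                "semantic_scores": ann.semantic_scores,
            })
            manifest["labels"][f"n{i}/{ann.reader_id}"] = {
                "individual": individual_label(ann.malignancy),
                "panel": plabel if plabel != EXCLUDED else EXCLUDED,
                "semantic": semantic_labels(ann.semantic_scores),
            }
    # nodule-level split, 60/20/20 in generation order
    n = len(nodule_ids)
    n_train, n_val = int(0.6 * n), int(0.2 * n)
    manifest["split"] = {
        "train": [nid for nid, _ in nodule_ids[:n_train]],
        "val": [nid for nid, _ in nodule_ids[n_train:n_train + n_val]],
        "test": [nid for nid, _ in nodule_ids[n_train + n_val:]],
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path
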