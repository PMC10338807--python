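"""CT preprocessing: nearest-neighbour resampling, HU windowing, and
extraction of paired nodule/mask cubes.

Pipeline: resample every scan to voxel spacing (0.68, 0.68, 1.75) mm with
nearest-neighbour interpolation, window to [-1200, 600] HU and rescale to
[0, 1], then crop an 80x80x80-voxel cube centred on the mean of the readers'
nodule centers.  Each reader's own segmentation is cropped with the same
geometry, so the nodule cube is observer-invariant while the mask cube is
observer-specific.  Regions falling outside the scan are zero padded (air
after windowing).  Arrays are indexed (x, y, z), 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

TARGET_SPACING = (0.68, 0.68, 1.75)
HU_WINDOW = (-1200.0, 600.0)
CUBE_SIDE = 80


@dataclass
class CTVolume:
    intensities: np.ndarray           # 3D, Hounsfield units (or [0,1] after windowing)
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def validate(self):
        if self.intensities.ndim != 3:
            raise ValueError(f"volume must be rank 3, got "
                             f"{self.intensities.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        return self


@dataclass
class ROIPair:
    nodule_cube: np.ndarray
    mask_cube: np.ndarray

    def validate(self, side: int = CUBE_SIDE):
        if self.nodule_cube.shape != (side,) * 3 or \
                self.mask_cube.shape != (side,) * 3:
            raise ValueError(
                f"cube shapes {self.nodule_cube.shape}/{self.mask_cube.shape}"
                f" differ from {(side,) * 3}")
        if self.nodule_cube.min() < 0 or self.nodule_cube.max() > 1:
            raise ValueError("nodule cube values must lie in [0, 1]")
        if not np.all(np.isin(np.unique(self.mask_cube), (0, 1))):
            raise ValueError("mask cube is not strictly binary")
        return self


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def resample_nearest(vol: CTVolume,
                     target_spacing=TARGET_SPACING) -> CTVolume:
    """Nearest-neighbour resample onto ``target_spacing``.

    The output grid has ``round(n * s_in / s_out)`` voxels per axis; every
    output value is copied from the nearest input voxel, so masks stay
    binary and no new intensities appear.
    """
    vol.validate()
    in_shape = vol.intensities.shape
    factors = [si / so for si, so in zip(vol.spacing, target_spacing)]
    out_shape = tuple(max(1, _round_half_up(n * f))
                      for n, f in zip(in_shape, factors))
    if out_shape == in_shape and all(abs(f - 1.0) < 1e-9 for f in factors):
        return CTVolume(vol.intensities.copy(), tuple(target_spacing),
                        vol.origin)
    out = ndimage.zoom(vol.intensities,
                       [o / i for o, i in zip(out_shape, in_shape)],
                       order=0, mode="nearest", grid_mode=True)
    # zoom can be off by one voxel on some axes; enforce the contract
    out = out[tuple(slice(0, s) for s in out_shape)]
    return CTVolume(out, tuple(target_spacing), vol.origin)


def window_normalize(vol: CTVolume, lo: float = HU_WINDOW[0],
                     hi: float = HU_WINDOW[1]) -> CTVolume:
    """Clip to the [lo, hi] HU window and rescale linearly to [0, 1]."""
    if lo >= hi:
        raise ValueError(f"window lower bound {lo} must be below {hi}")
    vol.validate()
    out = np.clip((vol.intensities.astype(np.float32) - lo) / (hi - lo),
                  0.0, 1.0)
    return CTVolume(out, vol.spacing, vol.origin)


def consensus_center(centers) -> tuple[int, int, int]:
    """Component-wise mean of the readers' centers, rounded half-up."""
    centers = list(centers)
    if not centers:
        raise ValueError("consensus center requires at least one center")
    mean = np.mean(np.asarray(centers, dtype=np.float64), axis=0)
    return tuple(_round_half_up(c) for c in mean)


def extract_cube(vol: CTVolume | np.ndarray, center,
                 side: int = CUBE_SIDE) -> np.ndarray:
    """Crop a ``side``^3 cube centred at ``center``; zero pad outside.

    The voxel at the cube's centre index ``side // 2`` equals the volume at
    ``center``.
    """
    arr = vol.intensities if isinstance(vol, CTVolume) else np.asarray(vol)
    if arr.ndim != 3:
        raise ValueError("expected a rank-3 volume")
    center = tuple(int(c) for c in center)
    for c, n in zip(center, arr.shape):
        if not 0 <= c < n:
            raise ValueError(f"center {center} outside volume {arr.shape}")
    half = side // 2
    out = np.zeros((side,) * 3, dtype=arr.dtype)
    src, dst = [], []
    for c, n in zip(center, arr.shape):
        lo, hi = c - half, c - half + side
        src.append(slice(max(lo, 0), min(hi, n)))
        dst.append(slice(max(lo, 0) - lo, side - (hi - min(hi, n))))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def build_mask_cube(mask: np.ndarray, center,
                    side: int = CUBE_SIDE) -> np.ndarray:
    """Crop a reader's binary segmentation with the same geometry as
    :func:`extract_cube` so the pair stays voxel aligned."""
    mask = np.asarray(mask)
    if not np.all(np.isin(np.unique(mask), (0, 1))):
        raise ValueError("mask is not strictly binary")
    return extract_cube(mask.astype(np.uint8), center, side)


def make_roi_pair(vol: CTVolume, mask: np.ndarray, centers,
                  side: int = CUBE_SIDE) -> ROIPair:
    """Full crop step for one annotation: consensus centre, aligned cubes."""
    center = consensus_center(centers)
    pair = ROIPair(nodule_cube=extract_cube(vol, center, side),
                   mask_cube=build_mask_cube(mask, center, side))
    return pair.validate(side)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def load_nifti(path: str | Path) -> CTVolume:
    import nibabel as nib

    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CTVolume(np.asarray(img.dataobj).astype(np.float32), spacing)


def save_nifti(vol: CTVolume | np.ndarray, path: str | Path,
               spacing=TARGET_SPACING):
    import nibabel as nib

    if isinstance(vol, CTVolume):
        arr, spacing = vol.intensities, vol.spacing
    else:
        arr = vol
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(arr), affine), str(path))


def load_dicom_series(directory: str | Path) -> CTVolume:
    """Assemble a CT volume from a directory of single-slice DICOM files.

    Slices are ordered by the z component of ImagePositionPatient (falling
    back to InstanceNumber), intensities are rescaled to Hounsfield units
    via RescaleSlope/RescaleIntercept, and the z spacing is taken from the
    slice-position increments.  Axis order of the result is (x, y, z).
    """
    import pydicom

    paths = sorted(Path(directory).glob("*.dcm"))
    if not paths:
        raise ValueError(f"no DICOM files in {directory}")
    slices = [pydicom.dcmread(str(p)) for p in paths]

    def z_of(ds):
        if getattr(ds, "ImagePositionPatient", None) is not None:
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=z_of)
    first = slices[0]
    slope = float(getattr(first, "RescaleSlope", 1.0))
    intercept = float(getattr(first, "RescaleIntercept", 0.0))
    # pixel_array is (row, col) = (y, x); transpose to (x, y)
    planes = [(s.pixel_array.astype(np.float32).T * slope + intercept)
              for s in slices]
    vol = np.stack(planes, axis=-1)
    row_spacing, col_spacing = (float(v) for v in first.PixelSpacing)
    if len(slices) > 1:
        dz = abs(z_of(slices[1]) - z_of(slices[0]))
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    return CTVolume(vol, (col_spacing, row_spacing, dz)).validate()
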