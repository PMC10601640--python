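"""Volume slicing and prediction I/O.

3-D image/label volumes (NIfTI) are sliced along a chosen axis into 2-D
records, min-max normalised per volume, and resized to the training
resolution (208 x 176 by default) with paired transforms: bilinear for the
image, nearest for the label, which is re-binarised at 0.5 afterwards.
Multi-modal volumes (a 4th dimension) become stacked channels.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclasses.dataclass
class SliceRecord:
    volume_id: str
    index: int
    image: np.ndarray          # (C, H, W) float in [0, 1]
    mask: np.ndarray           # (H, W) uint8 in {0, 1}
    norm_lo: float             # per-volume intensity range used for min-max
    norm_hi: float


def _resize2d(arr: np.ndarray, target: tuple[int, int], order: int) -> np.ndarray:
    zoom = (target[0] / arr.shape[0], target[1] / arr.shape[1])
    return ndimage.zoom(arr, zoom, order=order, mode="nearest", grid_mode=True)


def slice_volume(image_path: str | Path, label_path: str | Path,
                 axis: int = 2, target_shape: tuple[int, int] = (208, 176),
                 keep_empty: bool = True) -> list[SliceRecord]:
    """Slice an image/label NIfTI pair into resized 2-D records.

    `axis` selects the slicing axis of the 3-D grid (2 = axial for
    RAS-oriented volumes).  Set ``keep_empty=False`` to drop slices whose
    label is empty.
    """
    img_vol = np.asanyarray(nib.load(str(image_path)).dataobj, dtype=np.float64)
    lab_vol = np.asanyarray(nib.load(str(label_path)).dataobj, dtype=np.float64)
    if img_vol.shape[:3] != lab_vol.shape[:3]:
        raise ValueError(
            f"image {img_vol.shape} and label {lab_vol.shape} volumes disagree")
    lo, hi = float(img_vol.min()), float(img_vol.max())
    norm = (img_vol - lo) / (hi - lo) if hi > lo else np.zeros_like(img_vol)

    vid = Path(image_path).name
    records = []
    for i in range(img_vol.shape[axis]):
        img = np.take(norm, i, axis=axis)
        lab = np.take(lab_vol, i, axis=axis)
        if img.ndim == 2:
            img = img[..., None]
        channels = [np.clip(_resize2d(img[..., c], target_shape, order=1), 0, 1)
                    for c in range(img.shape[-1])]
        mask = (_resize2d(lab[..., 0] if lab.ndim == 3 else lab,
                          target_shape, order=0) >= 0.5).astype(np.uint8)
        if not keep_empty and mask.sum() == 0:
            continue
        records.append(SliceRecord(volume_id=vid, index=i,
                                   image=np.stack(channels), mask=mask,
                                   norm_lo=lo, norm_hi=hi))
    return records


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), (np.asarray(mask) > 0).astype(np.uint8) * 255)


def load_mask_png(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    return (iio.imread(Path(path)) > 127).astype(np.uint8)


def save_prob_nifti(probs: np.ndarray, path: str | Path) -> None:
    """Stack (B, H, W) probability maps into a float NIfTI volume."""
    nib.save(nib.Nifti1Image(np.moveaxis(np.asarray(probs, np.float32), 0, -1),
                             affine=np.eye(4)), str(path))
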