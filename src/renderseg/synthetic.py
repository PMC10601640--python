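"""Synthetic low-contrast lesion images with binary ground-truth masks.

The generator emulates the statistics that make stroke-lesion slices hard to
segment: one or several disconnected foci with extremely irregular,
non-convex boundaries, placed at arbitrary positions, whose mean intensity
differs from the surrounding tissue by only a small, configurable contrast,
on top of a smooth intensity bias field and Gaussian noise.

Shapes are smoothed random radial polygons: around a random centre, the
boundary radius is a mean radius modulated by a low-order random Fourier
series in the polar angle, which yields lobed, non-convex blobs whose area
is analytically controllable (area scales with the squared mean radius).

All randomness flows through ``numpy.random.Generator`` objects seeded from
the arguments; identical seed and parameters give bit-identical samples.
Connected components are counted with 8-connectivity.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

#: 8-connectivity structuring element used for component counting.
CONNECTIVITY_8 = np.ones((3, 3), dtype=bool)

# intensity model constants (intensity units, image range [0, 1])
BACKGROUND_MEAN = 0.4
BIAS_AMPLITUDE = 0.04
_MAX_PLACEMENT_TRIES = 200


class CapacityError(ValueError):
    """Requested lesions cannot fit in the image."""


@dataclasses.dataclass(frozen=True)
class LesionSample:
    """One synthetic slice: image, binary mask, and generation metadata."""

    image: np.ndarray        # (H, W) float64 in [0, 1]
    mask: np.ndarray         # (H, W) uint8 in {0, 1}
    seed: int
    lesion_count: int
    contrast: float
    noise_sd: float

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")


def _radial_blob(rng: np.random.Generator, height: int, width: int,
                 target_area: float, margin: int = 1) -> np.ndarray | None:
    """Rasterise one smoothed radial polygon with roughly `target_area` pixels.

    Returns a boolean mask, or None if the blob could not be placed inside
    the frame (caller retries with a fresh draw).
    """
    # irregularity: radius(theta) = r0 * (1 + sum_k a_k cos(k theta + phi_k))
    n_harmonics = 4
    amps = rng.uniform(0.05, 0.22, size=n_harmonics) / np.arange(1, n_harmonics + 1)
    phases = rng.uniform(0, 2 * np.pi, size=n_harmonics)

    # mean area of the polar region is pi*r0^2*(1 + sum a_k^2 / 2)
    r0 = np.sqrt(target_area / (np.pi * (1.0 + 0.5 * np.sum(amps ** 2))))
    r_max = r0 * (1.0 + np.sum(amps))
    lo_r, hi_r = margin + r_max, height - margin - r_max
    lo_c, hi_c = margin + r_max, width - margin - r_max
    if lo_r >= hi_r or lo_c >= hi_c:
        return None
    cy = rng.uniform(lo_r, hi_r)
    cx = rng.uniform(lo_c, hi_c)

    yy, xx = np.mgrid[0:height, 0:width]
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    radius = r0 * (1.0 + sum(a * np.cos((k + 1) * theta + p)
                             for k, (a, p) in enumerate(zip(amps, phases))))
    return dy * dy + dx * dx <= radius * radius


def _scale_blob_to_range(rng: np.random.Generator, height: int, width: int,
                         min_area: int, max_area: int) -> np.ndarray | None:
    """Draw a blob and rescale its target area until it lands in range."""
    target = rng.uniform(min_area, max_area) if max_area > min_area else float(min_area)
    for _ in range(20):
        blob = _radial_blob(rng, height, width, target)
        if blob is None:
            return None
        area = int(blob.sum())
        if min_area <= area <= max_area:
            # single component and no holes expected from a star-shaped-ish blob,
            # but verify: discretisation of thin lobes can pinch off fragments
            n, _ = _label(blob)
            if n == 1:
                return blob
        # area scales ~ r0^2 ~ target, so correct multiplicatively
        mid = 0.5 * (min_area + max_area)
        target *= mid / max(area, 1)
    return None


def _label(mask: np.ndarray):
    labels, n = ndimage.label(mask, structure=CONNECTIVITY_8)
    return n, labels


def generate_sample(seed: int, height: int, width: int, lesion_count: int = 1,
                    contrast: float = 0.2, noise_sd: float = 0.05,
                    min_area: int = 20, max_area: int = 120) -> LesionSample:
    """Generate one lesion image + mask.

    Parameters
    ----------
    seed : int
        Seeds every random draw; same arguments => bit-identical sample.
    height, width : int
        Image shape in pixels; both must be >= 16.
    lesion_count : int
        Exact number of 8-connected foreground components to emit.
    contrast : float
        Mean intensity offset of lesion over background, in intensity units
        (image range is [0, 1]), applied before noise.
    noise_sd : float
        Standard deviation of additive Gaussian noise.
    min_area, max_area : int
        Inclusive per-component area bounds in pixels.
    """
    if height < 16 or width < 16:
        raise ValueError(f"image must be at least 16x16, got {height}x{width}")
    if lesion_count < 0:
        raise ValueError("lesion_count must be >= 0")
    if not (0 <= min_area <= max_area < height * width):
        raise ValueError("need 0 <= min_area <= max_area < height*width")
    if contrast < 0 or noise_sd < 0:
        raise ValueError("contrast and noise_sd must be >= 0")
    if lesion_count * min_area > 0.5 * height * width:
        raise CapacityError(
            f"{lesion_count} lesions of >= {min_area} px exceed half the "
            f"{height}x{width} image")

    rng = np.random.default_rng(seed)
    mask = np.zeros((height, width), dtype=bool)

    placed = 0
    tries = 0
    while placed < lesion_count:
        if tries >= _MAX_PLACEMENT_TRIES:
            raise CapacityError(
                f"could not place {lesion_count} disjoint lesions of area "
                f"[{min_area}, {max_area}] in a {height}x{width} image")
        tries += 1
        blob = _scale_blob_to_range(rng, height, width, min_area, max_area)
        if blob is None:
            continue
        # keep components disjoint even under 8-connectivity: require a
        # one-pixel dilated halo free of existing foreground
        halo = ndimage.binary_dilation(blob, structure=CONNECTIVITY_8)
        if (halo & mask).any():
            continue
        mask |= blob
        placed += 1

    n_components, _ = _label(mask)
    assert n_components == lesion_count

    # intensity model: constant + smooth bias field + lesion offset + noise
    bias = _smooth_bias(rng, height, width)
    image = BACKGROUND_MEAN + bias + contrast * mask
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, size=(height, width))
    image = np.clip(image, 0.0, 1.0)

    return LesionSample(image=image, mask=mask.astype(np.uint8), seed=int(seed),
                        lesion_count=int(lesion_count), contrast=float(contrast),
                        noise_sd=float(noise_sd))


def _smooth_bias(rng: np.random.Generator, height: int, width: int) -> np.ndarray:
    """Low-frequency multiplicative-style bias: smoothed coarse noise, zero mean."""
    coarse = rng.normal(size=(4, 4))
    zoom = (height / 4, width / 4)
    field = ndimage.zoom(coarse, zoom, order=3, mode="nearest", grid_mode=True)
    field = field - field.mean()
    peak = np.abs(field).max()
    if peak > 0:
        field *= BIAS_AMPLITUDE / peak
    return field


def generate_dataset(seed: int, n: int, **params) -> tuple[list[LesionSample], pd.DataFrame]:
    """Generate `n` samples with per-sample seeds derived from `seed`.

    Returns the samples and a summary frame (one row per sample: sample id,
    derived seed, lesion count, component areas) that doubles as the dataset
    manifest.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF
    samples, rows = [], []
    for i, s in enumerate(child_seeds):
        try:
            sample = generate_sample(int(s), **params)
        except Exception as exc:
            raise type(exc)(f"sample {i}: {exc}") from exc
        samples.append(sample)
        _, labels = _label(sample.mask.astype(bool))
        areas = np.bincount(labels.ravel())[1:]
        rows.append({
            "sample_id": i,
            "seed": int(s),
            "lesion_count": sample.lesion_count,
            "areas": ";".join(str(int(a)) for a in areas),
        })
    return samples, pd.DataFrame(rows)


def save_dataset(samples: list[LesionSample], manifest: pd.DataFrame,
                 out_dir: str | Path) -> Path:
    """Write image/mask PNG pairs plus the CSV manifest; returns manifest path."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(samples):
        iio.imwrite(out_dir / f"sample_{i:04d}_image.png",
                    np.round(s.image * 65535).astype(np.uint16))
        iio.imwrite(out_dir / f"sample_{i:04d}_mask.png",
                    (s.mask * 255).astype(np.uint8))
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def load_dataset(data_dir: str | Path) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Read image/mask PNG pairs written by :func:`save_dataset`."""
    import imageio.v3 as iio

    data_dir = Path(data_dir)
    manifest = pd.read_csv(data_dir / "manifest.csv")
    images, masks = [], []
    for i in manifest["sample_id"]:
        img = iio.imread(data_dir / f"sample_{i:04d}_image.png")
        msk = iio.imread(data_dir / f"sample_{i:04d}_mask.png")
        images.append(img.astype(np.float64) / 65535.0)
        masks.append((msk > 127).astype(np.uint8))
    return images, masks
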