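"""Synthetic brain-like image generator with ground-truth tumour masks.

Produces two-class (healthy / tumour) grayscale-or-RGB images that mimic the
statistical structure of a screening dataset: a dark background, a bright
elliptical "skull/brain" region, optional additive noise, and — for the
tumour class — a brighter circular blob whose pixel set is recorded as a
ground-truth mask.  Real screening datasets rarely ship segmentation masks;
the synthetic masks make localisation claims absolutely checkable instead of
only relatively comparable.

All randomness flows through :class:`numpy.random.Generator` objects so a
dataset is a pure function of its configuration (seed included).
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "ImageSample",
    "generate_image",
    "generate_dataset",
    "augment",
    "apply_transform",
    "write_dataset",
    "read_dataset",
]


class ConfigurationError(ValueError):
    """Raised when a configuration object violates its invariants."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic tumour-screening dataset.

    Lengths are expressed as fractions of the (square) image side so the same
    geometry scales from desk-size 64 px images to the 150 px study scale.
    """

    image_size: int = 64
    channels: int = 3
    n_images: int = 400
    tumour_fraction: float = 0.55
    skull_axes_range: tuple[float, float] = (0.30, 0.42)
    tumour_radius_range: tuple[float, float] = (0.06, 0.12)
    tumour_intensity_gain: float = 1.8
    noise_sd: float = 0.03
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 1:
            raise ConfigurationError("image_size must be a positive integer")
        if self.channels not in (1, 3):
            raise ConfigurationError("channels must be 1 or 3")
        if self.n_images < 2:
            raise ConfigurationError("n_images must be at least 2")
        if not 0.0 < self.tumour_fraction < 1.0:
            raise ConfigurationError("tumour_fraction must lie in (0, 1)")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError("train_fraction must lie in (0, 1)")
        lo, hi = self.skull_axes_range
        rlo, rhi = self.tumour_radius_range
        if not (0 < lo <= hi):
            raise ConfigurationError("skull_axes_range must be 0 < min <= max")
        if not (0 < rlo <= rhi):
            raise ConfigurationError("tumour_radius_range must be 0 < min <= max")
        if rhi >= lo:
            raise ConfigurationError(
                "tumour_radius_range max must be smaller than skull_axes_range "
                "min so the tumour lies inside the skull"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.tumour_intensity_gain <= 0:
            raise ConfigurationError("tumour_intensity_gain must be positive")


@dataclass
class ImageSample:
    """One labelled image, optionally carrying a ground-truth tumour mask."""

    id: str
    pixels: np.ndarray  # (H, W, channels) floats in [0, 1]
    label: int  # 0 = healthy, 1 = tumour
    tumour_mask: Optional[np.ndarray] = None  # (H, W) bool
    split: str = "train"

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3:
            raise ValueError("pixels must have shape (H, W, channels)")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if self.tumour_mask is not None:
            if self.tumour_mask.shape != self.pixels.shape[:2]:
                raise ValueError("tumour_mask shape must equal image spatial shape")


# intensity levels of the phantom; the blob is brighter than the skull by
# construction (gain > 1), which the localisation tests rely on
_BACKGROUND = 0.08
_SKULL = 0.45


def generate_image(
    cfg: SyntheticConfig, label: int, rng: np.random.Generator
) -> ImageSample:
    """Draw one synthetic image of the requested class.

    The skull is a filled ellipse centred near the image centre with
    semi-axes drawn from ``skull_axes_range``; a tumour (label 1) is a filled
    disc placed uniformly at random fully inside the skull, with its
    intensity multiplied by ``tumour_intensity_gain``.  Additive Gaussian
    noise of sd ``noise_sd`` is applied last and the result clipped to [0,1].
    """
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    s = cfg.image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)

    # skull ellipse: centre jittered by up to 3% of the side
    cx = (s - 1) / 2 + rng.uniform(-0.03, 0.03) * s
    cy = (s - 1) / 2 + rng.uniform(-0.03, 0.03) * s
    a = rng.uniform(*cfg.skull_axes_range) * s  # semi-axis, x direction
    b = rng.uniform(*cfg.skull_axes_range) * s  # semi-axis, y direction
    skull = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0

    img = np.full((s, s), _BACKGROUND, dtype=np.float64)
    img[skull] = _SKULL

    mask: Optional[np.ndarray] = None
    if label == 1:
        r = rng.uniform(*cfg.tumour_radius_range) * s
        # uniform position such that the disc lies fully inside the ellipse:
        # rejection-sample the centre from the ellipse shrunk by r
        sa, sb = a - r, b - r
        for _ in range(1000):
            px = cx + rng.uniform(-sa, sa)
            py = cy + rng.uniform(-sb, sb)
            if ((px - cx) / sa) ** 2 + ((py - cy) / sb) ** 2 <= 1.0:
                break
        else:  # pragma: no cover - cannot happen for valid configs
            px, py = cx, cy
        mask = (xx - px) ** 2 + (yy - py) ** 2 <= r**2
        img[mask] = np.clip(_SKULL * cfg.tumour_intensity_gain, 0.0, 1.0)

    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    pixels = np.repeat(img[:, :, None], cfg.channels, axis=2)
    return ImageSample(id="", pixels=pixels, label=label, tumour_mask=mask)


def generate_dataset(cfg: SyntheticConfig) -> list[ImageSample]:
    """Generate the full labelled dataset with a stratified train/test split.

    Exactly ``round(n_images * tumour_fraction)`` samples carry label 1, and
    within each class ``round(n_class * train_fraction)`` samples go to the
    train split, so the class prevalence is preserved in both splits.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_images
    n_pos = int(round(n * cfg.tumour_fraction))
    n_neg = n - n_pos
    for cls, count in ((1, n_pos), (0, n_neg)):
        n_train = int(round(count * cfg.train_fraction))
        if count < 2 or n_train < 1 or count - n_train < 1:
            raise ConfigurationError(
                f"class {cls} has {count} samples; too few for a stratified "
                f"{cfg.train_fraction:.0%} train split"
            )

    labels = np.array([1] * n_pos + [0] * n_neg)
    rng.shuffle(labels)

    samples: list[ImageSample] = []
    for i, label in enumerate(labels):
        sample = generate_image(cfg, int(label), rng)
        sample.id = f"img{i:04d}"
        samples.append(sample)

    # stratified split: shuffle indices within each class, first chunk trains
    for cls in (0, 1):
        idx = [i for i, sm in enumerate(samples) if sm.label == cls]
        order = rng.permutation(len(idx))
        n_train = int(round(len(idx) * cfg.train_fraction))
        for rank, j in enumerate(order):
            samples[idx[j]].split = "train" if rank < n_train else "test"
    return samples


def apply_transform(
    sample: ImageSample,
    angle_deg: float = 0.0,
    zoom: float = 1.0,
    sharpness: float = 1.0,
) -> ImageSample:
    """Apply a deterministic rotate/zoom/sharpen transform to a sample.

    The tumour mask (if present) undergoes the identical geometric transform
    (nearest-neighbour so it stays binary).  Rotations by exact multiples of
    90 degrees are performed losslessly.  Identity parameters return the
    pixels bit-unchanged.
    """
    pixels = sample.pixels.astype(np.float64, copy=True)
    mask = None if sample.tumour_mask is None else sample.tumour_mask.copy()

    if angle_deg % 360 != 0:
        if angle_deg % 90 == 0:
            k = int(angle_deg // 90) % 4
            pixels = np.rot90(pixels, k=k, axes=(0, 1)).copy()
            if mask is not None:
                mask = np.rot90(mask, k=k).copy()
        else:
            pixels = ndi.rotate(
                pixels, angle_deg, axes=(1, 0), reshape=False, order=1,
                mode="constant", cval=_BACKGROUND,
            )
            if mask is not None:
                mask = ndi.rotate(
                    mask.astype(np.float64), angle_deg, axes=(1, 0),
                    reshape=False, order=0, mode="constant", cval=0.0,
                ) > 0.5

    if zoom != 1.0:
        h, w = pixels.shape[:2]
        centre = np.array([(h - 1) / 2, (w - 1) / 2])
        matrix = np.diag([1.0 / zoom, 1.0 / zoom, 1.0])
        offset = np.append(centre - centre / zoom, 0.0)
        pixels = ndi.affine_transform(
            pixels, matrix, offset=offset, order=1,
            mode="constant", cval=_BACKGROUND,
        )
        if mask is not None:
            mask = ndi.affine_transform(
                mask.astype(np.float64), matrix[:2, :2], offset=offset[:2],
                order=0, mode="constant", cval=0.0,
            ) > 0.5

    if sharpness != 1.0:
        # unsharp mask: factor 1 is identity, >1 sharpens, <1 blurs
        blurred = ndi.gaussian_filter(pixels, sigma=(1.0, 1.0, 0.0))
        pixels = blurred + sharpness * (pixels - blurred)

    pixels = np.clip(pixels, 0.0, 1.0)
    return ImageSample(
        id=sample.id, pixels=pixels, label=sample.label,
        tumour_mask=mask, split=sample.split,
    )


def augment(
    sample: ImageSample,
    rng: np.random.Generator,
    rotation_deg_max: float = 15.0,
    zoom_range: tuple[float, float] = (0.9, 1.1),
    sharpness_range: tuple[float, float] = (0.8, 1.2),
) -> ImageSample:
    """Randomly rotate, zoom and sharpen a sample, preserving label and split.

    Draws the rotation angle uniformly from ``[-rotation_deg_max,
    +rotation_deg_max]`` and the zoom and sharpness factors uniformly from
    their ranges.
    """
    if rotation_deg_max < 0:
        raise ConfigurationError("rotation_deg_max must be non-negative")
    for name, rng_pair in (("zoom_range", zoom_range), ("sharpness_range", sharpness_range)):
        lo, hi = rng_pair
        if not (lo <= hi and lo > 0):
            raise ConfigurationError(f"{name} must satisfy 0 < min <= max")
    angle = rng.uniform(-rotation_deg_max, rotation_deg_max) if rotation_deg_max else 0.0
    zoom = rng.uniform(*zoom_range) if zoom_range != (1.0, 1.0) else 1.0
    sharp = rng.uniform(*sharpness_range) if sharpness_range != (1.0, 1.0) else 1.0
    return apply_transform(sample, angle_deg=angle, zoom=zoom, sharpness=sharp)


# ---------------------------------------------------------------------------
# disk round-trip: PNG images + PNG masks + CSV manifest

_MANIFEST = "manifest.csv"


def write_dataset(samples: Sequence[ImageSample], directory: str) -> None:
    """Write samples as 8-bit PNGs plus a CSV manifest."""
    import imageio.v3 as iio

    os.makedirs(directory, exist_ok=True)
    rows = []
    for sample in samples:
        fname = f"{sample.id}.png"
        arr = np.clip(np.round(sample.pixels * 255), 0, 255).astype(np.uint8)
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        iio.imwrite(os.path.join(directory, fname), arr)
        mask_fname = ""
        if sample.tumour_mask is not None:
            mask_fname = f"{sample.id}_mask.png"
            iio.imwrite(
                os.path.join(directory, mask_fname),
                (sample.tumour_mask.astype(np.uint8) * 255),
            )
        rows.append((sample.id, fname, sample.label, sample.split, mask_fname))
    with open(os.path.join(directory, _MANIFEST), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "filename", "label", "split", "mask_filename"])
        writer.writerows(rows)
    logger.info("wrote %d samples to %s", len(samples), directory)


def read_dataset(directory: str) -> list[ImageSample]:
    """Read a dataset previously written by :func:`write_dataset`.

    Labels, splits and masks round-trip exactly; pixels round-trip up to
    8-bit quantisation (max error 1/255).
    """
    import imageio.v3 as iio

    manifest = os.path.join(directory, _MANIFEST)
    if not os.path.exists(manifest):
        raise FileNotFoundError(f"manifest not found: {manifest}")
    samples = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            path = os.path.join(directory, row["filename"])
            if not os.path.exists(path):
                raise FileNotFoundError(f"referenced image not found: {path}")
            arr = iio.imread(path)
            if arr.ndim == 2:
                arr = arr[:, :, None]
            pixels = arr.astype(np.float64) / 255.0
            mask = None
            if row["mask_filename"]:
                mpath = os.path.join(directory, row["mask_filename"])
                if not os.path.exists(mpath):
                    raise FileNotFoundError(f"referenced mask not found: {mpath}")
                mask = iio.imread(mpath) > 127
            samples.append(
                ImageSample(
                    id=row["id"], pixels=pixels, label=int(row["label"]),
                    tumour_mask=mask, split=row["split"],
                )
            )
    return samples
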