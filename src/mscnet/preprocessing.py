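"""Input preparation: green-channel + CLAHE, patch sampling, augmentation,
ordered tiling with exact inverse stitching, and label-safe resizing."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure, transform

from .io_datasets import FundusSample

#: CLAHE defaults (clip limit on the common 0-40 scale; 8x8 tile grid).
DEFAULT_CLAHE_CLIP = 2.0
DEFAULT_CLAHE_GRID = 8
DEFAULT_NOISE_SD_MAX = 0.02


def vessel_input_channels(image: np.ndarray, clahe_clip: float = DEFAULT_CLAHE_CLIP,
                          clahe_grid: int = DEFAULT_CLAHE_GRID) -> np.ndarray:
    """CLAHE-equalized green channel in [0, 1], shape (1, H, W).

    This feeds the vessel-segmentation branch only; the A/V branch consumes
    the raw RGB image.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 image, got shape {image.shape}")
    green = image[:, :, 1].astype(np.float64)
    if np.issubdtype(image.dtype, np.integer):
        green = green / 255.0  # float images are assumed to be in [0, 1]
    if green.max() - green.min() < 1e-12:
        # zero dynamic range: histogram equalization is undefined, pass through
        return green[None].astype(np.float32)
    h, w = green.shape
    kernel = (max(h // clahe_grid, 1), max(w // clahe_grid, 1))
    out = exposure.equalize_adapthist(green, kernel_size=kernel,
                                      clip_limit=clahe_clip / 100.0)
    return out[None].astype(np.float32)


def random_patches(sample: FundusSample, n: int, patch: int = 256,
                   rng_seed: int = 0) -> list[tuple]:
    """``n`` aligned random crops of (image, vessel_mask, av_labels)."""
    h, w = sample.shape
    if h < patch or w < patch:
        raise ValueError(
            f"image {h}x{w} smaller than patch {patch}; resize the sample first"
        )
    rng = np.random.default_rng(rng_seed)
    crops = []
    for _ in range(n):
        r = int(rng.integers(0, h - patch + 1))
        c = int(rng.integers(0, w - patch + 1))
        sl = (slice(r, r + patch), slice(c, c + patch))
        crops.append((
            sample.image[sl],
            None if sample.vessel_mask is None else sample.vessel_mask[sl],
            None if sample.av_labels is None else sample.av_labels[sl],
        ))
    return crops


def augment(crop: tuple, rng_seed: int = 0,
            noise_sd_max: float = DEFAULT_NOISE_SD_MAX,
            rotation_mode: str = "right-angle") -> tuple:
    """Joint rotation of image and labels + image-only Gaussian noise.

    ``rotation_mode="right-angle"`` (default) draws from {0, 90, 180, 270}
    degrees so categorical labels are never interpolated;
    ``rotation_mode="arbitrary"`` draws any angle, rotating the image
    bilinearly and the labels with nearest-neighbor interpolation.  The image
    is returned as float in [0, 1]; labels keep their dtype and never
    receive noise.
    """
    image, mask, av = crop
    if image.shape[0] != image.shape[1]:
        raise ValueError(f"augment expects square crops, got {image.shape[:2]}")
    rng = np.random.default_rng(rng_seed)
    if rotation_mode == "right-angle":
        k = int(rng.integers(0, 4))
        rot_img = lambda a: np.rot90(a, k, axes=(0, 1))
        rot_lbl = rot_img
    elif rotation_mode == "arbitrary":
        angle = float(rng.uniform(0.0, 360.0))
        rot_img = lambda a: transform.rotate(a, angle, order=1, mode="edge",
                                             preserve_range=True)
        rot_lbl = lambda a: transform.rotate(a.astype(float), angle, order=0,
                                             mode="edge",
                                             preserve_range=True).astype(a.dtype)
    else:
        raise ValueError(f"unknown rotation_mode {rotation_mode!r}")
    sd = float(rng.uniform(0.0, noise_sd_max))

    img = np.asarray(image, dtype=np.float64)
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        img = img / 255.0
    img = rot_img(img)
    if sd > 0:
        img = img + rng.normal(0.0, sd, img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)

    rot = lambda a: None if a is None else np.ascontiguousarray(rot_lbl(a))
    return img, rot(mask), rot(av)


@dataclass(frozen=True)
class PatchGrid:
    """Ordered tiling of a (padded) image; non-overlapping by default."""

    image_size: tuple[int, int]
    patch_size: int
    origins: tuple[tuple[int, int], ...]
    pad: tuple[int, int]  # (bottom, right) zero padding before tiling
    stride: int | None = None  # None or == patch_size: no overlap

    @property
    def effective_stride(self) -> int:
        return self.patch_size if self.stride is None else self.stride


def _padded_extent(n: int, patch: int, stride: int) -> int:
    if n <= patch:
        return patch
    return patch + -(-(n - patch) // stride) * stride


def tile(image_like: np.ndarray, patch: int,
         stride: int | None = None) -> tuple[PatchGrid, list[np.ndarray]]:
    """Split an array (spatial axes first) into an ordered raster of patches.

    The array is zero-padded on the bottom/right so patches cover it exactly;
    :func:`stitch` inverts the operation exactly.  With ``stride < patch``
    patches overlap and :func:`stitch` averages the overlapping outputs.
    """
    arr = np.asarray(image_like)
    s = patch if stride is None else stride
    if not 1 <= s <= patch:
        raise ValueError(f"stride {s} must lie in [1, patch={patch}]")
    h, w = arr.shape[:2]
    pad_b = _padded_extent(h, patch, s) - h
    pad_r = _padded_extent(w, patch, s) - w
    width = [(0, pad_b), (0, pad_r)] + [(0, 0)] * (arr.ndim - 2)
    padded = np.pad(arr, width)
    origins = []
    patches = []
    for r in range(0, h + pad_b - patch + 1, s):
        for c in range(0, w + pad_r - patch + 1, s):
            origins.append((r, c))
            patches.append(padded[r:r + patch, c:c + patch])
    grid = PatchGrid(image_size=(h, w), patch_size=patch,
                     origins=tuple(origins), pad=(pad_b, pad_r), stride=stride)
    return grid, patches


def stitch(grid: PatchGrid, patch_outputs: list[np.ndarray]) -> np.ndarray:
    """Reassemble patch outputs onto the original (unpadded) extent.

    Overlapping grids (stride < patch) average contributions per pixel.
    """
    if len(patch_outputs) != len(grid.origins):
        raise ValueError(
            f"expected {len(grid.origins)} patches, got {len(patch_outputs)}"
        )
    p = grid.patch_size
    first = np.asarray(patch_outputs[0])
    h, w = grid.image_size
    overlapping = grid.effective_stride < p
    dtype = np.result_type(first.dtype, np.float64) if overlapping else first.dtype
    full = np.zeros((h + grid.pad[0], w + grid.pad[1]) + first.shape[2:],
                    dtype=dtype)
    counts = np.zeros(full.shape[:2], dtype=np.int64)
    for (r, c), out in zip(grid.origins, patch_outputs):
        out = np.asarray(out)
        if out.shape[:2] != (p, p):
            raise ValueError(f"patch output {out.shape[:2]} != {(p, p)}")
        if overlapping:
            full[r:r + p, c:c + p] += out
            counts[r:r + p, c:c + p] += 1
        else:
            full[r:r + p, c:c + p] = out
    if overlapping:
        full /= counts.reshape(counts.shape + (1,) * (full.ndim - 2))
    return full[:h, :w]


def resize_sample(sample: FundusSample, target: tuple[int, int]) -> FundusSample:
    """Bilinear-resize the image; nearest-neighbor for categorical labels."""
    th, tw = target
    if th <= 0 or tw <= 0:
        raise ValueError(f"target size must be positive, got {target}")
    if (th, tw) == sample.shape:
        return sample
    img = transform.resize(sample.image, (th, tw), order=1, mode="edge",
                           anti_aliasing=False, preserve_range=True)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    def nn(a):
        if a is None:
            return None
        return transform.resize(a, (th, tw), order=0, mode="edge",
                                anti_aliasing=False,
                                preserve_range=True).astype(a.dtype)

    return FundusSample(image=img, vessel_mask=nn(sample.vessel_mask),
                        av_labels=nn(sample.av_labels),
                        sample_id=sample.sample_id)


__all__ = [
    "DEFAULT_CLAHE_CLIP", "DEFAULT_CLAHE_GRID", "DEFAULT_NOISE_SD_MAX",
    "PatchGrid", "vessel_input_channels", "random_patches", "augment",
    "tile", "stitch", "resize_sample",
]
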