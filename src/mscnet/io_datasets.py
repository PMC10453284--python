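"""Reading and writing fundus images, vessel masks and artery/vein label maps.

Canonical on-disk label colors (8-bit RGB):

* artery    = (255, 0, 0)
* vein      = (0, 0, 255)
* uncertain = (0, 255, 0)
* background = (0, 0, 0)

with a per-channel tolerance of +/-10 at load time to absorb compression
artifacts.  In memory, label maps are ``uint8`` arrays over :class:`AVLabel`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image


class AVLabel(enum.IntEnum):
    BACKGROUND = 0
    ARTERY = 1
    VEIN = 2
    UNCERTAIN = 3


#: channel order of class-probability maps / logits
CLASS_CHANNELS = (AVLabel.BACKGROUND, AVLabel.ARTERY, AVLabel.VEIN)

LABEL_COLORS: dict[AVLabel, tuple[int, int, int]] = {
    AVLabel.BACKGROUND: (0, 0, 0),
    AVLabel.ARTERY: (255, 0, 0),
    AVLabel.VEIN: (0, 0, 255),
    AVLabel.UNCERTAIN: (0, 255, 0),
}

COLOR_TOLERANCE = 10


class DatasetError(ValueError):
    """Structured error for malformed sample files."""


@dataclass
class FundusSample:
    """An RGB fundus image with optional pixel-aligned annotations."""

    image: np.ndarray                      # (H, W, 3) uint8
    vessel_mask: np.ndarray | None = None  # (H, W) uint8 in {0, 1}
    av_labels: np.ndarray | None = None    # (H, W) uint8 over AVLabel
    sample_id: str = ""

    def __post_init__(self):
        h, w = self.image.shape[:2]
        for name, arr in (("vessel_mask", self.vessel_mask),
                          ("av_labels", self.av_labels)):
            if arr is not None and arr.shape != (h, w):
                raise DatasetError(
                    f"{name} shape {arr.shape} does not match image shape {(h, w)}"
                )
        # every labelled vessel pixel must be in the mask
        if self.vessel_mask is not None and self.av_labels is not None:
            self.vessel_mask = (
                self.vessel_mask.astype(bool)
                | (self.av_labels != AVLabel.BACKGROUND)
            ).astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]


def _load_array(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB") if im.mode not in ("L", "RGB") else im)


def decode_av_colors(rgb: np.ndarray) -> np.ndarray:
    """Decode a color-coded A/V label image into an AVLabel array.

    Raises :class:`DatasetError` if any pixel is outside the per-channel
    tolerance of every canonical color (e.g. white, which marks vessels only
    in *binary* label files and is invalid here).
    """
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise DatasetError(f"A/V label image must be RGB, got shape {rgb.shape}")
    rgb = rgb.astype(np.int16)
    out = np.full(rgb.shape[:2], 255, dtype=np.uint8)
    matched = np.zeros(rgb.shape[:2], dtype=bool)
    for label, color in LABEL_COLORS.items():
        hit = (np.abs(rgb - np.array(color)) <= COLOR_TOLERANCE).all(axis=2)
        out[hit & ~matched] = int(label)
        matched |= hit
    if not matched.all():
        bad = rgb[~matched]
        counts: dict[tuple[int, int, int], int] = {}
        for px in map(tuple, bad[:10000]):
            counts[px] = counts.get(px, 0) + 1
        worst = sorted(counts.items(), key=lambda kv: -kv[1])[:5]
        total = int((~matched).sum())
        raise DatasetError(
            f"{total} pixels have unrecognized label colors "
            f"(tolerance +/-{COLOR_TOLERANCE}); most frequent: "
            + ", ".join(f"RGB{c}x{n}" for c, n in worst)
        )
    return out


def encode_av_colors(av: np.ndarray) -> np.ndarray:
    """Inverse of :func:`decode_av_colors` (exact canonical colors)."""
    rgb = np.zeros((*av.shape, 3), dtype=np.uint8)
    for label, color in LABEL_COLORS.items():
        rgb[av == int(label)] = color
    return rgb


def read_sample(image_path, mask_path=None, av_path=None,
                sample_id: str | None = None) -> FundusSample:
    """Load an image plus optional vessel mask and A/V label map.

    The vessel mask decodes any nonzero intensity as vessel; the A/V map must
    use the canonical four-color code.  All files must agree on dimensions.
    """
    image_path = Path(image_path)
    image = _load_array(image_path)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    h, w = image.shape[:2]

    mask = None
    if mask_path is not None:
        raw = _load_array(Path(mask_path))
        if raw.ndim == 3:
            raw = raw.max(axis=2)
        if raw.shape != (h, w):
            raise DatasetError(
                f"mask shape {raw.shape} does not match image shape {(h, w)}"
            )
        mask = (raw > 0).astype(np.uint8)

    av = None
    if av_path is not None:
        raw = _load_array(Path(av_path))
        if raw.ndim == 2:
            raw = np.stack([raw] * 3, axis=-1)
        if raw.shape[:2] != (h, w):
            raise DatasetError(
                f"A/V label shape {raw.shape[:2]} does not match image shape {(h, w)}"
            )
        av = decode_av_colors(raw)

    return FundusSample(
        image=image, vessel_mask=mask, av_labels=av,
        sample_id=sample_id if sample_id is not None else image_path.stem,
    )


def write_image(array: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        Image.fromarray(array).save(path)
    except OSError as exc:
        raise DatasetError(f"cannot write {path}: {exc}") from exc
    return path


def write_prediction(sample_id: str, vessel_prob: np.ndarray,
                     av_classes: np.ndarray, out_dir,
                     av_argmax: np.ndarray | None = None) -> dict[str, Path]:
    """Write prediction artifacts for one sample as PNGs.

    * ``<id>_vessel_prob.png`` — 8-bit grayscale, round(p * 255)
    * ``<id>_av.png``          — color-coded classes (canonical colors)
    * ``<id>_vessel_mask.png`` — binary mask, threshold 0.5
    * ``<id>_av_argmax.png``   — optional artery-vs-vein argmax at *every*
      pixel (ignoring the background channel), used for A/V evaluation.
    """
    vessel_prob = np.asarray(vessel_prob)
    if vessel_prob.ndim == 3:
        vessel_prob = vessel_prob[0]
    if vessel_prob.shape != av_classes.shape:
        raise DatasetError(
            f"vessel_prob shape {vessel_prob.shape} does not match "
            f"av_classes shape {av_classes.shape}"
        )
    out_dir = Path(out_dir)
    paths = {
        "vessel_prob": write_image(
            np.round(vessel_prob * 255).astype(np.uint8),
            out_dir / f"{sample_id}_vessel_prob.png"),
        "av": write_image(
            encode_av_colors(av_classes), out_dir / f"{sample_id}_av.png"),
        "vessel_mask": write_image(
            ((vessel_prob >= 0.5) * 255).astype(np.uint8),
            out_dir / f"{sample_id}_vessel_mask.png"),
    }
    if av_argmax is not None:
        paths["av_argmax"] = write_image(
            encode_av_colors(av_argmax), out_dir / f"{sample_id}_av_argmax.png")
    return paths


__all__ = [
    "AVLabel", "CLASS_CHANNELS", "LABEL_COLORS", "COLOR_TOLERANCE",
    "DatasetError", "FundusSample", "decode_av_colors", "encode_av_colors",
    "read_sample", "write_image", "write_prediction",
]
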