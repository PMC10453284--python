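"""Seeded synthetic fundus-like samples for end-to-end testing.

Each sample is a textured disc (emulating the circular field of view) with
binary-branching vascular trees drawn as hard, tapering strokes.  Half of the
trees are arteries (bright / orange) and half veins (dark / red-purple);
pixels where an artery and a vein overlap are labelled UNCERTAIN, mirroring
crossing ambiguity in real annotations.  Ground truth is exact by
construction: the vessel mask is precisely the union of the drawn strokes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .io_datasets import AVLabel, FundusSample, encode_av_colors, write_image


@dataclass
class SynthConfig:
    height: int = 256
    width: int = 256
    n_trees: int = 4
    branch_depth: int = 4
    root_caliber: int = 5
    taper: float = 0.75
    # both classes sit below the background level in the green channel (as in
    # real fundus photographs); arteries are brighter and redder overall
    artery_color_mean: tuple[int, int, int] = (200, 80, 70)
    vein_color_mean: tuple[int, int, int] = (105, 45, 60)
    color_noise_sd: float = 8.0
    background_texture_sd: float = 6.0
    background_level: int = 120
    seed: int = 0

    def validate(self) -> None:
        if self.height < 64 or self.width < 64:
            raise ValueError(f"image size must be >= 64, got {self.height}x{self.width}")
        if self.n_trees < 1:
            raise ValueError(f"n_trees must be >= 1, got {self.n_trees}")
        if self.root_caliber < 1:
            raise ValueError(f"root_caliber must be >= 1, got {self.root_caliber}")
        if not 0.0 < self.taper < 1.0:
            raise ValueError(f"taper must lie in (0, 1), got {self.taper}")


def _disk_offsets(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    keep = dy * dy + dx * dx <= radius * radius
    return np.stack([dy[keep], dx[keep]], axis=1)


def _stamp_line(mask: np.ndarray, p0: np.ndarray, p1: np.ndarray,
                thickness: float) -> None:
    """Draw a hard stroke from p0 to p1 with the given caliber (pixels)."""
    h, w = mask.shape
    length = max(int(np.ceil(np.hypot(*(p1 - p0)))) * 2, 2)
    ts = np.linspace(0.0, 1.0, length)
    pts = np.round(p0[None, :] + ts[:, None] * (p1 - p0)[None, :]).astype(int)
    pts = np.unique(pts, axis=0)
    offs = _disk_offsets(max(thickness / 2.0, 0.5))
    all_pts = (pts[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    ok = ((all_pts[:, 0] >= 0) & (all_pts[:, 0] < h)
          & (all_pts[:, 1] >= 0) & (all_pts[:, 1] < w))
    all_pts = all_pts[ok]
    mask[all_pts[:, 0], all_pts[:, 1]] = True


def _grow_tree(cfg: SynthConfig, rng: np.random.Generator,
               root: np.ndarray, direction: np.ndarray,
               waypoint: np.ndarray | None) -> np.ndarray:
    """Binary-branching polyline tree; returns the stroke mask."""
    mask = np.zeros((cfg.height, cfg.width), dtype=bool)
    seg_len = 0.55 * min(cfg.height, cfg.width) / cfg.branch_depth
    # (position, unit direction, level)
    first_dir = direction
    if waypoint is not None:
        v = waypoint - root
        first_dir = v / (np.linalg.norm(v) + 1e-9)
    frontier = [(root.astype(float), first_dir, 0)]
    while frontier:
        pos, d, level = frontier.pop()
        if level >= cfg.branch_depth:
            continue
        caliber = max(cfg.root_caliber * cfg.taper ** level, 1.0)
        wobble = rng.uniform(-0.25, 0.25)
        c, s = np.cos(wobble), np.sin(wobble)
        d = np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])
        end = pos + d * seg_len * rng.uniform(0.8, 1.2)
        _stamp_line(mask, pos, end, caliber)
        if level + 1 < cfg.branch_depth:
            split = rng.uniform(0.35, 0.65)
            for sign in (-1.0, 1.0):
                ang = sign * split
                c, s = np.cos(ang), np.sin(ang)
                nd = np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])
                frontier.append((end, nd, level + 1))
    return mask


def generate_sample(cfg: SynthConfig) -> FundusSample:
    """Generate one synthetic sample; bit-identical for identical configs."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.height, cfg.width
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    fov_radius = 0.5 * min(h, w) - 2

    artery_mask = np.zeros((h, w), dtype=bool)
    vein_mask = np.zeros((h, w), dtype=bool)

    # one shared waypoint forces an artery-vein crossing for trees 0 and 1
    waypoint = np.array([cy, cx]) + rng.uniform(-0.1, 0.1, 2) * min(h, w)
    for t in range(cfg.n_trees):
        theta = 2 * np.pi * (t + rng.uniform(-0.2, 0.2)) / cfg.n_trees
        root = np.array([cy + 0.9 * fov_radius * np.sin(theta),
                         cx + 0.9 * fov_radius * np.cos(theta)])
        inward = np.array([cy, cx]) - root
        inward /= np.linalg.norm(inward) + 1e-9
        wp = waypoint if (t < 2 and cfg.n_trees >= 2) else None
        tree = _grow_tree(cfg, rng, root, inward, wp)
        if t % 2 == 0:
            artery_mask |= tree
        else:
            vein_mask |= tree

    # clip strokes to the field of view
    yy, xx = np.mgrid[0:h, 0:w]
    fov = (yy - cy) ** 2 + (xx - cx) ** 2 <= fov_radius ** 2
    artery_mask &= fov
    vein_mask &= fov

    vessel_mask = (artery_mask | vein_mask).astype(np.uint8)
    av = np.zeros((h, w), dtype=np.uint8)
    av[artery_mask] = AVLabel.ARTERY
    av[vein_mask] = AVLabel.VEIN
    av[artery_mask & vein_mask] = AVLabel.UNCERTAIN

    image = np.full((h, w, 3), float(cfg.background_level))
    image += rng.normal(0.0, cfg.background_texture_sd, image.shape)
    for m, color in ((vein_mask, cfg.vein_color_mean),
                     (artery_mask & ~vein_mask, cfg.artery_color_mean)):
        n = int(m.sum())
        if n:
            image[m] = np.array(color) + rng.normal(0.0, cfg.color_noise_sd, (n, 3))
    image[~fov] = 0.0
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)

    return FundusSample(image=image, vessel_mask=vessel_mask, av_labels=av,
                        sample_id=f"synth_{cfg.seed:08d}")


def sample_seed(base_seed: int, index: int) -> int:
    """Deterministic per-sample seed derivation."""
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0])


def generate_dataset(cfg: SynthConfig, n_samples: int, out_dir) -> dict:
    """Write ``n_samples`` samples + a JSON manifest; returns the manifest."""
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "samples": {}}
    for i in range(n_samples):
        sub = SynthConfig(**{**asdict(cfg), "seed": sample_seed(cfg.seed, i)})
        sample = generate_sample(sub)
        sid = f"sample_{i:03d}"
        paths = {
            "image": str(write_image(sample.image, out_dir / f"{sid}.png")),
            "mask": str(write_image(sample.vessel_mask * 255,
                                    out_dir / f"{sid}_mask.png")),
            "av": str(write_image(encode_av_colors(sample.av_labels),
                                  out_dir / f"{sid}_av.png")),
        }
        manifest["samples"][sid] = paths
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


__all__ = ["SynthConfig", "generate_sample", "generate_dataset", "sample_seed"]
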