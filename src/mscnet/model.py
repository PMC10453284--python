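"""The full three-stage network: vessel extraction, A/V extraction, fusion."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._nn import Module, Tensor, cat, no_grad
from .mae import MaeNet
from .mfi import FuseHead, vessel_enhance_t
from .mve import MveConfig, MveNet
from .preprocessing import vessel_input_channels


@dataclass
class ModelConfig:
    base_width: int = 64
    depth: int = 4
    n_subsets: int = 4
    cot_groups: int = 4
    key_kernel: int = 3
    attn_kernel: int = 3
    fuse_hidden: int = 16
    fuse_mode: str = "concat"    # concat | gate
    mve_style: str = "res2net"   # res2net | plain
    mae_style: str = "cot"       # cot | plain
    mae_decoder_attention: bool = False
    use_mfi: bool = True
    seed: int = 0


class MscNet(Module):
    """Chained MVE -> MAE -> (optional) MFI network."""

    def __init__(self, cfg: ModelConfig | None = None):
        super().__init__()
        cfg = cfg or ModelConfig()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.mve = MveNet(
            MveConfig(base_width=cfg.base_width, depth=cfg.depth,
                      n_subsets=cfg.n_subsets),
            plain=(cfg.mve_style == "plain"), rng=rng)
        self.mae = MaeNet(base_width=cfg.base_width, depth=cfg.depth,
                          cot_groups=cfg.cot_groups, key_kernel=cfg.key_kernel,
                          attn_kernel=cfg.attn_kernel,
                          plain=(cfg.mae_style == "plain"),
                          decoder_attention=cfg.mae_decoder_attention, rng=rng)
        self.fuse_head = FuseHead(feat_ch=cfg.base_width,
                                  hidden=cfg.fuse_hidden, mode=cfg.fuse_mode,
                                  rng=rng)

    def forward(self, rgb: Tensor, vessel_in: Tensor
                ) -> tuple[Tensor, Tensor, Tensor]:
        """(N,3,H,W) RGB in [0,1] + (N,1,H,W) vessel input.

        Returns (vessel probability, final A/V logits, MAE A/V logits).
        """
        vessel_prob = self.mve(vessel_in)
        mae_logits, mae_feats = self.mae(cat([rgb, vessel_prob], axis=1))
        if not self.cfg.use_mfi:
            return vessel_prob, mae_logits, mae_logits
        enhanced = vessel_enhance_t(vessel_prob)
        final = self.fuse_head(mae_logits, mae_feats, enhanced)
        return vessel_prob, final, mae_logits


def prepare_inputs(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """uint8 HxWx3 image -> ((3,H,W) RGB in [0,1], (1,H,W) vessel input)."""
    rgb = np.asarray(image, dtype=np.float32)
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        rgb = rgb / 255.0
    rgb = rgb.transpose(2, 0, 1)
    vessel_in = vessel_input_channels(np.asarray(image))
    return rgb, vessel_in


def msc_forward(image: np.ndarray, model: MscNet
                ) -> tuple[np.ndarray, np.ndarray]:
    """Run one uint8 HxWx3 image; returns ((1,H,W) vessel prob, (3,H,W) logits)."""
    rgb, vessel_in = prepare_inputs(image)
    model.eval()
    with no_grad():
        vp, logits, _ = model(Tensor(rgb[None]), Tensor(vessel_in[None]))
    return vp.data[0], logits.data[0]


def save_checkpoint(model: MscNet, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    np.savez(path, __config__=json.dumps(asdict(model.cfg)), **state)
    return path


def load_checkpoint(path) -> MscNet:
    with np.load(Path(path), allow_pickle=False) as data:
        cfg = ModelConfig(**json.loads(str(data["__config__"])))
        state = {k: data[k] for k in data.files if k != "__config__"}
    model = MscNet(cfg)
    model.load_state_dict(state)
    return model


__all__ = ["ModelConfig", "MscNet", "prepare_inputs", "msc_forward",
           "save_checkpoint", "load_checkpoint"]
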