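"""Full segmentation network: encoder + LCAM decoder, plus construction
and profiling helpers shared by the pipeline and the efficiency report."""

from __future__ import annotations

import numpy as np

from . import nn
from .backbone import Encoder, VariantConfig, get_variant
from .lcam_decoder import Decoder
from .nn import Tensor


class LCMambaNet(nn.Module):
    """2-D liver-tumor segmentation network on selective state-space blocks."""

    def __init__(self, variant: str | VariantConfig = "T", gamma: float = 0.5,
                 seed: int = 0, lcam_enabled: bool = True):
        super().__init__()
        cfg = get_variant(variant) if isinstance(variant, str) else variant
        self.cfg = cfg
        self.encoder = Encoder(cfg, seed=seed)
        self.decoder = Decoder(cfg.channels, cfg.decoder_dim, gamma=gamma,
                               seed=seed, use_attention=lcam_enabled)

    def __call__(self, x: Tensor):
        """Returns (full-resolution probability map, prediction pyramid)."""
        features = self.encoder(x)
        return self.decoder(features, (x.shape[2], x.shape[3]))

    def forward_numpy(self, images: np.ndarray) -> np.ndarray:
        """Convenience inference entry point: (B, 3, H, W) -> (B, H, W) probs."""
        prob, _ = self(Tensor(images))
        return prob.data[:, 0]

    def profile(self, input_shape):
        """(trainable parameter count, multiply-accumulate count) by shape
        propagation; no numeric forward pass is executed."""
        feature_shapes, macs = self.encoder.profile(input_shape)
        macs += self.decoder.profile(feature_shapes)
        return self.num_params(), macs


def build_model(variant: str = "T", gamma: float = 0.5, seed: int = 0,
                lcam_enabled: bool = True) -> LCMambaNet:
    return LCMambaNet(variant=variant, gamma=gamma, seed=seed,
                      lcam_enabled=lcam_enabled)
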