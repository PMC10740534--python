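"""Volumetric translation networks.

Generator: encoder-decoder with residual blocks — a 7x7x7 stem
(convolution + instance norm + ReLU), two stride-2 downsampling stages, six
residual blocks, two fractional-strided upsampling stages and a 7x7x7 output
convolution with tanh.  All convolutions use replicate padding.  The encoder
half (stem, downsampling stages, first half of the residual blocks) doubles
as the feature extractor for the contrastive loss and the intensity
distribution comparison.

Discriminator: a 3D PatchGAN — three stride-2 4x4x4 stages, one stride-1
4x4x4 stage, and a 1-channel 4x4x4 output head followed by a sigmoid, so the
output is a patch-level score map in (0, 1).  Leaky-ReLU slope 0.2.
"""

from __future__ import annotations

import numpy as np

from ..nn import (
    Conv3d,
    ConvTranspose3d,
    InstanceNorm3d,
    LeakyReLU,
    Linear,
    Module,
    ReLU,
    Sequential,
    Sigmoid,
    Tanh,
    Tensor,
    take_rows,
)

__all__ = ["ResnetGenerator3d", "PatchGANDiscriminator3d", "PatchSampleMLP"]


class ResidualBlock3d(Module):
    def __init__(self, channels: int, rng: np.random.Generator):
        self.body = Sequential(
            Conv3d(channels, channels, 3, rng),
            InstanceNorm3d(),
            ReLU(),
            Conv3d(channels, channels, 3, rng),
            InstanceNorm3d(),
        )

    def forward(self, x: Tensor) -> Tensor:
        return x + self.body(x)


class ResnetGenerator3d(Module):
    """Encoder-decoder generator; input/output (1, D, H, W) volumes."""

    def __init__(
        self,
        rng: np.random.Generator,
        ngf: int = 64,
        n_downsample: int = 2,
        n_residual: int = 6,
        in_channels: int = 1,
    ):
        self.stem = Sequential(
            Conv3d(in_channels, ngf, 7, rng), InstanceNorm3d(), ReLU()
        )
        downs = []
        ch = ngf
        for _ in range(n_downsample):
            downs.append(
                Sequential(Conv3d(ch, ch * 2, 3, rng, stride=2), InstanceNorm3d(), ReLU())
            )
            ch *= 2
        self.downs = downs
        n_enc_res = n_residual // 2
        self.enc_res = [ResidualBlock3d(ch, rng) for _ in range(n_enc_res)]
        self.dec_res = [ResidualBlock3d(ch, rng) for _ in range(n_residual - n_enc_res)]
        ups = []
        for _ in range(n_downsample):
            ups.append(
                Sequential(ConvTranspose3d(ch, ch // 2, 3, rng), InstanceNorm3d(), ReLU())
            )
            ch //= 2
        self.ups = ups
        self.head = Sequential(Conv3d(ch, in_channels, 7, rng), Tanh())
        #: channel width of each encoder tap (stem, downs..., bottleneck)
        self.tap_channels = [ngf] + [ngf * 2 ** (i + 1) for i in range(n_downsample)] + [
            ngf * 2**n_downsample
        ]

    def encode(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        """Run the encoder half; returns (bottleneck, tap features)."""
        taps = []
        h = self.stem(x)
        taps.append(h)
        for down in self.downs:
            h = down(h)
            taps.append(h)
        for block in self.enc_res:
            h = block(h)
        taps.append(h)
        return h, taps

    def decode(self, h: Tensor) -> Tensor:
        for block in self.dec_res:
            h = block(h)
        for up in self.ups:
            h = up(h)
        return self.head(h)

    def forward(self, x: Tensor) -> Tensor:
        h, _ = self.encode(x)
        return self.decode(h)


class PatchGANDiscriminator3d(Module):
    """3D PatchGAN with sigmoid patch-score output in (0, 1)."""

    def __init__(
        self,
        rng: np.random.Generator,
        ndf: int = 64,
        in_channels: int = 1,
        n_strided: int = 3,
    ):
        layers = [Conv3d(in_channels, ndf, 4, rng, stride=2, pad=1), LeakyReLU(0.2)]
        ch = ndf
        for _ in range(n_strided - 1):
            layers += [
                Conv3d(ch, ch * 2, 4, rng, stride=2, pad=1),
                InstanceNorm3d(),
                LeakyReLU(0.2),
            ]
            ch *= 2
        layers += [
            Conv3d(ch, ch, 4, rng, stride=1, pad=1),
            InstanceNorm3d(),
            LeakyReLU(0.2),
            Conv3d(ch, 1, 4, rng, stride=1, pad=1),
            Sigmoid(),
        ]
        self.body = Sequential(*layers)
        self.n_strided = n_strided

    def forward(self, x: Tensor) -> Tensor:
        # the receptive-field chain needs ~2^(n_strided+1) voxels per axis
        if min(x.shape[1:]) < 2 ** self.n_strided * 3:
            raise ValueError(
                f"volume shape {x.shape[1:]} too small for a PatchGAN with "
                f"{self.n_strided} strided stages"
            )
        return self.body(x)


class PatchSampleMLP(Module):
    """Two-layer MLP embedding of sampled feature-map locations.

    One MLP per tapped encoder layer; embeddings are L2-normalized so the
    contrastive similarities are cosines.
    """

    def __init__(self, tap_channels: list[int], rng: np.random.Generator, dim: int = 256):
        self.mlps = [
            Sequential(Linear(c, dim, rng), ReLU(), Linear(dim, dim, rng))
            for c in tap_channels
        ]
        self.dim = dim

    def sample(
        self,
        feats: list[Tensor],
        n_locations: int,
        rng: np.random.Generator | None = None,
        ids: list[np.ndarray] | None = None,
    ) -> tuple[list[Tensor], list[np.ndarray]]:
        """Embed ``n_locations`` spatial positions of each tapped feature map.

        Pass the ``ids`` returned by a previous call to sample the *same*
        locations of another volume's features (queries and positives must
        correspond spatially).
        """
        if ids is None:
            if rng is None:
                raise ValueError("need an rng when location ids are not given")
            ids = []
            for f in feats:
                n_spatial = int(np.prod(f.shape[1:]))
                k = min(n_locations, n_spatial)
                ids.append(rng.choice(n_spatial, size=k, replace=False))
        out = []
        for f, mlp, loc in zip(feats, self.mlps, ids):
            c = f.shape[0]
            flat = f.reshape(c, -1).transpose((1, 0))  # (N, C)
            z = mlp(take_rows(flat, loc))
            norm = ((z * z).sum(axis=1, keepdims=True) + 1e-8).pow(-0.5)
            out.append(z * norm)
        return out, ids
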