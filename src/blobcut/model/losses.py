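"""Loss terms of the translation objective.

The total objective is

    L = L_GAN + lambda_in * L_NCE(source) + lambda_ic * L_NCE(target)
        + lambda_conv * L_convex + lambda_kld * L_KLD

where L_NCE is the multilayer patchwise contrastive loss, L_convex penalizes
changes of the inverted-image Hessian convexity indicator inside a region
mask, and L_KLD compares per-channel intensity-distribution representations
of the translated volume and a synthetic phantom with the same blob count.

The convexity indicator is piecewise constant, so training uses a smooth
surrogate (products of sigmoids of the Sylvester minors, with sharpness
scaled per minor order to keep the three factors on comparable footing);
the hard indicator value is what gets logged and reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import hessian
from ..nn import Tensor, as_tensor, conv3d, take_rows

__all__ = [
    "LossWeights",
    "adversarial_objective",
    "discriminator_loss",
    "generator_gan_loss",
    "patch_nce_loss",
    "convexity_loss",
    "soft_convexity_loss",
    "feature_log_distribution",
    "kld_loss",
    "total_loss",
]

_EPS = 1e-7


@dataclass
class LossWeights:
    """Non-negative weights of the four auxiliary loss terms."""

    lambda_in: float = 1.0
    lambda_ic: float = 1.0
    lambda_conv: float = 1.0
    lambda_kld: float = 1.0

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")


def _scores(x) -> np.ndarray:
    arr = x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)
    return np.clip(arr, _EPS, 1.0 - _EPS)


def adversarial_objective(real_scores, fake_scores) -> float:
    """The GAN objective as printed: E[log D(real)] + E[1 - log D(fake)].

    A diagnostic value only; gradient steps use :func:`discriminator_loss`
    and :func:`generator_gan_loss` (the standard opposing-sign objectives,
    which are bounded and saturation-free).
    """
    r, f = _scores(real_scores), _scores(fake_scores)
    return float(np.mean(np.log(r)) + np.mean(1.0 - np.log(f)))


def discriminator_loss(d_real: Tensor, d_fake: Tensor) -> Tensor:
    """-E[log D(real)] - E[log(1 - D(fake))]; ``d_fake`` should be detached."""
    return -((d_real + _EPS).log().mean() + (1.0 - d_fake + _EPS).log().mean())


def generator_gan_loss(d_fake: Tensor) -> Tensor:
    """Non-saturating generator objective: -E[log D(fake)]."""
    return -(d_fake + _EPS).log().mean()


def patch_nce_loss(z_query: list[Tensor], z_key: list[Tensor], tau: float = 0.07) -> Tensor:
    """Multilayer patchwise contrastive (InfoNCE) loss.

    ``z_query[l]`` and ``z_key[l]`` are (S_l, dim) L2-normalized embeddings of
    the *same* S_l spatial locations in the translated and source volumes.
    For each query the positive is the same-location key; the other S_l - 1
    keys are negatives.  Returns the mean over locations, averaged across
    layers, so uniform similarities give log(S_l) exactly.
    """
    if not z_query or len(z_query) != len(z_key):
        raise ValueError("need matching non-empty query/key feature lists")
    terms = []
    for zq, zk in zip(z_query, z_key):
        if zq.shape[0] < 2:
            raise ValueError("need at least 2 sampled locations per layer")
        logits = (zq @ zk.transpose((1, 0))) * (1.0 / tau)  # (S, S)
        pos = (zq * zk).sum(axis=1) * (1.0 / tau)
        terms.append((logits.logsumexp(axis=1) - pos).mean())
    out = terms[0]
    for t in terms[1:]:
        out = out + t
    return out * (1.0 / len(terms))


def convexity_loss(
    input_volume: np.ndarray,
    translated_volume: np.ndarray,
    region_mask: np.ndarray | None = None,
) -> float:
    """Hard convexity-consistency loss (reported value).

    Mean over voxels of |HI(J - translated) - HI(J - input)| restricted to
    the region mask (default: the input's own inverted-image convexity mask,
    so the loss charges for losing input blob convexity while leaving the
    translator free to remove spurious convexity elsewhere).
    """
    input_volume = np.asarray(input_volume, dtype=np.float64)
    translated_volume = np.asarray(translated_volume, dtype=np.float64)
    if input_volume.shape != translated_volume.shape:
        raise ValueError(
            f"shape mismatch: {input_volume.shape} vs {translated_volume.shape}"
        )
    hi_in = hessian.convexity_mask_of_image(input_volume, invert=True)
    hi_tr = hessian.convexity_mask_of_image(translated_volume, invert=True)
    m = hi_in if region_mask is None else (np.asarray(region_mask) > 0).astype(np.uint8)
    diff = np.abs(hi_tr.astype(np.int8) - hi_in.astype(np.int8)) * m
    return float(diff.mean())


def _hessian_stencil_weights() -> np.ndarray:
    """Fixed conv kernels producing the 6 unique Hessian components."""
    d2 = np.array([1.0, -2.0, 1.0])
    d1 = np.array([0.5, 0.0, -0.5])
    delta = np.array([0.0, 1.0, 0.0])
    w = np.zeros((6, 1, 3, 3, 3), dtype=np.float32)
    comps = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))
    for k, (i, j) in enumerate(comps):
        kernels = [delta, delta, delta]
        if i == j:
            kernels[i] = d2
        else:
            kernels[i] = d1
            kernels[j] = d1
        w[k, 0] = kernels[0][:, None, None] * kernels[1][None, :, None] * kernels[2][None, None, :]
    return w


_HESSIAN_W = Tensor(_hessian_stencil_weights())


def soft_convexity_loss(
    translated: Tensor,
    hard_input_indicator: np.ndarray,
    region_mask: np.ndarray,
    sharpness: float = 25.0,
) -> Tensor:
    """Differentiable surrogate of :func:`convexity_loss`.

    ``translated`` is a (1, D, H, W) tensor in [0, 1].  The inverted-image
    Hessian minors m1, m2, m3 are pushed through sigmoids with sharpness
    k, k^2, k^3 (matching their units: curvature to the 1st, 2nd, 3rd power)
    and multiplied into a soft negative-definiteness indicator.
    """
    h = conv3d(translated, _HESSIAN_W, None, stride=1, pad=1, pad_mode="replicate")
    s = -h  # Hessian of the inverted volume
    # autograd views of the six unique components via row gathering on (6, N)
    flat = s.reshape(6, -1)
    c = [take_rows(flat, np.array([k])) for k in range(6)]
    m1 = c[0]
    m2 = c[0] * c[3] - c[1] * c[1]
    m3 = (
        c[0] * (c[3] * c[5] - c[4] * c[4])
        - c[1] * (c[1] * c[5] - c[4] * c[2])
        + c[2] * (c[1] * c[4] - c[3] * c[2])
    )
    k1, k2, k3 = sharpness, sharpness**2, sharpness**3
    soft = ((-k1) * m1).sigmoid() * (k2 * m2).sigmoid() * ((-k3) * m3).sigmoid()
    target = np.asarray(hard_input_indicator, dtype=np.float32).reshape(1, -1)
    mask = np.asarray(region_mask, dtype=np.float32).copy()
    # the hard indicator never marks the 1-voxel border; exclude it here too
    interior = np.zeros(mask.shape, dtype=np.float32)
    interior[1:-1, 1:-1, 1:-1] = 1.0
    mask = (mask * interior).reshape(1, -1)
    return ((soft - Tensor(target)) * Tensor(mask)).abs().mean()


def feature_log_distribution(feat: Tensor) -> Tensor:
    """Per-channel log-probabilities over spatial positions (softmax)."""
    c = feat.shape[0]
    flat = feat.reshape(c, -1)
    return flat - flat.logsumexp(axis=1, keepdims=True)


def kld_loss(feat_translated: Tensor, feat_synthetic: Tensor) -> Tensor:
    """KL(translated || synthetic) between per-channel spatial distributions.

    Each encoder channel's activations are softmax-normalized over space to
    a probability distribution; the KL divergences are averaged over
    channels.  Zero iff the feature stacks induce identical distributions.
    """
    if feat_translated.shape != feat_synthetic.shape:
        raise ValueError(
            f"feature shape mismatch: {feat_translated.shape} vs {feat_synthetic.shape}"
        )
    logp = feature_log_distribution(feat_translated)
    logq = feature_log_distribution(feat_synthetic)
    p = logp.exp()
    return (p * (logp - logq)).sum(axis=1).mean()


def total_loss(parts: dict, weights: LossWeights) -> Tensor:
    """Weighted sum: GAN + lambda_In NCE_in + lambda_Ic NCE_ic + conv + KLD."""
    return (
        as_tensor(parts["gan"])
        + weights.lambda_in * as_tensor(parts["nce_in"])
        + weights.lambda_ic * as_tensor(parts["nce_ic"])
        + weights.lambda_conv * as_tensor(parts["conv"])
        + weights.lambda_kld * as_tensor(parts["kld"])
    )
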