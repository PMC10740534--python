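"""The unpaired translation model: configuration, training loop, checkpoints.

One generator and one discriminator are trained adversarially to map noisy
blob volumes (source domain) toward clean synthetic phantoms (target
domain), with patchwise contrastive losses tying translated content to the
input, a convexity-consistency penalty preserving input blob geometry, and a
KL intensity-distribution penalty against a freshly synthesized phantom with
the translated volume's blob count.  Batch size is 1 volume; optimization is
Adam at learning rate 2e-4 with no decay.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .. import hessian, identify, phantom
from ..nn import Adam, Tensor
from . import inference, losses
from .losses import LossWeights
from .networks import PatchGANDiscriminator3d, PatchSampleMLP, ResnetGenerator3d

__all__ = ["ModelConfig", "TrainState", "BlobTranslator", "smoke_config"]


@dataclass
class ModelConfig:
    """Architecture, loss and optimization settings."""

    ngf: int = 64
    ndf: int = 64
    d_layers: int = 3
    n_downsample: int = 2
    n_residual: int = 6
    resize_factor: int = 2
    nce_locations: int = 256
    nce_dim: int = 256
    nce_tau: float = 0.07
    weights: LossWeights = field(default_factory=LossWeights)
    lr: float = 2e-4
    betas: tuple[float, float] = (0.5, 0.999)
    epochs: int = 25
    conv_sharpness: float = 25.0
    conv_region_mask: str = "ones"  # "ones" | "input_convex"
    binarize_threshold: float = 0.5
    kld_min_blobs: int = 1
    kld_max_blobs: int = 800
    kld_sigma_range: tuple[float, float] = (0.5, 1.5)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["weights"] = LossWeights(**d["weights"])
        d["betas"] = tuple(d["betas"])
        d["kld_sigma_range"] = tuple(d["kld_sigma_range"])
        return cls(**d)


def smoke_config() -> ModelConfig:
    """Narrow-network configuration for CPU-scale experiments and tests."""
    return ModelConfig(ngf=8, ndf=8, nce_locations=64, nce_dim=32)


@dataclass
class TrainState:
    """Epoch counter and per-epoch loss history."""

    epoch: int = 0
    seed: int = 0
    history: list[dict] = field(default_factory=list)

    def last(self) -> dict:
        return self.history[-1] if self.history else {}


class TrainingDiverged(RuntimeError):
    """A loss became non-finite during training."""


class BlobTranslator:
    """One-sided contrastive translation model for 3D blob volumes."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        self.seed = int(seed)
        ss = np.random.SeedSequence(self.seed)
        sg, sd, sf, st = ss.spawn(4)
        cfg = self.config
        self.generator = ResnetGenerator3d(
            np.random.default_rng(sg), cfg.ngf, cfg.n_downsample, cfg.n_residual
        )
        self.discriminator = PatchGANDiscriminator3d(
            np.random.default_rng(sd), cfg.ndf, n_strided=cfg.d_layers
        )
        self.sampler = PatchSampleMLP(
            self.generator.tap_channels, np.random.default_rng(sf), cfg.nce_dim
        )
        self.train_rng = np.random.default_rng(st)
        self.opt_g = Adam(
            self.generator.parameters() + self.sampler.parameters(),
            lr=cfg.lr, betas=cfg.betas,
        )
        self.opt_d = Adam(self.discriminator.parameters(), lr=cfg.lr, betas=cfg.betas)
        self.state = TrainState(seed=self.seed)

    # ------------------------------------------------------------------
    def translate(self, volume: np.ndarray) -> np.ndarray:
        """Denoise one volume; output shape equals input shape, range [0, 1]."""
        return inference.run_generator(
            self.generator, volume, self.config.resize_factor
        )

    # ------------------------------------------------------------------
    def _kld_counterpart(self, y01: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
        """Synthesize a phantom with the translated volume's blob count."""
        cfg = self.config
        bm = (y01 < cfg.binarize_threshold)
        k = identify.connected_components(bm, connectivity=26, min_size=1).count
        k = int(np.clip(k, cfg.kld_min_blobs, cfg.kld_max_blobs))
        sig = tuple(s * cfg.resize_factor for s in cfg.kld_sigma_range)
        seed = int(self.train_rng.integers(0, 2**31))
        ph = phantom.compose_phantom(
            shape, (k, k), sig, seed=seed
        )
        return ph.image

    def _train_step(self, x_np: np.ndarray, ic_np: np.ndarray) -> dict:
        cfg = self.config
        w = cfg.weights
        x = Tensor(x_np)
        ic = Tensor(ic_np)

        # generator forward on the source volume
        h_x, taps_x = self.generator.encode(x)
        y = self.generator.decode(h_x)
        y01 = (y + 1.0) * 0.5

        # --- discriminator update ---------------------------------------
        y01_det = y01.detach()
        d_real = self.discriminator(ic)
        d_fake = self.discriminator(y01_det)
        d_loss = losses.discriminator_loss(d_real, d_fake)
        self.opt_d.zero_grad()
        d_loss.backward()
        self.opt_d.step()

        # --- generator / sampler update ---------------------------------
        d_fake_g = self.discriminator(y01)
        gan = losses.generator_gan_loss(d_fake_g)

        _, taps_y = self.generator.encode(y01)
        z_q, ids = self.sampler.sample(taps_y, cfg.nce_locations, self.train_rng)
        z_k, _ = self.sampler.sample(taps_x, cfg.nce_locations, ids=ids)
        nce_in = losses.patch_nce_loss(z_q, z_k, cfg.nce_tau)

        h_ic, taps_ic = self.generator.encode(ic)
        idt = self.generator.decode(h_ic)
        idt01 = (idt + 1.0) * 0.5
        _, taps_idt = self.generator.encode(idt01)
        z_q2, ids2 = self.sampler.sample(taps_idt, cfg.nce_locations, self.train_rng)
        z_k2, _ = self.sampler.sample(taps_ic, cfg.nce_locations, ids=ids2)
        nce_ic = losses.patch_nce_loss(z_q2, z_k2, cfg.nce_tau)

        hi_in = hessian.convexity_mask_of_image(x_np[0], invert=True)
        region = hi_in if cfg.conv_region_mask == "input_convex" else np.ones_like(hi_in)
        conv = losses.soft_convexity_loss(y01, hi_in, region, cfg.conv_sharpness)

        y01_np = y01.data[0]
        synth = self._kld_counterpart(y01_np, y01_np.shape)
        h_t, _ = self.generator.encode(y01)
        h_s, _ = self.generator.encode(Tensor(synth[None]))
        kld = losses.kld_loss(h_t, h_s)

        parts = {"gan": gan, "nce_in": nce_in, "nce_ic": nce_ic, "conv": conv, "kld": kld}
        g_loss = losses.total_loss(parts, w)
        self.opt_g.zero_grad()
        g_loss.backward()
        self.opt_g.step()

        hi_tr = hessian.convexity_mask_of_image(y01_np, invert=True)
        log = {
            "d_loss": d_loss.item(),
            "gan": gan.item(),
            "nce_in": nce_in.item(),
            "nce_ic": nce_ic.item(),
            "conv_soft": conv.item(),
            "conv_hard": losses.convexity_loss(x_np[0], y01_np, region),
            "kld": kld.item(),
            "total": g_loss.item(),
            "adversarial_objective": losses.adversarial_objective(d_real, d_fake),
            "convexity_count_input": hessian.convexity_count(hi_in),
            "convexity_count_translated": hessian.convexity_count(hi_tr),
        }
        for name, v in log.items():
            if not np.isfinite(v):
                raise TrainingDiverged(f"non-finite {name} at epoch {self.state.epoch}: {v}")
        return log

    def train(
        self,
        source_volumes: list[np.ndarray],
        target_volumes: list[np.ndarray],
        epochs: int | None = None,
        validation_volumes: list[np.ndarray] | None = None,
        verbose: bool = False,
    ) -> TrainState:
        """Alternating Adam updates over unpaired source/target volumes.

        One epoch visits every source volume once (shuffled), pairing each
        with a randomly drawn target volume.  Per-epoch mean losses (and a
        validation convexity trend, when validation volumes are given) are
        appended to ``state.history``.
        """
        if not source_volumes or not target_volumes:
            raise ValueError("source and target datasets must be non-empty")
        epochs = self.config.epochs if epochs is None else int(epochs)
        src = [inference.preprocess(v, self.config.resize_factor)[0] for v in source_volumes]
        tgt = [inference.preprocess(v, self.config.resize_factor)[0] for v in target_volumes]
        for _ in range(epochs):
            order = self.train_rng.permutation(len(src))
            logs = []
            for i in order:
                j = int(self.train_rng.integers(len(tgt)))
                logs.append(self._train_step(src[i], tgt[j]))
            epoch_log = {k: float(np.mean([l[k] for l in logs])) for k in logs[0]}
            epoch_log["epoch"] = self.state.epoch
            if validation_volumes is not None:
                frac = self._validation_convexity_trend(validation_volumes)
                epoch_log["val_convexity_noninc_frac"] = frac
            self.state.history.append(epoch_log)
            self.state.epoch += 1
            if verbose:
                print({k: round(v, 4) for k, v in epoch_log.items()})
        return self.state

    def _validation_convexity_trend(self, volumes: list[np.ndarray]) -> float:
        """Fraction of volumes whose translation does not add convex voxels."""
        ok = 0
        for v in volumes:
            t = self.translate(v)
            c_in = hessian.convexity_count(hessian.convexity_mask_of_image(v, invert=True))
            c_tr = hessian.convexity_count(hessian.convexity_mask_of_image(t, invert=True))
            ok += int(c_tr <= c_in)
        return ok / len(volumes)

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Checkpoint: weights + optimizer state (.npz) with a JSON sidecar."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays: dict[str, np.ndarray] = {}
        for prefix, module in (
            ("G", self.generator), ("D", self.discriminator), ("F", self.sampler)
        ):
            for name, arr in module.state_dict().items():
                arrays[f"{prefix}/{name}"] = arr
        for prefix, opt in (("optG", self.opt_g), ("optD", self.opt_d)):
            for i, (m, v) in enumerate(zip(opt.m, opt.v)):
                arrays[f"{prefix}/m/{i}"] = m
                arrays[f"{prefix}/v/{i}"] = v
        np.savez(path, **arrays)
        digest = hashlib.sha256()
        for key in sorted(arrays):
            digest.update(np.ascontiguousarray(arrays[key]).tobytes())
        sidecar = {
            "config": self.config.to_dict(),
            "seed": self.seed,
            "epoch": self.state.epoch,
            "history": self.state.history,
            "opt_t": {"G": self.opt_g.t, "D": self.opt_d.t},
            "train_rng_state": _rng_state_to_json(self.train_rng),
            "weights_sha256": digest.hexdigest(),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "BlobTranslator":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        model = cls(ModelConfig.from_dict(sidecar["config"]), seed=sidecar["seed"])
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
            for prefix, module in (
                ("G", model.generator), ("D", model.discriminator), ("F", model.sampler)
            ):
                state = {
                    k[len(prefix) + 1:]: data[k]
                    for k in data.files
                    if k.startswith(prefix + "/")
                }
                module.load_state_dict(state)
            for prefix, opt in (("optG", model.opt_g), ("optD", model.opt_d)):
                for i in range(len(opt.params)):
                    opt.m[i] = data[f"{prefix}/m/{i}"]
                    opt.v[i] = data[f"{prefix}/v/{i}"]
        model.opt_g.t = sidecar["opt_t"]["G"]
        model.opt_d.t = sidecar["opt_t"]["D"]
        model.state = TrainState(
            epoch=sidecar["epoch"], seed=sidecar["seed"], history=sidecar["history"]
        )
        model.train_rng = _rng_state_from_json(sidecar["train_rng_state"])
        return model


def _rng_state_to_json(rng: np.random.Generator) -> dict:
    state = rng.bit_generator.state
    return json.loads(json.dumps(state, default=int))


def _rng_state_from_json(state: dict) -> np.random.Generator:
    rng = np.random.default_rng(0)
    rng.bit_generator.state = state
    return rng
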