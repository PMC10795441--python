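"""Unpaired with-bone -> without-bone translation (CycleGAN).

Two ResNet generators (X->Y and Y->X) and two PatchGAN discriminators are
trained with a least-squares adversarial objective plus an L1
cycle-consistency term (optionally an identity term), Adam with lr 0.0002,
beta1 0.5, beta2 0.999, one generator and one discriminator update per
iteration, and a replay buffer of past fakes for the discriminators. X is
the with-bone domain, Y the bone-free domain; ``G_XY`` is the bone
suppressor.

Images enter the networks scaled from [0, 255] to [-1, 1] (tanh output
range). Everything is CPU numpy; a fixed config seed yields bit-identical
training histories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .errors import ConfigurationError, NumericalError, SizeError
from .projection import ImageDataset, ProjectionImage, tile_3x3, reassemble

__all__ = [
    "GanConfig",
    "TrainedModel",
    "ReplayBuffer",
    "init_models",
    "compute_losses",
    "train",
    "suppress_bone",
    "save_model",
    "load_model",
]

F32 = np.float32


@dataclass(frozen=True)
class GanConfig:
    learning_rate: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    lambda_cycle: float = 10.0
    lambda_identity: float = 0.0  # 0 disables the identity term
    n_res_blocks: int = 2
    base_channels: int = 16
    residual_generator: bool = True  # generator predicts a bounded correction to x
    image_size: int = 64
    batch_size: int = 1  # reference CycleGAN trains with batch 1 + instance norm
    n_epochs: int = 10
    max_updates: int | None = None  # optional cap on generator updates
    replay_buffer_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "learning_rate": self.learning_rate, "beta1": self.beta1, "beta2": self.beta2,
            "lambda_cycle": self.lambda_cycle, "n_res_blocks": self.n_res_blocks,
            "base_channels": self.base_channels, "image_size": self.image_size,
            "batch_size": self.batch_size, "n_epochs": self.n_epochs,
            "replay_buffer_size": self.replay_buffer_size,
        }
        for name, v in positive.items():
            if v <= 0:
                raise ConfigurationError(f"{name} must be positive, got {v}")
        if self.lambda_identity < 0:
            raise ConfigurationError("lambda_identity must be >= 0")
        if self.image_size % 4 != 0:
            raise ConfigurationError(
                f"image_size {self.image_size} must be divisible by 4 "
                "(two stride-2 stages in the generator)"
            )


class ResidualWrap(nn.Layer):
    """y = clip(x + body(x), -1, 1): the body predicts a bounded correction.

    With the body's output conv zero-initialized the generator starts as the
    exact identity, so training only has to learn the bone-signal deviation
    rather than re-synthesize the whole image through the bottleneck.
    """

    def __init__(self, body: nn.Sequential):
        self.body = body

    def params(self):
        return self.body.params()

    def forward(self, x):
        d, ctx = self.body.forward(x)
        y = x + d
        mask = (y > -1.0) & (y < 1.0)
        return np.clip(y, -1.0, 1.0), (ctx, mask)

    def backward(self, dy, ctx, accumulate=True):
        body_ctx, mask = ctx
        dy = dy * mask
        return dy + self.body.backward(dy.astype(np.float32), body_ctx, accumulate)


def _make_generator(cfg: GanConfig, rng: np.random.Generator) -> nn.Layer:
    c = cfg.base_channels
    layers: list[nn.Layer] = [
        nn.Conv2d(1, c, 7, pad=3, rng=rng), nn.InstanceNorm2d(c), nn.ReLU(),
        nn.Conv2d(c, 2 * c, 3, stride=2, pad=1, rng=rng), nn.InstanceNorm2d(2 * c), nn.ReLU(),
        nn.Conv2d(2 * c, 4 * c, 3, stride=2, pad=1, rng=rng), nn.InstanceNorm2d(4 * c), nn.ReLU(),
    ]
    for _ in range(cfg.n_res_blocks):
        layers.append(nn.ResBlock(4 * c, rng))
    layers += [
        nn.UpsampleNearest2x(), nn.Conv2d(4 * c, 2 * c, 3, pad=1, rng=rng),
        nn.InstanceNorm2d(2 * c), nn.ReLU(),
        nn.UpsampleNearest2x(), nn.Conv2d(2 * c, c, 3, pad=1, rng=rng),
        nn.InstanceNorm2d(c), nn.ReLU(),
        nn.Conv2d(c, 1, 7, pad=3, rng=rng,
                  w_sd=0.0 if cfg.residual_generator else 0.02),
        nn.Tanh(),
    ]
    body = nn.Sequential(*layers)
    return ResidualWrap(body) if cfg.residual_generator else body


def _make_discriminator(cfg: GanConfig, rng: np.random.Generator) -> nn.Sequential:
    c = cfg.base_channels
    return nn.Sequential(
        nn.Conv2d(1, c, 4, stride=2, pad=1, rng=rng), nn.LeakyReLU(0.2),
        nn.Conv2d(c, 2 * c, 4, stride=2, pad=1, rng=rng), nn.InstanceNorm2d(2 * c), nn.LeakyReLU(0.2),
        nn.Conv2d(2 * c, 4 * c, 4, stride=2, pad=1, rng=rng), nn.InstanceNorm2d(4 * c), nn.LeakyReLU(0.2),
        nn.Conv2d(4 * c, 1, 3, pad=1, rng=rng),
    )


@dataclass
class TrainedModel:
    G_XY: nn.Sequential
    G_YX: nn.Sequential
    D_X: nn.Sequential
    D_Y: nn.Sequential
    history: list[dict] = field(default_factory=list)
    config: GanConfig = field(default_factory=GanConfig)
    val_log: list[dict] = field(default_factory=list)


def init_models(config: GanConfig) -> TrainedModel:
    """Deterministically initialize the four networks from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    return TrainedModel(
        G_XY=_make_generator(config, rng),
        G_YX=_make_generator(config, rng),
        D_X=_make_discriminator(config, rng),
        D_Y=_make_discriminator(config, rng),
        config=config,
    )


class ReplayBuffer:
    """Pool of past generator outputs fed to the discriminators.

    For each incoming fake: while the pool is not full, store it and return
    it unchanged; once full, with probability 0.5 return the fake as-is,
    otherwise return a randomly chosen stored image and replace it with the
    incoming fake.
    """

    def __init__(self, size: int, rng: np.random.Generator):
        self.size = size
        self.rng = rng
        self.images: list[np.ndarray] = []

    def query(self, batch: np.ndarray) -> np.ndarray:
        out = []
        for img in batch:
            img = img.copy()
            if len(self.images) < self.size:
                self.images.append(img)
                out.append(img)
            elif self.rng.random() < 0.5:
                out.append(img)
            else:
                idx = int(self.rng.integers(len(self.images)))
                out.append(self.images[idx])
                self.images[idx] = img
        return np.stack(out)


def _mse_to(x: np.ndarray, target: float) -> float:
    return float(np.mean((x - F32(target)) ** 2))


def _l1(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean(np.abs(a - b)))


def to_unit(images_u8: np.ndarray) -> np.ndarray:
    """[0,255] -> [-1,1] float32, adding the channel axis."""
    x = np.asarray(images_u8, dtype=F32) / F32(127.5) - F32(1.0)
    return x[:, None] if x.ndim == 3 else x


def from_unit(x: np.ndarray) -> np.ndarray:
    """[-1,1] -> uint8 [0,255], rounded half-up."""
    y = (np.asarray(x, dtype=np.float64) + 1.0) * 127.5
    return np.clip(np.floor(y + 0.5), 0, 255).astype(np.uint8)


def compute_losses(batch_X: np.ndarray, batch_Y: np.ndarray, model: TrainedModel,
                   config: GanConfig | None = None) -> dict[str, float]:
    """Forward-only loss components on one batch pair (no parameter updates).

    ``adv_G`` uses least-squares targets (fakes scored against 1); each
    ``adv_D`` is the average of its real term (target 1) and fake term
    (target 0). ``cycle`` and ``identity`` are L1 terms scaled by their
    lambda weights.
    """
    cfg = config or model.config
    x, y = np.asarray(batch_X, F32), np.asarray(batch_Y, F32)
    fake_y, _ = model.G_XY.forward(x)
    fake_x, _ = model.G_YX.forward(y)
    rec_x, _ = model.G_YX.forward(fake_y)
    rec_y, _ = model.G_XY.forward(fake_x)
    d_fake_y, _ = model.D_Y.forward(fake_y)
    d_fake_x, _ = model.D_X.forward(fake_x)
    d_real_y, _ = model.D_Y.forward(y)
    d_real_x, _ = model.D_X.forward(x)
    losses = {
        "adv_G": _mse_to(d_fake_y, 1.0) + _mse_to(d_fake_x, 1.0),
        "adv_D_X": 0.5 * (_mse_to(d_real_x, 1.0) + _mse_to(d_fake_x, 0.0)),
        "adv_D_Y": 0.5 * (_mse_to(d_real_y, 1.0) + _mse_to(d_fake_y, 0.0)),
        "cycle": cfg.lambda_cycle * (_l1(rec_x, x) + _l1(rec_y, y)),
        "identity": 0.0,
    }
    if cfg.lambda_identity > 0:
        id_y, _ = model.G_XY.forward(y)
        id_x, _ = model.G_YX.forward(x)
        losses["identity"] = cfg.lambda_identity * (_l1(id_y, y) + _l1(id_x, x))
    for k, v in losses.items():
        if not np.isfinite(v):
            raise NumericalError(f"non-finite loss component {k}", iteration=None)
    return losses


def _generator_step(x, y, model: TrainedModel, cfg: GanConfig, opt_G: nn.Adam) -> dict:
    """One generator update: adversarial + cycle (+ identity), grads through both G's."""
    G_XY, G_YX, D_X, D_Y = model.G_XY, model.G_YX, model.D_X, model.D_Y
    opt_G.zero_grad()

    fake_y, t_gxy = G_XY.forward(x)
    rec_x, t_gyx_rec = G_YX.forward(fake_y)
    fake_x, t_gyx = G_YX.forward(y)
    rec_y, t_gxy_rec = G_XY.forward(fake_x)
    d_fy, t_dy = D_Y.forward(fake_y)
    d_fx, t_dx = D_X.forward(fake_x)

    adv = _mse_to(d_fy, 1.0) + _mse_to(d_fx, 1.0)
    cyc = cfg.lambda_cycle * (_l1(rec_x, x) + _l1(rec_y, y))
    idt = 0.0

    # adversarial grads flow through the (frozen) discriminators
    d_fy_grad = (2.0 / d_fy.size) * (d_fy - F32(1.0))
    d_fx_grad = (2.0 / d_fx.size) * (d_fx - F32(1.0))
    dfake_y = D_Y.backward(d_fy_grad.astype(F32), t_dy, accumulate=False)
    dfake_x = D_X.backward(d_fx_grad.astype(F32), t_dx, accumulate=False)

    # cycle grads
    lam = F32(cfg.lambda_cycle)
    drec_x = lam * np.sign(rec_x - x) / F32(rec_x.size)
    drec_y = lam * np.sign(rec_y - y) / F32(rec_y.size)
    dfake_y = dfake_y + G_YX.backward(drec_x.astype(F32), t_gyx_rec)
    dfake_x = dfake_x + G_XY.backward(drec_y.astype(F32), t_gxy_rec)

    G_XY.backward(dfake_y.astype(F32), t_gxy)
    G_YX.backward(dfake_x.astype(F32), t_gyx)

    if cfg.lambda_identity > 0:
        mu = F32(cfg.lambda_identity)
        id_y, t_idy = G_XY.forward(y)
        id_x, t_idx = G_YX.forward(x)
        idt = cfg.lambda_identity * (_l1(id_y, y) + _l1(id_x, x))
        G_XY.backward((mu * np.sign(id_y - y) / F32(id_y.size)).astype(F32), t_idy)
        G_YX.backward((mu * np.sign(id_x - x) / F32(id_x.size)).astype(F32), t_idx)

    opt_G.step()
    return {"adv_G": adv, "cycle": cyc, "identity": idt,
            "fake_x": fake_x, "fake_y": fake_y}


def _discriminator_step(D: nn.Sequential, real, fake, opt: nn.Adam) -> float:
    d_real, t_r = D.forward(real)
    d_fake, t_f = D.forward(fake)
    loss = 0.5 * (_mse_to(d_real, 1.0) + _mse_to(d_fake, 0.0))
    D.backward(((1.0 / d_real.size) * (d_real - F32(1.0))).astype(F32), t_r)
    D.backward(((1.0 / d_fake.size) * d_fake).astype(F32), t_f)
    opt.step()
    return loss


def train(dataset: ImageDataset | tuple[np.ndarray, np.ndarray], config: GanConfig,
          out_dir: str | Path | None = None,
          val_pairs: list | None = None, val_every: int = 500) -> TrainedModel:
    """Train the CycleGAN on the training split of ``dataset``.

    ``dataset`` may be an :class:`ImageDataset` or a plain ``(X, Y)`` pair of
    uint8 stacks. Runs ``n_epochs`` epochs (optionally capped at
    ``max_updates`` generator updates), updating generators and
    discriminators once per iteration, with replay buffers feeding the
    discriminators. Per-iteration loss components are recorded in
    ``model.history``; with ``out_dir`` set, a checkpoint and CSV log are
    written per epoch. Non-finite losses abort with the last checkpoint
    retained on disk.

    Adversarial training at this scale has no objective stopping rule, so
    when ``val_pairs`` (aligned with/without-bone uint8 pairs, e.g. drawn
    from the *training* split) are given, suppression MSSIM is probed every
    ``val_every`` generator updates and the best-scoring parameters are
    restored at the end; the probe trace is kept in ``model.val_log``.
    """
    if isinstance(dataset, ImageDataset):
        X = dataset.train_arrays("X")
        Y = dataset.train_arrays("Y")
    else:
        X, Y = dataset
    if len(X) == 0 or len(Y) == 0:
        raise ConfigurationError("both domains must be non-empty")
    Xf, Yf = to_unit(X), to_unit(Y)

    model = init_models(config)
    rng = np.random.default_rng(config.seed + 1)
    opt_G = nn.Adam(model.G_XY.params() + model.G_YX.params(),
                    lr=config.learning_rate, beta1=config.beta1, beta2=config.beta2)
    opt_DX = nn.Adam(model.D_X.params(), lr=config.learning_rate,
                     beta1=config.beta1, beta2=config.beta2)
    opt_DY = nn.Adam(model.D_Y.params(), lr=config.learning_rate,
                     beta1=config.beta1, beta2=config.beta2)
    buf_X = ReplayBuffer(config.replay_buffer_size, rng)
    buf_Y = ReplayBuffer(config.replay_buffer_size, rng)

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    model.val_log = []
    best = {"mssim": -np.inf, "params": None}

    def probe_validation(it: int) -> None:
        if not val_pairs:
            return
        score = _val_mssim(model, val_pairs)
        model.val_log.append({"iteration": it, "val_mssim": score})
        if score > best["mssim"]:
            best["mssim"] = score
            best["params"] = [p.value.copy() for p in
                              model.G_XY.params() + model.G_YX.params()]

    bs = config.batch_size
    it = 0
    done = False
    for epoch in range(config.n_epochs):
        perm_x = rng.permutation(len(Xf))
        perm_y = rng.permutation(len(Yf))
        n_batches = min(len(Xf), len(Yf)) // bs
        for b in range(n_batches):
            x = Xf[perm_x[b * bs : (b + 1) * bs]]
            y = Yf[perm_y[b * bs : (b + 1) * bs]]
            g = _generator_step(x, y, model, config, opt_G)
            opt_DX.zero_grad()
            adv_dx = _discriminator_step(model.D_X, x, buf_X.query(g["fake_x"]), opt_DX)
            opt_DY.zero_grad()
            adv_dy = _discriminator_step(model.D_Y, y, buf_Y.query(g["fake_y"]), opt_DY)
            row = {"iteration": it, "epoch": epoch, "adv_G": g["adv_G"],
                   "adv_D_X": adv_dx, "adv_D_Y": adv_dy,
                   "cycle": g["cycle"], "identity": g["identity"]}
            if not all(np.isfinite(v) for v in row.values()):
                raise NumericalError("training diverged (non-finite loss)", iteration=it)
            model.history.append(row)
            it += 1
            if it % val_every == 0:
                probe_validation(it)
            if config.max_updates is not None and it >= config.max_updates:
                done = True
                break
        if out is not None:
            save_model(model, out / f"checkpoint_epoch{epoch:03d}")
            _write_log(model.history, out / "training_log.csv")
        if done:
            break
    if it % val_every != 0:
        probe_validation(it)
    if best["params"] is not None:
        for p, v in zip(model.G_XY.params() + model.G_YX.params(), best["params"]):
            p.value = v
    return model


def _val_mssim(model: TrainedModel, val_pairs) -> float:
    from .metrics import mssim

    scores = []
    for xb, yb in val_pairs:
        y, _ = model.G_XY.forward(to_unit(np.asarray(xb)[None]))
        scores.append(mssim(from_unit(y[0, 0]), np.asarray(yb)))
    return float(np.mean(scores))


def _write_log(history: list[dict], path: Path) -> None:
    import pandas as pd

    pd.DataFrame(history).to_csv(path, index=False)


def suppress_bone(model: TrainedModel, image: ProjectionImage) -> ProjectionImage:
    """Translate an 8-bit with-bone (or treatment-like) image to its bone-free look.

    Images larger than the training tile size are processed tile-wise (3x3)
    and reassembled; tiles whose sides are not multiples of 4 are padded by
    edge replication and cropped back. Output is 8-bit with domain tag
    ``suppressed``.
    """
    h, w = image.pixels.shape
    ts = model.config.image_size
    if h < 4 or w < 4:
        raise SizeError(f"image {h}x{w} smaller than the minimum translatable size")

    def run_tile(pix: np.ndarray) -> np.ndarray:
        ph = (-pix.shape[0]) % 4
        pw = (-pix.shape[1]) % 4
        padded = np.pad(pix, ((0, ph), (0, pw)), mode="edge")
        y, _ = model.G_XY.forward(to_unit(padded[None]))
        out = from_unit(y[0, 0])
        return out[: pix.shape[0], : pix.shape[1]]

    if h > ts or w > ts:
        grid = tile_3x3(image)
        for tile in grid.tiles:
            tile.pixels = run_tile(tile.pixels)
        out_pix = reassemble(grid)
    else:
        out_pix = run_tile(np.asarray(image.pixels))
    return ProjectionImage(
        pixels=out_pix, value_domain="8bit", angle_deg=image.angle_deg,
        domain_tag="suppressed", phantom_id=image.phantom_id, tile_index=image.tile_index,
    )


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Write a self-describing checkpoint: config JSON + parameter arrays (npz)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for name in ("G_XY", "G_YX", "D_X", "D_Y"):
        for i, p in enumerate(getattr(model, name).params()):
            arrays[f"{name}__{i}"] = p.value
    np.savez(str(path) + ".npz", **arrays)
    meta = {"config": asdict(model.config), "n_iterations": len(model.history)}
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def load_model(path: str | Path) -> TrainedModel:
    meta = json.loads(Path(str(path) + ".json").read_text())
    config = GanConfig(**meta["config"])
    model = init_models(config)
    with np.load(str(path) + ".npz") as npz:
        for name in ("G_XY", "G_YX", "D_X", "D_Y"):
            for i, p in enumerate(getattr(model, name).params()):
                p.value = npz[f"{name}__{i}"].astype(F32)
    return model
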