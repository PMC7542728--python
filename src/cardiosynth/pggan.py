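"""Progressive GAN for grayscale cardiac MR frames.

The generator maps a 64-dimensional latent vector to a square grayscale image,
growing from 4x4 up to (at most) 256x256 by successively adding
resolution-doubling blocks; the critic mirrors the generator and scores images
with a single scalar.  New blocks are faded in linearly (blend weight alpha)
while all existing layers remain trainable.  Stabilizers follow the
progressive-growing recipe: pixelwise feature normalization in the generator,
a minibatch-standard-deviation channel in the critic, and a Wasserstein
objective stabilized by critic weight clipping (a finite-difference
directional gradient penalty along the real-to-fake line is available as an
alternative).

Filter counts default to 48, 32, 24, 16, 16, 16, 16 for the seven resolution
blocks; batch size shrinks from 64 to 16 as resolution grows.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .errors import (ConfigError, EmptyDatasetError, StageError,
                     TrainingDivergedError)
from .io import ImageFrame
from .nn import DTYPE, fade_in_blend

DEFAULT_FILTERS = (48, 32, 24, 16, 16, 16, 16)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class GANConfig:
    latent_dim: int = 64
    leakiness: float = 0.2
    output_channels: int = 1
    max_resolution: int = 256
    filters_per_stage: tuple[int, ...] = DEFAULT_FILTERS
    epsilon_pixelnorm: float = 1e-8
    learning_rate: float = 1e-3
    adam_beta1: float = 0.0
    adam_beta2: float = 0.99
    gradient_penalty_weight: float = 10.0
    drift_weight: float = 1e-3
    stabilizer: str = "clip"           # "clip" | "fd_gp"
    clip_limit: float = 0.01
    equalized_lr: bool = False
    fd_epsilon: float = 1e-2           # finite-difference step for the penalty

    def __post_init__(self):
        n_stages = int(math.log2(self.max_resolution)) - 1
        if 2 ** (n_stages + 1) != self.max_resolution:
            raise ConfigError(f"max_resolution {self.max_resolution} not a power of two")
        self.filters_per_stage = tuple(self.filters_per_stage)
        if len(self.filters_per_stage) != n_stages:
            raise ConfigError(
                f"need {n_stages} filter counts for max_resolution "
                f"{self.max_resolution}, got {len(self.filters_per_stage)}")
        if self.latent_dim < 1:
            raise ConfigError("latent_dim must be >= 1")
        if not 0.0 < self.leakiness < 1.0:
            raise ConfigError("leakiness must be in (0, 1)")
        if self.stabilizer not in ("fd_gp", "clip"):
            raise ConfigError(f"unknown stabilizer {self.stabilizer!r}")

    @property
    def n_stages(self) -> int:
        return len(self.filters_per_stage)

    @property
    def stage_resolutions(self) -> tuple[int, ...]:
        return tuple(4 * 2 ** i for i in range(self.n_stages))


def default_batch_schedule(n_stages: int, start: int = 64,
                           end: int = 16) -> tuple[int, ...]:
    """Non-increasing batch sizes from ``start`` down to ``end`` across stages."""
    if n_stages == 1:
        return (start,)
    sizes = []
    for i in range(n_stages):
        f = i / (n_stages - 1)
        b = start * (end / start) ** f
        sizes.append(max(end, int(2 ** round(math.log2(b)))))
    return tuple(sizes)


@dataclass
class GrowthSchedule:
    steps_per_stage: tuple[int, ...]
    batch_per_stage: tuple[int, ...]
    fade_fraction: float = 0.5

    def __post_init__(self):
        self.steps_per_stage = tuple(self.steps_per_stage)
        self.batch_per_stage = tuple(self.batch_per_stage)
        if len(self.steps_per_stage) != len(self.batch_per_stage):
            raise ConfigError("steps_per_stage and batch_per_stage lengths differ")
        if any(b2 > b1 for b1, b2 in zip(self.batch_per_stage,
                                         self.batch_per_stage[1:])):
            raise ConfigError("batch sizes must be non-increasing across stages")
        if not 0.0 <= self.fade_fraction < 1.0:
            raise ConfigError("fade_fraction must be in [0, 1)")

    @property
    def n_stages(self) -> int:
        return len(self.steps_per_stage)

    @classmethod
    def uniform(cls, n_stages: int, steps_per_stage: int,
                fade_fraction: float = 0.5) -> "GrowthSchedule":
        """Same step count per stage, with the default batch schedule."""
        return cls(steps_per_stage=(steps_per_stage,) * n_stages,
                   batch_per_stage=default_batch_schedule(n_stages),
                   fade_fraction=fade_fraction)


@dataclass
class GrowthState:
    current_stage: int = 0
    alpha: float = 1.0
    global_step: int = 0


# ---------------------------------------------------------------------------
# architecture specs (declarative; the models are built from these)


@dataclass
class LayerDescriptor:
    kind: str                  # conv4x4|conv3x3|upscale2x|avgpool2x|minibatch_stddev|pixelnorm|to_image|from_image|dense_score
    in_channels: int = 0
    out_channels: int = 0
    activation: str = "none"   # "lrelu" | "none"
    leakiness: float = 0.0


@dataclass
class ArchitectureSpec:
    """Ordered resolution blocks of layer descriptors plus I/O shapes."""

    role: str                              # "generator" | "discriminator"
    stage: int
    resolution: int
    blocks: list[list[LayerDescriptor]]
    head: list[LayerDescriptor] = field(default_factory=list)
    tail: list[LayerDescriptor] = field(default_factory=list)

    def all_descriptors(self) -> list[LayerDescriptor]:
        out = list(self.head)
        for b in self.blocks:
            out.extend(b)
        out.extend(self.tail)
        return out


def _check_stage(config: GANConfig, stage: int) -> None:
    if not 0 <= stage < config.n_stages:
        raise StageError(
            f"stage {stage} out of range [0, {config.n_stages - 1}]")


def build_generator_spec(config: GANConfig, stage: int) -> ArchitectureSpec:
    """Generator blueprint for one growth stage.

    Block 0 maps the latent vector to a 4x4 map through a 4x4 convolution
    (realized as a dense projection) and a 3x3 convolution; each later block
    upscales 2x and applies two 3x3 convolutions.  All convolutions use leaky
    ReLU followed by pixelwise feature normalization.
    """
    _check_stage(config, stage)
    f = config.filters_per_stage
    lk = config.leakiness
    blocks = [[
        LayerDescriptor("conv4x4", config.latent_dim, f[0], "lrelu", lk),
        LayerDescriptor("pixelnorm", f[0], f[0]),
        LayerDescriptor("conv3x3", f[0], f[0], "lrelu", lk),
        LayerDescriptor("pixelnorm", f[0], f[0]),
    ]]
    for i in range(1, stage + 1):
        blocks.append([
            LayerDescriptor("upscale2x", f[i - 1], f[i - 1]),
            LayerDescriptor("conv3x3", f[i - 1], f[i], "lrelu", lk),
            LayerDescriptor("pixelnorm", f[i], f[i]),
            LayerDescriptor("conv3x3", f[i], f[i], "lrelu", lk),
            LayerDescriptor("pixelnorm", f[i], f[i]),
        ])
    tail = [LayerDescriptor("to_image", f[stage], config.output_channels)]
    return ArchitectureSpec("generator", stage, config.stage_resolutions[stage],
                            blocks, head=[], tail=tail)


def build_discriminator_spec(config: GANConfig, stage: int) -> ArchitectureSpec:
    """Critic blueprint: mirrors the generator in reverse.

    The head reads the image through a 1x1 from_image convolution; each block
    applies two 3x3 convolutions and halves resolution by average pooling.  The
    final block prepends the minibatch-standard-deviation channel and reduces
    the 4x4 map to a scalar score via a 4x4 convolution (dense) and a linear
    score layer.
    """
    _check_stage(config, stage)
    f = config.filters_per_stage
    lk = config.leakiness
    head = [LayerDescriptor("from_image", config.output_channels, f[stage],
                            "lrelu", lk)]
    blocks = []
    for i in range(stage, 0, -1):
        blocks.append([
            LayerDescriptor("conv3x3", f[i], f[i], "lrelu", lk),
            LayerDescriptor("conv3x3", f[i], f[i - 1], "lrelu", lk),
            LayerDescriptor("avgpool2x", f[i - 1], f[i - 1]),
        ])
    blocks.append([
        LayerDescriptor("minibatch_stddev", f[0], f[0] + 1),
        LayerDescriptor("conv3x3", f[0] + 1, f[0], "lrelu", lk),
        LayerDescriptor("conv4x4", f[0], f[0], "lrelu", lk),
    ])
    tail = [LayerDescriptor("dense_score", f[0], 1)]
    return ArchitectureSpec("discriminator", stage,
                            config.stage_resolutions[stage], blocks,
                            head=head, tail=tail)


# ---------------------------------------------------------------------------
# models


class Generator:
    """Progressive generator; holds blocks for every stage up to max."""

    def __init__(self, config: GANConfig, rng: np.random.Generator):
        self.config = config
        f = config.filters_per_stage
        lk = config.leakiness
        eps = config.epsilon_pixelnorm
        eq = config.equalized_lr
        self.base_dense = nn.Dense(config.latent_dim, f[0] * 16, rng, eq_lr=eq)
        self.base_act = nn.LeakyReLU(lk)
        self.base_norm = nn.PixelNorm(eps)
        self.base_conv = nn.Conv2d(f[0], f[0], 3, rng, eq_lr=eq)
        self.base_act2 = nn.LeakyReLU(lk)
        self.base_norm2 = nn.PixelNorm(eps)
        self.blocks = []            # per stage >= 1: (up, c1, a1, n1, c2, a2, n2)
        for i in range(1, config.n_stages):
            self.blocks.append((
                nn.Upsample2x(),
                nn.Conv2d(f[i - 1], f[i], 3, rng, eq_lr=eq), nn.LeakyReLU(lk),
                nn.PixelNorm(eps),
                nn.Conv2d(f[i], f[i], 3, rng, eq_lr=eq), nn.LeakyReLU(lk),
                nn.PixelNorm(eps),
            ))
        self.to_image = [nn.Conv2d(f[i], config.output_channels, 1, rng,
                                   gain=0.3, eq_lr=eq)
                         for i in range(config.n_stages)]
        self._trace = None

    def parameters(self) -> list[nn.Parameter]:
        out = []
        for layer in [self.base_dense, self.base_conv, *self.to_image]:
            out.extend(layer.parameters())
        for blk in self.blocks:
            for layer in blk:
                out.extend(layer.parameters())
        return out

    def forward(self, z: np.ndarray, stage: int, alpha: float) -> np.ndarray:
        _check_stage(self.config, stage)
        f0 = self.config.filters_per_stage[0]
        n = z.shape[0]
        h = self.base_dense.forward(z.astype(DTYPE)).reshape(n, f0, 4, 4)
        h = self.base_norm.forward(self.base_act.forward(h))
        h = self.base_norm2.forward(self.base_act2.forward(self.base_conv.forward(h)))
        prev = None
        for i in range(1, stage + 1):
            up, c1, a1, n1, c2, a2, n2 = self.blocks[i - 1]
            if i == stage:
                prev = h
            h = up.forward(h)
            if i == stage:
                self._up_cache = h          # upscaled coarse features
            h = n1.forward(a1.forward(c1.forward(h)))
            h = n2.forward(a2.forward(c2.forward(h)))
        fine = self.to_image[stage].forward(h)
        self._stage, self._alpha = stage, float(alpha)
        if stage > 0 and alpha < 1.0:
            coarse_img = self.to_image[stage - 1].forward(prev)
            coarse_up = nn.upsample2x(coarse_img)
            self._blend = True
            return fade_in_blend(coarse_up, fine, alpha)
        self._blend = False
        return fine

    def backward(self, dy: np.ndarray) -> None:
        stage, alpha = self._stage, self._alpha
        if self._blend:
            d_fine = DTYPE(alpha) * dy
            d_coarse_up = (1 - DTYPE(alpha)) * dy
            n, c, h2, w2 = d_coarse_up.shape
            d_coarse_img = d_coarse_up.reshape(
                n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
            d_prev_skip = self.to_image[stage - 1].backward(d_coarse_img)
        else:
            d_fine = dy
            d_prev_skip = None
        dh = self.to_image[stage].backward(d_fine)
        for i in range(stage, 0, -1):
            up, c1, a1, n1, c2, a2, n2 = self.blocks[i - 1]
            dh = c1.backward(a1.backward(n1.backward(
                c2.backward(a2.backward(n2.backward(dh))))))
            dh = up.backward(dh)
            if i == stage and d_prev_skip is not None:
                dh = dh + d_prev_skip
        dh = self.base_conv.backward(self.base_act2.backward(
            self.base_norm2.backward(dh)))
        dh = self.base_act.backward(self.base_norm.backward(dh))
        self.base_dense.backward(dh.reshape(dh.shape[0], -1))


class Discriminator:
    """Progressive critic; mirrors the generator's filter schedule in reverse."""

    def __init__(self, config: GANConfig, rng: np.random.Generator):
        self.config = config
        f = config.filters_per_stage
        lk = config.leakiness
        eq = config.equalized_lr
        self.from_image = [nn.Conv2d(config.output_channels, f[i], 1, rng,
                                     eq_lr=eq)
                           for i in range(config.n_stages)]
        self.blocks = []            # per stage >= 1: (c1, a1, c2, a2, pool)
        for i in range(1, config.n_stages):
            self.blocks.append((
                nn.Conv2d(f[i], f[i], 3, rng, eq_lr=eq), nn.LeakyReLU(lk),
                nn.Conv2d(f[i], f[i - 1], 3, rng, eq_lr=eq), nn.LeakyReLU(lk),
                nn.AvgPool2x(),
            ))
        self.mbstd = nn.MinibatchStdDev()
        self.final_conv = nn.Conv2d(f[0] + 1, f[0], 3, rng, eq_lr=eq)
        self.final_act = nn.LeakyReLU(lk)
        self.final_dense = nn.Dense(f[0] * 16, f[0], rng, eq_lr=eq)  # 4x4 conv
        self.final_act2 = nn.LeakyReLU(lk)
        self.score = nn.Dense(f[0], 1, rng, eq_lr=eq)

    def parameters(self) -> list[nn.Parameter]:
        out = []
        for layer in [*self.from_image, self.final_conv, self.final_dense,
                      self.score]:
            out.extend(layer.parameters())
        for blk in self.blocks:
            for layer in blk:
                out.extend(layer.parameters())
        return out

    def forward(self, x: np.ndarray, stage: int, alpha: float) -> np.ndarray:
        _check_stage(self.config, stage)
        x = x.astype(DTYPE, copy=False)
        self._stage, self._alpha = stage, float(alpha)
        self._blend = stage > 0 and alpha < 1.0
        h = self.from_image[stage].forward(x)
        for i in range(stage, 0, -1):
            c1, a1, c2, a2, pool = self.blocks[i - 1]
            h = pool.forward(a2.forward(c2.forward(a1.forward(c1.forward(h)))))
            if i == stage and self._blend:
                coarse = self.from_image[stage - 1].forward(
                    nn.avgpool2x(x))
                h = fade_in_blend(coarse, h, alpha)
                self._x_shape = x.shape
        h = self.mbstd.forward(h)
        h = self.final_act.forward(self.final_conv.forward(h))
        self._pre_dense_shape = h.shape
        h = self.final_act2.forward(self.final_dense.forward(
            h.reshape(h.shape[0], -1)))
        return self.score.forward(h)

    def backward(self, dscore: np.ndarray) -> np.ndarray:
        stage, alpha = self._stage, self._alpha
        dh = self.score.backward(dscore.astype(DTYPE, copy=False))
        dh = self.final_dense.backward(self.final_act2.backward(dh))
        dh = dh.reshape(self._pre_dense_shape)
        dh = self.final_conv.backward(self.final_act.backward(dh))
        dh = self.mbstd.backward(dh)
        dx_skip = None
        for i in range(1, stage + 1):
            c1, a1, c2, a2, pool = self.blocks[i - 1]
            if i == stage and self._blend:
                d_coarse = (1 - DTYPE(alpha)) * dh
                d_fine = DTYPE(alpha) * dh
                dxc = self.from_image[stage - 1].backward(d_coarse)
                dx_skip = dxc.repeat(2, axis=2).repeat(2, axis=3) * DTYPE(0.25)
                dh = d_fine
            dh = pool.backward(dh)
            dh = c1.backward(a1.backward(c2.backward(a2.backward(dh))))
        dx = self.from_image[stage].backward(dh)
        if dx_skip is not None:
            dx = dx + dx_skip
        return dx


# ---------------------------------------------------------------------------
# objective


def critic_losses(real_scores: np.ndarray, fake_scores: np.ndarray,
                  gradient_penalty: float = 0.0,
                  gp_weight: float = 0.0) -> tuple[float, float]:
    """Wasserstein critic and generator losses.

    critic = mean(fake) - mean(real) + gp_weight * gradient_penalty;
    generator = -mean(fake).
    """
    real = np.asarray(real_scores, dtype=np.float64).ravel()
    fake = np.asarray(fake_scores, dtype=np.float64).ravel()
    if real.size == 0 or fake.size == 0:
        raise ValueError("score vectors must be non-empty")
    critic = float(fake.mean() - real.mean() + gp_weight * gradient_penalty)
    gen = float(-fake.mean())
    return critic, gen


# ---------------------------------------------------------------------------
# training


@dataclass
class LogRecord:
    step: int
    stage: int
    alpha: float
    critic_loss: float
    generator_loss: float


@dataclass
class TrainingLog:
    records: list[LogRecord] = field(default_factory=list)

    def append(self, rec: LogRecord) -> None:
        self.records.append(rec)

    def losses(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.array([r.critic_loss for r in self.records])
        g = np.array([r.generator_loss for r in self.records])
        return c, g


class GeneratorModel:
    """A trained generator frozen at a growth state, plus sampling helpers."""

    def __init__(self, generator: Generator, config: GANConfig,
                 state: GrowthState):
        self.generator = generator
        self.config = config
        self.state = state

    @property
    def resolution(self) -> int:
        return self.config.stage_resolutions[self.state.current_stage]

    def save(self, path: str | Path) -> None:
        arrays = {f"p{i}": p.value for i, p in
                  enumerate(self.generator.parameters())}
        meta = {"config": asdict(self.config), "state": asdict(self.state)}
        np.savez(Path(path), __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "GeneratorModel":
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            config = GANConfig(**meta["config"])
            state = GrowthState(**meta["state"])
            gen = Generator(config, np.random.default_rng(0))
            for i, p in enumerate(gen.parameters()):
                p.value = data[f"p{i}"].astype(DTYPE)
        return cls(gen, config, state)


def _dataset_to_array(dataset, max_resolution: int) -> np.ndarray:
    """Load training images as (N, 1, R, R) in [-1, 1]."""
    from .io import read_frame
    from .phantom import PhantomDataset

    if isinstance(dataset, PhantomDataset):
        base = Path(dataset.manifest_path).parent
        paths = [base / e.frame for e in dataset.entries]
    elif isinstance(dataset, (str, Path)):
        paths = sorted(Path(dataset).glob("*.png"))
    else:  # already a list of ImageFrame / arrays
        frames = [f.pixels if isinstance(f, ImageFrame) else np.asarray(f)
                  for f in dataset]
        paths = None
    if paths is not None:
        frames = [read_frame(p).pixels for p in paths]
    if not frames:
        raise EmptyDatasetError("no training images found")
    arr = np.stack(frames)[:, None].astype(DTYPE)
    while arr.shape[-1] > max_resolution:
        arr = nn.avgpool2x(arr)
    return arr * 2.0 - 1.0


def downscale_to(images: np.ndarray, resolution: int) -> np.ndarray:
    out = images
    while out.shape[-1] > resolution:
        out = nn.avgpool2x(out)
    return out


def train_pggan(dataset, config: GANConfig, schedule: GrowthSchedule,
                rng_seed: int) -> tuple[GeneratorModel, TrainingLog]:
    """Run the progressive training loop over all scheduled stages.

    Stage alpha rises linearly from 0 to 1 over the stage's fade window
    (``fade_fraction`` of its steps); stage 0 trains at alpha = 1.  One critic
    update and one generator update per step.  Raises TrainingDivergedError on
    the first non-finite loss (the partial log is attached to the exception).
    """
    if schedule.n_stages > config.n_stages:
        raise ConfigError("schedule has more stages than the config supports")
    max_res = config.stage_resolutions[schedule.n_stages - 1]
    images = _dataset_to_array(dataset, max_res)

    rng = np.random.default_rng(rng_seed)
    gen = Generator(config, np.random.default_rng(rng.integers(2 ** 31)))
    disc = Discriminator(config, np.random.default_rng(rng.integers(2 ** 31)))
    opt_g = nn.Adam(gen.parameters(), lr=config.learning_rate,
                    beta1=config.adam_beta1, beta2=config.adam_beta2)
    opt_d = nn.Adam(disc.parameters(), lr=config.learning_rate,
                    beta1=config.adam_beta1, beta2=config.adam_beta2)

    log = TrainingLog()
    state = GrowthState()
    global_step = 0
    for stage in range(schedule.n_stages):
        res = config.stage_resolutions[stage]
        reals = downscale_to(images, res)
        n_steps = schedule.steps_per_stage[stage]
        batch = min(schedule.batch_per_stage[stage], reals.shape[0])
        fade_steps = int(schedule.fade_fraction * n_steps)
        for step in range(n_steps):
            if stage == 0 or fade_steps == 0:
                alpha = 1.0
            else:
                alpha = min(1.0, step / fade_steps)
            idx = rng.choice(reals.shape[0], size=batch, replace=False)
            x_real = reals[idx]
            z = rng.standard_normal((batch, config.latent_dim)).astype(DTYPE)

            # --- critic update
            x_fake = gen.forward(z, stage, alpha)
            opt_d.zero_grad()
            s_real = disc.forward(x_real, stage, alpha)
            d_real = np.full_like(s_real, -1.0 / batch)
            d_real += 2.0 * config.drift_weight * s_real / batch  # drift term
            disc.backward(d_real)
            s_fake = disc.forward(x_fake, stage, alpha)
            disc.backward(np.full_like(s_fake, 1.0 / batch))
            gp_value = 0.0
            if config.stabilizer == "fd_gp" and config.gradient_penalty_weight > 0:
                gp_value = _fd_gradient_penalty(
                    disc, x_real, x_fake, stage, alpha,
                    config.gradient_penalty_weight, config.fd_epsilon, rng)
            opt_d.step()
            if config.stabilizer == "clip":
                opt_d.clip_weights(config.clip_limit)

            c_loss, _ = critic_losses(s_real, s_fake, gp_value,
                                      config.gradient_penalty_weight
                                      if config.stabilizer == "fd_gp" else 0.0)

            # --- generator update
            opt_g.zero_grad()
            opt_d.zero_grad()                       # discard critic grads
            x_fake = gen.forward(z, stage, alpha)
            s_fake = disc.forward(x_fake, stage, alpha)
            dx = disc.backward(np.full_like(s_fake, -1.0 / batch))
            gen.backward(dx)
            opt_g.step()
            _, g_loss = critic_losses(s_real, s_fake)

            state = GrowthState(stage, alpha, global_step)
            log.append(LogRecord(global_step, stage, alpha, c_loss, g_loss))
            if not (np.isfinite(c_loss) and np.isfinite(g_loss)):
                err = TrainingDivergedError(
                    f"non-finite loss at step {global_step} (stage {stage})")
                err.log = log
                raise err
            global_step += 1

    return GeneratorModel(gen, config, state), log


def _fd_gradient_penalty(disc: Discriminator, x_real: np.ndarray,
                         x_fake: np.ndarray, stage: int, alpha: float,
                         weight: float, fd_eps: float,
                         rng: np.random.Generator) -> float:
    """Finite-difference directional gradient penalty, accumulated into grads.

    Penalizes ((D(x+eps*v) - D(x)) / (eps*||v||_scaled) - 1)^2 at points x on
    the real->fake line, with v the real->fake direction: a first-order
    estimator of the unit-slope constraint on the critic along that line.
    """
    batch = x_real.shape[0]
    u = rng.uniform(size=(batch, 1, 1, 1)).astype(DTYPE)
    x_hat = x_real + u * (x_fake - x_real)
    v = x_fake - x_real
    vnorm = np.sqrt(np.sum(np.square(v.astype(np.float64)), axis=(1, 2, 3),
                           keepdims=True)) + 1e-12
    v_unit = (v / vnorm).astype(DTYPE)
    s0 = disc.forward(x_hat, stage, alpha)
    slope0 = s0.astype(np.float64).ravel()
    s1 = disc.forward(x_hat + DTYPE(fd_eps) * v_unit, stage, alpha)
    slope = (s1.astype(np.float64).ravel() - slope0) / fd_eps
    resid = slope - 1.0
    # d penalty / d s1 = 2 resid / (eps * batch); d / d s0 = -that
    coeff = (2.0 * weight * resid / (fd_eps * batch)).astype(DTYPE)
    disc.backward(coeff[:, None])                 # through the s1 pass
    s0b = disc.forward(x_hat, stage, alpha)       # re-prime cache for s0 pass
    disc.backward(-coeff[:, None])
    del s0b
    return float(np.mean(resid ** 2))


def sample_synthetic(model: GeneratorModel, n: int, rng_seed: int,
                     batch: int = 32) -> list[ImageFrame]:
    """Draw n frames from the generator at its trained resolution, in [0, 1]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    frames: list[ImageFrame] = []
    stage = model.state.current_stage
    while len(frames) < n:
        k = min(batch, n - len(frames))
        z = rng.standard_normal((k, model.config.latent_dim)).astype(DTYPE)
        out = model.generator.forward(z, stage, 1.0)
        out = np.clip((out + 1.0) / 2.0, 0.0, 1.0)
        for i in range(k):
            frames.append(ImageFrame(out[i, 0].astype(np.float64)))
    return frames
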