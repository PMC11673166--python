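"""Statistics-conditioned GAN.

The generator receives random noise concatenated with a (normalized)
statistics vector, and the same statistics are injected a second time
after two hidden layers so the network keeps attending to its
conditioning while it reconstructs the table.  One forward pass emits an
entire patient table (766 x 9 by default) with entries in [0, 1], which
are then denormalized through the schema's per-column ranges.  The
discriminator scores a flattened table, with the statistics concatenated
onto its feature map at a configurable middle layer.

Training alternates the usual adversarial updates (Adam, discriminator
learning rate below the generator's to damp mode collapse) with the
table-similarity loss added to the generator objective:

    L_D = -(1/m) sum_i [ log D(x_i) + log(1 - D(G(z_i))) ]
    L_G =  (1/m) sum_i   log(1 - D(G(z_i)))  +  L_TS

Networks are small fully connected stacks (LeakyReLU hidden units,
sigmoid output) implemented directly on numpy with hand-written
backpropagation; the table-similarity term uses the analytic subgradient
from :mod:`statsynth.ts_loss`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import (
    STAT_MAX,
    STAT_MEAN,
    STAT_MIN,
    STAT_OR,
    STAT_PREVALENCE,
    STAT_RISKY,
    StatisticsVector,
    Table,
    TableSchema,
    ValidationError,
)
from .synthesis import TrainingCorpus
from .ts_loss import ts_batch_loss_and_grad

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "TrainConfig",
    "TrainHistory",
    "Generator",
    "Discriminator",
    "build_generator",
    "build_discriminator",
    "discriminator_loss",
    "generator_loss",
    "train",
    "generate_table",
    "iterations_per_epoch",
    "save_checkpoint",
    "load_checkpoint",
    "normalize_table",
    "denormalize_table",
    "normalize_stats",
]

LEAKY_SLOPE = 0.2
SCORE_EPS = 1e-7          # keeps log terms finite
ADAM_BETAS = (0.5, 0.999)  # common GAN-stabilizing choice


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorConfig:
    stat_dim: int
    noise_dim: int = 128
    layer_widths: tuple[int, ...] = (256, 256, 256)
    reinjection_layer: int = 2          # statistics re-enter after this many layers
    output_shape: tuple[int, int] = (766, 9)

    def __post_init__(self) -> None:
        n_layers = len(self.layer_widths) + 1   # + output layer
        if not 1 <= self.reinjection_layer < n_layers:
            raise ValidationError("reinjection_layer must be < number of layers")
        if min(self.output_shape) < 1 or self.stat_dim < 1 or self.noise_dim < 1:
            raise ValidationError("generator dimensions must be positive")


@dataclass(frozen=True)
class DiscriminatorConfig:
    stat_dim: int
    input_shape: tuple[int, int] = (766, 9)
    layer_widths: tuple[int, ...] = (256, 128)
    stat_injection_layer: int = 1       # statistics concatenated after this layer

    def __post_init__(self) -> None:
        n_layers = len(self.layer_widths) + 1
        if not 1 <= self.stat_injection_layer < n_layers:
            raise ValidationError("stat_injection_layer must be < number of layers")


@dataclass(frozen=True)
class TrainConfig:
    lr_generator: float = 0.0001
    lr_discriminator: float = 0.00005
    batch_size: int = 64
    max_epochs: int = 70
    drop_last_batch: bool = True
    seed: int = 0
    monitor_feature_pair: tuple[int, int] = (5, 7)

    def __post_init__(self) -> None:
        if self.lr_generator <= 0 or self.lr_discriminator <= 0:
            raise ValidationError("learning rates must be positive")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")


@dataclass
class TrainHistory:
    """Per-iteration losses and per-epoch scatter snapshots."""

    disc_loss: list[float] = field(default_factory=list)
    gen_loss: list[float] = field(default_factory=list)
    ts_loss: list[float] = field(default_factory=list)
    #: (epoch, x values, y values) of the monitored feature pair, one per epoch
    scatter: list[tuple[int, np.ndarray, np.ndarray]] = field(default_factory=list)

    @property
    def n_iterations(self) -> int:
        return len(self.gen_loss)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": np.arange(self.n_iterations),
            "disc_loss": self.disc_loss,
            "gen_loss": self.gen_loss,
            "ts_loss": self.ts_loss,
        })

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def iterations_per_epoch(n_pairs: int, batch_size: int,
                         drop_last: bool = True) -> int:
    if drop_last:
        return n_pairs // batch_size
    return -(-n_pairs // batch_size)


# ---------------------------------------------------------------------------
# normalization between schema units and network units
# ---------------------------------------------------------------------------

def normalize_table(values: np.ndarray, schema: TableSchema) -> np.ndarray:
    lo = np.array([c.min_value for c in schema.columns])
    rng = np.array([max(c.value_range, 1e-12) for c in schema.columns])
    return (values - lo) / rng


def denormalize_table(unit_values: np.ndarray, schema: TableSchema) -> np.ndarray:
    lo = np.array([c.min_value for c in schema.columns])
    rng = np.array([max(c.value_range, 1e-12) for c in schema.columns])
    return unit_values * rng + lo


def normalize_stats(values: np.ndarray, schema: TableSchema) -> np.ndarray:
    """Map a raw statistics vector onto comparable [0, 1]-ish network units.

    min/max/mean are scaled by their column's range, fractions pass
    through, odds ratios are squashed by x/(1+x).  Pure function of the
    schema, so the same statistics always condition the nets identically.
    """
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    for i, (col, kind) in enumerate(schema.statistic_menu()):
        c = schema.column(col)
        v = values[i]
        if kind in (STAT_MIN, STAT_MAX, STAT_MEAN):
            out[i] = (v - c.min_value) / max(c.value_range, 1e-12)
        elif kind in (STAT_RISKY, STAT_PREVALENCE):
            out[i] = v
        elif kind == STAT_OR:
            out[i] = v / (1.0 + v)
    return out


# ---------------------------------------------------------------------------
# dense layers with hand-written backprop
# ---------------------------------------------------------------------------

class _Dense:
    def __init__(self, fan_in: int, fan_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
        self.b = np.zeros(fan_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.dW += self._x.T @ g
        self.db += g.sum(axis=0)
        return g @ self.W.T

    def zero_grad(self) -> None:
        self.dW[:] = 0.0
        self.db[:] = 0.0


def _leaky(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0, z, LEAKY_SLOPE * z)


def _leaky_grad(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0, 1.0, LEAKY_SLOPE)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


class _Adam:
    def __init__(self, layers: list[_Dense], lr: float):
        self.layers = layers
        self.lr = lr
        self.b1, self.b2 = ADAM_BETAS
        self.eps = 1e-8
        self.t = 0
        self.m = [np.zeros_like(p) for l in layers for p in (l.W, l.b)]
        self.v = [np.zeros_like(p) for l in layers for p in (l.W, l.b)]

    def step(self) -> None:
        self.t += 1
        params = [p for l in self.layers for p in (l.W, l.b)]
        grads = [g for l in self.layers for g in (l.dW, l.db)]
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# generator / discriminator
# ---------------------------------------------------------------------------

class Generator:
    """(noise, statistics) -> table in [0, 1]^{n_rows x n_cols}."""

    def __init__(self, config: GeneratorConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        n_out = config.output_shape[0] * config.output_shape[1]
        dims_in = config.noise_dim + config.stat_dim
        self.layers: list[_Dense] = []
        widths = list(config.layer_widths) + [n_out]
        for li, w in enumerate(widths):
            if li == config.reinjection_layer:
                dims_in += config.stat_dim       # second statistics injection
            self.layers.append(_Dense(dims_in, w, rng))
            dims_in = w
        self._cache: dict = {}

    def forward(self, noise: np.ndarray, stats: np.ndarray) -> np.ndarray:
        noise = np.atleast_2d(np.asarray(noise, dtype=float))
        stats = np.atleast_2d(np.asarray(stats, dtype=float))
        if stats.shape[1] != self.config.stat_dim:
            raise ValidationError(
                f"expected stat_dim {self.config.stat_dim}, got {stats.shape[1]}")
        if noise.shape[1] != self.config.noise_dim:
            raise ValidationError(
                f"expected noise_dim {self.config.noise_dim}, got {noise.shape[1]}")
        h = np.concatenate([noise, stats], axis=1)
        zs = []
        for li, layer in enumerate(self.layers):
            if li == self.config.reinjection_layer:
                h = np.concatenate([h, stats], axis=1)
            z = layer.forward(h)
            zs.append(z)
            h = _leaky(z) if li < len(self.layers) - 1 else _sigmoid(z)
        self._cache = {"zs": zs, "out": h}
        B = noise.shape[0]
        return h.reshape(B, *self.config.output_shape)

    def backward(self, dout: np.ndarray) -> None:
        """Accumulate parameter gradients; dout has the output's shape."""
        y = self._cache["out"]
        g = dout.reshape(y.shape) * y * (1.0 - y)        # through sigmoid
        for li in range(len(self.layers) - 1, -1, -1):
            g = self.layers[li].backward(g)
            if li == self.config.reinjection_layer:
                g = g[:, : g.shape[1] - self.config.stat_dim]
            if li > 0:
                g = g * _leaky_grad(self._cache["zs"][li - 1])

    def zero_grad(self) -> None:
        for l in self.layers:
            l.zero_grad()


class Discriminator:
    """(table, statistics) -> probability of being real, strictly in (0, 1)."""

    def __init__(self, config: DiscriminatorConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        dims_in = config.input_shape[0] * config.input_shape[1]
        self.layers: list[_Dense] = []
        widths = list(config.layer_widths) + [1]
        for li, w in enumerate(widths):
            if li == config.stat_injection_layer:
                dims_in += config.stat_dim
            self.layers.append(_Dense(dims_in, w, rng))
            dims_in = w
        self._cache: dict = {}

    def forward(self, tables: np.ndarray, stats: np.ndarray) -> np.ndarray:
        tables = np.asarray(tables, dtype=float)
        stats = np.atleast_2d(np.asarray(stats, dtype=float))
        if tables.ndim == 3:
            tables = tables.reshape(tables.shape[0], -1)
        tables = np.atleast_2d(tables)
        if tables.shape[1] != self.config.input_shape[0] * self.config.input_shape[1]:
            raise ValidationError("discriminator input shape mismatch")
        h = tables
        zs = []
        for li, layer in enumerate(self.layers):
            if li == self.config.stat_injection_layer:
                h = np.concatenate([h, stats], axis=1)
            z = layer.forward(h)
            zs.append(z)
            h = _leaky(z) if li < len(self.layers) - 1 else _sigmoid(z)
        p = np.clip(h[:, 0], SCORE_EPS, 1.0 - SCORE_EPS)
        self._cache = {"zs": zs, "p": h[:, 0]}
        return p

    def backward(self, dp: np.ndarray) -> np.ndarray:
        """Accumulate parameter grads; return gradient w.r.t. the input table
        (flattened), for backpropagating into the generator."""
        p = self._cache["p"]
        g = (dp * p * (1.0 - p))[:, None]               # through sigmoid
        for li in range(len(self.layers) - 1, -1, -1):
            g = self.layers[li].backward(g)
            if li == self.config.stat_injection_layer:
                g = g[:, : g.shape[1] - self.config.stat_dim]
            if li > 0:
                g = g * _leaky_grad(self._cache["zs"][li - 1])
        return g

    def zero_grad(self) -> None:
        for l in self.layers:
            l.zero_grad()


def build_generator(config: GeneratorConfig, seed: int = 0) -> Generator:
    return Generator(config, seed=seed)


def build_discriminator(config: DiscriminatorConfig, seed: int = 0) -> Discriminator:
    return Discriminator(config, seed=seed)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(p, dtype=float), SCORE_EPS, 1.0 - SCORE_EPS)


def discriminator_loss(real_scores, fake_scores) -> float:
    """-(1/m) sum [log D(x) + log(1 - D(G(z)))], minimized by the critic."""
    r, f = _clamp(real_scores), _clamp(fake_scores)
    return float(-(np.mean(np.log(r)) + np.mean(np.log(1.0 - f))))


def generator_loss(fake_scores, ts: float) -> float:
    """(1/m) sum log(1 - D(G(z))) + L_TS (the saturating form, plus the
    table-similarity term)."""
    if ts < 0:
        raise ValidationError("generator_loss: ts must be >= 0")
    f = _clamp(fake_scores)
    return float(np.mean(np.log(1.0 - f)) + ts)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _load_corpus_arrays(corpus: TrainingCorpus) -> tuple[np.ndarray, np.ndarray]:
    schema = corpus.schema
    stats = np.stack([normalize_stats(s.values, schema)
                      for s in corpus.load_statistics()])
    tables = np.stack([normalize_table(corpus.load_table(i).values, schema)
                       for i in range(corpus.n_pairs)])
    return stats, tables


def train(corpus: TrainingCorpus, gen_cfg: GeneratorConfig,
          disc_cfg: DiscriminatorConfig, train_cfg: TrainConfig,
          ) -> tuple[Generator, TrainHistory]:
    """Alternating adversarial training on (statistics, table) pairs.

    The real table fed to the discriminator is the corpus table paired
    with the same statistics row the generator is conditioned on.
    Incomplete trailing batches are dropped by default, so an epoch runs
    ``floor(n_pairs / batch_size)`` iterations.
    """
    stats_all, tables_all = _load_corpus_arrays(corpus)
    n_pairs = stats_all.shape[0]
    if gen_cfg.stat_dim != stats_all.shape[1]:
        raise ValidationError(
            f"gen_cfg.stat_dim {gen_cfg.stat_dim} != corpus statistics width "
            f"{stats_all.shape[1]}")
    m = train_cfg.batch_size
    n_iter = iterations_per_epoch(n_pairs, m, train_cfg.drop_last_batch)
    if n_iter == 0:
        raise ValidationError("batch_size larger than the corpus")

    rng = np.random.default_rng(train_cfg.seed)
    G = Generator(gen_cfg, seed=int(rng.integers(2**31 - 1)))
    D = Discriminator(disc_cfg, seed=int(rng.integers(2**31 - 1)))
    opt_g = _Adam(G.layers, train_cfg.lr_generator)
    opt_d = _Adam(D.layers, train_cfg.lr_discriminator)
    history = TrainHistory()
    schema = corpus.schema

    for epoch in range(train_cfg.max_epochs):
        order = rng.permutation(n_pairs)
        last_fake = None
        for it in range(n_iter):
            idx = order[it * m: (it + 1) * m]
            stats_b = stats_all[idx]
            real_b = tables_all[idx]
            real_flat = real_b.reshape(len(idx), -1)

            # --- discriminator update
            z = rng.standard_normal((len(idx), gen_cfg.noise_dim))
            fake = G.forward(z, stats_b)
            fake_flat = fake.reshape(len(idx), -1)
            D.zero_grad()
            p_real = D.forward(real_flat, stats_b)
            D.backward(-1.0 / (len(idx) * p_real))
            p_fake = D.forward(fake_flat, stats_b)
            D.backward(1.0 / (len(idx) * (1.0 - p_fake)))
            d_loss = discriminator_loss(p_real, p_fake)
            opt_d.step()

            # --- generator update
            z = rng.standard_normal((len(idx), gen_cfg.noise_dim))
            fake = G.forward(z, stats_b)
            fake_flat = fake.reshape(len(idx), -1)
            D.zero_grad()
            p_fake = D.forward(fake_flat, stats_b)
            d_table = D.backward(-1.0 / (len(idx) * (1.0 - p_fake)))
            D.zero_grad()                       # discriminator is frozen here
            ts_val, ts_grad = ts_batch_loss_and_grad(real_b, fake)
            G.zero_grad()
            G.backward(d_table.reshape(fake.shape) + ts_grad)
            opt_g.step()
            g_loss = generator_loss(p_fake, ts_val)

            if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, iteration {it}: "
                    f"disc={d_loss}, gen={g_loss}")
            history.disc_loss.append(d_loss)
            history.gen_loss.append(g_loss)
            history.ts_loss.append(ts_val)
            last_fake = fake[0]

        if last_fake is not None:
            snap = denormalize_table(last_fake, schema)
            i, j = train_cfg.monitor_feature_pair
            i %= schema.n_cols
            j %= schema.n_cols
            history.scatter.append((epoch, snap[:, i].copy(), snap[:, j].copy()))
    return G, history


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_table(generator: Generator, stats: StatisticsVector,
                   schema: TableSchema, seed: int = 0,
                   postprocess: bool = True) -> Table:
    """One seeded forward pass; optional postprocessing clips cells to
    column ranges, rounds count columns, thresholds the outcome at 0.5 and
    guarantees both outcome classes appear."""
    z = np.random.default_rng(seed).standard_normal((1, generator.config.noise_dim))
    unit = generator.forward(z, normalize_stats(stats.values, schema)[None, :])[0]
    values = denormalize_table(unit, schema)
    if postprocess:
        raw_outcome = values[:, schema.outcome_index].copy()
        for j, c in enumerate(schema.columns):
            values[:, j] = np.clip(values[:, j], c.min_value, c.max_value)
            if c.kind == "count":
                values[:, j] = np.round(values[:, j])
        oj = schema.outcome_index
        values[:, oj] = (raw_outcome > 0.5).astype(float)
        y = values[:, oj]
        if y.sum() == 0:
            values[np.argmax(raw_outcome), oj] = 1.0
        elif y.sum() == len(y):
            values[np.argmin(raw_outcome), oj] = 0.0
    return Table(values, schema)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, generator: Generator, schema: TableSchema,
                    discriminator: Discriminator | None = None) -> None:
    """Parameters + configs + schema in one .npz file."""
    arrays: dict[str, np.ndarray] = {}
    for i, l in enumerate(generator.layers):
        arrays[f"g_W{i}"], arrays[f"g_b{i}"] = l.W, l.b
    meta = {"gen_cfg": generator.config.__dict__ | {
                "layer_widths": list(generator.config.layer_widths),
                "output_shape": list(generator.config.output_shape)},
            "schema": schema.to_yaml()}
    if discriminator is not None:
        for i, l in enumerate(discriminator.layers):
            arrays[f"d_W{i}"], arrays[f"d_b{i}"] = l.W, l.b
        meta["disc_cfg"] = discriminator.config.__dict__ | {
            "layer_widths": list(discriminator.config.layer_widths),
            "input_shape": list(discriminator.config.input_shape)}
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[Generator, TableSchema]:
    data = np.load(path)
    meta = json.loads(bytes(data["meta"]).decode())
    gc = meta["gen_cfg"]
    cfg = GeneratorConfig(stat_dim=gc["stat_dim"], noise_dim=gc["noise_dim"],
                          layer_widths=tuple(gc["layer_widths"]),
                          reinjection_layer=gc["reinjection_layer"],
                          output_shape=tuple(gc["output_shape"]))
    gen = Generator(cfg, seed=0)
    for i, l in enumerate(gen.layers):
        l.W = data[f"g_W{i}"].copy()
        l.b = data[f"g_b{i}"].copy()
    return gen, TableSchema.from_yaml(meta["schema"])
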