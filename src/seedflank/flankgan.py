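"""Conditional adversarial model of flanking sequence given fixed seed motifs.

The generator G maps a seed-constrained input (hard one-hot rows at motif
positions, random row-stochastic rows elsewhere — the latent draw z) to a
relaxed one-hot matrix over the whole window; the emitted matrix always has
its seed rows overwritten with the motifs, so seeds are preserved by
construction.  The critic D scores (motif encoding, sequence encoding) pairs.
Training is a Wasserstein GAN with gradient penalty plus an L1 reconstruction
term on flanking positions, as in conditional image translation models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .layers import (Adam, Conv1d, Dense, Module, MultiHeadAttention,
                     ResBlock, global_avg_pool, load_checkpoint,
                     save_checkpoint)
from .seqcore import (GeneratorInput, SeedSpec, build_generator_input,
                      decode_onehot, encode_onehot, random_flank_rows)


@dataclass
class CGANTrainConfig:
    batch_size: int = 32
    total_batches: int = 50_000          # generator steps
    learning_rate: float = 1e-4
    beta1: float = 0.5
    beta2: float = 0.9
    l1_weight: float = 10.0              # Pix2Pix convention
    gp_weight: float = 10.0
    critic_steps_per_gen_step: int = 5
    loss_form: str = "wgan-gp"           # or "log" (vanilla adversarial loss)
    checkpoint_every: int = 0            # 0 disables
    checkpoint_path: str = ""
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.batch_size, self.total_batches,
               self.critic_steps_per_gen_step) <= 0:
            raise ValueError("counts must be positive")
        if self.l1_weight < 0 or self.gp_weight < 0:
            raise ValueError("l1_weight and gp_weight must be >= 0")
        if self.loss_form not in ("wgan-gp", "log"):
            raise ValueError("loss_form must be 'wgan-gp' or 'log'")


class GeneratorModel(Module):
    """Per-position embedding -> multi-head attention -> two conv resblocks ->
    row-softmax projection to L x 4."""

    def __init__(self, window_length, d_k=64, heads=4, kernel=3, rng_seed=0):
        rng = np.random.default_rng(rng_seed)
        self.config = {"window_length": window_length, "d_k": d_k,
                       "heads": heads, "kernel": kernel, "rng_seed": rng_seed,
                       "kind": "generator"}
        self.window_length = window_length
        self.embed = Dense(4, d_k, rng)
        self.attn = MultiHeadAttention(d_k, heads, rng)
        self.res1 = ResBlock(d_k, kernel, rng)
        self.res2 = ResBlock(d_k, kernel, rng)
        self.proj = Dense(d_k, 4, rng)

    def forward_tensor(self, x: ad.Tensor, seed_mask=None,
                       seed_rows=None) -> ad.Tensor:
        """x: (B, L, 4) relaxed encodings; returns row-stochastic (B, L, 4).

        If ``seed_mask``/``seed_rows`` are given, seed rows of the output are
        replaced by the hard rows (constraint applied inside the graph, so
        their gradient contribution is exactly zero).
        """
        h = self.embed(x)
        h = ad.add(h, self.attn(h))
        h = self.res1(h)
        h = self.res2(h)
        out = ad.softmax(self.proj(h), axis=-1)
        if not np.isfinite(out.data).all():
            raise FloatingPointError("non-finite activations in generator output")
        if seed_mask is not None:
            m = seed_mask.astype(np.float64)[None, :, None]
            out = ad.add(ad.mul(out, ad.Tensor(1.0 - m)),
                         ad.Tensor(seed_rows[None] * m))
        return out


def generator_forward(model: GeneratorModel, ginput: GeneratorInput) -> np.ndarray:
    """Single-input forward pass returning the constrained L x 4 matrix."""
    seed_rows = ginput.matrix * ginput.seed_mask[:, None]
    with ad.no_grad():
        out = model.forward_tensor(ad.Tensor(ginput.matrix[None]),
                                   ginput.seed_mask, seed_rows)
    return out.data[0]


def generate_sequences(model: GeneratorModel, spec: SeedSpec, n: int,
                       rng_seed: int = 0, batch=64) -> list:
    """Sample n designs by drawing latent inputs and decoding the outputs."""
    rng = np.random.default_rng(rng_seed)
    mask = spec.seed_mask
    seed_rows = encode_onehot(spec.seed_string()) * mask[:, None]
    seqs = []
    for start in range(0, n, batch):
        b = min(batch, n - start)
        mats = np.empty((b, spec.window_length, 4))
        for i in range(b):
            mats[i] = build_generator_input(spec, int(rng.integers(2 ** 31))).matrix
        with ad.no_grad():
            out = model.forward_tensor(ad.Tensor(mats), mask, seed_rows)
        for row in out.data:
            seqs.append(spec.apply_to(decode_onehot(row)))
    return seqs


def multi_head_attention(X: np.ndarray, params: MultiHeadAttention) -> np.ndarray:
    """Apply one multi-head self-attention layer to an n_positions x d_k map."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != params.d_k:
        raise ValueError(f"expected (n, {params.d_k}) input, got {X.shape}")
    with ad.no_grad():
        out = params(ad.Tensor(X[None]))
    return out.data[0]


class CriticModel(Module):
    """Same front-end family as the generator, ending in a scalar head.

    Input is the channel-wise concatenation of the motif encoding and the
    (real or generated) sequence encoding: (B, L, 8).
    """

    def __init__(self, window_length, d_k=64, heads=4, kernel=3, rng_seed=1):
        rng = np.random.default_rng(rng_seed)
        self.config = {"window_length": window_length, "d_k": d_k,
                       "heads": heads, "kernel": kernel, "rng_seed": rng_seed,
                       "kind": "critic"}
        self.window_length = window_length
        self.embed = Dense(8, d_k, rng)
        self.attn = MultiHeadAttention(d_k, heads, rng)
        self.res1 = ResBlock(d_k, kernel, rng)
        self.res2 = ResBlock(d_k, kernel, rng)
        self.head = Dense(d_k, 1, rng)

    def forward_tensor(self, motif_enc: ad.Tensor, seq_enc: ad.Tensor) -> ad.Tensor:
        x = ad.concat([motif_enc, seq_enc], axis=2)
        h = self.embed(x)
        h = ad.add(h, self.attn(h))
        h = self.res1(h)
        h = self.res2(h)
        pooled = global_avg_pool(h)
        return self.head(pooled)  # (B, 1)


def critic_forward(model: CriticModel, motif_encoding: np.ndarray,
                   seq_encoding: np.ndarray) -> float:
    if motif_encoding.shape != seq_encoding.shape or motif_encoding.shape[1] != 4:
        raise ValueError("motif and sequence encodings must both be L x 4")
    with ad.no_grad():
        out = model.forward_tensor(ad.Tensor(motif_encoding[None]),
                                   ad.Tensor(seq_encoding[None]))
    val = float(out.data[0, 0])
    if not np.isfinite(val):
        raise FloatingPointError("non-finite critic output")
    return val


def gradient_penalty(critic: CriticModel, motif_enc: ad.Tensor,
                     real: np.ndarray, fake: np.ndarray,
                     rng: np.random.Generator) -> ad.Tensor:
    """E[(||grad_x D(m, x_hat)|| - 1)^2] at per-sample random interpolates."""
    eps = rng.uniform(size=(real.shape[0], 1, 1))
    x_hat = ad.parameter(eps * real + (1 - eps) * fake)
    score = ad.tsum(critic.forward_tensor(motif_enc, x_hat))
    (g,) = ad.grad(score, [x_hat], create_graph=True)
    norm = ad.sqrt(ad.add(ad.tsum(ad.mul(g, g), axis=(1, 2)), 1e-12))
    return ad.tmean(ad.power(ad.sub(norm, 1.0), 2.0))


def cgan_losses(gen: GeneratorModel, critic: CriticModel, real_batch: np.ndarray,
                inputs: np.ndarray, seed_mask: np.ndarray, seed_rows: np.ndarray,
                config: CGANTrainConfig, rng=None):
    """The four loss terms on one batch (numbers, no update).

    real_batch: (B, L, 4) hard encodings of real sequences; inputs: matching
    (B, L, 4) generator inputs (same seed rows, fresh latent rows).
    """
    if real_batch.shape[0] == 0:
        raise ValueError("empty batch")
    rng = np.random.default_rng(0) if rng is None else rng
    motif_enc = ad.Tensor(np.broadcast_to(
        (seed_rows * seed_mask[:, None])[None], real_batch.shape).copy())
    fake = gen.forward_tensor(ad.Tensor(inputs), seed_mask, seed_rows)
    d_fake = ad.tmean(critic.forward_tensor(motif_enc, fake.detach()))
    d_real = ad.tmean(critic.forward_tensor(motif_enc, ad.Tensor(real_batch)))
    gp = gradient_penalty(critic, motif_enc, real_batch, fake.data, rng)
    critic_loss = ad.add(ad.sub(d_fake, d_real), ad.mul(config.gp_weight, gp))
    flank = 1.0 - seed_mask.astype(np.float64)[None, :, None]
    n_flank = max(int(flank.sum()), 1)
    l1 = ad.div(ad.tsum(ad.mul(ad.absolute(ad.sub(ad.Tensor(real_batch), fake)),
                               ad.Tensor(flank))),
                float(real_batch.shape[0] * n_flank))
    d_fake_gen = ad.tmean(critic.forward_tensor(motif_enc, fake))
    gen_loss = ad.add(ad.neg(d_fake_gen), ad.mul(config.l1_weight, l1))
    return (float(critic_loss.data), float(gen_loss.data),
            float(l1.data), float(gp.data))


def _sample_batch(onehots, specs, batch_size, rng):
    idx = rng.integers(len(onehots), size=batch_size)
    real = onehots[idx]
    inputs = real.copy()
    for row, i in enumerate(idx):
        mask = specs[i].seed_mask
        inputs[row, ~mask] = random_flank_rows(int((~mask).sum()), rng)
    return real, inputs, idx


def train_cgan(dataset, specs, config: CGANTrainConfig,
               gen: GeneratorModel | None = None,
               critic: CriticModel | None = None):
    """Alternating critic/generator updates; returns models and a log.

    ``specs`` is one SeedSpec per record (or a single spec reused for all).
    The log records the four loss terms at every generator step.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    L = dataset.window_length
    if isinstance(specs, SeedSpec):
        specs = [specs] * len(dataset)
    if len(specs) != len(dataset):
        raise ValueError("one SeedSpec per record required")
    rng = np.random.default_rng(config.rng_seed)
    gen = GeneratorModel(L, rng_seed=config.rng_seed) if gen is None else gen
    critic = CriticModel(L, rng_seed=config.rng_seed + 1) if critic is None else critic
    onehots = np.stack([encode_onehot(r.seq) for r in dataset.records])
    opt_g = Adam(gen.parameters(), config.learning_rate, config.beta1, config.beta2)
    opt_d = Adam(critic.parameters(), config.learning_rate, config.beta1, config.beta2)
    log = []
    for step in range(config.total_batches):
        gp_val = 0.0
        for _ in range(config.critic_steps_per_gen_step):
            real, inputs, idx = _sample_batch(onehots, specs, config.batch_size, rng)
            mask = specs[idx[0]].seed_mask
            seed_rows = onehots[idx[0]] * mask[:, None]
            motif_enc = ad.Tensor(real * mask[None, :, None])
            with ad.no_grad():
                fake = gen.forward_tensor(ad.Tensor(inputs), mask, seed_rows)
            if config.loss_form == "wgan-gp":
                d_fake = ad.tmean(critic.forward_tensor(motif_enc, ad.Tensor(fake.data)))
                d_real = ad.tmean(critic.forward_tensor(motif_enc, ad.Tensor(real)))
                gp = gradient_penalty(critic, motif_enc, real, fake.data, rng)
                loss_d = ad.add(ad.sub(d_fake, d_real), ad.mul(config.gp_weight, gp))
                gp_val = float(gp.data)
            else:
                d_fake = critic.forward_tensor(motif_enc, ad.Tensor(fake.data))
                d_real = critic.forward_tensor(motif_enc, ad.Tensor(real))
                loss_d = ad.neg(ad.tmean(ad.add(
                    ad.log(ad.add(ad.sigmoid(d_real), 1e-12)),
                    ad.log(ad.add(ad.sub(1.0, ad.sigmoid(d_fake)), 1e-12)))))
            if not np.isfinite(loss_d.data):
                raise FloatingPointError(f"critic loss diverged at step {step}")
            opt_d.step(ad.grad(loss_d, opt_d.params))
        # generator update
        real, inputs, idx = _sample_batch(onehots, specs, config.batch_size, rng)
        mask = specs[idx[0]].seed_mask
        seed_rows = onehots[idx[0]] * mask[:, None]
        motif_enc = ad.Tensor(real * mask[None, :, None])
        fake = gen.forward_tensor(ad.Tensor(inputs), mask, seed_rows)
        if config.loss_form == "wgan-gp":
            adv = ad.neg(ad.tmean(critic.forward_tensor(motif_enc, fake)))
        else:
            adv = ad.neg(ad.tmean(ad.log(ad.add(
                ad.sigmoid(critic.forward_tensor(motif_enc, fake)), 1e-12))))
        flank = 1.0 - mask.astype(np.float64)[None, :, None]
        n_flank = max(int(flank.sum()), 1)
        l1 = ad.div(ad.tsum(ad.mul(ad.absolute(ad.sub(ad.Tensor(real), fake)),
                                   ad.Tensor(flank))),
                    float(real.shape[0] * n_flank))
        loss_g = ad.add(adv, ad.mul(config.l1_weight, l1))
        if not np.isfinite(loss_g.data):
            raise FloatingPointError(f"generator loss diverged at step {step}")
        opt_g.step(ad.grad(loss_g, opt_g.params))
        log.append({"step": step, "critic_loss": float(loss_d.data),
                    "gen_loss": float(loss_g.data), "l1": float(l1.data),
                    "gp": gp_val})
        if (config.checkpoint_every and config.checkpoint_path
                and (step + 1) % config.checkpoint_every == 0):
            save_checkpoint(config.checkpoint_path, gen, gen.config)
    return gen, critic, log


def save_generator(path, model: GeneratorModel):
    save_checkpoint(path, model, model.config)


def load_generator(path) -> GeneratorModel:
    config, arrays = load_checkpoint(path)
    model = GeneratorModel(config["window_length"], config["d_k"],
                           config["heads"], config["kernel"], config["rng_seed"])
    model.load_state_arrays(arrays)
    return model
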