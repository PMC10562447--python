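"""Sequence-to-activity predictor with saliency and embedding introspection.

Architecture: 1-D convolution -> bidirectional LSTM -> densely connected
convolutional blocks -> global average pooling -> one dense output unit.  The
pooled vector feeding the output unit is exposed as the penultimate-layer
embedding; the gradient of the prediction with respect to the one-hot input
is exposed as a saliency map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from . import autodiff as ad
from .layers import (Adam, Conv1d, Dense, LSTM, Module, global_avg_pool,
                     load_checkpoint, save_checkpoint)
from .seqcore import encode_onehot


@dataclass
class PredictorConfig:
    window_length: int = 165
    conv1_channels: int = 64
    conv1_kernel: int = 7
    lstm_hidden: int = 64
    bidirectional: bool = True
    dense_blocks: tuple = (2, 2, 4, 2)
    growth_rate: int = 32
    dense_layer_kernels: tuple = (1, 3)
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 64
    max_epochs: int = 50
    patience: int = 10
    val_fraction: float = 0.2
    zscore_activities: bool = True
    rng_seed: int = 0

    def __post_init__(self):
        if len(self.dense_blocks) != 4:
            raise ValueError("dense_blocks must list 4 block sizes")
        if self.growth_rate <= 0:
            raise ValueError("growth_rate must be positive")


class _DenseLayer(Module):
    """One DenseNet layer: kernel-1 bottleneck then kernel-3 conv emitting
    ``growth_rate`` channels, concatenated onto the running feature map."""

    def __init__(self, c_in, growth, kernels, rng):
        k1, k3 = kernels
        self.conv1 = Conv1d(c_in, 2 * growth, k1, rng)
        self.conv3 = Conv1d(2 * growth, growth, k3, rng)

    def __call__(self, x):
        h = ad.relu(self.conv1(x))
        h = ad.relu(self.conv3(h))
        return ad.concat([x, h], axis=2)


class _Transition(Module):
    """Kernel-1 compression to half the channels, then length-2 average pool."""

    def __init__(self, c_in, rng):
        self.c_out = max(c_in // 2, 1)
        self.conv = Conv1d(c_in, self.c_out, 1, rng)

    def __call__(self, x):
        h = ad.relu(self.conv(x))
        B, L, C = h.shape
        if L % 2:
            h = h[(slice(None), slice(0, L - 1))]
            L -= 1
        h = ad.reshape(h, (B, L // 2, 2, C))
        return ad.tmean(h, axis=2)


class PredictorModel(Module):
    def __init__(self, config: PredictorConfig):
        self.config = config
        rng = np.random.default_rng(config.rng_seed)
        self.conv1 = Conv1d(4, config.conv1_channels, config.conv1_kernel, rng)
        self.lstm = LSTM(config.conv1_channels, config.lstm_hidden, rng,
                         config.bidirectional)
        c = self.lstm.out_channels
        self.blocks = []
        self.transitions = []
        for bi, n_layers in enumerate(config.dense_blocks):
            block = [( _DenseLayer(c + j * config.growth_rate, config.growth_rate,
                                   config.dense_layer_kernels, rng))
                     for j in range(n_layers)]
            self.blocks.append(block)
            c += n_layers * config.growth_rate
            if bi < len(config.dense_blocks) - 1:
                tr = _Transition(c, rng)
                self.transitions.append(tr)
                c = tr.c_out
        self.embed_dim = c
        self.head = Dense(c, 1, rng)

    def _modules(self):
        # blocks is a list of lists, invisible to the base-class scan
        yield from super()._modules()
        for block in self.blocks:
            yield from block

    def forward_tensor(self, x: ad.Tensor, return_embedding=False):
        h = ad.relu(self.conv1(x))
        h = self.lstm(h)
        for bi, block in enumerate(self.blocks):
            for layer in block:
                h = layer(h)
            if bi < len(self.transitions):
                h = self.transitions[bi](h)
        emb = global_avg_pool(h)
        out = self.head(emb)
        if return_embedding:
            return out, emb
        return out


@dataclass
class SaliencyMap:
    values: np.ndarray  # L x 4
    seq: str


def _encode_batch(seqs):
    return np.stack([encode_onehot(s) for s in seqs])


def predict_activity(model: PredictorModel, seqs, batch=64,
                     destandardize=None) -> np.ndarray:
    """One predicted activity per sequence (batched forward passes)."""
    L = model.config.window_length
    for s in seqs:
        if len(s) != L:
            raise ValueError(f"sequence length {len(s)} != model window {L}")
    out = np.empty(len(seqs))
    for start in range(0, len(seqs), batch):
        chunk = seqs[start:start + batch]
        with ad.no_grad():
            y = model.forward_tensor(ad.Tensor(_encode_batch(chunk)))
        out[start:start + len(chunk)] = y.data[:, 0]
    if destandardize is not None:
        mu, sd = destandardize
        out = out * sd + mu
    return out


def predict_matrices(model: PredictorModel, mats: np.ndarray, batch=64) -> np.ndarray:
    """Score relaxed one-hot matrices directly (used by the GA)."""
    out = np.empty(mats.shape[0])
    for start in range(0, mats.shape[0], batch):
        with ad.no_grad():
            y = model.forward_tensor(ad.Tensor(mats[start:start + batch]))
        out[start:start + y.data.shape[0]] = y.data[:, 0]
    return out


def penultimate_embedding(model: PredictorModel, seqs, batch=64) -> np.ndarray:
    """Activations of the pooled layer feeding the output unit (n x d)."""
    out = np.empty((len(seqs), model.embed_dim))
    for start in range(0, len(seqs), batch):
        chunk = seqs[start:start + batch]
        with ad.no_grad():
            _, emb = model.forward_tensor(ad.Tensor(_encode_batch(chunk)),
                                          return_embedding=True)
        out[start:start + len(chunk)] = emb.data
    return out


def saliency_map(model: PredictorModel, seq: str, masked=True) -> SaliencyMap:
    """Gradient of the predicted activity w.r.t. the one-hot input.

    With ``masked=True`` (default) the gradient is multiplied elementwise by
    the input encoding, restricting attribution to the observed bases.
    """
    x = ad.parameter(encode_onehot(seq)[None])
    y = ad.tsum(model.forward_tensor(x))
    if not np.isfinite(y.data).all():
        raise FloatingPointError("non-finite prediction; is the model trained?")
    (g,) = ad.grad(y, [x])
    values = g.data[0]
    if masked:
        values = values * x.data[0]
    return SaliencyMap(values=values, seq=seq)


def cluster_saliency(maps, k, rng_seed=0, members_per_cluster=30):
    """K-means over flattened saliency maps.

    Returns (labels, per-cluster mean maps, representative member indices —
    a seeded random subsample of up to ``members_per_cluster`` per cluster).
    """
    if k > len(maps):
        raise ValueError(f"k={k} exceeds number of maps {len(maps)}")
    shapes = {m.values.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError("saliency maps must share one shape")
    X = np.stack([m.values.ravel() for m in maps])
    km = KMeans(n_clusters=k, n_init=10, random_state=rng_seed)
    labels = km.fit_predict(X)
    shape = maps[0].values.shape
    centroids = [km.cluster_centers_[i].reshape(shape) for i in range(k)]
    rng = np.random.default_rng(rng_seed)
    members = []
    for i in range(k):
        idx = np.flatnonzero(labels == i)
        take = min(members_per_cluster, len(idx))
        members.append(np.sort(rng.choice(idx, size=take, replace=False)))
    return labels, centroids, members


@dataclass
class ValidationReport:
    pearson: float
    spearman: float
    mse: float
    n_train: int
    n_val: int
    epochs_run: int
    activity_mean: float = 0.0
    activity_sd: float = 1.0


def train_predictor(dataset, config: PredictorConfig | None = None):
    """Fit the predictor by MSE on (optionally z-scored) activities.

    Early stopping on held-out loss; returns (model, ValidationReport).
    """
    if config is None:
        config = PredictorConfig(window_length=dataset.window_length)
    if config.window_length != dataset.window_length:
        raise ValueError("config window_length does not match dataset")
    if len(dataset) < 50:
        raise ValueError("need at least 50 records to train")
    acts = dataset.activities()
    if acts.std() == 0:
        raise ValueError("degenerate target: all activities identical")
    mu, sd = (acts.mean(), acts.std()) if config.zscore_activities else (0.0, 1.0)
    y = (acts - mu) / sd
    X = _encode_batch(dataset.sequences())
    rng = np.random.default_rng(config.rng_seed)
    perm = rng.permutation(len(dataset))
    n_val = max(int(len(dataset) * config.val_fraction), 1)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    model = PredictorModel(config)
    opt = Adam(model.parameters(), config.learning_rate, config.beta1, config.beta2)
    best_val, best_state, patience_left = np.inf, None, config.patience
    epochs_run = 0
    for epoch in range(config.max_epochs):
        epochs_run = epoch + 1
        order = rng.permutation(train_idx)
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            pred = model.forward_tensor(ad.Tensor(X[idx]))
            err = ad.sub(pred, ad.Tensor(y[idx][:, None]))
            loss = ad.tmean(ad.mul(err, err))
            opt.step(ad.grad(loss, opt.params))
        val_pred = predict_matrices(model, X[val_idx])
        val_loss = float(np.mean((val_pred - y[val_idx]) ** 2))
        if val_loss < best_val - 1e-6:
            best_val, patience_left = val_loss, config.patience
            best_state = [a.copy() for a in model.state_arrays()]
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    if best_state is not None:
        model.load_state_arrays(best_state)
    val_pred = predict_matrices(model, X[val_idx])
    report = ValidationReport(
        pearson=float(stats.pearsonr(val_pred, y[val_idx])[0]),
        spearman=float(stats.spearmanr(val_pred, y[val_idx])[0]),
        mse=float(np.mean((val_pred - y[val_idx]) ** 2)),
        n_train=len(train_idx), n_val=len(val_idx), epochs_run=epochs_run,
        activity_mean=float(mu), activity_sd=float(sd))
    return model, report


def save_predictor(path, model: PredictorModel):
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in vars(model.config).items()}
    save_checkpoint(path, model, cfg)


def load_predictor(path) -> PredictorModel:
    cfg, arrays = load_checkpoint(path)
    cfg["dense_blocks"] = tuple(cfg["dense_blocks"])
    cfg["dense_layer_kernels"] = tuple(cfg["dense_layer_kernels"])
    model = PredictorModel(PredictorConfig(**cfg))
    model.load_state_arrays(arrays)
    return model
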