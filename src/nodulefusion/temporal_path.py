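"""Temporal (inter-slice) path: convolutional auto-encoder + transformer.

A convolutional auto-encoder (CAE) is trained unsupervised, by mean squared
reconstruction error, on lung-parenchyma slices; its bottleneck supplies a
per-slice embedding.  The per-case sequence of slice embeddings (zero-padded
to 25, the maximum number of nodule-bearing slices per case) is processed by
3 stacked transformer-encoder blocks with fixed sinusoidal positional
encoding over the slice order.  Padded positions are excluded from the
attention keys and from the global max pool, so the zero padding is exactly
inert.  The pooled vector passes through a 32-unit rectified MLP whose
output is the case's temporal feature.

Two model scales are provided.  The ``full`` scale follows the published
architecture (256x256 input, encoder filters 16/32/64/128/256 each with 2x2
max pooling, 256-d bottleneck, transformer width 256).  The ``reduced``
scale (128x128 input after downsampling, filters 8/16/32/32/64, 64-d
bottleneck) is what the package's CPU-scale evaluation runs use; the method
is unchanged, only the widths shrink.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from . import _nn
from ._nn import Tensor
from .dataio import StageConfig
from .preprocess import LungSliceStack

__all__ = [
    "MAX_SLICES", "CAEConfig", "CAEModel", "EmbeddingSequence",
    "TemporalEncoder", "cae_pretrain", "cae_finetune", "embed_sequence",
    "temporal_forward", "temporal_train", "sinusoidal_encoding",
]

MAX_SLICES = 25


@dataclass(frozen=True)
class CAEConfig:
    input_size: int = 256
    filters: tuple[int, ...] = (16, 32, 64, 128, 256)
    embedding: int = 256

    def __post_init__(self):
        if self.input_size % (2 ** len(self.filters)):
            raise ValueError("input size must survive one 2x2 pooling per stage")

    @classmethod
    def reduced(cls) -> "CAEConfig":
        # 128 px keeps sub-centimetre nodule texture resolvable (at 64 px the
        # embeddings of small nodules stop separating the classes)
        return cls(input_size=128, filters=(8, 16, 32, 32, 64), embedding=64)

    @property
    def bottleneck_hw(self) -> int:
        return self.input_size // (2 ** len(self.filters))


class CAEModel(_nn.Module):
    """Symmetric convolutional auto-encoder with a dense bottleneck."""

    def __init__(self, config: CAEConfig, rng: np.random.Generator):
        self.config = config
        f = config.filters
        chans = (1,) + f
        self.enc_convs = [_nn.Conv2d(chans[i], chans[i + 1], 3, rng)
                          for i in range(len(f))]
        hw = config.bottleneck_hw
        flat = f[-1] * hw * hw
        self.enc_dense = _nn.Linear(flat, config.embedding, rng)
        self.dec_dense = _nn.Linear(config.embedding, flat, rng)
        rev = f[::-1]
        self.dec_convs = [_nn.Conv2d(rev[i], rev[i + 1], 3, rng)
                          for i in range(len(f) - 1)]
        self.out_conv = _nn.Conv2d(f[0], 1, 3, rng)

    # -- forward pieces ----------------------------------------------------
    def encode(self, x: Tensor) -> Tensor:
        """(N, 1, S, S) -> (N, embedding)."""
        h = x
        for conv in self.enc_convs:
            h = _nn.maxpool2d(_nn.relu(conv(h)))
        n = h.shape[0]
        h = _nn.reshape(h, (n, -1))
        return self.enc_dense(h)

    def decode(self, z: Tensor) -> Tensor:
        hw, c = self.config.bottleneck_hw, self.config.filters[-1]
        h = _nn.relu(self.dec_dense(z))
        h = _nn.reshape(h, (h.shape[0], c, hw, hw))
        for conv in self.dec_convs:
            h = _nn.relu(conv(_nn.upsample2(h)))
        return self.out_conv(_nn.upsample2(h))

    def reconstruct(self, x: Tensor) -> Tensor:
        return self.decode(self.encode(x))

    # -- fine-tune freeze policy --------------------------------------------
    def bottleneck_parameters(self) -> list[Tensor]:
        """The middle dense layers plus the adjacent convolutions (the only
        weights updated during fine-tuning)."""
        mods = [self.enc_convs[-1], self.enc_dense, self.dec_dense,
                self.dec_convs[0] if self.dec_convs else self.out_conv]
        out: list[Tensor] = []
        for m in mods:
            out.extend(m.parameters())
        return out

    def prepare(self, images: np.ndarray) -> np.ndarray:
        """Resize (n, H, W) lung images to the configured input size."""
        s = self.config.input_size
        if images.shape[1:] == (s, s):
            return images[:, None].astype(np.float64)
        out = np.stack([
            resize(img, (s, s), order=1, mode="edge", anti_aliasing=True)
            for img in images])
        return out[:, None]


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def _make_optimizer(params, cfg: StageConfig):
    cls = {"adam": _nn.Adam, "adamw": _nn.AdamW}[cfg.optimizer.lower()]
    return cls(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)


def _train_autoencoder(model: CAEModel, params, images: np.ndarray,
                       cfg: StageConfig, seed: int,
                       val_fraction: float = 0.2) -> dict:
    """MSE training loop shared by pre-training and fine-tuning.

    Keeps the best-so-far weights according to held-out reconstruction MSE
    (an internal 80-20 split), mirroring hold-out model selection.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 11]))
    x = model.prepare(images)
    n = x.shape[0]
    n_val = max(1, int(round(val_fraction * n))) if n > 1 else 0
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0:
        train_idx = perm
    xtr, xva = x[train_idx], x[val_idx] if n_val else x

    def val_mse(m):
        rec = m.reconstruct(Tensor(xva))
        return float(((rec.data - xva) ** 2).mean())

    opt = _make_optimizer(params, cfg)
    history = {"train": [], "val": [val_mse(model)]}
    best = history["val"][0]
    best_state = model.state()
    for _ in range(cfg.epochs):
        losses = []
        for idx in _batches(len(xtr), cfg.batch_size, rng):
            xb = xtr[idx]
            opt.zero_grad()
            loss = _nn.mse_loss(model.reconstruct(Tensor(xb)), xb)
            if not np.isfinite(loss.data):
                raise FloatingPointError("non-finite reconstruction loss")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["train"].append(float(np.mean(losses)))
        v = val_mse(model)
        history["val"].append(v)
        if v < best:
            best = v
            best_state = model.state()
    model.load_state(best_state)
    history["best_val"] = best
    return history


def cae_pretrain(images: np.ndarray, cfg: StageConfig, seed: int,
                 config: CAEConfig | None = None) -> tuple[CAEModel, dict]:
    """Unsupervised pre-training on lung slices (all layers trained)."""
    if len(images) < 1:
        raise ValueError("need at least one training image")
    config = config or CAEConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 10]))
    model = CAEModel(config, rng)
    history = _train_autoencoder(model, model.parameters(), images, cfg, seed)
    return model, history


def cae_finetune(model: CAEModel, images: np.ndarray, cfg: StageConfig,
                 seed: int) -> dict:
    """Fine-tune only the bottleneck dense layers and the adjacent
    convolutions; every other weight stays bitwise unchanged."""
    return _train_autoencoder(model, model.bottleneck_parameters(), images,
                              cfg, seed + 1)


# ---------------------------------------------------------------------------
# slice sequences
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingSequence:
    """Per-slice embeddings zero-padded to MAX_SLICES with a validity mask."""

    embeddings: np.ndarray    # (25, E)
    validity: np.ndarray      # (25,) in {0,1}
    case_id: str = ""

    def __post_init__(self):
        self.embeddings = np.asarray(self.embeddings, dtype=np.float64)
        self.validity = np.asarray(self.validity)
        if self.embeddings.shape[0] != MAX_SLICES:
            raise ValueError(f"sequence must be padded to {MAX_SLICES}")
        if self.validity.shape != (MAX_SLICES,):
            raise ValueError("validity mask shape mismatch")
        if not np.isin(self.validity, (0, 1)).all():
            raise ValueError("validity must be binary")
        if self.true_length < 1:
            raise ValueError("sequence has no valid slices")
        if np.any(self.embeddings[self.validity == 0] != 0):
            raise ValueError("padded rows must be zero")

    @property
    def true_length(self) -> int:
        return int(self.validity.sum())


def embed_sequence(model: CAEModel, lung_stack: LungSliceStack,
                   subsample: bool = False) -> EmbeddingSequence:
    """Encode each selected slice and zero-pad the sequence to 25 rows."""
    images = lung_stack.images
    n = images.shape[0]
    if n > MAX_SLICES:
        if not subsample:
            raise ValueError(
                f"{n} slices exceed the maximum of {MAX_SLICES}; pass "
                "subsample=True to subsample uniformly"
            )
        keep = np.unique(np.linspace(0, n - 1, MAX_SLICES).round().astype(int))
        images = images[keep]
        n = images.shape[0]
    emb = model.encode(Tensor(model.prepare(images))).data
    e = emb.shape[1]
    padded = np.zeros((MAX_SLICES, e))
    padded[:n] = emb
    validity = np.zeros(MAX_SLICES, dtype=np.uint8)
    validity[:n] = 1
    return EmbeddingSequence(embeddings=padded, validity=validity,
                             case_id=lung_stack.case_id)


def sinusoidal_encoding(length: int, dim: int) -> np.ndarray:
    """Fixed sine/cosine positional code over slice order."""
    pos = np.arange(length)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe


class TemporalEncoder(_nn.Module):
    """3 transformer-encoder stacks + masked GMP + 32-unit rectified MLP."""

    N_BLOCKS = 3
    FEATURE_DIM = 32

    def __init__(self, embed_dim: int, rng: np.random.Generator,
                 heads: int = 4, dropout: float = 0.3):
        self.embed_dim = embed_dim
        self.dropout = dropout
        #: per-dimension standardisation of the embeddings, fitted on the
        #: training fold's valid rows.  The raw auto-encoder embeddings are
        #: tiny against the O(1) positional code, and a row-local
        #: normalisation would discard the magnitude information the class
        #: signal partly lives in.
        self.normalizer: tuple[np.ndarray, np.ndarray] | None = None
        self.blocks = [
            _nn.TransformerBlock(embed_dim, heads, 2 * embed_dim, rng,
                                 drop=dropout)
            for _ in range(self.N_BLOCKS)
        ]
        self.mlp = _nn.Linear(embed_dim, self.FEATURE_DIM, rng)
        self.head = _nn.Linear(self.FEATURE_DIM, 2, rng)
        self.pe = sinusoidal_encoding(MAX_SLICES, embed_dim)

    def fit_normalizer(self, sequences: list["EmbeddingSequence"]) -> None:
        rows = np.concatenate([s.embeddings[s.validity > 0]
                               for s in sequences])
        self.normalizer = (rows.mean(axis=0),
                           np.maximum(rows.std(axis=0), 1e-8))

    def _standardize(self, emb: np.ndarray, validity: np.ndarray
                     ) -> np.ndarray:
        if self.normalizer is None:
            return emb
        mu, sd = self.normalizer
        # padded rows stay exactly zero
        return (emb - mu) / sd * validity[:, :, None]

    def _forward_batch(self, emb: np.ndarray, validity: np.ndarray,
                       rng: np.random.Generator | None = None,
                       return_pooled: bool = False):
        """(B, 25, E), (B, 25) -> (B, 32) temporal features."""
        x = Tensor(self._standardize(emb, validity))
        x = _nn.add(x, Tensor(self.pe[None] * validity[:, :, None]))
        # padded keys removed from attention; padded rows removed from GMP
        key_mask = np.where(validity[:, None, None, :] > 0, 0.0, -1e9)
        for block in self.blocks:
            x = block(x, mask=key_mask, rng=rng)
        neg = np.where(validity[:, :, None] > 0, 0.0, -1e18)
        pooled = _nn.tmax(_nn.add(x, Tensor(neg)), axis=1)
        feat = _nn.relu(self.mlp(_nn.dropout(pooled, self.dropout, rng)))
        if return_pooled:
            return feat, pooled
        return feat

    def features(self, sequences: list[EmbeddingSequence]) -> np.ndarray:
        emb = np.stack([s.embeddings for s in sequences])
        val = np.stack([s.validity for s in sequences])
        return self._forward_batch(emb, val).data

    def logits(self, sequences: list[EmbeddingSequence],
               rng: np.random.Generator | None = None) -> Tensor:
        emb = np.stack([s.embeddings for s in sequences])
        val = np.stack([s.validity for s in sequences])
        return self.head(self._forward_batch(emb, val, rng=rng))


def temporal_forward(encoder: TemporalEncoder, seq: EmbeddingSequence
                     ) -> np.ndarray:
    """The 32-d temporal feature of one case (inference, no dropout)."""
    return encoder.features([seq])[0]


def temporal_train(sequences: list[EmbeddingSequence], labels: np.ndarray,
                   cfg: StageConfig, seed: int,
                   encoder: TemporalEncoder | None = None
                   ) -> tuple[TemporalEncoder, dict]:
    """Supervised training of the temporal encoder with a 2-way head on top
    of the temporal feature (binary cross-entropy)."""
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 20]))
    if encoder is None:
        embed_dim = sequences[0].embeddings.shape[1]
        encoder = TemporalEncoder(embed_dim, rng, dropout=cfg.dropout)
        encoder.head.weight.data[...] = 0.0
    if encoder.normalizer is None:
        encoder.fit_normalizer(sequences)
    params = encoder.parameters()
    opt = _make_optimizer(params, cfg)
    history = {"loss": []}
    n = len(sequences)
    base_lr, step, warmup = cfg.learning_rate, 0, 20
    for _ in range(cfg.epochs):
        losses = []
        for idx in _batches(n, cfg.batch_size, rng):
            batch = [sequences[i] for i in idx]
            opt.zero_grad()
            loss = _nn.cross_entropy_logits(encoder.logits(batch, rng=rng),
                                            labels[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError("non-finite training loss")
            loss.backward()
            _nn.clip_grad_norm(params, 5.0)
            step += 1
            opt.lr = base_lr * min(1.0, step / warmup)
            opt.step()
            losses.append(float(loss.data))
        history["loss"].append(float(np.mean(losses)))
    return encoder, history
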