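"""Spatial (within-slice) path: hierarchical shifted-window attention.

Nodule patches are split into non-overlapping 4x4 patches, linearly
embedded, and processed by four stages of windowed multi-head
self-attention blocks that alternate regular and cyclically shifted window
partitions; a patch-merging step between stages halves the token grid and
doubles the channel width.  Attention in shifted blocks is masked so that
tokens wrapped together from non-adjacent windows by the cyclic shift never
attend to each other.  The spatially averaged stage-4 map is the per-slice
feature; per subject, slice features are combined by global max pooling.

Two configurations exist: ``full`` mirrors the published backbone (224
input, window 7, embedding width 128, stage depths 2/2/18/2 — the SWin-B
layout) with a hook for loading externally pretrained weights, and
``reduced`` (input downsampled to 64, window 2, width 32, depths 2/2/2/2)
which all CPU-scale evaluation runs use.  Without a weights hook, training
starts from random initialisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize

from . import _nn
from ._nn import Tensor
from .dataio import StageConfig

__all__ = [
    "SpatialEncoderConfig", "SwinBackbone", "SubjectSpatialFeature",
    "window_partition", "window_reverse", "build_shift_attention_mask",
    "spatial_forward", "subject_pool", "spatial_train",
]


@dataclass(frozen=True)
class SpatialEncoderConfig:
    input_size: int = 224         # size of the incoming nodule patch
    backbone_size: int = 224      # internal resolution fed to the backbone
    patch_size: int = 4
    window: int = 7
    embed_dim: int = 128
    depths: tuple[int, ...] = (2, 2, 18, 2)
    heads: tuple[int, ...] = (4, 8, 16, 32)
    dropout: float = 0.1
    pretrained_path: str | None = None
    #: mask all-zero (padding) tokens out of attention keys and the final
    #: pooling.  With a pretrained backbone the network can learn to assign
    #: padding low attention on its own, but when training from random
    #: initialisation the zero-variance padding tokens destabilise layer
    #: normalisation, so explicit masking is the default.
    mask_padding: bool = True

    def __post_init__(self):
        if self.backbone_size % self.patch_size:
            raise ValueError("input side must be divisible by the patch size")
        g = self.backbone_size // self.patch_size
        for i in range(len(self.depths)):
            if g % self.window:
                raise ValueError(
                    f"token grid {g} at stage {i + 1} is not divisible by "
                    f"window {self.window}"
                )
            if i < len(self.depths) - 1:
                if g % 2:
                    raise ValueError(f"grid {g} cannot be patch-merged")
                g //= 2
        if any(d < 1 for d in self.depths):
            raise ValueError("stage depths must be positive")

    @classmethod
    def full(cls, pretrained_path: str | None = None) -> "SpatialEncoderConfig":
        return cls(pretrained_path=pretrained_path)

    @classmethod
    def reduced(cls) -> "SpatialEncoderConfig":
        return cls(backbone_size=64, window=2, embed_dim=32,
                   depths=(2, 2, 2, 2), heads=(1, 2, 4, 8))

    @property
    def out_dim(self) -> int:
        # three patch merges double the width three times
        return self.embed_dim * 2 ** (len(self.depths) - 1)


# ---------------------------------------------------------------------------
# window bookkeeping
# ---------------------------------------------------------------------------

def window_partition(x: Tensor, window: int) -> Tensor:
    """(B, H, W, C) -> (B*nW, window*window, C)."""
    b, h, w, c = x.shape
    x = _nn.reshape(x, (b, h // window, window, w // window, window, c))
    x = _nn.transpose(x, (0, 1, 3, 2, 4, 5))
    return _nn.reshape(x, (-1, window * window, c))


def window_reverse(x: Tensor, window: int, h: int, w: int) -> Tensor:
    """Inverse of :func:`window_partition`."""
    c = x.shape[-1]
    b = x.shape[0] // ((h // window) * (w // window))
    x = _nn.reshape(x, (b, h // window, w // window, window, window, c))
    x = _nn.transpose(x, (0, 1, 3, 2, 4, 5))
    return _nn.reshape(x, (b, h, w, c))


def build_shift_attention_mask(h: int, w: int, window: int, shift: int
                               ) -> np.ndarray:
    """Additive attention mask (nW, T, T) for a cyclically shifted partition:
    0 where both tokens come from the same pre-shift image region, -1e9
    where the wrap-around stitched tokens from non-adjacent regions."""
    img = np.zeros((h, w))
    bounds = (slice(0, -window), slice(-window, -shift), slice(-shift, None))
    region = 0
    for hs in bounds:
        for ws in bounds:
            img[hs, ws] = region
            region += 1
    shifted = np.roll(img, (-shift, -shift), axis=(0, 1))
    win = window_partition(Tensor(shifted[None, :, :, None]), window).data
    win = win[:, :, 0]  # (nW, T)
    same = win[:, :, None] == win[:, None, :]
    return np.where(same, 0.0, -1e9)


# ---------------------------------------------------------------------------
# backbone
# ---------------------------------------------------------------------------

class SwinBlock(_nn.Module):
    def __init__(self, dim: int, heads: int, window: int, shift: int,
                 grid: int, rng: np.random.Generator, drop: float):
        self.window, self.shift, self.grid = window, shift, grid
        self.norm1 = _nn.LayerNorm(dim)
        self.attn = _nn.MultiHeadSelfAttention(dim, heads, rng)
        self.norm2 = _nn.LayerNorm(dim)
        self.fc1 = _nn.Linear(dim, 4 * dim, rng)
        self.fc2 = _nn.Linear(4 * dim, dim, rng)
        self.drop = drop
        self.mask = (build_shift_attention_mask(grid, grid, window, shift)
                     if shift else None)

    def _attn_mask(self, b: int, token_mask: np.ndarray | None
                   ) -> np.ndarray | None:
        """Combined additive mask: shifted-window regions + padding keys."""
        mask = None
        if self.mask is not None:
            mask = np.tile(self.mask[:, None], (b, 1, 1, 1))  # (B*nW,1,T,T)
        if token_mask is not None:
            tm = token_mask
            if self.shift:
                tm = np.roll(tm, (-self.shift, -self.shift), axis=(1, 2))
            win = window_partition(Tensor(tm[..., None]), self.window).data
            key_mask = np.where(win[:, None, :, 0][:, :, None] > 0, 0.0, -1e9)
            mask = key_mask if mask is None else mask + key_mask
        return mask

    def __call__(self, x: Tensor, token_mask: np.ndarray | None = None,
                 rng: np.random.Generator | None = None) -> Tensor:
        b, h, w, c = x.shape
        shortcut = x
        y = self.norm1(x)
        if self.shift:
            y = _nn.roll2d(y, (-self.shift, -self.shift), (1, 2))
        ywin = window_partition(y, self.window)
        ywin = self.attn(ywin, mask=self._attn_mask(b, token_mask))
        y = window_reverse(ywin, self.window, h, w)
        if self.shift:
            y = _nn.roll2d(y, (self.shift, self.shift), (1, 2))
        x = _nn.add(shortcut, _nn.dropout(y, self.drop, rng))
        m = self.fc2(_nn.dropout(_nn.gelu(self.fc1(self.norm2(x))), self.drop,
                                 rng))
        return _nn.add(x, _nn.dropout(m, self.drop, rng))

    def attention_weights(self, x: Tensor,
                          token_mask: np.ndarray | None = None) -> np.ndarray:
        """Attention tensor of this block (for mask introspection)."""
        b = x.shape[0]
        y = self.norm1(x)
        if self.shift:
            y = _nn.roll2d(y, (-self.shift, -self.shift), (1, 2))
        ywin = window_partition(y, self.window)
        _, attn = self.attn(ywin, mask=self._attn_mask(b, token_mask),
                            return_attn=True)
        return attn.data


class PatchMerging(_nn.Module):
    def __init__(self, dim: int, rng: np.random.Generator):
        self.norm = _nn.LayerNorm(4 * dim)
        self.reduce = _nn.Linear(4 * dim, 2 * dim, rng, bias=False)

    def __call__(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        x = _nn.reshape(x, (b, h // 2, 2, w // 2, 2, c))
        x = _nn.transpose(x, (0, 1, 3, 2, 4, 5))
        x = _nn.reshape(x, (b, h // 2, w // 2, 4 * c))
        return self.reduce(self.norm(x))


class SwinBackbone(_nn.Module):
    """Four-stage windowed-attention encoder yielding one vector per slice."""

    def __init__(self, config: SpatialEncoderConfig, rng: np.random.Generator):
        self.config = config
        p = config.patch_size
        self.patch_embed = _nn.Linear(p * p, config.embed_dim, rng)
        self.embed_norm = _nn.LayerNorm(config.embed_dim)
        grid = config.backbone_size // p
        dim = config.embed_dim
        self.stages: list[list[SwinBlock]] = []
        self.merges: list[PatchMerging] = []
        for s, (depth, heads) in enumerate(zip(config.depths, config.heads)):
            blocks = []
            for i in range(depth):
                shift = 0 if i % 2 == 0 else config.window // 2
                blocks.append(SwinBlock(dim, heads, config.window, shift,
                                        grid, rng, config.dropout))
            self.stages.append(blocks)
            if s < len(config.depths) - 1:
                self.merges.append(PatchMerging(dim, rng))
                dim *= 2
                grid //= 2
        self.final_norm = _nn.LayerNorm(dim)
        if config.pretrained_path:
            self.load_weights(config.pretrained_path)

    def parameters(self):
        out = self.patch_embed.parameters() + self.embed_norm.parameters()
        for blocks in self.stages:
            for blk in blocks:
                out += blk.parameters()
        for m in self.merges:
            out += m.parameters()
        out += self.final_norm.parameters()
        return out

    def load_weights(self, path: str | Path) -> None:
        """Hook for externally pretrained weights stored as npz arrays in
        parameter order."""
        arrays = np.load(path)
        self.load_state([arrays[k] for k in arrays.files])

    def save_weights(self, path: str | Path) -> None:
        np.savez(path, *[p.data for p in self.parameters()])

    def _prep(self, patches: np.ndarray) -> np.ndarray:
        s = self.config.backbone_size
        if patches.shape[1:] == (s, s):
            return patches.astype(np.float64)
        return np.stack([
            resize(p, (s, s), order=1, mode="edge", anti_aliasing=True)
            for p in patches])

    def forward(self, patches: np.ndarray,
                rng: np.random.Generator | None = None) -> Tensor:
        """(n, S, S) normalised patches -> (n, out_dim) stage-4 vectors."""
        x = self._prep(patches)
        if x.ndim != 3 or x.shape[1] != self.config.input_size and \
                x.shape[1] != self.config.backbone_size:
            raise ValueError(
                f"expected ({self.config.input_size}, {self.config.input_size})"
                f" patches, got {x.shape[1:]}"
            )
        n = x.shape[0]
        p = self.config.patch_size
        g = self.config.backbone_size // p
        tokens = (x.reshape(n, g, p, g, p).transpose(0, 1, 3, 2, 4)
                  .reshape(n, g, g, p * p))
        token_mask = None
        if self.config.mask_padding:
            token_mask = (np.abs(tokens) > 0).any(axis=-1).astype(np.float64)
        t = Tensor(tokens)
        t = self.embed_norm(self.patch_embed(t))

        def kill_dead(t):
            # keep padding tokens exactly zero: they then contribute nothing
            # forward, and no gradient flows into their (zero-variance, hence
            # ill-conditioned) normalisation paths
            if token_mask is None:
                return t
            return _nn.mul(t, Tensor(token_mask[..., None]))

        t = kill_dead(t)
        for s, blocks in enumerate(self.stages):
            for blk in blocks:
                t = kill_dead(blk(t, token_mask=token_mask, rng=rng))
            if s < len(self.stages) - 1:
                t = self.merges[s](t)
                if token_mask is not None:
                    # a merged token is content if any of its 2x2 parents is
                    b, h2, w2 = (token_mask.shape[0], token_mask.shape[1] // 2,
                                 token_mask.shape[2] // 2)
                    token_mask = token_mask.reshape(b, h2, 2, w2, 2).max((2, 4))
                t = kill_dead(t)
        t = self.final_norm(t)
        b, h, w, c = t.shape
        flat = _nn.reshape(t, (b, h * w, c))
        if token_mask is None:
            return _nn.tmean(flat, axis=1)
        counts = token_mask.reshape(b, h * w).sum(axis=1)
        if np.any(counts == 0):   # pathological all-padding input
            return _nn.tmean(flat, axis=1)
        weights = (token_mask.reshape(b, h * w, 1)
                   / counts[:, None, None])
        return _nn.tsum(_nn.mul(flat, Tensor(weights)), axis=1)


def spatial_forward(model: SwinBackbone, patch: np.ndarray) -> np.ndarray:
    """Stage-4 feature vector of a single 224x224 normalised patch."""
    if patch.shape != (model.config.input_size, model.config.input_size):
        raise ValueError(
            f"expected ({model.config.input_size}, {model.config.input_size}) "
            f"patch, got {patch.shape}"
        )
    return model.forward(patch[None]).data[0]


@dataclass
class SubjectSpatialFeature:
    case_id: str
    per_slice: np.ndarray   # (n_slices, out_dim)
    pooled: np.ndarray      # (out_dim,) element-wise max over slices

    def __post_init__(self):
        assert self.per_slice.ndim == 2 and len(self.per_slice)
        assert np.array_equal(self.pooled, self.per_slice.max(axis=0))


def subject_pool(per_slice_vectors: np.ndarray, case_id: str = ""
                 ) -> SubjectSpatialFeature:
    """Global max pooling across a subject's slice vectors."""
    v = np.asarray(per_slice_vectors, dtype=np.float64)
    if v.ndim != 2 or v.shape[0] == 0:
        raise ValueError("need at least one slice vector")
    return SubjectSpatialFeature(case_id=case_id, per_slice=v,
                                 pooled=v.max(axis=0))


def _subsample_slices(patches: np.ndarray, k: int | None) -> np.ndarray:
    """Keep at most k slices, uniformly spread, central slice included."""
    if k is None or patches.shape[0] <= k:
        return patches
    idx = np.unique(np.linspace(0, patches.shape[0] - 1, k).round().astype(int))
    return patches[idx]


def spatial_train(case_patches: dict[str, np.ndarray], labels: dict[str, int],
                  cfg: StageConfig, seed: int,
                  config: SpatialEncoderConfig | None = None,
                  max_train_slices: int | None = 3,
                  val_fraction: float = 0.2,
                  warmup_steps: int = 20
                  ) -> tuple[SwinBackbone, dict]:
    """Supervised training with a temporary 2-way head over the pooled
    subject feature; early stopping on held-out loss; the head is kept on
    the returned history for inspection, the backbone is the product.

    The learning rate ramps linearly over the first ``warmup_steps``
    optimiser steps — training this backbone from random initialisation
    diverges into a constant-output collapse without warmup.
    """
    ids = sorted(case_patches)
    y = np.array([labels[i] for i in ids], dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("training set must contain both classes")
    config = config or SpatialEncoderConfig.reduced()
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 30]))
    model = SwinBackbone(config, rng)
    head = _nn.Linear(config.out_dim, 2, rng)
    head.weight.data[...] = 0.0   # start at the chance-level loss plateau
    params = model.parameters() + head.parameters()
    opt = {"adam": _nn.Adam, "adamw": _nn.AdamW}[cfg.optimizer.lower()](
        params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay,
        decay_mask=[p.data.ndim > 1 for p in params])

    n_val = max(1, int(round(val_fraction * len(ids)))) if len(ids) > 4 else 0
    perm = rng.permutation(len(ids))
    val_ids = [ids[i] for i in perm[:n_val]]
    train_ids = [ids[i] for i in perm[n_val:]]

    prepped = {
        i: model._prep(_subsample_slices(case_patches[i], max_train_slices))
        for i in ids
    }

    def subject_logits(case_id, train_rng=None) -> Tensor:
        vecs = model.forward(prepped[case_id], rng=train_rng)
        pooled = _nn.tmax(vecs, axis=0)
        return head(_nn.reshape(pooled, (1, -1)))

    def eval_loss(id_list) -> float:
        if not id_list:
            return np.nan
        tot = 0.0
        for cid in id_list:
            logits = subject_logits(cid)
            tot += float(_nn.cross_entropy_logits(
                logits, np.array([labels[cid]])).data)
        return tot / len(id_list)

    best = eval_loss(val_ids) if n_val else np.inf
    best_state = [p.data.copy() for p in params]
    bad_epochs = 0
    history = {"train": [], "val": []}
    base_lr = cfg.learning_rate
    step = 0
    for _ in range(cfg.epochs):
        losses = []
        order = rng.permutation(len(train_ids))
        for i in range(0, len(order), cfg.batch_size):
            batch = [train_ids[j] for j in order[i:i + cfg.batch_size]]
            opt.zero_grad()
            logits = _nn.concat([subject_logits(cid, rng) for cid in batch],
                                axis=0)
            loss = _nn.cross_entropy_logits(
                logits, np.array([labels[cid] for cid in batch]))
            if not np.isfinite(loss.data):
                raise FloatingPointError("non-finite training loss")
            loss.backward()
            _nn.clip_grad_norm(params, 5.0)
            step += 1
            opt.lr = base_lr * min(1.0, step / warmup_steps) \
                if warmup_steps else base_lr
            opt.step()
            losses.append(float(loss.data))
        history["train"].append(float(np.mean(losses)))
        if n_val:
            v = eval_loss(val_ids)
            history["val"].append(v)
            if v < best - 1e-6:
                best = v
                best_state = [p.data.copy() for p in params]
                bad_epochs = 0
            else:
                bad_epochs += 1
                if cfg.patience is not None and bad_epochs > cfg.patience:
                    break
    if n_val:
        for p, s in zip(params, best_state):
            p.data[...] = s
    history["head"] = head
    return model, history


def spatial_features(model: SwinBackbone, case_patches: dict[str, np.ndarray],
                     max_slices: int | None = None) -> dict[str, np.ndarray]:
    """Pooled subject features for a set of cases."""
    out = {}
    for cid, patches in case_patches.items():
        p = _subsample_slices(patches, max_slices)
        vecs = model.forward(p).data
        out[cid] = subject_pool(vecs, cid).pooled
    return out
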