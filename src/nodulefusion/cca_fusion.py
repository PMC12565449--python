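"""Three-way feature fusion by criss-cross attention (CCA).

The three path features — radiomic (36-d), spatial (backbone width) and
temporal (32-d) — are z-scored with training-fold statistics, linearly
projected to a common dimension of 100 and reshaped row-major to 10x10
maps, assigned to Q (radiomic), K (spatial) and V (temporal).  For each map
position u = (r, c) the affinity d_{i,u} = Q_u . Omega_{i,u} is computed
against the H+W-1 K-positions sharing u's row or column (the criss-cross
set, centre counted once), softmax-normalised into attention weights
A_{i,u}, and the fused value H_u = sum_i A_{i,u} Phi_{i,u} aggregates V
over the same set in the same order.  No scaling by 1/sqrt(C), no softmax
temperature and, by default, no residual term (a flag adds V_u back).
The flattened fused map feeds a 2-unit dense layer with softmax for the
G1/G2 decision.

Each fused value is a convex combination of V on the cross set, so per
channel H_u always lies within [min, max] of those values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _nn
from ._nn import Tensor
from .dataio import StageConfig

__all__ = [
    "MAP_H", "MAP_W", "PROJ_DIM", "ProjectedTriple", "CrossAttentionMap",
    "FusedMap", "FusionModel", "project_triple", "cca_affinity",
    "cca_aggregate", "fuse_and_classify", "fusion_train",
]

MAP_H = 10
MAP_W = 10
PROJ_DIM = MAP_H * MAP_W   # the common projection dimension of 100


@dataclass
class ProjectedTriple:
    q_map: np.ndarray   # (H, W, C) — radiomic
    k_map: np.ndarray   # (H, W, C) — spatial
    v_map: np.ndarray   # (H, W, C) — temporal

    def __post_init__(self):
        shapes = {self.q_map.shape, self.k_map.shape, self.v_map.shape}
        if len(shapes) != 1:
            raise ValueError("Q/K/V maps must share a shape")
        h, w, c = self.q_map.shape
        if h * w * c != PROJ_DIM * c or (h, w) != (MAP_H, MAP_W):
            raise ValueError(f"maps must be {MAP_H}x{MAP_W}xC")


@dataclass
class CrossAttentionMap:
    """Affinities and softmax weights over each position's criss-cross set.

    The cross set of u = (r, c) is ordered row-first: K[r, 0..W-1], then
    K[0..H-1, c] excluding K[r, c] (the centre is counted once), giving
    H+W-1 entries.
    """

    affinities: np.ndarray   # (H, W, H+W-1)
    weights: np.ndarray      # (H, W, H+W-1), rows sum to 1

    def __post_init__(self):
        h, w, n = self.weights.shape
        if n != h + w - 1:
            raise ValueError("cross set must have H+W-1 entries")
        sums = self.weights.sum(axis=-1)
        if np.any(np.abs(sums - 1.0) > 1e-6) or np.any(self.weights < 0):
            raise ValueError("attention weights must be a distribution")


@dataclass
class FusedMap:
    map: np.ndarray    # (H, W, C)
    flat: np.ndarray   # (H*W*C,)


def _cross_order(r: int, c: int, h: int, w: int) -> list[tuple[int, int]]:
    """Positions of u's criss-cross set in the documented order."""
    return [(r, j) for j in range(w)] + [(i, c) for i in range(h) if i != r]


def cca_affinity(q_map: np.ndarray, k_map: np.ndarray) -> CrossAttentionMap:
    """Affinity + softmax over each position's criss-cross set."""
    q = np.asarray(q_map, dtype=np.float64)
    k = np.asarray(k_map, dtype=np.float64)
    if q.shape != k.shape:
        raise ValueError("Q and K maps must be congruent")
    if q.ndim == 2:
        q, k = q[..., None], k[..., None]
    h, w, _ = q.shape
    # row part: d[r, c, j] = Q[r, c] . K[r, j]
    d_row = np.einsum("rwc,rjc->rwj", q, k)
    # column part: d[r, c, i] = Q[r, c] . K[i, c]
    d_col = np.einsum("rwc,iwc->rwi", q, k)
    rows = np.arange(h)
    aff = np.empty((h, w, h + w - 1))
    aff[:, :, :w] = d_row
    for r in rows:  # drop the duplicated centre from the column run
        aff[r, :, w:] = d_col[r][:, np.delete(np.arange(h), r)]
    z = aff - aff.max(axis=-1, keepdims=True)
    e = np.exp(z)
    weights = e / e.sum(axis=-1, keepdims=True)
    return CrossAttentionMap(affinities=aff, weights=weights)


def cca_aggregate(attn: CrossAttentionMap, v_map: np.ndarray,
                  residual: bool = False) -> FusedMap:
    """Weighted sum of V over each position's criss-cross set."""
    v = np.asarray(v_map, dtype=np.float64)
    if v.ndim == 2:
        v = v[..., None]
    h, w, c = v.shape
    a = attn.weights
    out = np.einsum("rwj,rjc->rwc", a[:, :, :w], v)
    for r in range(h):
        rows = np.delete(np.arange(h), r)
        out[r] += np.einsum("wi,iwc->wc", a[r, :, w:], v[rows])
    if residual:
        out = out + v
    return FusedMap(map=out, flat=out.reshape(-1))


class FusionModel(_nn.Module):
    """Learned projections + CCA + dense-2 head.

    ``normalizer`` holds per-path z-score statistics fitted on the training
    fold only.
    """

    def __init__(self, dims: dict[str, int], rng: np.random.Generator,
                 bias: bool = False, residual: bool = False,
                 assignment: tuple[str, str, str] = ("radiomic", "spatial",
                                                     "temporal")):
        self.assignment = assignment
        self.proj = {path: _nn.Linear(dims[path], PROJ_DIM, rng, bias=bias)
                     for path in ("radiomic", "spatial", "temporal")}
        self.head = _nn.Linear(PROJ_DIM, 2, rng)
        self.residual = residual
        self.normalizer: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        # duplicate-centre mask for the joint row+column softmax
        mask = np.zeros((MAP_H, MAP_W, MAP_W + MAP_H))
        for r in range(MAP_H):
            mask[r, :, MAP_W + r] = -1e9
        self._dup_mask = mask

    def parameters(self):
        out = []
        for p in ("radiomic", "spatial", "temporal"):
            out += self.proj[p].parameters()
        return out + self.head.parameters()

    def fit_normalizer(self, features: dict[str, np.ndarray]) -> None:
        for path, x in features.items():
            mu = x.mean(axis=0)
            sd = x.std(axis=0)
            self.normalizer[path] = (mu, np.where(sd > 1e-8, sd, 1.0))

    def _normalize(self, path: str, x: np.ndarray) -> np.ndarray:
        if path not in self.normalizer:
            return x
        mu, sd = self.normalizer[path]
        return (x - mu) / sd

    def _project(self, features: dict[str, np.ndarray]) -> dict[str, Tensor]:
        maps = {}
        for path in ("radiomic", "spatial", "temporal"):
            x = Tensor(self._normalize(path, np.atleast_2d(features[path])))
            z = self.proj[path](x)
            maps[path] = _nn.reshape(z, (-1, MAP_H, MAP_W, 1))
        return maps

    def _fuse(self, features: dict[str, np.ndarray]) -> Tensor:
        maps = self._project(features)
        q = maps[self.assignment[0]]
        k = maps[self.assignment[1]]
        v = maps[self.assignment[2]]
        # row affinities: (B, H, W, C) x (B, H, W, C) -> (B, H, W, W)
        kt_row = _nn.transpose(k, (0, 1, 3, 2))
        d_row = _nn.matmul(q, kt_row)
        # column affinities: transpose to (B, W, H, C) -> (B, W, H, H)
        qt = _nn.transpose(q, (0, 2, 1, 3))
        kt_col = _nn.transpose(k, (0, 2, 3, 1))
        d_col = _nn.transpose(_nn.matmul(qt, kt_col), (0, 2, 1, 3))
        d = _nn.concat([d_row, d_col], axis=-1)      # (B, H, W, W+H)
        a = _nn.softmax(_nn.add(d, Tensor(self._dup_mask[None])), axis=-1)
        a_row = _nn._index(a, (slice(None), slice(None), slice(None),
                               slice(0, MAP_W)))
        a_col = _nn._index(a, (slice(None), slice(None), slice(None),
                               slice(MAP_W, MAP_W + MAP_H)))
        fused_row = _nn.matmul(a_row, v)             # (B, H, W, C)
        a_col_t = _nn.transpose(a_col, (0, 2, 1, 3))  # (B, W, H, H)
        v_t = _nn.transpose(v, (0, 2, 1, 3))          # (B, W, H, C)
        fused_col = _nn.transpose(_nn.matmul(a_col_t, v_t), (0, 2, 1, 3))
        fused = _nn.add(fused_row, fused_col)
        if self.residual:
            fused = _nn.add(fused, v)
        return _nn.reshape(fused, (-1, PROJ_DIM))

    def logits(self, features: dict[str, np.ndarray]) -> Tensor:
        return self.head(self._fuse(features))

    def predict_proba(self, features: dict[str, np.ndarray]) -> np.ndarray:
        return _nn.softmax(self.logits(features), axis=-1).data


def project_triple(model: FusionModel, radiomic: np.ndarray,
                   spatial: np.ndarray, temporal: np.ndarray
                   ) -> ProjectedTriple:
    """Project one case's three path features to 10x10 Q/K/V maps."""
    maps = model._project({"radiomic": radiomic[None],
                           "spatial": spatial[None],
                           "temporal": temporal[None]})
    by_path = {p: maps[p].data[0] for p in maps}
    return ProjectedTriple(q_map=by_path[model.assignment[0]],
                           k_map=by_path[model.assignment[1]],
                           v_map=by_path[model.assignment[2]])


def fuse_and_classify(model: FusionModel, triple: ProjectedTriple
                      ) -> np.ndarray:
    """Class probabilities (p_G1, p_G2) for a projected triple."""
    attn = cca_affinity(triple.q_map, triple.k_map)
    fused = cca_aggregate(attn, triple.v_map, residual=model.residual)
    if not np.all(np.isfinite(fused.flat)):
        raise FloatingPointError("non-finite values after CCA aggregation")
    logits = model.head(Tensor(fused.flat[None]))
    return _nn.softmax(logits, axis=-1).data[0]


def fusion_train(features: dict[str, np.ndarray], labels: np.ndarray,
                 cfg: StageConfig, seed: int, bias: bool = False,
                 val_fraction: float = 0.2
                 ) -> tuple[FusionModel, dict]:
    """Train projections and head jointly under binary cross-entropy with
    early stopping on an internal validation split; upstream feature
    extractors are frozen inputs here."""
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("training fold must contain both classes")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 40]))
    dims = {p: features[p].shape[1] for p in features}
    model = FusionModel(dims, rng, bias=bias)
    model.fit_normalizer(features)
    n = len(labels)
    n_val = max(1, int(round(val_fraction * n))) if n > 4 else 0
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    def subset(idx):
        return {p: features[p][idx] for p in features}

    params = model.parameters()
    opt = {"adam": _nn.Adam, "adamw": _nn.AdamW}[cfg.optimizer.lower()](
        params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay,
        decay_mask=[p.data.ndim > 1 for p in params])

    def eval_loss(idx) -> float:
        if len(idx) == 0:
            return np.nan
        return float(_nn.cross_entropy_logits(
            model.logits(subset(idx)), labels[idx]).data)

    best = eval_loss(val_idx) if n_val else np.inf
    best_state = [p.data.copy() for p in params]
    bad = 0
    history = {"train": [], "val": []}
    for _ in range(cfg.epochs):
        order = rng.permutation(len(train_idx))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = train_idx[order[i:i + cfg.batch_size]]
            opt.zero_grad()
            loss = _nn.cross_entropy_logits(model.logits(subset(idx)),
                                            labels[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError("non-finite training loss")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["train"].append(float(np.mean(losses)))
        if n_val:
            v = eval_loss(val_idx)
            history["val"].append(v)
            if v < best - 1e-6:
                best, bad = v, 0
                best_state = [p.data.copy() for p in params]
            else:
                bad += 1
                if cfg.patience is not None and bad > cfg.patience:
                    break
    if n_val:
        for p, s in zip(params, best_state):
            p.data[...] = s
    return model, history
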