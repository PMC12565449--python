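"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own vectorised code paths: naive
per-pixel convolution, direct moment formulas, exhaustive per-position
attention loops, and the rank-statistic form of the AUC.
"""

import math

import numpy as np


def naive_log_value(x: float, y: float, sigma: float) -> float:
    r2 = x * x + y * y
    return (-1.0 / (math.pi * sigma**4)
            * (1.0 - r2 / (2.0 * sigma**2))
            * math.exp(-r2 / (2.0 * sigma**2)))


def naive_filter_at(slice_hu: np.ndarray, kernel: np.ndarray,
                    points: list[tuple[int, int]]) -> np.ndarray:
    """Convolution values at selected pixels, symmetric-reflect boundary."""
    r = kernel.shape[0] // 2
    padded = np.pad(slice_hu, r, mode="symmetric")
    out = np.empty(len(points))
    for n, (i, j) in enumerate(points):
        window = padded[i:i + 2 * r + 1, j:j + 2 * r + 1]
        out[n] = float((window * kernel).sum())
    return out


def naive_stats(values: np.ndarray) -> dict:
    """Direct moment formulas + 64-bin entropy, population conventions."""
    v = np.asarray(values, dtype=np.float64)
    n = v.size
    mean = v.sum() / n
    var = ((v - mean) ** 2).sum() / n
    sd = math.sqrt(var)
    vmin, vmax = v.min(), v.max()
    if vmax > vmin:
        edges = np.linspace(vmin, vmax, 65)
        counts = np.zeros(64)
        for x in v:
            b = min(int((x - vmin) / (vmax - vmin) * 64), 63)
            counts[b] += 1
        p = counts[counts > 0] / n
        entropy = float(-(p * np.log2(p)).sum())
    else:
        entropy = 0.0
    pos = v[v > 0]
    mpp = float(pos.sum() / pos.size) if pos.size else 0.0
    if sd > 0:
        skew = float((((v - mean) / sd) ** 3).sum() / n)
        kurt = float((((v - mean) / sd) ** 4).sum() / n - 3.0)
    else:
        skew = kurt = 0.0
    return {"mean": float(mean), "sd": sd, "entropy": entropy, "mpp": mpp,
            "skewness": skew, "kurtosis": kurt}


def naive_radiomics(voxels: np.ndarray, mask: np.ndarray, spacing: float,
                    ssf_values=(0, 2, 3, 4, 5, 6)) -> np.ndarray:
    """Per-scale naive filtration at in-mask pixels + direct statistics."""
    from nodulefusion.radiomics3d import build_log_kernel  # kernel only

    feats = []
    slice_hits = np.flatnonzero(mask.reshape(mask.shape[0], -1).any(axis=1))
    for ssf in ssf_values:
        pooled = []
        kernel = None if ssf == 0 else build_log_kernel(float(ssf), spacing)
        for idx in slice_hits:
            pts = [tuple(p) for p in np.argwhere(mask[idx] > 0)]
            if kernel is None:
                pooled.extend(voxels[idx][i, j] for i, j in pts)
            else:
                pooled.extend(naive_filter_at(voxels[idx], kernel.kernel, pts))
        s = naive_stats(np.array(pooled))
        feats.extend([s["mean"], s["sd"], s["entropy"], s["mpp"],
                      s["skewness"], s["kurtosis"]])
    return np.array(feats)


def naive_cca(q: np.ndarray, k: np.ndarray, v: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustive per-position criss-cross attention and aggregation."""
    h, w, c = q.shape
    n = h + w - 1
    weights = np.zeros((h, w, n))
    fused = np.zeros((h, w, c))
    for r in range(h):
        for col in range(w):
            omega = [(r, j) for j in range(w)] + \
                    [(i, col) for i in range(h) if i != r]
            d = np.array([float(q[r, col] @ k[i, j]) for i, j in omega])
            e = np.exp(d - d.max())
            a = e / e.sum()
            weights[r, col] = a
            fused[r, col] = sum(ai * v[i, j] for ai, (i, j) in zip(a, omega))
    return weights, fused


def naive_confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> dict:
    total = tp + tn + fp + fn
    out = {"accuracy": (tp + tn) / total}
    out["sensitivity"] = tp / (tp + fn) if tp + fn else None
    out["specificity"] = tn / (tn + fp) if tn + fp else None
    out["precision"] = tp / (tp + fp) if tp + fp else None
    if out["precision"] is not None and out["sensitivity"] is not None \
            and out["precision"] + out["sensitivity"] > 0:
        out["f1_g2"] = (2 * out["precision"] * out["sensitivity"]
                        / (out["precision"] + out["sensitivity"]))
    else:
        out["f1_g2"] = None
    prec_n = tn / (tn + fn) if tn + fn else None
    rec_n = out["specificity"]
    if prec_n is not None and rec_n is not None and prec_n + rec_n > 0:
        out["f1_g1"] = 2 * prec_n * rec_n / (prec_n + rec_n)
    else:
        out["f1_g1"] = None
    return out


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney statistic with half credit for ties."""
    pos = np.asarray(scores)[np.asarray(labels) == 1]
    neg = np.asarray(scores)[np.asarray(labels) == 0]
    wins = 0.0
    for p in pos:
        wins += float((p > neg).sum()) + 0.5 * float((p == neg).sum())
    return wins / (len(pos) * len(neg))
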