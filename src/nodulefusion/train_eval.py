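"""Staged training, stratified k-fold cross-validation and reporting.

Per fold, every fitted quantity — auto-encoder weights, temporal and
spatial encoders, feature z-scores, fusion weights, early-stopping
decisions — is a function of the training fold only; the test fold is
scored exactly once.  Radiomic features involve no fitting and are computed
once per case.  Metrics follow the standard confusion-matrix definitions
with G2 (invasive) as the positive class; per-class F1 is obtained by
recomputing with each class as positive.  ROC/AUC uses all distinct score
thresholds with trapezoidal integration (equivalent to the Mann-Whitney
rank statistic with half credit for ties).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn import metrics as skm

from . import _nn
from .dataio import (CTVolume, NoduleMask, CohortTable, RunConfig,
                     StageConfig, POSITIVE_LABEL)
from .preprocess import select_slices, build_patch_stack, lung_slices
from .radiomics3d import extract_radiomics, FEATURE_NAMES
from .temporal_path import (CAEConfig, cae_pretrain, cae_finetune,
                            embed_sequence, temporal_train)
from .cca_fusion import fusion_train
from .spatial_path import SpatialEncoderConfig, spatial_train, spatial_features

log = logging.getLogger("nodulefusion")

__all__ = [
    "ConfusionCounts", "FoldMetrics", "CVSummary", "CaseData",
    "stratified_folds", "compute_metrics", "roc_auc", "reduced_config",
    "prepare_cases", "run_cross_validation", "label_shuffle_control",
    "report",
]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(counts: ConfusionCounts) -> dict:
    """Accuracy, sensitivity, specificity, precision and F1 from counts.

    Ratios with a zero denominator are reported as None together with a
    flag naming the undefined quantity (never silently 0).  ``f1_g2`` is
    the F1 of the positive (invasive) class; ``f1_g1`` recomputes with G1
    as positive.
    """
    if counts.total == 0:
        raise ValueError("no evaluated cases")
    sens = _ratio(counts.tp, counts.tp + counts.fn)
    spec = _ratio(counts.tn, counts.tn + counts.fp)
    prec = _ratio(counts.tp, counts.tp + counts.fp)
    if prec is not None and sens is not None and (prec + sens) > 0:
        f1_pos = 2 * prec * sens / (prec + sens)
    else:
        f1_pos = None
    # G1 as positive class: swap roles
    prec_n = _ratio(counts.tn, counts.tn + counts.fn)
    rec_n = spec
    if prec_n is not None and rec_n is not None and (prec_n + rec_n) > 0:
        f1_neg = 2 * prec_n * rec_n / (prec_n + rec_n)
    else:
        f1_neg = None
    out = {
        "accuracy": (counts.tp + counts.tn) / counts.total,
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f1_g2": f1_pos,
        "f1_g1": f1_neg,
        "flags": [k for k, v in
                  (("sensitivity", sens), ("specificity", spec),
                   ("precision", prec), ("f1_g2", f1_pos), ("f1_g1", f1_neg))
                  if v is None],
    }
    return out


def roc_auc(scores: np.ndarray, labels: np.ndarray
            ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus ROC curve points (fpr, tpr); labels are 0/1 with 1 positive."""
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("ROC needs both classes")
    fpr, tpr, _ = skm.roc_curve(labels, scores)
    return float(skm.auc(fpr, tpr)), fpr, tpr


def stratified_folds(labels: dict[str, str], k: int = 10, seed: int = 42
                     ) -> list[tuple[list[str], list[str]]]:
    """Patient-level class-stratified partition into k folds."""
    ids = list(labels)
    y = [labels[i] for i in ids]
    counts = pd.Series(y).value_counts()
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} cases, fewer than k={k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for train_idx, test_idx in skf.split(ids, y):
        folds.append(([ids[i] for i in train_idx], [ids[i] for i in test_idx]))
    return folds


# ---------------------------------------------------------------------------
# study-scale configuration
# ---------------------------------------------------------------------------

def reduced_config(seed: int = 42) -> RunConfig:
    """The CPU-scale study configuration used by the package's own
    evaluation runs: reduced model widths and epoch budgets.  Training
    starts from random initialisation, so the two fine-tuning learning
    rates of the published protocol are raised to from-scratch values;
    optimisers, weight decay, dropout and the fusion budget are kept."""
    cfg = RunConfig(seed=seed, reduced=True)
    cfg.cae_pretrain = StageConfig(optimizer="adam", learning_rate=1e-3,
                                   epochs=6, batch_size=32)
    cfg.cae_finetune = StageConfig(optimizer="adam", learning_rate=1e-4,
                                   epochs=2, batch_size=32)
    cfg.cae_transformer = StageConfig(optimizer="adam", learning_rate=1e-3,
                                      epochs=60, batch_size=16, dropout=0.3)
    cfg.spatial = StageConfig(optimizer="adamw", learning_rate=3e-4,
                              epochs=20, batch_size=8, weight_decay=0.05,
                              patience=6, dropout=0.1)
    cfg.cca = StageConfig(optimizer="adamw", learning_rate=1e-3, epochs=20,
                          batch_size=8, weight_decay=0.05, patience=5)
    return cfg


# ---------------------------------------------------------------------------
# case preparation
# ---------------------------------------------------------------------------

@dataclass
class CaseData:
    """Everything the learned and hand-crafted paths need for one case."""

    case_id: str
    label: str
    radiomic: np.ndarray        # (36,)
    patches: np.ndarray         # (n_slices, 224, 224)
    lung_images: np.ndarray     # (n_slices, 256, 256)

    @property
    def y(self) -> int:
        return 1 if self.label == POSITIVE_LABEL else 0


def prepare_cases(pairs: list[tuple[CTVolume, NoduleMask, str]],
                  segmenter="fallback") -> list[CaseData]:
    """Deterministic, label-free preprocessing + radiomics for all cases."""
    out = []
    for volume, mask, label in pairs:
        sel = select_slices(mask)
        patch_stack = build_patch_stack(volume, mask, sel)
        lung_stack = lung_slices(volume, sel, segmenter)
        rad = extract_radiomics(volume, mask)
        out.append(CaseData(case_id=volume.case_id, label=label,
                            radiomic=rad.values, patches=patch_stack.patches,
                            lung_images=lung_stack.images))
    return out


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldMetrics:
    fold: int
    counts: ConfusionCounts
    metrics: dict
    auc: float
    probabilities: dict[str, float]      # case_id -> p(G2)
    path_accuracy: dict[str, float]      # per-path test accuracy

    def __post_init__(self):
        recomputed = compute_metrics(self.counts)
        for key in ("accuracy", "sensitivity", "specificity"):
            a, b = recomputed[key], self.metrics[key]
            assert (a is None and b is None) or abs(a - b) < 1e-12


@dataclass
class CVSummary:
    folds: list[FoldMetrics]
    mean: dict[str, float]
    std: dict[str, float]
    cv_percent: float                     # 100 * std/mean of fold accuracies
    mean_roc: tuple[np.ndarray, np.ndarray]
    path_mean_accuracy: dict[str, float]
    fold_features: list[dict] = field(default_factory=list, repr=False)
    fold_assignments: list[tuple[list[str], list[str]]] = field(
        default_factory=list, repr=False)
    labels: dict[str, int] = field(default_factory=dict, repr=False)
    config: dict = field(default_factory=dict, repr=False)


_METRIC_KEYS = ("accuracy", "sensitivity", "specificity", "precision",
                "f1_g1", "f1_g2", "auc")


def _counts_from_predictions(y_true: np.ndarray, p_pos: np.ndarray,
                             threshold: float = 0.5) -> ConfusionCounts:
    pred = (p_pos >= threshold).astype(int)
    return ConfusionCounts(
        tp=int(((pred == 1) & (y_true == 1)).sum()),
        tn=int(((pred == 0) & (y_true == 0)).sum()),
        fp=int(((pred == 1) & (y_true == 0)).sum()),
        fn=int(((pred == 0) & (y_true == 1)).sum()),
    )


def _fold_seed(seed: int, fold: int, stage: int) -> int:
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, fold, stage])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def fit_fold_features(cases: dict[str, CaseData], train_ids: list[str],
                      config: RunConfig, fold: int,
                      max_cae_slices: int = 96,
                      spatial_train_slices: int | None = 3,
                      spatial_infer_slices: int | None = 3
                      ) -> tuple[dict, dict]:
    """Train the two learned paths on the training fold and extract features
    for every case.  Returns (features, heads): features maps path name ->
    {case_id: vector}; heads carries the per-path classifiers used for the
    single-path comparison."""
    seed = config.seed
    all_ids = sorted(cases)
    labels = {i: cases[i].y for i in all_ids}

    # -- temporal path ------------------------------------------------------
    rng = np.random.default_rng(_fold_seed(seed, fold, 1))
    train_slices = np.concatenate(
        [cases[i].lung_images for i in train_ids], axis=0)
    if len(train_slices) > max_cae_slices:
        keep = rng.choice(len(train_slices), max_cae_slices, replace=False)
        train_slices = train_slices[keep]
    cae_cfg = CAEConfig.reduced() if config.reduced else CAEConfig()
    cae, _ = cae_pretrain(train_slices, config.cae_pretrain,
                          _fold_seed(seed, fold, 2), cae_cfg)
    cae_finetune(cae, train_slices, config.cae_finetune,
                 _fold_seed(seed, fold, 3))
    sequences = {i: embed_sequence(cae, _as_stack(cases[i])) for i in all_ids}
    encoder, _ = temporal_train([sequences[i] for i in train_ids],
                                np.array([labels[i] for i in train_ids]),
                                config.cae_transformer,
                                _fold_seed(seed, fold, 4))
    temporal = {i: encoder.features([sequences[i]])[0] for i in all_ids}

    # -- spatial path -------------------------------------------------------
    sp_cfg = (SpatialEncoderConfig.reduced() if config.reduced
              else SpatialEncoderConfig.full())
    backbone, hist = spatial_train(
        {i: cases[i].patches for i in train_ids},
        labels, config.spatial, _fold_seed(seed, fold, 5), sp_cfg,
        max_train_slices=spatial_train_slices)
    spatial = spatial_features(backbone, {i: cases[i].patches for i in all_ids},
                               max_slices=spatial_infer_slices)

    features = {
        "radiomic": {i: cases[i].radiomic for i in all_ids},
        "spatial": spatial,
        "temporal": temporal,
    }
    heads = {"temporal": (encoder, sequences), "spatial": hist["head"]}
    return features, heads


def _as_stack(case: CaseData):
    from .preprocess import LungSliceStack
    return LungSliceStack(case_id=case.case_id, images=case.lung_images,
                          lung_masks=np.ones_like(case.lung_images,
                                                  dtype=np.uint8))


def _path_test_accuracy(features: dict, heads: dict, cases, train_ids,
                        test_ids, seed: int) -> dict[str, float]:
    """Single-path test accuracies for the fusion-benefit comparison."""
    y_tr = np.array([cases[i].y for i in train_ids])
    y_te = np.array([cases[i].y for i in test_ids])
    out = {}
    # radiomic path: logistic head on the 36 features (fit on train fold)
    scaler = StandardScaler().fit(
        np.stack([features["radiomic"][i] for i in train_ids]))
    lr = LogisticRegression(max_iter=2000, random_state=seed)
    lr.fit(scaler.transform(
        np.stack([features["radiomic"][i] for i in train_ids])), y_tr)
    pred = lr.predict(scaler.transform(
        np.stack([features["radiomic"][i] for i in test_ids])))
    out["radiomic"] = float((pred == y_te).mean())
    # temporal path: the trained temporal head
    encoder, sequences = heads["temporal"]
    logits = encoder.logits([sequences[i] for i in test_ids]).data
    out["temporal"] = float((logits.argmax(axis=1) == y_te).mean())
    # spatial path: the trained spatial head on pooled features
    head = heads["spatial"]
    sp = np.stack([features["spatial"][i] for i in test_ids])
    pred = head(_nn.Tensor(sp)).data.argmax(axis=1)
    out["spatial"] = float((pred == y_te).mean())
    return out


def run_cross_validation(case_list: list[CaseData], config: RunConfig,
                         k: int = 10, path_accuracies: bool = True,
                         **feature_kw) -> CVSummary:
    """Full staged protocol under stratified k-fold cross-validation."""
    cases = {c.case_id: c for c in case_list}
    label_map = {c.case_id: c.label for c in case_list}
    folds = stratified_folds(label_map, k=k, seed=config.seed)
    fold_metrics: list[FoldMetrics] = []
    fold_features = []
    curves = []
    path_acc_acc: dict[str, list[float]] = {}
    for f, (train_ids, test_ids) in enumerate(folds):
        log.info("fold %d/%d: train %d test %d (config %s)", f + 1, k,
                 len(train_ids), len(test_ids), config.config_hash())
        features, heads = fit_fold_features(cases, train_ids, config, f,
                                            **feature_kw)
        train_feats = {p: np.stack([features[p][i] for i in train_ids])
                       for p in features}
        y_train = np.array([cases[i].y for i in train_ids])
        fusion, _ = fusion_train(train_feats, y_train, config.cca,
                                 _fold_seed(config.seed, f, 6))
        test_feats = {p: np.stack([features[p][i] for i in test_ids])
                      for p in features}
        proba = fusion.predict_proba(test_feats)[:, 1]
        y_test = np.array([cases[i].y for i in test_ids])
        counts = _counts_from_predictions(y_test, proba)
        m = compute_metrics(counts)
        auc, fpr, tpr = roc_auc(proba, y_test)
        m["auc"] = auc
        pa = (_path_test_accuracy(features, heads, cases, train_ids,
                                  test_ids, config.seed)
              if path_accuracies else {})
        for p, a in pa.items():
            path_acc_acc.setdefault(p, []).append(a)
        fold_metrics.append(FoldMetrics(
            fold=f, counts=counts, metrics=m, auc=auc,
            probabilities=dict(zip(test_ids, proba.tolist())),
            path_accuracy=pa))
        curves.append((fpr, tpr))
        fold_features.append(features)

    mean, std = {}, {}
    for key in _METRIC_KEYS:
        vals = [fm.metrics[key] for fm in fold_metrics
                if fm.metrics.get(key) is not None]
        mean[key] = float(np.mean(vals)) if vals else None
        std[key] = float(np.std(vals)) if vals else None
    accs = [fm.metrics["accuracy"] for fm in fold_metrics]
    cv_percent = float(100.0 * np.std(accs) / np.mean(accs)) \
        if np.mean(accs) > 0 else float("nan")
    grid = np.linspace(0, 1, 101)
    tprs = [np.interp(grid, fpr, tpr) for fpr, tpr in curves]
    return CVSummary(
        folds=fold_metrics, mean=mean, std=std, cv_percent=cv_percent,
        mean_roc=(grid, np.mean(tprs, axis=0)),
        path_mean_accuracy={p: float(np.mean(v))
                            for p, v in path_acc_acc.items()},
        fold_features=fold_features,
        fold_assignments=folds,
        labels={c.case_id: c.y for c in case_list},
        config=dataclasses.asdict(config),
    )


def label_shuffle_control(summary: CVSummary, cfg: StageConfig, seed: int,
                          n_shuffles: int = 10) -> dict:
    """Permutation null for the fused accuracy: per shuffle, permute the
    case labels globally, retrain the fusion stage per fold on the (frozen)
    training-fold path features, and score the test folds.  The unsupervised
    auto-encoder and the deterministic radiomics never see labels, so the
    fusion stage is where a label permutation can act."""
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 99]))
    ids = sorted(summary.labels)
    y = np.array([summary.labels[i] for i in ids])
    means = []
    for s in range(n_shuffles):
        perm = rng.permutation(len(ids))
        shuffled = dict(zip(ids, y[perm]))
        correct = total = 0
        for f, (train_ids, test_ids) in enumerate(summary.fold_assignments):
            features = summary.fold_features[f]
            train_feats = {p: np.stack([features[p][i] for i in train_ids])
                           for p in features}
            y_tr = np.array([shuffled[i] for i in train_ids])
            if len(set(y_tr.tolist())) < 2:   # degenerate shuffle
                continue
            fusion, _ = fusion_train(train_feats, y_tr, cfg,
                                     int(rng.integers(0, 2**31)))
            test_feats = {p: np.stack([features[p][i] for i in test_ids])
                          for p in features}
            pred = fusion.predict_proba(test_feats)[:, 1] >= 0.5
            y_te = np.array([shuffled[i] for i in test_ids])
            correct += int((pred == y_te).sum())
            total += len(test_ids)
        means.append(correct / total)
    means = np.asarray(means)
    return {
        "mean_accuracy": float(means.mean()),
        "se": float(means.std(ddof=1) / np.sqrt(len(means))),
        "per_shuffle": means.tolist(),
    }


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def _fold_row(fm: FoldMetrics) -> dict:
    row = {"fold": fm.fold}
    row.update({k: fm.metrics.get(k) for k in _METRIC_KEYS})
    row.update({"tp": fm.counts.tp, "tn": fm.counts.tn,
                "fp": fm.counts.fp, "fn": fm.counts.fn})
    for p, a in fm.path_accuracy.items():
        row[f"acc_{p}"] = a
    return row


def report(summary: CVSummary, out_dir: str | Path, plots: bool = False
           ) -> dict[str, Path]:
    """Write summary.json, folds.csv, roc.csv and per-fold confusion text."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    payload = {
        "mean": summary.mean,
        "std": summary.std,
        "cv_percent": summary.cv_percent,
        "path_mean_accuracy": summary.path_mean_accuracy,
        "n_folds": len(summary.folds),
        "folds": [_fold_row(fm) for fm in summary.folds],
    }
    paths["summary"] = out_dir / "summary.json"
    paths["summary"].write_text(json.dumps(payload, indent=2))

    frame = pd.DataFrame([_fold_row(fm) for fm in summary.folds])
    paths["folds"] = out_dir / "folds.csv"
    frame.to_csv(paths["folds"], index=False)

    fpr, tpr = summary.mean_roc
    paths["roc"] = out_dir / "roc.csv"
    pd.DataFrame({"fpr": fpr, "mean_tpr": tpr}).to_csv(paths["roc"],
                                                       index=False)

    for fm in summary.folds:
        p = out_dir / f"confusion_fold{fm.fold}.txt"
        p.write_text(
            f"fold {fm.fold}\n"
            f"            pred G1  pred G2\n"
            f"true G1     {fm.counts.tn:7d}  {fm.counts.fp:7d}\n"
            f"true G2     {fm.counts.fn:7d}  {fm.counts.tp:7d}\n"
        )
    if plots:
        try:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
            fig, ax = plt.subplots()
            ax.plot(fpr, tpr, label="mean ROC")
            ax.plot([0, 1], [0, 1], "k--", alpha=0.4)
            ax.set_xlabel("false positive rate")
            ax.set_ylabel("true positive rate")
            ax.legend()
            fig.savefig(out_dir / "roc.png", dpi=120)
            plt.close(fig)
        except ImportError:
            log.warning("matplotlib unavailable; skipping plots")
    return paths
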