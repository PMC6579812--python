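"""CNN architecture grid search with stratified cross-validation.

Protocol: 20% of the data is first held out in a stratified manner; the
remaining training portion is split into stratified folds (default 3).
Each candidate architecture trains for a fixed number of epochs per fold,
validation metrics (accuracy, F1, AUC) are recorded after every epoch, and
a fold's result is its best-validation-F1 epoch (earliest epoch on ties).
The grid winner maximises mean fold F1, with mean AUC breaking ties and
the smaller parameter count breaking any remainder.

The default grid crosses 1-3 conv layers x 1-3 dense layers x a shared
layer width from the powers of two in [2, 256]: 72 architectures.  A
"tapered" preset with per-layer decreasing widths is also provided.

DL scores — per-variant driver probabilities used downstream as a feature —
are produced leakage-free by default: training-portion samples are scored
out-of-fold and holdout samples by a model refit on the full training
portion.  ``paper_mode=True`` instead scores the entire dataset with the
single refit model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import metrics
from ._network import SmallCNN
from .encoders import BLOCK_SIZE

logger = logging.getLogger(__name__)

ALLOWED_WIDTHS = (2, 4, 8, 16, 32, 64, 128, 256)


@dataclass(frozen=True)
class ArchitectureSpec:
    """One CNN configuration: conv filter counts, dense widths, kernel, dropout."""

    conv_filters: tuple[int, ...]
    dense_widths: tuple[int, ...]
    kernel_symbols: int = 3
    dropout: float = 0.25

    def __post_init__(self) -> None:
        for name, widths in (("conv_filters", self.conv_filters), ("dense_widths", self.dense_widths)):
            if not 1 <= len(widths) <= 3:
                raise ValueError(f"{name} must list 1-3 layers, got {len(widths)}")
            for w in widths:
                if w not in ALLOWED_WIDTHS:
                    raise ValueError(f"{name} width {w} must be a power of 2 in [2, 256]")
        if not 0 <= self.dropout < 1:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")

    def describe(self) -> str:
        return f"conv{list(self.conv_filters)}-dense{list(self.dense_widths)}"

    def build(self, input_len: int, block: int = 1, learning_rate: float = 1e-3, seed: int = 0) -> SmallCNN:
        return SmallCNN(
            conv_filters=self.conv_filters,
            dense_widths=self.dense_widths,
            input_len=input_len,
            block=block,
            kernel_symbols=self.kernel_symbols,
            dropout=self.dropout,
            learning_rate=learning_rate,
            seed=seed,
        )

    def param_count(self, input_len: int, block: int = 1) -> int:
        return self.build(input_len, block=block, seed=0).param_count()


@dataclass
class TrainingConfig:
    """Shared training protocol settings."""

    epochs: int = 100
    folds: int = 3
    holdout: float = 0.20
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    block: int = 1  # per-symbol column width of the encoding scheme

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not 0 < self.holdout < 1:
            raise ValueError("holdout fraction must be in (0, 1)")

    @classmethod
    def for_scheme(cls, scheme: str, **kwargs) -> "TrainingConfig":
        return cls(block=BLOCK_SIZE[scheme], **kwargs)


@dataclass
class FoldRecord:
    """Per-fold training outcome with the full per-epoch validation history."""

    fold: int
    history: pd.DataFrame  # columns: epoch, accuracy, f1, auc
    best_epoch: int
    best_accuracy: float
    best_f1: float
    best_auc: float
    train_index: np.ndarray = field(repr=False, default=None)
    val_index: np.ndarray = field(repr=False, default=None)


@dataclass
class GridSearchResult:
    summaries: pd.DataFrame  # one row per architecture: mean_f1, mean_auc, params
    selected: ArchitectureSpec
    fold_records: dict[str, list[FoldRecord]]
    config: TrainingConfig


def enumerate_architectures(
    conv_depths=(1, 2, 3),
    dense_depths=(1, 2, 3),
    widths=ALLOWED_WIDTHS,
    kernel_symbols: int = 3,
    dropout: float = 0.25,
) -> list[ArchitectureSpec]:
    """Shared-width grid: one spec per (conv depth, dense depth, width)."""
    if not conv_depths or not dense_depths or not widths:
        raise ValueError("grid axes must be non-empty")
    specs = []
    for cd in sorted(conv_depths):
        for dd in sorted(dense_depths):
            for w in sorted(widths):
                specs.append(
                    ArchitectureSpec(
                        conv_filters=(w,) * cd,
                        dense_widths=(w,) * dd,
                        kernel_symbols=kernel_symbols,
                        dropout=dropout,
                    )
                )
    return specs


#: tapered per-layer width lists (trailing 2-node output head omitted):
#: the last width is the dense stack, preceding widths are conv filters;
#: a single width serves as both.
TAPERED_LAYERS = [
    (32,),
    (16, 8),
    (16, 16),
    (32, 16),
    (32, 8),
    (64, 32),
    (64, 16),
    (64, 64, 16),
    (128, 64, 16),
    (128, 64, 32),
    (128, 64, 32, 16),
]


def tapered_preset(kernel_symbols: int = 3, dropout: float = 0.25) -> list[ArchitectureSpec]:
    specs = []
    for widths in TAPERED_LAYERS:
        if len(widths) == 1:
            conv, dense = widths, widths
        else:
            conv, dense = widths[:-1], widths[-1:]
        specs.append(ArchitectureSpec(conv, dense, kernel_symbols, dropout))
    return specs


def _check_dataset(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int)
    if X.ndim != 3 or X.shape[0] != y.size:
        raise ValueError(f"X must be (n, channels, width) aligned with y; got {X.shape} vs {y.size}")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return X, y


def _fit_and_track(
    X_tr, y_tr, X_val, y_val, arch: ArchitectureSpec, cfg: TrainingConfig, seed: int
) -> tuple[SmallCNN, pd.DataFrame]:
    net = arch.build(X_tr.shape[2], block=cfg.block, learning_rate=cfg.learning_rate, seed=seed)
    rows = []
    for epoch in range(cfg.epochs):
        net.train_epoch(X_tr, y_tr, batch_size=cfg.batch_size)
        p = net.predict_proba(X_val)
        rep = metrics.evaluate(y_val, (p >= 0.5).astype(int), scores=p)
        rows.append({"epoch": epoch, "accuracy": rep.accuracy, "f1": rep.f1, "auc": rep.auc})
    return net, pd.DataFrame(rows)


def train_evaluate_cv(
    X: np.ndarray, y: np.ndarray, arch: ArchitectureSpec, cfg: TrainingConfig
) -> list[FoldRecord]:
    """Stratified k-fold training with per-epoch validation tracking."""
    X, y = _check_dataset(X, y)
    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
    records = []
    for fold, (tr, val) in enumerate(skf.split(np.zeros(len(y)), y)):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[val])) < 2:
            raise ValueError(f"fold {fold} is single-class; need >= 2 samples per class per fold")
        net_seed = int(np.random.SeedSequence([cfg.seed, fold]).generate_state(1)[0] % (2**31))
        _, history = _fit_and_track(X[tr], y[tr], X[val], y[val], arch, cfg, net_seed)
        # best epoch by validation F1, earliest on ties
        best = int(history["f1"].idxmax())
        records.append(
            FoldRecord(
                fold=fold,
                history=history,
                best_epoch=best,
                best_accuracy=float(history.loc[best, "accuracy"]),
                best_f1=float(history.loc[best, "f1"]),
                best_auc=float(history.loc[best, "auc"]),
                train_index=tr,
                val_index=val,
            )
        )
    return records


def grid_search(
    X: np.ndarray, y: np.ndarray, grid: list[ArchitectureSpec], cfg: TrainingConfig
) -> GridSearchResult:
    """Evaluate every architecture by CV; select by mean F1, then AUC, then size."""
    if not grid:
        raise ValueError("architecture grid is empty")
    X, y = _check_dataset(X, y)
    rows, fold_records = [], {}
    for arch in grid:
        records = train_evaluate_cv(X, y, arch, cfg)
        fold_records[arch.describe()] = records
        rows.append(
            {
                "architecture": arch.describe(),
                "mean_f1": float(np.mean([r.best_f1 for r in records])),
                "mean_auc": float(np.mean([r.best_auc for r in records])),
                "mean_accuracy": float(np.mean([r.best_accuracy for r in records])),
                "params": arch.param_count(X.shape[2], block=cfg.block),
            }
        )
    summaries = pd.DataFrame(rows)
    order = summaries.sort_values(
        by=["mean_f1", "mean_auc", "params"], ascending=[False, False, True], kind="mergesort"
    )
    selected = grid[int(order.index[0])]
    logger.info("grid search selected %s (mean F1 %.4f)", selected.describe(), order.iloc[0]["mean_f1"])
    return GridSearchResult(summaries=summaries, selected=selected, fold_records=fold_records, config=cfg)


def compute_dl_scores(
    X: np.ndarray,
    y: np.ndarray,
    arch: ArchitectureSpec,
    cfg: TrainingConfig,
    keys: list[str] | None = None,
    paper_mode: bool = False,
) -> pd.DataFrame:
    """Driver-probability (DL) score for every sample.

    Default: stratified 80/20 split; training-portion samples are scored by
    the fold model that never saw them (out-of-fold) and holdout samples by
    a model refit on the whole training portion.  With ``paper_mode`` the
    refit model scores the entire dataset instead.

    Returns a DataFrame with columns key, label, score, provenance and the
    original sample index; provenance records the scoring fold or
    "holdout-model".
    """
    X, y = _check_dataset(X, y)
    n = len(y)
    if keys is None:
        keys = [str(i) for i in range(n)]
    idx = np.arange(n)
    train_idx, hold_idx = train_test_split(
        idx, test_size=cfg.holdout, stratify=y, random_state=cfg.seed, shuffle=True
    )

    scores = np.full(n, np.nan)
    provenance = np.empty(n, dtype=object)

    refit_seed = int(np.random.SeedSequence([cfg.seed, 9999]).generate_state(1)[0] % (2**31))
    net_full = arch.build(X.shape[2], block=cfg.block, learning_rate=cfg.learning_rate, seed=refit_seed)
    for _ in range(cfg.epochs):
        net_full.train_epoch(X[train_idx], y[train_idx], batch_size=cfg.batch_size)

    if paper_mode:
        scores[:] = net_full.predict_proba(X)
        provenance[:] = "holdout-model"
    else:
        skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
        for fold, (tr, val) in enumerate(skf.split(np.zeros(len(train_idx)), y[train_idx])):
            net_seed = int(np.random.SeedSequence([cfg.seed, fold]).generate_state(1)[0] % (2**31))
            net = arch.build(X.shape[2], block=cfg.block, learning_rate=cfg.learning_rate, seed=net_seed)
            tr_abs, val_abs = train_idx[tr], train_idx[val]
            for _ in range(cfg.epochs):
                net.train_epoch(X[tr_abs], y[tr_abs], batch_size=cfg.batch_size)
            scores[val_abs] = net.predict_proba(X[val_abs])
            provenance[val_abs] = f"out-of-fold:{fold}"
        scores[hold_idx] = net_full.predict_proba(X[hold_idx])
        provenance[hold_idx] = "holdout-model"

    assert not np.isnan(scores).any()
    return pd.DataFrame(
        {
            "key": keys,
            "label": y,
            "score": scores,
            "provenance": provenance,
            "sample_index": idx,
            "in_holdout": np.isin(idx, hold_idx),
        }
    )
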