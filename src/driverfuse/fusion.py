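"""Fusing the sequence-derived DL score with functional feature tables.

The classical-classifier stage: a feature table of per-variant numeric
scores (ensemble functional predictors, conservation scores, and the CNN's
DL score) is fit with random forest, gradient boosted trees or an RBF SVM
on an 80/20 stratified split.  Feature importance (impurity decrease,
normalized), recursive feature elimination and pairwise Spearman
correlation support the feature-reduction analysis; an auxiliary
information-value / weight-of-evidence report is available for tables
where that criterion is preferred.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import metrics

logger = logging.getLogger(__name__)

ALGORITHMS = ("random_forest", "gradient_boosted_trees", "svm")

#: named column-selection profiles from the feature-reduction analysis
PROFILES = {
    "top8": ["RadialSVM", "LR", "DL_score", "GerpRS", "LRT", "verPhyloP", "SiPhy", "GerpN"],
    "top3": ["RadialSVM", "LR", "DL_score"],
}


@dataclass
class FeatureTable:
    """Variants x named numeric features with a driver/passenger label column."""

    df: pd.DataFrame
    key_column: str = "key"
    label_column: str = "label"

    def __post_init__(self) -> None:
        if self.df[self.key_column].duplicated().any():
            dup = self.df[self.key_column][self.df[self.key_column].duplicated()].iloc[0]
            raise ValueError(f"duplicate variant key {dup!r}")
        self.df = self.df.reset_index(drop=True)
        labels = self.df[self.label_column].astype(str).str.lower()
        bad = set(labels) - {"driver", "passenger"}
        if bad:
            raise ValueError(f"labels must be driver/passenger, found {sorted(bad)}")
        self.df[self.label_column] = labels

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in (self.key_column, self.label_column)]

    @property
    def y(self) -> np.ndarray:
        return (self.df[self.label_column] == "driver").to_numpy(dtype=int)

    def features(self, columns: list[str] | None = None) -> pd.DataFrame:
        return self.df[columns if columns is not None else self.feature_columns]

    def select(self, columns: list[str]) -> "FeatureTable":
        missing = [c for c in columns if c not in self.df.columns]
        if missing:
            raise KeyError(f"features not in table: {missing}")
        return FeatureTable(
            self.df[[self.key_column, self.label_column] + list(columns)].copy(),
            self.key_column,
            self.label_column,
        )


def read_feature_table(
    path, key_columns: list[str] | str = "key", label_column: str = "label"
) -> FeatureTable:
    """Read a header-carrying TSV of numeric features keyed by variant.

    Missing values (empty cells, NA, .) stay masked as NaN.  Non-numeric
    feature cells raise with their location; duplicate keys raise.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA", "na", ".", ""])
    if isinstance(key_columns, str):
        key_columns = [key_columns]
    for col in [*key_columns, label_column]:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if len(key_columns) > 1:
        df["key"] = df[key_columns].astype(str).agg(":".join, axis=1)
        df = df.drop(columns=key_columns)
        key = "key"
    else:
        key = key_columns[0]
    for col in df.columns:
        if col in (key, label_column):
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(f"{path}: non-numeric value {df[col].iloc[row]!r} in column {col!r}, row {row + 2}")
        df[col] = coerced
    table = FeatureTable(df, key_column=key, label_column=label_column)
    logger.info("feature table: %d rows, %d features", len(df), len(table.feature_columns))
    return table


def attach_dl_score(
    table: FeatureTable, scores: pd.DataFrame, join: str = "inner", column: str = "DL_score"
) -> FeatureTable:
    """Join the DL-score table (columns key, score) onto the feature table."""
    score_map = scores.set_index("key")["score"]
    overlap = table.df[table.key_column].isin(score_map.index).sum()
    if overlap == 0:
        raise ValueError("no variant keys shared between feature table and DL scores")
    df = table.df.copy()
    df[column] = df[table.key_column].map(score_map)
    if join == "inner":
        df = df[df[column].notna()].reset_index(drop=True)
    elif join != "left":
        raise ValueError(f"join must be inner or left, got {join!r}")
    logger.info("attached %s: %d/%d keys matched (%s join)", column, overlap, len(table.df), join)
    return FeatureTable(df, table.key_column, table.label_column)


@dataclass
class FusionConfig:
    holdout: float = 0.20
    seed: int = 0
    n_estimators: int = 200


@dataclass
class FittedModel:
    algorithm: str
    model: object
    feature_names: list[str]
    medians: pd.Series
    scaler: StandardScaler | None
    report: metrics.ClassificationReport
    train_index: np.ndarray = field(repr=False, default=None)
    holdout_index: np.ndarray = field(repr=False, default=None)

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        X = features[self.feature_names].fillna(self.medians).to_numpy(dtype=float)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return self.model.predict_proba(X)[:, 1]


def _make_estimator(algorithm: str, cfg: FusionConfig):
    if algorithm == "random_forest":
        return RandomForestClassifier(n_estimators=cfg.n_estimators, random_state=cfg.seed, n_jobs=1)
    if algorithm == "gradient_boosted_trees":
        return GradientBoostingClassifier(random_state=cfg.seed)
    if algorithm == "svm":
        # probability outputs via internal cross-validated calibration
        return CalibratedClassifierCV(SVC(kernel="rbf", random_state=cfg.seed), ensemble=False)
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


def train_classifier(
    table: FeatureTable,
    algorithm: str,
    cfg: FusionConfig | None = None,
    feature_columns: list[str] | None = None,
) -> FittedModel:
    """Fit one classifier on the stratified 80/20 split and report holdout metrics.

    Missing values take the training-split median; features are standardized
    for the SVM only.  The split is reproducible: the same seed yields the
    same holdout membership for every algorithm.
    """
    cfg = cfg or FusionConfig()
    y = table.y
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    cols = feature_columns or table.feature_columns
    X = table.features(cols)
    idx = np.arange(len(y))
    tr, ho = train_test_split(idx, test_size=cfg.holdout, stratify=y, random_state=cfg.seed, shuffle=True)

    medians = X.iloc[tr].median(numeric_only=True)
    X_tr = X.iloc[tr].fillna(medians).to_numpy(dtype=float)
    X_ho = X.iloc[ho].fillna(medians).to_numpy(dtype=float)
    scaler = None
    if algorithm == "svm":
        scaler = StandardScaler().fit(X_tr)
        X_tr, X_ho = scaler.transform(X_tr), scaler.transform(X_ho)

    model = _make_estimator(algorithm, cfg).fit(X_tr, y[tr])
    p = model.predict_proba(X_ho)[:, 1]
    if np.ptp(p) == 0:  # constant scores: AUC 0.5 by the tie convention
        report = metrics.evaluate(y[ho], (p >= 0.5).astype(int))
        report.auc = 0.5
    else:
        report = metrics.evaluate(y[ho], (p >= 0.5).astype(int), scores=p)
    return FittedModel(
        algorithm=algorithm,
        model=model,
        feature_names=list(cols),
        medians=medians,
        scaler=scaler,
        report=report,
        train_index=tr,
        holdout_index=ho,
    )


@dataclass
class FeatureImportanceReport:
    importances: pd.Series  # normalized, descending
    normalization: str = "impurity importances scaled to sum to 1"

    def rank(self, feature: str) -> int:
        return int(self.importances.index.get_loc(feature)) + 1


def feature_importance(fitted: FittedModel) -> FeatureImportanceReport:
    """Normalized impurity-decrease importances of a fitted tree ensemble."""
    model = fitted.model
    if not hasattr(model, "feature_importances_"):
        raise ValueError(f"feature importance is defined for tree ensembles, not {fitted.algorithm}")
    imp = pd.Series(model.feature_importances_, index=fitted.feature_names)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return FeatureImportanceReport(imp.sort_values(ascending=False, kind="mergesort"))


def recursive_feature_elimination(
    table: FeatureTable,
    algorithm: str,
    k: int,
    cfg: FusionConfig | None = None,
) -> tuple[list[str], list[str]]:
    """Drop the least-important feature, refit, repeat until k features remain.

    Returns (retained features ranked by final importance, elimination order).
    """
    cfg = cfg or FusionConfig()
    cols = list(table.feature_columns)
    if not 1 <= k <= len(cols):
        raise ValueError(f"k must be in [1, {len(cols)}], got {k}")
    eliminated: list[str] = []
    current = cols
    fitted = train_classifier(table, algorithm, cfg, feature_columns=current)
    while len(current) > k:
        report = feature_importance(fitted)
        worst = report.importances.index[-1]
        eliminated.append(worst)
        current = [c for c in current if c != worst]
        fitted = train_classifier(table, algorithm, cfg, feature_columns=current)
    ranked = [c for c in feature_importance(fitted).importances.index]
    return ranked, eliminated


def spearman_matrix(table: FeatureTable, features: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Spearman rank correlations (average-rank ties, pairwise-complete).

    Zero-variance columns yield NaN coefficients with a warning.
    """
    cols = features or table.feature_columns
    X = table.features(cols)
    if len(X) < 2:
        raise ValueError("need >= 2 rows for a correlation matrix")
    for c in cols:
        col = X[c].dropna()
        if len(col) > 0 and col.nunique() == 1:
            warnings.warn(f"zero-variance feature {c!r}: Spearman undefined, reported as NaN")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = X.corr(method="spearman")
    np.fill_diagonal(corr.values, [1.0 if X[c].dropna().nunique() > 1 else np.nan for c in cols])
    return corr


def information_value_report(table: FeatureTable, features: list[str] | None = None, bins: int = 10) -> pd.Series:
    """Auxiliary information-value criterion per feature (decile bins).

    IV = sum over bins of (driver share - passenger share) * WoE, with
    WoE = ln(driver share / passenger share); shares are Laplace-smoothed.
    """
    cols = features or table.feature_columns
    y = table.y
    out = {}
    for c in cols:
        x = table.df[c]
        ok = x.notna()
        try:
            binned = pd.qcut(x[ok], q=bins, duplicates="drop")
        except ValueError:
            out[c] = 0.0
            continue
        iv = 0.0
        n_pos, n_neg = max(y[ok].sum(), 1), max((1 - y[ok]).sum(), 1)
        for _, grp in pd.DataFrame({"bin": binned, "y": y[ok]}).groupby("bin", observed=True):
            pd_share = (grp["y"].sum() + 0.5) / n_pos
            pp_share = ((1 - grp["y"]).sum() + 0.5) / n_neg
            iv += (pd_share - pp_share) * np.log(pd_share / pp_share)
        out[c] = float(iv)
    return pd.Series(out).sort_values(ascending=False)
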