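"""Random-forest site classifier, mRNA/lncRNA ensemble, feature selection.

The core estimator is a random forest over the 144-value site encoding.
Because base-resolution lncRNA methylation data are scarce while mRNA
sites are abundant, a weighted ensemble blends the probability of an
mRNA-trained and a lncRNA-trained model:

    P_en = alpha * P_m + (1 - alpha) * P_lnc,  alpha in [0, 1]

with alpha chosen by grid search on a validation split carved from the
training data (never the test set).

The module is organised statsmodels-style: :class:`SiteClassifier` is
built from a feature matrix and ``fit()`` returns
:class:`SiteClassifierResults`; :class:`EnsembleModel` combines two
results objects and ``fit()`` returns :class:`EnsembleResults` with the
selected blend weight and its AUC curve.  The plain functions underneath
(`train_classifier`, `kfold_cv`, `select_alpha`, ...) are the reusable
primitives.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold

from . import metrics as met
from .features import DEFAULT_CATALOG, FeatureCatalog

ALPHA_GRID = tuple(round(0.1 * i, 1) for i in range(11))
ARCHIVE_VERSION = 1


@dataclass(frozen=True)
class RandomForestConfig:
    """Forest hyperparameters; defaults: 500 trees, sqrt(p) per split."""

    n_estimators: int = 500
    max_features: str | float = "sqrt"
    seed: int = 0

    def build(self) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            random_state=self.seed,
            n_jobs=1,
        )


Trainer = Callable[[np.ndarray, np.ndarray], object]


def _as_array(X) -> np.ndarray:
    return X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)


def train_classifier(X, y, config: RandomForestConfig | None = None):
    """Fit the random forest; errors on single-class labels."""
    config = config or RandomForestConfig()
    X = _as_array(X)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    clf = config.build()
    clf.fit(X, y)
    return clf


def predict_probability(clf, X) -> np.ndarray:
    """Positive-class probability for each row."""
    X = _as_array(X)
    pos = list(clf.classes_).index(1)
    return clf.predict_proba(X)[:, pos]


def ensemble_probability(p_m, p_lnc, alpha: float) -> np.ndarray:
    """P_en = alpha * P_m + (1 - alpha) * P_lnc (vectorised, range-checked)."""
    p_m = np.asarray(p_m, dtype=float)
    p_lnc = np.asarray(p_lnc, dtype=float)
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha {alpha} outside [0, 1]")
    for name, p in (("p_m", p_m), ("p_lnc", p_lnc)):
        if p.size and (p.min() < 0 or p.max() > 1):
            raise ValueError(f"{name} contains values outside [0, 1]")
    return alpha * p_m + (1.0 - alpha) * p_lnc


def select_alpha(model_m, model_lnc, X_val, y_val,
                 grid: Sequence[float] = ALPHA_GRID) -> tuple[float, dict[float, float]]:
    """Grid member maximising blended AUC on the validation set.

    Ties go to the smaller alpha.  Returns (alpha, {alpha: auc}).
    """
    if len(grid) == 0:
        raise ValueError("empty alpha grid")
    p_m = predict_probability(model_m, X_val)
    p_lnc = predict_probability(model_lnc, X_val)
    return select_alpha_from_probs(p_m, p_lnc, y_val, grid)


def select_alpha_from_probs(p_m, p_lnc, y_val,
                            grid: Sequence[float] = ALPHA_GRID
                            ) -> tuple[float, dict[float, float]]:
    if len(grid) == 0:
        raise ValueError("empty alpha grid")
    curve = {}
    for a in grid:
        auc, _ = met.roc_auc(y_val, ensemble_probability(p_m, p_lnc, a))
        curve[a] = auc
    best = min(curve, key=lambda a: (-curve[a], a))
    return best, curve


def kfold_cv(X, y, k: int = 10, seed: int = 0,
             trainer: Trainer | None = None) -> tuple[np.ndarray, list[dict]]:
    """Stratified k-fold CV; returns out-of-fold probabilities + fold metrics.

    When k exceeds the size of the smaller class (e.g. leave-one-out)
    folds are unstratified; per-fold AUC is reported as None for folds
    holding a single class (pooled out-of-fold metrics remain defined).
    """
    X = _as_array(X)
    y = np.asarray(y).astype(int)
    trainer = trainer or (lambda Xt, yt: train_classifier(
        Xt, yt, RandomForestConfig(seed=seed)))
    if k <= int(np.bincount(y).min()):
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.full(len(y), np.nan)
    folds = []
    for train_idx, test_idx in splitter.split(X, y):
        clf = trainer(X[train_idx], y[train_idx])
        probs = predict_probability(clf, X[test_idx])
        oof[test_idx] = probs
        if len(np.unique(y[test_idx])) == 2:
            auc, _ = met.roc_auc(y[test_idx], probs)
        else:
            auc = None
        folds.append({"n": len(test_idx), "auc": auc})
    assert not np.isnan(oof).any()
    return oof, folds


def cv_auc(X, y, k: int = 10, seed: int = 0, trainer: Trainer | None = None) -> float:
    """AUC of pooled out-of-fold predictions."""
    oof, _ = kfold_cv(X, y, k, seed, trainer)
    auc, _ = met.roc_auc(y, oof)
    return auc


def rank_features(X: pd.DataFrame, y, k: int = 10, seed: int = 0,
                  trainer: Trainer | None = None) -> list[str]:
    """Features sorted by descending single-feature k-fold CV AUC.

    Ties are broken by catalog (column) order.
    """
    y = np.asarray(y).astype(int)
    scored = []
    for j, name in enumerate(X.columns):
        col = X.iloc[:, [j]]
        if np.allclose(col.to_numpy().std(), 0):
            auc = 0.5  # constant feature carries no signal
        else:
            auc = cv_auc(col, y, k, seed, trainer)
        scored.append((-auc, j, name))
    scored.sort()
    return [name for _, _, name in scored]


@dataclass
class FeatureSelectionResult:
    ranked: list[str]
    auc_curve: list[float]
    selected_size: int

    @property
    def selected_features(self) -> list[str]:
        return self.ranked[: self.selected_size]


def greedy_forward_selection(ranked: list[str], X: pd.DataFrame, y,
                             k: int = 10, seed: int = 0,
                             trainer: Trainer | None = None
                             ) -> FeatureSelectionResult:
    """CV AUC of every prefix of the ranked list; best prefix wins (ties -> shortest)."""
    y = np.asarray(y).astype(int)
    curve = []
    for i in range(1, len(ranked) + 1):
        curve.append(cv_auc(X[ranked[:i]], y, k, seed, trainer))
    best = int(np.argmax(curve)) + 1  # argmax takes the first (shortest) maximum
    return FeatureSelectionResult(ranked=list(ranked), auc_curve=curve,
                                  selected_size=best)


# ---------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------

class SiteClassifier:
    """Random-forest site model over a feature matrix.

    Parameters
    ----------
    X : DataFrame or array, one row per candidate site.
    y : binary labels (1 = methylated).
    feature_names : taken from the DataFrame columns when omitted.
    config : forest hyperparameters.
    """

    def __init__(self, X, y, feature_names: list[str] | None = None,
                 config: RandomForestConfig | None = None,
                 catalog: FeatureCatalog | None = None):
        if isinstance(X, pd.DataFrame):
            feature_names = feature_names or list(X.columns)
        self.X = _as_array(X)
        self.y = np.asarray(y).astype(int)
        if self.X.shape[0] != len(self.y):
            raise ValueError("X and y disagree in length")
        self.feature_names = feature_names or [
            f"f{i}" for i in range(self.X.shape[1])
        ]
        self.config = config or RandomForestConfig()
        self.catalog = catalog or DEFAULT_CATALOG

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, label_col: str = "label",
                       **kwargs) -> "SiteClassifier":
        y = frame[label_col].to_numpy()
        X = frame.drop(columns=[label_col])
        return cls(X, y, **kwargs)

    def fit(self) -> "SiteClassifierResults":
        clf = train_classifier(self.X, self.y, self.config)
        return SiteClassifierResults(self, clf)

    def cross_validate(self, k: int = 10) -> tuple[np.ndarray, list[dict]]:
        return kfold_cv(self.X, self.y, k=k, seed=self.config.seed,
                        trainer=lambda Xt, yt: train_classifier(Xt, yt, self.config))


class SiteClassifierResults:
    """Fitted forest with evaluation, prediction and summary."""

    def __init__(self, model: SiteClassifier, estimator):
        self.model = model
        self.estimator = estimator
        self.catalog_hash = model.catalog.hash()

    def predict(self, X) -> np.ndarray:
        return predict_probability(self.estimator, X)

    def evaluate(self, X, y, threshold: float = met.DEFAULT_THRESHOLD) -> met.EvaluationReport:
        return met.evaluate(y, self.predict(X), threshold)

    @property
    def feature_importances(self) -> pd.Series:
        return pd.Series(self.estimator.feature_importances_,
                         index=self.model.feature_names)

    def summary(self, X=None, y=None) -> str:
        lines = [
            "Random-forest m6A site classifier",
            "=" * 45,
            f"observations:        {len(self.model.y)}",
            f"features:            {len(self.model.feature_names)}",
            f"trees:               {self.model.config.n_estimators}",
            f"max features/split:  {self.model.config.max_features}",
            f"seed:                {self.model.config.seed}",
        ]
        if X is not None and y is not None:
            rep = self.evaluate(X, y)
            lines += [
                "-" * 45,
                f"Sn   {rep.sn:.3f}   Sp   {rep.sp:.3f}   ACC  {rep.acc:.3f}",
                f"MCC  {rep.mcc:.3f}   AUC  {rep.auc:.3f}",
            ]
        top = self.feature_importances.sort_values(ascending=False).head(5)
        lines += ["-" * 45, "top impurity importances:"]
        lines += [f"  {name:<28s} {v:.4f}" for name, v in top.items()]
        return "\n".join(lines)


@dataclass
class EnsemblePredictor:
    """Two trained forests plus the blend weight."""

    model_m: object
    model_lnc: object
    alpha: float

    def predict(self, X) -> np.ndarray:
        return ensemble_probability(
            predict_probability(self.model_m, X),
            predict_probability(self.model_lnc, X),
            self.alpha,
        )


class EnsembleModel:
    """Blend of an mRNA-trained and a lncRNA-trained results object.

    ``fit(X_val, y_val)`` grid-searches alpha on the supplied validation
    data (by hygiene, a split carved from training data).
    """

    def __init__(self, results_m: SiteClassifierResults,
                 results_lnc: SiteClassifierResults,
                 grid: Sequence[float] = ALPHA_GRID):
        if results_m.catalog_hash != results_lnc.catalog_hash:
            raise ValueError("member models were trained on different catalogs")
        self.results_m = results_m
        self.results_lnc = results_lnc
        self.grid = tuple(grid)

    def fit(self, X_val, y_val) -> "EnsembleResults":
        alpha, curve = select_alpha(
            self.results_m.estimator, self.results_lnc.estimator,
            X_val, y_val, self.grid,
        )
        return EnsembleResults(self, alpha, curve)


@dataclass
class EnsembleResults:
    model: EnsembleModel
    alpha: float
    auc_curve: dict[float, float] = field(default_factory=dict)

    @property
    def predictor(self) -> EnsemblePredictor:
        return EnsemblePredictor(self.model.results_m.estimator,
                                 self.model.results_lnc.estimator, self.alpha)

    def predict(self, X) -> np.ndarray:
        return self.predictor.predict(X)

    def evaluate(self, X, y, threshold: float = met.DEFAULT_THRESHOLD) -> met.EvaluationReport:
        return met.evaluate(y, self.predict(X), threshold)

    def summary(self) -> str:
        lines = [
            "Ensemble m6A site predictor",
            "=" * 45,
            f"selected alpha (mRNA weight): {self.alpha:.1f}",
            "alpha grid AUC (validation):",
        ]
        lines += [f"  alpha={a:.1f}  AUC={auc:.4f}"
                  for a, auc in sorted(self.auc_curve.items())]
        return "\n".join(lines)


# ---------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------

def save_model(path, estimator, catalog: FeatureCatalog | None = None,
               mode: str = "", rna_class: str = "", alpha: float | None = None,
               seeds: dict | None = None, manifest: dict | None = None) -> None:
    """Versioned archive: pickled estimator + JSON metadata."""
    catalog = catalog or DEFAULT_CATALOG
    payload = {
        "version": ARCHIVE_VERSION,
        "meta": {
            "catalog_hash": catalog.hash(),
            "mode": mode,
            "rna_class": rna_class,
            "alpha": alpha,
            "seeds": seeds or {},
            "manifest": manifest or {},
        },
        "estimator": estimator,
    }
    with open(path, "wb") as fh:
        fh.write(b"LNCM6A1\n")
        fh.write(json.dumps(payload["meta"]).encode() + b"\n")
        pickle.dump(payload["estimator"], fh)


def load_model(path, catalog: FeatureCatalog | None = None):
    """Load an archive; refuses when the feature catalog hash differs."""
    catalog = catalog or DEFAULT_CATALOG
    with open(path, "rb") as fh:
        magic = fh.readline()
        if magic != b"LNCM6A1\n":
            raise ValueError(f"{path}: not a model archive (bad magic)")
        meta = json.loads(fh.readline().decode())
        estimator = pickle.load(fh)
    if meta["catalog_hash"] != catalog.hash():
        raise ValueError(
            "feature catalog hash mismatch: the model was trained on a "
            "different feature definition; refusing to predict"
        )
    return estimator, meta
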