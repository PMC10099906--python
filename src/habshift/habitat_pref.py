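"""Case-control habitat-preference modelling with boosted regression trees.

One model per taxon contrasts covariates at observed fixes (label 1)
against simulated availability fixes (label 0) with a Bernoulli loss.
Defaults follow standard ecological BRT practice: learning rate 0.01,
bag fraction 0.5, interaction depth ("tree complexity") 5, and the tree
count chosen by k-fold cross-validation blocked by individual so that no
animal contributes to both the training and validation side of a fold.

Because the case:control ratio is fixed by design, predictions are a
*relative* habitat preference, not an absolute occurrence probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupKFold

from .env_match import MODEL_COVARIATES

__all__ = ["BRTConfig", "HabitatModelFit", "fit_brt", "evaluate_model",
           "blocking_validation", "partial_dependence"]


@dataclass(frozen=True)
class BRTConfig:
    learning_rate: float = 0.01
    bag_fraction: float = 0.5
    tree_complexity: int = 5
    max_trees: int = 2000
    tree_step: int = 100
    n_folds: int = 10
    group_col: str = "individual_id"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not (0 < self.bag_fraction <= 1):
            raise ValueError("bag fraction must lie in (0, 1]")
        if self.tree_complexity < 1:
            raise ValueError("tree complexity must be >= 1")

    @property
    def tree_grid(self) -> np.ndarray:
        return np.arange(self.tree_step, self.max_trees + 1, self.tree_step)


@dataclass
class HabitatModelFit:
    model: GradientBoostingClassifier
    features: tuple[str, ...]
    n_trees: int
    importance: pd.Series            # percent, sums to 100
    cv_results: pd.DataFrame         # fold, trees, deviance, auc
    cv_auc_mean: float
    cv_auc_sd: float
    pct_deviance_explained: float
    r2: float
    config: BRTConfig = field(default_factory=BRTConfig)

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Relative preference on the probability scale."""
        X = _as_matrix(X, self.features)
        return self.model.predict_proba(X)[:, 1]

    def decision(self, X) -> np.ndarray:
        """Model output on the link (logit) scale."""
        return self.model.decision_function(_as_matrix(X, self.features))


def _as_matrix(X, features):
    if isinstance(X, pd.DataFrame):
        return X[list(features)].to_numpy(float)
    return np.asarray(X, float)


def _bernoulli_deviance(y, p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _sigmoid(f):
    return 1.0 / (1.0 + np.exp(-f))


def _gbm(cfg: BRTConfig, n_trees: int, seed: int) -> GradientBoostingClassifier:
    return GradientBoostingClassifier(
        loss="log_loss", learning_rate=cfg.learning_rate,
        n_estimators=int(n_trees), subsample=cfg.bag_fraction,
        max_depth=cfg.tree_complexity, random_state=seed)


def default_features(table: pd.DataFrame) -> tuple[str, ...]:
    return tuple(c for c in MODEL_COVARIATES if c in table.columns)


def fit_brt(table: pd.DataFrame, cfg: BRTConfig = BRTConfig(),
            seed: int = 0, features: tuple[str, ...] | None = None,
            ) -> HabitatModelFit:
    """Fit the boosted-tree preference model with individual-blocked CV.

    The candidate tree counts are ``tree_step, 2*tree_step, ...,
    max_trees``; the count minimising the mean held-out Bernoulli deviance
    is selected and the final model refit on all rows at that count.
    Deterministic given ``seed``.
    """
    features = features or default_features(table)
    y = table["label"].to_numpy(int)
    if len(np.unique(y)) < 2:
        raise ValueError("case-control table must contain both labels")
    X = _as_matrix(table, features)
    groups = table[cfg.group_col].to_numpy()

    n_groups = len(np.unique(groups))
    n_folds = cfg.n_folds
    if n_groups < n_folds:
        warnings.warn(f"only {n_groups} individuals; reducing folds "
                      f"from {n_folds} to {n_groups}")
        n_folds = n_groups
    if n_folds < 2:
        raise ValueError("need at least 2 individuals for blocked CV")

    grid = cfg.tree_grid
    records = []
    for fold, (tr, te) in enumerate(
            GroupKFold(n_splits=n_folds).split(X, y, groups)):
        if len(np.unique(y[tr])) < 2:
            raise ValueError("a CV training fold contains a single class")
        est = _gbm(cfg, cfg.max_trees, seed + 1000 + fold)
        est.fit(X[tr], y[tr])
        want = set(grid - 1)
        for stage, f in enumerate(est.staged_decision_function(X[te])):
            if stage in want:
                p = _sigmoid(f.ravel())
                auc = (roc_auc_score(y[te], p)
                       if len(np.unique(y[te])) == 2 else np.nan)
                records.append({"fold": fold, "trees": stage + 1,
                                "deviance": _bernoulli_deviance(y[te], p),
                                "auc": auc})
    cv = pd.DataFrame(records)
    mean_dev = cv.groupby("trees")["deviance"].mean()
    n_trees = int(mean_dev.idxmin())

    at_sel = cv[cv["trees"] == n_trees]["auc"].dropna()
    cv_auc_mean = float(at_sel.mean())
    cv_auc_sd = float(at_sel.std(ddof=1)) if len(at_sel) > 1 else 0.0

    final = _gbm(cfg, n_trees, seed)
    final.fit(X, y)
    imp = pd.Series(final.feature_importances_ * 100.0, index=list(features))

    p_train = final.predict_proba(X)[:, 1]
    dev_model = _bernoulli_deviance(y, p_train)
    dev_null = _bernoulli_deviance(y, np.full_like(p_train, y.mean()))
    pct_dev = 100.0 * (1.0 - dev_model / dev_null)
    r2 = float(np.corrcoef(y, p_train)[0, 1] ** 2)

    return HabitatModelFit(model=final, features=tuple(features),
                           n_trees=n_trees, importance=imp, cv_results=cv,
                           cv_auc_mean=cv_auc_mean, cv_auc_sd=cv_auc_sd,
                           pct_deviance_explained=float(pct_dev), r2=r2,
                           config=cfg)


def evaluate_model(fit: HabitatModelFit, table: pd.DataFrame) -> dict:
    """Performance summary in the usual reporting format: tree count,
    percent Bernoulli deviance explained, R-squared (squared correlation
    of label with fitted preference) and blocked-CV AUC mean +- sd."""
    y = table["label"].to_numpy(int)
    p = fit.predict(table)
    dev_model = _bernoulli_deviance(y, p)
    dev_null = _bernoulli_deviance(y, np.full_like(p, y.mean()))
    return {
        "n_trees": fit.n_trees,
        "pct_deviance_explained": 100.0 * (1.0 - dev_model / dev_null),
        "r2": float(np.corrcoef(y, p)[0, 1] ** 2),
        "cv_auc_mean": fit.cv_auc_mean,
        "cv_auc_sd": fit.cv_auc_sd,
    }


def blocking_validation(table: pd.DataFrame, cfg: BRTConfig = BRTConfig(),
                        seed: int = 0, features: tuple[str, ...] | None = None,
                        n_trees: int | None = None, threshold: float = 0.5,
                        ) -> pd.DataFrame:
    """Colony-level transferability check.

    For each colony the model is refit on all other colonies and its
    predictions on the held-out colony are thresholded (default 0.5) into
    a 2x2 confusion matrix with sensitivity/specificity/accuracy.  Pass
    ``n_trees`` to skip the inner tree-count search (using a fixed count)
    — recommended when the count was already selected on the full table.
    Held-out colonies carrying a single class are emitted flagged.
    """
    features = features or default_features(table)
    colonies = sorted(table["colony_id"].unique())
    if len(colonies) < 2:
        raise ValueError("blocking validation needs at least 2 colonies")
    rows = []
    for colony in colonies:
        hold = table["colony_id"] == colony
        train, test = table[~hold], table[hold]
        if n_trees is None:
            sub = fit_brt(train, cfg, seed=seed, features=features)
            p = sub.predict(test)
        else:
            est = _gbm(cfg, n_trees, seed)
            est.fit(_as_matrix(train, features), train["label"].to_numpy(int))
            p = est.predict_proba(_as_matrix(test, features))[:, 1]
        y = test["label"].to_numpy(int)
        pred = (p > threshold).astype(int)
        tp = int(np.sum((y == 1) & (pred == 1)))
        fp = int(np.sum((y == 0) & (pred == 1)))
        fn = int(np.sum((y == 1) & (pred == 0)))
        tn = int(np.sum((y == 0) & (pred == 0)))
        one_class = len(np.unique(y)) < 2
        rows.append({
            "colony_id": colony, "n": len(y), "tp": tp, "fp": fp,
            "fn": fn, "tn": tn,
            "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
            "specificity": tn / (tn + fp) if tn + fp else np.nan,
            "accuracy": (tp + tn) / len(y),
            "auc": roc_auc_score(y, p) if not one_class else np.nan,
            "single_class": one_class,
        })
    return pd.DataFrame(rows)


def partial_dependence(fit: HabitatModelFit, variable: str,
                       grid: np.ndarray, table: pd.DataFrame) -> pd.Series:
    """Partial-dependence curve on the link (logit) scale, centred to
    mean zero: average model output over the table with ``variable``
    clamped to each grid value."""
    if variable not in fit.features:
        raise KeyError(f"variable {variable!r} not in model features "
                       f"{list(fit.features)}")
    X = _as_matrix(table, fit.features).copy()
    j = list(fit.features).index(variable)
    vals = []
    for v in np.asarray(grid, float):
        X[:, j] = v
        vals.append(float(np.mean(fit.model.decision_function(X))))
    curve = pd.Series(vals, index=np.asarray(grid, float), name=variable)
    return curve - curve.mean()
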