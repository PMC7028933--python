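"""Gradient-boosted prediction of therapy response from radiomic features.

The learner is a stage-wise gradient-boosting machine on binomial log-loss:
the model starts from the prior log-odds F0, and each stage fits a
depth-limited regression tree to the current residual (y − p), applies a
Newton step per terminal node, and adds the tree scaled by the shrinkage.
Evaluation follows a repeated stratified k-fold protocol (default 2×5): all
held-out predictions are pooled and scored for accuracy with an exact
Clopper–Pearson 95% CI, sensitivity/specificity (positive class =
responder), rank-statistic AUROC, and a one-sided exact binomial test of
the accuracy against the no-information rate (the majority-class
proportion).

The module exposes a small model/results API: :class:`ResponseModel` is
built from a feature table and labels, ``fit`` returns a fitted ensemble,
and ``evaluate_cv`` returns an :class:`EvaluationReport` with a
``summary()`` table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.tree import DecisionTreeRegressor

from .radiomics import FeatureTable, apply_normalization, fit_normalization


@dataclass(frozen=True)
class BoostConfig:
    """Tuning parameters of the boosted-tree learner."""

    n_iterations: int = 100
    max_tree_depth: int = 2
    shrinkage: float = 0.1
    min_terminal_node_size: int = 10

    def __post_init__(self) -> None:
        if self.n_iterations < 0 or self.max_tree_depth < 1:
            raise ValueError("n_iterations >= 0 and max_tree_depth >= 1 required")
        if not (0 < self.shrinkage <= 1):
            raise ValueError("shrinkage must be in (0, 1]")
        if self.min_terminal_node_size < 1:
            raise ValueError("min_terminal_node_size must be >= 1")


def default_tuning_grid() -> list[BoostConfig]:
    """The frozen default grid: iterations {50,100,150} × depth {1,2,3} ×
    shrinkage {0.1} × min node size {5,10}."""
    return [
        BoostConfig(n_iterations=it, max_tree_depth=d, shrinkage=0.1,
                    min_terminal_node_size=mn)
        for it, d, mn in itertools.product((50, 100, 150), (1, 2, 3), (5, 10))
    ]


@dataclass(frozen=True)
class CVConfig:
    k: int = 5
    repeats: int = 2
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2 or self.repeats < 1:
            raise ValueError("need k >= 2 and repeats >= 1")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


class GradientBoostedTrees:
    """Stage-wise boosted regression trees on binomial log-loss.

    F0 is the prior log-odds; each stage fits a CART tree to the residual
    y − p and replaces each leaf value by the Newton step
    Σr / Σ p(1−p) over the leaf, scaled by the shrinkage on prediction.
    Deterministic given (data, config, seed).
    """

    def __init__(self, config: BoostConfig | None = None, seed: int = 0) -> None:
        self.config = config or BoostConfig()
        self.seed = int(seed)
        self.trees_: list[DecisionTreeRegressor] = []
        self.leaf_values_: list[np.ndarray] = []
        self.f0_: float | None = None
        self.train_losses_: list[float] = []
        self.n_features_: int | None = None

    @property
    def is_fitted(self) -> bool:
        return self.f0_ is not None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GradientBoostedTrees":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.isnan(X).any():
            raise ValueError("X contains missing values")
        classes = np.unique(y)
        if not np.all(np.isin(classes, (0.0, 1.0))) or len(classes) < 2:
            raise ValueError("y must contain both classes, coded 0/1")
        cfg = self.config
        n = len(y)
        p_bar = y.mean()
        self.f0_ = float(np.log(p_bar / (1.0 - p_bar)))
        self.n_features_ = X.shape[1]
        F = np.full(n, self.f0_)
        self.trees_, self.leaf_values_, self.train_losses_ = [], [], []
        eps = 1e-12
        for m in range(cfg.n_iterations):
            p = _sigmoid(F)
            self.train_losses_.append(
                float(-(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)).mean())
            )
            r = y - p
            tree = DecisionTreeRegressor(
                max_depth=cfg.max_tree_depth,
                min_samples_leaf=cfg.min_terminal_node_size,
                random_state=self.seed + m,
            )
            tree.fit(X, r)
            leaves = tree.apply(X)
            values = np.zeros(tree.tree_.node_count)
            w = p * (1.0 - p)
            for leaf in np.unique(leaves):
                sel = leaves == leaf
                denom = w[sel].sum()
                values[leaf] = r[sel].sum() / max(denom, eps)
            self.trees_.append(tree)
            self.leaf_values_.append(values)
            F = F + cfg.shrinkage * values[leaves]
        p = _sigmoid(F)
        self.train_losses_.append(
            float(-(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)).mean())
        )
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        if not self.is_fitted:
            raise ValueError("model is not fitted")
        X = np.asarray(X, dtype=float)
        F = np.full(len(X), self.f0_)
        for tree, values in zip(self.trees_, self.leaf_values_):
            F = F + self.config.shrinkage * values[tree.apply(X)]
        return F

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(self.decision_function(X))

    def predict(self, X: np.ndarray, cutoff: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= cutoff).astype(int)

    @property
    def feature_importances_(self) -> np.ndarray:
        """Total squared-error reduction per feature over all splits of all
        stages, normalized to sum to 1 (all-zero if the model has no splits)."""
        if not self.is_fitted:
            raise ValueError("model is not fitted")
        total = np.zeros(self.n_features_)
        for tree in self.trees_:
            total += tree.tree_.compute_feature_importances(normalize=False)
        s = total.sum()
        return total / s if s > 0 else total


def fit_boosted_trees(
    X: np.ndarray, y: np.ndarray, cfg: BoostConfig | None = None, seed: int = 0
) -> GradientBoostedTrees:
    return GradientBoostedTrees(cfg, seed=seed).fit(X, y)


def feature_importance(
    model: GradientBoostedTrees, feature_names: Sequence[str] | None = None
) -> pd.Series:
    """Ranked (descending) normalized importance per feature."""
    imp = model.feature_importances_
    names = list(feature_names) if feature_names is not None else [
        f"x{j}" for j in range(len(imp))
    ]
    return pd.Series(imp, index=names).sort_values(ascending=False, kind="stable")


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def repeated_cv_predict(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    cfg: BoostConfig | None = None,
    cv: CVConfig | None = None,
    *,
    paper_mode: bool = False,
) -> pd.DataFrame:
    """Pooled held-out predictions from repeated stratified k-fold CV.

    Each repeat partitions the rows into k stratified folds; the model is
    fitted on k−1 folds and predicts the held-out fold, so each row is
    predicted exactly ``repeats`` times.  Features are z-scored on the
    training folds only and that state applied to the held-out rows;
    ``paper_mode`` instead z-scores the full table once up front (the
    global-normalization variant).
    """
    cv = cv or CVConfig()
    cfg = cfg or BoostConfig()
    Xdf = pd.DataFrame(X).reset_index(drop=True)
    y = np.asarray(y, dtype=int)
    if len(Xdf) < cv.k:
        raise ValueError("need n >= k")
    if paper_mode:
        from .radiomics import zscore_normalize

        Xdf = zscore_normalize(FeatureTable(Xdf)).data
    min_class = int(np.bincount(y).min())
    stratified = cv.stratified and cv.k <= min_class
    rows = []
    for rep in range(cv.repeats):
        for attempt in range(10):
            cls = StratifiedKFold if stratified else KFold
            splitter = cls(
                n_splits=cv.k, shuffle=True,
                random_state=cv.seed + 1000 * rep + attempt,
            )
            args = (Xdf, y) if stratified else (Xdf,)
            try:
                folds = list(splitter.split(*args))
                if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
                    break
            except ValueError:
                continue
        else:
            raise ValueError("could not build stratified folds with both classes")
        for fold_id, (tr, te) in enumerate(folds):
            Xtr, Xte = Xdf.iloc[tr], Xdf.iloc[te]
            if not paper_mode:
                state = fit_normalization(FeatureTable(Xtr))
                Xtr = apply_normalization(FeatureTable(Xtr), state).data
                Xte = apply_normalization(FeatureTable(Xte), state).data
            model = fit_boosted_trees(
                Xtr.to_numpy(), y[tr], cfg, seed=cv.seed + 1000 * rep + fold_id
            )
            proba = model.predict_proba(Xte.to_numpy())
            for i, pr in zip(te, proba):
                rows.append({"row": int(i), "repeat": rep, "fold": fold_id,
                             "proba": float(pr), "label": int(y[i])})
    return pd.DataFrame(rows)


def tune(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    grid: Sequence[BoostConfig] | None = None,
    cv: CVConfig | None = None,
) -> BoostConfig:
    """Pick the grid point maximizing mean held-out accuracy; ties go to
    fewer iterations, then shallower trees."""
    grid = list(default_tuning_grid() if grid is None else grid)
    if not grid:
        raise ValueError("empty tuning grid")
    cv = cv or CVConfig(repeats=1)
    best: tuple[float, int, int] | None = None
    best_cfg: BoostConfig | None = None
    for cfg in grid:
        preds = repeated_cv_predict(X, y, cfg, cv)
        acc = float((preds["proba"].ge(0.5).astype(int) == preds["label"]).mean())
        key = (acc, -cfg.n_iterations, -cfg.max_tree_depth)
        if best is None or key > best:
            best, best_cfg = key, cfg
    return best_cfg


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval via beta quantiles."""
    if n <= 0 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n, n > 0")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def auroc(proba: np.ndarray, labels: np.ndarray) -> float | None:
    """Area under the ROC curve via the rank (Mann–Whitney) statistic with
    midrank tie correction; None if only one class is present."""
    proba = np.asarray(proba, float)
    labels = np.asarray(labels, int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = stats.rankdata(proba)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


@dataclass
class EvaluationReport:
    """Held-out performance of the response classifier.

    Rates are fractions in [0, 1]; ``summary()`` prints percentages.
    """

    predictions: pd.DataFrame = field(repr=False)
    accuracy: float = 0.0
    ci_low: float = 0.0
    ci_high: float = 0.0
    sensitivity: float | None = None
    specificity: float | None = None
    auroc: float | None = None
    no_information_rate: float = 0.0
    binomial_p: float = 1.0
    n: int = 0
    cutoff: float = 0.5
    feature_importances: pd.Series | None = field(default=None, repr=False)

    def summary(self) -> str:
        fmt = lambda v: "   n/a" if v is None else f"{100 * v:6.1f}%"
        lines = [
            "Response classifier evaluation (pooled held-out predictions)",
            "=" * 60,
            f"held-out predictions     {self.n:6d}",
            f"accuracy                 {fmt(self.accuracy)}"
            f"   (95% CI {100 * self.ci_low:.1f}-{100 * self.ci_high:.1f}%)",
            f"sensitivity (responder)  {fmt(self.sensitivity)}",
            f"specificity              {fmt(self.specificity)}",
            f"AUROC                    "
            + ("   n/a" if self.auroc is None else f"{self.auroc:6.3f}"),
            f"no-information rate      {fmt(self.no_information_rate)}",
            f"P(accuracy > NIR)        {self.binomial_p:9.2e}",
        ]
        if self.feature_importances is not None:
            lines.append("top features:")
            for name, v in self.feature_importances.head(5).items():
                lines.append(f"  {name:40s} {v:.3f}")
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """ROC curve of the pooled held-out predictions."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        proba = self.predictions["proba"].to_numpy()
        lab = self.predictions["label"].to_numpy()
        order = np.argsort(-proba)
        tp = np.cumsum(lab[order] == 1)
        fp = np.cumsum(lab[order] == 0)
        ax.plot(fp / max(fp[-1], 1), tp / max(tp[-1], 1), label="classifier")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="chance")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
        return ax


def evaluate(
    predictions: pd.DataFrame,
    *,
    cutoff: float = 0.5,
    importances: pd.Series | None = None,
    average_repeats: bool = False,
) -> EvaluationReport:
    """Score held-out predictions (columns ``proba``, ``label``).

    By default all pooled predictions count (each animal `repeats` times);
    ``average_repeats`` first averages each animal's probability across
    repeats, scoring one prediction per animal.
    """
    if average_repeats and "row" in predictions.columns:
        predictions = (predictions.groupby("row")
                       .agg(proba=("proba", "mean"), label=("label", "first"))
                       .reset_index())
    proba = predictions["proba"].to_numpy(float)
    y = predictions["label"].to_numpy(int)
    if len(y) == 0:
        raise ValueError("no predictions to evaluate")
    pred = (proba >= cutoff).astype(int)
    n = len(y)
    correct = int((pred == y).sum())
    acc = correct / n
    lo, hi = clopper_pearson(correct, n)
    n_pos = int((y == 1).sum())
    n_neg = n - n_pos
    sens = float((pred[y == 1] == 1).mean()) if n_pos else None
    spec = float((pred[y == 0] == 0).mean()) if n_neg else None
    nir = max(n_pos, n_neg) / n
    p = float(stats.binomtest(correct, n, nir, alternative="greater").pvalue)
    return EvaluationReport(
        predictions=predictions,
        accuracy=acc, ci_low=lo, ci_high=hi,
        sensitivity=sens, specificity=spec,
        auroc=auroc(proba, y),
        no_information_rate=nir, binomial_p=p, n=n, cutoff=cutoff,
        feature_importances=importances,
    )


# ---------------------------------------------------------------------------
# model/results front end
# ---------------------------------------------------------------------------

class ResponseModel:
    """Response-prediction model over a radiomic feature table.

    Parameters
    ----------
    X : DataFrame (animals × features), raw (unnormalized) values.
    y : binary labels, 1 = responder.
    config : boosting parameters; ``tune_grid`` in :meth:`evaluate_cv` can
        override per-fit tuning.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y: Sequence[int] | np.ndarray,
        config: BoostConfig | None = None,
    ) -> None:
        self.X = pd.DataFrame(X).reset_index(drop=True)
        self.y = np.asarray(y, dtype=int)
        if len(self.X) != len(self.y):
            raise ValueError("X and y lengths differ")
        self.config = config or BoostConfig()
        self.feature_names = list(self.X.columns)

    @classmethod
    def from_dataframe(
        cls,
        features: pd.DataFrame,
        labels: pd.DataFrame,
        *,
        on: str = "animal_id",
        label_col: str = "responder",
        config: BoostConfig | None = None,
    ) -> "ResponseModel":
        merged = features.merge(labels[[on, label_col]], on=on, validate="1:1")
        y = merged[label_col].astype(int).to_numpy()
        X = merged.drop(columns=[on, label_col])
        return cls(X, y, config=config)

    def fit(self, seed: int = 0) -> GradientBoostedTrees:
        """Fit on all rows (z-scored); returns the fitted ensemble."""
        from .radiomics import zscore_normalize

        Xz = zscore_normalize(FeatureTable(self.X)).data
        return fit_boosted_trees(Xz.to_numpy(), self.y, self.config, seed=seed)

    def evaluate_cv(
        self,
        cv: CVConfig | None = None,
        *,
        paper_mode: bool = False,
        tune_grid: Sequence[BoostConfig] | None = None,
        average_repeats: bool = False,
    ) -> EvaluationReport:
        """Repeated stratified k-fold evaluation (default 2×5-fold)."""
        cv = cv or CVConfig()
        cfg = self.config
        if tune_grid is not None:
            cfg = tune(self.X, self.y, tune_grid,
                       replace(cv, repeats=1, seed=cv.seed + 77))
        preds = repeated_cv_predict(self.X, self.y, cfg, cv, paper_mode=paper_mode)
        state = fit_normalization(FeatureTable(self.X))
        Xz = apply_normalization(FeatureTable(self.X), state).data
        model = fit_boosted_trees(Xz.to_numpy(), self.y, cfg, seed=cv.seed)
        imps = feature_importance(model, self.feature_names)
        return evaluate(preds, importances=imps, average_repeats=average_repeats)
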