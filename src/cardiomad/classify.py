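"""Diagnostic classifiers for the madSD/maxT2 edema features.

Implements the published decision layer end to end:

* the combined cut-off rule (madSD > 0.22 AND maxT2 > 68 ms -> ACM);
* multiple logistic regression fitted by iteratively reweighted least
  squares, with Wald standard errors and odds ratios
  (:class:`DiagnosticLogit` / :class:`DiagnosticLogitResults`);
* single Gini classification trees (recursive partitioning with midpoint
  thresholds) and a random forest whose importance is the mean Gini
  impurity decrease;
* stratified k-fold cross-validation, ROC/AUC via the Mann-Whitney pairwise
  formulation, and the layer-specific reference-range (mean + k*SD)
  baseline classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "apply_cutoff_rule",
    "DiagnosticLogit",
    "DiagnosticLogitResults",
    "gini_impurity",
    "GiniTreeClassifier",
    "fit_tree",
    "rf_importance",
    "cross_validate",
    "roc",
    "ROCResult",
    "ReferenceRange",
    "DEFAULT_REFERENCE_RANGE",
    "reference_range_classify",
    "LogitEstimator",
    "TreeEstimator",
    "CutoffEstimator",
]

MADSD_CUTOFF = 0.22
MAXT2_CUTOFF_MS = 68.0


# ---------------------------------------------------------------------------
# combined cut-off rule
# ---------------------------------------------------------------------------

def apply_cutoff_rule(features, madsd_cut: float = MADSD_CUTOFF,
                      maxt2_cut: float = MAXT2_CUTOFF_MS,
                      combine: str = "and"):
    """Classify a subject (or a feature table) by the combined cut-off rule.

    Default semantics: ACM iff ``madSD > madsd_cut`` AND ``maxT2 >
    maxt2_cut`` (strict inequalities, so values sitting exactly on a cut-off
    count as HV). ``combine='or'`` selects the more sensitive disjunctive
    variant.
    """
    if combine not in ("and", "or"):
        raise ValueError("combine must be 'and' or 'or'")
    if isinstance(features, pd.DataFrame):
        missing = {"madSD", "maxT2"} - set(features.columns)
        if missing:
            raise KeyError(f"missing features: {sorted(missing)}")
        madsd, maxt2 = features["madSD"], features["maxT2"]
    else:
        try:
            madsd, maxt2 = features["madSD"], features["maxT2"]
        except (KeyError, IndexError, TypeError) as exc:
            raise KeyError("features must provide 'madSD' and 'maxT2'") from exc
    above_sd, above_t2 = madsd > madsd_cut, maxt2 > maxt2_cut
    positive = (above_sd & above_t2) if combine == "and" else (above_sd | above_t2)
    if isinstance(positive, (pd.Series, np.ndarray)):
        return pd.Series(np.where(positive, "ACM", "HV"),
                         index=getattr(positive, "index", None), name="predicted")
    return "ACM" if positive else "HV"


# ---------------------------------------------------------------------------
# logistic regression (IRLS)
# ---------------------------------------------------------------------------

class DiagnosticLogit:
    """Binary logistic regression model, statsmodels-style.

    Parameters
    ----------
    X : (n, p) feature matrix or DataFrame (a constant is added internally)
    y : binary labels (0/1, booleans, or two string labels with the
        positive class given by ``positive``)
    feature_names : names for the p columns (taken from the DataFrame if
        omitted)
    """

    def __init__(self, X, y, feature_names=None, positive="ACM"):
        if isinstance(X, pd.DataFrame):
            feature_names = list(X.columns) if feature_names is None else feature_names
            X = X.to_numpy(dtype=float)
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        if y.dtype.kind in "UOS":
            y = (y == positive).astype(float)
        self.y = np.asarray(y, dtype=float).ravel()
        if set(np.unique(self.y)) - {0.0, 1.0}:
            raise ValueError("labels must be binary")
        n, p = self.X.shape
        if self.y.size != n:
            raise ValueError("X and y disagree in length")
        if n <= p + 1:
            raise ValueError("need n > p + 1 observations")
        if np.any(self.X.std(axis=0) == 0):
            raise ValueError("constant feature column in the design")
        self.feature_names = (list(feature_names) if feature_names is not None
                              else [f"x{i}" for i in range(p)])
        self.exog = np.column_stack([np.ones(n), self.X])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, features, label_col: str = "label",
                       positive: str = "ACM") -> "DiagnosticLogit":
        return cls(df[list(features)], df[label_col].to_numpy(), positive=positive)

    def loglike(self, beta: np.ndarray) -> float:
        eta = self.exog @ beta
        return float(np.sum(self.y * eta - np.logaddexp(0.0, eta)))

    def fit(self, max_iter: int = 100, tol: float = 1e-10) -> "DiagnosticLogitResults":
        """Maximum likelihood by IRLS; flags complete separation instead of
        returning silently diverging coefficients."""
        X, y = self.exog, self.y
        n, p1 = X.shape
        if np.linalg.matrix_rank(X) < p1:
            raise ValueError("singular design matrix")
        beta = np.zeros(p1)
        converged = False
        separation = False
        for _ in range(max_iter):
            eta = X @ beta
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = np.maximum(mu * (1.0 - mu), 1e-12)
            # perfect separation: fitted probabilities pinned to the labels
            if np.all(np.abs(y - mu) < 1e-8) or np.max(np.abs(beta)) > 1e3:
                separation = True
                break
            z = eta + (y - mu) / w
            xtw = X.T * w
            try:
                beta_new = np.linalg.solve(xtw @ X, xtw @ z)
            except np.linalg.LinAlgError as exc:
                raise ValueError("singular weighted design during IRLS") from exc
            if np.max(np.abs(beta_new - beta)) < tol:
                beta = beta_new
                converged = True
                break
            beta = beta_new
        mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        info = (X.T * w) @ X
        try:
            cov = np.linalg.inv(info)
            bse = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            cov = np.full((p1, p1), np.nan)
            bse = np.full(p1, np.nan)
        names = ["Intercept"] + self.feature_names
        return DiagnosticLogitResults(
            model=self,
            params=pd.Series(beta, index=names),
            bse=pd.Series(bse, index=names),
            cov_params=cov,
            llf=self.loglike(beta),
            converged=converged and not separation,
            separation=separation,
        )


@dataclass
class DiagnosticLogitResults:
    """Fitted logistic model: coefficients, Wald SEs, odds ratios, prediction."""

    params: pd.Series
    bse: pd.Series | None = None
    model: DiagnosticLogit | None = None
    cov_params: np.ndarray | None = None
    llf: float = np.nan
    converged: bool = True
    separation: bool = False

    @classmethod
    def from_coefficients(cls, coefficients: dict) -> "DiagnosticLogitResults":
        """Instantiate a results object from published coefficients, e.g.
        ``{"Intercept": -7.00, "maxT2": 0.03, "madSD": 20.34}``."""
        params = pd.Series({str(k): float(v) for k, v in coefficients.items()})
        if "Intercept" not in params.index:
            raise ValueError("coefficients must include an 'Intercept'")
        return cls(params=params)

    @property
    def feature_names(self) -> list[str]:
        return [n for n in self.params.index if n != "Intercept"]

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        """Odds ratios with Wald confidence intervals (Table-4 layout)."""
        z = sps.norm.ppf(1 - alpha / 2)
        se = self.bse if self.bse is not None else pd.Series(np.nan, index=self.params.index)
        out = pd.DataFrame({
            "B": self.params,
            "SE": se,
            "odds_ratio": np.exp(self.params),
            "ci_lower": np.exp(self.params - z * se),
            "ci_upper": np.exp(self.params + z * se),
        })
        return out.drop(index="Intercept", errors="ignore")

    def predict(self, X) -> np.ndarray:
        """Predicted P(positive class) for rows of X (array or DataFrame)."""
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        beta = self.params.to_numpy()
        eta = beta[0] + X @ beta[1:]
        return 1.0 / (1.0 + np.exp(-eta))

    def odds_factor(self, feature: str, delta: float) -> float:
        """Multiplicative change of the odds when ``feature`` rises by
        ``delta``: ``exp(B_feature * delta)``."""
        if feature not in self.params.index or feature == "Intercept":
            raise KeyError(f"unknown feature: {feature!r}")
        return float(np.exp(self.params[feature] * delta))

    def summary(self) -> str:
        lines = ["Multiple logistic regression (IRLS)",
                 f"  converged: {self.converged}   separation: {self.separation}",
                 f"  log-likelihood: {self.llf:.4f}" if np.isfinite(self.llf) else "",
                 "",
                 f"  {'term':<12}{'B':>9}{'SE':>9}{'OR':>11}{'2.5%':>11}{'97.5%':>11}"]
        z = sps.norm.ppf(0.975)
        for name, b in self.params.items():
            se = self.bse[name] if self.bse is not None else np.nan
            if name == "Intercept":
                lines.append(f"  {name:<12}{b:>9.2f}{se:>9.2f}" if np.isfinite(se)
                             else f"  {name:<12}{b:>9.2f}")
                continue
            orr = np.exp(b)
            lo, hi = np.exp(b - z * se), np.exp(b + z * se)
            lines.append(f"  {name:<12}{b:>9.2f}{se:>9.2f}"
                         f"{orr:>11.4g}{lo:>11.4g}{hi:>11.4g}")
        return "\n".join(l for l in lines if l != "")


# ---------------------------------------------------------------------------
# Gini trees and random forest
# ---------------------------------------------------------------------------

def gini_impurity(counts) -> float:
    """Gini impurity ``1 - sum_i p_i^2`` of a node with the given class counts."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0) or c.sum() == 0:
        raise ValueError("counts must be non-negative and not all zero")
    p = c / c.sum()
    return float(1.0 - np.sum(p**2))


@dataclass
class TreeNode:
    n: int
    counts: np.ndarray
    impurity: float
    prediction: int            # index into classes_
    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


class GiniTreeClassifier:
    """Greedy binary recursive partitioning with Gini impurity.

    Candidate thresholds are midpoints between consecutive sorted unique
    feature values; the split minimising the weighted child impurity wins,
    with ties broken toward the lower feature index, then the lower
    threshold. ``mtry`` (random feature subsetting per node) and a seeded
    ``rng`` turn the same machinery into a forest member.
    """

    def __init__(self, max_depth: int | None = 2, min_leaf: int = 5,
                 mtry: int | None = None, rng: np.random.Generator | None = None):
        self.max_depth = max_depth
        self.min_leaf = int(min_leaf)
        self.mtry = mtry
        self.rng = rng
        self.root: TreeNode | None = None
        self.classes_: np.ndarray | None = None
        self.n_features_: int = 0
        self.feature_names: list[str] | None = None

    # -- fitting ------------------------------------------------------------
    def fit(self, X, y, feature_names=None) -> "GiniTreeClassifier":
        if isinstance(X, pd.DataFrame):
            feature_names = list(X.columns) if feature_names is None else feature_names
            X = X.to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if X.shape[0] != y_enc.size:
            raise ValueError("X and y disagree in length")
        if X.shape[0] < 2 * self.min_leaf and np.unique(y_enc).size > 1:
            raise ValueError("too few samples for the requested min_leaf")
        self.n_features_ = X.shape[1]
        self.feature_names = feature_names
        self.root = self._grow(X, y_enc, depth=0)
        return self

    def _node_of(self, y_enc: np.ndarray) -> TreeNode:
        counts = np.bincount(y_enc, minlength=self.classes_.size)
        return TreeNode(n=y_enc.size, counts=counts,
                        impurity=gini_impurity(counts),
                        prediction=int(np.argmax(counts)))

    def _best_split(self, X: np.ndarray, y_enc: np.ndarray):
        n, p = X.shape
        node_imp = gini_impurity(np.bincount(y_enc, minlength=self.classes_.size))
        if node_imp == 0.0:
            return None
        feats = np.arange(p)
        if self.mtry is not None and self.mtry < p:
            feats = np.sort(self.rng.choice(p, size=self.mtry, replace=False))
        best = None  # (gini, feature, threshold)
        k = self.classes_.size
        onehot = np.eye(k)[y_enc]
        for f in feats:
            order = np.argsort(X[:, f], kind="stable")
            xs = X[order, f]
            cum = np.cumsum(onehot[order], axis=0)
            total = cum[-1]
            i = np.arange(1, n)  # split after position i-1
            valid = (xs[1:] > xs[:-1]) & (i >= self.min_leaf) & (n - i >= self.min_leaf)
            if not valid.any():
                continue
            nl = i[valid].astype(float)
            nr = n - nl
            cl = cum[:-1][valid]
            cr = total - cl
            gl = 1.0 - np.sum((cl / nl[:, None]) ** 2, axis=1)
            gr = 1.0 - np.sum((cr / nr[:, None]) ** 2, axis=1)
            wg = (nl * gl + nr * gr) / n
            j = int(np.argmin(wg))  # first minimum -> lowest threshold
            if best is None or wg[j] < best[0] - 1e-12:
                idx = i[valid][j]
                thr = 0.5 * (xs[idx - 1] + xs[idx])
                best = (float(wg[j]), int(f), float(thr))
        if best is None or best[0] >= node_imp - 1e-12:
            return None
        return best

    def _grow(self, X: np.ndarray, y_enc: np.ndarray, depth: int) -> TreeNode:
        node = self._node_of(y_enc)
        if node.impurity == 0.0:
            return node
        if self.max_depth is not None and depth >= self.max_depth:
            return node
        if y_enc.size < 2 * self.min_leaf:
            return node
        split = self._best_split(X, y_enc)
        if split is None:
            return node
        _, f, thr = split
        go_left = X[:, f] <= thr
        node.feature, node.threshold = f, thr
        node.left = self._grow(X[go_left], y_enc[go_left], depth + 1)
        node.right = self._grow(X[~go_left], y_enc[~go_left], depth + 1)
        return node

    # -- inspection & prediction -------------------------------------------
    def predict(self, X) -> np.ndarray:
        if self.root is None:
            raise ValueError("tree is not fitted")
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty(X.shape[0], dtype=int)
        for idx, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.feature] <= node.threshold else node.right
            out[idx] = node.prediction
        return self.classes_[out]

    def splits(self) -> list[tuple[int, float]]:
        """(feature index, threshold) of every internal node, breadth first."""
        if self.root is None:
            return []
        out, queue = [], [self.root]
        while queue:
            node = queue.pop(0)
            if not node.is_leaf:
                out.append((node.feature, node.threshold))
                queue.extend([node.left, node.right])
        return out

    def threshold_for(self, feature) -> float | None:
        """Threshold of the shallowest split on the named/indexed feature."""
        if isinstance(feature, str):
            if not self.feature_names:
                raise KeyError("tree was fitted without feature names")
            feature = self.feature_names.index(feature)
        for f, thr in self.splits():
            if f == feature:
                return thr
        return None

    def to_dict(self) -> dict:
        def rec(node: TreeNode) -> dict:
            d = {"n": node.n, "counts": node.counts.tolist(),
                 "impurity": node.impurity,
                 "prediction": str(self.classes_[node.prediction])}
            if not node.is_leaf:
                d.update(feature=int(node.feature), threshold=float(node.threshold),
                         left=rec(node.left), right=rec(node.right))
            return d
        return {"classes": [str(c) for c in self.classes_], "tree": rec(self.root)}


def fit_tree(X, y, max_depth: int = 2, min_leaf: int = 5,
             feature_names=None) -> GiniTreeClassifier:
    """Fit a single Gini classification tree (recursive partitioning)."""
    return GiniTreeClassifier(max_depth=max_depth, min_leaf=min_leaf).fit(
        X, y, feature_names=feature_names)


def rf_importance(X, y, n_trees: int = 500, mtry: int | None = None,
                  seed: int = 0, max_depth: int | None = None,
                  min_leaf: int = 1, feature_names=None) -> pd.Series:
    """Random-forest variable importance: mean decrease of Gini impurity.

    Bootstrap-resampled trees with ``mtry`` (default floor(sqrt(p))) randomly
    subsetted candidate features per node; each split credits its feature
    with ``(n_node / n) * (parent impurity - weighted child impurity)``,
    summed per tree and averaged over trees. Deterministic for a fixed seed.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns) if feature_names is None else feature_names
        X = X.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    n, p = X.shape
    if p == 0:
        raise ValueError("need at least one feature")
    if mtry is None:
        mtry = max(1, int(np.sqrt(p)))
    importances = np.zeros(p)
    streams = np.random.SeedSequence(seed).spawn(n_trees)
    for ss in streams:
        rng = np.random.default_rng(ss)
        idx = rng.integers(0, n, n)
        tree = GiniTreeClassifier(max_depth=max_depth, min_leaf=min_leaf,
                                  mtry=mtry, rng=rng)
        tree.fit(X[idx], y[idx])
        stack = [tree.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                continue
            child_imp = (node.left.n * node.left.impurity
                         + node.right.n * node.right.impurity) / node.n
            importances[node.feature] += (node.n / n) * (node.impurity - child_imp)
            stack.extend([node.left, node.right])
    imp = importances / n_trees
    names = feature_names if feature_names is not None else [f"x{i}" for i in range(p)]
    return pd.Series(imp, index=names, name="gini_importance")


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

class LogitEstimator:
    """fit/predict adapter over :class:`DiagnosticLogit` (threshold 0.5)."""

    def fit(self, X, y):
        self._classes, y_enc = np.unique(np.asarray(y), return_inverse=True)
        self._res = DiagnosticLogit(X, y_enc.astype(float)).fit()
        return self

    def predict(self, X):
        return self._classes[(self._res.predict(X) > 0.5).astype(int)]


class TreeEstimator:
    def __init__(self, max_depth: int = 2, min_leaf: int = 5):
        self.max_depth, self.min_leaf = max_depth, min_leaf

    def fit(self, X, y):
        self._tree = fit_tree(X, y, max_depth=self.max_depth, min_leaf=self.min_leaf)
        return self

    def predict(self, X):
        return self._tree.predict(X)


class CutoffEstimator:
    """The fixed published cut-off rule; `fit` is a no-op.

    Expects X columns ordered (madSD, maxT2) or a DataFrame with those
    columns."""

    def __init__(self, madsd_cut=MADSD_CUTOFF, maxt2_cut=MAXT2_CUTOFF_MS,
                 combine: str = "and"):
        self.madsd_cut, self.maxt2_cut, self.combine = madsd_cut, maxt2_cut, combine

    def fit(self, X, y):
        return self

    def predict(self, X):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.atleast_2d(np.asarray(X, float)),
                             columns=["madSD", "maxT2"])
        return apply_cutoff_rule(X, self.madsd_cut, self.maxt2_cut,
                                 self.combine).to_numpy()


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator):
    folds = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % k].append(i)
    return [np.sort(np.array(f, dtype=int)) for f in folds]


@dataclass
class CVResult:
    accuracy: float
    fold_accuracies: list[float]
    k: int


def cross_validate(estimator_factory, X, y, k: int = 10, seed: int = 0) -> CVResult:
    """Stratified k-fold cross-validation; returns the pooled accuracy.

    ``estimator_factory`` is a zero-argument callable returning an object
    with ``fit(X, y)`` and ``predict(X)``.
    """
    if isinstance(X, pd.DataFrame):
        Xv = X.reset_index(drop=True)
        take = lambda idx: Xv.iloc[idx]
    else:
        Xv = np.atleast_2d(np.asarray(X, dtype=float))
        take = lambda idx: Xv[idx]
    y = np.asarray(y)
    n = y.size
    if n < k:
        raise ValueError("need at least k observations")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    folds = _stratified_folds(y, k, rng)
    correct = 0
    fold_acc = []
    for test_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        train_idx = np.flatnonzero(train_mask)
        if np.unique(y[train_idx]).size < np.unique(y).size:
            raise ValueError("a class is absent from a training fold")
        est = estimator_factory().fit(take(train_idx), y[train_idx])
        pred = np.asarray(est.predict(take(test_idx)))
        hits = int(np.sum(pred == y[test_idx]))
        correct += hits
        fold_acc.append(hits / test_idx.size if test_idx.size else np.nan)
    return CVResult(accuracy=correct / n, fold_accuracies=fold_acc, k=k)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def roc(scores, labels, positive=None) -> ROCResult:
    """ROC curve and AUC for a score that increases with disease.

    AUC is the Mann-Whitney pairwise probability with 0.5 credit for tied
    scores; sensitivity/specificity are reported at every distinct score,
    with the convention "positive iff score >= threshold".
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel()
    if positive is None:
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("labels must contain exactly two classes")
        positive = "ACM" if "ACM" in classes.astype(str) else classes.max()
    pos = (y.astype(str) == str(positive)) if y.dtype.kind in "UOS" else (y == positive)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(s)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    thresholds = np.unique(s)[::-1]
    sens = np.array([(s[pos] >= t).mean() for t in thresholds])
    spec = np.array([(s[~pos] < t).mean() for t in thresholds])
    return ROCResult(thresholds=thresholds, sensitivity=sens,
                     specificity=spec, auc=float(auc))


# ---------------------------------------------------------------------------
# reference-range baseline
# ---------------------------------------------------------------------------

@dataclass
class ReferenceRange:
    """Layer-specific normal T2 (mean, SD) in ms for basal/mid/apical."""

    levels: dict = field(default_factory=lambda: {
        "basal": (56.7, 4.1), "mid": (58.1, 4.2), "apical": (62.2, 5.2)})

    def __post_init__(self):
        for level, (mean, sd) in self.levels.items():
            if sd <= 0:
                raise ValueError(f"non-positive SD for level {level!r}")

    def threshold(self, level: str, k: float) -> float:
        if k <= 0:
            raise ValueError("k must be positive")
        if level not in self.levels:
            raise ValueError(f"unknown level: {level!r}")
        mean, sd = self.levels[level]
        return mean + k * sd


DEFAULT_REFERENCE_RANGE = ReferenceRange()


def reference_range_classify(table: pd.DataFrame,
                             ref: ReferenceRange = DEFAULT_REFERENCE_RANGE,
                             k: float = 2.0) -> bool:
    """Reference-value baseline: positive iff any segment's mean T2 exceeds
    its layer's mean + k*SD (the any-segment aggregation rule)."""
    if not {"mean_T2_ms", "level"} <= set(table.columns):
        raise ValueError("table must carry mean_T2_ms and level columns")
    thr = table["level"].map(lambda lv: ref.threshold(lv, k))
    return bool((table["mean_T2_ms"] > thr).any())
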