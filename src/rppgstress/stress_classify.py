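"""Classifier benchmark: four models, stratified 10-fold CV, five metrics.

The stress label is predicted from the feature variants with four
classifiers configured exactly as the study that motivated this package
ran them in Weka:

* SVM with the Pearson VII universal kernel (PUK), C = 1, omega = sigma = 1;
* 1-nearest-neighbour on min-max-normalized features;
* a C4.5-style decision tree (gain-ratio splits at numeric midpoints,
  pessimistic-error pruning, confidence factor 0.25, >= 2 instances/leaf);
* a random forest of 100 bagged gain-ratio trees with a per-node random
  feature subset of size floor(log2 m) + 1, seed 1, unlimited depth.

Evaluation pools the confusion matrix over the 10 folds and reports
accuracy, sensitivity, specificity, Cohen's kappa, and the rank-based AUC,
plus the conventional kappa agreement band.

The C4.5 tree is implemented here because no installed library provides
gain-ratio splitting or confidence-bound pruning; the split search is
vectorized so a 100-tree forest on ~700 instances stays fast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import beta as beta_dist
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .errors import InputError, ValidationError

CLASSIFIER_KINDS = ("svm_puk", "knn", "c45", "random_forest")


@dataclass
class ClassifierSpec:
    """One classifier configuration; defaults are the study's settings."""

    kind: str
    svm_c: float = 1.0
    puk_omega: float = 1.0
    puk_sigma: float = 1.0
    knn_k: int = 1
    c45_confidence_factor: float = 0.25
    c45_min_instances: int = 2
    rf_n_trees: int = 100
    rf_seed: int = 1
    rf_max_depth: int = 0          # 0 = unlimited

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise InputError(f"unknown classifier kind {self.kind!r}")


def default_specs() -> List[ClassifierSpec]:
    return [ClassifierSpec(kind=k) for k in CLASSIFIER_KINDS]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts (positive class = high stress = 1)."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise InputError("confusion counts must be non-negative")
        if self.total == 0:
            raise InputError("confusion matrix must be non-empty")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def transpose(self) -> "ConfusionMatrix":
        """Swap the roles of rater and prediction (FN <-> FP)."""
        return ConfusionMatrix(tp=self.tp, fn=self.fp, fp=self.fn,
                               tn=self.tn)

    @classmethod
    def from_labels(cls, y_true: np.ndarray, y_pred: np.ndarray
                    ) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(tp=int(np.sum((y_true == 1) & (y_pred == 1))),
                   fn=int(np.sum((y_true == 1) & (y_pred == 0))),
                   fp=int(np.sum((y_true == 0) & (y_pred == 1))),
                   tn=int(np.sum((y_true == 0) & (y_pred == 0))))


@dataclass
class EvalReport:
    """Pooled confusion matrix plus the five metrics for one run."""

    classifier: str
    variant: int
    confusion: ConfusionMatrix
    accuracy: float
    sensitivity: float
    specificity: float
    kappa: float
    auc: float
    kappa_band: str

    def to_dict(self) -> dict:
        c = self.confusion
        return {"classifier": self.classifier, "variant": self.variant,
                "cm": [c.tp, c.fn, c.fp, c.tn],
                "accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "kappa": self.kappa,
                "auc": self.auc, "kappa_band": self.kappa_band}


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def metrics_from_cm(cm: ConfusionMatrix) -> Tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); 0 on an empty denominator."""
    acc = (cm.tp + cm.tn) / cm.total
    sens = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else 0.0
    spec = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp else 0.0
    return acc, sens, spec


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement (po - pe) / (1 - pe) for binary counts."""
    n = cm.total
    po = (cm.tp + cm.tn) / n
    pe = ((cm.tp + cm.fn) * (cm.tp + cm.fp)
          + (cm.fp + cm.tn) * (cm.fn + cm.tn)) / n ** 2
    if pe == 1.0:
        if po == 1.0:
            return 1.0
        raise ZeroDivisionError("kappa undefined: pe = 1 with po < 1")
    return (po - pe) / (1.0 - pe)


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) AUC; tied scores count half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValidationError("AUC needs both classes present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


#: Conventional agreement bands for Cohen's kappa.
KAPPA_BANDS = ((0.20, "Poor agreement"), (0.40, "Fair agreement"),
               (0.60, "Moderate agreement"), (0.80, "Substantial agreement"),
               (1.00, "Almost perfect agreement"))


def interpret_kappa(kappa: float) -> str:
    if not -1.0 <= kappa <= 1.0:
        raise InputError(f"kappa must lie in [-1, 1], got {kappa}")
    if kappa < 0:
        return "None agreement"
    for upper, band in KAPPA_BANDS:
        if kappa <= upper + 1e-12:
            return band
    return KAPPA_BANDS[-1][1]       # pragma: no cover


# ---------------------------------------------------------------------------
# PUK kernel
# ---------------------------------------------------------------------------

def puk_kernel(u: Sequence[float], v: Sequence[float],
               omega: float = 1.0, sigma: float = 1.0) -> float:
    """Pearson VII universal kernel between two vectors.

    K = 1 / [1 + (2 ||u-v|| sqrt(2^(1/omega) - 1) / sigma)^2]^omega
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise InputError(f"arity mismatch: {u.shape} vs {v.shape}")
    return float(puk_gram(u[None, :], v[None, :], omega, sigma)[0, 0])


def puk_gram(A: np.ndarray, B: np.ndarray,
             omega: float = 1.0, sigma: float = 1.0) -> np.ndarray:
    """PUK Gram matrix between the rows of A and of B."""
    if omega <= 0 or sigma <= 0:
        raise InputError("omega and sigma must be positive")
    d = cdist(np.atleast_2d(A), np.atleast_2d(B))
    base = (2.0 * d * np.sqrt(2.0 ** (1.0 / omega) - 1.0) / sigma) ** 2
    return 1.0 / (1.0 + base) ** omega


# ---------------------------------------------------------------------------
# C4.5-style decision tree (gain ratio + pessimistic pruning)
# ---------------------------------------------------------------------------

def _entropy(pos: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Binary entropy of pos/n in bits, elementwise, with 0 log 0 = 0."""
    pos = np.asarray(pos, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, pos / np.maximum(n, 1), 0.0)
        h = -(np.where(p > 0, p * np.log2(p), 0.0)
              + np.where(p < 1, (1 - p) * np.log2(1 - p), 0.0))
    return h


def _pessimistic_upper(errors: float, n: float, cf: float) -> float:
    """Upper confidence bound on the error rate of a leaf.

    The bound is the error probability p solving
    ``P(X <= errors | n, p) = cf`` for X ~ Binomial(n, p), computed via the
    beta-quantile identity; for errors = 0 this reduces to 1 - cf^(1/n).
    """
    if n <= 0:
        return 0.0
    if errors >= n:
        return 1.0
    return float(beta_dist.ppf(1.0 - cf, errors + 1.0, n - errors))


class C45Tree:
    """Binary-split decision tree for numeric features, C4.5 flavoured.

    Splits maximize the gain ratio at midpoint thresholds (among
    attributes whose information gain reaches the average positive gain);
    optional pessimistic-error pruning replaces a subtree with a leaf when
    the leaf's estimated error bound does not exceed the subtree's.  With
    ``n_feature_subset`` set, each node searches a random feature subset
    (the random-forest base learner); such trees are grown unpruned.
    """

    def __init__(self, min_instances: int = 2,
                 confidence_factor: float = 0.25, prune: bool = True,
                 n_feature_subset: Optional[int] = None,
                 max_depth: int = 0,
                 rng: Optional[np.random.Generator] = None):
        self.min_instances = min_instances
        self.confidence_factor = confidence_factor
        self.prune = prune
        self.n_feature_subset = n_feature_subset
        self.max_depth = max_depth
        self.rng = rng

    def fit(self, X: np.ndarray, y: np.ndarray) -> "C45Tree":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        self.root_ = self._build(X, y, depth=0)
        if self.prune:
            self._prune(self.root_)
        return self

    # node layout: dict with either {leaf, n, pos} or
    # {feature, threshold, left, right, n, pos}
    def _leaf(self, y: np.ndarray) -> dict:
        n = y.size
        pos = int(y.sum())
        return {"leaf": True, "n": n, "pos": pos}

    def _build(self, X: np.ndarray, y: np.ndarray, depth: int) -> dict:
        n = y.size
        pos = int(y.sum())
        if pos in (0, n) or n < 2 * self.min_instances:
            return self._leaf(y)
        if self.max_depth and depth >= self.max_depth:
            return self._leaf(y)
        split = self._best_split(X, y)
        if split is None:
            return self._leaf(y)
        f, thr = split
        mask = X[:, f] <= thr
        node = {"leaf": False, "feature": int(f), "threshold": float(thr),
                "n": n, "pos": pos,
                "left": self._build(X[mask], y[mask], depth + 1),
                "right": self._build(X[~mask], y[~mask], depth + 1)}
        return node

    def _best_split(self, X: np.ndarray, y: np.ndarray
                    ) -> Optional[Tuple[int, float]]:
        n, m = X.shape
        if self.n_feature_subset is not None and self.n_feature_subset < m:
            feats = self.rng.choice(m, size=self.n_feature_subset,
                                    replace=False)
        else:
            feats = np.arange(m)
        h_parent = float(_entropy(y.sum(), n))
        gains, ratios, thrs, cols = [], [], [], []
        for f in feats:
            x = X[:, f]
            order = np.argsort(x, kind="stable")
            xs, ys = x[order], y[order]
            cum_pos = np.cumsum(ys)
            i = np.arange(1, n)                        # left size candidates
            valid = xs[1:] > xs[:-1]
            valid &= (i >= self.min_instances)
            valid &= ((n - i) >= self.min_instances)
            if not valid.any():
                continue
            nl = i[valid].astype(float)
            nr = n - nl
            pl = cum_pos[:-1][valid].astype(float)
            pr = y.sum() - pl
            h = (nl * _entropy(pl, nl) + nr * _entropy(pr, nr)) / n
            gain = h_parent - h
            fl, fr = nl / n, nr / n
            split_info = -(fl * np.log2(fl) + fr * np.log2(fr))
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(split_info > 0, gain / split_info, 0.0)
            best = int(np.argmax(gain))
            if gain[best] <= 1e-12:
                continue
            k = i[valid][best]
            gains.append(float(gain[best]))
            ratios.append(float(ratio[best]))
            thrs.append(float((xs[k - 1] + xs[k]) / 2.0))
            cols.append(int(f))
        if not gains:
            return None
        mean_gain = np.mean(gains)
        eligible = [j for j in range(len(gains))
                    if gains[j] >= mean_gain - 1e-12]
        j = max(eligible, key=lambda j: ratios[j])
        return cols[j], thrs[j]

    def _subtree_error(self, node: dict) -> float:
        cf = self.confidence_factor
        if node["leaf"]:
            n = node["n"]
            e = n - max(node["pos"], n - node["pos"])
            return n * _pessimistic_upper(e, n, cf)
        return (self._subtree_error(node["left"])
                + self._subtree_error(node["right"]))

    def _prune(self, node: dict) -> None:
        if node["leaf"]:
            return
        self._prune(node["left"])
        self._prune(node["right"])
        n = node["n"]
        e_leaf = n - max(node["pos"], n - node["pos"])
        est_leaf = n * _pessimistic_upper(e_leaf, n, self.confidence_factor)
        est_subtree = self._subtree_error(node)
        if est_leaf <= est_subtree + 0.1:
            pos = node["pos"]
            node.clear()
            node.update({"leaf": True, "n": n, "pos": pos})

    def predict_proba1(self, X: np.ndarray) -> np.ndarray:
        """P(class 1) per row: the class frequency of the reached leaf."""
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[0])
        for i, row in enumerate(X):
            node = self.root_
            while not node["leaf"]:
                node = (node["left"] if row[node["feature"]]
                        <= node["threshold"] else node["right"])
            out[i] = node["pos"] / node["n"] if node["n"] else 0.5
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba1(X) >= 0.5).astype(int)


class RandomForestGR:
    """Bagged gain-ratio trees with per-node random feature subsets."""

    def __init__(self, n_trees: int = 100, seed: int = 1,
                 max_depth: int = 0):
        self.n_trees = n_trees
        self.seed = seed
        self.max_depth = max_depth

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RandomForestGR":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        n, m = X.shape
        k = int(np.floor(np.log2(m))) + 1
        rng = np.random.default_rng(self.seed)
        self.trees_ = []
        for _ in range(self.n_trees):
            idx = rng.integers(0, n, size=n)
            tree = C45Tree(min_instances=1, prune=False,
                           n_feature_subset=min(k, m),
                           max_depth=self.max_depth, rng=rng)
            tree.fit(X[idx], y[idx])
            self.trees_.append(tree)
        return self

    def predict_proba1(self, X: np.ndarray) -> np.ndarray:
        votes = np.mean([t.predict_proba1(X) for t in self.trees_], axis=0)
        return votes

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba1(X) >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# Shared train/predict interface
# ---------------------------------------------------------------------------

def train_predict(spec: ClassifierSpec, train_X: np.ndarray,
                  train_y: np.ndarray, test_X: np.ndarray
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Fit ``spec`` on the training split; return (labels, ranking scores).

    Scores are continuous where the model provides them: the SVM decision
    function, a distance-derived score for 1-NN, leaf class frequencies
    for the tree, and the forest's mean vote.
    """
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y).astype(int)
    test_X = np.asarray(test_X, dtype=float)
    if np.unique(train_y).size < 2:
        raise ValidationError("training split must contain both classes")

    if spec.kind == "svm_puk":
        gram = puk_gram(train_X, train_X, spec.puk_omega, spec.puk_sigma)
        model = SVC(C=spec.svm_c, kernel="precomputed")
        model.fit(gram, train_y)
        gram_te = puk_gram(test_X, train_X, spec.puk_omega, spec.puk_sigma)
        scores = model.decision_function(gram_te)
        return model.predict(gram_te).astype(int), scores

    if spec.kind == "knn":
        scaler = MinMaxScaler().fit(train_X)
        tr = scaler.transform(train_X)
        te = scaler.transform(test_X)
        d = cdist(te, tr)
        k = spec.knn_k
        nearest = np.argsort(d, axis=1, kind="stable")[:, :k]
        labels = (train_y[nearest].mean(axis=1) >= 0.5).astype(int)
        # distance-derived ranking score: nearer to class 1 -> higher
        d1 = d[:, train_y == 1].min(axis=1)
        d0 = d[:, train_y == 0].min(axis=1)
        scores = d0 / (d0 + d1 + 1e-300)
        return labels, scores

    if spec.kind == "c45":
        tree = C45Tree(min_instances=spec.c45_min_instances,
                       confidence_factor=spec.c45_confidence_factor,
                       prune=True).fit(train_X, train_y)
        scores = tree.predict_proba1(test_X)
        return (scores >= 0.5).astype(int), scores

    if spec.kind == "random_forest":
        forest = RandomForestGR(n_trees=spec.rf_n_trees, seed=spec.rf_seed,
                                max_depth=spec.rf_max_depth
                                ).fit(train_X, train_y)
        scores = forest.predict_proba1(test_X)
        return (scores >= 0.5).astype(int), scores

    raise InputError(f"unknown classifier kind {spec.kind!r}")


def stratified_kfold(y: Sequence[int], k: int = 10, seed: int = 1
                     ) -> np.ndarray:
    """Deterministic stratified fold assignment (0..k-1 per instance)."""
    y = np.asarray(y).astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValidationError(
            f"each class needs >= {k} instances, got counts {counts}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(y.size, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros_like(y), y)):
        assignment[test_idx] = fold
    return assignment


def crossval_report(dataset, spec: ClassifierSpec, k: int = 10,
                    seed: int = 1) -> EvalReport:
    """Pooled k-fold evaluation of one classifier on one dataset."""
    X, y = dataset.X, dataset.y
    folds = stratified_kfold(y, k=k, seed=seed)
    y_pred = np.empty_like(y)
    scores = np.empty(y.size, dtype=float)
    for fold in range(k):
        test = folds == fold
        labels, s = train_predict(spec, X[~test], y[~test], X[test])
        y_pred[test] = labels
        scores[test] = s
    cm = ConfusionMatrix.from_labels(y, y_pred)
    acc, sens, specif = metrics_from_cm(cm)
    kappa = cohens_kappa(cm)
    return EvalReport(classifier=spec.kind, variant=dataset.variant,
                      confusion=cm, accuracy=acc, sensitivity=sens,
                      specificity=specif, kappa=kappa,
                      auc=auc(scores, y), kappa_band=interpret_kappa(kappa))


def run_experiment(datasets: Mapping[int, "FeatureDataset"],
                   specs: Optional[Sequence[ClassifierSpec]] = None,
                   k: int = 10, seed: int = 1) -> List[EvalReport]:
    """Evaluate every classifier on every dataset variant."""
    if specs is None:
        specs = default_specs()
    reports = []
    for variant in sorted(datasets):
        for spec in specs:
            reports.append(crossval_report(datasets[variant], spec,
                                           k=k, seed=seed))
    return reports


def reports_to_json(reports: Sequence[EvalReport], path: str) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=2)


# ---------------------------------------------------------------------------
# Published confusion-matrix fixtures
# ---------------------------------------------------------------------------

def load_table4_fixtures(only_consistent: bool = False) -> pd.DataFrame:
    """The 20 published per-(classifier, dataset) confusion matrices.

    Columns: classifier, dataset, tp, fn, fp, tn, sum_consistent.  See the
    note in the CSV header about cell order: the published off-diagonal
    captions are transposed relative to the sensitivity/specificity
    definitions, so cells are stored in the order that reproduces the
    published metric table (tp, fn, fp, tn).  One J48 matrix does not sum
    to the common instance total (an apparent misprint) and is flagged
    ``sum_consistent=False``.
    """
    path = resources.files("rppgstress").joinpath(
        "data/table4_confusion_matrices.csv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, comment="#")
    df["sum_consistent"] = df["sum_consistent"].astype(bool)
    if only_consistent:
        df = df[df["sum_consistent"]].reset_index(drop=True)
    return df


def fixture_matrix(row: pd.Series) -> ConfusionMatrix:
    return ConfusionMatrix(tp=int(row.tp), fn=int(row.fn),
                           fp=int(row.fp), tn=int(row.tn))
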