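"""Therapy-response prediction from ISN edge weights.

Two independent protocols, both using the endoscopic-remission label:

* a random forest with per-tree class-balanced down-sampling (each tree's
  bootstrap draws equal counts per class), feature ranking by out-of-bag
  permutation importance inside every fold of a repeated stratified CV, and
  rank aggregation of the fold-level rankings into one global list;
* a radial-kernel SVM with leave-one-out CV, screening the features with the
  highest absolute point-biserial correlation on each training set (strictly
  inside the loop, so no information leaks from the held-out sample).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from isnkit.lioness import IsnSet


def compute_auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with averaged ties."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = y == np.max(y) if y.dtype != bool else y
    n1 = int(pos.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: only one class present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


class BalancedRandomForest:
    """Random forest whose every tree is grown on a class-balanced bootstrap.

    Each tree draws m samples per class with replacement, m being the
    minority-class count; feature importance is out-of-bag permutation
    importance (mean accuracy drop over trees when a feature is shuffled
    among that tree's OOB samples).
    """

    def __init__(self, n_trees: int = 100, max_features: str = "sqrt",
                 random_state: int = 0):
        self.n_trees = n_trees
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BalancedRandomForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary outcome required")
        rng = np.random.default_rng(self.random_state)
        idx_by_class = [np.flatnonzero(y == c) for c in self.classes_]
        m = min(len(ix) for ix in idx_by_class)
        n = len(y)
        self.trees_, self.oob_, self.bootstrap_counts_ = [], [], []
        for t in range(self.n_trees):
            boot = np.concatenate([rng.choice(ix, size=m, replace=True)
                                   for ix in idx_by_class])
            tree = DecisionTreeClassifier(
                max_features=self.max_features,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X[boot], y[boot])
            oob = np.setdiff1d(np.arange(n), np.unique(boot))
            self.trees_.append(tree)
            self.oob_.append(oob)
            self.bootstrap_counts_.append(
                {c: int((y[boot] == c).sum()) for c in self.classes_})
        self._X, self._y = X, y
        self._rng = rng
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        prob = np.zeros((X.shape[0], 2))
        for tree in self.trees_:
            p = tree.predict_proba(X)
            for k, c in enumerate(tree.classes_):
                prob[:, np.flatnonzero(self.classes_ == c)[0]] += p[:, k]
        return prob / len(self.trees_)

    def oob_permutation_importance(self) -> np.ndarray:
        """Per-feature mean OOB accuracy drop across trees."""
        X, y = self._X, self._y
        p = X.shape[1]
        drops = np.zeros(p)
        counts = np.zeros(p)
        for tree, oob in zip(self.trees_, self.oob_):
            if len(oob) == 0:
                continue
            Xo, yo = X[oob], y[oob]
            base = np.mean(tree.predict(Xo) == yo)
            # one batched predict per tree: block f has feature f permuted
            n_oob = len(oob)
            Xrep = np.tile(Xo, (p, 1))
            for f in range(p):
                perm = self._rng.permutation(n_oob)
                Xrep[f * n_oob:(f + 1) * n_oob, f] = Xo[perm, f]
            pred = tree.predict(Xrep).reshape(p, n_oob)
            drops += base - (pred == yo[None, :]).mean(axis=1)
            counts += 1
        with np.errstate(invalid="ignore"):
            return np.where(counts > 0, drops / np.maximum(counts, 1), 0.0)


def borda_aggregate(rankings: list, features: list) -> list:
    """Weighted Borda: order features by mean rank across lists (ties by id)."""
    pos = pd.DataFrame(
        {k: {f: r for r, f in enumerate(ranking)} for k, ranking in enumerate(rankings)}
    ).reindex(features)
    mean_rank = pos.mean(axis=1)
    return list(mean_rank.sort_values(kind="stable").index)


def monte_carlo_aggregate(rankings: list, features: list, n_iter: int = 200,
                          seed: int = 0) -> list:
    """Seeded stochastic refinement of the Borda order by footrule distance."""
    rng = np.random.default_rng(seed)
    pos = {f: np.array([list(r).index(f) if f in r else len(r) for r in rankings])
           for f in features}

    def cost(order):
        return sum(abs(pos[f] - i).sum() for i, f in enumerate(order))

    best = borda_aggregate(rankings, features)
    best_cost = cost(best)
    order = list(best)
    for _ in range(n_iter):
        i, j = rng.integers(0, len(order), size=2)
        order[i], order[j] = order[j], order[i]
        c = cost(order)
        if c < best_cost:
            best, best_cost = list(order), c
        else:
            order[i], order[j] = order[j], order[i]
    return best


@dataclass
class FeatureRanking:
    per_fold: list                   # one ranked feature list per fold x repeat
    aggregated: list
    top_k: list


@dataclass
class PredictionResult:
    scores: pd.Series                # per-sample predicted score in [0, 1]
    auc: float
    accuracy: float
    selected_features: list = field(default_factory=list)
    scheme: str = ""
    seed: int = 0


def _as_matrix(isns, outcome):
    if isinstance(isns, IsnSet):
        X = isns.weights
    else:
        X = isns
    outcome = outcome.loc[X.index]
    keep = outcome.notna() & (outcome != "missing")
    X = X.loc[keep.values]
    outcome = outcome[keep.values]
    classes = pd.unique(outcome)
    if len(classes) != 2:
        raise ValueError(f"binary outcome required, found {list(classes)}")
    y = (outcome == sorted(classes)[-1]).astype(int).values
    return X, y


def rf_rank_select(
    isns,
    outcome: pd.Series,
    folds: int = 5,
    repeats: int = 10,
    top_k: int = 10,
    n_trees: int = 100,
    aggregation: str = "borda",
    seed: int = 0,
) -> tuple[FeatureRanking, PredictionResult]:
    """Down-sampled RF with repeated-CV OOB feature ranking and aggregation."""
    X, y = _as_matrix(isns, outcome)
    if min((y == 0).sum(), (y == 1).sum()) < folds:
        folds = max(2, int(min((y == 0).sum(), (y == 1).sum())))
    feats = list(X.columns)
    Xv = X.values

    rankings = []
    scores = np.zeros(len(y))
    n_scored = np.zeros(len(y))
    rng = np.random.default_rng(seed)
    for r in range(repeats):
        for attempt in range(10):
            skf = StratifiedKFold(n_splits=folds, shuffle=True,
                                  random_state=int(rng.integers(2**31 - 1)))
            splits = list(skf.split(Xv, y))
            if all(len(np.unique(y[tr])) == 2 for tr, _ in splits):
                break
        else:
            raise RuntimeError("could not draw folds with both classes present")
        for tr, te in splits:
            forest = BalancedRandomForest(
                n_trees=n_trees, random_state=int(rng.integers(2**31 - 1)))
            forest.fit(Xv[tr], y[tr])
            imp = forest.oob_permutation_importance()
            order = np.lexsort((np.arange(len(feats)), -imp))
            rankings.append([feats[i] for i in order])
            prob = forest.predict_proba(Xv[te])[:, 1]
            scores[te] += prob
            n_scored[te] += 1

    scores = scores / np.maximum(n_scored, 1)
    if aggregation == "borda":
        aggregated = borda_aggregate(rankings, feats)
    elif aggregation == "mc":
        aggregated = monte_carlo_aggregate(rankings, feats, seed=seed)
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    ranking = FeatureRanking(rankings, aggregated, aggregated[:top_k])
    result = PredictionResult(
        scores=pd.Series(scores, index=X.index, name="rf_score"),
        auc=compute_auc(scores, y),
        accuracy=float(np.mean((scores > 0.5).astype(int) == y)),
        selected_features=ranking.top_k,
        scheme=f"rf down-sampled, {folds}-fold x {repeats} repeats, {aggregation} aggregation",
        seed=seed,
    )
    return ranking, result


def svm_loo_predict(
    isns,
    outcome: pd.Series,
    n_screen: int = 20,
    C: float = 1.0,
    seed: int = 0,
) -> PredictionResult:
    """Radial SVM with LOO CV and in-loop univariate correlation screening."""
    X, y = _as_matrix(isns, outcome)
    n = len(y)
    if n < 10:
        raise ValueError(f"need N >= 10 samples for LOO, got {n}")
    Xv = X.values
    scores = np.zeros(n)
    screened_union: set = set()
    for q in range(n):
        tr = np.setdiff1d(np.arange(n), [q])
        Xt, yt = Xv[tr], y[tr]
        sd = Xt.std(axis=0)
        usable = np.flatnonzero(sd > 0)
        yc = yt - yt.mean()
        corr = np.zeros(Xt.shape[1])
        corr[usable] = np.abs(
            (Xt[:, usable] - Xt[:, usable].mean(axis=0)).T @ yc
        ) / (sd[usable] * yt.std() * len(yt) + 1e-300)
        keep = np.lexsort((np.arange(len(corr)), -corr))[:min(n_screen, len(usable))]
        keep = keep[sd[keep] > 0]
        screened_union.update(X.columns[keep])
        scaler = StandardScaler().fit(Xt[:, keep])
        svm = SVC(kernel="rbf", C=C, gamma="scale")
        svm.fit(scaler.transform(Xt[:, keep]), yt)
        df = svm.decision_function(scaler.transform(Xv[q][keep].reshape(1, -1)))[0]
        scores[q] = 1.0 / (1.0 + np.exp(-df))
    return PredictionResult(
        scores=pd.Series(scores, index=X.index, name="svm_score"),
        auc=compute_auc(scores, y),
        accuracy=float(np.mean((scores > 0.5).astype(int) == y)),
        selected_features=sorted(screened_union),
        scheme=f"svm radial, LOO CV, top-{n_screen} correlation screen",
        seed=seed,
    )


def model_state_hash(forest: BalancedRandomForest) -> str:
    """Hash of the fitted forest's structure (for no-leakage checks)."""
    h = hashlib.sha256()
    for tree in forest.trees_:
        h.update(tree.tree_.feature.tobytes())
        h.update(tree.tree_.threshold.tobytes())
        h.update(tree.tree_.value.tobytes())
    return h.hexdigest()
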