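"""Base classifiers and metaclassifier behind a uniform fit/score contract.

Every learner exposes ``fit(X, y, seed)`` and ``score(X)`` where ``score``
returns one real per row in [0, 1] interpreted as the probability of the
positive class.  Margin-based learners squash their margin through a
logistic so the stacking layer consumes a single score type.  Fitting is
deterministic given the seed.

Registry entries (the ensemble's default base set plus its meta):

``bayesnet``
    Discrete Bayes network: features are supervised-discretized (recursive
    entropy splits with an MDL stopping rule), then scored with
    class-conditional categorical tables.  Default structure is
    naive-Bayes (class is each feature's only parent); ``structure="tan"``
    augments it with a Chow-Liu tree of one extra feature parent each,
    selected by class-conditional mutual information (quadratic in the
    number of features — intended for low-dimensional use).
``nb_multinomial``
    Multinomial naive Bayes with Laplace smoothing (alpha = 1).
``svm``
    RBF-kernel support vector machine, C = 1, gamma = 1/dim, Platt-scaled
    probability outputs.
``voted_perceptron``
    Freund-Schapire voted perceptron (linear kernel, 1 epoch default); the
    sequence of prediction vectors is weighted by survival counts and the
    normalised vote margin is squashed through a logistic.
``logistic``
    L2-regularised logistic regression with weak regularisation — the
    metaclassifier.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from typing import Optional

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import MultinomialNB
from sklearn.svm import SVC


class NotFittedError(RuntimeError):
    pass


def _check_Xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"{X.shape[0]} rows of X for {y.shape[0]} labels")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(f"need both classes 0 and 1 in y, got classes {classes}")
    return X, y


class Learner(ABC):
    """Uniform contract: fit(X, y, seed) then score(X') -> P(label=1) per row."""

    name: str = "learner"

    def __init__(self) -> None:
        self.fitted = False
        self.n_features_: Optional[int] = None
        self.meta_: dict = {}

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int = 0) -> "Learner":
        X, y = _check_Xy(X, y)
        self._fit(X, y, seed)
        self.fitted = True
        self.n_features_ = X.shape[1]
        self.meta_ = {
            "name": self.name,
            "seed": int(seed),
            "n": int(X.shape[0]),
            "dim": int(X.shape[1]),
            "hyperparams": self.hyperparams(),
        }
        return self

    def score(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise NotFittedError(f"{self.name}: fit before score")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_:
            raise ValueError(
                f"{self.name}: {X.shape[1]} features, trained with {self.n_features_}"
            )
        s = np.clip(self._score(X), 0.0, 1.0)
        return s

    def predict_label(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        """Hard labels; a score exactly at the threshold counts positive."""
        return (self.score(X) >= threshold).astype(int)

    def hyperparams(self) -> dict:
        return {}

    @abstractmethod
    def _fit(self, X: np.ndarray, y: np.ndarray, seed: int) -> None: ...

    @abstractmethod
    def _score(self, X: np.ndarray) -> np.ndarray: ...


# ---------------------------------------------------------------------------
# discrete Bayes network


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _mdl_split(values: np.ndarray, y: np.ndarray, depth: int, max_depth: int) -> list[float]:
    """Recursive entropy-minimising cut points with the MDL acceptance test."""
    n = values.shape[0]
    if n < 4 or depth >= max_depth:
        return []
    order = np.argsort(values, kind="mergesort")
    v, lab = values[order], y[order]
    # candidate boundaries between distinct values
    distinct = np.nonzero(np.diff(v))[0]
    if distinct.size == 0:
        return []
    total = np.bincount(lab, minlength=2).astype(float)
    ent_total = _entropy(total)
    left = np.zeros(2)
    best = None
    prev = 0
    for b in distinct:
        left = left + np.bincount(lab[prev: b + 1], minlength=2)
        prev = b + 1
        right = total - left
        nl, nr = left.sum(), right.sum()
        e = (nl / n) * _entropy(left) + (nr / n) * _entropy(right)
        if best is None or e < best[0]:
            best = (e, b, left.copy(), right.copy())
    ent_split, b, cl, cr = best
    gain = ent_total - ent_split
    k = np.count_nonzero(total)
    k1, k2 = np.count_nonzero(cl), np.count_nonzero(cr)
    delta = (
        math.log2(3 ** k - 2)
        - (k * ent_total - k1 * _entropy(cl) - k2 * _entropy(cr))
    )
    if gain <= (math.log2(n - 1) + delta) / n:
        return []
    cut = (v[b] + v[b + 1]) / 2.0
    lmask = values <= cut
    return sorted(
        _mdl_split(values[lmask], y[lmask], depth + 1, max_depth)
        + [cut]
        + _mdl_split(values[~lmask], y[~lmask], depth + 1, max_depth)
    )


class DiscreteBayesNet(Learner):
    """Bayes network over supervised-discretized features.

    Each feature is cut into intervals by recursive entropy minimisation
    with an MDL stop (features for which no cut is accepted collapse to a
    single bin and contribute nothing).  With ``structure="naive"`` the
    class is every feature's only parent; ``structure="tan"`` adds one
    feature parent each via a maximum-spanning tree on class-conditional
    mutual information.  Conditional tables use symmetric Dirichlet
    smoothing (prior_count per cell).
    """

    name = "bayesnet"

    def __init__(self, structure: str = "naive", prior_count: float = 0.5,
                 max_depth: int = 3):
        super().__init__()
        if structure not in ("naive", "tan"):
            raise ValueError("structure must be 'naive' or 'tan'")
        self.structure = structure
        self.prior_count = float(prior_count)
        self.max_depth = int(max_depth)

    def hyperparams(self) -> dict:
        return {
            "structure": self.structure,
            "prior_count": self.prior_count,
            "max_depth": self.max_depth,
        }

    def _discretize(self, X: np.ndarray) -> np.ndarray:
        D = np.empty(X.shape, dtype=np.int64)
        for j, cuts in enumerate(self.cuts_):
            D[:, j] = np.searchsorted(cuts, X[:, j], side="left") if cuts.size else 0
        return D

    def _fit(self, X: np.ndarray, y: np.ndarray, seed: int) -> None:
        n, d = X.shape
        self.cuts_ = [
            np.asarray(_mdl_split(X[:, j], y, 0, self.max_depth), dtype=float)
            for j in range(d)
        ]
        self.n_bins_ = np.array([c.size + 1 for c in self.cuts_])
        D = self._discretize(X)
        self.class_logprior_ = np.log(
            (np.bincount(y, minlength=2) + self.prior_count)
            / (n + 2 * self.prior_count)
        )
        self.parents_ = np.full(d, -1, dtype=int)
        if self.structure == "tan":
            self.parents_ = self._chow_liu_parents(D, y)
        # CPTs: log P(x_j = b | y, parent bin)
        self.cpt_: list[np.ndarray] = []
        for j in range(d):
            bj = self.n_bins_[j]
            p = self.parents_[j]
            bp = self.n_bins_[p] if p >= 0 else 1
            counts = np.full((2, bp, bj), self.prior_count)
            pcol = D[:, p] if p >= 0 else np.zeros(n, dtype=int)
            np.add.at(counts, (y, pcol, D[:, j]), 1.0)
            self.cpt_.append(np.log(counts / counts.sum(axis=2, keepdims=True)))

    def _chow_liu_parents(self, D: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Maximum spanning tree on class-conditional mutual information."""
        n, d = D.shape
        M = np.zeros((d, d))
        for c in (0, 1):
            Dc = D[y == c]
            w = Dc.shape[0] / n
            for a in range(d):
                for b in range(a + 1, d):
                    tab = np.zeros((self.n_bins_[a], self.n_bins_[b]))
                    np.add.at(tab, (Dc[:, a], Dc[:, b]), 1.0)
                    tot = tab.sum()
                    if tot == 0:
                        continue
                    pj = tab / tot
                    pa = pj.sum(axis=1, keepdims=True)
                    pb = pj.sum(axis=0, keepdims=True)
                    with np.errstate(divide="ignore", invalid="ignore"):
                        t = pj * np.log(pj / (pa * pb))
                    mi = np.nansum(t)
                    M[a, b] += w * mi
        # Prim's algorithm rooted at feature 0
        parents = np.full(d, -1, dtype=int)
        in_tree = {0}
        while len(in_tree) < d:
            best = (-1.0, None, None)
            for a in in_tree:
                for b in range(d):
                    if b in in_tree:
                        continue
                    wgt = M[min(a, b), max(a, b)]
                    if wgt > best[0]:
                        best = (wgt, a, b)
            _, a, b = best
            parents[b] = a
            in_tree.add(b)
        return parents

    def _joint_loglik(self, X: np.ndarray) -> np.ndarray:
        D = self._discretize(X)
        # clamp unseen high bins (values beyond training range land in last bin)
        for j in range(D.shape[1]):
            np.clip(D[:, j], 0, self.n_bins_[j] - 1, out=D[:, j])
        n = X.shape[0]
        ll = np.tile(self.class_logprior_, (n, 1))
        for j, cpt in enumerate(self.cpt_):
            p = self.parents_[j]
            pcol = D[:, p] if p >= 0 else np.zeros(n, dtype=int)
            ll[:, 0] += cpt[0, pcol, D[:, j]]
            ll[:, 1] += cpt[1, pcol, D[:, j]]
        return ll

    def _score(self, X: np.ndarray) -> np.ndarray:
        ll = self._joint_loglik(X)
        m = ll.max(axis=1, keepdims=True)
        p = np.exp(ll - m)
        return p[:, 1] / p.sum(axis=1)


class MultinomialNBLearner(Learner):
    """Multinomial naive Bayes (Laplace alpha = 1) on nonnegative features."""

    name = "nb_multinomial"

    def __init__(self, alpha: float = 1.0):
        super().__init__()
        self.alpha = float(alpha)

    def hyperparams(self) -> dict:
        return {"alpha": self.alpha}

    def _fit(self, X: np.ndarray, y: np.ndarray, seed: int) -> None:
        if np.any(X < 0):
            raise ValueError("nb_multinomial requires nonnegative features")
        self.model_ = MultinomialNB(alpha=self.alpha).fit(X, y)

    def _score(self, X: np.ndarray) -> np.ndarray:
        return self.model_.predict_proba(X)[:, 1]


class SVMLearner(Learner):
    """RBF-kernel SVM (C = 1) with Platt-style sigmoid probability calibration.

    ``gamma="scale"`` (1 / (dim * var(X))) is the default: the encoders
    apply no feature scaling, so the variance-normalised kernel width is
    what keeps the RBF kernel informative on raw frequency/EIIP features.
    ``gamma="auto"`` (1/dim) is available for strict LibSVM-default
    behaviour.  Calibration uses 5-fold cross-validated sigmoid fitting on
    a single underlying SVM (no ensembling), deterministic given the data.
    """

    name = "svm"

    def __init__(self, C: float = 1.0, gamma: str | float = "scale",
                 cache_size: float = 500.0, calibration_folds: int = 5):
        super().__init__()
        self.C = float(C)
        self.gamma = gamma
        self.cache_size = cache_size
        self.calibration_folds = int(calibration_folds)

    def hyperparams(self) -> dict:
        return {"C": self.C, "gamma": self.gamma, "kernel": "rbf",
                "calibration_folds": self.calibration_folds}

    def _fit(self, X: np.ndarray, y: np.ndarray, seed: int) -> None:
        svc = SVC(
            C=self.C,
            kernel="rbf",
            gamma=self.gamma,
            cache_size=self.cache_size,
            random_state=seed,
        )
        cv = min(self.calibration_folds, int(np.bincount(y).min()))
        self.model_ = CalibratedClassifierCV(
            svc, method="sigmoid", cv=max(cv, 2), ensemble=False
        ).fit(X, y)

    def _score(self, X: np.ndarray) -> np.ndarray:
        return self.model_.predict_proba(X)[:, 1]


class VotedPerceptron(Learner):
    """Freund-Schapire voted perceptron with a linear (degree-1) kernel.

    Training keeps every intermediate weight vector w_i together with its
    survival count c_i (number of consecutive correct predictions).  The
    vote for a point x is v(x) = sum_i c_i sign(w_i . x) / sum_i c_i in
    [-1, 1]; the reported score is sigmoid(v), a monotone map onto (0, 1)
    whose 0.5 crossing coincides with the majority vote.  One epoch by
    default; data order is shuffled once per epoch from the seed.
    """

    name = "voted_perceptron"

    def __init__(self, epochs: int = 1, shuffle: bool = True):
        super().__init__()
        self.epochs = int(epochs)
        self.shuffle = bool(shuffle)

    def hyperparams(self) -> dict:
        return {"epochs": self.epochs, "shuffle": self.shuffle}

    def _fit(self, X: np.ndarray, y: np.ndarray, seed: int) -> None:
        rng = np.random.default_rng(seed)
        n, d = X.shape
        t = 2 * y - 1  # {-1, +1}
        Xa = np.hstack([X, np.ones((n, 1))])  # bias via augmentation
        w = np.zeros(d + 1)
        c = 1
        ws, cs = [], []
        for _ in range(self.epochs):
            order = rng.permutation(n) if self.shuffle else np.arange(n)
            for i in order:
                pred = 1.0 if Xa[i] @ w >= 0 else -1.0
                if pred == t[i]:
                    c += 1
                else:
                    ws.append(w.copy())
                    cs.append(c)
                    w = w + t[i] * Xa[i]
                    c = 1
        ws.append(w.copy())
        cs.append(c)
        self.W_ = np.array(ws)
        self.c_ = np.array(cs, dtype=float)

    def vote_margin(self, X: np.ndarray) -> np.ndarray:
        Xa = np.hstack([X, np.ones((X.shape[0], 1))])
        signs = np.sign(Xa @ self.W_.T)
        signs[signs == 0] = 1.0
        return (signs @ self.c_) / self.c_.sum()

    def _score(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.vote_margin(X)))


class LogisticLearner(Learner):
    """Weakly L2-regularised logistic regression (the metaclassifier)."""

    name = "logistic"

    def __init__(self, C: float = 100.0, max_iter: int = 1000):
        super().__init__()
        self.C = float(C)
        self.max_iter = int(max_iter)

    def hyperparams(self) -> dict:
        return {"C": self.C, "penalty": "l2", "max_iter": self.max_iter}

    def _fit(self, X: np.ndarray, y: np.ndarray, seed: int) -> None:
        self.model_ = LogisticRegression(
            C=self.C, max_iter=self.max_iter, solver="lbfgs"
        ).fit(X, y)

    @property
    def coef_(self) -> np.ndarray:
        return self.model_.coef_.ravel()

    @property
    def intercept_(self) -> float:
        return float(self.model_.intercept_[0])

    def _score(self, X: np.ndarray) -> np.ndarray:
        return self.model_.predict_proba(X)[:, 1]


LEARNERS: dict[str, type[Learner]] = {
    "bayesnet": DiscreteBayesNet,
    "nb_multinomial": MultinomialNBLearner,
    "svm": SVMLearner,
    "voted_perceptron": VotedPerceptron,
    "logistic": LogisticLearner,
}


def make_learner(name: str, **hyperparams) -> Learner:
    """Instantiate a registered learner by name with hyperparameter overrides."""
    if name not in LEARNERS:
        raise KeyError(f"unknown learner {name!r}; known: {sorted(LEARNERS)}")
    return LEARNERS[name](**hyperparams)


def register_learner(name: str, cls: type[Learner]) -> None:
    """Register a third-party learner class against the Learner contract."""
    LEARNERS[name] = cls
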