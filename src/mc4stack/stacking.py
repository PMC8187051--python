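"""Two-stage stacked generalization with out-of-fold meta-features.

The training set is split into k stratified folds (default 10).  For each
base learner, k models are trained, each with one fold held out; the
held-out scores are stacked vertically into that learner's training
meta-column (matrix **A**, strictly out-of-fold), and the k models' scores
on the test set are averaged into its test meta-column (matrix **B**).  A
logistic metaclassifier is then fitted on (A, y) and applied to B.  New
data at deployment time follows the same path: per-row base features are
fold-model averages (the B construction); base learners are never refitted
on the full training set.

Meta-features are positive-class probabilities rather than hard labels, so
the fold averaging of test predictions preserves calibration and ranking.

The module is organised around a model/results pair —
:class:`StackedEnsembleModel` holds the data and configuration,
``fit()`` returns :class:`StackedEnsembleResults` carrying the fitted fold
models, both meta-matrices, per-base diagnostics and a ``summary()``
table — with thin functional wrappers (:func:`fit_stack`,
:func:`predict_stack`, :func:`oof_base_predictions`) over it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold

from .config import StackConfig
from .learners import Learner, make_learner

BUNDLE_FORMAT_VERSION = 1


@dataclass(frozen=True)
class FoldAssignment:
    """Stratified instance -> fold map for k-fold cross-validation.

    Fold ids run 1..k; fold sizes differ by at most one and per-fold class
    proportions are within one instance of the global proportions.
    """

    n: int
    k: int
    fold_of: np.ndarray  # shape (n,), values in 1..k
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "fold_of", np.asarray(self.fold_of, dtype=int)
        )
        if self.fold_of.shape != (self.n,):
            raise ValueError("fold_of must have one entry per instance")
        if not np.all((self.fold_of >= 1) & (self.fold_of <= self.k)):
            raise ValueError("fold ids must lie in 1..k")

    def heldout_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


def make_folds(
    n: int, labels: Sequence[int], k: int = 10, seed: int = 1
) -> FoldAssignment:
    """Stratified k-fold assignment, deterministic given the seed."""
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != n:
        raise ValueError(f"{labels.shape[0]} labels for n={n}")
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} instances")
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.zeros(n, dtype=int)
    for fold_id, (_, held) in enumerate(skf.split(np.zeros((n, 1)), labels), start=1):
        fold_of[held] = fold_id
    return FoldAssignment(n=n, k=k, fold_of=fold_of, seed=seed)


@dataclass(frozen=True)
class MetaMatrix:
    """n x n_base matrix of base-learner scores (role 'train' = A, 'test' = B)."""

    values: np.ndarray
    base_names: tuple[str, ...]
    role: str  # "train" | "test"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[1] != len(self.base_names):
            raise ValueError("one column per base learner required")
        if self.role not in ("train", "test"):
            raise ValueError("role must be 'train' or 'test'")
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError("meta-features must be probabilities in [0, 1]")


@dataclass
class FoldModel:
    """A fold-trained base model with the indices it was trained on."""

    learner: Learner
    fold: int
    train_index: np.ndarray


def oof_base_predictions(
    learner_name: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: Optional[np.ndarray],
    folds: FoldAssignment,
    seed: int = 0,
    hyperparams: Optional[dict] = None,
) -> tuple[np.ndarray, Optional[np.ndarray], list[FoldModel]]:
    """One base learner's out-of-fold column A and fold-averaged column B.

    ``A[i]`` is instance i's score from the model whose held-out fold
    contains i; ``B`` is the arithmetic mean of the k fold models' score
    vectors on ``X_test`` (``None`` when no test set is given).  The k
    fitted fold models are returned with their training-index sets, so the
    no-leakage property is machine-checkable.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    if X_train.shape[0] != folds.n:
        raise ValueError(
            f"X_train has {X_train.shape[0]} rows, fold assignment expects {folds.n}"
        )
    A = np.empty(folds.n, dtype=float)
    B_parts = []
    fold_models: list[FoldModel] = []
    for fold in range(1, folds.k + 1):
        tr = folds.train_indices(fold)
        held = folds.heldout_indices(fold)
        if np.unique(y_train[tr]).size < 2:
            raise ValueError(
                f"fold {fold}: training split contains a single class"
            )
        learner = make_learner(learner_name, **(hyperparams or {}))
        learner.fit(X_train[tr], y_train[tr], seed=seed + fold)
        A[held] = learner.score(X_train[held])
        if X_test is not None:
            B_parts.append(learner.score(X_test))
        fold_models.append(FoldModel(learner=learner, fold=fold, train_index=tr))
    B = np.mean(B_parts, axis=0) if B_parts else None
    return A, B, fold_models


@dataclass
class StackedEnsembleResults:
    """Fitted two-stage ensemble: per-base fold models plus the metaclassifier.

    Attributes
    ----------
    meta_train : MetaMatrix
        A — strictly out-of-fold base scores on the training set.
    meta_test : MetaMatrix or None
        B — fold-averaged base scores on the test set passed at fit time.
    fold_models : dict
        base name -> list of k :class:`FoldModel`.
    meta : Learner
        Fitted metaclassifier over the base columns.
    """

    config: StackConfig
    folds: FoldAssignment
    base_names: tuple[str, ...]
    fold_models: dict[str, list[FoldModel]]
    meta: Learner
    meta_train: MetaMatrix
    meta_test: Optional[MetaMatrix]
    y_train: np.ndarray
    encoder_name: str = "multifeature"
    diagnostics: dict = field(default_factory=dict)

    # -- prediction ---------------------------------------------------------

    def base_features(self, X_new: np.ndarray) -> np.ndarray:
        """Fold-averaged base scores for new rows (the B construction)."""
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim == 1:
            X_new = X_new[None, :]
        cols = []
        for name in self.base_names:
            scores = [fm.learner.score(X_new) for fm in self.fold_models[name]]
            cols.append(np.mean(scores, axis=0))
        return np.column_stack(cols)

    def predict_score(self, X_new: np.ndarray) -> np.ndarray:
        return self.meta.score(self.base_features(X_new))

    def predict(
        self, X_new: np.ndarray, threshold: Optional[float] = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """(scores, labels) for new encoded rows; ties at threshold go positive."""
        thr = self.config.threshold if threshold is None else threshold
        scores = self.predict_score(X_new)
        return scores, (scores >= thr).astype(int)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit summary: bases, their OOF quality, meta weights."""
        from .evaluation import confusion, metrics, roc_auc

        lines = [
            "Stacked ensemble (out-of-fold generalization)",
            f"  training instances : {self.folds.n}",
            f"  folds              : {self.folds.k} (seed {self.folds.seed})",
            f"  encoder            : {self.encoder_name}",
            "",
            f"  {'base learner':<18}{'OOF ACC':>9}{'OOF AUC':>9}{'meta coef':>11}",
        ]
        coefs = getattr(self.meta, "coef_", np.full(len(self.base_names), np.nan))
        for b, name in enumerate(self.base_names):
            col = self.meta_train.values[:, b]
            rep = metrics(confusion(self.y_train, (col >= 0.5).astype(int)))
            auc, _ = roc_auc(self.y_train, col)
            lines.append(
                f"  {name:<18}{rep.acc:>9.3f}{auc:>9.3f}{coefs[b]:>11.3f}"
            )
        intercept = getattr(self.meta, "intercept_", float("nan"))
        lines.append(f"  {'(meta intercept)':<18}{'':>9}{'':>9}{intercept:>11.3f}")
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, bundle_dir: str | Path) -> None:
        """Persist a versioned bundle (JSON manifest + model parameter blobs)."""
        bundle_dir = Path(bundle_dir)
        bundle_dir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format_version": BUNDLE_FORMAT_VERSION,
            "base_names": list(self.base_names),
            "encoder": self.encoder_name,
            "k": self.folds.k,
            "fold_seed": self.folds.seed,
            "config": self.config.to_dict(),
        }
        (bundle_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        joblib.dump(
            {
                "fold_models": self.fold_models,
                "meta": self.meta,
                "folds": self.folds,
                "meta_train": self.meta_train,
                "meta_test": self.meta_test,
                "y_train": self.y_train,
                "diagnostics": self.diagnostics,
            },
            bundle_dir / "models.joblib",
        )

    @classmethod
    def load(cls, bundle_dir: str | Path) -> "StackedEnsembleResults":
        bundle_dir = Path(bundle_dir)
        manifest = json.loads((bundle_dir / "manifest.json").read_text())
        if manifest["format_version"] != BUNDLE_FORMAT_VERSION:
            raise ValueError(
                f"bundle format {manifest['format_version']} unsupported"
            )
        blobs = joblib.load(bundle_dir / "models.joblib")
        return cls(
            config=StackConfig.from_dict(manifest["config"]),
            folds=blobs["folds"],
            base_names=tuple(manifest["base_names"]),
            fold_models=blobs["fold_models"],
            meta=blobs["meta"],
            meta_train=blobs["meta_train"],
            meta_test=blobs["meta_test"],
            y_train=blobs["y_train"],
            encoder_name=manifest["encoder"],
            diagnostics=blobs["diagnostics"],
        )


#: alias used in prose and type hints: the fitted ensemble object
StackedEnsemble = StackedEnsembleResults


class StackedEnsembleModel:
    """Unfitted two-stage stacking model over an encoded training set.

    Parameters
    ----------
    X_train, y_train
        Encoded feature matrix and binary labels.
    config
        :class:`~mc4stack.config.StackConfig`; defaults reproduce the
        four-base (bayesnet, nb_multinomial, svm, voted_perceptron) +
        logistic configuration with k = 10 folds.
    """

    def __init__(
        self,
        X_train: np.ndarray,
        y_train: Sequence[int],
        config: Optional[StackConfig] = None,
        encoder_name: str = "multifeature",
    ):
        self.X_train = np.asarray(X_train, dtype=float)
        self.y_train = np.asarray(y_train, dtype=int)
        if self.X_train.shape[0] != self.y_train.shape[0]:
            raise ValueError("X_train and y_train disagree on n")
        self.config = config or StackConfig()
        if len(self.config.base_learners) < 2:
            raise ValueError("stacking needs at least 2 base learners")
        self.encoder_name = encoder_name

    @classmethod
    def from_windows(cls, ws, config: Optional[StackConfig] = None):
        """Build the model straight from a labelled WindowSet."""
        from .encoders import encode_set, get_scheme

        config = config or StackConfig()
        scheme = get_scheme(config.encoder, **config.encoder_params)
        X, y, _ = encode_set(ws, scheme)
        if y is None:
            raise ValueError("WindowSet must be labelled to fit")
        return cls(X, y, config=config, encoder_name=config.encoder)

    def fit(
        self, X_test: Optional[np.ndarray] = None, seed: Optional[int] = None
    ) -> StackedEnsembleResults:
        """Run the full stacking procedure; returns the fitted results object."""
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        folds = make_folds(
            self.X_train.shape[0], self.y_train, k=cfg.k, seed=seed
        )
        base_names = tuple(name for name, _ in cfg.base_learners)
        A_cols, B_cols = [], []
        fold_models: dict[str, list[FoldModel]] = {}
        for b, (name, hp) in enumerate(cfg.base_learners):
            A_col, B_col, fms = oof_base_predictions(
                name,
                self.X_train,
                self.y_train,
                X_test,
                folds,
                seed=seed * 1000 + b * 100,
                hyperparams=hp,
            )
            A_cols.append(A_col)
            if B_col is not None:
                B_cols.append(B_col)
            fold_models[name] = fms
        A = MetaMatrix(np.column_stack(A_cols), base_names, role="train")
        B = (
            MetaMatrix(np.column_stack(B_cols), base_names, role="test")
            if B_cols
            else None
        )
        meta = make_learner(cfg.meta_learner, **cfg.meta_params)
        meta.fit(A.values, self.y_train, seed=seed)
        return StackedEnsembleResults(
            config=cfg,
            folds=folds,
            base_names=base_names,
            fold_models=fold_models,
            meta=meta,
            meta_train=A,
            meta_test=B,
            y_train=self.y_train,
            encoder_name=self.encoder_name,
        )


def fit_stack(
    X_train: np.ndarray,
    y_train: Sequence[int],
    X_test: Optional[np.ndarray] = None,
    config: Optional[StackConfig] = None,
) -> tuple[StackedEnsembleResults, MetaMatrix, Optional[MetaMatrix]]:
    """Functional facade: fit the stack, return (ensemble, A, B)."""
    results = StackedEnsembleModel(X_train, y_train, config=config).fit(X_test)
    return results, results.meta_train, results.meta_test


def predict_stack(
    ensemble: StackedEnsembleResults,
    X_new: np.ndarray,
    threshold: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(scores, labels) for new rows encoded with the ensemble's scheme."""
    return ensemble.predict(X_new, threshold=threshold)
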