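"""RBF-kernel SVM deletion classifier: grid search, training and calling.

The kernel is parameterized by a bandwidth ``sigma``:
``k(x, y) = exp(-||x - y||^2 / (2 sigma^2))``, i.e. scikit-learn's
``gamma = 1 / (2 sigma^2)``. Model selection runs a grid search over
exponentially growing C and sigma with repeated stratified k-fold cross
validation; concordance is plain held-out accuracy and ties are broken by
smallest C then smallest sigma. Features enter the SVM unscaled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from stsdel.errors import ContractError, ValidationError
from stsdel.features import FEATURE_COLUMNS, FeatureMatrix

DELETED = "deleted"
NOT_DELETED = "not_deleted"
NOT_EVALUATED = "not_evaluated"

DEFAULT_GRID = tuple(2.0 ** np.arange(-5, 16))


def sigma_to_gamma(sigma: float) -> float:
    return 1.0 / (2.0 * sigma * sigma)


@dataclass(frozen=True)
class SVMConfig:
    """Grid-search and cross-validation settings."""

    c_grid: tuple[float, ...] = DEFAULT_GRID
    sigma_grid: tuple[float, ...] = DEFAULT_GRID
    cv_folds: int = 4
    cv_repetitions: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.c_grid or not self.sigma_grid:
            raise ValidationError("parameter grids must be nonempty")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if self.cv_repetitions < 1:
            raise ValidationError("cv_repetitions must be >= 1")


@dataclass
class TrainingSet:
    """Labeled (sample, STS) events with attached features.

    ``table`` columns: sample_id, sts_id, f1, f2, f3, deleted (bool).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "sts_id", "deleted", *FEATURE_COLUMNS}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"training table missing columns {sorted(missing)}")
        if self.table.duplicated(["sample_id", "sts_id"]).any():
            raise ValidationError("duplicate (sample, STS) pairs in training set")
        y = self.table["deleted"].astype(bool)
        if y.nunique() < 2:
            raise ValidationError("training set must contain both classes")
        X = self.table[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
        if not np.isfinite(X).all():
            i = int(np.argwhere(~np.isfinite(X))[0, 0])
            row = self.table.iloc[i]
            raise ValidationError(
                f"non-finite feature for pair ({row['sample_id']}, {row['sts_id']})"
            )

    def __len__(self) -> int:
        return len(self.table)

    def X(self) -> np.ndarray:
        return self.table[list(FEATURE_COLUMNS)].to_numpy(dtype=float)

    def y(self) -> np.ndarray:
        return self.table["deleted"].astype(bool).to_numpy()

    @classmethod
    def from_tsv(cls, path) -> "TrainingSet":
        table = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "sts_id": str})
        return cls(table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def grid_search_cv(
    train: TrainingSet, config: SVMConfig = SVMConfig()
) -> tuple[float, float, pd.DataFrame]:
    """Mean CV concordance per (C, sigma); returns (best C, best sigma, table).

    Fold partitions are stratified by class and shared across all grid cells
    of a repetition, so cells are compared on identical held-out splits. The
    argmax is tie-broken toward smallest C, then smallest sigma.
    """
    X, y = train.X(), train.y()
    rng = np.random.default_rng(config.seed)
    cells = [(c, s) for c in config.c_grid for s in config.sigma_grid]
    correct = np.zeros(len(cells))
    total = np.zeros(len(cells))
    # precompute one full kernel matrix per sigma; folds then slice it, which
    # is much cheaper than re-evaluating the RBF inside every SVC fit
    d2 = (
        (X * X).sum(axis=1)[:, None]
        + (X * X).sum(axis=1)[None, :]
        - 2.0 * X @ X.T
    )
    kernels = {s: np.exp(-sigma_to_gamma(s) * d2) for s in set(config.sigma_grid)}
    models = [SVC(C=c, kernel="precomputed") for c, _ in cells]
    for _ in range(config.cv_repetitions):
        splitter = StratifiedKFold(
            n_splits=config.cv_folds,
            shuffle=True,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        for tr_idx, te_idx in splitter.split(X, y):
            y_tr, y_te = y[tr_idx], y[te_idx]
            for k, ((_, s), model) in enumerate(zip(cells, models)):
                K = kernels[s]
                model.fit(K[np.ix_(tr_idx, tr_idx)], y_tr)
                pred = model.predict(K[np.ix_(te_idx, tr_idx)])
                correct[k] += int((pred == y_te).sum())
                total[k] += len(te_idx)
    concordance = correct / total
    table = pd.DataFrame(
        {
            "C": [c for c, _ in cells],
            "sigma": [s for _, s in cells],
            "concordance": concordance,
        }
    )
    # argmax with deterministic tie-break: highest concordance, then smallest
    # C, then smallest sigma
    order = table.sort_values(
        ["concordance", "C", "sigma"], ascending=[False, True, True]
    )
    best = order.iloc[0]
    return float(best["C"]), float(best["sigma"]), table


@dataclass
class DeletionClassifier:
    """Fitted RBF SVM plus the provenance needed to reproduce its calls."""

    C: float
    sigma: float
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    feature_names: tuple[str, ...] = FEATURE_COLUMNS
    seed: int | None = None
    resubstitution_accuracy: float | None = None
    _svc: SVC | None = field(default=None, repr=False, compare=False)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Signed distance to the boundary; positive means deleted."""
        X = np.asarray(X, dtype=float)
        gamma = sigma_to_gamma(self.sigma)
        d2 = (
            (X * X).sum(axis=1)[:, None]
            + (self.support_vectors * self.support_vectors).sum(axis=1)[None, :]
            - 2.0 * X @ self.support_vectors.T
        )
        K = np.exp(-gamma * d2)
        return K @ self.dual_coef.ravel() + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.decision_function(X) > 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "stsdel-svm-v1",
            "kernel": "rbf",
            "C": self.C,
            "sigma": self.sigma,
            "gamma": sigma_to_gamma(self.sigma),
            "feature_names": list(self.feature_names),
            "seed": self.seed,
            "resubstitution_accuracy": self.resubstitution_accuracy,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.ravel().tolist(),
            "intercept": self.intercept,
        }
        Path(path).write_text(json.dumps(payload) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "DeletionClassifier":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "stsdel-svm-v1":
            raise ValidationError(f"unrecognized classifier artifact {path}")
        return cls(
            C=payload["C"],
            sigma=payload["sigma"],
            support_vectors=np.asarray(payload["support_vectors"], dtype=float),
            dual_coef=np.asarray(payload["dual_coef"], dtype=float),
            intercept=float(payload["intercept"]),
            feature_names=tuple(payload["feature_names"]),
            seed=payload.get("seed"),
            resubstitution_accuracy=payload.get("resubstitution_accuracy"),
        )


def train_classifier(
    train: TrainingSet, C: float, sigma: float, seed: int | None = None
) -> DeletionClassifier:
    """Fit the soft-margin RBF SVM on all training events."""
    X, y = train.X(), train.y()
    svc = SVC(C=C, kernel="rbf", gamma=sigma_to_gamma(sigma))
    svc.fit(X, y)
    resub = float((svc.predict(X) == y).mean())
    # sklearn orders classes [False, True]; its decision function is positive
    # for the second class (deleted), matching our convention.
    return DeletionClassifier(
        C=C,
        sigma=sigma,
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_.copy(),
        intercept=float(svc.intercept_[0]),
        seed=seed,
        resubstitution_accuracy=resub,
        _svc=svc,
    )


@dataclass
class CallMatrix:
    """Per (sample, STS) deletion state plus classifier provenance.

    ``table`` columns: sample_id, sts_id, state in
    {deleted, not_deleted, not_evaluated}.
    """

    table: pd.DataFrame
    C: float | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        required = {"sample_id", "sts_id", "state"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"call table missing columns {sorted(missing)}")
        bad = set(self.table["state"]) - {DELETED, NOT_DELETED, NOT_EVALUATED}
        if bad:
            raise ValidationError(f"unknown call states {sorted(bad)}")

    def deleted_pairs(self) -> pd.DataFrame:
        return self.table[self.table["state"] == DELETED]

    def deleted_sts(self, sample_id: str) -> list[str]:
        t = self.table
        mask = (t["sample_id"] == sample_id) & (t["state"] == DELETED)
        return list(t.loc[mask, "sts_id"])

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["sample_id"]))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CallMatrix":
        table = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "sts_id": str})
        return cls(table)


def classify(
    classifier: DeletionClassifier,
    features: FeatureMatrix,
    not_evaluated_sts: tuple[str, ...] | None = None,
) -> CallMatrix:
    """Call every qualified (sample, STS) pair deleted / not_deleted.

    STSs excluded as degenerate upstream (``features.excluded_sts`` by
    default) are emitted with state ``not_evaluated`` for every sample.
    """
    if tuple(classifier.feature_names) != FEATURE_COLUMNS:
        raise ContractError(
            f"classifier was trained on features {classifier.feature_names}, "
            f"expected {FEATURE_COLUMNS}"
        )
    pred = classifier.predict(features.X())
    table = features.table[["sample_id", "sts_id"]].copy()
    table["state"] = np.where(pred, DELETED, NOT_DELETED)
    skipped = not_evaluated_sts if not_evaluated_sts is not None else features.excluded_sts
    if skipped:
        samples = list(dict.fromkeys(table["sample_id"]))
        extra = pd.DataFrame(
            {
                "sample_id": np.repeat(samples, len(skipped)),
                "sts_id": np.tile(list(skipped), len(samples)),
                "state": NOT_EVALUATED,
            }
        )
        table = pd.concat([table, extra], ignore_index=True)
    return CallMatrix(table, C=classifier.C, sigma=classifier.sigma)
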