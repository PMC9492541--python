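"""Variance-weighted classifier ensemble over CA coordinates.

Terminal nodes (extant species) provide the labelled training set: their
CA coordinates are the features and in-group membership (e.g. metazoan or
fungal) the label.  Several probabilistic classifiers are tuned by
stratified cross-validated grid search and refit on all terminals; every
opisthokont node — terminal or ancestral, the latter projected into the CA
space as supplementary points — is then scored by each model, and the
ensemble reports a weighted average probability.

The weights derive from inter-model disagreement: for every node the mean
probability over models is computed, each model's variance is its mean
squared deviation from those per-node means, and a model's weight is the
inverse of its relative variance (its variance divided by the sum of all
models' variances), renormalized to sum to 1.  Models that track the
consensus closely therefore count more; a variance floor keeps the weights
defined when a model is constant, and the all-agree case degenerates to
equal weights by symmetry.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .io import InputError


def default_model_specs(seed: int = 0) -> list[tuple[str, BaseEstimator, dict]]:
    """Nearest-neighbour, calibrated margin, tree-ensemble and small MLP."""
    return [
        ("knn", KNeighborsClassifier(), {"n_neighbors": [1, 3, 5]}),
        ("svc", SVC(probability=True, random_state=seed), {"C": [0.1, 1.0, 10.0]}),
        (
            "rf",
            RandomForestClassifier(n_estimators=60, random_state=seed),
            {"max_depth": [2, None]},
        ),
        (
            "mlp",
            MLPClassifier(hidden_layer_sizes=(8,), max_iter=400, tol=1e-3,
                          random_state=seed),
            {"alpha": [1e-4, 1e-2]},
        ),
    ]


def weigh_models(probabilities: pd.DataFrame, variance_floor: float = 1e-12) -> pd.Series:
    """Inverse-relative-variance weights from a models x nodes probability table."""
    if probabilities.shape[0] < 1 or probabilities.shape[1] < 1:
        raise InputError("need at least one model and one node")
    if probabilities.shape[0] == 1:
        return pd.Series([1.0], index=probabilities.index)
    node_means = probabilities.mean(axis=0)
    variances = ((probabilities - node_means) ** 2).mean(axis=1)
    variances = variances.clip(lower=variance_floor)
    relative = variances / variances.sum()
    raw = 1.0 / relative
    return raw / raw.sum()


class VarianceWeightedEnsemble(BaseEstimator, ClassifierMixin):
    """Ensemble of CV-tuned probabilistic classifiers with consensus weights.

    Parameters
    ----------
    model_specs :
        List of ``(name, estimator, param_grid)``; estimators must support
        ``fit`` and ``predict_proba``.  ``None`` uses the default roster.
    cv_folds :
        Requested stratified CV folds for the grid search (default 5);
        capped at the minority-class count when the training set is small.
    variance_floor :
        Lower bound on per-model variance in the weighting step.
    random_state :
        Seed for fold shuffling and any stochastic base model.
    """

    def __init__(
        self,
        model_specs: list[tuple[str, BaseEstimator, dict]] | None = None,
        cv_folds: int = 5,
        variance_floor: float = 1e-12,
        random_state: int = 0,
    ):
        self.model_specs = model_specs
        self.cv_folds = cv_folds
        self.variance_floor = variance_floor
        self.random_state = random_state

    def fit(self, X, y) -> "VarianceWeightedEnsemble":
        X = pd.DataFrame(X)
        y = np.asarray(y).astype(int)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise InputError("training labels contain a single class")
        specs = self.model_specs or default_model_specs(self.random_state)
        if len(specs) < 2:
            raise InputError("at least two model specs are required")
        folds = int(min(self.cv_folds, counts.min()))
        self.cv_folds_used_ = folds
        self.models_ = {}
        self.cv_scores_ = {}
        for name, estimator, grid in specs:
            if folds >= 2:
                search = GridSearchCV(
                    clone(estimator),
                    grid,
                    cv=StratifiedKFold(folds, shuffle=True, random_state=self.random_state),
                    scoring="accuracy",
                )
                search.fit(X, y)
                self.models_[name] = search.best_estimator_
                self.cv_scores_[name] = float(search.best_score_)
            else:  # too few members per class to cross-validate
                model = clone(estimator).fit(X, y)
                self.models_[name] = model
                self.cv_scores_[name] = float("nan")
        self.classes_ = classes
        self.feature_names_ = list(X.columns)
        self.training_index_ = list(X.index)
        self.weights_ = None  # computed at scoring time over the scored node set
        return self

    def model_probabilities(self, X) -> pd.DataFrame:
        """Positive-class probability per model (rows) and node (columns)."""
        check_is_fitted(self, "models_")
        X = pd.DataFrame(X)[self.feature_names_]
        rows = {}
        for name, model in self.models_.items():
            pos = list(model.classes_).index(1)
            rows[name] = model.predict_proba(X)[:, pos]
        return pd.DataFrame(rows, index=X.index).T

    def predict_proba(self, X) -> np.ndarray:
        scores = self.score_nodes(X)
        return np.column_stack([1.0 - scores, scores])

    def predict(self, X) -> np.ndarray:
        return (self.score_nodes(X).to_numpy() >= 0.5).astype(int)

    def score_nodes(self, X) -> pd.Series:
        """Weighted-average in-group probability for every row of ``X``.

        The inverse-relative-variance weights are computed over exactly the
        node set being scored and stored on ``weights_``.
        """
        probs = self.model_probabilities(X)
        self.weights_ = weigh_models(probs, self.variance_floor)
        combined = probs.mul(self.weights_, axis=0).sum(axis=0)
        return combined.clip(0.0, 1.0)


def train_ensemble(
    features: pd.DataFrame,
    labels,
    model_specs=None,
    cv_folds: int = 5,
    seed: int = 0,
) -> VarianceWeightedEnsemble:
    """Fit a :class:`VarianceWeightedEnsemble` on terminal-node features."""
    ens = VarianceWeightedEnsemble(
        model_specs=model_specs, cv_folds=cv_folds, random_state=seed
    )
    return ens.fit(features, labels)


def score_nodes(
    ensemble: VarianceWeightedEnsemble,
    ca_model,
    table: pd.DataFrame,
    nodes: list[str],
) -> pd.Series:
    """Score arbitrary tree nodes through the CA space.

    ``table`` must be the same column-then-row-normalized matrix the CA was
    fitted on (computed over every node, terminals and ancestors alike), so
    supplementary projections live in the training feature space; rows are
    projected via the transition formula (training rows reproduce their own
    coordinates) and restricted to the ensemble's feature dimensions.
    """
    check_is_fitted(ensemble, "models_")
    coords = ca_model.transform(table.loc[nodes])
    feats = coords[ensemble.feature_names_]
    return ensemble.score_nodes(feats)
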