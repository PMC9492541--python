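"""Correspondence analysis of compositional category tables.

Relative functional-category compositions are compositional data: rows are
sum-constrained, so parts are neither orthogonal nor collinear-free and raw
PCA is inappropriate.  Correspondence analysis (CA) works on the chi-square
geometry instead: with correspondence matrix P = X / grand total, row
masses r and column masses c, the standardized residuals

    S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}

are decomposed as S = U Sigma V^T.  Principal row coordinates are
D_r^{-1/2} U Sigma, standard column coordinates D_c^{-1/2} V, and the total
inertia sum(sigma_k^2) equals the table's Pearson chi-square divided by the
grand total.  Supplementary rows (e.g. ancestral nodes kept out of the
fit) enter through the transition formula: row profile times standard
column coordinates.

``CorrespondenceAnalysis`` follows the scikit-learn estimator protocol
(``fit`` / ``transform``, fitted attributes with trailing underscores) so
it can sit in sklearn pipelines feeding the classifier ensemble.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .content import CompositionMatrix
from .io import InputError, UNKNOWN_CATEGORY
from .tree import SpeciesTree


def normalize_for_ca(matrix: CompositionMatrix, drop_unknown: bool = True) -> pd.DataFrame:
    """Column-normalize then row-normalize a relative composition table.

    The S (unknown function) column is dropped first when ``drop_unknown``
    is set; all-zero columns are dropped with a warning.  Each surviving
    column is divided by its column sum, then each row by its row sum, so
    the output is row-stochastic.
    """
    if matrix.mode != "relative":
        raise InputError("normalize_for_ca expects a relative composition")
    frame = matrix.frame
    if drop_unknown and UNKNOWN_CATEGORY in frame.columns:
        frame = frame.drop(columns=[UNKNOWN_CATEGORY])
    col_sums = frame.sum(axis=0)
    dead = list(col_sums.index[col_sums == 0])
    if dead:
        warnings.warn(f"dropping all-zero categories: {dead}", stacklevel=2)
        frame = frame.drop(columns=dead)
        col_sums = col_sums.drop(dead)
    frame = frame.div(col_sums, axis=1)
    row_sums = frame.sum(axis=1)
    frame = frame.div(row_sums.replace(0.0, 1.0), axis=0)
    return frame


class CorrespondenceAnalysis(BaseEstimator, TransformerMixin):
    """Classical (simple) correspondence analysis of a non-negative table.

    Parameters
    ----------
    n_components :
        Number of dimensions to keep; ``None`` keeps all
        ``min(n_rows, n_cols) - 1`` of them.

    Attributes
    ----------
    row_labels_, col_labels_ : index/columns of the fitted table
    row_masses_, col_masses_ : marginal masses (each sums to 1)
    singular_values_ : singular values of the standardized residuals
    inertia_shares_ : sigma_k^2 / total inertia (sums to 1 when inertia > 0)
    total_inertia_ : sum of squared singular values (= chi-square / n)
    row_coords_ : principal row coordinates (rows x dims)
    col_coords_ : principal column coordinates
    col_standard_coords_ : standard column coordinates (for supplementary rows)
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X: pd.DataFrame, y=None) -> "CorrespondenceAnalysis":
        frame = pd.DataFrame(X).astype(float)
        if (frame.to_numpy() < 0).any():
            raise InputError("CA requires a non-negative table")
        if frame.shape[0] < 2 or frame.shape[1] < 2:
            raise InputError("CA requires at least a 2x2 table")
        total = frame.to_numpy().sum()
        if total <= 0 or (frame.sum(axis=1) == 0).any() or (frame.sum(axis=0) == 0).any():
            raise InputError("CA requires positive row and column sums")

        P = frame.to_numpy() / total
        r = P.sum(axis=1)
        c = P.sum(axis=0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        U, sigma, Vt = np.linalg.svd(S, full_matrices=False)

        max_dims = min(P.shape) - 1
        keep = sigma[:max_dims] > 1e-12
        sigma = sigma[:max_dims][keep]
        U = U[:, :max_dims][:, keep]
        V = Vt[:max_dims][keep].T
        if self.n_components is not None:
            sigma = sigma[: self.n_components]
            U = U[:, : self.n_components]
            V = V[:, : self.n_components]

        self.row_labels_ = list(frame.index)
        self.col_labels_ = list(frame.columns)
        self.row_masses_ = pd.Series(r, index=self.row_labels_)
        self.col_masses_ = pd.Series(c, index=self.col_labels_)
        self.singular_values_ = sigma
        self.total_inertia_ = float(np.sum(sigma**2))
        self.inertia_shares_ = (
            sigma**2 / self.total_inertia_ if self.total_inertia_ > 0 else sigma * 0.0
        )
        dims = [f"dim{i + 1}" for i in range(len(sigma))]
        self.row_coords_ = pd.DataFrame(
            (U * sigma) / np.sqrt(r)[:, None], index=self.row_labels_, columns=dims
        )
        self.col_standard_coords_ = pd.DataFrame(
            V / np.sqrt(c)[:, None], index=self.col_labels_, columns=dims
        )
        self.col_coords_ = self.col_standard_coords_ * sigma
        return self

    @property
    def n_dimensions_(self) -> int:
        return len(self.singular_values_)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Project (supplementary) rows via the transition formula."""
        if not hasattr(self, "col_standard_coords_"):
            raise InputError("CorrespondenceAnalysis is not fitted")
        frame = pd.DataFrame(X).astype(float)
        missing = [c for c in self.col_labels_ if c not in frame.columns]
        if missing:
            raise InputError(f"supplementary rows lack columns {missing}")
        frame = frame[self.col_labels_]
        sums = frame.sum(axis=1)
        if (sums <= 0).any():
            bad = list(sums.index[sums <= 0])
            raise InputError(f"supplementary rows with zero mass: {bad}")
        profiles = frame.div(sums, axis=0)
        return profiles @ self.col_standard_coords_

    def features(self, coords: pd.DataFrame, min_inertia: float = 0.9) -> pd.DataFrame:
        """Restrict coordinates to the leading dims covering ``min_inertia``."""
        cum = np.cumsum(self.inertia_shares_)
        d = int(np.searchsorted(cum, min_inertia - 1e-12) + 1) if len(cum) else 0
        d = max(1, min(d, coords.shape[1]))
        return coords.iloc[:, :d]


def correspondence_analysis(matrix: pd.DataFrame) -> CorrespondenceAnalysis:
    """Functional wrapper: fit a :class:`CorrespondenceAnalysis` on a table."""
    return CorrespondenceAnalysis().fit(matrix)


def group_categories(
    model: CorrespondenceAnalysis, positive_rows: set[str]
) -> dict[str, set[str]]:
    """Split category letters by their dimension-1 side.

    Orientation comes from the mean dimension-1 principal coordinate of
    ``positive_rows`` (e.g. the in-group terminals); letters whose
    dimension-1 column coordinate has that sign are "related", the rest
    "other".  The split is invariant to the global sign indeterminacy of
    the SVD.
    """
    missing = positive_rows - set(model.row_labels_)
    if missing:
        raise InputError(f"positive rows not in the model: {sorted(missing)}")
    if model.n_dimensions_ == 0:
        raise InputError("model has no dimensions (zero inertia)")
    mean_coord = model.row_coords_.loc[sorted(positive_rows), "dim1"].mean()
    if mean_coord == 0:
        raise InputError("positive rows centred exactly at 0 on dim 1; orient manually")
    sign = np.sign(mean_coord)
    related, other = set(), set()
    for letter, coord in model.col_coords_["dim1"].items():
        if coord * sign > 0:
            related.add(letter)
        else:
            if coord == 0:
                warnings.warn(f"category {letter!r} sits at 0 on dim 1", stacklevel=2)
            other.add(letter)
    return {"related": related, "other": other}


def compositional_shift(
    relative: CompositionMatrix,
    tree: SpeciesTree,
    node: str,
    related_letters: set[str],
) -> float:
    """Shift, in percentage points, of the related-set mass at ``node``.

    100 x (sum of the node's relative weights over ``related_letters``
    minus the same sum at its parent); positive values mean the composition
    moved toward the related set on the branch into ``node``.
    """
    if node == tree.root:
        raise InputError("the root has no parent to compare against")
    if node in relative.zero_nodes or tree.parent[node] in relative.zero_nodes:
        raise InputError(f"zero-content node involved in shift at {node!r}")
    cols = [c for c in relative.frame.columns if c in related_letters]
    here = relative.frame.loc[node, cols].sum()
    parent = relative.frame.loc[tree.parent[node], cols].sum()
    return float(100.0 * (here - parent))
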