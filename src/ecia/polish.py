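"""Two-way median polish of the bait x prey absorbance matrix.

Each row of the screen matrix is one bait protein preparation and each column
one prey preparation.  Preparations differ in background binding (expression
level, stability, plate coating, intrinsic stickiness), which inflates or
deflates every well they touch.  Tukey's median polish decomposes the matrix
additively,

    value(i, j) = overall + row_effect[i] + col_effect[j] + residual(i, j),

by iteratively sweeping row medians and column medians out of the residuals.
Because medians are robust, the handful of truly interacting wells in a row
or column do not drag its effect estimate, so genuine interactions survive in
the residuals as right-tail outliers while preparation biases are removed.

The decomposition is exactly additive after every sweep — reconstruction
always returns the input — and the residual matrix is what downstream MAD
scoring consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


@dataclass
class PolishDecomposition:
    """Result of a two-way median polish.

    Attributes
    ----------
    overall : float
        Assay-wide level (absorbance units).
    row_effects, col_effects : pandas.Series
        Additive per-bait-preparation and per-prey-preparation effects,
        keyed by identifier.
    residuals : pandas.DataFrame
        Same shape and keys as the input; missing cells stay missing.
    n_iterations : int
        Full row+column sweeps performed.
    converged : bool
        Whether the largest absolute median removed in the final sweep fell
        below the tolerance before ``max_iter`` was reached.
    max_abs_change_last_iter : float
        That largest absolute median, for diagnostics.
    """

    overall: float
    row_effects: pd.Series
    col_effects: pd.Series
    residuals: pd.DataFrame
    n_iterations: int
    converged: bool
    max_abs_change_last_iter: float


class MedianPolish(TransformerMixin, BaseEstimator):
    """Two-way additive median-polish transformer.

    ``fit`` runs the iterative polish on a bait x prey matrix; ``transform``
    subtracts the fitted overall, row and column effects, returning
    residuals.  On the fitting matrix itself ``transform`` reproduces
    ``residuals_`` exactly.

    Parameters
    ----------
    max_iter : int, default 20
        Maximum number of full (row + column) sweeps.  The polish converges
        in a handful of sweeps on screen-scale matrices.
    tol : float, default 1e-8
        Convergence tolerance on the largest absolute row/column median
        removed during a sweep (absorbance units).

    Attributes
    ----------
    overall_ : float
    row_effects_ : pandas.Series keyed by bait id
    col_effects_ : pandas.Series keyed by prey id
    residuals_ : pandas.DataFrame
    n_iter_ : int
    converged_ : bool
    max_abs_change_ : float

    Notes
    -----
    Sweep order is rows first, then columns; the median of an even number of
    values is the mean of the two central order statistics.  Missing cells
    are excluded from every median and never imputed.  The polish fixed
    point is not unique in general, so the sweep order is fixed for
    determinism.
    """

    def __init__(self, max_iter: int = 20, tol: float = 1e-8):
        self.max_iter = max_iter
        self.tol = tol

    def _validate_matrix(self, X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        X = X.astype(float)
        if X.shape[0] < 2 or X.shape[1] < 2:
            raise ValueError(
                f"median polish requires a matrix of at least 2x2, got {X.shape}"
            )
        finite = np.isfinite(X.to_numpy())
        empty_rows = X.index[~finite.any(axis=1)]
        if len(empty_rows):
            raise ValueError(f"row(s) entirely missing: {list(empty_rows)}")
        empty_cols = X.columns[~finite.any(axis=0)]
        if len(empty_cols):
            raise ValueError(f"column(s) entirely missing: {list(empty_cols)}")
        return X

    def fit(self, X, y=None):
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.tol > 0:
            raise ValueError("tol must be > 0")
        X = self._validate_matrix(X)
        res = X.to_numpy(copy=True)
        n_rows, n_cols = res.shape
        overall = 0.0
        row_eff = np.zeros(n_rows)
        col_eff = np.zeros(n_cols)

        converged = False
        max_change = np.inf
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            # row sweep
            row_med = np.nanmedian(res, axis=1)
            res -= row_med[:, None]
            row_eff += row_med
            delta = np.median(col_eff)
            col_eff -= delta
            overall += delta
            # column sweep
            col_med = np.nanmedian(res, axis=0)
            res -= col_med[None, :]
            col_eff += col_med
            delta = np.median(row_eff)
            row_eff -= delta
            overall += delta

            max_change = max(np.abs(row_med).max(), np.abs(col_med).max())
            if max_change <= self.tol:
                converged = True
                break

        self.overall_ = float(overall)
        self.row_effects_ = pd.Series(row_eff, index=X.index, name="row_effect")
        self.col_effects_ = pd.Series(col_eff, index=X.columns, name="col_effect")
        self.residuals_ = pd.DataFrame(res, index=X.index, columns=X.columns)
        self.n_iter_ = int(n_iter)
        self.converged_ = bool(converged)
        self.max_abs_change_ = float(max_change)
        return self

    def transform(self, X) -> pd.DataFrame:
        """Subtract the fitted effects from ``X``, returning residuals."""
        check_is_fitted(self, "overall_")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(
                np.asarray(X, dtype=float),
                index=self.row_effects_.index,
                columns=self.col_effects_.index,
            )
        fitted = np.add.outer(
            self.row_effects_.reindex(X.index).to_numpy(),
            self.col_effects_.reindex(X.columns).to_numpy(),
        )
        return X - fitted - self.overall_

    def decomposition_(self) -> PolishDecomposition:
        """Fitted results bundled as a :class:`PolishDecomposition`."""
        check_is_fitted(self, "overall_")
        return PolishDecomposition(
            overall=self.overall_,
            row_effects=self.row_effects_,
            col_effects=self.col_effects_,
            residuals=self.residuals_,
            n_iterations=self.n_iter_,
            converged=self.converged_,
            max_abs_change_last_iter=self.max_abs_change_,
        )


def median_polish(
    matrix: pd.DataFrame, max_iter: int = 20, tol: float = 1e-8
) -> PolishDecomposition:
    """Run a two-way median polish; thin wrapper over :class:`MedianPolish`."""
    return MedianPolish(max_iter=max_iter, tol=tol).fit(matrix).decomposition_()


def reconstruct(decomp: PolishDecomposition) -> pd.DataFrame:
    """Invert the decomposition: overall + row + column + residual per cell.

    Missing residual cells stay missing.  Used mainly to verify the exact
    additivity of the decomposition.
    """
    fitted = np.add.outer(
        decomp.row_effects.to_numpy(), decomp.col_effects.to_numpy()
    )
    return decomp.residuals + fitted + decomp.overall
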