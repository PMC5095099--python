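"""Expression preprocessing: unit-interval scaling and block averaging.

Raw intensities are first rescaled to [0, 1] so that the sigmoid regressors
operate on comparable inputs, then consecutive samples are averaged in blocks
to damp sample-to-sample technical noise.  Both steps exist as plain functions
over :class:`~bpgrn.matrix.ExpressionMatrix` and as scikit-learn transformers
over samples x genes arrays.

Scaling rule (per scope, gene row or whole matrix):

    x' = (x - x_min) / (x_max - x_min)      if x_min != x_max
    x' = x_min                              if x_min == x_max

The degenerate branch is applied exactly as stated; for unscaled raw data it
can leave a constant gene outside [0, 1], in which case a warning is logged.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import InvalidInputError
from .matrix import ExpressionMatrix

__all__ = [
    "normalize_expression",
    "block_average",
    "UnitIntervalScaler",
    "BlockAverager",
]

logger = logging.getLogger("bpgrn")

_SCOPES = ("per_gene", "global")


def _minmax_scale(values: np.ndarray, scope: str) -> np.ndarray:
    """Min-max scale a genes x samples array under the given scope."""
    if scope not in _SCOPES:
        raise InvalidInputError(f"scope must be one of {_SCOPES}, got {scope!r}")
    out = np.empty_like(values, dtype=np.float64)
    if scope == "global":
        lo, hi = values.min(), values.max()
        if lo == hi:
            out[...] = lo
        else:
            out[...] = (values - lo) / (hi - lo)
    else:
        lo = values.min(axis=1, keepdims=True)
        hi = values.max(axis=1, keepdims=True)
        span = hi - lo
        flat = (span == 0.0).ravel()
        safe = np.where(span == 0.0, 1.0, span)
        out[...] = (values - lo) / safe
        out[flat, :] = lo[flat]
    if out.min() < 0.0 or out.max() > 1.0:
        logger.warning(
            "degenerate min==max rule left values outside [0, 1] "
            "(min=%g, max=%g); raw data was not on a unit scale",
            out.min(), out.max(),
        )
    return out


def normalize_expression(matrix: ExpressionMatrix, scope: str = "per_gene"
                         ) -> ExpressionMatrix:
    """Rescale expression values to [0, 1].

    Parameters
    ----------
    matrix : ExpressionMatrix
        Finite-valued expression matrix.
    scope : {"per_gene", "global"}
        Whether min/max are taken over each gene row (default) or over the
        whole matrix.

    Returns
    -------
    ExpressionMatrix
        Same genes/samples, values rescaled.  Constant rows (or a constant
        matrix) map to their constant value unchanged.
    """
    return matrix.with_values(_minmax_scale(matrix.values, scope))


def block_average(matrix: ExpressionMatrix, block_size: int = 2
                  ) -> ExpressionMatrix:
    """Average consecutive sample blocks of size *block_size*.

    Samples are grouped in stable input order; each complete block is replaced
    by its element-wise mean, and a trailing incomplete block is dropped, so
    the output has ``floor(n_samples / block_size)`` samples.
    """
    if int(block_size) != block_size or block_size < 1:
        raise InvalidInputError(f"block_size must be a positive integer, "
                                f"got {block_size!r}")
    block_size = int(block_size)
    if matrix.n_samples < block_size:
        raise InvalidInputError(
            f"need at least block_size={block_size} samples, "
            f"have {matrix.n_samples}"
        )
    n_blocks = matrix.n_samples // block_size
    kept = matrix.values[:, : n_blocks * block_size]
    averaged = kept.reshape(matrix.n_genes, n_blocks, block_size).mean(axis=2)
    ids = [
        "+".join(matrix.sample_ids[b * block_size:(b + 1) * block_size])
        for b in range(n_blocks)
    ]
    return matrix.with_values(averaged, sample_ids=ids)


class UnitIntervalScaler(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer applying the package's [0, 1] scaling.

    Operates on samples x genes arrays (features are genes, so
    ``scope="per_gene"`` scales each column).  Stateless: min/max are taken
    from the data being transformed, matching the batch semantics of the
    pipeline (the scaling is a fixed preprocessing of one dataset, not a
    fitted mapping applied to unseen data).
    """

    def __init__(self, scope: str = "per_gene"):
        self.scope = scope

    def fit(self, X, y=None):  # noqa: D102 - sklearn protocol
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.size == 0:
            raise InvalidInputError("X must be a non-empty 2-D array")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):  # noqa: D102 - sklearn protocol
        X = np.asarray(X, dtype=np.float64)
        return _minmax_scale(X.T, self.scope).T


class BlockAverager(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer averaging consecutive sample rows in blocks.

    Reduces the number of rows (samples); trailing rows that do not fill a
    block are dropped.  ``block_size=1`` is the identity.
    """

    def __init__(self, block_size: int = 2):
        self.block_size = block_size

    def fit(self, X, y=None):  # noqa: D102 - sklearn protocol
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise InvalidInputError("X must be 2-D")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):  # noqa: D102 - sklearn protocol
        X = np.asarray(X, dtype=np.float64)
        if int(self.block_size) != self.block_size or self.block_size < 1:
            raise InvalidInputError("block_size must be a positive integer")
        b = int(self.block_size)
        if X.shape[0] < b:
            raise InvalidInputError(
                f"need at least block_size={b} samples, have {X.shape[0]}"
            )
        n_blocks = X.shape[0] // b
        return X[: n_blocks * b].reshape(n_blocks, b, X.shape[1]).mean(axis=1)
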