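"""Single-layer sigmoid perceptrons trained by on-line back-propagation.

Each gene is modelled as the output neuron of a two-layer (input/output)
perceptron whose inputs are the other ``n - 1`` genes:

    o_j = f(sum_i w_ij * x_i - b),      f(z) = 1 / (1 + exp(-z))

Training minimises the whole error ``E = 1/2 * sum_P E^P`` with
``E^P = 1/2 * sum_j (t_j - o_j)^2`` by the generalized delta rule with a
momentum term,

    delta   = f'(o) * (t - o),          f'(o) = o * (1 - o)
    dw_i    = eta * delta * x_i + alpha * dw_i(previous pattern)

where ``eta`` is the learning rate and ``alpha`` the momentum.  Patterns
(samples) are presented in their fixed column order, weights are updated after
every pattern, and training stops when ``E`` falls below the error tolerance
(default 1e-2) or the cycle budget is exhausted.  The neuron threshold ``b``
is fixed at -1 by default and can optionally be trained like a weight with
constant input -1.

One regressor is trained per gene, all starting from the same small random
initial weight vector (drawn once from the seed, with the self-weight removed
per target) so that trained weights are comparable across targets; stacking
the trained weight vectors column-wise gives the n x n weight matrix ``W``
with zero diagonal, which doubles as the signed adjacency matrix of the
regulatory network (entry ``W[i, j]`` = influence of gene i on gene j).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

from .errors import InvalidInputError
from .matrix import ExpressionMatrix

__all__ = [
    "sigmoid",
    "forward",
    "pattern_error",
    "backprop_step",
    "TrainingConfig",
    "GeneRegressor",
    "WeightMatrix",
    "train_gene_regressor",
    "train_all_regressors",
    "BPNetworkInferrer",
]


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def sigmoid(x):
    """Logistic transfer function ``1 / (1 + exp(-x))`` (element-wise)."""
    out = expit(x)
    return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out


def forward(weights, bias: float, inputs):
    """Output of the neuron: ``sigmoid(sum_i w_i x_i - bias)``."""
    weights = np.asarray(weights, dtype=np.float64)
    inputs = np.asarray(inputs, dtype=np.float64)
    if weights.shape != inputs.shape:
        raise InvalidInputError(
            f"weights and inputs length mismatch: {weights.shape} vs {inputs.shape}"
        )
    return float(expit(weights @ inputs - bias))


def pattern_error(target, output) -> float:
    """Per-pattern error ``1/2 * sum_j (t_j - o_j)**2``."""
    target = np.atleast_1d(np.asarray(target, dtype=np.float64))
    output = np.atleast_1d(np.asarray(output, dtype=np.float64))
    if target.shape != output.shape:
        raise InvalidInputError(
            f"target and output length mismatch: {target.shape} vs {output.shape}"
        )
    return float(0.5 * np.sum((target - output) ** 2))


# ---------------------------------------------------------------------------
# configuration and result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingConfig:
    """Hyper-parameters of the on-line BP training loop.

    Attributes
    ----------
    learning_rate : float in (0, 1)
        Step size of the delta rule (default 0.7).
    momentum : float in (0, 1)
        Fraction of the previous pattern's weight change added to the current
        update (default 0.5).
    bias : float
        The neuron threshold ``b`` in ``sigmoid(w.x - b)`` (default -1).
    max_cycles : int >= 1
        Maximum number of passes over the training samples (default 1000).
    error_tolerance : float > 0
        Stop when the whole error ``E`` drops below this (default 1e-2).
    init_scale : float > 0
        Initial weights are uniform on ``[-init_scale, +init_scale]``.
    seed : int
        Seed for the (single, shared) initial weight draw.
    bias_trainable : bool
        If True the threshold is trained like a weight with input -1.
    """

    learning_rate: float = 0.7
    momentum: float = 0.5
    bias: float = -1.0
    max_cycles: int = 1000
    error_tolerance: float = 1e-2
    init_scale: float = 0.1
    seed: int = 0
    bias_trainable: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.learning_rate < 1.0:
            raise InvalidInputError("learning_rate must be in (0, 1)")
        if not 0.0 < self.momentum < 1.0:
            raise InvalidInputError("momentum must be in (0, 1)")
        if self.max_cycles < 1:
            raise InvalidInputError("max_cycles must be >= 1")
        if self.error_tolerance <= 0.0:
            raise InvalidInputError("error_tolerance must be positive")
        if self.init_scale <= 0.0:
            raise InvalidInputError("init_scale must be positive")


@dataclass
class GeneRegressor:
    """A trained (or in-training) single-gene perceptron."""

    target_gene: str
    input_gene_ids: list[str]
    weights: np.ndarray
    bias: float
    final_error: float = float("inf")
    cycles_run: int = 0
    converged: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.target_gene in self.input_gene_ids:
            raise InvalidInputError("target gene may not regress on itself")
        if len(self.input_gene_ids) != self.weights.shape[0]:
            raise InvalidInputError("weights/input gene ids length mismatch")


@dataclass
class WeightMatrix:
    """Stacked trained weights: ``W[i, j]`` = weight of input gene i for target j.

    The diagonal is identically zero (no self-regulation).  Per-target training
    diagnostics are carried alongside when produced by
    :func:`train_all_regressors`.
    """

    gene_ids: list[str]
    W: np.ndarray
    biases: Optional[np.ndarray] = None
    final_errors: Optional[np.ndarray] = None
    converged: Optional[np.ndarray] = None
    cycles_run: Optional[np.ndarray] = None
    config: Optional[TrainingConfig] = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        n = len(self.gene_ids)
        if self.W.shape != (n, n):
            raise InvalidInputError(f"W must be {n}x{n}, got {self.W.shape}")
        if np.any(np.diag(self.W) != 0.0):
            raise InvalidInputError("W must have a zero diagonal")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, index=self.gene_ids, columns=self.gene_ids)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def backprop_step(regressor: GeneRegressor, input: Sequence[float],
                  target: float, config: TrainingConfig,
                  prev_change: Sequence[float]
                  ) -> tuple[GeneRegressor, np.ndarray]:
    """One on-line update for a single pattern.

    Computes the output at the current weights, the output-neuron error term
    ``delta = o (1 - o) (t - o)``, and the momentum-smoothed weight change
    ``dw = eta * delta * x + alpha * prev_change``.  When
    ``config.bias_trainable`` is set, *prev_change* carries one extra trailing
    element for the threshold (whose input is the constant -1).

    Returns the updated regressor and the change vector to feed into the next
    pattern's momentum term.
    """
    x = np.asarray(input, dtype=np.float64)
    prev = np.asarray(prev_change, dtype=np.float64)
    w = regressor.weights
    if x.shape != w.shape:
        raise InvalidInputError(
            f"input length {x.shape} does not match weights {w.shape}"
        )
    n_changes = w.shape[0] + (1 if config.bias_trainable else 0)
    if prev.shape != (n_changes,):
        raise InvalidInputError(
            f"prev_change must have length {n_changes}, got {prev.shape}"
        )
    o = expit(w @ x - regressor.bias)
    delta = o * (1.0 - o) * (target - o)
    if config.bias_trainable:
        grad_inputs = np.concatenate([x, [-1.0]])
    else:
        grad_inputs = x
    change = config.learning_rate * delta * grad_inputs + config.momentum * prev
    new_w = w + change[: w.shape[0]]
    new_b = regressor.bias + (change[-1] if config.bias_trainable else 0.0)
    updated = replace(regressor, weights=new_w, bias=new_b,
                      input_gene_ids=list(regressor.input_gene_ids))
    return updated, change


def _train_online(X_in: np.ndarray, t: np.ndarray, w0: np.ndarray,
                  config: TrainingConfig
                  ) -> tuple[np.ndarray, float, float, int, bool]:
    """Inner training loop.

    Parameters are the (P, n-1) input pattern matrix, the length-P target
    vector, the initial weights, and the config.  Returns
    ``(weights, bias, whole_error, cycles_run, converged)``.
    """
    lr, mom, tol = config.learning_rate, config.momentum, config.error_tolerance
    w = w0.astype(np.float64).copy()
    b = float(config.bias)
    P = X_in.shape[0]
    dw = np.zeros_like(w)
    db = 0.0
    E = float("inf")
    cycles = 0
    for cycles in range(1, config.max_cycles + 1):
        E = 0.0
        for p in range(P):
            x = X_in[p]
            o = expit(x @ w - b)
            delta = o * (1.0 - o) * (t[p] - o)
            dw = lr * delta * x + mom * dw
            w += dw
            if config.bias_trainable:
                db = lr * delta * (-1.0) + mom * db
                b += db
            E += 0.5 * (t[p] - o) ** 2
        E *= 0.5
        if E < tol:
            return w, b, E, cycles, True
    return w, b, E, cycles, False


def _initial_weights(n_genes: int, config: TrainingConfig) -> np.ndarray:
    """The single shared initial weight draw (length n, self-entry deleted
    per target downstream)."""
    rng = np.random.default_rng(config.seed)
    return rng.uniform(-config.init_scale, config.init_scale, size=n_genes)


def train_gene_regressor(matrix: ExpressionMatrix, target_gene: str,
                         config: TrainingConfig = TrainingConfig()
                         ) -> GeneRegressor:
    """Train the perceptron predicting *target_gene* from the other genes.

    The matrix is expected to hold values on the unit interval (see
    :func:`bpgrn.preprocess.normalize_expression`).  Samples are presented in
    column order each cycle; training stops at ``E < error_tolerance`` or
    after ``max_cycles`` passes, recorded in ``converged``.
    """
    if matrix.n_genes < 2:
        raise InvalidInputError("need at least 2 genes to train a regressor")
    j = matrix.gene_index(target_gene)
    idx = [i for i in range(matrix.n_genes) if i != j]
    X_in = np.ascontiguousarray(matrix.values[idx].T)  # (P, n-1)
    t = matrix.values[j]
    w0 = np.delete(_initial_weights(matrix.n_genes, config), j)
    w, b, E, cycles, conv = _train_online(X_in, t, w0, config)
    return GeneRegressor(
        target_gene=target_gene,
        input_gene_ids=[matrix.gene_ids[i] for i in idx],
        weights=w,
        bias=b,
        final_error=E,
        cycles_run=cycles,
        converged=conv,
    )


def train_all_regressors(matrix: ExpressionMatrix,
                         config: TrainingConfig = TrainingConfig()
                         ) -> WeightMatrix:
    """Train one regressor per gene and assemble the n x n weight matrix.

    Every regressor starts from the same seed-derived initial weight vector
    (with its own target entry removed), so the columns of ``W`` are
    comparable.  ``W[i, j]`` is the trained weight of input gene i in the
    regressor for target gene j; the diagonal is zero.
    """
    if matrix.n_genes < 2:
        raise InvalidInputError("need at least 2 genes")
    n = matrix.n_genes
    w0_full = _initial_weights(n, config)
    W = np.zeros((n, n), dtype=np.float64)
    biases = np.empty(n)
    errs = np.empty(n)
    conv = np.empty(n, dtype=bool)
    cyc = np.empty(n, dtype=np.int64)
    values_T = np.ascontiguousarray(matrix.values.T)  # (P, n)
    for j in range(n):
        idx = np.array([i for i in range(n) if i != j])
        X_in = np.ascontiguousarray(values_T[:, idx])
        t = matrix.values[j]
        w0 = w0_full[idx]
        w, b, E, c, ok = _train_online(X_in, t, w0, config)
        W[idx, j] = w
        biases[j], errs[j], conv[j], cyc[j] = b, E, ok, c
    return WeightMatrix(
        gene_ids=list(matrix.gene_ids), W=W, biases=biases,
        final_errors=errs, converged=conv, cycles_run=cyc, config=config,
    )


# ---------------------------------------------------------------------------
# scikit-learn estimator
# ---------------------------------------------------------------------------

class BPNetworkInferrer(BaseEstimator):
    """Infer a gene-gene weight matrix with per-gene BP perceptrons.

    Follows the scikit-learn estimator protocol: ``X`` is samples x genes
    (an array or a DataFrame whose columns name the genes).  ``fit`` trains
    one sigmoid perceptron per gene (target = that gene, inputs = all other
    genes) and stores the stacked weight matrix.

    Attributes set by :meth:`fit`
    -----------------------------
    weight_matrix_ : WeightMatrix
        Trained weights with per-gene diagnostics.
    W_ : ndarray of shape (n_genes, n_genes)
        Convenience view of ``weight_matrix_.W``.
    errors_, converged_, cycles_ : ndarray
        Final whole error, convergence flag, and cycles used per target gene.
    """

    def __init__(self, learning_rate: float = 0.7, momentum: float = 0.5,
                 bias: float = -1.0, max_cycles: int = 1000,
                 error_tolerance: float = 1e-2, init_scale: float = 0.1,
                 bias_trainable: bool = False, random_state: int = 0):
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.bias = bias
        self.max_cycles = max_cycles
        self.error_tolerance = error_tolerance
        self.init_scale = init_scale
        self.bias_trainable = bias_trainable
        self.random_state = random_state

    def _config(self) -> TrainingConfig:
        return TrainingConfig(
            learning_rate=self.learning_rate, momentum=self.momentum,
            bias=self.bias, max_cycles=self.max_cycles,
            error_tolerance=self.error_tolerance, init_scale=self.init_scale,
            seed=self.random_state, bias_trainable=self.bias_trainable,
        )

    def _as_matrix(self, X) -> ExpressionMatrix:
        if isinstance(X, ExpressionMatrix):
            return X
        if isinstance(X, pd.DataFrame):
            genes = list(map(str, X.columns))
            samples = list(map(str, X.index))
            values = X.to_numpy(dtype=np.float64).T
        else:
            X = np.asarray(X, dtype=np.float64)
            if X.ndim != 2:
                raise InvalidInputError("X must be 2-D (samples x genes)")
            genes = [f"g{i}" for i in range(X.shape[1])]
            samples = [f"s{i}" for i in range(X.shape[0])]
            values = X.T
        return ExpressionMatrix(gene_ids=genes, sample_ids=samples, values=values)

    def fit(self, X, y=None):
        """Train all per-gene regressors on samples x genes data *X*."""
        matrix = self._as_matrix(X)
        wm = train_all_regressors(matrix, self._config())
        self.weight_matrix_ = wm
        self.W_ = wm.W
        self.biases_ = wm.biases
        self.errors_ = wm.final_errors
        self.converged_ = wm.converged
        self.cycles_ = wm.cycles_run
        self.feature_names_in_ = np.asarray(matrix.gene_ids, dtype=object)
        self.n_features_in_ = matrix.n_genes
        return self

    def transform(self, X):
        """Reconstruct expression through the trained network: F(W^T x - b).

        On training data with converged regressors the reconstruction is close
        to the input, which is the fixed-point reading of the trained model.
        """
        if not hasattr(self, "W_"):
            raise InvalidInputError("estimator is not fitted")
        matrix = self._as_matrix(X)
        Z = matrix.values.T @ self.W_ - self.biases_[np.newaxis, :]  # (P, n)
        return expit(Z)
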