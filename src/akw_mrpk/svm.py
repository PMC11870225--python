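"""Polynomial-kernel soft-margin SVM trained by sequential minimal
optimization (SMO).

The classifier solves the standard dual problem

    maximize  sum_i alpha_i - 1/2 sum_ij alpha_i alpha_j q_i q_j K(p_i, p_j)
    subject to  0 <= alpha_i <= C_i,   sum_i alpha_i q_i = 0,

with the polynomial kernel K(a, b) = (<a, b> + r)^d and per-sample box
bounds C_i = RP * w_class(i) so that class weighting enters as a weighted
soft margin.  The solver repeatedly picks the maximal-violating pair of
dual variables and solves the two-variable subproblem analytically, which
is deterministic and converges to the dual optimum on the small problems
this package targets.  Prediction is sign(sum_i q_i alpha_i K(x, p_i) + b)
with the tie sign(0) resolved to +1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .datasets import KeyedInstance


@dataclass(frozen=True)
class KernelParams:
    """Polynomial kernel (<a, b> + r)^d.

    ``r`` < 0 can break positive semidefiniteness of the Gram matrix, so it
    is rejected unless ``allow_negative_r`` is set explicitly.
    """

    r: float = 1.0
    d: int = 2
    allow_negative_r: bool = False

    def __post_init__(self) -> None:
        if int(self.d) != self.d or self.d < 1:
            raise ValueError("polynomial degree d must be a positive integer")
        object.__setattr__(self, "d", int(self.d))
        if self.r < 0 and not self.allow_negative_r:
            raise ValueError(
                "negative kernel coefficient r may yield an indefinite Gram "
                "matrix; pass allow_negative_r=True to override"
            )
        if self.r < 0:
            warnings.warn("r < 0: polynomial kernel may not be PSD", stacklevel=2)


def poly_kernel(x, y, params: KernelParams) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("kernel arguments must have equal length")
    return float((np.dot(x, y) + params.r) ** params.d)


def gram_matrix(X, Y, params: KernelParams) -> np.ndarray:
    """Pairwise polynomial kernel values between the rows of X and Y."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("kernel arguments must have equal feature dimension")
    return (X @ Y.T + params.r) ** params.d


@dataclass(frozen=True)
class SVMModel:
    """Trained dual SVM: stored training vectors, alphas and bias."""

    support_vectors: np.ndarray  # all retained training vectors (n, m)
    alphas: np.ndarray  # dual coefficients, 0 <= alpha_i <= C_i
    targets: np.ndarray  # q_i in {+1, -1}
    bias: float
    kernel: KernelParams
    RP: float
    per_sample_C: np.ndarray
    converged: bool = True

    def decision_function(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.support_vectors.shape[1]:
            raise ValueError(
                f"expected {self.support_vectors.shape[1]} features, got {X.shape[1]}"
            )
        K = gram_matrix(X, self.support_vectors, self.kernel)
        return K @ (self.alphas * self.targets) + self.bias

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return np.where(scores >= 0.0, 1, -1).astype(int)

    def dual_objective(self) -> float:
        """W(alpha) = sum alpha - 1/2 alpha^T Q alpha at the stored solution."""
        K = gram_matrix(self.support_vectors, self.support_vectors, self.kernel)
        qa = self.alphas * self.targets
        return float(self.alphas.sum() - 0.5 * qa @ K @ qa)

    def without_non_support(self, atol: float = 1e-12) -> "SVMModel":
        """Drop vectors with alpha ~ 0; the decision function is unchanged."""
        keep = self.alphas > atol
        return SVMModel(
            support_vectors=self.support_vectors[keep],
            alphas=self.alphas[keep],
            targets=self.targets[keep],
            bias=self.bias,
            kernel=self.kernel,
            RP=self.RP,
            per_sample_C=self.per_sample_C[keep],
            converged=self.converged,
        )


def instances_to_arrays(
    instances: Sequence[KeyedInstance],
) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack([inst.features for inst in instances])
    y = np.array([inst.target for inst in instances], dtype=float)
    return X, y


def train_svm(
    train: Sequence[KeyedInstance],
    RP: float,
    params: KernelParams,
    class_weight: Mapping[int, float] | None = None,
    tol: float = 1e-3,
    max_passes: int = 100,
    seed: int = 0,
) -> SVMModel:
    """Fit the polynomial-kernel SVM on keyed training instances.

    ``class_weight`` maps the original labels {0, 1} (or targets {-1, +1})
    to multipliers of RP, giving per-sample box bounds C_i.  ``max_passes``
    bounds the solver at ``max_passes * n`` pair updates; exhaustion sets
    ``converged=False`` on the model and emits a warning rather than
    failing.  ``seed`` is accepted for interface stability; the
    maximal-violating-pair solver itself is deterministic.
    """
    del seed
    if RP <= 0:
        raise ValueError("regularization parameter RP must be positive")
    X, y = instances_to_arrays(train)
    if set(np.unique(y)) != {-1.0, 1.0}:
        raise ValueError("training set must contain both targets +1 and -1")

    C = np.full(X.shape[0], float(RP))
    if class_weight is not None:
        weights = dict(class_weight)
        for i, target in enumerate(y):
            label = 1 if target > 0 else 0
            w = weights.get(label, weights.get(int(target), 1.0))
            C[i] = RP * w

    K = gram_matrix(X, X, params)
    alphas, bias, converged = _smo_solve(K, y, C, tol, max_passes * X.shape[0])
    if not converged:
        warnings.warn(
            "SMO did not reach the requested KKT tolerance; increase max_passes",
            stacklevel=2,
        )
    return SVMModel(
        support_vectors=X,
        alphas=alphas,
        targets=y.astype(int),
        bias=bias,
        kernel=params,
        RP=float(RP),
        per_sample_C=C,
        converged=converged,
    )


def _smo_solve(
    K: np.ndarray, y: np.ndarray, C: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, float, bool]:
    """Maximal-violating-pair SMO on a precomputed Gram matrix.

    Minimizes f(alpha) = 1/2 alpha^T Q alpha - e^T alpha with
    Q_ij = y_i y_j K_ij under the box and equality constraints.  Stops when
    the maximal KKT violation m(alpha) - M(alpha) <= tol.
    """
    n = y.size
    alphas = np.zeros(n)
    grad = -np.ones(n)  # gradient of f at alpha = 0
    converged = False

    for _ in range(max_iter):
        yg = -y * grad
        up = ((y > 0) & (alphas < C)) | ((y < 0) & (alphas > 0))
        low = ((y < 0) & (alphas < C)) | ((y > 0) & (alphas > 0))
        if not up.any() or not low.any():
            converged = True
            break
        i = int(np.flatnonzero(up)[np.argmax(yg[up])])
        j = int(np.flatnonzero(low)[np.argmin(yg[low])])
        m, M = yg[i], yg[j]
        if m - M <= tol:
            converged = True
            break

        # analytic solve of the two-variable subproblem along
        # alpha_i += y_i * t, alpha_j -= y_j * t
        curv = K[i, i] + K[j, j] - 2.0 * K[i, j]
        if curv <= 0:
            curv = 1e-12
        t = (m - M) / curv
        if y[i] > 0:
            t = min(t, C[i] - alphas[i])
        else:
            t = min(t, alphas[i])
        if y[j] > 0:
            t = min(t, alphas[j])
        else:
            t = min(t, C[j] - alphas[j])
        if t <= 0:
            converged = True  # numerically pinned at a boundary optimum
            break
        alphas[i] += y[i] * t
        alphas[j] -= y[j] * t
        grad += t * y * (K[:, i] - K[:, j])

    yg = -y * grad
    up = ((y > 0) & (alphas < C)) | ((y < 0) & (alphas > 0))
    low = ((y < 0) & (alphas < C)) | ((y > 0) & (alphas > 0))
    free = (alphas > 1e-12) & (alphas < C - 1e-12)
    if free.any():
        bias = float(yg[free].mean())
    elif up.any() and low.any():
        bias = float((yg[up].max() + yg[low].min()) / 2.0)
    else:
        bias = 0.0
    return alphas, bias, converged


def predict(model: SVMModel, x) -> int:
    """Classify one feature vector; a decision value of exactly 0 maps to +1."""
    return int(model.predict(np.atleast_2d(np.asarray(x, dtype=float)))[0])
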