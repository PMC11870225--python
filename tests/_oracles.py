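"""Independent reference computations used to cross-check the package."""

import numpy as np
from scipy.optimize import minimize


def qp_dual_optimum(K: np.ndarray, y: np.ndarray, C: np.ndarray) -> float:
    """Solve the weighted soft-margin SVM dual with a generic QP method.

    maximize  sum(a) - 1/2 a^T (yy^T * K) a   s.t.  0 <= a_i <= C_i, y.a = 0

    Uses SLSQP from an independent code path (no SMO); returns the optimal
    dual objective value.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    Q = np.outer(y, y) * K

    def fun(a):
        return 0.5 * a @ Q @ a - a.sum()

    def jac(a):
        return Q @ a - 1.0

    res = minimize(
        fun,
        np.zeros(n),
        jac=jac,
        bounds=[(0.0, float(c)) for c in C],
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    return -float(res.fun)


def kkt_violation(K: np.ndarray, y: np.ndarray, C: np.ndarray, alphas: np.ndarray) -> float:
    """Maximal KKT violation m(alpha) - M(alpha) of a dual feasible point."""
    y = np.asarray(y, dtype=float)
    grad = (np.outer(y, y) * K) @ alphas - 1.0
    yg = -y * grad
    up = ((y > 0) & (alphas < C - 1e-12)) | ((y < 0) & (alphas > 1e-12))
    low = ((y < 0) & (alphas < C - 1e-12)) | ((y > 0) & (alphas > 1e-12))
    if not up.any() or not low.any():
        return 0.0
    return float(yg[up].max() - yg[low].min())
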