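"""Multiple kernel learning: joint estimation of simplex-constrained kernel
weights and a soft-margin SVM on the composite kernel.

The solver follows the SimpleMKL template. Write J(lambda) for the optimal
value of the SVM dual on the composite kernel K(lambda) = sum_l lambda_l K_l:

    J(lambda) = max_alpha  sum_i alpha_i - 1/2 sum_ij alpha_i alpha_j y_i y_j K(lambda)_ij
                s.t.  0 <= alpha_i <= C,  sum_i alpha_i y_i = 0.

J is convex and differentiable in lambda with, by Danskin's theorem,
dJ/dlambda_l = -1/2 d' K_l d at the optimal signed duals d_i = alpha_i y_i.
Training alternates (a) an exact SVM dual solve at fixed lambda with
(b) a reduced-gradient descent step on the probability simplex with a
halving line search that only accepts steps decreasing J, so the objective
trace is non-increasing by construction. Uniform weights initialize lambda.

The inner dual solve delegates to libsvm via scikit-learn's
``SVC(kernel="precomputed")``; the surrounding weight learning, the
composite decision function and the missing-group prediction path live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .kernels import (
    KernelSet,
    KernelWeights,
    NoPredictionPossibleError,
    compose_kernel,
    rescale_weights,
)

__all__ = ["MKLModel", "train_mkl", "decision_function", "predict"]

_SVC_TOL = 1e-7


@dataclass
class MKLModel:
    """Learned MKL-SVM: kernel weights, signed dual coefficients
    (alpha_i y_i), bias, and the kernel construction metadata needed to
    score new variants against the training set."""

    weights: KernelWeights
    dual_coef: np.ndarray
    bias: float
    support_index: np.ndarray
    C: float
    kernel_set: KernelSet | None = None
    objective_path: list[float] = field(default_factory=list)
    n_iter: int = 0

    @property
    def group_names(self) -> list[str] | None:
        return None if self.kernel_set is None else list(self.kernel_set.names)


def _solve_svm(K: np.ndarray, y: np.ndarray, C: float):
    """Exact soft-margin dual solve on a precomputed kernel.

    Returns (signed dual coefficients d with d_i = alpha_i y_i, bias,
    dual objective value J)."""
    svc = SVC(C=C, kernel="precomputed", tol=_SVC_TOL, shrinking=True)
    svc.fit(K, y)
    n = K.shape[0]
    d = np.zeros(n)
    d[svc.support_] = svc.dual_coef_[0]
    alpha = d * y  # alpha_i >= 0
    objective = float(alpha.sum() - 0.5 * d @ K @ d)
    return d, float(svc.intercept_[0]), objective


def _descent_direction(lam: np.ndarray, grad: np.ndarray) -> np.ndarray:
    """Reduced-gradient descent direction on the simplex.

    The coordinate with the largest weight is the reference; zero-weight
    coordinates whose reduced gradient points outward are frozen."""
    mu = int(np.argmax(lam))
    reduced = grad - grad[mu]
    direction = -reduced
    frozen = (lam <= 0) & (reduced > 0)
    direction[frozen] = 0.0
    direction[mu] = 0.0
    direction[mu] = -direction.sum()
    return direction


def train_mkl(
    kernels: KernelSet | Sequence[np.ndarray],
    labels: Sequence[int] | np.ndarray,
    C: float = 1.0,
    tol: float = 1e-5,
    max_iter: int = 100,
    weight_tol: float = 1e-4,
    seed: int | None = None,
) -> MKLModel:
    """Learn kernel weights and the composite-kernel SVM.

    ``tol`` is the relative-objective stopping threshold and ``weight_tol``
    the max-norm threshold on the weight update; whichever fires first ends
    the outer loop (at most ``max_iter`` iterations). The procedure is
    deterministic; ``seed`` is accepted for interface uniformity only.

    Raises ``ValueError`` for single-class labels or fewer than two
    examples.
    """
    if isinstance(kernels, KernelSet):
        kernel_set: KernelSet | None = kernels
        mats = [np.asarray(K, dtype=float) for K in kernels.matrices]
    else:
        kernel_set = None
        mats = [np.asarray(K, dtype=float) for K in kernels]
    if not mats:
        raise ValueError("need at least one kernel")
    y = np.asarray(labels, dtype=float)
    n = mats[0].shape[0]
    if y.shape != (n,):
        raise ValueError("labels misaligned with kernels")
    if n < 2 or len(np.unique(y)) < 2:
        raise ValueError("training requires >= 2 examples of both classes")
    if not set(np.unique(y)) <= {-1.0, 1.0}:
        raise ValueError("labels must be +1/-1")
    if C <= 0:
        raise ValueError("C must be positive")

    p = len(mats)
    lam = np.full(p, 1.0 / p)
    d, bias, obj = _solve_svm(compose_kernel(mats, lam), y, C)
    path = [obj]
    n_iter = 0

    for n_iter in range(1, max_iter + 1):
        if p == 1:
            break
        grad = np.array([-0.5 * d @ K @ d for K in mats])
        direction = _descent_direction(lam, grad)
        if np.abs(direction).max() < 1e-12:
            break
        # largest feasible step keeping every weight nonnegative
        shrinking = direction < 0
        if shrinking.any():
            step = float(np.min(-lam[shrinking] / direction[shrinking]))
        else:  # pragma: no cover - direction sums to zero so some entry < 0
            step = 1.0
        accepted = False
        for _ in range(15):
            cand = lam + step * direction
            cand = np.clip(cand, 0.0, None)
            cand /= cand.sum()
            d_new, bias_new, obj_new = _solve_svm(compose_kernel(mats, cand), y, C)
            if obj_new < obj - 1e-12 * max(abs(obj), 1.0):
                accepted = True
                break
            step /= 2.0
        if not accepted:
            break
        delta_lam = np.abs(cand - lam).max()
        rel_drop = (obj - obj_new) / max(abs(obj), 1.0)
        lam, d, bias, obj = cand, d_new, bias_new, obj_new
        path.append(obj)
        if rel_drop < tol or delta_lam < weight_tol:
            break

    support = np.flatnonzero(d != 0.0)
    alpha = d * y
    if (alpha < -1e-9).any() or (alpha > C * (1 + 1e-6)).any():  # pragma: no cover
        raise RuntimeError("dual solution violates box constraints")
    return MKLModel(
        weights=KernelWeights(lam),
        dual_coef=d,
        bias=bias,
        support_index=support,
        C=float(C),
        kernel_set=kernel_set,
        objective_path=path,
        n_iter=n_iter,
    )


def decision_function(
    model: MKLModel,
    test_kernels: Sequence[np.ndarray],
    available: np.ndarray | None = None,
) -> np.ndarray:
    """Composite decision values phi for test rows.

    ``test_kernels`` holds one (n_test x n_train) cross block per group;
    ``available`` is the per-row boolean group mask (all-available when
    omitted). For each row the model weights are renormalized over its
    available groups and phi = sum_l lambda'_l sum_i d_i K_l(test, i) + b.
    Rows with no available positively-weighted group yield NaN, the
    no-prediction marker.
    """
    p = len(model.weights)
    if len(test_kernels) != p:
        raise ValueError(f"expected {p} cross blocks, got {len(test_kernels)}")
    blocks = [np.asarray(B, dtype=float) for B in test_kernels]
    m, n_train = blocks[0].shape
    for B in blocks:
        if B.shape != (m, n_train):
            raise ValueError("cross block dimension mismatch")
    if n_train != model.dual_coef.size:
        raise ValueError("cross blocks misaligned with training set")
    if available is None:
        available = np.ones((m, p), dtype=bool)
    available = np.asarray(available, dtype=bool)
    if available.shape != (m, p):
        raise ValueError("availability mask shape mismatch")

    # per-group projections onto the dual coefficients
    proj = np.column_stack([B @ model.dual_coef for B in blocks])  # (m, p)
    phi = np.full(m, np.nan)
    for pattern in {tuple(row) for row in available}:
        rows = np.all(available == np.array(pattern, dtype=bool), axis=1)
        try:
            lam = rescale_weights(model.weights, np.array(pattern, dtype=bool))
        except NoPredictionPossibleError:
            continue  # phi stays NaN: no prediction possible
        phi[rows] = proj[rows] @ lam.lam + model.bias
    return phi


def predict(
    model: MKLModel,
    test_kernels: Sequence[np.ndarray],
    available: np.ndarray | None = None,
) -> np.ndarray:
    """Predicted labels: sign of phi with the tie phi = 0 mapped to +1
    (the at-or-above convention); NaN propagates as no-prediction."""
    phi = decision_function(model, test_kernels, available)
    out = np.where(phi >= 0.0, 1.0, -1.0)
    out[np.isnan(phi)] = np.nan
    return out
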