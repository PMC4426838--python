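"""Posterior probabilities from SVM decision values and cautious
classification.

A sigmoid P(y=1 | phi) = 1 / (1 + exp(a*phi + b)) is fitted to decision
values by minimizing the cross-entropy against Platt's smoothed targets
t+ = (N+ + 1)/(N+ + 2) and t- = 1/(N- + 2), using the damped Newton
iteration of Lin, Weng & Keerthi (2007), which is deterministic and robust
to separable inputs. When positives score higher than negatives on average
the fitted slope ``a`` is negative, so the posterior increases with phi.

Cautious classification keeps a prediction only when its confidence
max(P, 1-P) reaches a cutoff: accuracy on the kept subset rises with the
cutoff at the price of coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PlattCalibrator",
    "PlattConvergenceError",
    "fit_platt",
    "posterior",
    "make_prediction_records",
    "cautious_subset",
]


class PlattConvergenceError(RuntimeError):
    """Newton iteration failed to converge; carries the last iterate."""

    def __init__(self, message: str, a: float, b: float):
        super().__init__(message)
        self.a = a
        self.b = b


@dataclass(frozen=True)
class PlattCalibrator:
    """Sigmoid parameters: P(y=1 | phi) = 1 / (1 + exp(a*phi + b))."""

    a: float
    b: float


def _stable_sigmoid(z: np.ndarray) -> np.ndarray:
    """1 / (1 + exp(z)) without overflow for large |z|."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = np.exp(-z[pos]) / (1.0 + np.exp(-z[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(z[~pos]))
    return out


def fit_platt(
    phis: Sequence[float] | np.ndarray,
    labels: Sequence[int] | np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> PlattCalibrator:
    """Fit the sigmoid (a, b) on decision values and +1/-1 labels.

    Deterministic damped Newton minimization of the smoothed-target
    cross-entropy; raises ``ValueError`` unless both classes are present
    and :class:`PlattConvergenceError` (carrying the last iterate) if the
    gradient does not vanish within ``max_iter`` iterations.
    """
    phi = np.asarray(phis, dtype=float)
    y = np.asarray(labels, dtype=float)
    if phi.shape != y.shape or phi.ndim != 1:
        raise ValueError("phis and labels must be aligned 1-D vectors")
    n_pos = int((y == 1).sum())
    n_neg = int((y == -1).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to fit the sigmoid")

    hi = (n_pos + 1.0) / (n_pos + 2.0)
    lo = 1.0 / (n_neg + 2.0)
    t = np.where(y == 1, hi, lo)

    a = 0.0
    b = float(np.log((n_neg + 1.0) / (n_pos + 1.0)))
    sigma = 1e-12  # Hessian floor

    def loss(a_: float, b_: float) -> float:
        # -sum t log p + (1-t) log(1-p) with p = 1/(1+exp(z)), written
        # against log(1+exp(z)) for stability
        z = a_ * phi + b_
        return float(np.sum(np.logaddexp(0.0, z) - (1.0 - t) * z))

    f_old = loss(a, b)
    for _ in range(max_iter):
        z = a * phi + b
        p = _stable_sigmoid(z)  # P(y=1)
        # per-point d loss / dz = t - p; gradient in (a, b) follows
        diff = t - p
        g_a = float(np.sum(diff * phi))
        g_b = float(np.sum(diff))
        if max(abs(g_a), abs(g_b)) < 1e-6:
            return PlattCalibrator(a, b)
        w = p * (1.0 - p)
        h_aa = float(np.sum(w * phi * phi)) + sigma
        h_bb = float(np.sum(w)) + sigma
        h_ab = float(np.sum(w * phi))
        det = h_aa * h_bb - h_ab * h_ab
        da = -(h_bb * g_a - h_ab * g_b) / det
        db = -(h_aa * g_b - h_ab * g_a) / det
        # backtracking on the Newton step
        step = 1.0
        g_dot_dir = g_a * da + g_b * db
        while step >= 1e-10:
            f_new = loss(a + step * da, b + step * db)
            if f_new < f_old + 1e-4 * step * g_dot_dir:
                break
            step /= 2.0
        else:
            raise PlattConvergenceError("line search failed", a, b)
        a += step * da
        b += step * db
        if abs(f_old - f_new) < tol * max(abs(f_old), 1.0):
            return PlattCalibrator(a, b)
        f_old = f_new
    raise PlattConvergenceError("Newton iteration did not converge", a, b)


def posterior(cal: PlattCalibrator, phi: float | np.ndarray) -> float | np.ndarray:
    """P(y = 1 | phi) under the fitted sigmoid, overflow-safe, in (0, 1)."""
    scalar = np.isscalar(phi)
    p = _stable_sigmoid(cal.a * np.atleast_1d(np.asarray(phi, float)) + cal.b)
    return float(p[0]) if scalar else p


def make_prediction_records(
    phi: np.ndarray,
    cal: PlattCalibrator,
    keys: Sequence | None = None,
    groups_used: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble per-variant prediction records.

    Columns: key, phi, posterior, predicted (+1/-1/NaN at no-prediction),
    confidence = max(P, 1-P), groups_used. NaN decision values (variants
    with no available feature group) propagate into every derived column.
    """
    phi = np.asarray(phi, dtype=float)
    n = phi.size
    post = np.full(n, np.nan)
    ok = ~np.isnan(phi)
    post[ok] = posterior(cal, phi[ok])
    predicted = np.where(phi >= 0.0, 1.0, -1.0)
    predicted[~ok] = np.nan
    confidence = np.maximum(post, 1.0 - post)
    df = pd.DataFrame(
        {
            "key": list(keys) if keys is not None else list(range(n)),
            "phi": phi,
            "posterior": post,
            "predicted": predicted,
            "confidence": confidence,
        }
    )
    if groups_used is not None:
        groups_used = np.asarray(groups_used, dtype=bool)
        df["groups_used"] = ["".join("1" if g else "0" for g in row)
                             for row in groups_used]
    return df


def cautious_subset(
    records: pd.DataFrame, cutoff: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split prediction records at a confidence cutoff.

    Keeps records with confidence >= cutoff (inclusive); abstains on the
    rest, including no-prediction rows. ``cutoff`` must lie in [0.5, 1]
    since confidence = max(P, 1-P) never falls below 0.5.
    """
    if not 0.5 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0.5, 1]")
    conf = records["confidence"].to_numpy()
    keep = ~np.isnan(conf) & (conf >= cutoff)
    return records.loc[keep], records.loc[~keep]
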