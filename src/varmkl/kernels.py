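"""Base-kernel construction, composite-kernel algebra and weight rescaling.

Each feature group (one annotation source) is turned into a square similarity
matrix over the training variants: features are standardized on the training
rows, missing cells are imputed at the feature mean (zero after
standardization), a linear or RBF kernel is computed, and the kernel is
unit-diagonal normalized so groups of very different dimensionality
contribute on comparable scales. The composite kernel is the convex
combination K = sum_l lambda_l K_l with simplex-constrained weights.

When a variant lacks entire feature groups at prediction time, the weights of
the available groups are renormalized to sum to one (lambda'_l =
lambda_l / sum over available lambda_l); a variant with no available group
admits no prediction at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .variant_data import FeatureGroupSet

__all__ = [
    "KernelWeights",
    "KernelSet",
    "GroupKernelTransform",
    "NoPredictionPossibleError",
    "compute_base_kernels",
    "cross_kernels",
    "compose_kernel",
    "rescale_weights",
    "median_heuristic_gamma",
]

SYM_TOL = 1e-9
PSD_REL_TOL = 1e-8


class NoPredictionPossibleError(ValueError):
    """No feature group with positive weight is available for a variant."""


@dataclass(frozen=True)
class KernelWeights:
    """Simplex-constrained kernel weights lambda (sum to 1, nonnegative)."""

    lam: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.lam, dtype=float)
        object.__setattr__(self, "lam", lam)
        if lam.ndim != 1 or lam.size == 0:
            raise ValueError("weights must form a nonempty vector")
        if (lam < -SYM_TOL).any():
            raise ValueError("kernel weights must be nonnegative")
        if abs(lam.sum() - 1.0) > 1e-9:
            raise ValueError(f"kernel weights must sum to 1, got {lam.sum()!r}")

    def __len__(self) -> int:
        return self.lam.size

    @classmethod
    def uniform(cls, p: int) -> "KernelWeights":
        return cls(np.full(p, 1.0 / p))


@dataclass
class GroupKernelTransform:
    """Everything needed to kernelize new variants against the training set
    for one feature group: the fitted scaler, the standardized training
    matrix, the construction kind and the unnormalized training
    self-similarities."""

    name: str
    kind: str                      # "linear" | "rbf"
    means: np.ndarray
    stds: np.ndarray               # zero kept as zero; constant columns -> 0
    gamma: float | None
    x_train: np.ndarray            # standardized, mean-imputed training rows
    train_self: np.ndarray         # unnormalized k(x_i, x_i) on training rows

    def transform(self, raw: np.ndarray) -> np.ndarray:
        """Standardize and impute a raw feature block with the stored scaler."""
        raw = np.asarray(raw, dtype=float)
        safe = np.where(self.stds > 0, self.stds, 1.0)
        z = (raw - self.means) / safe
        z[:, self.stds == 0] = 0.0
        return np.nan_to_num(z, nan=0.0)

    def cross(self, raw: np.ndarray) -> np.ndarray:
        """Normalized cross-kernel block (test x train)."""
        z = self.transform(raw)
        if self.kind == "linear":
            block = z @ self.x_train.T
            self_sim = np.einsum("ij,ij->i", z, z)
        elif self.kind == "rbf":
            sq = (
                np.einsum("ij,ij->i", z, z)[:, None]
                + np.einsum("ij,ij->i", self.x_train, self.x_train)[None, :]
                - 2.0 * z @ self.x_train.T
            )
            block = np.exp(-self.gamma * np.maximum(sq, 0.0))
            self_sim = np.ones(z.shape[0])
        else:  # pragma: no cover - guarded at construction
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        return _normalize_cross(block, self_sim, self.train_self)


@dataclass
class KernelSet:
    """Aligned base kernel matrices, one per feature group."""

    names: list[str]
    matrices: list[np.ndarray]
    transforms: list[GroupKernelTransform] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.matrices):
            raise ValueError("names and matrices disagree in length")
        n = None
        for name, K in zip(self.names, self.matrices):
            K = np.asarray(K, dtype=float)
            if K.ndim != 2 or K.shape[0] != K.shape[1]:
                raise ValueError(f"kernel {name!r} is not square")
            if n is None:
                n = K.shape[0]
            elif K.shape[0] != n:
                raise ValueError("kernels must share dimension")
            if np.abs(K - K.T).max(initial=0.0) > SYM_TOL:
                raise ValueError(f"kernel {name!r} is not symmetric")
            eig = np.linalg.eigvalsh(K)
            if eig.size and eig[0] < -PSD_REL_TOL * max(eig[-1], 1.0):
                raise ValueError(f"kernel {name!r} is not positive semidefinite")
        self.n = 0 if n is None else int(n)

    def __len__(self) -> int:
        return len(self.names)


def median_heuristic_gamma(x: np.ndarray) -> float:
    """RBF bandwidth gamma = 1 / median pairwise squared distance."""
    n = x.shape[0]
    if n < 2:
        return 1.0 / max(x.shape[1], 1)
    sq = (
        np.einsum("ij,ij->i", x, x)[:, None]
        + np.einsum("ij,ij->i", x, x)[None, :]
        - 2.0 * x @ x.T
    )
    med = float(np.median(sq[np.triu_indices(n, k=1)]))
    if med <= 0:
        return 1.0 / max(x.shape[1], 1)
    return 1.0 / med


def _normalize_square(K: np.ndarray) -> np.ndarray:
    """Unit-diagonal normalization K_ij / sqrt(K_ii K_jj) with 0/0 -> 0."""
    diag = np.diag(K).copy()
    scale = np.sqrt(np.maximum(diag, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = K / np.outer(scale, scale)
    out[~np.isfinite(out)] = 0.0
    np.fill_diagonal(out, np.where(diag > 0, 1.0, 0.0))
    return (out + out.T) / 2.0


def _normalize_cross(block: np.ndarray, self_sim: np.ndarray,
                     train_self: np.ndarray) -> np.ndarray:
    scale = np.sqrt(np.maximum(np.outer(self_sim, train_self), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = block / scale
    out[~np.isfinite(out)] = 0.0
    return out


def compute_base_kernels(
    features: FeatureGroupSet,
    kind: str | dict[str, str] = "linear",
    gamma: float | dict[str, float] | None = None,
    standardize: bool = True,
    normalize: bool = True,
) -> KernelSet:
    """Build one base kernel per feature group from training-row features.

    Training rows must have no group-level missingness (assemble the
    training set first). Per group the pipeline is: standardize each feature
    column to zero mean / unit variance (constant columns are zeroed),
    impute missing cells as 0 post-standardization, compute the kernel
    (linear inner products, or rbf with the median-heuristic gamma unless
    one is supplied), then unit-diagonal normalize.
    """
    names, mats, transforms = [], [], []
    for name in features.group_names:
        if features.group_missing[name].any():
            raise ValueError(
                f"group {name!r} has group-missing training rows; filter first"
            )
        raw = features.matrices[name]
        if raw.shape[1] == 0:
            raise ValueError(f"group {name!r} has zero usable features")
        group_kind = kind[name] if isinstance(kind, dict) else kind
        if group_kind not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel kind {group_kind!r}")
        if standardize:
            means = np.nanmean(raw, axis=0)
            stds = np.nanstd(raw, axis=0)
        else:
            means = np.zeros(raw.shape[1])
            stds = np.ones(raw.shape[1])
        means = np.nan_to_num(means, nan=0.0)
        stds = np.nan_to_num(stds, nan=0.0)
        tr = GroupKernelTransform(name, group_kind, means, stds, None,
                                  np.empty(0), np.empty(0))
        z = tr.transform(raw)
        if group_kind == "linear":
            K = z @ z.T
            train_self = np.diag(K).copy()
        else:
            g = gamma[name] if isinstance(gamma, dict) else gamma
            if g is None:
                g = median_heuristic_gamma(z)
            tr.gamma = float(g)
            sq = (
                np.einsum("ij,ij->i", z, z)[:, None]
                + np.einsum("ij,ij->i", z, z)[None, :]
                - 2.0 * z @ z.T
            )
            K = np.exp(-tr.gamma * np.maximum(sq, 0.0))
            train_self = np.ones(z.shape[0])
        if normalize:
            K = _normalize_square(K)
        else:
            K = (K + K.T) / 2.0
        tr.x_train = z
        tr.train_self = train_self
        names.append(name)
        mats.append(K)
        transforms.append(tr)
    return KernelSet(names, mats, transforms)


def cross_kernels(
    kernel_set: KernelSet, features: FeatureGroupSet
) -> tuple[list[np.ndarray], np.ndarray]:
    """Cross-kernel blocks (test x train) per group plus the per-row
    group-availability mask.

    Group-missing test rows get zero-filled block rows and ``available``
    False; their prediction is handled by weight rescaling downstream.
    """
    if not kernel_set.transforms:
        raise ValueError("kernel set carries no transforms (built manually?)")
    blocks: list[np.ndarray] = []
    available = np.zeros((features.n_variants, len(kernel_set)), dtype=bool)
    for j, tr in enumerate(kernel_set.transforms):
        if tr.name not in features.matrices:
            raise KeyError(f"feature group {tr.name!r} absent from input")
        raw = features.matrices[tr.name]
        if raw.shape[1] != tr.means.size:
            raise ValueError(
                f"group {tr.name!r}: expected {tr.means.size} features, "
                f"got {raw.shape[1]}"
            )
        block = tr.cross(raw)
        missing = features.group_missing[tr.name]
        block[missing] = 0.0
        blocks.append(block)
        available[:, j] = ~missing
    return blocks, available


def compose_kernel(
    kernels: KernelSet | Sequence[np.ndarray], weights: KernelWeights | np.ndarray
) -> np.ndarray:
    """Composite kernel K = sum_l lambda_l K_l."""
    mats = kernels.matrices if isinstance(kernels, KernelSet) else list(kernels)
    lam = weights.lam if isinstance(weights, KernelWeights) else np.asarray(weights, float)
    if len(mats) != lam.size:
        raise ValueError(
            f"{len(mats)} kernels but {lam.size} weights"
        )
    out = np.zeros_like(np.asarray(mats[0], dtype=float))
    for w, K in zip(lam, mats):
        if np.asarray(K).shape != out.shape:
            raise ValueError("kernel dimension mismatch")
        out += w * np.asarray(K, dtype=float)
    return out


def rescale_weights(
    weights: KernelWeights, available: Sequence[bool] | np.ndarray
) -> KernelWeights:
    """Renormalize weights over the available feature groups.

    Missing groups get weight 0 and the remaining weights are divided by
    their sum (lambda'_l = lambda_l / sum of available lambda). Raises
    :class:`NoPredictionPossibleError` when no available group carries
    positive weight — such a variant cannot be scored at all.
    """
    mask = np.asarray(available, dtype=bool)
    if mask.shape != (len(weights),):
        raise ValueError("availability mask length mismatch")
    lam = np.where(mask, weights.lam, 0.0)
    total = lam.sum()
    if total <= 0:
        raise NoPredictionPossibleError(
            "no available feature group carries positive weight"
        )
    return KernelWeights(lam / total)
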