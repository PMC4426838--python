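"""Model/Results interface tying the pipeline together.

:class:`VariantMKLClassifier` is built from a labeled dataset plus its
feature-group matrices; ``fit()`` learns the kernel weights and SVM, selects
the regularization constant by inner cross-validation when a grid is given,
calibrates the posterior sigmoid on out-of-fold decision values, and returns
a :class:`VariantMKLResults` carrying the estimates, diagnostics and a
``summary()`` table. Prediction, cautious classification and plotting hang
off the results object.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import evaluation
from .confidence import PlattCalibrator, fit_platt, make_prediction_records
from .kernels import (
    GroupKernelTransform,
    KernelSet,
    KernelWeights,
    _normalize_square,
    compute_base_kernels,
    cross_kernels,
)
from .mkl import MKLModel, decision_function, train_mkl
from .variant_data import (
    FeatureGroupSet,
    LabeledDataset,
    assemble_training_set,
    read_feature_group,
    read_variant_table,
)

__all__ = ["VariantMKLClassifier", "VariantMKLResults"]

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
MODEL_FORMAT_VERSION = 1


def _oof_phi(mats, y, folds, C, tol, max_iter):
    """Out-of-fold composite decision values over the training gram."""
    phi = np.empty(y.size)
    for tr, te in folds:
        sub = [K[np.ix_(tr, tr)] for K in mats]
        m = train_mkl(sub, y[tr], C=C, tol=tol, max_iter=max_iter)
        blocks = [K[np.ix_(te, tr)] for K in mats]
        phi[te] = decision_function(m, blocks)
    return phi


class VariantMKLClassifier:
    """MKL-SVM pathogenicity classifier over feature-group kernels.

    Parameters
    ----------
    dataset : LabeledDataset
        Labeled variants; only rows with +1/-1 labels and complete data in
        the selected groups are used for training.
    features : FeatureGroupSet
        Per-variant feature matrices aligned to ``dataset``.
    groups : sequence of str, optional
        Feature groups to use (default: all).
    kernel : {"linear", "rbf"} or mapping group -> kind
    gamma : float or mapping, optional
        RBF bandwidth; median heuristic when omitted.
    C : float, optional
        Fixed SVM regularization constant. When omitted, C is chosen from
        ``C_grid`` (default grid 0.01 ... 100) by inner stratified
        cross-validated AUC, the standard way the soft-margin constant is
        determined during training.
    C_grid : sequence of float, optional
        Candidate grid for C selection; ignored when ``C`` is fixed.
    cv_folds : int, default 3
        Folds for C selection and posterior calibration.
    seed : int
        Seed for every fold shuffle.
    """

    def __init__(
        self,
        dataset: LabeledDataset,
        features: FeatureGroupSet,
        groups: Sequence[str] | None = None,
        kernel: str | dict[str, str] = "linear",
        gamma: float | dict[str, float] | None = None,
        C: float | None = None,
        C_grid: Sequence[float] | None = None,
        cv_folds: int = 3,
        seed: int = 0,
    ):
        labeled = dataset.labels != 0
        dataset = dataset.subset(labeled)
        features = features.subset(labeled)
        self.dataset, self.features = assemble_training_set(
            dataset, features, groups=groups, balanced=False
        )
        if len(self.dataset) == 0:
            raise ValueError("no labeled variants with complete feature groups")
        self.groups = list(self.features.group_names)
        self.kernel = kernel
        self.gamma = gamma
        self.C = None if C is None else float(C)
        if C is not None:
            self.C_grid = None
        else:
            self.C_grid = tuple(C_grid) if C_grid is not None else DEFAULT_C_GRID
        self.cv_folds = int(cv_folds)
        self.seed = int(seed)

    @classmethod
    def from_tables(
        cls,
        variant_path: str | Path,
        feature_paths: Mapping[str, str | Path],
        dialect: str = "tsv",
        **kwargs,
    ) -> "VariantMKLClassifier":
        """Build the model from a variant table and per-group feature TSVs."""
        dataset = read_variant_table(variant_path, dialect=dialect)
        matrices = {
            name: read_feature_group(path, dataset)
            for name, path in feature_paths.items()
        }
        features = FeatureGroupSet(matrices, group_names=list(feature_paths))
        return cls(dataset, features, **kwargs)

    def fit(
        self,
        tol: float = 1e-5,
        max_iter: int = 100,
        calibrate: bool = True,
    ) -> "VariantMKLResults":
        y = self.dataset.labels.astype(float)
        kset = compute_base_kernels(self.features, kind=self.kernel,
                                    gamma=self.gamma)
        mats = kset.matrices
        folds = evaluation.kfold_cv(
            len(y), k=self.cv_folds, stratified=True, labels=y, seed=self.seed
        )

        C = self.C if self.C is not None else 1.0
        c_scores: dict[float, float] | None = None
        if self.C_grid is not None:
            c_scores = {}
            for cand in self.C_grid:
                phi = _oof_phi(mats, y, folds, cand, tol, max_iter)
                c_scores[cand] = evaluation.roc_auc(phi, y)
            C = max(c_scores, key=lambda c: (c_scores[c], -c))

        model = train_mkl(kset, y, C=C, tol=tol, max_iter=max_iter)

        calibrator = None
        cv_auc = None
        oof_phi = None
        if calibrate:
            oof_phi = _oof_phi(mats, y, folds, C, tol, max_iter)
            cv_auc = evaluation.roc_auc(oof_phi, y)
            calibrator = fit_platt(oof_phi, y)

        # single-kernel out-of-fold AUC per group, for the relevance report
        single_auc = {}
        for name, K in zip(kset.names, mats):
            phi_k = _oof_phi([K], y, folds, C, tol, max_iter)
            single_auc[name] = evaluation.roc_auc(phi_k, y)

        return VariantMKLResults(
            model=self,
            mkl_model=model,
            calibrator=calibrator,
            cv_auc=cv_auc,
            single_kernel_auc=single_auc,
            c_scores=c_scores,
            oof_phi=oof_phi,
        )


class VariantMKLResults:
    """Fitted MKL-SVM: kernel weights, duals, calibration and diagnostics."""

    def __init__(
        self,
        model: VariantMKLClassifier | None,
        mkl_model: MKLModel,
        calibrator: PlattCalibrator | None,
        cv_auc: float | None = None,
        single_kernel_auc: dict[str, float] | None = None,
        c_scores: dict[float, float] | None = None,
        oof_phi: np.ndarray | None = None,
    ):
        self.model = model
        self.mkl_model = mkl_model
        self.calibrator = calibrator
        self.cv_auc = cv_auc
        self.single_kernel_auc = single_kernel_auc or {}
        self.c_scores = c_scores
        self.oof_phi = oof_phi

    # -- estimates --------------------------------------------------------

    @property
    def kernel_weights(self) -> pd.Series:
        names = self.mkl_model.group_names or [
            f"K{i}" for i in range(len(self.mkl_model.weights))
        ]
        return pd.Series(self.mkl_model.weights.lam, index=names, name="lambda")

    @property
    def n_support(self) -> int:
        return int(self.mkl_model.support_index.size)

    # -- prediction -------------------------------------------------------

    def decision_function(self, features: FeatureGroupSet) -> np.ndarray:
        kset = self.mkl_model.kernel_set
        if kset is None:
            raise ValueError("results carry no kernel transforms")
        blocks, available = cross_kernels(kset, features)
        return decision_function(self.mkl_model, blocks, available)

    def predict(
        self,
        features: FeatureGroupSet,
        keys: Sequence | None = None,
    ) -> pd.DataFrame:
        """Prediction records (phi, posterior, predicted label, confidence,
        groups_used) for new variants; rows lacking every feature group get
        no-prediction markers (NaN)."""
        if self.calibrator is None:
            raise ValueError("fit with calibrate=True to predict posteriors")
        kset = self.mkl_model.kernel_set
        if kset is None:
            raise ValueError("results carry no kernel transforms")
        blocks, available = cross_kernels(kset, features)
        phi = decision_function(self.mkl_model, blocks, available)
        return make_prediction_records(phi, self.calibrator, keys=keys,
                                       groups_used=available)

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        model = self.mkl_model
        lines = []
        lines.append("MKL-SVM variant pathogenicity classifier")
        lines.append("=" * 56)
        if self.model is not None:
            y = self.model.dataset.labels
            lines.append(
                f"Training variants:   {y.size} "
                f"({int((y == 1).sum())} pathogenic / {int((y == -1).sum())} control)"
            )
        lines.append(f"Feature groups:      {len(model.weights)}")
        lines.append(f"C (soft margin):     {model.C:g}")
        lines.append(f"Support vectors:     {self.n_support}")
        lines.append(f"Outer iterations:    {model.n_iter}")
        if self.cv_auc is not None:
            lines.append(f"Cross-validated AUC: {self.cv_auc:.3f}")
        if self.calibrator is not None:
            lines.append(
                f"Sigmoid (a, b):      ({self.calibrator.a:.4f}, "
                f"{self.calibrator.b:.4f})"
            )
        lines.append("-" * 56)
        lines.append(f"{'group':<12}{'kernel weight':>16}{'single-kernel AUC':>20}")
        for name, lam in self.kernel_weights.items():
            auc = self.single_kernel_auc.get(name)
            auc_s = f"{auc:.3f}" if auc is not None else "-"
            lines.append(f"{name:<12}{lam:>16.4f}{auc_s:>20}")
        lines.append("-" * 56)
        return "\n".join(lines)

    # -- plotting ---------------------------------------------------------

    def plot_cautious(self, records: pd.DataFrame, labels: np.ndarray,
                      cutoffs: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9, 0.95),
                      ax=None):
        """Accuracy and coverage of the kept subset versus confidence cutoff."""
        from .confidence import cautious_subset
        import matplotlib.pyplot as plt

        labels = np.asarray(labels)
        acc, cov = [], []
        for cutoff in cutoffs:
            kept, _ = cautious_subset(records, cutoff)
            if len(kept) == 0:
                acc.append(np.nan)
                cov.append(0.0)
                continue
            correct = kept["predicted"].to_numpy() == labels[kept.index]
            acc.append(float(np.mean(correct)))
            cov.append(len(kept) / len(records))
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(cutoffs, acc, marker="o", label="accuracy (kept)")
        ax.plot(cutoffs, cov, marker="s", label="coverage")
        ax.set_xlabel("confidence cutoff")
        ax.set_ylabel("fraction")
        ax.set_ylim(0, 1.05)
        ax.legend()
        return ax

    # -- serialization ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the fitted model to a versioned single-file JSON container."""
        kset = self.mkl_model.kernel_set
        if kset is None:
            raise ValueError("results carry no kernel transforms")
        payload = {
            "format": "varmkl-model",
            "version": MODEL_FORMAT_VERSION,
            "C": self.mkl_model.C,
            "bias": self.mkl_model.bias,
            "weights": self.mkl_model.weights.lam.tolist(),
            "dual_coef": self.mkl_model.dual_coef.tolist(),
            "calibrator": (
                None
                if self.calibrator is None
                else {"a": self.calibrator.a, "b": self.calibrator.b}
            ),
            "cv_auc": self.cv_auc,
            "single_kernel_auc": self.single_kernel_auc,
            "groups": [
                {
                    "name": tr.name,
                    "kind": tr.kind,
                    "gamma": tr.gamma,
                    "means": tr.means.tolist(),
                    "stds": tr.stds.tolist(),
                    "x_train": tr.x_train.tolist(),
                    "train_self": tr.train_self.tolist(),
                }
                for tr in kset.transforms
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "VariantMKLResults":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "varmkl-model":
            raise ValueError(f"{path}: not a varmkl model file")
        if payload.get("version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"{path}: unsupported model version")
        transforms, names, mats = [], [], []
        for g in payload["groups"]:
            tr = GroupKernelTransform(
                name=g["name"],
                kind=g["kind"],
                means=np.asarray(g["means"], float),
                stds=np.asarray(g["stds"], float),
                gamma=g["gamma"],
                x_train=np.asarray(g["x_train"], float),
                train_self=np.asarray(g["train_self"], float),
            )
            transforms.append(tr)
            names.append(tr.name)
            # rebuild the training gram from the stored standardized rows
            if tr.kind == "linear":
                K = _normalize_square(tr.x_train @ tr.x_train.T)
            else:
                z = tr.x_train
                sq = (
                    np.einsum("ij,ij->i", z, z)[:, None]
                    + np.einsum("ij,ij->i", z, z)[None, :]
                    - 2.0 * z @ z.T
                )
                K = np.exp(-tr.gamma * np.maximum(sq, 0.0))
            mats.append(K)
        kset = KernelSet(names, mats, transforms)
        dual = np.asarray(payload["dual_coef"], float)
        mkl_model = MKLModel(
            weights=KernelWeights(np.asarray(payload["weights"], float)),
            dual_coef=dual,
            bias=float(payload["bias"]),
            support_index=np.flatnonzero(dual != 0.0),
            C=float(payload["C"]),
            kernel_set=kset,
        )
        cal = payload["calibrator"]
        calibrator = None if cal is None else PlattCalibrator(cal["a"], cal["b"])
        return cls(
            model=None,
            mkl_model=mkl_model,
            calibrator=calibrator,
            cv_auc=payload.get("cv_auc"),
            single_kernel_auc=payload.get("single_kernel_auc") or {},
        )
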