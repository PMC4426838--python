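"""Synthetic labeled-variant benchmark generator.

Emulates the structure of a pathogenic-versus-control SNV study: variants
scattered over chromosomes with negatives clustered near positives, a
minor-allele-frequency model in which controls are common while pathogenic
variants (and control contaminants that are secretly pathogenic-like) are
rare, several feature groups of differing informativeness, and both
group-level and value-level missingness.

Feature groups draw from class-conditional multivariate normals with
identity covariance; a signal group separates the latent class means of each
feature by ``effect_size`` standard deviations, a noise-only group by
nothing. A fraction ``contamination_rate`` of the negatives is drawn from
the positive feature distribution but labeled -1 with a low-mean MAF — the
mislabeled true positives that a real control set inevitably contains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variant_data import (
    LABEL_CONTROL,
    LABEL_PATHOGENIC,
    FeatureGroupSet,
    LabeledDataset,
)

__all__ = ["GroupSpec", "SyntheticConfig", "generate"]

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class GroupSpec:
    """One synthetic feature group.

    ``effect_size`` is the separation of the two latent-class means of each
    feature, in units of the feature standard deviation; ``noise_only``
    forces it to zero.
    """

    n_features: int = 8
    effect_size: float = 2.0
    noise_only: bool = False

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")

    @property
    def shift(self) -> float:
        return 0.0 if self.noise_only else self.effect_size


def _default_groups() -> tuple[GroupSpec, ...]:
    return (
        GroupSpec(n_features=8, effect_size=2.0),
        GroupSpec(n_features=8, noise_only=True),
        GroupSpec(n_features=8, noise_only=True),
        GroupSpec(n_features=8, noise_only=True),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic benchmark.

    MAF models are Beta distributions on allele frequency, truncated to the
    minor-allele range by taking min(f, 1-f): ``maf_control`` is the
    common-variant model for clean controls, ``maf_rare`` the low-mean model
    shared by pathogenic variants and contaminated controls. Positions are
    drawn so that ``within_window_fraction`` of the negatives land within
    ``cluster_window`` nucleotides of some positive.
    """

    n_pos: int = 200
    n_neg: int = 200
    group_specs: tuple[GroupSpec, ...] = field(default_factory=_default_groups)
    group_missing_rate: float | tuple[float, ...] = 0.0
    value_missing_rate: float = 0.0
    maf_control: tuple[float, float] = (2.0, 5.0)
    maf_rare: tuple[float, float] = (1.0, 19.0)
    contamination_rate: float = 0.05
    cluster_window: int = 1000
    within_window_fraction: float = 0.8
    coding_fraction: float = 0.5
    n_chromosomes: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in ("value_missing_rate", "contamination_rate",
                     "within_window_fraction", "coding_fraction"):
            v = getattr(self, rate)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{rate} must lie in [0, 1]")
        gmr = self.group_missing_rate
        rates = gmr if isinstance(gmr, tuple) else (gmr,)
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("group_missing_rate must lie in [0, 1]")
        if len(self.group_specs) < 1:
            raise ValueError("need at least one feature group")

    @property
    def n_groups(self) -> int:
        return len(self.group_specs)

    def missing_rates(self) -> tuple[float, ...]:
        gmr = self.group_missing_rate
        if isinstance(gmr, tuple):
            if len(gmr) != self.n_groups:
                raise ValueError("one group_missing_rate per group required")
            return gmr
        return (gmr,) * self.n_groups


def _draw_maf(rng: np.random.Generator, params: tuple[float, float],
              size: int) -> np.ndarray:
    f = rng.beta(params[0], params[1], size=size)
    return np.minimum(f, 1.0 - f)


def generate(
    config: SyntheticConfig,
) -> tuple[LabeledDataset, FeatureGroupSet, pd.DataFrame]:
    """Draw one synthetic benchmark.

    Returns the labeled dataset, the feature-group set aligned to it, and a
    truth table with the latent class (+1/-1) and the contamination flag per
    variant. Bit-identical for identical configs (including the seed).
    """
    if config.n_pos < 1 or config.n_neg < 1:
        raise ValueError("need at least one example per class")
    rng = np.random.default_rng(config.seed)
    n = config.n_pos + config.n_neg

    label = np.concatenate(
        [np.full(config.n_pos, LABEL_PATHOGENIC),
         np.full(config.n_neg, LABEL_CONTROL)]
    )
    contaminated = np.zeros(n, dtype=bool)
    neg_rows = np.arange(config.n_pos, n)
    n_contam = int(round(config.contamination_rate * config.n_neg))
    if n_contam:
        contaminated[rng.choice(neg_rows, size=n_contam, replace=False)] = True
    latent = np.where((label == LABEL_PATHOGENIC) | contaminated, 1, -1)

    # genomic coordinates: positives scattered, negatives mostly clustered
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    pos_chrom = rng.integers(0, config.n_chromosomes, size=config.n_pos)
    pos_pos = rng.integers(10_000, 50_000_000, size=config.n_pos)
    chrom = np.empty(n, dtype=object)
    pos = np.empty(n, dtype=np.int64)
    chrom[: config.n_pos] = [chrom_names[c] for c in pos_chrom]
    pos[: config.n_pos] = pos_pos
    near = rng.random(config.n_neg) < config.within_window_fraction
    anchor = rng.integers(0, config.n_pos, size=config.n_neg)
    offset_near = rng.integers(-config.cluster_window, config.cluster_window + 1,
                               size=config.n_neg)
    offset_far = rng.integers(config.cluster_window + 1, 10_000_000,
                              size=config.n_neg)
    for i, row in enumerate(neg_rows):
        a = anchor[i]
        chrom[row] = chrom_names[pos_chrom[a]]
        delta = offset_near[i] if near[i] else offset_far[i]
        pos[row] = max(1, pos_pos[a] + delta)

    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4

    maf = np.empty(n)
    rare = (label == LABEL_PATHOGENIC) | contaminated
    maf[rare] = _draw_maf(rng, config.maf_rare, int(rare.sum()))
    maf[~rare] = _draw_maf(rng, config.maf_control, int((~rare).sum()))
    coding = rng.random(n) < config.coding_fraction

    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "label": label,
            "maf": maf,
            "coding": coding,
        }
    )
    # collisions on (chrom,pos,ref,alt) are astronomically unlikely but the
    # dataset invariant demands uniqueness; nudge any duplicate position
    while df.duplicated(subset=["chrom", "pos", "ref", "alt"]).any():
        dup = df.duplicated(subset=["chrom", "pos", "ref", "alt"])
        df.loc[dup, "pos"] = df.loc[dup, "pos"] + 1
    dataset = LabeledDataset(df)

    matrices: dict[str, np.ndarray] = {}
    group_missing: dict[str, np.ndarray] = {}
    names = [chr(ord("A") + j) for j in range(config.n_groups)]
    for name, spec, gmr in zip(names, config.group_specs, config.missing_rates()):
        mean = 0.5 * spec.shift * latent[:, None]  # class means shift apart
        mat = rng.normal(loc=mean, scale=1.0, size=(n, spec.n_features))
        if config.value_missing_rate > 0:
            cell = rng.random(mat.shape) < config.value_missing_rate
            mat[cell] = np.nan
        gm = rng.random(n) < gmr
        mat[gm] = np.nan
        matrices[name] = mat
        group_missing[name] = gm | np.isnan(mat).all(axis=1)
    features = FeatureGroupSet(matrices, group_missing, names)

    truth = pd.DataFrame({"latent": latent, "contaminated": contaminated})
    return dataset, features, truth
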