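"""Variant data model, file I/O and dataset-assembly rules.

The training-set construction conventions implemented here mirror common
practice for pathogenic-versus-control SNV benchmarks: controls are kept only
when common (minor allele frequency at or above a cutoff, 1% by default),
controls that collide with a pathogenic variant key are dropped, negatives may
be restricted to a fixed nucleotide window around some positive to mitigate
genomic sampling bias, datasets are split by whether the variant changes an
encoded amino acid, and balanced per-class training sets are drawn with an
explicit seed.

Coordinates are 1-based fully closed (VCF convention) and variants are
biallelic SNVs identified by the (chrom, pos, ref, alt) key.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LABEL_PATHOGENIC",
    "LABEL_CONTROL",
    "LABEL_UNLABELED",
    "Variant",
    "LabeledDataset",
    "FeatureGroupSet",
    "VariantTableError",
    "read_variant_table",
    "write_variant_table",
    "read_feature_group",
    "write_feature_group",
    "filter_controls_by_maf",
    "remove_pathogenic_overlap",
    "select_negatives_within_window",
    "split_by_coding",
    "assemble_training_set",
]

LABEL_PATHOGENIC = 1
LABEL_CONTROL = -1
LABEL_UNLABELED = 0

_VALID_LABELS = {LABEL_PATHOGENIC, LABEL_CONTROL, LABEL_UNLABELED}
_NUCLEOTIDES = {"A", "C", "G", "T"}


class VariantTableError(ValueError):
    """Raised for malformed variant tables or invariant violations."""


@dataclass(frozen=True)
class Variant:
    """One labeled biallelic SNV.

    ``label`` is +1 (pathogenic), -1 (control) or 0 (unlabeled); ``maf`` is
    the minor allele frequency in [0, 0.5] or NaN when unknown; ``coding``
    is True when the variant introduces an amino acid substitution, False
    when not, None when unannotated.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    label: int = LABEL_UNLABELED
    maf: float = float("nan")
    coding: bool | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantTableError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise VariantTableError(
                f"ref and alt alleles must differ at {self.chrom}:{self.pos}"
            )
        if self.label not in _VALID_LABELS:
            raise VariantTableError(f"unknown label {self.label!r}")
        if not np.isnan(self.maf) and not (0.0 <= self.maf <= 0.5):
            raise VariantTableError(
                f"maf must lie in [0, 0.5], got {self.maf} at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


class LabeledDataset:
    """Ordered collection of :class:`Variant` with a unique-key index.

    Wraps a pandas DataFrame with columns ``chrom, pos, ref, alt, label,
    maf, coding``; row order is stable and meaningful.
    """

    COLUMNS = ("chrom", "pos", "ref", "alt", "label", "maf", "coding")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise VariantTableError(f"missing columns: {missing}")
        df = df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        df["label"] = df["label"].astype(np.int64)
        df["maf"] = df["maf"].astype(float)
        if (df["pos"] < 1).any():
            raise VariantTableError("positions must be >= 1")
        bad_label = ~df["label"].isin(sorted(_VALID_LABELS))
        if bad_label.any():
            raise VariantTableError(
                f"unknown label values: {sorted(df.loc[bad_label, 'label'].unique())}"
            )
        keys = list(zip(df["chrom"], df["pos"], df["ref"], df["alt"]))
        index: dict[tuple[str, int, str, str], int] = {}
        for row, key in enumerate(keys):
            if key in index:
                raise VariantTableError(f"duplicate variant key {key}")
            index[key] = row
        self._df = df
        self._index = index

    # -- construction -----------------------------------------------------

    @classmethod
    def from_variants(cls, variants: Iterable[Variant]) -> "LabeledDataset":
        rows = [
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "label": v.label,
                "maf": v.maf,
                "coding": v.coding,
            }
            for v in variants
        ]
        df = pd.DataFrame(rows, columns=list(cls.COLUMNS))
        if df.empty:
            df = pd.DataFrame({c: [] for c in cls.COLUMNS})
        return cls(df)

    # -- basic protocol ---------------------------------------------------

    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self):
        for row in self._df.itertuples(index=False):
            coding = row.coding
            if coding is not None and not isinstance(coding, bool):
                coding = None if pd.isna(coding) else bool(coding)
            yield Variant(row.chrom, int(row.pos), row.ref, row.alt,
                          int(row.label), float(row.maf), coding)

    def __eq__(self, other) -> bool:
        if not isinstance(other, LabeledDataset):
            return NotImplemented
        a, b = self._df, other._df
        if len(a) != len(b):
            return False
        num = a[["pos", "label", "maf"]].to_numpy(dtype=float)
        num_b = b[["pos", "label", "maf"]].to_numpy(dtype=float)
        if not np.array_equal(num, num_b, equal_nan=True):
            return False
        for col in ("chrom", "ref", "alt"):
            if not (a[col].to_numpy() == b[col].to_numpy()).all():
                return False
        ca = a["coding"].map(lambda x: None if pd.isna(x) else bool(x))
        cb = b["coding"].map(lambda x: None if pd.isna(x) else bool(x))
        return list(ca) == list(cb)

    @property
    def df(self) -> pd.DataFrame:
        """Copy-free view of the underlying table (do not mutate)."""
        return self._df

    @property
    def index(self) -> Mapping[tuple[str, int, str, str], int]:
        return self._index

    def keys(self) -> list[tuple[str, int, str, str]]:
        return list(self._index.keys())

    @property
    def labels(self) -> np.ndarray:
        return self._df["label"].to_numpy()

    def subset(self, rows: Sequence[int] | np.ndarray) -> "LabeledDataset":
        """Row subset preserving the given order (boolean mask or indices)."""
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return LabeledDataset(self._df.iloc[rows])


class FeatureGroupSet:
    """Named per-variant feature matrices with explicit missingness.

    Each group holds a (n_variants, n_features) float matrix where NaN marks
    a missing value. ``group_missing[name]`` flags variants with no data at
    all in that group (which implies every cell of the row is NaN).
    """

    def __init__(
        self,
        matrices: Mapping[str, np.ndarray],
        group_missing: Mapping[str, np.ndarray] | None = None,
        group_names: Sequence[str] | None = None,
    ):
        self.group_names = list(group_names) if group_names is not None else list(matrices)
        if set(self.group_names) != set(matrices):
            raise ValueError("group_names must match matrices keys")
        self.matrices: dict[str, np.ndarray] = {}
        self.group_missing: dict[str, np.ndarray] = {}
        n = None
        for name in self.group_names:
            mat = np.asarray(matrices[name], dtype=float)
            if mat.ndim != 2:
                raise ValueError(f"group {name!r}: matrix must be 2-D")
            if n is None:
                n = mat.shape[0]
            elif mat.shape[0] != n:
                raise ValueError("all groups must cover the same variants")
            if group_missing is not None and name in group_missing:
                gm = np.asarray(group_missing[name], dtype=bool)
                if gm.shape != (mat.shape[0],):
                    raise ValueError(f"group {name!r}: bad group_missing shape")
                if mat.size and not np.isnan(mat[gm]).all():
                    raise ValueError(
                        f"group {name!r}: group-missing rows must be all-NaN"
                    )
            else:
                gm = np.isnan(mat).all(axis=1) if mat.shape[1] else np.zeros(n, bool)
            self.matrices[name] = mat
            self.group_missing[name] = gm
        self.n_variants = 0 if n is None else int(n)

    @property
    def value_missing(self) -> dict[str, np.ndarray]:
        return {name: np.isnan(mat) for name, mat in self.matrices.items()}

    def subset(self, rows: Sequence[int] | np.ndarray) -> "FeatureGroupSet":
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return FeatureGroupSet(
            {name: self.matrices[name][rows] for name in self.group_names},
            {name: self.group_missing[name][rows] for name in self.group_names},
            self.group_names,
        )

    def select_groups(self, names: Sequence[str]) -> "FeatureGroupSet":
        unknown = [g for g in names if g not in self.matrices]
        if unknown:
            raise KeyError(f"unknown feature groups: {unknown}")
        return FeatureGroupSet(
            {name: self.matrices[name] for name in names},
            {name: self.group_missing[name] for name in names},
            list(names),
        )

    def complete_mask(self, groups: Sequence[str] | None = None) -> np.ndarray:
        """True for variants with data in every one of the given groups."""
        groups = self.group_names if groups is None else list(groups)
        mask = np.ones(self.n_variants, dtype=bool)
        for name in groups:
            mask &= ~self.group_missing[name]
        return mask


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _parse_maf(token: str, where: str) -> float:
    if token in (".", "", "NA"):
        return float("nan")
    try:
        return float(token)
    except ValueError as exc:
        raise VariantTableError(f"{where}: bad maf value {token!r}") from exc


def _parse_coding(token: str, where: str) -> bool | None:
    if token in (".", "", "NA"):
        return None
    if token in ("1", "coding", "true", "True"):
        return True
    if token in ("0", "noncoding", "false", "False"):
        return False
    raise VariantTableError(f"{where}: bad coding flag {token!r}")


def _parse_label(token: str, where: str) -> int:
    try:
        value = int(token)
    except ValueError as exc:
        raise VariantTableError(f"{where}: unknown label token {token!r}") from exc
    if value not in _VALID_LABELS:
        raise VariantTableError(f"{where}: unknown label token {token!r}")
    return value


def read_variant_table(path: str | Path, dialect: str = "tsv") -> LabeledDataset:
    """Read a labeled variant table.

    ``dialect="tsv"``: '#'-headed tab-delimited file with columns
    chrom, pos, ref, alt, label, and optionally maf and coding ('.' for
    missing values).

    ``dialect="vcf-like"``: minimal VCF dialect with the usual first eight
    columns and LABEL/MAF/CODING key=value pairs in the INFO column.

    Errors name the offending line number; duplicate (chrom,pos,ref,alt)
    keys are rejected.
    """
    path = Path(path)
    if dialect == "tsv":
        variants = _read_tsv_variants(path)
    elif dialect == "vcf-like":
        variants = _read_vcf_like_variants(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        return LabeledDataset.from_variants(variants)
    except VariantTableError as exc:
        raise VariantTableError(f"{path}: {exc}") from exc


def _read_tsv_variants(path: Path) -> list[Variant]:
    variants = []
    columns: list[str] | None = None
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                columns = line.lstrip("#").split("\t")
                continue
            if columns is None:
                columns = ["chrom", "pos", "ref", "alt", "label", "maf", "coding"]
            fields = line.split("\t")
            if len(fields) != len(columns):
                raise VariantTableError(
                    f"{path}:{lineno}: expected {len(columns)} fields, got {len(fields)}"
                )
            rec = dict(zip(columns, fields))
            where = f"{path}:{lineno}"
            for required in ("chrom", "pos", "ref", "alt", "label"):
                if required not in rec:
                    raise VariantTableError(f"{where}: missing column {required!r}")
            try:
                pos = int(rec["pos"])
            except ValueError as exc:
                raise VariantTableError(f"{where}: bad position {rec['pos']!r}") from exc
            try:
                variants.append(
                    Variant(
                        chrom=rec["chrom"],
                        pos=pos,
                        ref=rec["ref"],
                        alt=rec["alt"],
                        label=_parse_label(rec["label"], where),
                        maf=_parse_maf(rec.get("maf", "."), where),
                        coding=_parse_coding(rec.get("coding", "."), where),
                    )
                )
            except VariantTableError as exc:
                raise VariantTableError(f"{where}: {exc}") from exc
    return variants


def _read_vcf_like_variants(path: Path) -> list[Variant]:
    variants = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise VariantTableError(
                    f"{path}:{lineno}: expected >= 8 VCF columns, got {len(fields)}"
                )
            chrom, pos_s, _id, ref, alt = fields[:5]
            info = fields[7]
            where = f"{path}:{lineno}"
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise VariantTableError(f"{where}: bad position {pos_s!r}") from exc
            kv = {}
            for item in info.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    kv[k.upper()] = v
            try:
                variants.append(
                    Variant(
                        chrom=chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        label=_parse_label(kv.get("LABEL", "0"), where),
                        maf=_parse_maf(kv.get("MAF", "."), where),
                        coding=_parse_coding(kv.get("CODING", "."), where),
                    )
                )
            except VariantTableError as exc:
                raise VariantTableError(f"{where}: {exc}") from exc
    return variants


def _format_coding(value) -> str:
    if value is None or (not isinstance(value, bool) and pd.isna(value)):
        return "."
    return "1" if value else "0"


def write_variant_table(dataset: LabeledDataset, path: str | Path,
                        dialect: str = "tsv") -> None:
    """Write a variant table in either supported dialect."""
    path = Path(path)
    with open(path, "w") as handle:
        if dialect == "tsv":
            handle.write("#chrom\tpos\tref\talt\tlabel\tmaf\tcoding\n")
            for v in dataset:
                maf = "." if np.isnan(v.maf) else repr(v.maf)
                handle.write(
                    f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.label}\t{maf}\t"
                    f"{_format_coding(v.coding)}\n"
                )
        elif dialect == "vcf-like":
            handle.write("##fileformat=VCFv4.2-minimal\n")
            handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for v in dataset:
                info = [f"LABEL={v.label}"]
                if not np.isnan(v.maf):
                    info.append(f"MAF={v.maf!r}")
                if v.coding is not None:
                    info.append(f"CODING={_format_coding(v.coding)}")
                handle.write(
                    f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t{';'.join(info)}\n"
                )
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def read_feature_group(path: str | Path, dataset: LabeledDataset) -> np.ndarray:
    """Read one feature-group TSV aligned to ``dataset``.

    Layout: 4 key columns (chrom, pos, ref, alt) then numeric feature
    columns; '.' encodes a missing value and a fully-'.' row encodes
    group-level missingness. Variants absent from the file are treated as
    group-missing (all-NaN row).
    """
    path = Path(path)
    rows: dict[tuple[str, int, str, str], list[float]] = {}
    width = None
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise VariantTableError(
                    f"{path}:{lineno}: expected key columns plus >= 1 feature"
                )
            chrom, pos_s, ref, alt = fields[:4]
            values = []
            for tok in fields[4:]:
                if tok == ".":
                    values.append(float("nan"))
                else:
                    try:
                        values.append(float(tok))
                    except ValueError as exc:
                        raise VariantTableError(
                            f"{path}:{lineno}: bad feature value {tok!r}"
                        ) from exc
            if width is None:
                width = len(values)
            elif len(values) != width:
                raise VariantTableError(f"{path}:{lineno}: ragged feature row")
            rows[(chrom, int(pos_s), ref, alt)] = values
    if width is None:
        raise VariantTableError(f"{path}: empty feature-group file")
    mat = np.full((len(dataset), width), np.nan)
    for key, values in rows.items():
        row = dataset.index.get(key)
        if row is not None:
            mat[row] = values
    return mat


def write_feature_group(name: str, features: FeatureGroupSet,
                        dataset: LabeledDataset, path: str | Path) -> None:
    mat = features.matrices[name]
    with open(path, "w") as handle:
        cols = "\t".join(f"f{j}" for j in range(mat.shape[1]))
        handle.write(f"#chrom\tpos\tref\talt\t{cols}\n")
        for row, key in enumerate(dataset.keys()):
            toks = ["." if np.isnan(x) else repr(float(x)) for x in mat[row]]
            handle.write("\t".join(map(str, key)) + "\t" + "\t".join(toks) + "\n")


# ---------------------------------------------------------------------------
# dataset-assembly operations
# ---------------------------------------------------------------------------

def filter_controls_by_maf(
    dataset: LabeledDataset,
    min_maf: float = 0.01,
    missing: str = "drop",
) -> LabeledDataset:
    """Keep controls with MAF >= ``min_maf`` (inclusive); pass pathogenic
    and unlabeled variants through untouched.

    Controls with missing MAF are dropped (``missing="drop"``, the count is
    reported via logging) or rejected (``missing="error"``).
    """
    df = dataset.df
    is_control = df["label"].to_numpy() == LABEL_CONTROL
    maf = df["maf"].to_numpy()
    missing_maf = is_control & np.isnan(maf)
    if missing_maf.any():
        if missing == "error":
            raise VariantTableError(
                f"{int(missing_maf.sum())} control variants lack a MAF value"
            )
        import logging

        logging.getLogger(__name__).info(
            "dropping %d controls with missing MAF", int(missing_maf.sum())
        )
    keep = ~is_control | (~np.isnan(maf) & (maf >= min_maf))
    return dataset.subset(keep)


def remove_pathogenic_overlap(
    controls: LabeledDataset, pathogenic: LabeledDataset
) -> LabeledDataset:
    """Drop controls whose (chrom,pos,ref,alt) key appears in ``pathogenic``."""
    bad = set(pathogenic.index)
    keep = [row for key, row in controls.index.items() if key not in bad]
    return controls.subset(sorted(keep))


def select_negatives_within_window(
    negatives: LabeledDataset,
    positives: LabeledDataset,
    window: int | float = 1000,
) -> LabeledDataset:
    """Keep a negative iff some positive on the same chromosome lies within
    ``window`` nucleotides (|Δpos| <= window, symmetric and inclusive).

    ``window=np.inf`` keeps every negative sharing a chromosome with at
    least one positive; ``window=0`` keeps only exact-coordinate matches.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    pos_by_chrom: dict[str, np.ndarray] = {
        chrom: np.sort(sub["pos"].to_numpy())
        for chrom, sub in positives.df.groupby("chrom", sort=False)
    }
    keep = np.zeros(len(negatives), dtype=bool)
    df = negatives.df
    for row, (chrom, pos) in enumerate(zip(df["chrom"], df["pos"])):
        sites = pos_by_chrom.get(chrom)
        if sites is None or len(sites) == 0:
            continue
        if np.isinf(window):
            keep[row] = True
            continue
        i = np.searchsorted(sites, pos)
        nearest = min(
            abs(pos - sites[j]) for j in (i - 1, i) if 0 <= j < len(sites)
        )
        keep[row] = nearest <= window
    return negatives.subset(keep)


def split_by_coding(dataset: LabeledDataset) -> tuple[LabeledDataset, LabeledDataset]:
    """Partition into (coding, noncoding) by the amino-acid-substitution flag."""
    coding_col = dataset.df["coding"]
    missing = [
        key for key, row in dataset.index.items() if pd.isna(coding_col.iloc[row])
    ]
    if missing:
        raise VariantTableError(f"variants missing coding flag: {missing}")
    flags = np.array([bool(v) for v in coding_col], dtype=bool)
    return dataset.subset(flags), dataset.subset(~flags)


def assemble_training_set(
    dataset: LabeledDataset,
    features: FeatureGroupSet,
    groups: Sequence[str] | None = None,
    balanced: bool = False,
    n_per_class: int | str = "max",
    seed: int = 0,
) -> tuple[LabeledDataset, FeatureGroupSet]:
    """Restrict to variants with data in every selected feature group and
    optionally draw a balanced per-class sample.

    Balanced sampling takes min(available per class, ``n_per_class``)
    examples per class, uniformly without replacement under ``seed``;
    selected rows keep their original relative order.
    """
    if features.n_variants != len(dataset):
        raise ValueError("features and dataset cover different variants")
    groups = list(features.group_names if groups is None else groups)
    unknown = [g for g in groups if g not in features.matrices]
    if unknown:
        raise KeyError(f"unknown feature groups: {unknown}")
    complete = features.complete_mask(groups)
    rows = np.flatnonzero(complete)
    labels = dataset.labels[rows]
    if balanced:
        pos_rows = rows[labels == LABEL_PATHOGENIC]
        neg_rows = rows[labels == LABEL_CONTROL]
        if len(pos_rows) == 0 or len(neg_rows) == 0:
            raise VariantTableError(
                "a class has zero complete examples in the selected groups"
            )
        n_take = min(len(pos_rows), len(neg_rows))
        if n_per_class != "max":
            n_take = min(n_take, int(n_per_class))
        rng = np.random.default_rng(seed)
        chosen = np.concatenate(
            [
                rng.choice(pos_rows, size=n_take, replace=False),
                rng.choice(neg_rows, size=n_take, replace=False),
            ]
        )
        rows = np.sort(chosen)
    sub_features = features.select_groups(groups).subset(rows)
    return dataset.subset(rows), sub_features
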