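"""Core data containers and delimited / GCT readers and writers.

An :class:`ExpressionDataset` holds a sample-major expression matrix
(rows = samples, columns = genes) together with a categorical class label
per sample.  On disk the package speaks plain TSV/CSV (header row of gene
identifiers plus a label column, ``class`` by default) and the GCT 1.2
microarray dialect (genes as rows; transposed on load; labels supplied via
a two-column sidecar of ``sample_id<TAB>class``).

Expression values are assumed preprocessed (log-scale intensities or
similar); no normalisation is applied here beyond an optional z-score
transform exposed as :func:`zscore`.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import FormatError, ValidationError

__all__ = [
    "ExpressionDataset",
    "RunConfig",
    "read_dataset",
    "write_dataset",
    "zscore",
    "load_config",
]

#: float format used when writing matrices; 8 significant digits so that a
#: write/read round trip preserves values well beyond 6 significant digits.
_FLOAT_FMT = "%.8g"


@dataclass
class ExpressionDataset:
    """Samples x genes expression matrix with per-sample class labels.

    Attributes
    ----------
    matrix : ndarray, shape (n_samples, n_features)
        Real-valued expression values.
    feature_ids : list of str
        Unique gene identifiers, one per column.
    sample_ids : list of str
        Unique sample identifiers, one per row.
    labels : ndarray of str, shape (n_samples,)
        Class label per sample; at least two distinct classes, each with
        at least two samples (required by stratified CV and SMOTE).
    """

    matrix: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n, p = self.matrix.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValidationError(
                f"matrix has {n} rows but {len(self.sample_ids)} sample ids "
                f"and {len(self.labels)} labels"
            )
        if len(self.feature_ids) != p:
            raise ValidationError(
                f"matrix has {p} columns but {len(self.feature_ids)} feature ids"
            )
        if p == 0:
            raise ValidationError("dataset has zero features")
        dup_f = _duplicates(self.feature_ids)
        if dup_f:
            raise FormatError(f"duplicate feature identifiers: {sorted(dup_f)[:5]}")
        dup_s = _duplicates(self.sample_ids)
        if dup_s:
            raise FormatError(f"duplicate sample identifiers: {sorted(dup_s)[:5]}")
        if not np.all(np.isfinite(self.matrix)):
            bad = int(np.count_nonzero(~np.isfinite(self.matrix)))
            raise ValidationError(
                f"{bad} missing/non-finite expression values (load with "
                f"impute='mean' to impute per-gene means)"
            )
        classes, counts = np.unique(self.labels.astype(str), return_counts=True)
        if len(classes) < 2:
            raise ValidationError("dataset must contain at least 2 classes")
        small = classes[counts < 2]
        if small.size:
            raise ValidationError(
                f"class {small[0]!r} has fewer than 2 samples"
            )

    # -- conveniences ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def classes(self) -> list[str]:
        """Canonical (sorted) class order."""
        return sorted({str(c) for c in self.labels})

    def class_counts(self) -> dict[str, int]:
        classes, counts = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(classes.tolist(), counts.tolist()))

    def subset_samples(self, index: Sequence[int]) -> "ExpressionDataset":
        index = np.asarray(index, dtype=int)
        return ExpressionDataset(
            matrix=self.matrix[index],
            feature_ids=list(self.feature_ids),
            sample_ids=[self.sample_ids[i] for i in index],
            labels=self.labels[index],
        )

    def __eq__(self, other: object) -> bool:  # field-for-field equality
        if not isinstance(other, ExpressionDataset):
            return NotImplemented
        return (
            self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and list(self.labels) == list(other.labels)
            and self.matrix.shape == other.matrix.shape
            and np.allclose(self.matrix, other.matrix, rtol=1e-6, atol=0.0)
        )


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for it in items:
        if it in seen:
            dups.add(it)
        seen.add(it)
    return dups


@dataclass
class RunConfig:
    """All knobs of one IEFS run.

    ``T`` is the number of alternating sampling / selection steps;
    ``n_features`` is the target signature size N_n.  Defaults follow the
    benchmark conditions: SMOTE with 5 neighbours, KNN with K=3, threshold
    delta 0 for FCBF, candidate window 50 for the mRMR forward search.
    """

    selector: str = "ranking"  # ranking | fcbf | mrmr
    sampler: str = "none"  # none | undersample | oversample
    T: int = 1
    n_features: int = 30
    classifier: str = "knn"  # knn | svm
    knn_k: int = 3
    smote_k: int = 5
    seed: int = 0
    cv_folds: int | str = "auto"
    mrmr_window: int = 50
    fcbf_delta: float = 0.0
    n_bins: int = 10

    _SELECTORS = ("ranking", "fcbf", "mrmr")
    _SAMPLERS = ("none", "undersample", "oversample")
    _CLASSIFIERS = ("knn", "svm")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.selector not in self._SELECTORS:
            raise ValidationError(f"unknown selector {self.selector!r}")
        if self.sampler not in self._SAMPLERS:
            raise ValidationError(f"unknown sampler {self.sampler!r}")
        if self.classifier not in self._CLASSIFIERS:
            raise ValidationError(f"unknown classifier {self.classifier!r}")
        if self.T < 1:
            raise ValidationError("T must be >= 1")
        if self.n_features < 1:
            raise ValidationError("n_features must be >= 1")
        if self.knn_k < 1 or self.smote_k < 1:
            raise ValidationError("knn_k and smote_k must be >= 1")
        if self.n_bins < 1:
            raise ValidationError("n_bins must be >= 1")
        if isinstance(self.cv_folds, str) and self.cv_folds != "auto":
            raise ValidationError("cv_folds must be an integer or 'auto'")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)


def load_config(path: str | os.PathLike, **overrides) -> RunConfig:
    """Load a RunConfig from a YAML (or ``key: value``) file.

    Keyword overrides (e.g. CLI flags) take precedence over file values;
    overrides set to ``None`` are ignored.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping of RunConfig fields")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig.from_mapping(data)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_dataset(
    path: str | os.PathLike,
    format: str = "tsv",
    label_column: str = "class",
    label_path: str | os.PathLike | None = None,
    impute: str | None = None,
) -> ExpressionDataset:
    """Read an expression dataset from TSV, CSV, or GCT 1.2.

    For tsv/csv the first column holds sample identifiers, the header holds
    gene identifiers, and ``label_column`` holds the class label.  For gct,
    labels come from the sidecar ``label_path`` (default ``<path>.labels.tsv``),
    a headerless two-column file of sample id and class.

    ``impute='mean'`` replaces missing cells by the per-gene mean; by
    default missing values are rejected.
    """
    if format in ("tsv", "csv"):
        ds = _read_delimited(path, sep="\t" if format == "tsv" else ",",
                             label_column=label_column)
    elif format == "gct":
        ds = _read_gct(path, label_path=label_path)
    else:
        raise ValidationError(f"unknown format {format!r}")
    if impute == "mean":
        ds = _impute_mean(ds)
    elif impute is not None:
        raise ValidationError(f"unknown imputation policy {impute!r}")
    # construction re-validates; done here so error messages carry the path
    try:
        ds.validate()
    except (ValidationError, FormatError) as exc:
        raise type(exc)(f"{path}: {exc}") from exc
    return ds


def _read_delimited(path, sep: str, label_column: str) -> ExpressionDataset:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dup = _duplicates(header)
    if dup:
        raise FormatError(f"{path}: duplicate feature identifiers {sorted(dup)[:5]}")
    try:
        frame = pd.read_csv(path, sep=sep, header=0, index_col=0, dtype=str)
    except Exception as exc:  # noqa: BLE001 - surface parser failures with path
        raise FormatError(f"{path}: cannot parse ({exc})") from exc
    if label_column not in frame.columns:
        raise FormatError(f"{path}: missing label column {label_column!r}")
    if pd.isna(frame[label_column]).any():
        raise FormatError(f"{path}: missing class label")
    labels = frame[label_column].astype(str).to_numpy()
    expr = frame.drop(columns=[label_column])
    matrix = np.empty(expr.shape, dtype=float)
    for j, col in enumerate(expr.columns):
        try:
            matrix[:, j] = pd.to_numeric(expr[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise FormatError(
                f"{path}: non-numeric expression value in column {col!r}"
            ) from exc
    return _build(matrix, list(expr.columns), list(expr.index.astype(str)), labels)


def _read_gct(path, label_path=None) -> ExpressionDataset:
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) < 3 or lines[0].strip() != "#1.2":
        raise FormatError(f"{path}: not a GCT 1.2 file (missing '#1.2' line)")
    try:
        n_genes, n_samples = (int(x) for x in lines[1].split("\t")[:2])
    except ValueError as exc:
        raise FormatError(f"{path}: bad GCT dimension line {lines[1]!r}") from exc
    header = lines[2].split("\t")
    if len(header) < 2 or header[0].upper() != "NAME":
        raise FormatError(f"{path}: bad GCT header (expected NAME/Description)")
    sample_ids = header[2:]
    if len(sample_ids) != n_samples:
        raise FormatError(
            f"{path}: declared {n_samples} samples but header lists {len(sample_ids)}"
        )
    data_lines = [ln for ln in lines[3:] if ln.strip() != ""]
    if len(data_lines) != n_genes:
        raise FormatError(
            f"{path}: declared {n_genes} data rows but found {len(data_lines)}"
        )
    feature_ids: list[str] = []
    matrix = np.empty((n_genes, n_samples), dtype=float)
    for i, ln in enumerate(data_lines):
        parts = ln.split("\t")
        if len(parts) != n_samples + 2:
            raise FormatError(f"{path}: row {parts[0]!r} has {len(parts) - 2} values")
        feature_ids.append(parts[0])
        try:
            matrix[i] = [float(x) for x in parts[2:]]
        except ValueError as exc:
            raise FormatError(
                f"{path}: non-numeric expression value in row {parts[0]!r}"
            ) from exc
    label_path = label_path or f"{os.fspath(path)}.labels.tsv"
    if not os.path.exists(label_path):
        raise FormatError(f"{path}: label sidecar {label_path} not found")
    label_map: dict[str, str] = {}
    with open(label_path, "r", encoding="utf-8") as fh:
        for ln in fh:
            if not ln.strip():
                continue
            sid, cls = ln.rstrip("\n").split("\t")[:2]
            label_map[sid] = cls
    missing = [s for s in sample_ids if s not in label_map]
    if missing:
        raise FormatError(f"{label_path}: no class label for sample {missing[0]!r}")
    labels = np.array([label_map[s] for s in sample_ids], dtype=object)
    # GCT is gene-major; in memory we are sample-major
    return _build(matrix.T, feature_ids, sample_ids, labels)


def _build(matrix, feature_ids, sample_ids, labels) -> ExpressionDataset:
    with np.errstate(invalid="ignore"):
        ds = ExpressionDataset.__new__(ExpressionDataset)
        ds.matrix = np.asarray(matrix, dtype=float)
        ds.feature_ids = [str(f) for f in feature_ids]
        ds.sample_ids = [str(s) for s in sample_ids]
        ds.labels = np.asarray(labels, dtype=object)
    return ds


def _impute_mean(ds: ExpressionDataset) -> ExpressionDataset:
    matrix = ds.matrix.copy()
    for j in range(matrix.shape[1]):
        col = matrix[:, j]
        bad = ~np.isfinite(col)
        if bad.all():
            raise ValidationError(
                f"feature {ds.feature_ids[j]!r} has no observed values to impute from"
            )
        if bad.any():
            col[bad] = col[~bad].mean()
    ds.matrix = matrix
    return ds


def write_dataset(
    dataset: ExpressionDataset,
    path: str | os.PathLike,
    format: str = "tsv",
    label_column: str = "class",
    label_path: str | os.PathLike | None = None,
) -> None:
    """Write a dataset so that :func:`read_dataset` reproduces it."""
    dataset.validate()
    try:
        if format in ("tsv", "csv"):
            _write_delimited(dataset, path, sep="\t" if format == "tsv" else ",",
                             label_column=label_column)
        elif format == "gct":
            _write_gct(dataset, path, label_path=label_path)
        else:
            raise ValidationError(f"unknown format {format!r}")
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def _write_delimited(ds, path, sep, label_column) -> None:
    buf = io.StringIO()
    buf.write("sample_id" + sep + sep.join(ds.feature_ids) + sep + label_column + "\n")
    for i, sid in enumerate(ds.sample_ids):
        vals = sep.join(_FLOAT_FMT % v for v in ds.matrix[i])
        buf.write(f"{sid}{sep}{vals}{sep}{ds.labels[i]}\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def _write_gct(ds, path, label_path=None) -> None:
    n, p = ds.matrix.shape
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#1.2\n")
        fh.write(f"{p}\t{n}\n")
        fh.write("NAME\tDescription\t" + "\t".join(ds.sample_ids) + "\n")
        for j, fid in enumerate(ds.feature_ids):
            vals = "\t".join(_FLOAT_FMT % v for v in ds.matrix[:, j])
            fh.write(f"{fid}\tna\t{vals}\n")
    label_path = label_path or f"{os.fspath(path)}.labels.tsv"
    with open(label_path, "w", encoding="utf-8") as fh:
        for sid, cls in zip(ds.sample_ids, ds.labels):
            fh.write(f"{sid}\t{cls}\n")


def zscore(dataset: ExpressionDataset) -> ExpressionDataset:
    """Per-gene standardisation (mean 0, SD 1; constant genes left at 0).

    Optional preprocessing for distance-based steps (KNN, SMOTE); off by
    default throughout the package.
    """
    m = dataset.matrix
    mu = m.mean(axis=0)
    sd = m.std(axis=0)
    sd[sd == 0] = 1.0
    return ExpressionDataset(
        matrix=(m - mu) / sd,
        feature_ids=list(dataset.feature_ids),
        sample_ids=list(dataset.sample_ids),
        labels=dataset.labels.copy(),
    )
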