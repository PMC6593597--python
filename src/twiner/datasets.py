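"""Core containers and I/O for two-cohort expression analysis.

Expression matrices are held samples x genes, with binary tumor/normal
labels (1 = tumor, 0 = normal). Readers accept delimited text in either
orientation; preprocessing applies the conventional RNA-Seq pipeline of
log transform followed by per-gene Z-scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "SurvivalTable",
    "read_expression",
    "write_expression",
    "read_labels",
    "read_gene_list",
    "read_survival",
    "preprocess",
    "subset_genes",
    "merge_cohorts",
]

Orientation = Literal["genes_in_columns", "genes_in_rows"]


@dataclass(frozen=True)
class ExpressionDataset:
    """An n-samples x p-genes expression matrix with binary labels.

    Parameters
    ----------
    values : ndarray of shape (n, p)
        Real expression values, no missing entries.
    sample_ids : list of str
        Unique sample identifiers, length n.
    gene_ids : list of str
        Unique gene identifiers, length p.
    labels : ndarray of shape (n,) or None
        Binary outcome, 1 = tumor, 0 = normal.
    cohort : str or None
        Optional cohort tag, e.g. ``"A"``, ``"B"``, ``"merged"``.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    labels: np.ndarray | None = None
    cohort: str | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D samples x genes matrix")
        object.__setattr__(self, "values", values)
        n, p = values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample_ids for {n} rows")
        if len(self.gene_ids) != p:
            raise ValueError(f"{len(self.gene_ids)} gene_ids for {p} columns")
        if len(set(self.gene_ids)) != p:
            dupes = _duplicates(self.gene_ids)
            raise ValueError(f"duplicate gene identifiers: {sorted(dupes)}")
        if len(set(self.sample_ids)) != n:
            dupes = _duplicates(self.sample_ids)
            raise ValueError(f"duplicate sample identifiers: {sorted(dupes)}")
        if not np.all(np.isfinite(values)):
            raise ValueError("values contain missing or non-finite entries")
        if self.labels is not None:
            labels = np.asarray(self.labels, dtype=int)
            if labels.shape != (n,):
                raise ValueError("labels must be a length-n vector")
            if not np.isin(labels, (0, 1)).all():
                raise ValueError("labels must be binary (0 = normal, 1 = tumor)")
            object.__setattr__(self, "labels", labels)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def with_labels(self, labels: np.ndarray) -> "ExpressionDataset":
        return replace(self, labels=np.asarray(labels, dtype=int))

    def select_samples(self, index: np.ndarray) -> "ExpressionDataset":
        """Row-subset by integer or boolean index, keeping alignment."""
        index = np.asarray(index)
        labels = None if self.labels is None else self.labels[index]
        sample_ids = [self.sample_ids[i] for i in np.arange(self.n_samples)[index]]
        return ExpressionDataset(
            self.values[index], sample_ids, list(self.gene_ids), labels, self.cohort
        )

    def require_two_classes(self) -> None:
        if self.labels is None:
            raise ValueError("dataset has no labels")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("both classes must be present")


@dataclass(frozen=True)
class SurvivalTable:
    """Follow-up times and event status aligned to an expression dataset.

    ``event`` is 1 when the event (death) was observed, 0 when censored.
    """

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event, dtype=int)
        if time.shape != (len(self.sample_ids),) or event.shape != time.shape:
            raise ValueError("time/event must align with sample_ids")
        if np.any(time < 0):
            raise ValueError("follow-up times must be non-negative")
        if not np.isin(event, (0, 1)).all():
            raise ValueError("event must be binary (1 = observed, 0 = censored)")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "time": self.time, "event": self.event}
        )


def _duplicates(ids: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in ids:
        (dup if x in seen else seen).add(x)
    return dup


def read_expression(
    path: str | Path,
    orientation: Orientation = "genes_in_columns",
    delimiter: str = "\t",
    cohort: str | None = None,
) -> ExpressionDataset:
    """Read a delimited expression matrix into samples x genes form.

    The first row and first column are identifiers. With
    ``orientation="genes_in_rows"`` the table is transposed on read so the
    returned dataset is always samples x genes.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split(delimiter)[1:]
    if len(set(header)) != len(header):
        dupes = _duplicates(header)
        raise ValueError(f"duplicate identifiers in header of {path}: {sorted(dupes)}")
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed delimited file {path}: {exc}") from exc
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).to_numpy().argmax()) + 2  # +header +1-based
        raise ValueError(f"missing/ragged values in {path} near line {bad}")
    if orientation == "genes_in_rows":
        df = df.T
    elif orientation != "genes_in_columns":
        raise ValueError(f"unknown orientation {orientation!r}")
    return ExpressionDataset(
        values=df.to_numpy(dtype=float),
        sample_ids=[str(s) for s in df.index],
        gene_ids=[str(g) for g in df.columns],
        cohort=cohort,
    )


def write_expression(
    ds: ExpressionDataset, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write samples x genes to delimited text (full float precision)."""
    df = pd.DataFrame(ds.values, index=ds.sample_ids, columns=ds.gene_ids)
    df.to_csv(Path(path), sep=delimiter, float_format="%.17g")


def read_labels(path: str | Path, delimiter: str = "\t") -> pd.Series:
    """Read a two-column (sample_id, label) table as a Series."""
    df = pd.read_csv(Path(path), sep=delimiter)
    if df.shape[1] < 2:
        raise ValueError("label file needs columns: sample_id, label")
    return pd.Series(
        df.iloc[:, 1].astype(int).to_numpy(), index=df.iloc[:, 0].astype(str)
    )


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list, one identifier per line."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def read_survival(path: str | Path, delimiter: str = "\t") -> SurvivalTable:
    """Read a (sample_id, time, event) table."""
    df = pd.read_csv(Path(path), sep=delimiter)
    required = {"sample_id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"survival file needs columns {sorted(required)}")
    return SurvivalTable(
        sample_ids=[str(s) for s in df["sample_id"]],
        time=df["time"].to_numpy(dtype=float),
        event=df["event"].to_numpy(dtype=int),
    )


def preprocess(
    ds: ExpressionDataset, log_offset: float = 1.0, ddof: int = 1
) -> tuple[ExpressionDataset, list[str]]:
    """log-transform and Z-score normalize expression values per gene.

    Each value x becomes ``log(x + log_offset)``, then every gene column is
    standardized to mean 0, sd 1 across samples (sample sd, ``ddof=1``).
    Genes with zero variance after the log transform carry no information
    and have undefined correlations, so they are dropped.

    Returns
    -------
    (dataset, dropped) : the preprocessed dataset and the identifiers of
    zero-variance genes that were removed.
    """
    if log_offset <= 0:
        raise ValueError("log_offset must be positive")
    if np.any(ds.values < 0):
        raise ValueError("negative expression values: input is not FPKM-like")
    logged = np.log(ds.values + log_offset)
    sd = logged.std(axis=0, ddof=ddof)
    keep = sd > 0
    dropped = [g for g, k in zip(ds.gene_ids, keep) if not k]
    logged = logged[:, keep]
    z = (logged - logged.mean(axis=0)) / logged.std(axis=0, ddof=ddof)
    out = ExpressionDataset(
        z,
        list(ds.sample_ids),
        [g for g, k in zip(ds.gene_ids, keep) if k],
        ds.labels,
        ds.cohort,
    )
    return out, dropped


def subset_genes(
    ds: ExpressionDataset, keep: Iterable[str]
) -> tuple[ExpressionDataset, int]:
    """Restrict to genes in ``keep`` (e.g. a protein-coding list).

    Original gene order is preserved. Returns the restricted dataset and
    the number of requested identifiers absent from the dataset.
    """
    keep = set(keep)
    if not keep:
        raise ValueError("keep set is empty")
    mask = np.array([g in keep for g in ds.gene_ids])
    if not mask.any():
        raise ValueError("no overlap between keep set and dataset genes")
    n_missing = len(keep - set(ds.gene_ids))
    out = ExpressionDataset(
        ds.values[:, mask],
        list(ds.sample_ids),
        [g for g, m in zip(ds.gene_ids, mask) if m],
        ds.labels,
        ds.cohort,
    )
    return out, n_missing


def merge_cohorts(a: ExpressionDataset, b: ExpressionDataset) -> ExpressionDataset:
    """Stack two cohorts into one classification dataset over shared genes.

    Genes are aligned by identifier intersection in cohort A's order; B's
    columns are permuted to match. Samples of A come first, then B.
    Tumor/normal labels are carried through unchanged, so the merged
    outcome is tumor (from either disease) vs normal.
    """
    shared = [g for g in a.gene_ids if g in set(b.gene_ids)]
    if not shared:
        raise ValueError("cohorts share no genes")
    overlap = set(a.sample_ids) & set(b.sample_ids)
    if overlap:
        raise ValueError(f"duplicate sample ids across cohorts: {sorted(overlap)[:5]}")
    a_idx = {g: i for i, g in enumerate(a.gene_ids)}
    b_idx = {g: i for i, g in enumerate(b.gene_ids)}
    a_cols = [a_idx[g] for g in shared]
    b_cols = [b_idx[g] for g in shared]
    values = np.vstack([a.values[:, a_cols], b.values[:, b_cols]])
    if (a.labels is None) != (b.labels is None):
        raise ValueError("either both or neither cohort may carry labels")
    labels = (
        None if a.labels is None else np.concatenate([a.labels, b.labels])
    )
    if len(shared) < min(a.n_genes, b.n_genes):
        warnings.warn(
            f"merged gene set restricted to {len(shared)} shared genes",
            stacklevel=2,
        )
    return ExpressionDataset(
        values,
        list(a.sample_ids) + list(b.sample_ids),
        shared,
        labels,
        cohort="merged",
    )
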