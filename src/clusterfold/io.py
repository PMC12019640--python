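"""Reading count matrices and group labels; writing similarity tables.

Matrices are features × cells everywhere internally.  Supported on-disk
formats: Matrix Market coordinate files accompanied by one-id-per-line
feature and cell files, or delimited dense tables (TSV/CSV) with a header
row of cell ids and an index column of feature ids.  Orientation is never
guessed: files with cells as rows must be read with ``transpose=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "Dataset",
    "SharedFeatureSpace",
    "read_dataset",
    "intersect_features",
    "write_similarity_table",
    "read_similarity_table",
]


@dataclass
class Dataset:
    """One single-cell dataset: raw counts plus a per-cell group label.

    Counts may be non-integer (e.g. ATAC gene-activity scores) but never
    negative.  Every group must hold at least two cells so that 1/3
    subsampling remains meaningful.
    """

    name: str
    counts: np.ndarray  # features × cells
    feature_ids: list[str]
    cell_ids: list[str]
    group_of: dict[str, str]  # cell id → group label

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError(f"{self.name}: counts must be 2-D")
        nf, nc = self.counts.shape
        if len(self.feature_ids) != nf:
            raise ValueError(
                f"{self.name}: {len(self.feature_ids)} feature ids for {nf} matrix rows"
            )
        if len(self.cell_ids) != nc:
            raise ValueError(
                f"{self.name}: {len(self.cell_ids)} cell ids for {nc} matrix columns"
            )
        if len(set(self.feature_ids)) != nf:
            raise ValueError(f"{self.name}: duplicate feature ids")
        if len(set(self.cell_ids)) != nc:
            raise ValueError(f"{self.name}: duplicate cell ids")
        if np.any(self.counts < 0):
            raise ValueError(f"{self.name}: negative entries in count matrix")
        missing = [c for c in self.cell_ids if c not in self.group_of]
        if missing:
            raise ValueError(
                f"{self.name}: cells missing from labels: {', '.join(missing[:5])}"
            )
        extra = set(self.group_of) - set(self.cell_ids)
        if extra:
            raise ValueError(
                f"{self.name}: labelled cells absent from matrix: "
                f"{', '.join(sorted(extra)[:5])}"
            )
        for g in self.groups:
            if len(self.cells_in_group(g)) < 2:
                raise ValueError(
                    f"{self.name}: group {g!r} has < 2 cells (subsampling needs >= 2)"
                )

    @property
    def groups(self) -> list[str]:
        """Group labels, lexicographically sorted."""
        return sorted(set(self.group_of.values()))

    def cells_in_group(self, group: str) -> np.ndarray:
        """Column indices of a group's cells, ordered by sorted cell id.

        Sampling indexes cells through this ordering so results are
        invariant to column permutations of the input matrix.
        """
        col = {c: i for i, c in enumerate(self.cell_ids)}
        return np.array(
            [col[c] for c in sorted(c for c, g in self.group_of.items() if g == group)],
            dtype=int,
        )


@dataclass
class SharedFeatureSpace:
    """Features common to all datasets, in a fixed lexicographic order."""

    feature_ids: list[str]
    row_index: dict[str, np.ndarray] = field(default_factory=dict)
    # row_index[dataset name][k] = row of feature_ids[k] in that dataset

    def __len__(self) -> int:
        return len(self.feature_ids)


def _read_id_file(path: Path) -> list[str]:
    with open(path) as fh:
        ids = [line.strip().split("\t")[0] for line in fh if line.strip()]
    return ids


def read_dataset(
    matrix_path: str | Path,
    labels_path: str | Path,
    name: str,
    features_path: str | Path | None = None,
    cells_path: str | Path | None = None,
    transpose: bool = False,
) -> Dataset:
    """Load a count matrix plus labels into a validated :class:`Dataset`.

    ``matrix_path`` ending in ``.mtx`` is read as Matrix Market coordinate
    format and requires ``features_path`` / ``cells_path``; any other
    extension is read as a delimited dense table (comma-separated for
    ``.csv``, else tab) whose index column holds feature ids and header
    holds cell ids.  ``labels_path`` is a two-column delimited table
    (cell id, group) with a header row.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        if features_path is None or cells_path is None:
            raise ValueError("MTX input requires features_path and cells_path")
        mat = scipy.io.mmread(matrix_path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        if transpose:
            mat = mat.T
        feature_ids = _read_id_file(Path(features_path))
        cell_ids = _read_id_file(Path(cells_path))
    else:
        sep = "," if matrix_path.suffix == ".csv" else "\t"
        df = pd.read_csv(matrix_path, sep=sep, index_col=0)
        if transpose:
            df = df.T
        mat = df.to_numpy(dtype=float)
        feature_ids = [str(i) for i in df.index]
        cell_ids = [str(c) for c in df.columns]

    lsep = "," if Path(labels_path).suffix == ".csv" else "\t"
    labels = pd.read_csv(labels_path, sep=lsep, dtype=str)
    if labels.shape[1] < 2:
        raise ValueError(f"{labels_path}: labels need two columns (cell id, group)")
    group_of = dict(zip(labels.iloc[:, 0], labels.iloc[:, 1]))
    return Dataset(
        name=name,
        counts=mat,
        feature_ids=feature_ids,
        cell_ids=cell_ids,
        group_of=group_of,
    )


def intersect_features(datasets: Sequence[Dataset]) -> SharedFeatureSpace:
    """Features present in every dataset, lexicographically sorted.

    Raises if fewer than two datasets are given or the intersection is
    empty.  The result is invariant to the order of ``datasets``.
    """
    if len(datasets) < 2:
        raise ValueError("need >= 2 datasets to intersect features")
    shared = set(datasets[0].feature_ids)
    for ds in datasets[1:]:
        shared &= set(ds.feature_ids)
    if not shared:
        raise ValueError("no shared features across datasets")
    ordered = sorted(shared)
    space = SharedFeatureSpace(feature_ids=ordered)
    for ds in datasets:
        pos = {f: i for i, f in enumerate(ds.feature_ids)}
        space.row_index[ds.name] = np.array([pos[f] for f in ordered], dtype=int)
    logger.info("shared features across %d datasets: %d", len(datasets), len(ordered))
    return space


_TABLE_COLUMNS = [
    "dataset_a",
    "group_a",
    "dataset_b",
    "group_b",
    "similarity",
    "weight_omega",
    "sum_sc",
    "top_features",
]


def write_similarity_table(records: Sequence, path: str | Path) -> None:
    """Write similarity records as TSV (schema: dataset_a … top_features).

    ``top_features`` is a semicolon-joined list of ``feature:SC`` pairs
    with SC printed to 6 significant digits.
    """
    if not records:
        raise ValueError("no similarity records to write")
    rows = []
    for r in records:
        top = ";".join(f"{fc.feature_id}:{fc.sc:.6g}" for fc in r.top_features)
        rows.append(
            {
                "dataset_a": r.dataset_a,
                "group_a": r.group_a,
                "dataset_b": r.dataset_b,
                "group_b": r.group_b,
                "similarity": f"{r.similarity:.6g}",
                "weight_omega": f"{r.omega:.6g}",
                "sum_sc": f"{r.sum_sc:.6g}",
                "top_features": top,
            }
        )
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_similarity_table(path: str | Path):
    """Parse a similarity table written by :func:`write_similarity_table`."""
    from .similarity import FeatureContribution, SimilarityRecord

    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    records = []
    for row in df.itertuples(index=False):
        top = []
        if isinstance(row.top_features, str) and row.top_features:
            for item in row.top_features.split(";"):
                fid, _, val = item.rpartition(":")
                top.append(FeatureContribution(feature_id=fid, sc=float(val)))
        records.append(
            SimilarityRecord(
                dataset_a=row.dataset_a,
                group_a=row.group_a,
                dataset_b=row.dataset_b,
                group_b=row.group_b,
                similarity=float(row.similarity),
                omega=float(row.weight_omega),
                sum_sc=float(row.sum_sc),
                n_pos=0,
                n_neg=0,
                top_features=top,
            )
        )
    return records
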