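"""Core containers and I/O for sample x feature count data.

The internal orientation is always samples x features: a "document" is a
sample and a "term" is a genus.  Counts are stored as floats so that
fractional, topic-assigned abundance tables flow through the same code
paths; integer inputs are preserved exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "TaxonomyTable",
    "TopicAbundanceTable",
    "DaResult",
    "read_count_table",
    "read_metadata",
    "read_taxonomy",
    "attach_metadata",
    "write_table",
]

_FLOAT_FMT = "%.17g"  # lossless float round-trip; integers print exactly


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} ID: {i!r}")
        seen.add(i)
    return ids


class CountTable:
    """A validated samples x features matrix of non-negative counts.

    Parameters
    ----------
    counts
        2-D array-like of non-negative, finite values, samples in rows.
    sample_ids, feature_ids
        Unique labels matching the matrix dimensions.
    group
        Optional per-sample categorical label (e.g. disease vs control).
    """

    def __init__(
        self,
        counts: np.ndarray,
        sample_ids: Sequence[str],
        feature_ids: Sequence[str],
        group: Sequence[str] | None = None,
    ) -> None:
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        self.sample_ids = _check_unique(sample_ids, "sample")
        self.feature_ids = _check_unique(feature_ids, "feature")
        if counts.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if not np.all(np.isfinite(counts)):
            d, v = np.argwhere(~np.isfinite(counts))[0]
            raise ValueError(
                f"non-finite count at sample {self.sample_ids[d]!r}, "
                f"feature {self.feature_ids[v]!r}"
            )
        if np.any(counts < 0):
            d, v = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[d]!r}, "
                f"feature {self.feature_ids[v]!r}"
            )
        self.counts = counts
        if group is not None:
            group = list(group)
            if len(group) != len(self.sample_ids):
                raise ValueError("group length does not match sample count")
        self.group: list | None = group

    # -- basic accessors ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def group_levels(self) -> list:
        if self.group is None:
            return []
        return sorted({g for g in self.group if g is not None})

    # -- manipulation ------------------------------------------------------
    def copy(self) -> "CountTable":
        return CountTable(
            self.counts.copy(),
            list(self.sample_ids),
            list(self.feature_ids),
            None if self.group is None else list(self.group),
        )

    def select_features(self, feature_ids: Sequence[str]) -> "CountTable":
        idx = [self.feature_ids.index(f) for f in feature_ids]
        return CountTable(
            self.counts[:, idx],
            list(self.sample_ids),
            [self.feature_ids[i] for i in idx],
            None if self.group is None else list(self.group),
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountTable(
            self.counts[idx, :],
            [self.sample_ids[i] for i in idx],
            list(self.feature_ids),
            None if self.group is None else [self.group[i] for i in idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.sample_ids, columns=self.feature_ids
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.feature_ids == other.feature_ids
            and np.array_equal(self.counts, other.counts)
            and self.group == other.group
        )

    def __repr__(self) -> str:
        return (
            f"CountTable({self.n_samples} samples x {self.n_features} features"
            + (", grouped)" if self.group is not None else ")")
        )


class TopicAbundanceTable:
    """Samples x topics matrix of reads assigned to topics (fractional)."""

    def __init__(
        self,
        values: np.ndarray,
        sample_ids: Sequence[str],
        topic_ids: Sequence[str],
        group: Sequence[str] | None = None,
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("assigned-read values must be finite and >= 0")
        self.values = values
        self.sample_ids = _check_unique(sample_ids, "sample")
        self.topic_ids = _check_unique(topic_ids, "topic")
        if values.shape != (len(self.sample_ids), len(self.topic_ids)):
            raise ValueError("values shape does not match ids")
        self.group = None if group is None else list(group)

    # aliases so DA code treats topics like features
    @property
    def counts(self) -> np.ndarray:
        return self.values

    @property
    def feature_ids(self) -> list[str]:
        return self.topic_ids

    @property
    def library_sizes(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.topic_ids)


@dataclass
class DaResult:
    """Per-feature differential-abundance statistics plus run metadata."""

    table: pd.DataFrame  # columns: feature, effect_log2, se, t, df, p, q, significant, degenerate
    meta: dict = field(default_factory=dict)

    COLUMNS = ["feature", "effect_log2", "se", "t", "df", "p", "q", "significant", "degenerate"]

    def to_dataframe(self) -> pd.DataFrame:
        return self.table.copy()

    def significant_features(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "feature"])


class TaxonomyTable:
    """feature_id -> ordered lineage of text labels (kingdom .. genus)."""

    def __init__(self, lineages: Mapping[str, Sequence[str]], ranks: Sequence[str]):
        self.ranks = [str(r) for r in ranks]
        self.lineages: dict[str, tuple[str, ...]] = {}
        for fid, lin in lineages.items():
            lin = tuple("" if x is None else str(x) for x in lin)
            if len(lin) != len(self.ranks):
                raise ValueError(
                    f"lineage for {fid!r} has length {len(lin)}, expected {len(self.ranks)}"
                )
            if fid in self.lineages:
                raise ValueError(f"duplicate feature ID in taxonomy: {fid!r}")
            self.lineages[str(fid)] = lin

    def label(self, feature_id: str, rank: str) -> str:
        if feature_id not in self.lineages:
            raise KeyError(f"feature {feature_id!r} absent from taxonomy")
        try:
            i = self.ranks.index(rank)
        except ValueError:
            raise ValueError(f"unknown rank {rank!r}; have {self.ranks}") from None
        return self.lineages[feature_id][i]

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.lineages


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_HDF5_MAGIC = b"\x89HDF\r\n\x1a\n"


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix == ".biom":
        return "biom"
    return "tsv"


def read_count_table(
    path: str | Path,
    format: str | None = None,
    orientation: str = "samples-in-rows",
) -> CountTable:
    """Read a count matrix from TSV, CSV, or BIOM (JSON or HDF5).

    ``orientation`` applies to the text formats; BIOM stores observations
    (features) in rows by specification and is normalized automatically.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = format or _infer_format(path)
    if fmt == "biom":
        return _read_biom(path)
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"unsupported format {fmt!r}")
    if orientation not in ("samples-in-rows", "features-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = "\t" if fmt == "tsv" else ","
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, float_precision="round_trip")
    mat = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            mat[:, j] = np.array([float(x) for x in df[col]])
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ValueError(
                f"non-numeric cell at row {bad!r}, column {col!r} in {path}"
            ) from None
    if orientation == "features-in-rows":
        mat = mat.T
        sample_ids, feature_ids = list(df.columns), list(df.index)
    else:
        sample_ids, feature_ids = list(df.index), list(df.columns)
    return CountTable(mat, sample_ids, feature_ids)


def _read_biom(path: Path) -> CountTable:
    with open(path, "rb") as fh:
        magic = fh.read(8)
    if magic == _HDF5_MAGIC:
        return _read_biom_hdf5(path)
    return _read_biom_json(path)


def _read_biom_json(path: Path) -> CountTable:
    with open(path) as fh:
        doc = json.load(fh)
    n_obs, n_samp = doc["shape"]
    feature_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    mat = np.zeros((n_obs, n_samp), dtype=float)
    if doc["matrix_type"] == "dense":
        mat[:] = np.asarray(doc["data"], dtype=float)
    elif doc["matrix_type"] == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = float(v)
    else:
        raise ValueError(f"unknown BIOM matrix_type {doc['matrix_type']!r}")
    # BIOM rows are observations (features) -> transpose to samples x features
    return CountTable(mat.T, sample_ids, feature_ids)


def _read_biom_hdf5(path: Path) -> CountTable:
    import h5py
    from scipy.sparse import csr_matrix

    with h5py.File(path, "r") as h5:
        feature_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in h5["observation/ids"][:]]
        sample_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in h5["sample/ids"][:]]
        grp = h5["observation/matrix"]
        mat = csr_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
            shape=(len(feature_ids), len(sample_ids)),
        ).toarray()
    return CountTable(mat.T, sample_ids, feature_ids)


def read_metadata(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a sample metadata table keyed by its first (ID) column."""
    path = Path(path)
    sep = "," if (format or _infer_format(path)) == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample ID in metadata: {dup!r}")
    return df


def read_taxonomy(path: str | Path, format: str | None = None) -> TaxonomyTable:
    """Read a taxonomy table: first column feature ID, remaining columns ranks."""
    path = Path(path)
    sep = "," if (format or _infer_format(path)) == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str).fillna("")
    return TaxonomyTable(
        {str(fid): tuple(row) for fid, row in df.iterrows()},
        ranks=[str(c) for c in df.columns],
    )


def attach_metadata(
    table: CountTable,
    metadata: Mapping[str, Mapping[str, object]] | pd.DataFrame,
    group_key: str,
    drop_uncovered: bool = False,
) -> CountTable:
    """Populate the per-sample group label from a metadata table.

    Sample order is preserved.  Samples missing from the metadata are an
    error unless ``drop_uncovered`` is set, in which case they are removed.
    """
    if isinstance(metadata, pd.DataFrame):
        records = {str(i): dict(row) for i, row in metadata.iterrows()}
    else:
        records = {str(k): dict(v) for k, v in metadata.items()}
    missing = [s for s in table.sample_ids if s not in records]
    if missing and not drop_uncovered:
        raise ValueError(
            f"metadata missing sample(s): {', '.join(map(repr, missing))}"
        )
    keep = [s for s in table.sample_ids if s in records]
    for s in keep:
        if group_key not in records[s]:
            raise ValueError(f"metadata for sample {s!r} lacks key {group_key!r}")
    idx = [table.sample_ids.index(s) for s in keep]
    return CountTable(
        table.counts[idx, :],
        keep,
        list(table.feature_ids),
        [records[s][group_key] for s in keep],
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_table(
    obj: CountTable | TopicAbundanceTable | DaResult,
    path: str | Path,
    format: str = "tsv",
) -> None:
    """Write a table to TSV/CSV (any table) or BIOM JSON (count tables).

    Round trip: ``read(write(x))`` reproduces the matrix to full float
    precision.
    """
    path = Path(path)
    if isinstance(obj, DaResult):
        if format not in ("tsv", "csv"):
            raise ValueError("DaResult supports tsv/csv only")
        sep = "\t" if format == "tsv" else ","
        obj.table.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)
        return
    if isinstance(obj, TopicAbundanceTable):
        df = obj.to_dataframe()
        if format not in ("tsv", "csv"):
            raise ValueError("TopicAbundanceTable supports tsv/csv only")
        sep = "\t" if format == "tsv" else ","
        df.to_csv(path, sep=sep, float_format=_FLOAT_FMT)
        return
    if isinstance(obj, CountTable):
        if format in ("tsv", "csv"):
            sep = "\t" if format == "tsv" else ","
            obj.to_dataframe().to_csv(path, sep=sep, float_format=_FLOAT_FMT)
        elif format == "biom":
            _write_biom_json(obj, path)
        else:
            raise ValueError(f"unsupported format {format!r}")
        return
    raise TypeError(f"cannot write object of type {type(obj).__name__}")


def _write_biom_json(table: CountTable, path: Path) -> None:
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "taxatopics",
        "date": "",
        "matrix_type": "dense",
        "matrix_element_type": "float",
        "shape": [table.n_features, table.n_samples],
        "rows": [{"id": f, "metadata": None} for f in table.feature_ids],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": table.counts.T.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_topic_table(path: str | Path, format: str = "tsv") -> TopicAbundanceTable:
    """Read a samples x topics table written by :func:`write_table`."""
    sep = "\t" if format == "tsv" else ","
    df = pd.read_csv(Path(path), sep=sep, index_col=0, float_precision="round_trip")
    return TopicAbundanceTable(
        df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]
    )
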