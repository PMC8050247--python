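"""Binary feature tables, phenotype metadata, and result files.

The central container is :class:`FeatureMatrix`: a strictly binary
(presence/absence) matrix with molecular features on the rows and samples on
the columns.  Absence must be encoded as 0 — missing values are not a concept
here, because the upstream feature extraction (spectral library search or
MS/MS clustering) already decides presence per sample.

Two on-disk dialects are supported:

* ``dense`` — tab-separated, first column = feature IDs, first row = sample
  IDs, matching common metabolomics bucket-table exports.
* ``sparse`` — MatrixMarket coordinate format plus two sidecar ID lists
  (``<base>.features.txt`` and ``<base>.samples.txt``, one ID per line),
  for repository-scale matrices where almost all entries are 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class ParseError(ValueError):
    """A file could not be interpreted in the declared dialect."""


class ValidationError(ValueError):
    """Parsed data violates a container invariant (e.g. a non-binary entry)."""


def _check_unique(ids: Sequence[str], axis: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {axis} ID {i!r}")
        seen.add(i)


@dataclass
class FeatureMatrix:
    """Binary features × samples matrix with named axes.

    Parameters
    ----------
    values
        Array of shape ``(n_features, n_samples)`` whose entries are exactly
        0 or 1.
    feature_ids, sample_ids
        Ordered, unique string identifiers for rows and columns.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValidationError("feature matrix must be two-dimensional")
        n_feat, n_samp = self.values.shape
        if len(self.feature_ids) != n_feat:
            raise ValidationError(
                f"{len(self.feature_ids)} feature IDs for {n_feat} rows"
            )
        if len(self.sample_ids) != n_samp:
            raise ValidationError(
                f"{len(self.sample_ids)} sample IDs for {n_samp} columns"
            )
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        bad = (self.values != 0) & (self.values != 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-binary value {self.values[i, j]!r} at feature "
                f"{self.feature_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        self.values = self.values.astype(np.int8)

    # -- convenience accessors -------------------------------------------------

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def column(self, sample_id: str) -> np.ndarray:
        """The binary profile of one sample, as a 1-D vector."""
        try:
            j = self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample ID {sample_id!r}") from None
        return self.values[:, j].copy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    def drop_features(self, feature_ids: Iterable[str]) -> "FeatureMatrix":
        drop = set(feature_ids)
        keep = [i for i, f in enumerate(self.feature_ids) if f not in drop]
        return FeatureMatrix(
            self.values[keep, :],
            [self.feature_ids[i] for i in keep],
            list(self.sample_ids),
        )

    def reorder_samples(self, sample_ids: Sequence[str]) -> "FeatureMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return FeatureMatrix(
            self.values[:, idx], list(self.feature_ids), list(sample_ids)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        return (
            self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass
class PhenotypeTable:
    """Sample → phenotype label and provenance metadata.

    ``samples`` is indexed by ``sample_id`` with columns ``label`` and
    ``dataset_id`` (the source study the sample came from).  ``standards``
    optionally maps a ``dataset_id`` to the feature IDs of internal-standard
    molecules spiked into that study's samples — the classic source of
    protocol-driven batch confounding.
    """

    samples: pd.DataFrame
    standards: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"label", "dataset_id"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValidationError(f"phenotype table missing columns {sorted(missing)}")
        if not self.samples.index.is_unique:
            dup = self.samples.index[self.samples.index.duplicated()][0]
            raise ValidationError(f"duplicate sample ID {dup!r}")
        self.samples = self.samples.copy()
        self.samples["label"] = self.samples["label"].astype(str)
        self.samples["dataset_id"] = self.samples["dataset_id"].astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.samples.index]

    @property
    def labels(self) -> np.ndarray:
        return self.samples["label"].to_numpy()

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.samples["label"]))

    def standard_feature_ids(self) -> set[str]:
        """Union of all internal-standard feature IDs across datasets."""
        out: set[str] = set()
        for ids in self.standards.values():
            out |= set(ids)
        return out


# -- readers / writers ---------------------------------------------------------


def read_feature_table(path: str | Path, dialect: str = "dense") -> FeatureMatrix:
    """Read a binary feature table.

    ``dialect="dense"`` expects a TSV with feature IDs in the first column and
    sample IDs in the header row.  ``dialect="sparse"`` expects a MatrixMarket
    coordinate file plus ``<base>.features.txt`` / ``<base>.samples.txt``
    sidecars; coordinates not listed are 0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "dense":
        return _read_dense(path)
    if dialect == "sparse":
        return _read_sparse(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_dense(path: Path) -> FeatureMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    cols = header.split("\t")
    if len(cols) < 2:
        raise ParseError(f"{path}:1: header row has no sample columns")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    values = np.empty(df.shape, dtype=np.int8)
    arr = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            v = arr[i, j]
            if v not in ("0", "1"):
                raise ValidationError(
                    f"non-binary value {v!r} at feature {df.index[i]!r}, "
                    f"sample {df.columns[j]!r}"
                )
            values[i, j] = int(v)
    return FeatureMatrix(values, list(df.index), list(df.columns))


def _sidecars(path: Path) -> tuple[Path, Path]:
    base = path.with_suffix("")
    return (
        base.with_suffix(".features.txt"),
        base.with_suffix(".samples.txt"),
    )


def _read_sparse(path: Path) -> FeatureMatrix:
    feat_path, samp_path = _sidecars(path)
    for p in (feat_path, samp_path):
        if not p.exists():
            raise ParseError(f"missing ID sidecar {p}")
    try:
        mat = scipy.io.mmread(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    dense = np.asarray(scipy.sparse.coo_matrix(mat).todense())
    feature_ids = feat_path.read_text().splitlines()
    sample_ids = samp_path.read_text().splitlines()
    return FeatureMatrix(dense, feature_ids, sample_ids)


def write_feature_table(
    matrix: FeatureMatrix, path: str | Path, dialect: str = "dense"
) -> None:
    """Write a :class:`FeatureMatrix`; inverse of :func:`read_feature_table`."""
    path = Path(path)
    if dialect == "dense":
        matrix.to_frame().to_csv(path, sep="\t")
    elif dialect == "sparse":
        coo = scipy.sparse.coo_matrix(matrix.values)
        with open(path, "wb") as fh:  # mmwrite appends .mtx to bare filenames
            scipy.io.mmwrite(fh, coo, field="integer")
        feat_path, samp_path = _sidecars(path)
        feat_path.write_text("\n".join(matrix.feature_ids) + "\n")
        samp_path.write_text("\n".join(matrix.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_phenotype_table(
    path: str | Path, standards_path: str | Path | None = None
) -> PhenotypeTable:
    """Read sample metadata (TSV: sample_id, label, dataset_id).

    ``standards_path`` optionally points to a two-column TSV mapping
    ``dataset_id`` to an internal-standard feature ID (one pair per line).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing 'sample_id' column")
    df = df.set_index("sample_id")
    standards: dict[str, set[str]] = {}
    if standards_path is not None:
        sdf = pd.read_csv(
            standards_path, sep="\t", dtype=str, names=["dataset_id", "feature_id"],
            comment="#",
        )
        for ds, grp in sdf.groupby("dataset_id"):
            standards[str(ds)] = set(grp["feature_id"])
    return PhenotypeTable(df, standards)


def write_phenotype_table(table: PhenotypeTable, path: str | Path) -> None:
    table.samples.rename_axis("sample_id").to_csv(path, sep="\t")


# -- alignment -----------------------------------------------------------------


def align_features(
    reference: FeatureMatrix, query: FeatureMatrix
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Put two matrices on a common feature axis.

    The output feature axis is the union of the inputs' feature IDs
    (reference order first, then query-only features in query order).
    A feature absent from one input is filled with 0 in that output —
    absence of evidence is absence, for binary presence calls.
    Column (sample) order is preserved.
    """
    ref_set = set(reference.feature_ids)
    union = list(reference.feature_ids) + [
        f for f in query.feature_ids if f not in ref_set
    ]
    if not union:
        raise ValidationError("empty feature union")
    return _expand_to(reference, union), _expand_to(query, union)


def _expand_to(matrix: FeatureMatrix, feature_ids: list[str]) -> FeatureMatrix:
    pos = {f: i for i, f in enumerate(matrix.feature_ids)}
    values = np.zeros((len(feature_ids), matrix.n_samples), dtype=np.int8)
    for i, f in enumerate(feature_ids):
        j = pos.get(f)
        if j is not None:
            values[i, :] = matrix.values[j, :]
    return FeatureMatrix(values, feature_ids, list(matrix.sample_ids))


# -- result files --------------------------------------------------------------


def write_result(result, path: str | Path, format: str = "json") -> None:
    """Serialize a decomposition result or biomarker report.

    ``format="json"`` writes the full structure (lossless round trip via
    :func:`read_result`).  ``format="tsv"`` writes one row per selected
    ingredient / ranked biomarker, with scalar metadata in ``#``-prefixed
    header comments so the TSV also round-trips.
    """
    path = Path(path)
    payload = result.to_dict()
    payload["__type__"] = type(result).__name__
    if format == "json":
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif format == "tsv":
        _write_result_tsv(payload, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _write_result_tsv(payload: Mapping, path: Path) -> None:
    table = payload.get("table")
    meta = {k: v for k, v in payload.items() if k != "table"}
    lines = [f"# {json.dumps(meta, sort_keys=True)}"]
    if table:
        cols = list(table[0].keys())
        lines.append("\t".join(cols))
        for row in table:
            lines.append("\t".join(str(row[c]) for c in cols))
    path.write_text("\n".join(lines) + "\n")


def read_result(path: str | Path, format: str = "json"):
    """Inverse of :func:`write_result`."""
    from .classification import BiomarkerReport
    from .decomposition import DecompositionResult

    path = Path(path)
    if format == "json":
        payload = json.loads(path.read_text())
    elif format == "tsv":
        payload = _read_result_tsv(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    kind = payload.pop("__type__")
    cls = {
        "DecompositionResult": DecompositionResult,
        "BiomarkerReport": BiomarkerReport,
    }[kind]
    return cls.from_dict(payload)


def _read_result_tsv(path: Path) -> dict:
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("# "):
        raise ParseError(f"{path}:1: missing metadata comment line")
    payload = json.loads(lines[0][2:])
    table = []
    if len(lines) > 1:
        cols = lines[1].split("\t")
        for line in lines[2:]:
            if not line:
                continue
            table.append(dict(zip(cols, line.split("\t"))))
    payload["table"] = table
    return payload
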