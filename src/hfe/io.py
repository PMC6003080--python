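"""Readers and writers for the tabular formats the pipeline touches.

Supported formats: the classic QIIME-style OTU table (TSV, leading
``#OTU ID`` header, optionally with a trailing ``taxonomy`` column), BIOM
v1 JSON (dense and sparse), a two-column taxonomy TSV, a two-column label
TSV, and the engineered feature table (samples x selected features, scaled
relative abundances with a trailing ``class`` column).

On disk OTU tables are oriented OTUs x samples; in memory they are held
samples x features, so there is exactly one transposition at the I/O
boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "LabelVector",
    "FormatError",
    "read_otu_table",
    "read_taxonomy",
    "read_labels",
    "normalize_relative",
    "write_feature_table",
    "write_otu_table",
    "write_labels",
    "write_taxonomy",
]

_NORM_TOL = 1e-9


class FormatError(ValueError):
    """Malformed input file (carries a line number where known)."""


@dataclass
class AbundanceTable:
    """Samples x features matrix of non-negative abundances.

    ``data`` is a pandas DataFrame indexed by sample id with feature-id
    columns.  ``normalized`` is True when every sample row sums to 1
    within 1e-9.
    """

    data: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise FormatError("duplicate sample ids")
        if self.data.columns.has_duplicates:
            raise FormatError("duplicate feature ids")
        if (self.data.values < 0).any():
            raise ValueError("negative abundance values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[list(sample_ids)], self.normalized)

    def subset_features(self, feature_ids: Sequence[str]) -> "AbundanceTable":
        return AbundanceTable(self.data[list(feature_ids)], self.normalized)


@dataclass
class LabelVector:
    """Per-sample categorical class labels."""

    mapping: dict[str, str]
    classes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.classes:
            self.classes = tuple(sorted(set(self.mapping.values())))
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")

    def for_samples(self, sample_ids: Sequence[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.mapping]
        if missing:
            raise KeyError(f"samples without labels: {missing[:5]}")
        return np.array([self.mapping[s] for s in sample_ids], dtype=object)

    def subset(self, sample_ids: Sequence[str]) -> "LabelVector":
        return LabelVector(
            {s: self.mapping[s] for s in sample_ids}, classes=self.classes
        )


def _read_classic_tsv(path: Path) -> tuple[pd.DataFrame, dict[str, str] | None]:
    with open(path) as fh:
        lines = fh.read().splitlines()
    # tolerate a QIIME comment line before the header
    start = 0
    while start < len(lines) and lines[start].startswith("#") and not lines[
        start
    ].startswith("#OTU ID"):
        start += 1
    if start >= len(lines) or not lines[start].startswith("#OTU ID"):
        raise FormatError(f"{path}: first header cell must be '#OTU ID'")
    header = lines[start].split("\t")
    has_tax = header and header[-1].strip().lower() == "taxonomy"
    sample_ids = header[1 : -1 if has_tax else None]
    rows: list[list[float]] = []
    otu_ids: list[str] = []
    taxonomy: dict[str, str] = {}
    for lineno, line in enumerate(lines[start + 1 :], start=start + 2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise FormatError(f"{path}:{lineno}: ragged row ({len(cells)} cells)")
        otu = cells[0]
        if has_tax:
            taxonomy[otu] = cells[-1].strip()
            cells = cells[:-1]
        try:
            rows.append([float(c) for c in cells[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
        otu_ids.append(otu)
    if len(set(otu_ids)) != len(otu_ids):
        raise FormatError(f"{path}: duplicate OTU ids")
    df = pd.DataFrame(rows, index=otu_ids, columns=sample_ids)
    return df, (taxonomy if has_tax else None)


def _read_biom_v1(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("rows", "columns", "data", "shape", "matrix_type"):
        if key not in doc:
            raise FormatError(f"{path}: BIOM v1 document missing {key!r}")
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    n_obs, n_samp = doc["shape"]
    mat = np.zeros((n_obs, n_samp), dtype=float)
    if doc["matrix_type"] == "sparse":
        for i, j, v in doc["data"]:
            mat[i, j] = v
    elif doc["matrix_type"] == "dense":
        mat[:] = np.asarray(doc["data"], dtype=float)
    else:
        raise FormatError(f"{path}: unknown matrix_type {doc['matrix_type']!r}")
    return pd.DataFrame(mat, index=otu_ids, columns=sample_ids)


def read_otu_table(
    path: str | Path, *, relative: bool | None = None
) -> tuple[AbundanceTable, dict[str, str] | None]:
    """Read an OTU table from classic TSV or BIOM v1 JSON.

    Returns the table (transposed to samples x features) plus the embedded
    taxonomy column (OTU id -> lineage string) if the TSV carried one.

    ``relative`` overrides auto-detection of whether the table already
    holds relative abundances (rows summing to ~1) rather than counts.
    """
    path = Path(path)
    if path.suffix.lower() in (".biom", ".json"):
        disk, taxonomy = _read_biom_v1(path), None
    else:
        disk, taxonomy = _read_classic_tsv(path)
    table = AbundanceTable(disk.T)
    if relative is None:
        sums = table.values().sum(axis=1)
        relative = bool(len(sums) and np.all(np.abs(sums - 1.0) <= 1e-6))
    table.normalized = relative
    return table, taxonomy


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """Read a 2-column Greengenes taxonomy TSV: OTU id -> lineage string."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
            if cells[0] in out:
                raise FormatError(f"{path}:{lineno}: duplicate OTU id {cells[0]!r}")
            out[cells[0]] = cells[1].strip()
    if not out:
        raise FormatError(f"{path}: empty taxonomy file")
    return out


def read_labels(path: str | Path) -> LabelVector:
    """Read a 2-column label TSV: sample id -> class."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
            mapping[cells[0]] = cells[1].strip()
    return LabelVector(mapping)


def normalize_relative(table: AbundanceTable) -> AbundanceTable:
    """Convert each sample row to relative abundances (row sum 1).

    Idempotent on already-normalized tables; an all-zero sample is an error
    because its composition is undefined.
    """
    vals = table.values()
    sums = vals.sum(axis=1)
    zero = np.nonzero(sums == 0)[0]
    if zero.size:
        raise ValueError(f"all-zero sample(s): {[table.sample_ids[i] for i in zero[:5]]}")
    if table.normalized and np.all(np.abs(sums - 1.0) <= _NORM_TOL):
        return table
    out = pd.DataFrame(
        vals / sums[:, None], index=table.data.index, columns=table.data.columns
    )
    return AbundanceTable(out, normalized=True)


def write_feature_table(
    table: AbundanceTable,
    labels: LabelVector,
    path: str | Path,
    *,
    scale: float = 1e5,
    decimals: int = 2,
) -> None:
    """Write the engineered feature table.

    One row per sample, one column per selected feature plus a trailing
    ``class`` column; values are relative abundances multiplied by ``scale``
    (default 1e5), printed with 2 decimals.
    """
    if not table.normalized:
        raise ValueError("feature table must be normalized before writing")
    if scale <= 0:
        raise ValueError("scale must be positive")
    classes = labels.for_samples(table.sample_ids)
    with open(path, "w") as fh:
        fh.write("\t".join(["#SampleID", *table.feature_ids, "class"]) + "\n")
        for sid, row, cls in zip(table.sample_ids, table.values(), classes):
            cells = [f"{v * scale:.{decimals}f}" for v in row]
            fh.write("\t".join([sid, *cells, cls]) + "\n")


def write_otu_table(
    table: AbundanceTable,
    path: str | Path,
    taxonomy: Mapping[str, str] | None = None,
) -> None:
    """Write a classic OTU-table TSV (OTUs x samples on disk)."""
    disk = table.data.T
    header = ["#OTU ID", *disk.columns]
    if taxonomy is not None:
        header.append("taxonomy")
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, header)) + "\n")
        for otu, row in zip(disk.index, disk.to_numpy()):
            cells = [_fmt_count(v) for v in row]
            if taxonomy is not None:
                cells.append(taxonomy[otu])
            fh.write("\t".join([str(otu), *cells]) + "\n")


def _fmt_count(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def write_labels(labels: LabelVector, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, cls in labels.mapping.items():
            fh.write(f"{sid}\t{cls}\n")


def write_taxonomy(taxonomy: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for otu, lin in taxonomy.items():
            fh.write(f"{otu}\t{lin}\n")
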