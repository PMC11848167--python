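"""Readers and writers for the on-disk artifacts.

Formats are deliberately plain text: Matrix Market coordinate files for the
sparse count matrix (1-based on disk, 0-based in memory), GMT for gene-set
collections, and UTF-8 TSV with ``NA`` for missing values everywhere else.
Every reader validates shape/label agreement and every writer round-trips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


@dataclass
class CountMatrix:
    """Sparse gene x cell integer count matrix with aligned label lists."""

    genes: list[str]
    cells: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.counts.nnz and (self.counts.data < 0).any():
            raise FormatError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None


#: column -> (dtype, allowed values or None) for the tables the pipeline reads.
EDGE_SCHEMA: Mapping[str, tuple[str, tuple | None]] = {
    "source": ("str", None),
    "target": ("str", None),
    "sign": ("str", ("+", "-", "unknown")),
    "mechanism": ("str", None),
    "tissue": ("str", None),
}
LR_SCHEMA: Mapping[str, tuple[str, tuple | None]] = {
    "ligand": ("str", None),
    "receptor": ("str", None),
}
CELL_META_SCHEMA: Mapping[str, tuple[str, tuple | None]] = {
    "cell_id": ("str", None),
    "subject_id": ("str", None),
    "cell_type": ("str", None),
    "condition": ("str", ("AD", "HC")),
    "sex": ("str", ("M", "F")),
    "braak": ("float", None),
    "age": ("float", None),
    "mmse": ("float", None),
}
SUBJECT_SCHEMA: Mapping[str, tuple[str, tuple | None]] = {
    "subject_id": ("str", None),
    "group": ("str", ("control", "early_ad", "intermediate_ad", "late_ad")),
    "condition": ("str", ("AD", "HC")),
    "sex": ("str", ("M", "F")),
    "braak": ("float", None),
    "age": ("float", None),
    "mmse": ("float", None),
}


def read_counts(mtx_path, genes_path, cells_path) -> CountMatrix:
    """Read a Matrix Market counts file with one-label-per-line gene/cell files."""
    mtx_path, genes_path, cells_path = Path(mtx_path), Path(genes_path), Path(cells_path)
    mat = scipy.io.mmread(mtx_path)
    genes = _read_labels(genes_path)
    cells = _read_labels(cells_path)
    if mat.shape != (len(genes), len(cells)):
        raise FormatError(
            f"{mtx_path.name} declares {mat.shape[0]} x {mat.shape[1]} but "
            f"{genes_path.name} has {len(genes)} lines and "
            f"{cells_path.name} has {len(cells)} lines"
        )
    dense_ok = np.allclose(mat.data, np.round(mat.data)) if mat.nnz else True
    if not dense_ok:
        raise FormatError(f"{mtx_path.name} contains non-integer entries")
    return CountMatrix(genes, cells, sp.csr_matrix(mat, dtype=np.int64))


def write_counts(cm: CountMatrix, mtx_path, genes_path, cells_path) -> None:
    scipy.io.mmwrite(str(mtx_path), cm.counts.tocoo(), field="integer")
    Path(genes_path).write_text("".join(g + "\n" for g in cm.genes))
    Path(cells_path).write_text("".join(c + "\n" for c in cm.cells))


def _read_labels(path: Path) -> list[str]:
    return [line.rstrip("\n") for line in path.read_text().splitlines()]


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets with an optional description per set."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> member genes."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"line {lineno}: expected >= 3 tab-separated fields")
        name, desc, *members = fields
        if name in sets:
            raise FormatError(f"line {lineno}: duplicate set name {name!r}")
        seen: list[str] = []
        for m in members:
            if m in seen:
                warnings.warn(f"set {name!r}: duplicate member {m!r} removed")
            elif m:
                seen.append(m)
        sets[name] = seen
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = []
    for name, members in collection.items():
        desc = collection.descriptions.get(name, "")
        lines.append("\t".join([name, desc, *members]))
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_table(path, schema: Mapping[str, tuple[str, tuple | None]]) -> pd.DataFrame:
    """Read a TSV with a header row, coercing and validating per ``schema``.

    Unknown columns are preserved verbatim; row order is preserved. Lines
    beginning with ``#`` (provenance headers) are skipped.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False,
                     na_values=["NA"])
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise FormatError(
            f"missing required column(s) {missing}; expected {list(schema)}, "
            f"found {list(df.columns)}"
        )
    for col, (dtype, allowed) in schema.items():
        if dtype == "float":
            df[col] = pd.to_numeric(df[col], errors="raise")
        elif dtype == "int":
            df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
        if allowed is not None:
            bad = set(df[col].dropna()) - set(allowed)
            if bad:
                raise FormatError(
                    f"column {col!r}: invalid value(s) {sorted(bad)}; "
                    f"allowed: {list(allowed)}"
                )
    return df


def write_table(df: pd.DataFrame, path, provenance: Mapping[str, object] | None = None) -> None:
    """Write a TSV with an optional ``# key: value`` provenance header block."""
    path = Path(path)
    with path.open("w") as fh:
        if provenance:
            for key, value in provenance.items():
                fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")
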