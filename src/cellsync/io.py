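"""Readers and writers for the on-disk formats the pipeline touches.

Count matrices are stored on disk in the 10x Genomics dialect of the
matrix-market triplet: ``matrix.mtx`` holds features (genes) as rows and
barcodes (cells) as columns, with ``features.tsv`` and ``barcodes.tsv``
sidecars.  In memory the orientation is always cells x genes; the readers
and writers transpose at the boundary.  Gzipped variants of all three
files are accepted transparently.

Gene sets use the GMT format: one set per line, tab separated, with the
set name in column 1, a free-text description in column 2 and the member
gene symbols from column 3 onward.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "GeneSetCollection",
    "FormatError",
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(ids) != len(pd.unique(ids)):
        dup = pd.Series(ids).value_counts()
        dup = dup[dup > 1].index.tolist()[:5]
        raise FormatError(f"duplicate {what} identifiers (e.g. {dup})")


@dataclass
class CountMatrix:
    """Sparse UMI count matrix, cells x genes.

    Parameters
    ----------
    values
        Non-negative integer counts, shape ``(n_cells, n_genes)``; any
        scipy sparse matrix is accepted and converted to CSR.
    cell_ids
        Unique cell barcodes, length ``n_cells``.
    gene_ids
        Unique gene identifiers, length ``n_genes``.
    gene_symbols
        Optional display symbols parallel to ``gene_ids``; defaults to the
        identifiers themselves.  Symbols need not be unique.
    """

    values: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    gene_symbols: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.values.eliminate_zeros()
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.gene_symbols is None:
            self.gene_symbols = self.gene_ids.copy()
        else:
            self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        n_cells, n_genes = self.values.shape
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"{len(self.cell_ids)} cell ids for a matrix with {n_cells} rows"
            )
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for a matrix with {n_genes} columns"
            )
        if len(self.gene_symbols) != n_genes:
            raise FormatError("gene_symbols length does not match gene_ids")
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")
        if self.values.nnz and self.values.data.min() < 0:
            raise FormatError("negative values in count matrix")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset(
        self,
        cells: np.ndarray | None = None,
        genes: np.ndarray | None = None,
    ) -> "CountMatrix":
        """Return a submatrix; ``cells``/``genes`` are boolean masks or index arrays."""
        v = self.values
        cid, gid, gsym = self.cell_ids, self.gene_ids, self.gene_symbols
        if cells is not None:
            v = v[cells]
            cid = cid[cells]
        if genes is not None:
            v = v[:, genes]
            gid = gid[genes]
            gsym = gsym[genes]
        return CountMatrix(v, cid, gid, gsym)


class GeneSetCollection(Mapping):
    """An ordered, named collection of gene sets.

    Maps set name to an ordered list of gene symbols.  Duplicate symbols
    within a set are dropped (first occurrence wins); a set that is empty
    after de-duplication is rejected.
    """

    def __init__(self, sets: Mapping[str, Sequence[str]], label: str = ""):
        self.label = label
        self._sets: dict[str, list[str]] = {}
        for name, genes in sets.items():
            if name in self._sets:
                raise FormatError(f"duplicate gene-set name {name!r}")
            deduped = list(dict.fromkeys(g for g in genes if g))
            if len(deduped) < len([g for g in genes if g]):
                warnings.warn(
                    f"gene set {name!r}: duplicate genes dropped", stacklevel=2
                )
            if not deduped:
                raise FormatError(f"gene set {name!r} is empty after de-duplication")
            self._sets[name] = deduped

    def __getitem__(self, name: str) -> list[str]:
        return self._sets[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __repr__(self) -> str:
        lbl = f" {self.label!r}" if self.label else ""
        return f"<GeneSetCollection{lbl}: {len(self)} sets>"

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def subset_to(self, universe: Sequence[str]) -> "GeneSetCollection":
        """Restrict every set to genes present in ``universe`` (order kept).

        Genes missing from the universe are dropped per set and the drop
        counts logged; sets emptied entirely are removed.
        """
        uni = set(universe)
        out: dict[str, list[str]] = {}
        for name, genes in self._sets.items():
            kept = [g for g in genes if g in uni]
            if len(kept) < len(genes):
                logger.info(
                    "gene set %s: %d/%d genes absent from matrix, dropped",
                    name, len(genes) - len(kept), len(genes),
                )
            if kept:
                out[name] = kept
            else:
                logger.warning("gene set %s: no genes in matrix, set removed", name)
        return GeneSetCollection(out, label=self.label)

    def union(self) -> list[str]:
        """All genes across sets, first-seen order, de-duplicated."""
        return list(dict.fromkeys(g for genes in self._sets.values() for g in genes))


def _find(dir: Path, stem: str) -> Path:
    for suffix in ("", ".gz"):
        p = dir / (stem + suffix)
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}[.gz] not found in {dir}")


def _read_tsv_column(path: Path) -> pd.DataFrame:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        return pd.DataFrame()
    return pd.DataFrame([ln.split("\t") for ln in lines])


def read_counts(dir: str | Path) -> CountMatrix:
    """Read a 10x-style matrix-market triplet directory into cells x genes.

    Expects ``matrix.mtx``, ``barcodes.tsv`` and ``features.tsv`` (or
    ``genes.tsv``), any of them optionally gzipped.  The features file may
    carry one column (id), two (id, symbol) or three (id, symbol, type).
    Input ordering of barcodes and features is preserved.
    """
    dir = Path(dir)
    mtx_path = _find(dir, "matrix.mtx")
    barcodes = _read_tsv_column(_find(dir, "barcodes.tsv"))
    try:
        features = _read_tsv_column(_find(dir, "features.tsv"))
    except FileNotFoundError:
        features = _read_tsv_column(_find(dir, "genes.tsv"))

    m = scipy.io.mmread(str(mtx_path))  # features x barcodes on disk
    n_feat, n_bc = m.shape
    if n_feat != len(features) or n_bc != len(barcodes):
        raise FormatError(
            f"matrix is {n_feat} features x {n_bc} barcodes but sidecars list "
            f"{len(features)} features and {len(barcodes)} barcodes"
        )
    cell_ids = barcodes[0].to_numpy(dtype=object) if len(barcodes) else np.array([], object)
    if len(features):
        gene_ids = features[0].to_numpy(dtype=object)
        symbols = (
            features[1].to_numpy(dtype=object) if features.shape[1] > 1 else None
        )
    else:
        gene_ids, symbols = np.array([], object), None
    values = sp.csr_matrix(m.T)
    if values.nnz and not np.allclose(values.data, np.round(values.data)):
        raise FormatError("matrix contains non-integer values")
    values = values.astype(np.int64)
    return CountMatrix(values, cell_ids, gene_ids, symbols)


def write_counts(matrix: CountMatrix, dir: str | Path) -> None:
    """Write ``matrix`` as an uncompressed 10x-style triplet (genes x cells on disk)."""
    dir = Path(dir)
    dir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(dir / "matrix.mtx"), sp.coo_matrix(matrix.values.T), field="integer"
    )
    with open(dir / "barcodes.tsv", "w") as fh:
        for bc in matrix.cell_ids:
            fh.write(f"{bc}\n")
    with open(dir / "features.tsv", "w") as fh:
        for gid, sym in zip(matrix.gene_ids, matrix.gene_symbols):
            fh.write(f"{gid}\t{sym}\tGene Expression\n")


def read_gmt(file: str | Path, label: str | None = None) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Each non-blank line must have at least three tab-separated fields
    (name, description, one or more genes); fewer raises
    :class:`FormatError`.  An empty file yields an empty collection.
    """
    file = Path(file)
    opener = gzip.open if file.suffix == ".gz" else open
    sets: dict[str, list[str]] = {}
    with opener(file, "rt") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{file.name}:{lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise FormatError(f"{file.name}:{lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in fields[2:] if g]
    return GeneSetCollection(sets, label=label if label is not None else file.stem)


def write_gmt(collection: GeneSetCollection, file: str | Path) -> None:
    file = Path(file)
    file.parent.mkdir(parents=True, exist_ok=True)
    with open(file, "w") as fh:
        for name, genes in collection.items():
            fh.write("\t".join([name, collection.label or "na", *genes]) + "\n")
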