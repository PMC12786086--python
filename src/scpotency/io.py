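"""Readers/writers for the formats the pipeline touches and the shared data model.

Count matrices travel as 10x-style triplets (MatrixMarket ``matrix.mtx`` plus
``features.tsv`` and ``barcodes.tsv``, optionally gzipped) or as dense TSV with
gene rows and barcode columns.  The codon-optimised transgene, when present, is
an ordinary feature row distinguished only by :attr:`CountMatrix.transgene_id`,
mirroring alignment against a custom reference that carries the transgene as an
extra contig.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

GENOTYPES = ("control", "KO", "patient")
TREATMENTS = ("NT", "RK", "CAG")

MTX_NAME = "matrix.mtx"
FEATURES_NAME = "features.tsv"
BARCODES_NAME = "barcodes.tsv"


class FormatError(ValueError):
    """Raised when an on-disk input violates its format contract."""


@dataclass
class CountMatrix:
    """Sparse non-negative integer gene x cell UMI matrix.

    Parameters
    ----------
    values
        ``(n_genes, n_cells)`` sparse integer matrix of UMI counts.
    gene_ids
        Ordered, unique feature names (symbols; case-sensitive).
    cell_barcodes
        Ordered, unique cell barcodes.
    transgene_id
        Name of the vector-derived transgene feature, or ``None`` when the
        matrix carries no transgene row.
    """

    values: sp.csr_matrix
    gene_ids: list[str]
    cell_barcodes: list[str]
    transgene_id: str | None = None

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_barcodes = [str(b) for b in self.cell_barcodes]
        self.validate()

    # -- basic properties -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def validate(self) -> None:
        if self.values.shape != (len(self.gene_ids), len(self.cell_barcodes)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} features x {len(self.cell_barcodes)} barcodes"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene identifiers")
        if len(set(self.cell_barcodes)) != len(self.cell_barcodes):
            raise FormatError("duplicate cell barcodes")
        data = self.values.data
        if data.size:
            if np.any(data < 0):
                raise FormatError("negative counts")
            if not np.allclose(data, np.round(data)):
                raise FormatError("non-integral counts")
        if self.transgene_id is not None and self.transgene_id not in self.gene_ids:
            raise FormatError(
                f"transgene_id {self.transgene_id!r} is not a feature of the matrix"
            )

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            self.values[:, idx],
            self.gene_ids,
            [self.cell_barcodes[i] for i in idx],
            self.transgene_id,
        )

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.gene_ids == other.gene_ids
            and self.cell_barcodes == other.cell_barcodes
            and self.transgene_id == other.transgene_id
            and (self.values != other.values).nnz == 0
        )


@dataclass
class MarkerTable:
    """Cell-type marker definitions: (cell_type, gene, direction) triples."""

    entries: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["cell_type", "gene", "direction"])
    )

    def __post_init__(self) -> None:
        bad = set(self.entries["direction"]) - {"positive", "negative"}
        if bad:
            raise FormatError(f"invalid marker direction token(s): {sorted(bad)}")
        ndup = self.entries.duplicated().sum()
        if ndup:
            warnings.warn(f"collapsed {ndup} duplicate marker entries", stacklevel=2)
            self.entries = self.entries.drop_duplicates(ignore_index=True)

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.entries["cell_type"].unique())

    def genes(self, cell_type: str, direction: str = "positive") -> list[str]:
        e = self.entries
        sel = (e["cell_type"] == cell_type) & (e["direction"] == direction)
        return e.loc[sel, "gene"].tolist()


# -- helpers ---------------------------------------------------------------

def _open_maybe_gz(path: Path, mode: str = "rt"):
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _find_triplet_file(d: Path, stem: str) -> Path | None:
    for cand in (d / stem, d / (stem + ".gz")):
        if cand.exists():
            return cand
    return None


def _read_tsv_column(path: Path) -> list[str]:
    with _open_maybe_gz(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


# -- operations ------------------------------------------------------------

def read_counts(path: str | Path, transgene_name: str | None = None) -> CountMatrix:
    """Read a count matrix from a 10x triplet directory or a dense TSV file.

    A triplet directory holds ``matrix.mtx(.gz)`` (MatrixMarket coordinate
    integer), ``features.tsv(.gz)`` and ``barcodes.tsv(.gz)``.  A dense TSV has
    a header row of barcodes and a first column of gene ids.
    """
    path = Path(path)
    if path.is_dir():
        mtx = _find_triplet_file(path, MTX_NAME)
        feats = _find_triplet_file(path, FEATURES_NAME)
        bcs = _find_triplet_file(path, BARCODES_NAME)
        missing = [
            n for n, p in ((MTX_NAME, mtx), (FEATURES_NAME, feats), (BARCODES_NAME, bcs))
            if p is None
        ]
        if missing:
            raise FormatError(f"triplet directory {path} missing {missing}")
        try:
            with _open_maybe_gz(mtx, "rb") as fh:
                values = sp.csr_matrix(scipy.io.mmread(fh))
        except Exception as exc:  # scipy raises plain ValueError on bad headers
            raise FormatError(f"malformed MatrixMarket file {mtx}: {exc}") from exc
        # features file may carry (id, name, type) columns; first column is the id
        gene_ids = _read_tsv_column(feats)
        barcodes = _read_tsv_column(bcs)
        if values.shape != (len(gene_ids), len(barcodes)):
            raise FormatError(
                f"matrix is {values.shape[0]}x{values.shape[1]} but features has "
                f"{len(gene_ids)} rows and barcodes has {len(barcodes)} rows"
            )
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        gene_ids = [str(g) for g in df.index]
        barcodes = [str(c) for c in df.columns]
        values = sp.csr_matrix(df.to_numpy())

    transgene_id = None
    if transgene_name is not None and transgene_name in gene_ids:
        transgene_id = transgene_name
    return CountMatrix(values, gene_ids, barcodes, transgene_id)


def write_counts(m: CountMatrix, path: str | Path, gzipped: bool = True) -> None:
    """Write a 10x-style triplet; inverse of :func:`read_counts` on directories."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if gzipped else ""
    coo = m.values.tocoo()
    with _open_maybe_gz(path / (MTX_NAME + suffix), "wt") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n%\n")
        fh.write(f"{m.n_genes} {m.n_cells} {coo.nnz}\n")
        # MatrixMarket is 1-based, column-major by convention
        order = np.lexsort((coo.row, coo.col))
        for i, j, v in zip(coo.row[order], coo.col[order], coo.data[order]):
            fh.write(f"{i + 1} {j + 1} {int(v)}\n")
    with _open_maybe_gz(path / (FEATURES_NAME + suffix), "wt") as fh:
        for g in m.gene_ids:
            ftype = "Transgene" if g == m.transgene_id else "Gene Expression"
            fh.write(f"{g}\t{g}\t{ftype}\n")
    with _open_maybe_gz(path / (BARCODES_NAME + suffix), "wt") as fh:
        fh.writelines(b + "\n" for b in m.cell_barcodes)


def read_cell_metadata(
    path: str | Path, barcodes: list[str] | None = None
) -> pd.DataFrame:
    """Read per-cell metadata (barcode, sample, genotype, treatment) from TSV.

    Genotype/treatment tokens are trimmed of whitespace and validated against
    the controlled vocabularies; when ``barcodes`` is given, metadata barcodes
    not present in the count matrix are reported as an error rather than
    silently dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["barcode", "sample", "genotype", "treatment"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"metadata file missing required column(s) {missing}")
    for col in required:
        df[col] = df[col].str.strip()
    for col, allowed in (("genotype", GENOTYPES), ("treatment", TREATMENTS)):
        bad = df.loc[~df[col].isin(allowed)]
        if len(bad):
            first = bad.iloc[0]
            raise FormatError(
                f"unknown {col} token {first[col]!r} (barcode {first['barcode']}); "
                f"allowed: {allowed}"
            )
    if df["barcode"].duplicated().any():
        raise FormatError("duplicate barcodes in metadata")
    if barcodes is not None:
        unknown = set(df["barcode"]) - set(barcodes)
        if unknown:
            raise FormatError(
                f"{len(unknown)} metadata barcode(s) absent from the count matrix, "
                f"e.g. {sorted(unknown)[:3]}"
            )
    return df.reset_index(drop=True)


def read_markers(path: str | Path) -> MarkerTable:
    """Read a marker table TSV with columns cell_type, gene, direction."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["cell_type", "gene", "direction"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"marker file missing required column(s) {missing}")
    for col in required:
        df[col] = df[col].str.strip()
    return MarkerTable(df[required].copy())


def write_markers(markers: MarkerTable, path: str | Path) -> None:
    markers.entries.to_csv(path, sep="\t", index=False)


def default_marker_table() -> MarkerTable:
    """Built-in retinal marker stand-in (canonical published biomarkers).

    A configurable starting point for real organoid data, not a reproduction
    of any specific study's marker list; synthetic datasets ship their own
    generated marker table instead.
    """
    return read_markers(Path(__file__).parent / "data" / "retina_markers.tsv")
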