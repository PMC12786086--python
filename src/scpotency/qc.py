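"""Cell-level quality control and expression normalisation.

Cells with fewer than 500 UMIs, more than 20% mitochondrial counts or more
than 20% ribosomal counts are excluded (strict inequalities: a 500-UMI cell
and a cell at exactly 20% are kept).  Expression is normalised to counts per
million and analysed on the log2(CPM + 1) scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix

MITO_PREFIX = ("MT-",)
RIBO_PREFIXES = ("RPS", "RPL")


@dataclass
class QCThresholds:
    """QC exclusion thresholds; defaults follow the strict-inequality rule
    "<500 UMIs, >20% mitochondrial, >20% ribosomal excluded"."""

    min_umis: int = 500
    max_pct_mito: float = 0.20
    max_pct_ribo: float = 0.20

    def __post_init__(self) -> None:
        if self.min_umis < 0:
            raise ValueError("min_umis must be >= 0")
        for name in ("max_pct_mito", "max_pct_ribo"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class ExpressionMatrix:
    """Dense gene x cell expression matrix on a declared scale."""

    values: np.ndarray
    gene_ids: list[str]
    cell_barcodes: list[str]
    scale: str  # "CPM" or "log2CPM1"
    transgene_id: str | None = None

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def gene_values(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index(gene)]


def mito_gene_mask(gene_ids: list[str]) -> np.ndarray:
    return np.array([g.startswith(MITO_PREFIX) for g in gene_ids])


def ribo_gene_mask(gene_ids: list[str]) -> np.ndarray:
    return np.array([g.startswith(RIBO_PREFIXES) for g in gene_ids])


def compute_qc(m: CountMatrix) -> pd.DataFrame:
    """Per-cell QC metrics: total_umis, pct_mito, pct_ribo.

    Mitochondrial genes are recognised by the "MT-" name prefix and ribosomal
    genes by "RPS"/"RPL" prefixes.  Transgene counts count toward the total
    (they are real molecules).  An all-zero cell has both fractions set to 0.
    """
    totals = np.asarray(m.values.sum(axis=0)).ravel()
    mito = np.asarray(m.values[mito_gene_mask(m.gene_ids)].sum(axis=0)).ravel()
    ribo = np.asarray(m.values[ribo_gene_mask(m.gene_ids)].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
        pct_ribo = np.where(totals > 0, ribo / np.maximum(totals, 1), 0.0)
    return pd.DataFrame(
        {
            "barcode": m.cell_barcodes,
            "total_umis": totals.astype(int),
            "pct_mito": pct_mito,
            "pct_ribo": pct_ribo,
        }
    )


def filter_cells(qc: pd.DataFrame, th: QCThresholds | None = None) -> np.ndarray:
    """Boolean keep-mask over the QC table.

    Boundary semantics follow the exclusion rule literally: exactly
    ``min_umis`` UMIs is kept and exactly ``max_pct`` fractions are kept.
    """
    th = th or QCThresholds()
    keep = (
        (qc["total_umis"].to_numpy() >= th.min_umis)
        & (qc["pct_mito"].to_numpy() <= th.max_pct_mito)
        & (qc["pct_ribo"].to_numpy() <= th.max_pct_ribo)
    )
    return keep


def cpm(m: CountMatrix) -> ExpressionMatrix:
    """Counts-per-million normalisation; requires QC-passing (nonzero) cells."""
    totals = np.asarray(m.values.sum(axis=0)).ravel()
    if np.any(totals == 0):
        bad = [m.cell_barcodes[i] for i in np.flatnonzero(totals == 0)[:3]]
        raise ValueError(
            f"zero-total cell(s) present (e.g. {bad}); filter cells before cpm()"
        )
    dense = np.asarray(m.values.todense(), dtype=float)
    values = dense / totals[None, :] * 1e6
    return ExpressionMatrix(values, list(m.gene_ids), list(m.cell_barcodes), "CPM", m.transgene_id)


def log_transform(e: ExpressionMatrix) -> ExpressionMatrix:
    """log2(CPM + 1) transform of a CPM matrix."""
    if e.scale != "CPM":
        raise ValueError(f"log_transform expects a CPM matrix, got scale={e.scale!r}")
    return ExpressionMatrix(
        np.log2(e.values + 1.0), e.gene_ids, e.cell_barcodes, "log2CPM1", e.transgene_id
    )


def qc_report(qc: pd.DataFrame, keep: np.ndarray) -> pd.DataFrame:
    out = qc.copy()
    out["qc_pass"] = keep
    return out
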