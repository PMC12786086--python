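"""Vector transduction profiling, two-model disease DEG calling, and
restoration-toward-control scoring — the potency read-outs of the analysis.

A cell is transgene-positive when its vector-transcript expression reaches
1e-4 CPM (for UMI data this is any nonzero count).  A disease-model DEG is a
gene significantly changed (BH-adjusted Wilcoxon p below alpha) with signed
fold-change magnitude >= 1.2 in BOTH the knockout and patient contrasts, in
the same direction.  A disease-model DEG counts as restored when treated
group-mean expression moves at least 20% of the disease-to-control gap back
toward control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qc import ExpressionMatrix
from .stats import benjamini_hochberg, rank_sum_genes, signed_fold_change

POSITIVITY_CPM = 1e-4
DEFAULT_ALPHA = 0.05
DEFAULT_FC_THRESHOLD = 1.2
DEFAULT_RESTORE_THRESHOLD = 0.2
MIN_CELLS_PER_SIDE = 20


# -- transduction ----------------------------------------------------------

def transgene_positive(e: ExpressionMatrix, threshold_cpm: float = POSITIVITY_CPM) -> np.ndarray:
    """Boolean per-cell transgene positivity at the CPM threshold."""
    if e.transgene_id is None:
        raise ValueError("expression matrix carries no transgene feature")
    vals = e.gene_values(e.transgene_id)
    if e.scale == "log2CPM1":
        vals = np.exp2(vals) - 1.0
    return vals >= threshold_cpm


def transduction_profile(cells: pd.DataFrame, positives: np.ndarray) -> pd.DataFrame:
    """Percent transgene-positive per sample, overall and per cell type.

    ``cells`` must carry sample and cell_type columns aligned with
    ``positives``.  Cell types with zero cells in a sample are absent from the
    output rather than reported as 0/0.
    """
    df = cells.copy()
    df["positive"] = np.asarray(positives, dtype=bool)
    rows = []
    for (sample, ct), sub in df.groupby(["sample", "cell_type"]):
        rows.append(
            {
                "sample": sample,
                "cell_type": ct,
                "n_cells": len(sub),
                "n_positive": int(sub["positive"].sum()),
            }
        )
    for sample, sub in df.groupby("sample"):
        rows.append(
            {
                "sample": sample,
                "cell_type": "all",
                "n_cells": len(sub),
                "n_positive": int(sub["positive"].sum()),
            }
        )
    out = pd.DataFrame(rows)
    out["pct_positive"] = 100.0 * out["n_positive"] / out["n_cells"]
    return out.sort_values(["sample", "cell_type"], ignore_index=True)


def transgene_level_in_positive(
    e: ExpressionMatrix, cells: pd.DataFrame, positives: np.ndarray
) -> pd.DataFrame:
    """Mean transgene log2(CPM+1) in positive cells, per sample x cell type."""
    if e.transgene_id is None:
        raise ValueError("expression matrix carries no transgene feature")
    vals = e.gene_values(e.transgene_id)
    if e.scale == "CPM":
        vals = np.log2(vals + 1.0)
    df = cells.copy()
    df["level"] = vals
    df = df[np.asarray(positives, dtype=bool)]
    out = (
        df.groupby(["sample", "cell_type"])["level"]
        .agg(n_positive="size", mean_level_in_positive="mean")
        .reset_index()
    )
    return out


# -- differential expression ----------------------------------------------

def call_degs(
    e: ExpressionMatrix,
    cells: pd.DataFrame,
    cell_type: str,
    disease_mask: np.ndarray,
    control_mask: np.ndarray,
    contrast: str = "KO_vs_CON",
    alpha: float = DEFAULT_ALPHA,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    min_cells: int = MIN_CELLS_PER_SIDE,
    fc_offset: float = 0.01,
) -> pd.DataFrame:
    """Per-gene disease-vs-control test within one cell type.

    Wilcoxon rank-sum on log2(CPM+1), BH over tested genes, signed fold change
    on arithmetic mean CPM.  Genes expressed in neither side are skipped.
    A gene is a DEG when p_adj < alpha and |signed_fc| >= fc_threshold.
    """
    if e.scale != "CPM":
        raise ValueError("call_degs expects a CPM matrix")
    in_type = (cells["cell_type"] == cell_type).to_numpy()
    a_idx = np.flatnonzero(in_type & np.asarray(disease_mask))
    b_idx = np.flatnonzero(in_type & np.asarray(control_mask))
    if len(a_idx) < min_cells or len(b_idx) < min_cells:
        raise ValueError(
            f"cell type {cell_type!r}: need >= {min_cells} cells per side, "
            f"got disease={len(a_idx)}, control={len(b_idx)}"
        )
    a = e.values[:, a_idx]
    b = e.values[:, b_idx]
    expressed = (a.sum(axis=1) > 0) | (b.sum(axis=1) > 0)
    genes = [g for g, keep in zip(e.gene_ids, expressed) if keep and g != e.transgene_id]
    rows = np.array([e.gene_index(g) for g in genes])
    if rows.size == 0:
        return pd.DataFrame(
            columns=["gene", "cell_type", "contrast", "mean_disease", "mean_control",
                     "signed_fc", "p_raw", "p_adj", "direction", "is_deg"]
        )
    p = rank_sum_genes(np.log2(a[rows] + 1.0), np.log2(b[rows] + 1.0))
    p_adj = benjamini_hochberg(p)
    mean_a = a[rows].mean(axis=1)
    mean_b = b[rows].mean(axis=1)
    fc = np.array(
        [signed_fold_change(ma, mb, fc_offset) for ma, mb in zip(mean_a, mean_b)]
    )
    out = pd.DataFrame(
        {
            "gene": genes,
            "cell_type": cell_type,
            "contrast": contrast,
            "mean_disease": mean_a,
            "mean_control": mean_b,
            "signed_fc": fc,
            "p_raw": p,
            "p_adj": p_adj,
            "direction": np.where(fc > 0, "up", "down"),
        }
    )
    out["is_deg"] = (out["p_adj"] < alpha) & (np.abs(out["signed_fc"]) >= fc_threshold)
    return out


def intersect_disease_degs(degs_ko: pd.DataFrame, degs_pt: pd.DataFrame) -> pd.DataFrame:
    """Genes that are DEGs in both contrasts with concordant direction."""
    ko = degs_ko[degs_ko["is_deg"]][["gene", "cell_type", "direction"]]
    pt = degs_pt[degs_pt["is_deg"]][["gene", "cell_type", "direction"]]
    merged = ko.merge(pt, on=["gene", "cell_type", "direction"])
    return merged.drop_duplicates(ignore_index=True)


def deg_direction_counts(degs: pd.DataFrame) -> dict[str, int]:
    """Up/down/total counts of a (disease-model) DEG table."""
    up = int((degs["direction"] == "up").sum())
    down = int((degs["direction"] == "down").sum())
    return {"up": up, "down": down, "total": up + down}


# -- restoration -----------------------------------------------------------

@dataclass
class RestorationConfig:
    threshold: float = DEFAULT_RESTORE_THRESHOLD
    mode: str = "both"  # require both vectors ("both") or either ("any")
    positives_only: bool = False  # treated means over transgene-positive cells only
    log_scale_means: bool = False  # group means on log2(CPM+1) instead of CPM

    def __post_init__(self) -> None:
        if self.mode not in ("both", "any"):
            raise ValueError("mode must be 'both' or 'any'")


def restoration_score(m_control: float, m_disease: float, m_treated: float) -> tuple[float, bool]:
    """Fraction of the disease-to-control gap recovered by treatment.

    Returns (improvement, degenerate).  When control and disease means are
    equal there is no gap to recover; improvement is 0 with the degenerate
    flag set.  Values below 0 mean worsening, above 1 overshoot.
    """
    if min(m_control, m_disease, m_treated) < 0:
        raise ValueError("means must be non-negative")
    gap = m_control - m_disease
    if gap == 0:
        return 0.0, True
    return (m_treated - m_disease) / gap, False


def report_fraction(n_restored: int, n_total: int) -> float:
    """Restored percentage as reported: 100 x restored / total."""
    if n_total == 0:
        return float("nan")
    return 100.0 * n_restored / n_total


def group_means(
    e: ExpressionMatrix,
    cells: pd.DataFrame,
    cell_type: str,
    genes: list[str],
    masks: dict[str, np.ndarray],
    log_scale: bool = False,
) -> pd.DataFrame:
    """Arithmetic group-mean expression (CPM by default) per gene x group."""
    in_type = (cells["cell_type"] == cell_type).to_numpy()
    rows = np.array([e.gene_index(g) for g in genes], dtype=int)
    out = {}
    for name, mask in masks.items():
        idx = np.flatnonzero(in_type & np.asarray(mask))
        if idx.size == 0:
            raise ValueError(f"group {name!r} has no {cell_type} cells")
        vals = e.values[rows][:, idx]
        if log_scale:
            vals = np.log2(vals + 1.0)
        out[name] = vals.mean(axis=1)
    return pd.DataFrame(out, index=genes)


def classify_restored(
    disease_degs: pd.DataFrame,
    means: pd.DataFrame,
    cfg: RestorationConfig | None = None,
) -> tuple[pd.DataFrame, float]:
    """Score every disease-model DEG for restoration by each vector.

    ``means`` is indexed by gene with columns control, disease, RK, CAG
    (group-mean CPM).  Returns the per-gene record table and the restored
    percentage 100 x restored / total.
    """
    cfg = cfg or RestorationConfig()
    records = []
    for gene in disease_degs["gene"]:
        m = means.loc[gene]
        imp_rk, deg_rk = restoration_score(m["control"], m["disease"], m["RK"])
        imp_cag, deg_cag = restoration_score(m["control"], m["disease"], m["CAG"])
        ok_rk = imp_rk >= cfg.threshold
        ok_cag = imp_cag >= cfg.threshold
        restored = (ok_rk and ok_cag) if cfg.mode == "both" else (ok_rk or ok_cag)
        records.append(
            {
                "gene": gene,
                "m_control": m["control"],
                "m_disease": m["disease"],
                "m_RK": m["RK"],
                "m_CAG": m["CAG"],
                "improvement_RK": imp_rk,
                "improvement_CAG": imp_cag,
                "restored": restored,
                "overshoot": bool(restored and (imp_rk > 1.0 or imp_cag > 1.0)),
                "degenerate": bool(deg_rk or deg_cag),
            }
        )
    table = pd.DataFrame(records)
    n_restored = int(table["restored"].sum()) if len(table) else 0
    return table, report_fraction(n_restored, len(table))


def full_rescue_flags(
    disease_degs: pd.DataFrame,
    e: ExpressionMatrix,
    cells: pd.DataFrame,
    cell_type: str,
    treated_mask: np.ndarray,
    control_mask: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-gene "no longer significantly different from control" flags.

    Wilcoxon treated-vs-control on log2(CPM+1) within the cell type, BH over
    the disease-model DEG set only; the flag is True when the adjusted p is
    at or above alpha.
    """
    if e.scale != "CPM":
        raise ValueError("full_rescue_flags expects a CPM matrix")
    genes = disease_degs.loc[disease_degs["cell_type"] == cell_type, "gene"].tolist()
    if not genes:
        return pd.DataFrame(columns=["gene", "cell_type", "p_raw", "p_adj", "full_rescue"])
    in_type = (cells["cell_type"] == cell_type).to_numpy()
    t_idx = np.flatnonzero(in_type & np.asarray(treated_mask))
    c_idx = np.flatnonzero(in_type & np.asarray(control_mask))
    if t_idx.size < MIN_CELLS_PER_SIDE or c_idx.size < MIN_CELLS_PER_SIDE:
        raise ValueError(
            f"cell type {cell_type!r}: need >= {MIN_CELLS_PER_SIDE} cells per side"
        )
    rows = np.array([e.gene_index(g) for g in genes])
    p = rank_sum_genes(
        np.log2(e.values[rows][:, t_idx] + 1.0),
        np.log2(e.values[rows][:, c_idx] + 1.0),
    )
    p_adj = benjamini_hochberg(p)
    return pd.DataFrame(
        {
            "gene": genes,
            "cell_type": cell_type,
            "p_raw": p,
            "p_adj": p_adj,
            "full_rescue": p_adj >= alpha,
        }
    )
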