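"""Synthetic retinal-organoid scRNA-seq experiments with known ground truth.

The generator emulates the design of an AAV vector-potency study: one control
organoid plus non-treated (NT), photoreceptor-promoter-treated (RK) and
ubiquitous-promoter-treated (CAG) disease organoids, each a single sample.
Counts are negative-binomial (gamma-Poisson) draws around cell-type expression
profiles; disease samples carry planted differential expression in rods and
cones; treated samples move a known subset of those planted genes back toward
control — but only inside transgene-positive cells, so the realised bulk
effect is diluted by the per-cell-type transduction rate, exactly the
confounder the downstream restoration scoring has to confront.

Every random choice is recorded in :class:`SimTruth` so downstream stages can
be scored for parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, MarkerTable, write_counts, write_markers

# Fig 3B-style day-280 organoid composition: rods dominate, then cones and
# Mueller glia; the remaining interneuron/progenitor classes share the rest.
DEFAULT_PROPORTIONS = {
    "Rods": 0.31,
    "Cones": 0.19,
    "MullerGlia": 0.13,
    "Bipolar": 0.10,
    "Amacrine": 0.08,
    "Horizontal": 0.07,
    "Progenitors": 0.07,
    "Other": 0.05,
}

# Rhodopsin-kinase promoter: photoreceptor-restricted with modest Mueller glia
# activity; CAG: strong and ubiquitous (~half of all cells positive).
DEFAULT_RK_PROFILE = {
    "Rods": 0.21,
    "Cones": 0.21,
    "MullerGlia": 0.10,
    "Bipolar": 0.02,
    "Amacrine": 0.02,
    "Horizontal": 0.02,
    "Progenitors": 0.02,
    "Other": 0.02,
}
DEFAULT_CAG_PROFILE = {t: 0.50 for t in DEFAULT_PROPORTIONS}

TRANSGENE_NAME = "optiKCNV2"


@dataclass
class SimConfig:
    """Study conditions for one simulated scRNA-seq project."""

    n_cells_per_sample: int = 2000
    cell_type_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    n_genes: int = 2000  # endogenous features incl. the MT-/RPS/RPL nuisance genes
    n_mito_genes: int = 10
    n_ribo_genes: int = 20
    baseline_mean_log_params: tuple[float, float] = (0.0, 1.0)
    nb_dispersion: float = 2.0  # gamma shape; var = mu + mu^2 / dispersion
    library_size_params: tuple[float, float] = (math.log(20000.0), 0.25)
    markers_per_type: int = 8
    marker_fold: float = 8.0
    marker_base_log_boost: float = 2.0  # markers are drawn from a high-expression stratum
    marker_off_scale: float = 0.02  # residual marker expression outside the native type
    n_true_degs_per_celltype: int = 200  # planted in rods and in cones
    deg_fold_range: tuple[float, float] = (1.5, 2.5)
    transduction_profile: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            **{("RK", t): p for t, p in DEFAULT_RK_PROFILE.items()},
            **{("CAG", t): p for t, p in DEFAULT_CAG_PROFILE.items()},
        }
    )
    transgene_expression_mean: dict[str, float] = field(
        default_factory=lambda: {"RK": 12.0, "CAG": 12.0}
    )
    fraction_restored: float = 0.2
    improvement_beta: tuple[float, float] = (5.0, 7.0)  # scaled to [0, 1.2]
    improvement_scale: float = 1.2
    mito_beta: tuple[float, float] = (2.0, 38.0)
    ribo_beta: tuple[float, float] = (3.0, 37.0)
    pct_low_quality: float = 0.05
    genotype_arms: tuple[str, ...] = ("KO",)
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.cell_type_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cell_type_proportions sum to {total}, expected 1")
        if self.deg_fold_range[0] < 1.2:
            raise ValueError("deg_fold_range low end must be >= 1.2")
        if self.deg_fold_range[0] > self.deg_fold_range[1]:
            raise ValueError("deg_fold_range must be (low, high) with low <= high")
        for key, p in self.transduction_profile.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"transduction probability {key} = {p} outside [0, 1]")
        if not 0.0 <= self.fraction_restored <= 1.0:
            raise ValueError("fraction_restored must lie in [0, 1]")
        if not 0.0 <= self.pct_low_quality <= 1.0:
            raise ValueError("pct_low_quality must lie in [0, 1]")
        bad = set(self.genotype_arms) - {"KO", "patient"}
        if bad:
            raise ValueError(f"unknown genotype arm(s) {sorted(bad)}")
        n_types = len(self.cell_type_proportions)
        n_regular = self.n_genes - self.n_mito_genes - self.n_ribo_genes
        needed = self.markers_per_type * n_types + 2 * self.n_true_degs_per_celltype
        if needed > n_regular:
            raise ValueError(
                f"infeasible config: {needed} marker+DEG genes needed but only "
                f"{n_regular} regular genes available"
            )

    @property
    def cell_types(self) -> list[str]:
        return list(self.cell_type_proportions)


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    cells: pd.DataFrame  # barcode, sample, genotype, treatment, true_type, true_transduced, forced_low_quality
    degs: pd.DataFrame  # cell_type, gene, signed_fold
    improvements: pd.DataFrame  # cell_type, gene, treatment, improvement

    def restored_fraction(self, threshold: float = 0.2, mode: str = "both") -> dict[str, float]:
        """True restored fraction per cell type under the scoring rule."""
        out = {}
        for ct, sub in self.improvements.groupby("cell_type"):
            wide = sub.pivot(index="gene", columns="treatment", values="improvement")
            if mode == "both":
                restored = (wide >= threshold).all(axis=1)
            else:
                restored = (wide >= threshold).any(axis=1)
            out[ct] = float(restored.mean()) if len(wide) else float("nan")
        return out


@dataclass
class SimulatedExperiment:
    counts: CountMatrix
    cells: pd.DataFrame  # barcode, sample, genotype, treatment
    markers: MarkerTable
    truth: SimTruth
    config: SimConfig


def _gene_names(cfg: SimConfig) -> list[str]:
    n_regular = cfg.n_genes - cfg.n_mito_genes - cfg.n_ribo_genes
    names = [f"G{i:05d}" for i in range(n_regular)]
    names += [f"MT-G{i:02d}" for i in range(cfg.n_mito_genes)]
    names += [
        (f"RPS-G{i:02d}" if i % 2 == 0 else f"RPL-G{i:02d}")
        for i in range(cfg.n_ribo_genes)
    ]
    return names


def _sample_plan(cfg: SimConfig) -> list[tuple[str, str, str]]:
    """(sample_id, genotype, treatment) rows of the experiment design."""
    plan = []
    prefix = {"KO": "KO", "patient": "PT"}
    for i, arm in enumerate(cfg.genotype_arms):
        plan.append((f"CON-{i + 1}", "control", "NT"))
        for trt in ("NT", "RK", "CAG"):
            plan.append((f"{prefix[arm]}-{trt}", arm, trt))
    return plan


def simulate_experiment(cfg: SimConfig) -> SimulatedExperiment:
    """Simulate one full vector-potency experiment with ground truth.

    Identical configs (including seed) yield identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    types = cfg.cell_types
    n_types = len(types)
    gene_names = _gene_names(cfg)
    n_regular = cfg.n_genes - cfg.n_mito_genes - cfg.n_ribo_genes
    mito_idx = np.arange(n_regular, n_regular + cfg.n_mito_genes)
    ribo_idx = np.arange(n_regular + cfg.n_mito_genes, cfg.n_genes)
    all_gene_names = gene_names + [TRANSGENE_NAME]

    # baseline relative expression of the regular genes (shared across samples)
    loc, scale = cfg.baseline_mean_log_params
    base = rng.lognormal(loc, scale, size=n_regular)
    mito_w = rng.lognormal(0.0, 0.5, size=cfg.n_mito_genes)
    mito_w /= mito_w.sum()
    ribo_w = rng.lognormal(0.0, 0.5, size=cfg.n_ribo_genes)
    ribo_w /= ribo_w.sum()

    # marker genes: a contiguous block per cell type, boosted marker_fold-fold
    # in their own type and drawn from a high-expression stratum (canonical
    # markers such as RHO/ARR3 are among the most abundant transcripts)
    marker_genes: dict[str, list[int]] = {}
    cursor = 0
    for t in types:
        marker_genes[t] = list(range(cursor, cursor + cfg.markers_per_type))
        cursor += cfg.markers_per_type
    base[:cursor] = rng.lognormal(loc + cfg.marker_base_log_boost, 0.5, size=cursor)

    # planted disease DEGs in photoreceptors, disjoint from markers and each other
    deg_types = [t for t in ("Rods", "Cones") if t in types] or types[:1]
    pool = rng.permutation(np.arange(cursor, n_regular))
    deg_rows = []
    deg_idx: dict[str, np.ndarray] = {}
    deg_fold: dict[str, np.ndarray] = {}
    start = 0
    for t in deg_types:
        idx = np.sort(pool[start : start + cfg.n_true_degs_per_celltype])
        start += cfg.n_true_degs_per_celltype
        mag = rng.uniform(*cfg.deg_fold_range, size=len(idx))
        sign = rng.choice([1.0, -1.0], size=len(idx))
        deg_idx[t] = idx
        deg_fold[t] = np.where(sign > 0, mag, -mag)
        for g, f in zip(idx, deg_fold[t]):
            deg_rows.append({"cell_type": t, "gene": gene_names[g], "signed_fold": f})

    # restoration ground truth: per planted DEG, per treatment
    a_imp, b_imp = cfg.improvement_beta
    imp_rows = []
    improvement: dict[str, dict[str, np.ndarray]] = {}
    for t in deg_types:
        n_deg = len(deg_idx[t])
        restored = rng.random(n_deg) < cfg.fraction_restored
        improvement[t] = {}
        for trt in ("RK", "CAG"):
            imp = np.where(
                restored, cfg.improvement_scale * rng.beta(a_imp, b_imp, size=n_deg), 0.0
            )
            improvement[t][trt] = imp
            for g, v in zip(deg_idx[t], imp):
                imp_rows.append(
                    {"cell_type": t, "gene": gene_names[g], "treatment": trt, "improvement": v}
                )

    # expression profiles: control / disease / treated+transduced per cell type
    all_marker_idx = np.arange(cursor)

    def profile(cell_type: str, diseased: bool, treatment: str | None) -> np.ndarray:
        # markers are near-exclusive: strongly expressed in their native type,
        # residual elsewhere (as canonical retinal markers behave)
        v = base.copy()
        v[all_marker_idx] *= cfg.marker_off_scale
        v[marker_genes[cell_type]] = base[marker_genes[cell_type]] * cfg.marker_fold
        if diseased and cell_type in deg_idx:
            idx, fold = deg_idx[cell_type], deg_fold[cell_type]
            dis = np.where(fold > 0, v[idx] * fold, v[idx] / np.abs(fold))
            if treatment is not None:
                imp = improvement[cell_type][treatment]
                dis = dis + imp * (v[idx] - dis)
            v = v.copy()
            v[idx] = dis
        return v / v.sum()

    plan = _sample_plan(cfg)
    type_p = np.array([cfg.cell_type_proportions[t] for t in types])
    n_cells = cfg.n_cells_per_sample

    blocks = []
    cell_rows = []
    for sample_id, genotype, treatment in plan:
        diseased = genotype != "control"
        t_idx = rng.choice(n_types, size=n_cells, p=type_p)
        lib = rng.lognormal(*cfg.library_size_params, size=n_cells)
        f_mito = rng.beta(*cfg.mito_beta, size=n_cells)
        f_ribo = rng.beta(*cfg.ribo_beta, size=n_cells)

        forced = rng.random(n_cells) < cfg.pct_low_quality
        fail_mode = rng.random(n_cells) < 0.5  # low library vs high mito
        lib = np.where(forced & fail_mode, rng.uniform(50, 400, size=n_cells), lib)
        f_mito = np.where(forced & ~fail_mode, rng.uniform(0.25, 0.45, size=n_cells), f_mito)

        if diseased and treatment in ("RK", "CAG"):
            p_trans = np.array(
                [cfg.transduction_profile.get((treatment, t), 0.0) for t in types]
            )
            transduced = rng.random(n_cells) < p_trans[t_idx]
        else:
            transduced = np.zeros(n_cells, dtype=bool)

        # expected endogenous counts, built per (type, transduced) stratum
        mean = np.zeros((cfg.n_genes + 1, n_cells))
        endo_scale = lib * np.clip(1.0 - f_mito - f_ribo, 0.0, 1.0)
        for ti, t in enumerate(types):
            for d in (False, True):
                sel = (t_idx == ti) & (transduced == d)
                if not sel.any():
                    continue
                prof = profile(t, diseased, treatment if (d and diseased) else None)
                mean[:n_regular, sel] = prof[:, None] * endo_scale[sel][None, :]
        mean[mito_idx] = mito_w[:, None] * (lib * f_mito)[None, :]
        mean[ribo_idx] = ribo_w[:, None] * (lib * f_ribo)[None, :]
        if treatment in ("RK", "CAG"):
            mean[-1, transduced] = cfg.transgene_expression_mean[treatment]

        lam = rng.gamma(cfg.nb_dispersion, mean / cfg.nb_dispersion)
        counts = rng.poisson(lam)
        blocks.append(sp.csr_matrix(counts))

        for i in range(n_cells):
            cell_rows.append(
                {
                    "barcode": f"{sample_id}:C{i:05d}",
                    "sample": sample_id,
                    "genotype": genotype,
                    "treatment": treatment,
                    "true_type": types[t_idx[i]],
                    "true_transduced": bool(transduced[i]),
                    "forced_low_quality": bool(forced[i]),
                }
            )

    values = sp.hstack(blocks, format="csr")
    truth_cells = pd.DataFrame(cell_rows)
    counts = CountMatrix(
        values,
        all_gene_names,
        truth_cells["barcode"].tolist(),
        transgene_id=TRANSGENE_NAME,
    )
    markers = MarkerTable(
        pd.DataFrame(
            [
                {"cell_type": t, "gene": gene_names[g], "direction": "positive"}
                for t in types
                for g in marker_genes[t]
            ]
        )
    )
    truth = SimTruth(
        cells=truth_cells,
        degs=pd.DataFrame(deg_rows, columns=["cell_type", "gene", "signed_fold"]),
        improvements=pd.DataFrame(
            imp_rows, columns=["cell_type", "gene", "treatment", "improvement"]
        ),
    )
    cells = truth_cells[["barcode", "sample", "genotype", "treatment"]].copy()
    return SimulatedExperiment(counts, cells, markers, truth, replace(cfg))


# -- persistence -----------------------------------------------------------

TRUTH_FILES = {
    "cells": "truth_cells.tsv",
    "degs": "truth_degs.tsv",
    "improvements": "truth_improvements.tsv",
}


def write_truth(t: SimTruth, path: str | Path) -> None:
    """Write the three ground-truth tables as TSV; lossless round trip."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    t.cells.to_csv(path / TRUTH_FILES["cells"], sep="\t", index=False)
    t.degs.to_csv(path / TRUTH_FILES["degs"], sep="\t", index=False)
    t.improvements.to_csv(path / TRUTH_FILES["improvements"], sep="\t", index=False)


def read_truth(path: str | Path) -> SimTruth:
    path = Path(path)
    cells = pd.read_csv(path / TRUTH_FILES["cells"], sep="\t")
    degs = pd.read_csv(path / TRUTH_FILES["degs"], sep="\t")
    improvements = pd.read_csv(path / TRUTH_FILES["improvements"], sep="\t")
    if len(degs) == 0:
        degs = pd.DataFrame(columns=["cell_type", "gene", "signed_fold"])
    if len(improvements) == 0:
        improvements = pd.DataFrame(columns=["cell_type", "gene", "treatment", "improvement"])
    return SimTruth(cells=cells, degs=degs, improvements=improvements)


def write_dataset(exp: SimulatedExperiment, path: str | Path) -> None:
    """Write the full dataset: 10x triplet, cell metadata, markers, truth."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_counts(exp.counts, path)
    exp.cells.to_csv(path / "cells.tsv", sep="\t", index=False)
    write_markers(exp.markers, path / "markers.tsv")
    write_truth(exp.truth, path)
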