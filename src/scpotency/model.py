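"""Model/results interface for the end-to-end potency analysis.

:class:`PotencyAnalysis` is constructed from a count matrix, per-cell
metadata, and a marker table (or directly from a simulated experiment);
``fit()`` runs QC -> normalisation -> annotation -> transduction profiling ->
disease-model DEG calling -> restoration scoring (+ optional enrichment) and
returns a :class:`PotencyResults` carrying every stage table, with
``summary()`` for a human-readable digest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotate import EmbeddingConfig, annotate_cells
from .enrichment import GeneSetCollection, run_ora
from .io import CountMatrix, MarkerTable, read_cell_metadata, read_counts, read_markers
from .potency import (
    DEFAULT_ALPHA,
    DEFAULT_FC_THRESHOLD,
    POSITIVITY_CPM,
    RestorationConfig,
    call_degs,
    classify_restored,
    deg_direction_counts,
    full_rescue_flags,
    group_means,
    intersect_disease_degs,
    transduction_profile,
    transgene_level_in_positive,
    transgene_positive,
)
from .qc import QCThresholds, compute_qc, cpm, filter_cells, log_transform, qc_report
from .simulate import SimConfig, SimulatedExperiment, simulate_experiment


@dataclass
class AnalysisConfig:
    """All tunable analysis parameters with their defaults."""

    qc: QCThresholds = field(default_factory=QCThresholds)
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    alpha: float = DEFAULT_ALPHA
    fc_threshold: float = DEFAULT_FC_THRESHOLD
    fc_offset: float = 0.01
    positivity_cpm: float = POSITIVITY_CPM
    restoration: RestorationConfig = field(default_factory=RestorationConfig)
    deg_cell_types: tuple[str, ...] = ("Rods", "Cones")
    min_cells: int = 20
    cluster_overrides: dict[int, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class PotencyAnalysis:
    """The vector-potency model for one scRNA-seq project.

    Parameters
    ----------
    counts
        Gene x cell UMI matrix, optionally carrying the transgene feature.
    cell_meta
        Per-cell frame with barcode, sample, genotype, treatment.
    markers
        Cell-type marker table used for annotation.
    config
        Analysis parameters; defaults follow the documented thresholds.
    """

    def __init__(
        self,
        counts: CountMatrix,
        cell_meta: pd.DataFrame,
        markers: MarkerTable,
        config: AnalysisConfig | None = None,
    ) -> None:
        meta = cell_meta.set_index("barcode").reindex(counts.cell_barcodes)
        if meta[["sample", "genotype", "treatment"]].isna().any().any():
            missing = meta.index[meta["sample"].isna()][:3].tolist()
            raise ValueError(f"metadata missing for barcode(s) e.g. {missing}")
        self.counts = counts
        self.cell_meta = meta.reset_index(names="barcode")
        self.markers = markers
        self.config = config or AnalysisConfig()

    @classmethod
    def from_directory(
        cls,
        path: str | Path,
        transgene_name: str | None = "optiKCNV2",
        config: AnalysisConfig | None = None,
    ) -> "PotencyAnalysis":
        path = Path(path)
        counts = read_counts(path, transgene_name=transgene_name)
        meta = read_cell_metadata(path / "cells.tsv", barcodes=counts.cell_barcodes)
        markers = read_markers(path / "markers.tsv")
        return cls(counts, meta, markers, config)

    @classmethod
    def from_simulation(
        cls,
        sim: SimulatedExperiment | SimConfig | int,
        config: AnalysisConfig | None = None,
    ) -> "PotencyAnalysis":
        if isinstance(sim, int):
            sim = simulate_experiment(SimConfig(seed=sim))
        elif isinstance(sim, SimConfig):
            sim = simulate_experiment(sim)
        model = cls(sim.counts, sim.cells, sim.markers, config)
        model.truth = sim.truth
        return model

    # -- fitting ----------------------------------------------------------
    def fit(self, gene_sets: GeneSetCollection | None = None) -> "PotencyResults":
        cfg = self.config
        notices: list[str] = []

        # stage 1: QC
        qc = compute_qc(self.counts)
        keep = filter_cells(qc, cfg.qc)
        qc_table = qc_report(qc, keep)
        counts = self.counts.subset_cells(keep)
        cells = self.cell_meta.loc[keep].reset_index(drop=True)

        # stage 2: normalisation
        e_cpm = cpm(counts)
        e_log = log_transform(e_cpm)

        # stage 3: annotation
        ann = annotate_cells(e_log, self.markers, cfg.embedding, cfg.cluster_overrides)
        cells = cells.merge(ann, on="barcode", validate="one_to_one")

        # stage 4: transduction
        transduction = None
        transgene_levels = None
        positives = np.zeros(len(cells), dtype=bool)
        if counts.transgene_id is not None:
            positives = transgene_positive(e_cpm, cfg.positivity_cpm)
            transduction = transduction_profile(cells, positives)
            transgene_levels = transgene_level_in_positive(e_cpm, cells, positives)
        else:
            notices.append("no transgene feature: transduction stage skipped")
        cells["transgene_positive"] = positives

        genotype = cells["genotype"].to_numpy()
        treatment = cells["treatment"].to_numpy()
        disease_genotypes = sorted(set(genotype) - {"control"})
        control_mask = genotype == "control"

        # stage 5: disease-vs-control DEGs per photoreceptor type and genotype
        deg_tables = []
        cell_types = [t for t in cfg.deg_cell_types if (cells["cell_type"] == t).any()]
        for ct in cell_types:
            for g in disease_genotypes:
                contrast = ("KO" if g == "KO" else "PT") + "_vs_CON"
                deg_tables.append(
                    call_degs(
                        e_cpm,
                        cells,
                        ct,
                        disease_mask=(genotype == g) & (treatment == "NT"),
                        control_mask=control_mask,
                        contrast=contrast,
                        alpha=cfg.alpha,
                        fc_threshold=cfg.fc_threshold,
                        min_cells=cfg.min_cells,
                        fc_offset=cfg.fc_offset,
                    )
                )
        degs = (
            pd.concat(deg_tables, ignore_index=True)
            if deg_tables
            else pd.DataFrame(columns=["gene", "cell_type", "contrast", "is_deg", "direction"])
        )

        # stage 6: disease-model DEG set (two-model intersection when possible)
        dm_tables = []
        for ct in cell_types:
            sub = degs[degs["cell_type"] == ct]
            contrasts = sorted(sub["contrast"].unique())
            if len(contrasts) >= 2:
                dm = intersect_disease_degs(
                    sub[sub["contrast"] == contrasts[0]],
                    sub[sub["contrast"] == contrasts[1]],
                )
            else:
                dm = sub.loc[sub["is_deg"], ["gene", "cell_type", "direction"]].reset_index(
                    drop=True
                )
                notices.append(
                    f"{ct}: single disease model only; concordance filter not applied"
                )
            dm_tables.append(dm)
        disease_model_degs = (
            pd.concat(dm_tables, ignore_index=True)
            if dm_tables
            else pd.DataFrame(columns=["gene", "cell_type", "direction"])
        )

        # stage 7: restoration scoring + full-rescue flags
        treatments_present = set(treatment[np.isin(genotype, disease_genotypes)])
        restoration = None
        restored_fractions: dict[tuple[str, str], float] = {}
        full_rescue = None
        if {"RK", "CAG"} <= treatments_present:
            rest_tables = []
            rescue_tables = []
            for g in disease_genotypes:
                for ct in cell_types:
                    dm = disease_model_degs[disease_model_degs["cell_type"] == ct]
                    if dm.empty:
                        restored_fractions[(ct, g)] = float("nan")
                        continue
                    masks = {
                        "control": control_mask,
                        "disease": (genotype == g) & (treatment == "NT"),
                    }
                    for trt in ("RK", "CAG"):
                        m = (genotype == g) & (treatment == trt)
                        if cfg.restoration.positives_only:
                            m = m & positives
                        masks[trt] = m
                    means = group_means(
                        e_cpm, cells, ct, dm["gene"].tolist(), masks,
                        log_scale=cfg.restoration.log_scale_means,
                    )
                    table, pct = classify_restored(dm, means, cfg.restoration)
                    table.insert(1, "cell_type", ct)
                    table.insert(2, "genotype", g)
                    rest_tables.append(table)
                    restored_fractions[(ct, g)] = pct
                    for trt in ("RK", "CAG"):
                        fr = full_rescue_flags(
                            dm, e_cpm, cells, ct,
                            treated_mask=(genotype == g) & (treatment == trt),
                            control_mask=control_mask,
                            alpha=cfg.alpha,
                        )
                        fr.insert(2, "genotype", g)
                        fr.insert(3, "vector", trt)
                        rescue_tables.append(fr)
            restoration = (
                pd.concat(rest_tables, ignore_index=True) if rest_tables else None
            )
            full_rescue = (
                pd.concat(rescue_tables, ignore_index=True) if rescue_tables else None
            )
        else:
            notices.append(
                "no treated (RK+CAG) samples: pipeline stopped after the DEG stage"
            )

        # stage 8: optional enrichment of disease-model DEGs
        enrichment = None
        if gene_sets is not None and len(disease_model_degs):
            enr_tables = []
            for ct in cell_types:
                dm_genes = set(
                    disease_model_degs.loc[disease_model_degs["cell_type"] == ct, "gene"]
                )
                if not dm_genes:
                    continue
                in_type = (cells["cell_type"] == ct).to_numpy()
                detected = np.asarray(
                    (counts.values[:, np.flatnonzero(in_type)] > 0).sum(axis=1)
                ).ravel() > 0
                background = {g for g, d in zip(counts.gene_ids, detected) if d}
                res = run_ora(dm_genes & background, background, gene_sets)
                res.insert(0, "cell_type", ct)
                enr_tables.append(res)
            if enr_tables:
                enrichment = pd.concat(enr_tables, ignore_index=True)

        return PotencyResults(
            model=self,
            qc=qc_table,
            cells=cells,
            degs=degs,
            disease_model_degs=disease_model_degs,
            transduction=transduction,
            transgene_levels=transgene_levels,
            restoration=restoration,
            restored_fractions=restored_fractions,
            full_rescue=full_rescue,
            enrichment=enrichment,
            notices=notices,
        )


@dataclass
class PotencyResults:
    """Fitted result tables of one :class:`PotencyAnalysis`."""

    model: PotencyAnalysis
    qc: pd.DataFrame
    cells: pd.DataFrame
    degs: pd.DataFrame
    disease_model_degs: pd.DataFrame
    transduction: pd.DataFrame | None
    transgene_levels: pd.DataFrame | None
    restoration: pd.DataFrame | None
    restored_fractions: dict[tuple[str, str], float]
    full_rescue: pd.DataFrame | None
    enrichment: pd.DataFrame | None
    notices: list[str]

    # -- derived tables ---------------------------------------------------
    def composition(self) -> pd.DataFrame:
        """Per-sample cell-type composition in percent (rows sum to 100)."""
        tab = pd.crosstab(self.cells["sample"], self.cells["cell_type"])
        return 100.0 * tab.div(tab.sum(axis=1), axis=0)

    def deg_counts(self) -> pd.DataFrame:
        rows = []
        for ct, sub in self.disease_model_degs.groupby("cell_type"):
            rows.append({"cell_type": ct, **deg_direction_counts(sub)})
        return pd.DataFrame(rows, columns=["cell_type", "up", "down", "total"])

    def restoration_zscores(self) -> pd.DataFrame | None:
        """Per restored gene, z-scores of group-mean expression across groups."""
        if self.restoration is None:
            return None
        sub = self.restoration[self.restoration["restored"]]
        cols = ["m_control", "m_disease", "m_RK", "m_CAG"]
        vals = sub[cols].to_numpy(dtype=float)
        mu = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, ddof=0, keepdims=True)
        z = np.where(sd > 0, (vals - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        out = sub[["gene", "cell_type", "genotype"]].copy()
        out[["z_control", "z_disease", "z_RK", "z_CAG"]] = z
        return out.reset_index(drop=True)

    def report(self) -> dict:
        """Machine-readable run report of per-stage counts and thresholds."""
        cfg = self.model.config
        rep = {
            "version": __version__,
            "config_hash": cfg.config_hash(),
            "thresholds": cfg.to_dict(),
            "n_cells_input": len(self.qc),
            "n_cells_pass_qc": int(self.qc["qc_pass"].sum()),
            "n_clusters": int(self.cells["cluster"].nunique()),
            "cell_type_counts": self.cells["cell_type"].value_counts().to_dict(),
            "deg_counts": self.deg_counts().to_dict(orient="records"),
            "restored_fractions_pct": {
                f"{ct}|{g}": v for (ct, g), v in self.restored_fractions.items()
            },
            "notices": self.notices,
        }
        if self.transduction is not None:
            overall = self.transduction[self.transduction["cell_type"] == "all"]
            rep["pct_positive_per_sample"] = dict(
                zip(overall["sample"], overall["pct_positive"])
            )
        return rep

    def summary(self) -> str:
        """Human-readable digest of the fitted analysis."""
        lines = ["Vector potency analysis", "=" * 46]
        rep = self.report()
        lines.append(
            f"cells: {rep['n_cells_pass_qc']}/{rep['n_cells_input']} pass QC; "
            f"{rep['n_clusters']} clusters"
        )
        comp = self.composition().mean(axis=0).sort_values(ascending=False)
        lines.append("mean composition (%): " + ", ".join(f"{t} {v:.1f}" for t, v in comp.items()))
        if self.transduction is not None and "pct_positive_per_sample" in rep:
            lines.append(
                "transgene-positive (% of sample): "
                + ", ".join(f"{s} {v:.1f}" for s, v in rep["pct_positive_per_sample"].items())
            )
        for row in rep["deg_counts"]:
            lines.append(
                f"disease-model DEGs [{row['cell_type']}]: {row['total']} "
                f"({row['up']} up, {row['down']} down)"
            )
        for key, v in rep["restored_fractions_pct"].items():
            ct, g = key.split("|")
            lines.append(f"restored [{ct}, {g}]: {v:.1f}% of disease-model DEGs")
        for n in self.notices:
            lines.append(f"note: {n}")
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        """Write every result table as TSV with a provenance header line."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = f"# scpotency {__version__} config={self.model.config.config_hash()}\n"
        tables = {
            "qc_report.tsv": self.qc,
            "cells.tsv": self.cells,
            "deg_table.tsv": self.degs,
            "disease_model_degs.tsv": self.disease_model_degs,
            "transduction_profile.tsv": self.transduction,
            "transgene_levels.tsv": self.transgene_levels,
            "restoration_table.tsv": self.restoration,
            "full_rescue.tsv": self.full_rescue,
            "enrichment.tsv": self.enrichment,
            "composition.tsv": self.composition().reset_index(),
            "restoration_zscores.tsv": self.restoration_zscores(),
        }
        for name, df in tables.items():
            if df is None:
                continue
            with open(outdir / name, "w") as fh:
                fh.write(header)
                df.to_csv(fh, sep="\t", index=False)
        with open(outdir / "report.json", "w") as fh:
            json.dump(self.report(), fh, indent=2, default=str)

    def plot_composition(self, ax=None):
        """Stacked per-sample composition bar chart (matplotlib)."""
        import matplotlib.pyplot as plt

        comp = self.composition()
        if ax is None:
            _, ax = plt.subplots()
        comp.plot(kind="bar", stacked=True, ax=ax, width=0.85)
        ax.set_ylabel("% of cells")
        ax.legend(fontsize=7, bbox_to_anchor=(1.02, 1), loc="upper left")
        return ax
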