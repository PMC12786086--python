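"""Config-file driven orchestration of the full analysis.

A run config is a flat YAML/key=value mapping; every key mirrors an
:class:`~scpotency.model.AnalysisConfig` or :class:`~scpotency.simulate.SimConfig`
field.  Exit-code conventions used by the CLI: 0 success, 2 validation error,
3 stage failure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .annotate import EmbeddingConfig
from .enrichment import read_gmt
from .model import AnalysisConfig, PotencyAnalysis, PotencyResults
from .potency import RestorationConfig
from .qc import QCThresholds
from .simulate import SimConfig, simulate_experiment, write_dataset

log = logging.getLogger("scpotency")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Paths plus analysis parameters for one pipeline run."""

    counts: str | None = None
    metadata: str | None = None
    markers: str | None = None
    gmt: str | None = None
    outdir: str = "scpotency_out"
    transgene_name: str = "optiKCNV2"
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0

    def validate(self) -> None:
        for name in ("counts", "metadata", "markers", "gmt"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} path does not exist: {p}")


_ANALYSIS_KEYS = {
    "min_umis": ("qc", int),
    "max_pct_mito": ("qc", float),
    "max_pct_ribo": ("qc", float),
    "n_top_features": ("embedding", int),
    "n_pcs": ("embedding", int),
    "knn": ("embedding", int),
    "cluster_resolution": ("embedding", float),
    "threshold": ("restoration", float),
    "mode": ("restoration", str),
    "positives_only": ("restoration", bool),
    "log_scale_means": ("restoration", bool),
}


def load_run_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML/key=value file plus overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            text = fh.read()
        loaded = yaml.safe_load(text)
        if isinstance(loaded, dict):
            data = loaded
        elif loaded is not None:
            raise ConfigError(f"config file {path} is not a mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})

    cfg = RunConfig()
    analysis = AnalysisConfig(
        qc=QCThresholds(), embedding=EmbeddingConfig(), restoration=RestorationConfig()
    )
    for key, value in data.items():
        if hasattr(cfg, key) and key != "analysis":
            setattr(cfg, key, value)
        elif key in _ANALYSIS_KEYS:
            sub, cast = _ANALYSIS_KEYS[key]
            setattr(getattr(analysis, sub), key, cast(value))
        elif hasattr(analysis, key):
            cur = getattr(analysis, key)
            setattr(analysis, key, type(cur)(value) if cur is not None else value)
        else:
            raise ConfigError(f"unknown config key {key!r}")
    analysis.embedding.seed = int(data.get("seed", cfg.seed))
    cfg.analysis = analysis
    cfg.validate()
    return cfg


def cmd_simulate(outdir: str | Path, seed: int = 0, **cfg_overrides) -> Path:
    """Generate a synthetic dataset directory (counts, metadata, markers, truth)."""
    cfg = SimConfig(seed=seed, **cfg_overrides)
    cfg.validate()
    log.info("simulate: %d cells/sample, %d genes, seed %d", cfg.n_cells_per_sample, cfg.n_genes, seed)
    exp = simulate_experiment(cfg)
    outdir = Path(outdir)
    write_dataset(exp, outdir)
    with open(outdir / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(
            {k: v for k, v in cfg.__dict__.items() if not isinstance(v, dict)}, fh
        )
    log.info("simulate: wrote %s (%d cells total)", outdir, exp.counts.n_cells)
    return outdir


def cmd_run(cfg: RunConfig) -> PotencyResults:
    """Run the full pipeline per the config and write all artifacts."""
    if cfg.counts is None or cfg.metadata is None or cfg.markers is None:
        raise ConfigError("counts, metadata and markers paths are all required")
    counts_path = Path(cfg.counts)
    from .io import read_cell_metadata, read_counts, read_markers

    log.info("run: reading inputs from %s", counts_path)
    counts = read_counts(counts_path, transgene_name=cfg.transgene_name)
    meta = read_cell_metadata(cfg.metadata, barcodes=counts.cell_barcodes)
    markers = read_markers(cfg.markers)
    gene_sets = read_gmt(cfg.gmt) if cfg.gmt else None

    model = PotencyAnalysis(counts, meta, markers, cfg.analysis)
    results = model.fit(gene_sets=gene_sets)
    results.save(cfg.outdir)
    for n in results.notices:
        log.warning("run: %s", n)
    log.info("run: artifacts written to %s", cfg.outdir)
    return results


REPORT_TABLES = ("composition.tsv", "transduction_profile.tsv", "restoration_zscores.tsv")


def cmd_report(outdir: str | Path) -> list[Path]:
    """List the summary tables of a completed run; error on missing artifacts."""
    outdir = Path(outdir)
    missing = [n for n in ("report.json", "cells.tsv") if not (outdir / n).exists()]
    if missing:
        raise FileNotFoundError(f"run artifacts missing from {outdir}: {missing}")
    return [outdir / n for n in REPORT_TABLES if (outdir / n).exists()]
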