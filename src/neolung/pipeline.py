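"""Configured, reproducible orchestration of the full analysis.

``run`` executes simulate -> QC -> proximity -> cell niches -> transcript
niches -> differential expression on one configuration, writing versioned
CSV outputs plus a JSON manifest (config echo, per-stage seeds, output
hashes, row counts) into the output directory. Stage seeds are derived
deterministically from the global seed, so a rerun with the same config
is byte-identical for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import benchmarks, differential, io_qc, niches, proximity, synthetic_data
from .embedding import EmbeddingConfig

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    cohort: synthetic_data.CohortConfig
    qc: io_qc.QCConfig = field(default_factory=io_qc.QCConfig)
    proximity: proximity.ProximityConfig = field(default_factory=proximity.ProximityConfig)
    cniche: niches.CNicheConfig = field(default_factory=niches.CNicheConfig)
    tniche_n_niches: int = 11
    tniche_embedding: str = "composition"  # "learned" for the trained encoder
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    run_tniche: bool = True
    de_terms_covariate: tuple[str, ...] = ("GA", "LS")
    de_exclude_immune: bool = True
    fdr1: float = 0.1
    fdr2: float = 0.2
    seed: int = 0


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seeds(seed: int, names: list[str]) -> dict[str, int]:
    import numpy as np

    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def run(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Execute all stages; return (and persist) the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = ["simulate", "qc", "proximity", "cniche", "tniche", "differential"]
    seeds = _stage_seeds(cfg.seed, stages)
    manifest: dict = {"seed": cfg.seed, "stage_seeds": seeds, "stages": []}

    def record(stage: str, outputs: dict[str, pd.DataFrame]) -> None:
        entry = {"stage": stage, "outputs": {}}
        for name, df in outputs.items():
            path = out / f"{name}.csv"
            df.to_csv(path, index=False)
            entry["outputs"][name] = {"rows": int(len(df)), "sha256": _sha256(path)}
        manifest["stages"].append(entry)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    try:
        stage = "simulate"
        cohort = synthetic_data.simulate_cohort(
            dataclasses.replace(cfg.cohort, seed=seeds["simulate"])
        )
        record(stage, {
            "transcripts": cohort.transcripts,
            "cells": cohort.cells,
            "metadata": cohort.metadata,
            "truth_cells": cohort.truth.cells,
        })

        stage = "qc"
        t_expr, cells_pass = benchmarks.standard_qc(
            cohort.transcripts, cohort.cells, cfg.qc
        )
        record(stage, {"cells_qc": cells_pass, "transcripts_qc": t_expr})

        stage = "proximity"
        screen = proximity.proximity_screen(cells_pass, cohort.metadata, cfg.proximity)
        patterns = proximity.binarize_and_cluster(screen, cfg.proximity.alpha_fdr)
        record(stage, {"proximity_results": screen, "proximity_patterns": patterns})

        stage = "cniche"
        cn = niches.cniche_assign(
            cells_pass, dataclasses.replace(cfg.cniche, seed=seeds["cniche"])
        )
        record(stage, {"cniche": cn})

        stage = "tniche"
        if cfg.run_tniche:
            tn = niches.tniche_pipeline(
                cohort.transcripts,
                cells_pass,
                list(cfg.cohort.panel.genes),
                n_niches=cfg.tniche_n_niches,
                embedding=cfg.tniche_embedding,
                emb_cfg=dataclasses.replace(cfg.embedding, seed=seeds["tniche"]),
                seed=seeds["tniche"],
            )
            record(stage, {"tniche_cells": tn.cell_assign, "tniche_bins": tn.bins})

        stage = "differential"
        pb = differential.pseudobulk(t_expr, cells_pass)
        pb = differential.filter_genes(pb)
        included = differential.select_samples(cohort.metadata)
        de_cov = differential.fit_covariate_model(
            pb, included, terms=cfg.de_terms_covariate, exclude_immune=cfg.de_exclude_immune
        )
        de_dx = differential.fit_covariate_model(
            pb, included, terms=("DX",), exclude_immune=cfg.de_exclude_immune
        )
        tables = {
            t: de_cov[de_cov["term"] == t] for t in cfg.de_terms_covariate
        }
        tables["DX"] = de_dx
        overlap = differential.overlap_terms(tables, cfg.fdr1, cfg.fdr2)
        record(stage, {"de_covariates": de_cov, "de_dx": de_dx, "overlap": overlap})
    except Exception as exc:  # persist partial manifest, then surface the stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise StageError(stage, exc) from exc

    return manifest


def report(run_dir: str | Path, make_plots: bool = False) -> dict[str, pd.DataFrame]:
    """Summary tables for a completed run.

    Per-stage niche-proportion tables (over cells, not transcripts), the
    enrichment pattern table, and DE gene counts per cell type. Writes the
    tables as CSVs next to the run outputs; optionally also stacked-bar
    plots.
    """
    run_dir = Path(run_dir)

    def need(name: str) -> pd.DataFrame:
        path = run_dir / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing stage output {name!r} ({path})")
        return pd.read_csv(path)

    cells = need("cells_qc")
    meta = need("metadata")
    out: dict[str, pd.DataFrame] = {}

    for col, name in (("cniche", "cniche"), ("tniche", "tniche_cells")):
        path = run_dir / f"{name}.csv"
        if not path.exists():
            continue
        lab = pd.read_csv(path)
        merged = cells.merge(lab, on="cell_id").merge(
            meta[["sample_id", "stage"]], on="sample_id"
        )
        all_labels = sorted(merged[col].unique())
        prop = (
            merged.groupby(["sample_id", col]).size().unstack(fill_value=0)
            .reindex(columns=all_labels, fill_value=0)
        )
        prop = prop.div(prop.sum(axis=1), axis=0)
        out[f"{col}_proportions"] = prop.reset_index()
        if make_plots:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            ax = prop.plot(kind="bar", stacked=True, figsize=(8, 4), width=0.9)
            ax.set_ylabel("proportion of cells")
            ax.figure.tight_layout()
            ax.figure.savefig(run_dir / f"{col}_proportions.png", dpi=120)
            plt.close(ax.figure)

    patt = run_dir / "proximity_patterns.csv"
    if patt.exists():
        out["patterns"] = pd.read_csv(patt)

    de_path = run_dir / "de_covariates.csv"
    if de_path.exists():
        de = pd.read_csv(de_path)
        sig = de[de["fdr"] < 0.1]
        out["de_counts"] = (
            sig.groupby(["cell_type", "term"]).size().rename("n_genes").reset_index()
        )

    for name, df in out.items():
        df.to_csv(run_dir / f"report_{name}.csv", index=False)
    return out
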