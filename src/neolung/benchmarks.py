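"""Fixed synthetic study conditions for validation benchmarks.

Each builder returns a seeded cohort configuration whose planted structure
a correct pipeline should recover. The parameter values are part of the
benchmark definitions: effect sizes follow the 3x-residual-SD convention
measured under the generator's default noise (pseudobulk residual SD
~0.14 on log expression), attraction coefficients place attracted cells
well inside the nearest-neighbor radius, and problem sizes are desk scale
(hundreds of cells per section, tens of thousands of transcripts).
"""

from __future__ import annotations

import pandas as pd

from . import io_qc, synthetic_data as sd

#: planted GA effect (log expression per week): 3x residual SD over the GA spread
BETA_GA = 0.06
#: planted LS effect (log expression per week)
BETA_LS = 0.08
#: attraction coefficient: shrinks the B-to-nearest-A distance by e^3 ~ 20x
ATTRACTION = 3.0


def standard_qc(
    transcripts: pd.DataFrame, cells: pd.DataFrame, cfg: io_qc.QCConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Transcript QC -> cell QC -> expression-ready tables.

    Returns ``(expression transcripts, passing cells)``: transcripts that
    pass QV/assignment/nuclear filters with controls removed and host cell
    QC-passing, and the QC-passing cell table with metrics attached.
    """
    cfg = cfg or io_qc.QCConfig()
    t_qc = io_qc.filter_transcripts(transcripts, cfg, drop_controls=False)
    cells_qc = io_qc.compute_cell_qc(t_qc, cells)
    cells_pass = io_qc.filter_cells(cells_qc, cfg)
    t_expr = t_qc[~io_qc.is_control(t_qc["feature"])]
    t_expr = t_expr[t_expr["cell_id"].isin(set(cells_pass["cell_id"]))].reset_index(drop=True)
    return t_expr, cells_pass


def proximity_benchmark_config(seed: int, attraction: float | None = ATTRACTION) -> sd.CohortConfig:
    """One 400-cell section, four cell types; optionally one attracted pair.

    With ``attraction`` set, cells of the second type are planted next to
    the nearest cell of the first type; ``None`` gives the spatial null
    (types placed independently).
    """
    tax = sd.make_taxonomy(4)
    cts = sorted(tax)
    panel = sd.make_panel(8, 4, 0, cell_types=cts, markers_per_type=1)
    plan = ((cts[0], cts[1], attraction),) if attraction else ()
    return sd.CohortConfig(
        samples=(sd.SampleSpec("S1", 30, 2, 1, False, n_replicates=1),),
        taxonomy=tax,
        panel=panel,
        niche_layout=sd.uniform_layout(cts),
        proximity_plan=plan,
        cells_per_sample=400,
        section_um=600.0,
        seed=seed,
    )


def regression_benchmark_config(
    seed: int,
) -> tuple[sd.CohortConfig, dict[tuple[str, str], tuple[float, float, float]]]:
    """Eleven eligible samples with planted GA and LS effects.

    The cohort is the study-shaped design restricted to the samples the
    GA/LS selection rule keeps (21-40 weeks GA, no rare disease). Effects
    of both signs are planted on structural cell types only (the
    regression excludes immune types). Returns (config, expression plan).
    """
    samples = tuple(
        s for s in sd.default_cohort_samples() if not s.rare_disease and s.ga_weeks >= 21
    )
    tax = sd.make_taxonomy(4)
    struct = sorted(ct for ct, lin in tax.items() if lin != "immune")
    cts = sorted(tax)
    panel = sd.make_panel(16, 8, 0, cell_types=cts, markers_per_type=2)
    g = panel.genes
    plan = {
        (g[16], struct[0]): (BETA_GA, 0.0, 0.0),
        (g[17], struct[1]): (-BETA_GA, 0.0, 0.0),
        (g[18], struct[2]): (0.0, BETA_LS, 0.0),
        (g[19], struct[0]): (0.0, -BETA_LS, 0.0),
    }
    cfg = sd.CohortConfig(
        samples=samples,
        taxonomy=tax,
        panel=panel,
        niche_layout=sd.uniform_layout(cts),
        expression_plan=plan,
        cells_per_sample=400,
        section_um=600.0,
        seed=seed,
    )
    return cfg, plan


def cniche_benchmark_config(seed: int, n_regions: int = 11) -> sd.CohortConfig:
    """One section with ``n_regions`` composition-distinct spatial regions.

    Each region is dominated (80% of cells) by its own cell type, with the
    remaining types as uniform background — the composition-based niche
    stage should recover one niche per region.
    """
    tax = sd.make_taxonomy(max(n_regions + 1, 12))
    cts = sorted(tax)
    panel = sd.make_panel(2 * len(cts), len(cts), 0, cell_types=cts, markers_per_type=1)
    regions = []
    for i in range(n_regions):
        comp = {ct: 0.2 / len(cts) for ct in cts}
        comp[cts[i]] += 0.8
        regions.append(sd.NicheRegion(name=f"region{i}", composition=comp))
    return sd.CohortConfig(
        samples=(sd.SampleSpec("S1", 30, 2, 1, False, n_replicates=1),),
        taxonomy=tax,
        panel=panel,
        niche_layout=tuple(regions),
        cells_per_sample=200 * n_regions,
        section_um=900.0,
        seed=seed,
    )


def tniche_benchmark_config(seed: int, n_regions: int = 4) -> sd.CohortConfig:
    """~50k transcripts in ``n_regions`` gene-composition regions.

    A single dense section with one cell type per lineage, no marker
    structure, and per-region boosts of disjoint 4-gene blocks (+2.5 on
    log expression), so regions differ molecularly but not cellularly —
    the segmentation-free transcript-niche route must recover them.
    """
    tax = sd.make_taxonomy(4)
    cts = sorted(tax)
    panel = sd.make_panel(16, 8, 0, cell_types=cts, markers_per_type=0)
    regions = sd.boosted_regions(
        cts, list(panel.genes), n_regions, genes_per_region=4, boost=2.5
    )
    return sd.CohortConfig(
        samples=(sd.SampleSpec("S1", 30, 2, 1, False, n_replicates=1),),
        taxonomy=tax,
        panel=panel,
        niche_layout=regions,
        cells_per_sample=1800,
        section_um=360.0,
        seed=seed,
    )
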