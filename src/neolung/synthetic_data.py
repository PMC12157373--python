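"""Seeded generator of Xenium-like multi-sample cohorts with ground truth.

The generator emulates the data a tissue-microarray Xenium run produces for
a neonatal-lung cohort: per-section transcript tables (feature, coordinates
in um, quality value, nuclear cell assignment, control species), per-cell
tables (centroid, nuclear area, cell type, lineage) and a cohort metadata
table (gestational age at birth, life span at collection, pathologist
disease-severity score, rare-disease flag).

Planted structure, all recorded in :class:`GroundTruth`:

* spatial niches — the square section is tiled into rectangular regions,
  each with its own cell-type composition and optional per-gene expression
  boost;
* cell-type attraction/repulsion — after placement, each cell of type B is
  displaced toward (or away from) its nearest type-A cell with an
  exponential kernel, monotone in the plan coefficient;
* covariate-linked expression — per-cell counts are negative-binomial with
  log-mean linear in gestational age, life span and disease score;
* QC artifacts — additive low-QV, unassigned and negative-control records
  at configured fractions.

Everything is reproducible from ``CohortConfig.seed``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_qc import NEG_CODEWORD, NEG_PROBE, UNASSIGNED, assign_stage
from .taxonomy import make_taxonomy

GA_REF_WEEKS = 30.0  # centering for the gestational-age term of the log-mean model


# ---------------------------------------------------------------------------
# gene panel

@dataclass(frozen=True)
class GenePanel:
    """A gene panel with marker structure.

    ``genes`` are unique symbols; ``marker_map`` maps each cell type to the
    subset of genes that act as its markers (elevated baseline expression).
    ``n_base``/``n_custom`` record panel provenance (how many symbols came
    from the platform base panel vs the custom add-on).
    """

    genes: tuple[str, ...]
    marker_map: dict[str, tuple[str, ...]] = field(default_factory=dict)
    n_base: int = 0
    n_custom: int = 0

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("panel gene symbols must be unique")
        for ct, markers in self.marker_map.items():
            unknown = set(markers) - set(self.genes)
            if unknown:
                raise ValueError(f"marker genes {sorted(unknown)} for {ct!r} not in panel")

    def __len__(self) -> int:
        return len(self.genes)


def make_panel(
    n_base: int,
    n_custom: int,
    overlap: int = 0,
    cell_types: list[str] | None = None,
    markers_per_type: int = 2,
) -> GenePanel:
    """Merge a base panel with a custom panel sharing ``overlap`` symbols.

    The resulting panel has ``n_base + n_custom - overlap`` unique genes.
    When ``cell_types`` is given, marker genes are assigned round-robin,
    ``markers_per_type`` per type (types wrap around the panel if needed).
    """
    if n_base < 0 or n_custom < 0 or overlap < 0:
        raise ValueError("panel counts must be non-negative")
    if overlap > min(n_base, n_custom):
        raise ValueError(
            f"overlap {overlap} exceeds the smaller panel (min(n_base, n_custom) = "
            f"{min(n_base, n_custom)})"
        )
    n_genes = n_base + n_custom - overlap
    genes = tuple(f"G{i:04d}" for i in range(n_genes))
    marker_map: dict[str, tuple[str, ...]] = {}
    if cell_types:
        need = markers_per_type * len(cell_types)
        idx = [i % n_genes for i in range(need)] if n_genes else []
        for j, ct in enumerate(cell_types):
            marker_map[ct] = tuple(
                genes[idx[j * markers_per_type + k]] for k in range(markers_per_type)
            )
    return GenePanel(genes=genes, marker_map=marker_map, n_base=n_base, n_custom=n_custom)


# ---------------------------------------------------------------------------
# cohort configuration

@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    ga_weeks: float
    lifespan_weeks: float
    dx_score: int
    rare_disease: bool = False
    n_replicates: int = 2  # adjacent sections per sample (technical replicates)


@dataclass(frozen=True)
class NicheRegion:
    """A spatial region with its own cell-type composition.

    ``composition`` maps cell type -> probability (must sum to 1).
    ``gene_boost`` optionally adds a per-gene log-fold term to the
    expression of cells in this region, giving regions distinct molecular
    identities for transcript-niche recovery. ``weight`` sets the region's
    share of the sample's cells.
    """

    name: str
    composition: dict[str, float]
    gene_boost: dict[str, float] = field(default_factory=dict)
    weight: float = 1.0

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"region {self.name!r} composition sums to {total}, not 1")


@dataclass(frozen=True)
class CohortConfig:
    samples: tuple[SampleSpec, ...]
    taxonomy: dict[str, str]
    panel: GenePanel
    niche_layout: tuple[NicheRegion, ...]
    # (type A, type B, coefficient): positive attracts B toward A, negative repels
    proximity_plan: tuple[tuple[str, str, float], ...] = ()
    # (gene, cell_type) -> (beta_ga per week, beta_ls per week, beta_dx per unit)
    expression_plan: dict[tuple[str, str], tuple[float, float, float]] = field(
        default_factory=dict
    )
    cells_per_sample: int = 800
    section_um: float = 1000.0
    marker_mean: float = 6.0  # baseline mean counts/cell for a type's marker genes
    base_mean: float = 0.4  # baseline mean counts/cell for non-marker genes
    dispersion: float = 0.3  # NB overdispersion (var = mu + a*mu^2); 0 -> Poisson
    sample_noise_sd: float = 0.05  # per-(sample, gene) lognormal biological noise
    frac_low_qv: float = 0.04  # artifact fractions, relative to clean transcript count
    frac_unassigned: float = 0.05
    frac_neg_codeword: float = 0.008
    frac_neg_probe: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.samples) == 0:
            raise ValueError("at least one sample must be configured")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in cohort config")
        if len(self.niche_layout) == 0:
            raise ValueError("niche_layout must contain at least one region")
        for key, betas in self.expression_plan.items():
            if not all(np.isfinite(betas)):
                raise ValueError(f"non-finite expression coefficients for {key}")
        for region in self.niche_layout:
            unknown = set(region.composition) - set(self.taxonomy)
            if unknown:
                raise ValueError(f"region {region.name!r} uses unknown types {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Per-cell, per-record and per-plan truth for a generated dataset."""

    cells: pd.DataFrame  # cell_id, sample_id, section_id, true_type, true_region
    transcript_kinds: pd.DataFrame  # transcript_id, kind in {clean, low_qv, unassigned, neg_codeword, neg_probe}
    proximity_plan: tuple[tuple[str, str, float], ...]
    expression_plan: dict[tuple[str, str], tuple[float, float, float]]

    def artifact_ids(self) -> pd.Series:
        return self.transcript_kinds.loc[
            self.transcript_kinds["kind"] != "clean", "transcript_id"
        ]


@dataclass
class Cohort:
    transcripts: pd.DataFrame
    cells: pd.DataFrame
    metadata: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# layout helpers

def uniform_layout(cell_types: list[str]) -> tuple[NicheRegion, ...]:
    """A single region covering the section with uniform type composition."""
    p = 1.0 / len(cell_types)
    return (NicheRegion("uniform", {ct: p for ct in cell_types}),)


def grid_layout(
    compositions: list[dict[str, float]],
    gene_boosts: list[dict[str, float]] | None = None,
    names: list[str] | None = None,
) -> tuple[NicheRegion, ...]:
    """One region per composition, laid out on a grid at simulation time."""
    regions = []
    for i, comp in enumerate(compositions):
        regions.append(
            NicheRegion(
                name=names[i] if names else f"region{i}",
                composition=comp,
                gene_boost=gene_boosts[i] if gene_boosts else {},
            )
        )
    return tuple(regions)


def _region_tiles(n_regions: int, section_um: float) -> list[tuple[float, float, float, float]]:
    """(x0, y0, w, h) tile per region, tiling the square section on a grid."""
    ncol = int(np.ceil(np.sqrt(n_regions)))
    nrow = int(np.ceil(n_regions / ncol))
    w, h = section_um / ncol, section_um / nrow
    return [((i % ncol) * w, (i // ncol) * h, w, h) for i in range(n_regions)]


def _rng_for(seed: int, *keys: str) -> np.random.Generator:
    parts = [seed] + [zlib.crc32(k.encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(parts))


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation proportional to weights, deterministic."""
    raw = weights / weights.sum() * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


# ---------------------------------------------------------------------------
# simulation

def _log_mu_matrix(
    cfg: CohortConfig,
    spec: SampleSpec,
    cell_types: np.ndarray,
    regions: np.ndarray,
    sample_noise: np.ndarray,
) -> np.ndarray:
    """Per-cell x per-gene log mean counts."""
    genes = list(cfg.panel.genes)
    gene_idx = {g: j for j, g in enumerate(genes)}
    types = sorted(cfg.taxonomy)
    type_idx = {t: i for i, t in enumerate(types)}

    base = np.full((len(types), len(genes)), np.log(cfg.base_mean))
    for ct, markers in cfg.panel.marker_map.items():
        if ct in type_idx:
            for g in markers:
                base[type_idx[ct], gene_idx[g]] = np.log(cfg.marker_mean)
    for (g, ct), (b_ga, b_ls, b_dx) in cfg.expression_plan.items():
        if ct in type_idx and g in gene_idx:
            base[type_idx[ct], gene_idx[g]] += (
                b_ga * (spec.ga_weeks - GA_REF_WEEKS)
                + b_ls * spec.lifespan_weeks
                + b_dx * spec.dx_score
            )

    boost = np.zeros((len(cfg.niche_layout), len(genes)))
    for r, region in enumerate(cfg.niche_layout):
        for g, lfc in region.gene_boost.items():
            if g in gene_idx:
                boost[r, gene_idx[g]] = lfc

    ct_codes = np.array([type_idx[t] for t in cell_types])
    return base[ct_codes] + boost[regions] + sample_noise[None, :]


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu)
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_sample(
    cfg: CohortConfig, sample_id: str, section_index: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate one tissue section for ``sample_id``.

    Returns (transcript table, cell table, ground truth). Sections of the
    same sample are independent draws from the same sample-level parameters
    (the per-(sample, gene) biological noise is shared across sections, so
    technical replicates look like replicates).
    """
    specs = {s.sample_id: s for s in cfg.samples}
    if sample_id not in specs:
        raise ValueError(f"sample {sample_id!r} not present in cohort config")
    spec = specs[sample_id]
    section_id = f"{sample_id}_s{section_index}"
    rng = _rng_for(cfg.seed, sample_id, f"section{section_index}")
    noise_rng = _rng_for(cfg.seed, sample_id, "sample-noise")
    sample_noise = noise_rng.normal(0.0, cfg.sample_noise_sd, size=len(cfg.panel.genes))

    # --- place cells region by region
    tiles = _region_tiles(len(cfg.niche_layout), cfg.section_um)
    weights = np.array([r.weight for r in cfg.niche_layout], float)
    n_per_region = _largest_remainder(weights, cfg.cells_per_sample)

    region_of = np.repeat(np.arange(len(cfg.niche_layout)), n_per_region)
    xs = np.empty(cfg.cells_per_sample)
    ys = np.empty(cfg.cells_per_sample)
    types = np.empty(cfg.cells_per_sample, dtype=object)
    pos = 0
    for r, region in enumerate(cfg.niche_layout):
        n = n_per_region[r]
        x0, y0, w, h = tiles[r]
        xs[pos : pos + n] = x0 + rng.uniform(0, w, n)
        ys[pos : pos + n] = y0 + rng.uniform(0, h, n)
        cts = sorted(region.composition)
        probs = np.array([region.composition[c] for c in cts])
        types[pos : pos + n] = rng.choice(cts, size=n, p=probs / probs.sum())
        pos += n

    # --- planted attraction/repulsion: move B toward/away from nearest A
    for a_type, b_type, coef in cfg.proximity_plan:
        if coef == 0:
            continue
        a_mask = types == a_type
        b_mask = types == b_type
        if not a_mask.any() or not b_mask.any():
            continue
        from scipy.spatial import cKDTree

        tree = cKDTree(np.column_stack([xs[a_mask], ys[a_mask]]))
        d, j = tree.query(np.column_stack([xs[b_mask], ys[b_mask]]))
        ax = xs[a_mask][j]
        ay = ys[a_mask][j]
        shrink = np.exp(-coef)  # <1 attracts, >1 repels
        xs[b_mask] = np.clip(ax + (xs[b_mask] - ax) * shrink, 0, cfg.section_um)
        ys[b_mask] = np.clip(ay + (ys[b_mask] - ay) * shrink, 0, cfg.section_um)

    areas = rng.gamma(shape=10.0, scale=3.2, size=cfg.cells_per_sample)  # mean 32 um^2
    cell_ids = np.array([f"{section_id}_c{i:05d}" for i in range(cfg.cells_per_sample)])
    lineages = np.array([cfg.taxonomy[t] for t in types], dtype=object)

    cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "sample_id": sample_id,
            "section_id": section_id,
            "centroid_x_um": xs,
            "centroid_y_um": ys,
            "nuclear_area_um2": areas,
            "cell_type": types,
            "lineage": lineages,
        }
    )

    # --- transcripts from the NB count model
    log_mu = _log_mu_matrix(cfg, spec, types, region_of, sample_noise)
    counts = _draw_counts(rng, np.exp(log_mu), cfg.dispersion)
    total_per_cell = counts.sum(axis=1)
    n_clean = int(total_per_cell.sum())

    genes = np.array(cfg.panel.genes, dtype=object)
    cell_rep = np.repeat(np.arange(cfg.cells_per_sample), total_per_cell)
    gene_rep = np.concatenate(
        [np.repeat(np.arange(len(genes)), counts[i]) for i in range(cfg.cells_per_sample)]
    ) if n_clean else np.empty(0, dtype=int)

    radius = np.sqrt(areas / np.pi)[cell_rep]
    theta = rng.uniform(0, 2 * np.pi, n_clean)
    rr = radius * np.sqrt(rng.uniform(0, 1, n_clean))
    tx = np.clip(xs[cell_rep] + rr * np.cos(theta), 0, cfg.section_um)
    ty = np.clip(ys[cell_rep] + rr * np.sin(theta), 0, cfg.section_um)

    frames = [
        pd.DataFrame(
            {
                "feature": genes[gene_rep],
                "x_um": tx,
                "y_um": ty,
                "qv": rng.uniform(25.0, 45.0, n_clean),
                "cell_id": cell_ids[cell_rep],
                "overlaps_nucleus": 1,
                "kind": "clean",
            }
        )
    ]

    # --- additive QC artifacts (binomial counts at the configured fractions)
    def _artifact(kind: str, frac: float) -> pd.DataFrame | None:
        n = int(rng.binomial(n_clean, frac)) if frac > 0 and n_clean else 0
        if n == 0:
            return None
        ax = rng.uniform(0, cfg.section_um, n)
        ay = rng.uniform(0, cfg.section_um, n)
        if kind == "low_qv":
            host = rng.integers(0, cfg.cells_per_sample, n)
            return pd.DataFrame(
                {
                    "feature": genes[rng.integers(0, len(genes), n)],
                    "x_um": ax,
                    "y_um": ay,
                    "qv": rng.uniform(2.0, 19.9, n),
                    "cell_id": cell_ids[host],
                    "overlaps_nucleus": 1,
                    "kind": kind,
                }
            )
        if kind == "unassigned":
            return pd.DataFrame(
                {
                    "feature": genes[rng.integers(0, len(genes), n)],
                    "x_um": ax,
                    "y_um": ay,
                    "qv": rng.uniform(25.0, 45.0, n),
                    "cell_id": UNASSIGNED,
                    "overlaps_nucleus": 0,
                    "kind": kind,
                }
            )
        feature = NEG_CODEWORD if kind == "neg_codeword" else NEG_PROBE
        host = rng.integers(0, cfg.cells_per_sample, n)
        return pd.DataFrame(
            {
                "feature": feature,
                "x_um": ax,
                "y_um": ay,
                "qv": rng.uniform(25.0, 45.0, n),
                "cell_id": cell_ids[host],
                "overlaps_nucleus": 1,
                "kind": kind,
            }
        )

    for kind, frac in (
        ("low_qv", cfg.frac_low_qv),
        ("unassigned", cfg.frac_unassigned),
        ("neg_codeword", cfg.frac_neg_codeword),
        ("neg_probe", cfg.frac_neg_probe),
    ):
        extra = _artifact(kind, frac)
        if extra is not None:
            frames.append(extra)

    transcripts = pd.concat(frames, ignore_index=True)
    transcripts.insert(0, "transcript_id", [f"{section_id}_t{i:07d}" for i in range(len(transcripts))])
    transcripts["sample_id"] = sample_id
    transcripts["section_id"] = section_id
    kinds = transcripts[["transcript_id", "kind"]].copy()
    transcripts = transcripts.drop(columns=["kind"])

    truth = GroundTruth(
        cells=pd.DataFrame(
            {
                "cell_id": cell_ids,
                "sample_id": sample_id,
                "section_id": section_id,
                "true_type": types,
                "true_region": np.array([cfg.niche_layout[r].name for r in region_of], dtype=object),
            }
        ),
        transcript_kinds=kinds,
        proximity_plan=cfg.proximity_plan,
        expression_plan=cfg.expression_plan,
    )
    return transcripts, cells, truth


def simulate_cohort(cfg: CohortConfig) -> Cohort:
    """Generate every configured sample (with its technical replicates)."""
    t_frames, c_frames, truth_cells, truth_kinds = [], [], [], []
    meta_rows = []
    for spec in cfg.samples:
        for section in range(spec.n_replicates):
            t, c, g = simulate_sample(cfg, spec.sample_id, section)
            t_frames.append(t)
            c_frames.append(c)
            truth_cells.append(g.cells)
            truth_kinds.append(g.transcript_kinds)
        meta_rows.append(
            {
                "sample_id": spec.sample_id,
                "ga_weeks": spec.ga_weeks,
                "lifespan_weeks": spec.lifespan_weeks,
                "dx_score": spec.dx_score,
                "rare_disease": spec.rare_disease,
                "stage": assign_stage(spec.ga_weeks, spec.rare_disease),
            }
        )
    truth = GroundTruth(
        cells=pd.concat(truth_cells, ignore_index=True),
        transcript_kinds=pd.concat(truth_kinds, ignore_index=True),
        proximity_plan=cfg.proximity_plan,
        expression_plan=cfg.expression_plan,
    )
    return Cohort(
        transcripts=pd.concat(t_frames, ignore_index=True),
        cells=pd.concat(c_frames, ignore_index=True),
        metadata=pd.DataFrame(meta_rows),
        truth=truth,
    )


def boosted_regions(
    cell_types: list[str],
    genes: list[str],
    n_regions: int,
    genes_per_region: int = 3,
    boost: float = 2.0,
    distinct_composition: bool = False,
    dominant_frac: float = 0.8,
) -> tuple[NicheRegion, ...]:
    """Regions with distinct molecular identity (and optionally cellular).

    Region ``i`` boosts a disjoint block of ``genes_per_region`` genes by
    ``boost`` on log expression in all its cells. With
    ``distinct_composition`` each region is additionally dominated
    (``dominant_frac`` of cells) by its own block of cell types, making
    cellular and molecular regions coincide.
    """
    if n_regions * genes_per_region > len(genes):
        raise ValueError("not enough genes for disjoint per-region boosts")
    regions = []
    uniform = {ct: 1.0 / len(cell_types) for ct in cell_types}
    per_region_types = max(1, len(cell_types) // n_regions)
    for i in range(n_regions):
        gb = {g: boost for g in genes[i * genes_per_region : (i + 1) * genes_per_region]}
        if distinct_composition:
            dom = cell_types[i * per_region_types : (i + 1) * per_region_types]
            if not dom:
                dom = [cell_types[i % len(cell_types)]]
            comp = {ct: (1.0 - dominant_frac) / len(cell_types) for ct in cell_types}
            for ct in dom:
                comp[ct] += dominant_frac / len(dom)
        else:
            comp = dict(uniform)
        regions.append(NicheRegion(name=f"region{i}", composition=comp, gene_boost=gb))
    return tuple(regions)


# ---------------------------------------------------------------------------
# study-shaped defaults

def default_cohort_samples() -> tuple[SampleSpec, ...]:
    """A 17-sample cohort shaped like the study design.

    Two early-canalicular samples under 21 weeks gestation, eleven samples
    spanning 21-40 weeks GA and 0-16 weeks of life, and four rare-disease
    samples (including an adult explant with a long life span). Exactly six
    samples are excluded by the GA/life-span regression selection rule.
    """
    rows = [
        ("PDL001", 16, 0, 0, False),
        ("PDL002", 18, 0, 0, False),
        ("PDL003", 21, 0, 1, False),
        ("PDL004", 22, 1, 1, False),
        ("PDL005", 23, 2, 2, False),
        ("PDL006", 24, 8, 2, False),
        ("PDL007", 25, 0, 1, False),
        ("PDL008", 27, 4, 2, False),
        ("PDL009", 30, 10, 3, False),
        ("PDL010", 33, 16, 3, False),
        ("PDL011", 36, 0, 0, False),
        ("PDL012", 38, 1, 0, False),
        ("PDL013", 40, 2, 0, False),
        ("PDL014", 30, 2, 3, True),
        ("PDL015", 28, 1, 3, True),
        ("PDL016", 26, 4, 2, True),
        ("PDL017", 40, 1560, 3, True),  # 30-year explant with BPD
    ]
    return tuple(
        SampleSpec(sid, ga, ls, dx, rare) for sid, ga, ls, dx, rare in rows
    )


def default_cohort_config(
    n_types: int = 8,
    cells_per_sample: int = 600,
    seed: int = 0,
    **overrides,
) -> CohortConfig:
    """A desk-scale, study-shaped cohort configuration.

    17 samples (2 early-canalicular, 11 eligible for the GA/LS model, 4
    rare), ``n_types`` cell types across the four lineages, a marker-
    structured panel, and a single uniform spatial region. Override any
    field via keyword arguments (e.g. ``niche_layout=...``,
    ``proximity_plan=...``).
    """
    taxonomy = make_taxonomy(n_types)
    cts = sorted(taxonomy)
    panel = make_panel(2 * n_types, n_types, 0, cell_types=cts, markers_per_type=2)
    cfg = CohortConfig(
        samples=default_cohort_samples(),
        taxonomy=taxonomy,
        panel=panel,
        niche_layout=uniform_layout(cts),
        cells_per_sample=cells_per_sample,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg
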