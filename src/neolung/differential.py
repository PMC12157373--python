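"""Pseudobulk differential expression on clinical covariates.

Counts are aggregated to one expression profile per (individual, cell
type) — both technical replicates of a sample pool into the same column —
then library-size normalized (counts per 10k) and log1p transformed.
Genes are filtered per cell type to those detected in > 20% of that cell
type's cells. Three regressions are supported:

* a two-covariate linear model on gestational age (weeks) and life span
  (weeks), fitted per (gene, cell type) over the included individuals;
* a one-covariate model on the pathologist disease-severity (DX) score;
* a moderated two-group contrast between two cell types (empirical-Bayes
  variance shrinkage across genes, limma-style).

Significance uses Benjamini-Hochberg FDR within each (cell type x term)
family at FDR < 0.1, and the two-level FDR overlap rule combines terms: a
(gene, cell type) pair overlaps two terms when it passes FDR < 0.1 in one
and FDR < 0.2 in the other.

Immune cell types are excluded from the covariate regressions by default:
immune nuclei are typically surrounded by structural cells and pick up
contaminating transcripts, which produces spurious covariate associations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

TERM_COLUMNS = {"GA": "ga_weeks", "LS": "lifespan_weeks", "DX": "dx_score"}


class CollinearityError(ValueError):
    """Design matrix is rank deficient for some cell type."""


@dataclass
class PseudobulkMatrix:
    """Genes x (individual, cell type) pseudobulk expression.

    ``counts`` holds summed raw counts; ``lognorm`` holds
    log1p(counts-per-10k) per column. ``pct_expressing`` is the percent of
    each cell type's cells (pooled across individuals) detecting each
    gene; ``gene_mask`` (genes x cell type) marks genes retained for that
    cell type and starts all-True.
    """

    counts: pd.DataFrame  # index: gene, columns: MultiIndex (sample_id, cell_type)
    lognorm: pd.DataFrame
    n_cells: pd.Series
    pct_expressing: pd.DataFrame  # genes x cell_type
    lineage_map: dict[str, str] = field(default_factory=dict)
    gene_mask: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.gene_mask is None:
            self.gene_mask = pd.DataFrame(
                True, index=self.counts.index, columns=self.pct_expressing.columns
            )

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.counts.columns.get_level_values(1).unique())


def export_mtx(pb: "PseudobulkMatrix", out_dir) -> None:
    """Write the pseudobulk count matrix as MatrixMarket triplets.

    Produces ``matrix.mtx`` (genes x columns), ``genes.txt`` (row labels)
    and ``columns.txt`` (tab-separated individual and cell type per
    column).
    """
    from pathlib import Path

    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(out / "matrix.mtx", csr_matrix(pb.counts.to_numpy()))
    (out / "genes.txt").write_text("\n".join(map(str, pb.counts.index)) + "\n")
    (out / "columns.txt").write_text(
        "\n".join(f"{s}\t{ct}" for s, ct in pb.counts.columns) + "\n"
    )


def read_mtx(in_dir) -> pd.DataFrame:
    """Read a pseudobulk count matrix written by :func:`export_mtx`."""
    from pathlib import Path

    from scipy.io import mmread

    out = Path(in_dir)
    mat = mmread(out / "matrix.mtx").toarray()
    genes = (out / "genes.txt").read_text().splitlines()
    cols = [tuple(line.split("\t")) for line in (out / "columns.txt").read_text().splitlines()]
    return pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=pd.MultiIndex.from_tuples(cols))


def counts_per_cell(transcripts: pd.DataFrame) -> pd.DataFrame:
    """Cell x gene count matrix from an expression-ready transcript table."""
    return (
        transcripts.groupby(["sample_id", "cell_id", "feature"])
        .size()
        .unstack(fill_value=0)
    )


def pseudobulk(
    transcripts: pd.DataFrame, cells: pd.DataFrame, cp10k: float = 1e4
) -> PseudobulkMatrix:
    """Aggregate QC-passed transcripts to (individual, cell type) profiles.

    ``transcripts`` must already be expression-filtered (QV, assignment,
    controls removed) and restricted to QC-passing cells; ``cells``
    supplies the cell-type label per cell. Counts are summed over all
    cells of an (individual, cell type) — technical replicates share the
    individual, so they merge — then CP10k-normalized per column and
    log1p-transformed.
    """
    typed = transcripts.merge(
        cells[["sample_id", "cell_id", "cell_type"]], on=["sample_id", "cell_id"], how="inner"
    )
    counts = (
        typed.groupby(["sample_id", "cell_type", "feature"], observed=True)
        .size()
        .unstack(level=["sample_id", "cell_type"], fill_value=0)
    )
    counts.index.name = "gene"
    counts = counts.sort_index(axis=1)
    lib = counts.sum(axis=0)
    lognorm = np.log1p(counts / lib.replace(0, np.nan) * cp10k).fillna(0.0)

    n_cells = cells.groupby(["sample_id", "cell_type"]).size()
    n_cells = n_cells.reindex(counts.columns, fill_value=0)

    # pooled per-cell-type detection percentages
    det = (
        typed.groupby(["cell_type", "feature", "cell_id"], observed=True)
        .size()
        .reset_index(name="n")
        .groupby(["cell_type", "feature"], observed=True)["cell_id"]
        .nunique()
        .unstack(level="cell_type", fill_value=0)
    )
    cells_per_type = cells.groupby("cell_type").size()
    det = det.reindex(index=counts.index, columns=sorted(cells_per_type.index), fill_value=0)
    pct = 100.0 * det / cells_per_type.reindex(det.columns)

    lineage_map = (
        cells.drop_duplicates("cell_type").set_index("cell_type")["lineage"].to_dict()
        if "lineage" in cells.columns
        else {}
    )
    return PseudobulkMatrix(
        counts=counts,
        lognorm=lognorm,
        n_cells=n_cells,
        pct_expressing=pct,
        lineage_map=lineage_map,
    )


def filter_genes(pb: PseudobulkMatrix, pct_min: float = 20.0) -> PseudobulkMatrix:
    """Per cell type, keep genes detected in strictly more than ``pct_min``%."""
    mask = pb.pct_expressing > pct_min
    return PseudobulkMatrix(
        counts=pb.counts,
        lognorm=pb.lognorm,
        n_cells=pb.n_cells,
        pct_expressing=pb.pct_expressing,
        lineage_map=pb.lineage_map,
        gene_mask=mask & pb.gene_mask,
    )


def select_samples(
    meta: pd.DataFrame, ga_min: float = 21.0, exclude_rare: bool = True, min_samples: int = 3
) -> pd.DataFrame:
    """Samples eligible for the gestational-age / life-span regression.

    Excludes samples under ``ga_min`` weeks gestation and (by default)
    rare-disease samples; refuses to proceed when fewer than
    ``min_samples`` remain.
    """
    keep = meta["ga_weeks"] >= ga_min
    if exclude_rare:
        keep &= ~meta["rare_disease"].astype(bool)
    out = meta.loc[keep].reset_index(drop=True)
    if len(out) < min_samples:
        raise ValueError(
            f"only {len(out)} samples remain after exclusions; need >= {min_samples} to fit"
        )
    return out


def _bh_within(df: pd.DataFrame, by: list[str]) -> pd.Series:
    fdr = pd.Series(np.nan, index=df.index)
    for _, idx in df.groupby(by, observed=True).groups.items():
        p = df.loc[idx, "p"]
        fdr.loc[idx] = multipletests(p, method="fdr_bh")[1]
    return fdr


def fit_covariate_model(
    pb: PseudobulkMatrix,
    meta: pd.DataFrame,
    terms: tuple[str, ...] = ("GA", "LS"),
    exclude_immune: bool = True,
    min_individuals: int = 3,
) -> pd.DataFrame:
    """OLS of log-normalized pseudobulk on the clinical covariates.

    Per (gene, cell type): ordinary least squares of the pseudobulk
    log-expression on an intercept plus the requested terms (``"GA"``,
    ``"LS"``, ``"DX"``), over the individuals present in ``meta`` (apply
    :func:`select_samples` first for the GA/LS model). Reports the
    coefficient per unit (week or score point) on natural-log expression,
    its standard error, a two-sided t p-value, and BH FDR within each
    (cell type x term) family. Genes constant across individuals get
    coefficient 0 and p = 1, flagged.
    """
    unknown = [t for t in terms if t not in TERM_COLUMNS]
    if unknown:
        raise ValueError(f"unknown model terms {unknown}")
    meta = meta.set_index("sample_id")
    rows = []
    for ct in pb.cell_types:
        if exclude_immune and pb.lineage_map.get(ct) == "immune":
            continue
        cols = [c for c in pb.lognorm.columns if c[1] == ct and c[0] in meta.index]
        if len(cols) < min_individuals:
            continue
        samples = [c[0] for c in cols]
        x = np.column_stack(
            [np.ones(len(samples))]
            + [meta.loc[samples, TERM_COLUMNS[t]].to_numpy(float) for t in terms]
        )
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise CollinearityError(
                f"design matrix rank deficient for cell type {ct!r} (terms {terms})"
            )
        genes = pb.gene_mask.index[pb.gene_mask[ct]] if ct in pb.gene_mask else pb.counts.index
        if len(genes) == 0:
            continue
        y = pb.lognorm.loc[genes, cols].to_numpy(float).T  # individuals x genes
        beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        dof = x.shape[0] - x.shape[1]
        rss = (resid**2).sum(axis=0)
        constant = y.std(axis=0) < 1e-12
        sigma2 = rss / max(dof, 1)
        xtx_inv = np.linalg.inv(x.T @ x)
        for k, term in enumerate(terms, start=1):
            se = np.sqrt(np.maximum(sigma2 * xtx_inv[k, k], 0.0))
            coef = beta[k].copy()
            with np.errstate(divide="ignore", invalid="ignore"):
                tval = np.where(se > 0, coef / se, 0.0)
            p = 2.0 * stats.t.sf(np.abs(tval), df=max(dof, 1))
            coef[constant] = 0.0
            p = np.where(constant | (dof < 1), 1.0, p)
            rows.append(
                pd.DataFrame(
                    {
                        "gene": genes,
                        "cell_type": ct,
                        "term": term,
                        "logFC": coef,
                        "se": se,
                        "p": p,
                        "constant": constant,
                        "n_individuals": len(samples),
                    }
                )
            )
    if not rows:
        return pd.DataFrame(
            columns=["gene", "cell_type", "term", "logFC", "se", "p", "constant", "n_individuals", "fdr"]
        )
    res = pd.concat(rows, ignore_index=True)
    res["fdr"] = _bh_within(res, ["cell_type", "term"])
    return res


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton, as in variance moderation)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def squeeze_variances(s2: np.ndarray, dof: int) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of per-gene variances.

    Fits a scaled inverse-chi-square prior (prior df d0, prior variance
    s0^2) to the observed residual variances by moment matching on the log
    scale, then returns the posterior variances
    (d0*s0^2 + dof*s2) / (d0 + dof) together with (d0, s0^2). Genes with
    zero variance are excluded from prior estimation but still squeezed.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return s2, 0.0, float(np.mean(s2[ok]) if ok.any() else 0.0)
    e = np.log(s2[ok]) - special.digamma(dof / 2.0) + np.log(dof / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, dof / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        post = (d0 * s0_2 + dof * s2) / (d0 + dof)
    else:
        # no excess spread beyond chi-square sampling noise: variances pool
        d0 = np.inf
        s0_2 = float(np.mean(s2))
        post = np.full_like(s2, s0_2)
    return post, float(d0), s0_2


def two_group_contrast(
    pb: PseudobulkMatrix, group_a: str, group_b: str, min_individuals: int = 3
) -> pd.DataFrame:
    """Moderated two-group contrast between two cell types.

    Per gene, compares pseudobulk log expression of ``group_a`` columns
    against ``group_b`` columns across individuals, shrinking per-gene
    residual variances toward a common prior (empirical Bayes) before the
    t-test. ``logFC`` is mean(A) - mean(B) on log expression. BH FDR across
    genes; the conventional significance threshold is FDR < 0.1.
    """
    cols_a = [c for c in pb.lognorm.columns if c[1] == group_a]
    cols_b = [c for c in pb.lognorm.columns if c[1] == group_b]
    if len(cols_a) < min_individuals or len(cols_b) < min_individuals:
        raise ValueError(
            f"need >= {min_individuals} individuals per group; "
            f"got {len(cols_a)} for {group_a!r} and {len(cols_b)} for {group_b!r}"
        )
    mask = None
    if pb.gene_mask is not None and group_a in pb.gene_mask and group_b in pb.gene_mask:
        mask = pb.gene_mask[group_a] | pb.gene_mask[group_b]
    genes = pb.counts.index if mask is None else pb.counts.index[mask]
    ya = pb.lognorm.loc[genes, cols_a].to_numpy(float)
    yb = pb.lognorm.loc[genes, cols_b].to_numpy(float)
    na, nb = ya.shape[1], yb.shape[1]
    dof = na + nb - 2
    logfc = ya.mean(axis=1) - yb.mean(axis=1)
    rss = ((ya - ya.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (yb - yb.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = rss / dof
    s2_post, d0, _ = squeeze_variances(s2, dof)
    stdev_unscaled = np.sqrt(1.0 / na + 1.0 / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = logfc / (stdev_unscaled * np.sqrt(s2_post))
    df_total = min(dof + d0, len(genes) * dof)  # cap at pooled residual df
    constant = s2_post <= 0
    p = np.where(constant, 1.0, 2.0 * stats.t.sf(np.abs(np.nan_to_num(tval)), df=df_total))
    res = pd.DataFrame(
        {
            "gene": genes,
            "cell_type": f"{group_a} vs {group_b}",
            "term": "group_contrast",
            "logFC": np.where(constant, 0.0, logfc),
            "se": stdev_unscaled * np.sqrt(s2_post),
            "p": p,
            "constant": constant,
        }
    )
    res["fdr"] = multipletests(res["p"], method="fdr_bh")[1]
    return res


def overlap_terms(
    results: dict[str, pd.DataFrame], fdr1: float = 0.1, fdr2: float = 0.2
) -> pd.DataFrame:
    """Two-level FDR intersection of per-term association tables.

    A (gene, cell type) pair overlaps terms T1 and T2 when it passes
    FDR < ``fdr1`` in one term and FDR < ``fdr2`` in the other. The triple
    overlap requires every pair of terms to overlap under that rule.
    Returns one row per (gene, cell type) seen in any term, with per-term
    FDRs, per-term-pair overlap flags, an ``overlap_all`` flag, and the
    counts of terms passing each level.
    """
    if not results:
        raise ValueError("at least one term table is required")
    frames = []
    for term, df in results.items():
        if df is None:
            raise ValueError(f"missing result table for term {term!r}")
        frames.append(
            df[["gene", "cell_type", "fdr"]].assign(term=term)
        )
    wide = (
        pd.concat(frames, ignore_index=True)
        .pivot_table(index=["gene", "cell_type"], columns="term", values="fdr")
        .reset_index()
    )
    canonical = {"GA": 0, "LS": 1, "DX": 2}
    terms = sorted(results, key=lambda t: (canonical.get(t, 99), t))
    out = wide.copy()
    fdr_cols = {t: wide[t] if t in wide else pd.Series(np.nan, index=wide.index) for t in terms}
    pair_flags = []
    for t1, t2 in itertools.combinations(terms, 2):
        f1, f2 = fdr_cols[t1], fdr_cols[t2]
        flag = ((f1 < fdr1) & (f2 < fdr2)) | ((f2 < fdr1) & (f1 < fdr2))
        col = f"overlap_{t1}_{t2}"
        out[col] = flag.fillna(False)
        pair_flags.append(col)
    if len(terms) >= 3:
        out["overlap_all"] = out[pair_flags].all(axis=1)
    out["terms_at_10"] = sum((fdr_cols[t] < fdr1).fillna(False).astype(int) for t in terms)
    out["terms_at_20"] = sum((fdr_cols[t] < fdr2).fillna(False).astype(int) for t in terms)
    return out
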