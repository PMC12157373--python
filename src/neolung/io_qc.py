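"""Table IO, quality-control filtering and developmental stage grouping.

Transcript tables follow the Xenium-style schema: one record per detected
transcript with a feature name (gene symbol or a control class), x/y
coordinates in micrometres, a phred-like quality value ``qv``, a segmented
cell assignment ``cell_id`` (``"UNASSIGNED"`` when the transcript fell
outside every nucleus), and a binary ``overlaps_nucleus`` flag. Control
species — "Negative codeword" (decoding error rate) and "Negative probe"
(chemistry background) — ride along in the same table and feed the
cell-level QC percentages but never the expression matrices.

Cells here are nuclei: transcripts are assigned to a cell when they overlap
the segmented nuclear boundary, so nuclear (``overlaps_nucleus == 1``)
transcripts are the ones retained for expression analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

UNASSIGNED = "UNASSIGNED"
NEG_CODEWORD = "Negative codeword"
NEG_PROBE = "Negative probe"
CONTROL_FEATURES = (NEG_CODEWORD, NEG_PROBE)

TRANSCRIPT_COLUMNS = (
    "transcript_id",
    "feature",
    "x_um",
    "y_um",
    "qv",
    "cell_id",
    "overlaps_nucleus",
    "sample_id",
)

CELL_COLUMNS = (
    "cell_id",
    "sample_id",
    "centroid_x_um",
    "centroid_y_um",
    "nuclear_area_um2",
    "cell_type",
    "lineage",
)

METADATA_COLUMNS = ("sample_id", "ga_weeks", "lifespan_weeks", "dx_score", "rare_disease")

STAGES = ("early_canalicular", "late_canalicular", "saccular", "alveolar")
UNSTAGED = "unstaged"
RARE = "rare"


class SchemaError(ValueError):
    """A required column is missing or a value violates the table contract."""


@dataclass(frozen=True)
class QCConfig:
    """Quality-control thresholds.

    Transcripts with ``qv`` below ``qv_min`` are dropped. Cells are kept
    only when strictly above ``min_transcripts`` total and ``min_unique``
    unique gene transcripts, strictly below ``max_area_um2`` nuclear area
    and ``max_pct_neg_codeword`` percent negative codewords, and with
    exactly ``max_pct_neg_probe`` (= 0) percent negative probes.
    """

    qv_min: float = 20.0
    min_transcripts: int = 10
    min_unique: int = 5
    max_area_um2: float = 75.0
    max_pct_neg_codeword: float = 15.0
    max_pct_neg_probe: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "qv_min",
            "min_transcripts",
            "min_unique",
            "max_area_um2",
            "max_pct_neg_codeword",
            "max_pct_neg_probe",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"QCConfig.{name} must be non-negative")


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def _read_table(path: str | Path, format: str | None) -> pd.DataFrame:
    path = Path(path)
    if format is None:
        format = "parquet" if path.suffix == ".parquet" else "csv"
    if format == "parquet":
        return pd.read_parquet(path)
    if format == "csv":
        return pd.read_csv(path)
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    raise ValueError(f"unknown table format {format!r}")


def read_transcripts(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a transcript table (CSV or Parquet) and validate its schema.

    Unknown extra columns are preserved. Raises :class:`SchemaError` naming
    the column when a required field is absent.
    """
    df = _read_table(path, format)
    return validate_transcripts(df)


def validate_transcripts(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, TRANSCRIPT_COLUMNS, "transcript table")
    if not np.isfinite(df["x_um"].to_numpy(float)).all() or not np.isfinite(
        df["y_um"].to_numpy(float)
    ).all():
        raise SchemaError("transcript coordinates must be finite")
    if (df["qv"].to_numpy(float) < 0).any():
        raise SchemaError("qv must be >= 0")
    if df["feature"].isna().any() or (df["feature"].astype(str) == "").any():
        raise SchemaError("feature must be non-empty")
    return df


def write_transcripts(df: pd.DataFrame, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "parquet" if path.suffix == ".parquet" else "csv"
    if format == "parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


def read_cells(path: str | Path, format: str | None = None) -> pd.DataFrame:
    df = _read_table(path, format)
    _require_columns(df, CELL_COLUMNS, "cell table")
    return df


def read_metadata(path: str | Path, format: str | None = None) -> pd.DataFrame:
    df = _read_table(path, format)
    _require_columns(df, METADATA_COLUMNS, "sample metadata table")
    if (df["ga_weeks"] <= 0).any():
        raise SchemaError("ga_weeks must be positive")
    if (df["lifespan_weeks"] < 0).any():
        raise SchemaError("lifespan_weeks must be non-negative")
    if not df["dx_score"].isin([0, 1, 2, 3]).all():
        raise SchemaError("dx_score must be in {0,1,2,3}")
    if "stage" not in df.columns:
        df = df.copy()
        df["stage"] = [
            assign_stage(ga, bool(rare))
            for ga, rare in zip(df["ga_weeks"], df["rare_disease"])
        ]
    return df


def is_control(feature: pd.Series) -> pd.Series:
    """Boolean mask of control (negative codeword / negative probe) records."""
    return feature.isin(CONTROL_FEATURES)


def filter_transcripts(
    t: pd.DataFrame,
    cfg: QCConfig | None = None,
    drop_controls: bool = True,
) -> pd.DataFrame:
    """Apply the transcript-level quality filters.

    Keeps records with ``qv >= qv_min`` (default 20), an actual cell
    assignment, and ``overlaps_nucleus == 1`` (nuclear transcripts are the
    ones partitioned into segmented nuclei and carried into expression
    matrices). With ``drop_controls=True`` (default) the negative-codeword /
    negative-probe records are also removed, which is what downstream
    expression analysis wants; pass ``drop_controls=False`` when the output
    feeds :func:`compute_cell_qc`, whose control percentages need them.
    """
    cfg = cfg or QCConfig()
    validate_transcripts(t)
    keep = (
        (t["qv"].to_numpy(float) >= cfg.qv_min)
        & (t["cell_id"].astype(str) != UNASSIGNED).to_numpy()
        & (t["overlaps_nucleus"].to_numpy(int) == 1)
    )
    if drop_controls:
        keep &= ~is_control(t["feature"]).to_numpy()
    return t.loc[keep].reset_index(drop=True)


def compute_cell_qc(t: pd.DataFrame, cells: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-cell QC metrics from an (assigned, QV-passing) transcript table.

    ``t`` should retain control records (``drop_controls=False`` upstream):
    negative codewords and probes count toward each cell's total transcript
    count, and the control percentages are 100 * control count / total
    count. ``n_unique_genes`` counts distinct non-control features.

    When ``cells`` is given, the metrics are merged into it (left join on
    ``(sample_id, cell_id)``); cells without any transcript get zero counts.
    Cells with zero transcripts never appear in the metric table itself, so
    no percentage is ever 0/0.
    """
    validate_transcripts(t)
    t = t[t["cell_id"].astype(str) != UNASSIGNED]
    key = ["sample_id", "cell_id"]
    ctrl = is_control(t["feature"])
    grp = t.groupby(key, sort=False)
    total = grp.size().rename("n_transcripts")
    neg_cw = t[t["feature"] == NEG_CODEWORD].groupby(key).size()
    neg_pr = t[t["feature"] == NEG_PROBE].groupby(key).size()
    uniq = t[~ctrl].groupby(key)["feature"].nunique()
    qc = total.to_frame()
    qc["n_unique_genes"] = uniq.reindex(qc.index).fillna(0).astype(int)
    qc["pct_neg_codeword"] = 100.0 * neg_cw.reindex(qc.index).fillna(0) / qc["n_transcripts"]
    qc["pct_neg_probe"] = 100.0 * neg_pr.reindex(qc.index).fillna(0) / qc["n_transcripts"]
    qc = qc.reset_index()
    if cells is None:
        return qc
    out = cells.drop(
        columns=[c for c in ("n_transcripts", "n_unique_genes", "pct_neg_codeword", "pct_neg_probe") if c in cells.columns]
    ).merge(qc, on=key, how="left")
    for col, fill in (
        ("n_transcripts", 0),
        ("n_unique_genes", 0),
        ("pct_neg_codeword", 0.0),
        ("pct_neg_probe", 0.0),
    ):
        out[col] = out[col].fillna(fill)
    out["n_transcripts"] = out["n_transcripts"].astype(int)
    out["n_unique_genes"] = out["n_unique_genes"].astype(int)
    return out


def filter_cells(c: pd.DataFrame, cfg: QCConfig | None = None) -> pd.DataFrame:
    """Keep cells passing all five printed thresholds (strict inequalities).

    >10 transcripts, >5 unique genes, <75 um^2 nuclear area, <15% negative
    codewords, and exactly 0% negative probes.
    """
    cfg = cfg or QCConfig()
    _require_columns(
        c,
        ("n_transcripts", "n_unique_genes", "nuclear_area_um2", "pct_neg_codeword", "pct_neg_probe"),
        "cell table (QC fields)",
    )
    keep = (
        (c["n_transcripts"] > cfg.min_transcripts)
        & (c["n_unique_genes"] > cfg.min_unique)
        & (c["nuclear_area_um2"] < cfg.max_area_um2)
        & (c["pct_neg_codeword"] < cfg.max_pct_neg_codeword)
        & (c["pct_neg_probe"] <= cfg.max_pct_neg_probe)
    )
    return c.loc[keep].reset_index(drop=True)


def assign_stage(ga_weeks: float, rare_disease: bool, saccular_from: float = 25.0) -> str:
    """Developmental-stage label from gestational age at birth.

    Early canalicular 16-18 wk, late canalicular 21-24 wk, saccular
    ``saccular_from``-35 wk (25 by default; 26 matches an alternative
    grouping), alveolar >= 36 wk. Samples with a rare developmental lung
    disease form their own "rare" group regardless of gestational age.
    Gestational ages in uncovered gaps (e.g. 19-20 wk) return the explicit
    ``"unstaged"`` label rather than being silently assigned.
    """
    if ga_weeks <= 0:
        raise ValueError("ga_weeks must be positive")
    if rare_disease:
        return RARE
    if 16 <= ga_weeks <= 18:
        return "early_canalicular"
    if 21 <= ga_weeks <= 24:
        return "late_canalicular"
    if saccular_from <= ga_weeks <= 35:
        return "saccular"
    if ga_weeks >= 36:
        return "alveolar"
    return UNSTAGED
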