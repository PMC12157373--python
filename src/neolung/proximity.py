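"""Stage-stratified cell-type proximity enrichment.

Every cell is designated an anchor; the distance and angular orientation to
neighboring cells within a fixed 60-um radius are recorded. For an ordered
pair (A, B), candidate cells (cells not of type A) are cross-classified as
proximal to an A anchor vs not, and type B vs not; a Fisher exact test on
the 2x2 table gives an odds ratio of B being found next to A. Under the
default ``nearest_one`` rule a candidate is proximal when it is the single
nearest neighbor of at least one A anchor; the ``all_within_radius`` rule
treats every candidate within the radius as proximal.

The screen runs the test within each developmental stage (early/late
canalicular, saccular, alveolar) pooled across that stage's sections, and
within each rare-disease sample separately, with Benjamini-Hochberg FDR
across all pair x group tests. Per-pair sign vectors across the four
stages are then binarized and clustered into enrichment/depletion patterns
(at most 2^4 = 16).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .io_qc import RARE, STAGES

logger = logging.getLogger(__name__)

STAGE_ORDER = STAGES  # (early_canalicular, late_canalicular, saccular, alveolar)
STAGE_ABBREV = {"early_canalicular": "EC", "late_canalicular": "LC", "saccular": "S", "alveolar": "A"}


@dataclass(frozen=True)
class ProximityConfig:
    radius_um: float = 60.0
    neighbor_rule: str = "nearest_one"  # or "all_within_radius"
    alpha_fdr: float = 0.1
    min_pair_count: int = 10

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius_um must be positive")
        if not (0 < self.alpha_fdr < 1):
            raise ValueError("alpha_fdr must lie in (0, 1)")
        if self.neighbor_rule not in ("nearest_one", "all_within_radius"):
            raise ValueError(f"unknown neighbor rule {self.neighbor_rule!r}")


def _section_key(cells: pd.DataFrame) -> pd.Series:
    return cells["section_id"] if "section_id" in cells.columns else cells["sample_id"]


def find_neighbors(cells: pd.DataFrame, cfg: ProximityConfig | None = None) -> pd.DataFrame:
    """All within-radius neighbor pairs per section, with distance and angle.

    Every cell acts as an anchor; for each anchor all cells within
    ``radius_um`` are recorded with their distance and the angular
    orientation (atan2, in [0, 2pi)) of the neighbor relative to the
    anchor. ``is_nearest`` marks the single closest neighbor of each
    anchor (ties broken by smallest neighbor cell_id). Pairs never cross
    section boundaries. Anchors with no neighbor in radius are simply
    absent.
    """
    cfg = cfg or ProximityConfig()
    frames = []
    for _, sec in cells.groupby(_section_key(cells), sort=False):
        xy = sec[["centroid_x_um", "centroid_y_um"]].to_numpy(float)
        ids = sec["cell_id"].to_numpy()
        if len(sec) < 2:
            continue
        tree = cKDTree(xy)
        pairs = tree.query_pairs(cfg.radius_um, output_type="ndarray")
        if len(pairs) == 0:
            continue
        i = np.concatenate([pairs[:, 0], pairs[:, 1]])
        j = np.concatenate([pairs[:, 1], pairs[:, 0]])
        d = np.linalg.norm(xy[j] - xy[i], axis=1)
        ang = np.mod(np.arctan2(xy[j, 1] - xy[i, 1], xy[j, 0] - xy[i, 0]), 2 * np.pi)
        nb = pd.DataFrame(
            {
                "anchor_cell_id": ids[i],
                "neighbor_cell_id": ids[j],
                "distance_um": d,
                "angle_rad": ang,
            }
        )
        # nearest: min distance per anchor, tie -> smallest neighbor cell_id
        nb = nb.sort_values(
            ["anchor_cell_id", "distance_um", "neighbor_cell_id"], kind="stable"
        ).reset_index(drop=True)
        nb["is_nearest"] = ~nb["anchor_cell_id"].duplicated()
        frames.append(nb)
    if not frames:
        return pd.DataFrame(
            columns=["anchor_cell_id", "neighbor_cell_id", "distance_um", "angle_rad", "is_nearest"]
        )
    return pd.concat(frames, ignore_index=True)


class DegeneratePairError(ValueError):
    """Raised when a (type A, type B) pair cannot form a 2x2 table."""


def proximity_contingency(
    nb: pd.DataFrame,
    cells: pd.DataFrame,
    a_type: str,
    b_type: str,
    neighbor_rule: str = "nearest_one",
) -> np.ndarray:
    """2x2 counts for the ordered pair (anchor type A, neighbor type B).

    Rows: candidate cell proximal to an A anchor vs not. Columns: candidate
    is type B vs not. Candidates are cells not of type A; each is counted
    once. Under ``nearest_one`` a candidate is proximal when it is the
    single nearest neighbor of at least one A anchor; under
    ``all_within_radius`` when it lies within the radius of one.
    """
    type_of = cells.set_index("cell_id")["cell_type"]
    if (type_of == a_type).sum() == 0 or (type_of == b_type).sum() == 0:
        raise DegeneratePairError(f"pair ({a_type!r}, {b_type!r}) absent from group")
    candidates = cells.loc[cells["cell_type"] != a_type, "cell_id"]
    if len(nb):
        anchors_a = nb["anchor_cell_id"].map(type_of) == a_type
        rows = nb[anchors_a]
        if neighbor_rule == "nearest_one":
            rows = rows[rows["is_nearest"]]
        proximal_ids = set(rows["neighbor_cell_id"])
    else:
        proximal_ids = set()
    is_prox = candidates.isin(proximal_ids).to_numpy()
    is_b = (candidates.map(type_of) == b_type).to_numpy()
    return np.array(
        [
            [int((is_prox & is_b).sum()), int((is_prox & ~is_b).sum())],
            [int((~is_prox & is_b).sum()), int((~is_prox & ~is_b).sum())],
        ]
    )


def fisher_logor(table: np.ndarray) -> tuple[float, float, float, float, bool]:
    """Fisher exact test and log odds ratio on a 2x2 table.

    Returns ``(logOR, ci_low, ci_high, p, degenerate)``. The p-value is the
    two-sided Fisher exact (hypergeometric) probability on the raw table.
    The log odds ratio uses the Haldane-Anscombe correction (0.5 added to
    every cell) whenever any cell is zero, and the 95% CI is the Woolf
    logit interval on the (corrected) table. ``degenerate`` flags tables
    with a zero row or column margin.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must be 2x2 with non-negative integer counts")
    _, p = stats.fisher_exact(np.round(t).astype(int), alternative="two-sided")
    degenerate = bool((t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any())
    if (t == 0).any():
        t = t + 0.5
    log_or = float(np.log(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0])))
    se = float(np.sqrt((1.0 / t).sum()))
    z = 1.959963984540054  # Phi^-1(0.975), Woolf 95% CI
    return log_or, log_or - z * se, log_or + z * se, float(p), degenerate


def proximity_screen(
    cells: pd.DataFrame,
    meta: pd.DataFrame,
    cfg: ProximityConfig | None = None,
    nb: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Test every ordered cell-type pair within every group.

    Groups are the developmental stages (samples pooled within stage) plus
    one group per rare-disease sample. Pairs are tested only when both
    types occur at least ``min_pair_count`` times in the group. 2x2 tables
    are summed over the group's sections (proximity never crosses section
    boundaries). BH FDR is computed across all tests of the screen.
    """
    cfg = cfg or ProximityConfig()
    meta = meta.set_index("sample_id")
    stage_of = cells["sample_id"].map(meta["stage"])
    rare_of = cells["sample_id"].map(meta["rare_disease"].astype(bool))
    group = np.where(rare_of, "rare:" + cells["sample_id"].astype(str), stage_of)
    cells = cells.assign(_group=group)
    if nb is None:
        nb = find_neighbors(cells, cfg)
    anchor_sets = nb.groupby("anchor_cell_id")

    rows = []
    for gname, gcells in cells.groupby("_group", sort=False):
        if gname == "unstaged":
            continue
        counts = gcells["cell_type"].value_counts()
        eligible = counts[counts >= cfg.min_pair_count].index.tolist()
        if len(eligible) < 2:
            logger.info("group %s skipped: fewer than 2 eligible cell types", gname)
            continue
        gnb = nb[nb["anchor_cell_id"].isin(set(gcells["cell_id"]))]
        for a_type, b_type in itertools.permutations(sorted(eligible), 2):
            try:
                table = proximity_contingency(gnb, gcells, a_type, b_type, cfg.neighbor_rule)
            except DegeneratePairError:
                logger.info("pair (%s, %s) skipped in group %s", a_type, b_type, gname)
                continue
            log_or, lo, hi, p, degen = fisher_logor(table)
            rows.append(
                {
                    "anchor_type": a_type,
                    "neighbor_type": b_type,
                    "group": gname,
                    "logOR": log_or,
                    "ci_low": lo,
                    "ci_high": hi,
                    "p_value": p,
                    "degenerate": degen,
                    "n_proximal_b": int(table[0, 0]),
                }
            )
    res = pd.DataFrame(rows)
    if len(res):
        res["fdr"] = multipletests(res["p_value"], method="fdr_bh")[1]
    else:
        res["fdr"] = pd.Series(dtype=float)
    return res


def binarize_and_cluster(results: pd.DataFrame, alpha_fdr: float = 0.1) -> pd.DataFrame:
    """Binarize per-stage logOR signs and cluster pairs into patterns.

    Input is a ProximityResult table covering the four developmental
    stages. Pairs are down-selected to those present in all four stages and
    significant (FDR < ``alpha_fdr``) in at least one. Each pair gets a
    4-long sign vector over (EC, LC, S, A) — logOR > 0 is "+", < 0 is "-",
    exactly 0 is "+" by convention with ``zero_flag`` set — and pairs are
    grouped by exact vector via hierarchical clustering on the binary
    distance matrix cut at zero distance. At most 16 patterns are possible;
    pattern ids follow the descending stepwise order ("+" before "-",
    earliest stage most significant), so (+,+,+,+) is pattern 1.
    """
    staged = results[results["group"].isin(STAGE_ORDER)]
    pivot_lor = staged.pivot_table(
        index=["anchor_type", "neighbor_type"], columns="group", values="logOR"
    )
    pivot_fdr = staged.pivot_table(
        index=["anchor_type", "neighbor_type"], columns="group", values="fdr"
    )
    have_all = pivot_lor.reindex(columns=STAGE_ORDER).dropna()
    if len(have_all) == 0:
        return pd.DataFrame(
            columns=["anchor_type", "neighbor_type", *STAGE_ABBREV.values(), "pattern_id", "zero_flag"]
        )
    sig_any = (pivot_fdr.reindex(have_all.index).reindex(columns=STAGE_ORDER) < alpha_fdr).any(axis=1)
    have_all = have_all[sig_any]
    if len(have_all) == 0:
        return pd.DataFrame(
            columns=["anchor_type", "neighbor_type", *STAGE_ABBREV.values(), "pattern_id", "zero_flag"]
        )

    lor = have_all.to_numpy()
    zero_flag = (lor == 0).any(axis=1)
    binary = (lor < 0).astype(int)  # 0 = "+", 1 = "-"; zeros count as "+"

    if len(binary) > 1 and len(np.unique(binary, axis=0)) > 1:
        z = linkage(pdist(binary, metric="hamming"), method="complete")
        flat = fcluster(z, t=0.0, criterion="distance")
    else:
        flat = np.ones(len(binary), dtype=int)

    # order patterns by their sign tuple: "+" (0) before "-" (1), EC first
    keys = {c: tuple(binary[np.flatnonzero(flat == c)[0]]) for c in np.unique(flat)}
    ordered = sorted(keys, key=lambda c: keys[c])
    pattern_id = {c: i + 1 for i, c in enumerate(ordered)}

    out = pd.DataFrame(
        {
            "anchor_type": [i[0] for i in have_all.index],
            "neighbor_type": [i[1] for i in have_all.index],
        }
    )
    for k, stage in enumerate(STAGE_ORDER):
        out[STAGE_ABBREV[stage]] = np.where(binary[:, k] == 0, "+", "-")
    out["pattern_id"] = [pattern_id[c] for c in flat]
    out["zero_flag"] = zero_flag
    return out
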