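"""Threshold-based cell classification and core-level quality control.

Cells segmented from multiplex-IF TMA images (Hoechst / CK / CD8 / FoxP3
channels) are assigned to tumor, CD8 T-cell, Treg, FoxP3-only, or
unclassified from their mean channel intensities. Lymphocyte markers take
priority over cytokeratin: a cell exceeding both the CK and a lymphocyte
threshold is a lymphocyte, never a tumor cell. Classification is a pure
per-cell function of the intensities and thresholds.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import CD8, CoreSummary, FOXP3_ONLY, ThresholdSet, TREG, TUMOR, UNCLASSIFIED
from .errors import ConfigurationError, SchemaError

INTENSITY_COLUMNS = (
    "intensity_hoechst",
    "intensity_ck",
    "intensity_cd8",
    "intensity_foxp3",
)


def classify_cells(cells: pd.DataFrame, thresholds: ThresholdSet) -> pd.DataFrame:
    """Assign ``cell_class`` to every row from channel intensities.

    Rules (comparison is >= throughout):

    * CD8 >= t_cd8 and FoxP3 >= t_foxp3  -> treg (double positive)
    * CD8 >= t_cd8 and FoxP3 <  t_foxp3  -> cd8
    * CD8 <  t_cd8 and FoxP3 >= t_foxp3  -> foxp3_only
    * otherwise CK >= t_ck               -> tumor
    * otherwise                          -> unclassified

    Returns a copy; input order is preserved and irrelevant to the result.
    """
    missing = [c for c in INTENSITY_COLUMNS if c not in cells.columns]
    if missing:
        raise SchemaError(f"cell table is missing intensity columns: {missing}")
    for col in INTENSITY_COLUMNS:
        bad = cells.index[cells[col].isna()]
        if len(bad):
            raise SchemaError(f"missing {col} value at row(s) {list(bad[:5])}")

    cd8_pos = cells["intensity_cd8"].to_numpy() >= thresholds.t_cd8
    foxp3_pos = cells["intensity_foxp3"].to_numpy() >= thresholds.t_foxp3
    ck_pos = cells["intensity_ck"].to_numpy() >= thresholds.t_ck

    cell_class = np.select(
        [cd8_pos & foxp3_pos, cd8_pos, foxp3_pos, ck_pos],
        [TREG, CD8, FOXP3_ONLY, TUMOR],
        default=UNCLASSIFIED,
    )
    out = cells.copy()
    out["cell_class"] = cell_class
    return out


def summarize_core(cells: pd.DataFrame) -> CoreSummary:
    """Tally cell classes for a single core.

    All rows must share one (participant_id, core_id); an empty frame is a
    valid core with all-zero counts only when identifiers are present as
    columns but then the summary cannot name the core, so empty input raises
    unless the frame carries exactly one id pair in its columns' metadata —
    in practice, pass the per-core group from :func:`summarize_cores`.
    """
    if cells.empty:
        raise SchemaError("summarize_core needs at least one row to identify the core; "
                          "use summarize_cores for cohort-level tallies")
    pids = cells["participant_id"].unique()
    cids = cells["core_id"].unique()
    if len(pids) != 1 or len(cids) != 1:
        raise SchemaError(f"mixed core identifiers: participants={list(pids)}, cores={list(cids)}")
    counts = cells["cell_class"].value_counts()
    return CoreSummary(
        participant_id=str(pids[0]),
        core_id=str(cids[0]),
        n_tumor=int(counts.get(TUMOR, 0)),
        n_cd8=int(counts.get(CD8, 0)),
        n_treg=int(counts.get(TREG, 0)),
        n_foxp3_only=int(counts.get(FOXP3_ONLY, 0)),
        n_unclassified=int(counts.get(UNCLASSIFIED, 0)),
    )


def summarize_cores(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-core class tallies for a whole cohort table.

    Returns one row per (participant_id, core_id) with columns n_tumor,
    n_cd8, n_treg, n_foxp3_only, n_unclassified, n_total and passed_qc
    (unset, pd.NA) — feed the result to :func:`qc_filter_cores`.
    """
    if "cell_class" not in cells.columns:
        raise SchemaError("cells must be classified first (no cell_class column)")
    tab = (
        cells.groupby(["participant_id", "core_id"], sort=True)["cell_class"]
        .value_counts()
        .unstack(fill_value=0)
    )
    for cls in (TUMOR, CD8, TREG, FOXP3_ONLY, UNCLASSIFIED):
        if cls not in tab.columns:
            tab[cls] = 0
    out = tab.rename(columns={TUMOR: "n_tumor", CD8: "n_cd8", TREG: "n_treg",
                              FOXP3_ONLY: "n_foxp3_only", UNCLASSIFIED: "n_unclassified"})
    out = out[["n_tumor", "n_cd8", "n_treg", "n_foxp3_only", "n_unclassified"]].reset_index()
    out["n_total"] = out[["n_tumor", "n_cd8", "n_treg", "n_foxp3_only", "n_unclassified"]].sum(axis=1)
    out["passed_qc"] = pd.NA
    return out


def qc_filter_cores(
    summaries: pd.DataFrame,
    min_tumor: int = 1000,
    min_total: int = 3000,
    mode: str = "and",
) -> pd.DataFrame:
    """Flag cores that fail the cell-count quality filter.

    mode='and' (default): a core is removed only when it has both fewer than
    ``min_tumor`` tumor cells and fewer than ``min_total`` total cells.
    mode='or': removed when it fails either bound. Failed cores are flagged
    (``passed_qc=False``), never deleted; downstream pooling uses only
    passed cores.
    """
    if min_tumor < 0 or min_total < 0:
        raise ConfigurationError("QC bounds must be nonnegative")
    if mode not in ("and", "or"):
        raise ConfigurationError(f"QC mode must be 'and' or 'or', got {mode!r}")
    low_tumor = summaries["n_tumor"] < min_tumor
    low_total = summaries["n_total"] < min_total
    failed = (low_tumor & low_total) if mode == "and" else (low_tumor | low_total)
    out = summaries.copy()
    out["passed_qc"] = ~failed
    return out
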