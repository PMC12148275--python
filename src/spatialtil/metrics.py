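"""Tumor->CD8 nearest-neighbor distances and the derived spatial biomarkers.

For each QC-passed TMA core, the Euclidean distance from every tumor cell to
its nearest CD8+ T-cell is computed (KD-tree), truncated at a cap (default
1000 um, the core-size bound). Distances are log10-transformed and pooled
across a participant's cores, then summarized as

* proximity   = 3 - mean(log10 NND)   (high: CD8 cells close to tumor)
* consistency = 1 - var(log10 NND)    (high: uniform tumor-CD8 spacing)

together with the lymphocyte count (CD8 + Treg over passed cores). Metrics
are binarized at cohort-level cutpoints (median or first quartile), and a
quartile-collapse explorer suggests data-driven cutpoints from survival.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .datatypes import CD8, CutpointSpec, NNDSample, ParticipantMetrics, TREG
from .errors import ConfigurationError, SchemaError

DEFAULT_CAP_UM = 1000.0


def nearest_neighbor_distances(
    tumor_points: np.ndarray,
    cd8_points: np.ndarray,
    cap: float = DEFAULT_CAP_UM,
    no_cd8_policy: str = "assign-cap",
) -> np.ndarray | None:
    """Distance from each tumor cell to the nearest CD8 cell, one core.

    Points are (n, 2) arrays in a common micron frame; distances are never
    computed across cores. Distances are truncated at ``cap``. A core with
    zero CD8 cells yields the cap for every tumor cell under
    ``no_cd8_policy='assign-cap'`` (default) or ``None`` (core dropped)
    under ``'drop-core'``.
    """
    if cap <= 0 or not np.isfinite(cap):
        raise ConfigurationError(f"cap must be positive and finite, got {cap}")
    if no_cd8_policy not in ("assign-cap", "drop-core"):
        raise ConfigurationError(f"unknown no-CD8 policy {no_cd8_policy!r}")
    tumor_points = np.asarray(tumor_points, dtype=float).reshape(-1, 2)
    cd8_points = np.asarray(cd8_points, dtype=float).reshape(-1, 2)
    if tumor_points.shape[0] == 0:
        return np.empty(0, dtype=float)
    if cd8_points.shape[0] == 0:
        if no_cd8_policy == "drop-core":
            return None
        return np.full(tumor_points.shape[0], cap, dtype=float)
    d, _ = cKDTree(cd8_points).query(tumor_points, k=1)
    return np.minimum(d, cap)


def pool_participant(
    core_distance_sets, participant_id: str, cap: float = DEFAULT_CAP_UM
) -> NNDSample:
    """Concatenate log10 NNDs across a participant's QC-passed cores.

    Pooling happens before moments are taken (all distances are aggregated
    into one sample, not averaged per core). Zero or negative distances mean
    coincident centroids of different classes and raise: they indicate
    upstream corruption, not a spatial signal.
    """
    parts = [np.asarray(d, dtype=float) for d in core_distance_sets if d is not None]
    if parts:
        dists = np.concatenate(parts)
    else:
        dists = np.empty(0, dtype=float)
    if dists.size and dists.min() <= 0:
        raise SchemaError(
            f"participant {participant_id}: nonpositive NND encountered "
            "(coincident tumor/CD8 centroids?)"
        )
    capped = int(np.count_nonzero(dists >= cap))
    return NNDSample(participant_id=participant_id, values=np.log10(dists), capped_count=capped)


def compute_metrics(sample: NNDSample, core_summaries: pd.DataFrame) -> ParticipantMetrics:
    """Participant-level proximity, consistency, and lymphocyte count.

    ``core_summaries`` holds this participant's QC-passed cores only; the
    lymphocyte count is the raw sum of n_cd8 + n_treg over those cores
    (not area-normalized). Consistency uses the sample variance (n-1);
    with a single distance it is undefined and reported as NaN. A negative
    consistency (log10-NND variance above 1) is allowed but flagged.
    """
    if sample.n_distances == 0:
        raise SchemaError(f"participant {sample.participant_id}: empty NND sample")
    v = sample.values
    proximity = 3.0 - float(np.mean(v))
    if v.size >= 2:
        consistency = 1.0 - float(np.var(v, ddof=1))
    else:
        consistency = float("nan")
    count = int((core_summaries["n_cd8"] + core_summaries["n_treg"]).sum())
    return ParticipantMetrics(
        participant_id=sample.participant_id,
        proximity=proximity,
        consistency=consistency,
        lymphocyte_count=count,
        n_cores_passed=int(len(core_summaries)),
        n_distances=sample.n_distances,
        consistency_flagged=bool(np.isfinite(consistency) and consistency < 0),
    )


_QUANTILE_FOR_RULE = {"median": 0.5, "q1": 0.25}


def binarize(values: pd.Series, spec: CutpointSpec) -> tuple[pd.Series, float]:
    """Split a cohort metric into 'high'/'low' at the spec's cutpoint.

    The cutpoint is computed on the analysis cohort (after exclusions) with
    the linear-interpolation quantile convention; value >= cutpoint maps to
    'high'. Returns (classes, cutpoint).
    """
    vals = values.astype(float)
    if vals.isna().any():
        raise SchemaError("binarize: metric values contain NaN; exclude those participants first")
    if spec.rule == "explicit":
        cut = float(spec.explicit_value)
    else:
        if vals.nunique() < 2:
            raise ConfigurationError("quantile cutpoint undefined: all metric values identical")
        cut = float(np.quantile(vals.to_numpy(), _QUANTILE_FOR_RULE[spec.rule]))
    classes = pd.Series(np.where(vals.to_numpy() >= cut, "high", "low"),
                        index=vals.index, name=f"{spec.metric}_class")
    return classes, cut


def cohort_metrics(
    classified_cells: pd.DataFrame,
    core_summaries: pd.DataFrame,
    cap: float = DEFAULT_CAP_UM,
    no_cd8_policy: str = "assign-cap",
    include_double_positive: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant metrics over all QC-passed cores.

    ``include_double_positive`` adds Treg (CD8+FoxP3+) cells to the CD8
    target set for the NND computation (sensitivity analysis); the
    lymphocyte count is unaffected (always CD8 + Treg).

    Returns (metrics, exclusions): metrics has one row per retained
    participant; exclusions lists dropped participants with reasons.
    """
    if "passed_qc" not in core_summaries.columns or core_summaries["passed_qc"].isna().any():
        raise SchemaError("core summaries must pass through qc_filter_cores first")
    passed = core_summaries[core_summaries["passed_qc"].astype(bool)]
    target_classes = (CD8, TREG) if include_double_positive else (CD8,)

    passed_keys = set(zip(passed["participant_id"], passed["core_id"]))
    cells_by_core = dict(iter(classified_cells.groupby(["participant_id", "core_id"], sort=False)))
    empty = classified_cells.iloc[:0]
    rows, excl = [], []
    for pid, p_cores in passed.groupby("participant_id", sort=True):
        dist_sets = []
        for _, core in p_cores.iterrows():
            sub = cells_by_core.get((pid, core["core_id"]), empty)
            tum = sub.loc[sub["cell_class"] == "tumor", ["x_um", "y_um"]].to_numpy()
            tgt = sub.loc[sub["cell_class"].isin(target_classes), ["x_um", "y_um"]].to_numpy()
            dist_sets.append(nearest_neighbor_distances(tum, tgt, cap=cap, no_cd8_policy=no_cd8_policy))
        sample = pool_participant(dist_sets, str(pid), cap=cap)
        if sample.n_distances == 0:
            excl.append({"participant_id": pid, "reason": "no tumor->CD8 distances in passed cores"})
            continue
        m = compute_metrics(sample, p_cores)
        rows.append({
            "participant_id": pid,
            "proximity": m.proximity,
            "consistency": m.consistency,
            "lymphocyte_count": m.lymphocyte_count,
            "n_cores_passed": m.n_cores_passed,
            "n_distances": m.n_distances,
            "n_capped": sample.capped_count,
            "consistency_flagged": m.consistency_flagged,
        })
    all_pids = core_summaries["participant_id"].unique()
    qc_lost = [p for p in all_pids if not any((p, c) in passed_keys
               for c in core_summaries.loc[core_summaries["participant_id"] == p, "core_id"])]
    for p in qc_lost:
        excl.append({"participant_id": p, "reason": "all cores failed QC"})
    metrics = pd.DataFrame(rows)
    exclusions = pd.DataFrame(excl, columns=["participant_id", "reason"])
    return metrics, exclusions


@dataclass
class CutpointExploration:
    """Result of the quartile-collapse cutpoint search (advisory only)."""

    quartile_log_hrs: np.ndarray        # log HR per quartile group, top quartile referent
    quartile_bounds: np.ndarray         # (q1, q2, q3) metric values
    blocks: list[tuple[int, ...]]       # final merged blocks of quartile indices
    suggested_boundary: str | None      # 'q1' | 'median' | 'q3' | None
    suggested_cutpoint: float | None


_BOUND_NAMES = ("q1", "median", "q3")


def explore_cutpoints(
    values: pd.Series,
    survival: pd.DataFrame,
    epsilon: float = float(np.log(1.5)),
    time_col: str = "time",
    event_col: str = "event",
) -> CutpointExploration:
    """Quartile-split / collapse search for a survival cutpoint.

    The cohort is split at the metric quartiles; a Cox model with group
    indicators (top quartile referent) yields one log HR per group.
    Adjacent groups are merged agglomeratively — closest pair first — while
    their block log HRs (event-weighted means) differ by less than
    ``epsilon``. The boundary between the two final blocks with the largest
    log-HR gap is the suggested cutpoint; if everything collapses to one
    block there is no cutpoint. Advisory only: pipeline defaults stay at
    the median (consistency, count) and first-quartile (proximity) rules.
    """
    from .survival import cox_fit  # local import to avoid cycle

    df = survival.set_index("participant_id").loc[values.index]
    v = values.to_numpy(dtype=float)
    bounds = np.quantile(v, [0.25, 0.5, 0.75])
    group = (v[:, None] >= bounds[None, :]).sum(axis=1)  # 0..3

    events = df[event_col].to_numpy(dtype=bool)
    # pre-merge zero-event groups upward so the Cox fit cannot separate
    blocks: list[list[int]] = [[0], [1], [2], [3]]
    def block_events(b):
        return int(events[np.isin(group, b)].sum())
    i = 0
    while i < len(blocks):
        if block_events(blocks[i]) == 0 and len(blocks) > 1:
            warnings.warn(f"quartile block {blocks[i]} has zero events; merged with neighbor")
            j = i + 1 if i + 1 < len(blocks) else i - 1
            blocks[min(i, j)] = blocks[min(i, j)] + blocks[max(i, j)]
            del blocks[max(i, j)]
            i = 0
        else:
            i += 1

    # fit Cox with block indicators, last (highest) block referent
    fit_df = df[[time_col, event_col]].copy()
    block_of = np.empty(4, dtype=int)
    for bi, b in enumerate(blocks):
        for g in b:
            block_of[g] = bi
    obs_block = block_of[group]
    covs = []
    for bi in range(len(blocks) - 1):
        name = f"grp{bi}"
        fit_df[name] = (obs_block == bi).astype(float)
        covs.append(name)
    if covs:
        fit = cox_fit(fit_df.reset_index(), covs, time_col=time_col, event_col=event_col)
        block_lhr = np.array([fit.coefficients[c] for c in covs] + [0.0])
    else:
        block_lhr = np.array([0.0])

    quartile_log_hrs = np.array([block_lhr[block_of[g]] for g in range(4)])

    # agglomerative collapse of adjacent blocks
    lhrs = list(block_lhr)
    wts = [block_events(b) for b in blocks]
    merged = [tuple(b) for b in blocks]
    while len(merged) > 1:
        gaps = [abs(lhrs[i + 1] - lhrs[i]) for i in range(len(merged) - 1)]
        k = int(np.argmin(gaps))
        if gaps[k] >= epsilon:
            break
        w = wts[k] + wts[k + 1]
        lhrs[k] = (lhrs[k] * wts[k] + lhrs[k + 1] * wts[k + 1]) / max(w, 1)
        wts[k] = w
        merged[k] = merged[k] + merged[k + 1]
        del merged[k + 1], lhrs[k + 1], wts[k + 1]

    if len(merged) == 1:
        return CutpointExploration(quartile_log_hrs, bounds, [tuple(b) for b in merged], None, None)
    gaps = [abs(lhrs[i + 1] - lhrs[i]) for i in range(len(merged) - 1)]
    k = int(np.argmax(gaps))
    top_group_of_lower_block = max(merged[k])
    boundary_idx = top_group_of_lower_block  # boundary after group g is bounds[g]
    return CutpointExploration(
        quartile_log_hrs=quartile_log_hrs,
        quartile_bounds=bounds,
        blocks=[tuple(b) for b in merged],
        suggested_boundary=_BOUND_NAMES[boundary_idx],
        suggested_cutpoint=float(bounds[boundary_idx]),
    )
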