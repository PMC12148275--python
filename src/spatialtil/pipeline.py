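"""End-to-end orchestration: classify -> QC -> metrics -> binarize ->
survival / association, from one validated config.

A run writes its outputs (metrics, model summaries, KM curves, exclusions)
and a manifest recording the config hash, seed, cutpoints used, and
participant counts at every filter step, so identical config + seed yields
byte-identical numeric outputs and the manifest alone suffices to re-run
the pipeline. Input files are never mutated.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .assoc import kruskal_wallis, odds_ratio_2x2
from .classify import classify_cells, qc_filter_cores, summarize_cores
from .datatypes import ContingencyTable2x2, CutpointSpec, ThresholdSet
from .errors import ConfigurationError
from .metrics import DEFAULT_CAP_UM, binarize, cohort_metrics
from .simulate import DEFAULT_CUTPOINTS, SimulationConfig, simulate_cohort
from .survival import cox_fit, km_estimate, logrank_test, lrt_nested, ph_test

METRIC_NAMES = ("proximity", "consistency", "lymphocyte_count")


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run.

    Exactly one of ``simulation`` or the input paths (cell_table +
    survival, labels optional) must be present. Classification thresholds
    are required for file inputs; simulated cohorts default to the
    generator's matched thresholds.
    """

    simulation: SimulationConfig | None = None
    cell_table: str | None = None
    survival: str | None = None
    labels: str | None = None
    thresholds: ThresholdSet | None = None
    qc_min_tumor: int = 1000
    qc_min_total: int = 3000
    qc_mode: str = "and"
    cap: float = DEFAULT_CAP_UM
    no_cd8_policy: str = "assign-cap"
    include_double_positive: bool = False
    cutpoints: dict = field(default_factory=lambda: dict(DEFAULT_CUTPOINTS))
    seed: int = 0

    def __post_init__(self) -> None:
        has_sim = self.simulation is not None
        has_files = self.cell_table is not None
        if has_sim == has_files:
            raise ConfigurationError(
                "config must contain exactly one of a simulation block or input paths"
            )
        if has_files and self.survival is None:
            raise ConfigurationError("file inputs require a survival path")
        if has_files and self.thresholds is None:
            raise ConfigurationError(
                "classification thresholds are required configuration for file inputs "
                "(no numeric defaults exist)"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d and d["simulation"] is not None:
            d["simulation"] = SimulationConfig(**d["simulation"])
        if "thresholds" in d and d["thresholds"] is not None:
            d["thresholds"] = ThresholdSet(**d["thresholds"])
        if "cutpoints" in d and d["cutpoints"] is not None:
            d["cutpoints"] = {
                m: CutpointSpec(metric=m, **spec) for m, spec in d["cutpoints"].items()
            }
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)
    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage in order and write the output bundle to ``out_dir``.

    Returns the bundle as a dict of DataFrames / dicts (metrics, tests,
    cox models, KM curves, associations, manifest). Participants excluded
    at any step are listed with reasons in exclusions.csv, never silently
    dropped.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": _config_hash(config), "seed": config.seed}

    # ---- inputs -----------------------------------------------------------
    if config.simulation is not None:
        sim = config.simulation
        cohort = simulate_cohort(sim, qc_min_tumor=config.qc_min_tumor,
                                 qc_min_total=config.qc_min_total, qc_mode=config.qc_mode)
        cells, surv_df, labels_df = cohort.cells, cohort.survival, cohort.labels
        thresholds = config.thresholds or sim.matched_thresholds
    else:
        cells = _io.read_cell_table(config.cell_table)
        surv_df = _io.read_survival(config.survival)
        labels_df = _io.read_labels(config.labels) if config.labels else None
        thresholds = config.thresholds
    manifest["n_participants_input"] = int(cells["participant_id"].nunique())
    manifest["n_cores_input"] = int(cells.groupby(["participant_id", "core_id"]).ngroups)

    # ---- classify + QC ----------------------------------------------------
    classified = classify_cells(cells, thresholds)
    summaries = qc_filter_cores(
        summarize_cores(classified),
        min_tumor=config.qc_min_tumor,
        min_total=config.qc_min_total,
        mode=config.qc_mode,
    )
    manifest["n_cores_passed_qc"] = int(summaries["passed_qc"].sum())

    # ---- spatial metrics --------------------------------------------------
    metrics, exclusions = cohort_metrics(
        classified, summaries,
        cap=config.cap,
        no_cd8_policy=config.no_cd8_policy,
        include_double_positive=config.include_double_positive,
    )
    manifest["n_participants_with_metrics"] = int(len(metrics))

    undefined = metrics["consistency"].isna()
    if undefined.any():
        exclusions = pd.concat([exclusions, pd.DataFrame({
            "participant_id": metrics.loc[undefined, "participant_id"],
            "reason": "consistency undefined (single NND)",
        })], ignore_index=True)
        metrics = metrics[~undefined].reset_index(drop=True)
    manifest["n_participants_analysis"] = int(len(metrics))

    # ---- binarize ---------------------------------------------------------
    m = metrics.set_index("participant_id")
    cutpoints_used = {}
    for name in METRIC_NAMES:
        spec = config.cutpoints.get(name, DEFAULT_CUTPOINTS[name])
        classes, cut = binarize(m[name], spec)
        m[f"{name}_class"] = classes
        cutpoints_used[name] = {"rule": spec.rule, "value": cut}
    manifest["cutpoints"] = cutpoints_used

    # ---- survival ---------------------------------------------------------
    sdf = surv_df.merge(m.reset_index(), on="participant_id", how="inner")
    for name in METRIC_NAMES:
        sdf[f"{name}_low"] = (sdf[f"{name}_class"] == "low").astype(float)

    km_rows, test_rows, cox_rows = [], [], []
    for name in METRIC_NAMES:
        curves = km_estimate(sdf, group=f"{name}_class")
        for g, cv in curves.items():
            for i in range(cv.event_times.size):
                km_rows.append({
                    "metric": name, "group": g, "time": cv.event_times[i],
                    "survival": cv.survival[i], "ci_lower": cv.ci_lower[i],
                    "ci_upper": cv.ci_upper[i], "n_risk": cv.n_risk[i],
                    "n_event": cv.n_event[i],
                })
        lr = logrank_test(sdf, group=f"{name}_class")
        test_rows.append({"test": f"logrank_{name}", "statistic": lr.statistic,
                          "df": lr.df, "p_value": lr.p_value})
        uni = cox_fit(sdf, [f"{name}_low"])
        hr, lo, hi = uni.hazard_ratios[f"{name}_low"]
        cox_rows.append({"model": f"univariate_{name}", "covariate": f"{name}_low",
                         "coef": uni.coefficients[f"{name}_low"], "hr": hr,
                         "ci_lower": lo, "ci_upper": hi, "loglik": uni.loglik,
                         "n": uni.n, "n_events": uni.n_events})

    full_covs = [f"{name}_low" for name in METRIC_NAMES]
    full = cox_fit(sdf, full_covs)
    for cov in full_covs:
        hr, lo, hi = full.hazard_ratios[cov]
        cox_rows.append({"model": "multivariate", "covariate": cov,
                         "coef": full.coefficients[cov], "hr": hr,
                         "ci_lower": lo, "ci_upper": hi, "loglik": full.loglik,
                         "n": full.n, "n_events": full.n_events})
    count_only = cox_fit(sdf, ["lymphocyte_count_low"])
    lrt = lrt_nested(full, count_only)
    test_rows.append({"test": "lrt_full_vs_count", "statistic": lrt.statistic,
                      "df": lrt.df, "p_value": lrt.p_value})
    spatial_only = cox_fit(sdf, ["proximity_low", "consistency_low"])
    lrt2 = lrt_nested(full, spatial_only)
    test_rows.append({"test": "lrt_full_vs_spatial", "statistic": lrt2.statistic,
                      "df": lrt2.df, "p_value": lrt2.p_value})
    for cov, tr in ph_test(sdf, full_covs).items():
        test_rows.append({"test": f"ph_{cov}", "statistic": tr.statistic,
                          "df": tr.df, "p_value": tr.p_value})

    # ---- associations -----------------------------------------------------
    assoc_rows = []
    if labels_df is not None:
        ldf = m.reset_index().merge(labels_df, on="participant_id", how="inner")
        for label_col in [c for c in labels_df.columns if c != "participant_id"]:
            levels = sorted(ldf[label_col].dropna().unique())
            for name in METRIC_NAMES:
                groups = {str(g): sub[name].to_numpy()
                          for g, sub in ldf.groupby(label_col)}
                kw = kruskal_wallis(groups)
                test_rows.append({"test": f"kw_{name}_by_{label_col}",
                                  "statistic": kw.statistic, "df": kw.df,
                                  "p_value": kw.p_value})
                if len(levels) == 2:
                    c1 = ldf[label_col] == levels[0]
                    hi = ldf[f"{name}_class"] == "high"
                    tab = ContingencyTable2x2(
                        a=int((c1 & hi).sum()), b=int((c1 & ~hi).sum()),
                        c=int((~c1 & hi).sum()), d=int((~c1 & ~hi).sum()),
                        row_labels=(str(levels[0]), str(levels[1])),
                    )
                    orr = odds_ratio_2x2(tab)
                    assoc_rows.append({
                        "label": label_col, "class1": levels[0], "metric": name,
                        "a": tab.a, "b": tab.b, "c": tab.c, "d": tab.d,
                        "odds_ratio": orr.odds_ratio, "ci_lower": orr.ci_lower,
                        "ci_upper": orr.ci_upper,
                    })

    # ---- write bundle -----------------------------------------------------
    bundle = {
        "metrics": m.reset_index(),
        "core_summaries": summaries,
        "exclusions": exclusions,
        "km_curves": pd.DataFrame(km_rows),
        "cox_models": pd.DataFrame(cox_rows),
        "tests": pd.DataFrame(test_rows),
        "associations": pd.DataFrame(assoc_rows, columns=[
            "label", "class1", "metric", "a", "b", "c", "d",
            "odds_ratio", "ci_lower", "ci_upper"]),
        "manifest": manifest,
    }
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            _io.write_table(obj, out / f"{name}.csv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return bundle
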