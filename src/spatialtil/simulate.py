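"""Seeded synthetic TMA cohorts with the statistical structure the
analysis assumes.

A cohort is a set of participants, each with several 1 mm-scale circular
cores. Tumor cells follow a Thomas (parent-offspring Gaussian) cluster
process — the simplest process producing realistically clumped epithelium —
and lymphocytes follow one of three infiltration modes: ``diffuse``
(homogeneous Poisson), ``hotspot`` (Gaussian clusters), or ``peripheral``
(intensity increasing with radial distance). Every cell draws per-channel
log-normal intensities from its true class, so the downstream threshold
classifier has a tunable error rate. Recurrence times are exponential with
proportional hazards on the binarized spatial metrics plus independent
exponential censoring, and categorical labels follow a logistic model with
configurable log odds — so hazard ratios and odds ratios recovered
downstream have known truth.

One global seed expands to independent substreams via numpy SeedSequence
spawn keys: core (participant, core) uses key (0, p_index, c_index),
survival uses (1,), labels (2,). Cores are therefore reproducible
independently of each other.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import qc_filter_cores, summarize_cores
from .datatypes import CD8, CutpointSpec, FOXP3_ONLY, ThresholdSet, TREG, TUMOR, UNCLASSIFIED
from .errors import ConfigurationError
from .metrics import binarize, cohort_metrics

CHANNELS = ("hoechst", "ck", "cd8", "foxp3")

# natural-log location/scale of the log-normal intensity model
_POS = (4.0, 0.4)
_NEG = (1.0, 0.5)


def default_intensity_params() -> dict[str, dict[str, tuple[float, float]]]:
    """Well-separated per-class per-channel (mu, sigma) on the log scale.

    Positive markers sit ~3 sd above the midpoint threshold, giving a
    per-cell misclassification rate of a few per mille.
    """
    return {
        TUMOR: {"hoechst": _POS, "ck": _POS, "cd8": _NEG, "foxp3": _NEG},
        CD8: {"hoechst": _POS, "ck": _NEG, "cd8": _POS, "foxp3": _NEG},
        TREG: {"hoechst": _POS, "ck": _NEG, "cd8": _POS, "foxp3": _POS},
        FOXP3_ONLY: {"hoechst": _POS, "ck": _NEG, "cd8": _NEG, "foxp3": _POS},
        UNCLASSIFIED: {"hoechst": _POS, "ck": _NEG, "cd8": _NEG, "foxp3": _NEG},
    }


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; identical config + seed gives a
    bit-identical cohort.

    ``treg_fraction`` is the fraction of lymphocytes on the FoxP3+
    regulatory lineage; of those, ``double_positive_fraction`` are
    CD8+FoxP3+ (the Treg class counted as lymphocytes) and the rest are
    FoxP3-only. Expected cell numbers per core are Poisson intensities.
    ``survival_betas`` are log hazard ratios on indicator(metric low);
    ``label_log_odds`` are log odds of the first label class per
    indicator(metric high), with the intercept centering the margins.
    """

    n_participants: int = 200
    cores_per_participant: int = 4
    core_radius: float = 500.0
    tumor_intensity: float = 1500.0
    lymphocyte_intensity: float = 200.0
    stroma_intensity: float = 1500.0
    infiltration_mode: str = "diffuse"
    hotspot_count: int = 3
    hotspot_sd: float = 75.0
    tumor_parent_count: int = 8
    tumor_cluster_sd: float = 60.0
    treg_fraction: float = 0.3
    double_positive_fraction: float = 0.5
    intensity_params: dict = field(default_factory=default_intensity_params)
    survival_betas: dict = field(default_factory=lambda: {"proximity": math.log(2.0)})
    baseline_hazard: float = 0.015
    censor_rate: float = 0.085
    label_log_odds: dict = field(default_factory=lambda: {"proximity": math.log(5.0)})
    label_name: str = "immune_class"
    label_classes: tuple[str, str] = ("adaptive_enriched", "ie_quiet")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if not 1 <= self.cores_per_participant <= 8:
            raise ConfigurationError("cores_per_participant must be in [1, 8]")
        if self.core_radius <= 0:
            raise ConfigurationError("core_radius must be positive")
        if self.tumor_intensity <= 0:
            raise ConfigurationError("tumor_intensity must be strictly positive")
        for name in ("lymphocyte_intensity", "stroma_intensity"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if self.infiltration_mode not in ("diffuse", "hotspot", "peripheral"):
            raise ConfigurationError(f"unknown infiltration_mode {self.infiltration_mode!r}")
        if self.hotspot_count < 1 or self.hotspot_sd <= 0:
            raise ConfigurationError("hotspot_count >= 1 and hotspot_sd > 0 required")
        if self.tumor_parent_count < 1 or self.tumor_cluster_sd <= 0:
            raise ConfigurationError("tumor_parent_count >= 1 and tumor_cluster_sd > 0 required")
        for name in ("treg_fraction", "double_positive_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.baseline_hazard <= 0 or self.censor_rate <= 0:
            raise ConfigurationError("baseline_hazard and censor_rate must be strictly positive")

    @property
    def matched_thresholds(self) -> ThresholdSet:
        """Per-channel thresholds at the log-scale midpoint between the
        highest and lowest class locations (used when classifying
        simulated cohorts)."""
        thr = {}
        for ch in ("ck", "cd8", "foxp3"):
            mus = [p[ch][0] for p in self.intensity_params.values()]
            thr[ch] = math.exp((max(mus) + min(mus)) / 2.0)
        return ThresholdSet(t_ck=thr["ck"], t_cd8=thr["cd8"], t_foxp3=thr["foxp3"])


@dataclass
class SyntheticCohort:
    cells: pd.DataFrame
    survival: pd.DataFrame
    labels: pd.DataFrame
    truth: pd.DataFrame       # per-participant true metrics + binarizations
    cutpoints: dict[str, float]
    config: SimulationConfig


def substream(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child generator for (seed, key...) — the documented
    seed-splitting rule."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def _uniform_disc(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    th = rng.random(n) * 2 * np.pi
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def _clustered_in_disc(rng, n: int, centers: np.ndarray, sd: float, radius: float) -> np.ndarray:
    """Offspring points: each assigned a random center, Gaussian offset,
    offsets redrawn until inside the disc."""
    idx = rng.integers(0, len(centers), n)
    pts = centers[idx] + rng.normal(0.0, sd, (n, 2))
    out = np.linalg.norm(pts, axis=1) > radius
    tries = 0
    while out.any():
        pts[out] = centers[idx[out]] + rng.normal(0.0, sd, (int(out.sum()), 2))
        out = np.linalg.norm(pts, axis=1) > radius
        tries += 1
        if tries > 10_000:  # pragma: no cover - centers inside disc, sd finite
            raise RuntimeError("rejection sampling failed to place clustered points")
    return pts


def simulate_core(
    config: SimulationConfig,
    participant_id: str,
    core_id: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One TMA core: clustered tumor cells, mode-dependent lymphocytes,
    diffuse stromal background; log-normal intensities per true class."""
    R = config.core_radius
    # tumor: Thomas process (Poisson parents, Gaussian offspring)
    n_parents = max(1, int(rng.poisson(config.tumor_parent_count)))
    parents = _uniform_disc(rng, n_parents, R)
    n_tumor = int(rng.poisson(config.tumor_intensity))
    tumor_xy = _clustered_in_disc(rng, n_tumor, parents, config.tumor_cluster_sd, R) \
        if n_tumor else np.empty((0, 2))

    # lymphocytes per infiltration mode
    n_lymph = int(rng.poisson(config.lymphocyte_intensity))
    if n_lymph == 0:
        lymph_xy = np.empty((0, 2))
    elif config.infiltration_mode == "diffuse":
        lymph_xy = _uniform_disc(rng, n_lymph, R)
    elif config.infiltration_mode == "hotspot":
        centers = _uniform_disc(rng, config.hotspot_count, R)
        lymph_xy = _clustered_in_disc(rng, n_lymph, centers, config.hotspot_sd, R)
    else:  # peripheral: radial intensity ~ r, so pdf(r) ~ r^2
        r = R * rng.random(n_lymph) ** (1.0 / 3.0)
        th = rng.random(n_lymph) * 2 * np.pi
        lymph_xy = np.column_stack([r * np.cos(th), r * np.sin(th)])

    # lymphocyte phenotypes: FoxP3 lineage -> treg (double positive) or FoxP3-only
    lineage = rng.random(n_lymph) < config.treg_fraction
    dp = rng.random(n_lymph) < config.double_positive_fraction
    lymph_cls = np.where(lineage, np.where(dp, TREG, FOXP3_ONLY), CD8)

    n_stroma = int(rng.poisson(config.stroma_intensity))
    stroma_xy = _uniform_disc(rng, n_stroma, R) if n_stroma else np.empty((0, 2))

    xy = np.vstack([tumor_xy, lymph_xy, stroma_xy])
    cls = np.concatenate([
        np.full(n_tumor, TUMOR, dtype=object),
        lymph_cls.astype(object),
        np.full(n_stroma, UNCLASSIFIED, dtype=object),
    ])
    df = pd.DataFrame({
        "participant_id": participant_id,
        "core_id": core_id,
        "x_um": xy[:, 0],
        "y_um": xy[:, 1],
    })
    for ch in CHANNELS:
        vals = np.empty(len(df))
        for c in np.unique(cls):
            mu, sigma = config.intensity_params[c][ch]
            mask = cls == c
            vals[mask] = rng.lognormal(mu, sigma, int(mask.sum()))
        df[f"intensity_{ch}"] = vals
    df["true_class"] = cls
    return df


def simulate_survival(
    metrics_binary: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Exponential event times under proportional hazards on the binarized
    metrics, with independent exponential censoring.

    ``metrics_binary`` is indexed by participant_id with 'high'/'low'
    columns; every metric named in ``config.survival_betas`` must be
    present. hazard = baseline_hazard * exp(sum beta * indicator(low)).
    """
    rng = substream(config.seed, 1) if rng is None else rng
    missing = [m for m in config.survival_betas if m not in metrics_binary.columns]
    if missing:
        raise ConfigurationError(f"metrics_binary lacks columns for betas: {missing}")
    n = len(metrics_binary)
    log_hr = np.zeros(n)
    for metric, beta in config.survival_betas.items():
        log_hr += beta * (metrics_binary[metric].to_numpy() == "low")
    hazard = config.baseline_hazard * np.exp(log_hr)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(1.0 / config.censor_rate, n)
    time = np.maximum(np.minimum(t_event, t_cens), 1e-12)
    return pd.DataFrame({
        "participant_id": metrics_binary.index,
        "time": time,
        "event": (t_event <= t_cens).astype(int),
    })


def simulate_labels(
    metrics_binary: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Categorical labels from a logistic model on the binarized metrics.

    log-odds of the first label class = -0.5 * sum(log_odds)  (balanced
    margins) + sum over metrics of log_odds * indicator(high).
    """
    rng = substream(config.seed, 2) if rng is None else rng
    missing = [m for m in config.label_log_odds if m not in metrics_binary.columns]
    if missing:
        raise ConfigurationError(f"metrics_binary lacks columns for log-odds: {missing}")
    eta = np.full(len(metrics_binary), -0.5 * sum(config.label_log_odds.values()))
    for metric, lo in config.label_log_odds.items():
        eta = eta + lo * (metrics_binary[metric].to_numpy() == "high")
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-eta))
    cls1 = rng.random(len(metrics_binary)) < p
    return pd.DataFrame({
        "participant_id": metrics_binary.index,
        config.label_name: np.where(cls1, config.label_classes[0], config.label_classes[1]),
    })


DEFAULT_CUTPOINTS = {
    "proximity": CutpointSpec("proximity", rule="q1"),
    "consistency": CutpointSpec("consistency", rule="median"),
    "lymphocyte_count": CutpointSpec("lymphocyte_count", rule="median"),
}


def simulate_cohort(
    config: SimulationConfig,
    qc_min_tumor: int = 1000,
    qc_min_total: int = 3000,
    qc_mode: str = "and",
) -> SyntheticCohort:
    """Full cohort: cells for every core, true per-participant metrics
    (recomputed with the production spatial-metrics code on the true
    classes), survival, and labels.

    The QC bounds used when deriving the truth metrics default to the
    analysis defaults; pass smaller bounds alongside reduced cell
    intensities. Truth binarizations use the analysis cutpoint rules
    (first quartile for proximity, median for consistency and count).
    """
    tables = []
    for p in range(config.n_participants):
        pid = f"P{p + 1:05d}"
        for c in range(config.cores_per_participant):
            rng = substream(config.seed, 0, p, c)
            tables.append(simulate_core(config, pid, f"{pid}-C{c + 1}", rng))
    cells = pd.concat(tables, ignore_index=True)

    truth_cells = cells.copy()
    truth_cells["cell_class"] = truth_cells["true_class"]
    summaries = qc_filter_cores(summarize_cores(truth_cells),
                                min_tumor=qc_min_tumor, min_total=qc_min_total, mode=qc_mode)
    if not summaries["passed_qc"].any():
        raise ConfigurationError(
            "every simulated core fails QC; raise the cell intensities or relax the QC bounds"
        )
    metrics, _ = cohort_metrics(truth_cells, summaries)
    metrics = metrics.set_index("participant_id")

    cutpoints: dict[str, float] = {}
    binary = pd.DataFrame(index=metrics.index)
    for name, spec in DEFAULT_CUTPOINTS.items():
        try:
            classes, cut = binarize(metrics[name], spec)
        except ConfigurationError:
            # degenerate cohort (e.g. zero lymphocytes everywhere): the
            # metric is constant, so the split carries no information
            warnings.warn(f"metric {name!r} is constant across the cohort; "
                          "all participants labelled 'high'")
            classes = pd.Series("high", index=metrics.index)
            cut = float(metrics[name].iloc[0])
        binary[name] = classes
        cutpoints[name] = cut

    survival = simulate_survival(binary, config)
    labels = simulate_labels(binary, config)
    truth = metrics.join(binary.add_suffix("_class")).reset_index()
    return SyntheticCohort(cells=cells, survival=survival, labels=labels,
                           truth=truth, cutpoints=cutpoints, config=config)
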