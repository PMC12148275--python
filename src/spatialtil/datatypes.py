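"""Core value types for the spatial-TIL analysis.

Cell tables, survival records and label maps travel through the pipeline as
pandas DataFrames with documented column schemas (see :mod:`spatialtil.io`);
the small result objects below carry per-core / per-participant summaries and
statistical results.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

# Cell classes assigned by the threshold classifier.
TUMOR = "tumor"
CD8 = "cd8"
TREG = "treg"
FOXP3_ONLY = "foxp3_only"
UNCLASSIFIED = "unclassified"
CELL_CLASSES = (TUMOR, CD8, TREG, FOXP3_ONLY, UNCLASSIFIED)

#: classes counted as lymphocytes for the count biomarker (CD8 + Treg;
#: FoxP3-only cells count toward totals but not the lymphocyte count)
LYMPHOCYTE_CLASSES = (CD8, TREG)


@dataclass(frozen=True)
class ThresholdSet:
    """Per-channel intensity thresholds for the simple threshold classifier.

    Units are the same arbitrary fluorescence units as the cell-table
    intensity columns. Comparison is ``>=`` everywhere (the left boundary is
    included in "exceeds").
    """

    t_ck: float
    t_cd8: float
    t_foxp3: float

    def __post_init__(self) -> None:
        for name in ("t_ck", "t_cd8", "t_foxp3"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ConfigurationError(f"threshold {name} must be finite and >= 0, got {v}")


@dataclass
class CoreSummary:
    """Class tallies for one TMA core; ``passed_qc`` is set by the QC filter."""

    participant_id: str
    core_id: str
    n_tumor: int
    n_cd8: int
    n_treg: int
    n_foxp3_only: int
    n_unclassified: int
    passed_qc: bool | None = None

    @property
    def n_total(self) -> int:
        return self.n_tumor + self.n_cd8 + self.n_treg + self.n_foxp3_only + self.n_unclassified


@dataclass
class NNDSample:
    """Pooled log10 tumor->CD8 nearest-neighbor distances for one participant.

    ``values`` holds log10(microns) over all QC-passed cores; ``capped_count``
    is the number of distances truncated at the cap (cap default 1000 um, so
    values never exceed 3).
    """

    participant_id: str
    values: np.ndarray
    capped_count: int = 0

    @property
    def n_distances(self) -> int:
        return int(self.values.size)


@dataclass
class ParticipantMetrics:
    """Proximity, consistency, and lymphocyte count for one participant.

    proximity = 3 - mean(log10 NND); consistency = 1 - var(log10 NND)
    (sample variance, n-1 denominator). ``consistency`` is NaN when fewer
    than two distances are available. ``consistency_flagged`` marks values
    below 0 (possible when the log10-NND variance exceeds 1).
    """

    participant_id: str
    proximity: float
    consistency: float
    lymphocyte_count: int
    n_cores_passed: int
    n_distances: int
    consistency_flagged: bool = False
    proximity_class: str | None = None
    consistency_class: str | None = None
    count_class: str | None = None


@dataclass(frozen=True)
class CutpointSpec:
    """How to binarize one metric across the cohort.

    rule: 'median', 'q1' (first quartile), or 'explicit'. Orientation is
    fixed: value >= cutpoint -> 'high'. Quantiles use linear interpolation.
    """

    metric: str
    rule: str = "median"
    explicit_value: float | None = None

    def __post_init__(self) -> None:
        if self.rule not in ("median", "q1", "explicit"):
            raise ConfigurationError(f"unknown cutpoint rule {self.rule!r}")
        if (self.rule == "explicit") != (self.explicit_value is not None):
            raise ConfigurationError("explicit_value is required iff rule='explicit'")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 counts: rows are classes, columns biomarker high/low.

    a = class-1 & high, b = class-1 & low, c = class-2 & high,
    d = class-2 & low.
    """

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("class1", "class2")
    col_labels: tuple[str, str] = ("high", "low")

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ConfigurationError("contingency counts must be nonnegative integers")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    method: str


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit estimate for one group.

    ``survival`` holds S(t) at each observed event time; ``ci_lower`` /
    ``ci_upper`` are pointwise 95% log-log (exponential Greenwood) bounds
    clamped to [0, 1].
    """

    group: str
    event_times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model.

    ``coefficients`` are log hazard ratios; ``hazard_ratios`` maps each
    covariate to (HR, lo95, hi95) on the HR scale (Wald intervals).
    """

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    hazard_ratios: dict[str, tuple[float, float, float]]
    loglik: float
    n: int
    n_events: int
    ties_method: str
    covariates: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.covariates:
            self.covariates = tuple(self.coefficients)
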