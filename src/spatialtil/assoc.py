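"""Non-survival inference: Kruskal-Wallis, Spearman, and 2x2 odds ratios.

Ranks use midranks throughout. The default odds-ratio method is the sample
OR (ad/bc) with a Woolf log-normal confidence interval; an exact
conditional-MLE estimate (noncentral hypergeometric) is available as
``method='conditional_mle'``. Published contingency counts relating the
spatial biomarkers to gene-expression immune classes ship as a packaged
fixture loadable with :func:`load_reference_tables`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ContingencyTable2x2, TestResult
from .errors import ConfigurationError, SchemaError

__all__ = [
    "kruskal_wallis",
    "spearman",
    "odds_ratio_2x2",
    "OddsRatioResult",
    "load_reference_tables",
]


def kruskal_wallis(groups: dict[str, np.ndarray]) -> TestResult:
    """Kruskal-Wallis H test (nonparametric one-way ANOVA) with midrank
    ties correction; chi-square reference with df = groups - 1."""
    if len(groups) < 2:
        raise SchemaError("Kruskal-Wallis needs >= 2 groups")
    arrays = []
    for name, vals in groups.items():
        a = np.asarray(vals, dtype=float)
        if a.size == 0:
            raise SchemaError(f"group {name!r} has zero observations")
        arrays.append(a)
    if sum(a.size for a in arrays) < 3:
        raise SchemaError("Kruskal-Wallis needs total n >= 3")
    try:
        h, p = stats.kruskal(*arrays)
    except ValueError as exc:  # all values identical
        if "identical" in str(exc):
            h, p = 0.0, 1.0
        else:  # pragma: no cover
            raise
    return TestResult(statistic=float(h), df=len(groups) - 1,
                      p_value=float(p), method="kruskal-wallis")


def spearman(x, y) -> tuple[float, TestResult]:
    """Spearman rank correlation (Pearson on midranks) with t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise SchemaError("spearman needs equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise SchemaError("spearman undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), TestResult(statistic=float(rho), df=x.size - 2,
                                  p_value=float(p), method="spearman")


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_lower: float
    ci_upper: float
    method: str
    degenerate: bool = False

    def rounded(self, ndigits: int = 1) -> float:
        """Display convention for published tables (one decimal)."""
        return round(self.odds_ratio, ndigits)


def odds_ratio_2x2(table: ContingencyTable2x2, method: str = "sample") -> OddsRatioResult:
    """Odds ratio for a 2x2 biomarker-by-class table with a 95% CI.

    method='sample': OR = (a*d)/(b*c) with the Woolf log-normal interval;
    any zero cell raises with a recommendation to use the exact method
    rather than applying a silent continuity correction.
    method='conditional_mle': exact conditional estimate (root of the
    noncentral hypergeometric likelihood) with an exact interval.
    An infinite/undefined OR (zero margin or zero cell under the exact
    method) is returned with ``degenerate=True``.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if method == "sample":
        if min(a, b, c, d) == 0:
            if b == 0 or c == 0:
                raise ConfigurationError(
                    "sample odds ratio undefined with a zero cell; "
                    "use method='conditional_mle' for an exact estimate"
                )
            # a or d zero: OR = 0 exactly; CI degenerate
            return OddsRatioResult(0.0, 0.0, float("nan"), "sample", degenerate=True)
        or_ = (a * d) / (b * c)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        z = stats.norm.ppf(0.975)
        return OddsRatioResult(
            odds_ratio=float(or_),
            ci_lower=float(math.exp(math.log(or_) - z * se)),
            ci_upper=float(math.exp(math.log(or_) + z * se)),
            method="sample (Woolf CI)",
        )
    if method == "conditional_mle":
        res = stats.contingency.odds_ratio([[a, b], [c, d]], kind="conditional")
        ci = res.confidence_interval(confidence_level=0.95)
        est = float(res.statistic)
        return OddsRatioResult(
            odds_ratio=est,
            ci_lower=float(ci.low),
            ci_upper=float(ci.high),
            method="conditional MLE (exact CI)",
            degenerate=not math.isfinite(est) or est == 0.0,
        )
    raise ConfigurationError(f"unknown odds-ratio method {method!r}")


_FIXTURE = "table1_contingency.csv"


def load_reference_tables() -> dict[tuple[str, str], ContingencyTable2x2]:
    """Packaged contingency counts: spatial biomarkers vs immune classes.

    Keys are (biomarker, comparison) with biomarker in {proximity,
    consistency, lymphocyte_count} and comparison in {immune_class
    (Adaptive-Enriched vs Innate-Enriched/Quiet), genomic_instability
    (AGI vs NGI)}. Row 1 of each table is the first class listed in the
    fixture (AE or AGI).
    """
    with resources.files("spatialtil.data").joinpath(_FIXTURE).open() as fh:
        df = pd.read_csv(fh)
    out: dict[tuple[str, str], ContingencyTable2x2] = {}
    for (bm, comp), sub in df.groupby(["biomarker", "comparison"], sort=False):
        if len(sub) != 2:
            raise SchemaError(f"fixture block ({bm}, {comp}) must have exactly 2 rows")
        r1, r2 = sub.iloc[0], sub.iloc[1]
        out[(bm, comp)] = ContingencyTable2x2(
            a=int(r1["n_high"]), b=int(r1["n_low"]),
            c=int(r2["n_high"]), d=int(r2["n_low"]),
            row_labels=(str(r1["class_label"]), str(r2["class_label"])),
        )
    return out
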