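"""Recurrence-free-survival estimation and group contrasts.

Kaplan-Meier curves with 95% log-log bounds, the (unweighted) log-rank
test, Cox proportional-hazards fits with Wald hazard-ratio intervals,
nested likelihood-ratio tests, and the Grambsch-Therneau proportionality
check on scaled Schoenfeld residuals (KM time transform, the cox.zph
default).

KM/log-rank and the proportionality test are backed by lifelines; Cox fits
use statsmodels PHReg, which exposes both Efron (default) and Breslow tie
handling. The hand-computed fixtures in the test suite are the binding
contract for all of them.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, proportional_hazard_test
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from .datatypes import CoxFit, KMCurve, TestResult
from .errors import ConvergenceError, SchemaError

__all__ = [
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "cox_score_test",
    "lrt_nested",
    "ph_test",
]


def _check_records(records: pd.DataFrame, time_col: str, event_col: str) -> None:
    if time_col not in records.columns or event_col not in records.columns:
        raise SchemaError(f"survival records need '{time_col}' and '{event_col}' columns")
    t = records[time_col].to_numpy(dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise SchemaError("follow-up times must be finite and > 0")
    e = records[event_col].to_numpy()
    if not np.isin(e, [0, 1, True, False]).all():
        raise SchemaError("event indicator must be 0/1")


def km_estimate(
    records: pd.DataFrame,
    group: str | None = None,
    time_col: str = "time",
    event_col: str = "event",
) -> dict[str, KMCurve]:
    """Product-limit RFS estimate per group, with Greenwood-based bounds.

    Confidence bounds are 95% pointwise on the log(-log S) scale
    (exponential Greenwood), clamped to [0, 1]. A group with zero events
    yields a flat curve at 1 with degenerate bounds and a warning.
    """
    _check_records(records, time_col, event_col)
    groups = {"all": records} if group is None else {
        str(g): sub for g, sub in records.groupby(group)
    }
    out: dict[str, KMCurve] = {}
    for name, sub in groups.items():
        if sub.empty:
            raise SchemaError(f"group {name!r} has no records")
        if sub[event_col].sum() == 0:
            warnings.warn(f"group {name!r} has zero events; KM curve is flat at 1")
        kmf = KaplanMeierFitter(alpha=0.05)
        kmf.fit(sub[time_col], event_observed=sub[event_col])
        tab = kmf.event_table
        ev = tab[tab["observed"] > 0]
        times = ev.index.to_numpy(dtype=float)
        surv = kmf.survival_function_.loc[times, "KM_estimate"].to_numpy()
        ci = kmf.confidence_interval_survival_function_
        lo = np.clip(ci.loc[times].iloc[:, 0].to_numpy(), 0.0, 1.0)
        hi = np.clip(ci.loc[times].iloc[:, 1].to_numpy(), 0.0, 1.0)
        out[name] = KMCurve(
            group=name,
            event_times=times,
            survival=surv,
            ci_lower=lo,
            ci_upper=hi,
            n_risk=ev["at_risk"].to_numpy(dtype=int),
            n_event=ev["observed"].to_numpy(dtype=int),
        )
    return out


def logrank_test(
    records: pd.DataFrame,
    group: str,
    time_col: str = "time",
    event_col: str = "event",
) -> TestResult:
    """Standard (unweighted) log-rank chi-square across >= 2 groups."""
    _check_records(records, time_col, event_col)
    k = records[group].nunique()
    if k < 2:
        raise SchemaError(f"log-rank test needs >= 2 groups, got {k}")
    if records[event_col].sum() == 0:
        raise SchemaError("log-rank test needs at least one event")
    res = multivariate_logrank_test(records[time_col], records[group], records[event_col])
    return TestResult(
        statistic=float(res.test_statistic),
        df=k - 1,
        p_value=float(res.p_value),
        method="log-rank",
    )


def cox_fit(
    records: pd.DataFrame,
    covariates: list[str],
    ties: str = "efron",
    time_col: str = "time",
    event_col: str = "event",
) -> CoxFit:
    """Cox proportional-hazards fit by partial-likelihood Newton-Raphson.

    Covariates must be numeric (binarized metric classes are encoded by the
    caller). Wald 95% intervals are reported on the hazard-ratio scale.
    Non-convergence or a monotone likelihood (complete separation) raises
    :class:`ConvergenceError` — never a silent result.
    """
    _check_records(records, time_col, event_col)
    if ties not in ("efron", "breslow"):
        raise SchemaError(f"ties must be 'efron' or 'breslow', got {ties!r}")
    if not covariates:
        raise SchemaError("at least one covariate is required")
    X = records[list(covariates)].to_numpy(dtype=float)
    if np.any(~np.isfinite(X)):
        raise SchemaError("covariates contain non-finite values")
    const = [c for c, s in zip(covariates, X.std(axis=0)) if s == 0]
    if const:
        raise ConvergenceError(f"covariate(s) with no contrast (constant): {const}")
    n_events = int(records[event_col].sum())
    if n_events == 0:
        raise SchemaError("Cox fit needs at least one event")

    model = PHReg(records[time_col].to_numpy(dtype=float), X,
                  status=records[event_col].to_numpy(dtype=float), ties=ties)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="newton", maxiter=100, tol=1e-9, disp=0)
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    converged = bool(res.mle_retvals.get("converged", True)) if hasattr(res, "mle_retvals") else True
    if (not converged) or np.any(~np.isfinite(params)) or np.any(~np.isfinite(bse)) \
            or np.max(np.abs(params)) > 20:
        raise ConvergenceError(
            "Cox partial likelihood did not converge (possible complete separation)"
        )
    z = stats.norm.ppf(0.975)
    coefs = dict(zip(covariates, params))
    ses = dict(zip(covariates, bse))
    hrs = {
        c: (float(np.exp(b)), float(np.exp(b - z * s)), float(np.exp(b + z * s)))
        for c, b, s in zip(covariates, params, bse)
    }
    return CoxFit(
        coefficients={c: float(v) for c, v in coefs.items()},
        standard_errors={c: float(v) for c, v in ses.items()},
        hazard_ratios=hrs,
        loglik=float(model.loglike(params)),
        n=int(len(records)),
        n_events=n_events,
        ties_method=ties,
        covariates=tuple(covariates),
    )


def cox_score_test(
    records: pd.DataFrame,
    covariates: list[str],
    ties: str = "breslow",
    time_col: str = "time",
    event_col: str = "event",
) -> TestResult:
    """Partial-likelihood score test at beta = 0.

    With a single binary covariate and no tied event times this equals the
    two-group log-rank chi-square exactly (classical equivalence).
    """
    _check_records(records, time_col, event_col)
    X = records[list(covariates)].to_numpy(dtype=float)
    model = PHReg(records[time_col].to_numpy(dtype=float), X,
                  status=records[event_col].to_numpy(dtype=float), ties=ties)
    beta0 = np.zeros(X.shape[1])
    u = model.score(beta0)
    info = -model.hessian(beta0)
    stat = float(u @ np.linalg.solve(info, u))
    df = X.shape[1]
    return TestResult(statistic=stat, df=df,
                      p_value=float(stats.chi2.sf(stat, df)), method="cox-score")


def lrt_nested(full: CoxFit, reduced: CoxFit) -> TestResult:
    """Likelihood-ratio test between nested Cox models on the same records."""
    if not set(reduced.covariates) <= set(full.covariates):
        raise SchemaError("models are not nested: reduced covariates are not a subset of full")
    if (full.n, full.n_events) != (reduced.n, reduced.n_events):
        raise SchemaError("nested models must be fit on the same records")
    df = len(full.covariates) - len(reduced.covariates)
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return TestResult(statistic=stat, df=df, p_value=p, method="likelihood-ratio")


def ph_test(
    records: pd.DataFrame,
    covariates: list[str],
    time_col: str = "time",
    event_col: str = "event",
    time_transform: str = "km",
) -> dict[str, TestResult]:
    """Grambsch-Therneau proportional-hazards check.

    Scaled Schoenfeld residuals are regressed on a transform of event time
    (default: the Kaplan-Meier transform, matching cox.zph's default);
    the result maps each covariate to a df-1 chi-square score test, plus a
    'global' entry (df = number of covariates) computed from the unscaled
    residuals and the inverse information matrix.
    """
    _check_records(records, time_col, event_col)
    n_events = int(records[event_col].sum())
    if n_events < 3:
        raise SchemaError("proportionality test needs at least 3 events")
    df_fit = records[[time_col, event_col] + list(covariates)].reset_index(drop=True)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df_fit, duration_col=time_col, event_col=event_col)
        res = proportional_hazard_test(cph, df_fit, time_transform=time_transform)
    out: dict[str, TestResult] = {}
    summ = res.summary
    for cov in covariates:
        stat = float(summ.loc[cov, "test_statistic"])
        out[cov] = TestResult(statistic=stat, df=1,
                              p_value=float(summ.loc[cov, "p"]),
                              method=f"grambsch-therneau ({time_transform})")

    # global statistic: T = (d/c) u' V u with u = sum (g_k - gbar) s_k,
    # V the inverse information, c = sum (g_k - gbar)^2, d = event count
    sch = cph.compute_residuals(df_fit, "schoenfeld")
    ev_times = df_fit.loc[sch.index, time_col].to_numpy(dtype=float)
    kmf = KaplanMeierFitter().fit(df_fit[time_col], df_fit[event_col])
    if time_transform == "km":
        g = 1.0 - kmf.predict(ev_times).to_numpy(dtype=float)
    elif time_transform == "rank":
        g = stats.rankdata(ev_times)
    elif time_transform == "log":
        g = np.log(ev_times)
    else:
        g = ev_times
    gc = g - g.mean()
    S = sch[list(covariates)].to_numpy(dtype=float)
    u = gc @ S
    V = cph.variance_matrix_.loc[list(covariates), list(covariates)].to_numpy(dtype=float)
    c = float(gc @ gc)
    stat = float(n_events / c * (u @ V @ u))
    k = len(covariates)
    out["global"] = TestResult(statistic=stat, df=k,
                               p_value=float(stats.chi2.sf(stat, k)),
                               method=f"grambsch-therneau global ({time_transform})")
    return out
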