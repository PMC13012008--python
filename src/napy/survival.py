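"""Kaplan-Meier estimation and Cox proportional-hazards models of overall survival.

Overall survival (OS) is modeled per subtype and against clinical
covariates (sex, T-effector score, TAM score, lines of therapy, age).
Kaplan-Meier medians use the smallest time at which the product-limit
estimate drops to 0.5 or below, with log-log confidence intervals; Cox
models use Efron handling of tied event times, Wald p values per
coefficient, and categorical covariates expanded against an explicit
reference level (subtype contrasts are conventionally reported relative to
SCLC-P, the poor-prognosis subtype).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import median_survival_times

from .errors import ContractError, ConvergenceError, DomainError, InsufficientDataError


@dataclass
class KMGroupFit:
    group: str
    n: int
    n_events: int
    survival: pd.DataFrame         # index: time, column 'S'
    median: float                  # NaN = not reached
    median_ci: tuple[float, float]


@dataclass
class CoxResult:
    summary: pd.DataFrame          # coef, hr, ci_low, ci_high, p per term
    n: int
    n_events: int
    reference_levels: dict[str, str]


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event"):
        if col not in records.columns:
            raise ContractError(f"survival records need a {col!r} column")
    t = records["time"].to_numpy(dtype=float)
    if not np.all(np.isfinite(t)) or (t <= 0).any():
        raise DomainError("survival times must be finite and positive")
    return records


def km_fit(records: pd.DataFrame, group_col: str | None = None,
           alpha: float = 0.05) -> dict[str, KMGroupFit]:
    """Product-limit OS estimate and median (log-log CI) per group.

    With ``group_col`` None, a single group named 'all' is fitted.
    All-censored groups yield a not-reached median (NaN), not an error.
    """
    records = _validate(records)
    if group_col is None:
        groups = {"all": records}
    else:
        if group_col not in records.columns:
            raise ContractError(f"unknown group column {group_col!r}")
        groups = {str(g): sub for g, sub in records.groupby(group_col)}
    out = {}
    for name, sub in groups.items():
        kmf = KaplanMeierFitter(alpha=alpha)
        kmf.fit(sub["time"], event_observed=sub["event"].astype(bool))
        surv = kmf.survival_function_.rename(columns=lambda _: "S")
        median = float(kmf.median_survival_time_)
        ci = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
        out[name] = KMGroupFit(name, len(sub), int(sub["event"].sum()),
                               surv, median, (lo, hi))
    return out


def cox_fit(records: pd.DataFrame, covariates: list[str],
            reference_levels: dict[str, str] | None = None,
            alpha: float = 0.05) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties) with Wald p values.

    Categorical covariates are dummy-expanded against ``reference_levels``
    (first-observed level if unspecified); numeric covariates enter as-is.
    """
    records = _validate(records)
    reference_levels = dict(reference_levels or {})
    if int(records["event"].sum()) < 1:
        raise InsufficientDataError("Cox model needs at least one event")
    design = pd.DataFrame(index=records.index)
    for cov in covariates:
        if cov not in records.columns:
            raise ContractError(f"unknown covariate {cov!r}")
        col = records[cov]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            if col.nunique() == 1:
                raise DomainError(f"covariate {cov!r} is constant")
            design[cov] = col.astype(float)
        else:
            levels = sorted(col.astype(str).unique())
            if len(levels) < 2:
                raise DomainError(f"covariate {cov!r} is constant")
            ref = str(reference_levels.get(cov, levels[0]))
            if ref not in levels:
                raise ContractError(f"reference level {ref!r} not found in {cov!r}")
            reference_levels[cov] = ref
            for lev in levels:
                if lev != ref:
                    design[f"{cov}[{lev} vs {ref}]"] = (
                        col.astype(str) == lev).astype(float)
    if design.std(ddof=0).eq(0).any():
        bad = design.columns[design.std(ddof=0).eq(0)].tolist()
        raise DomainError(f"constant design columns (singular design): {bad}")
    df = pd.concat([records[["time", "event"]].astype(float), design], axis=1)
    cph = CoxPHFitter(alpha=alpha)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:
        raise ConvergenceError(f"Cox fit failed: {exc}") from exc
    s = cph.summary
    summary = pd.DataFrame({
        "coef": s["coef"],
        "hr": s["exp(coef)"],
        "ci_low": np.exp(s["coef lower 95%"]),
        "ci_high": np.exp(s["coef upper 95%"]),
        "p": s["p"],
    })
    return CoxResult(summary, len(df), int(df["event"].sum()), reference_levels)


def cohort_filter(records: pd.DataFrame, criteria: dict) -> pd.DataFrame:
    """Declarative subcohort filter: {column: value or predicate}.

    Criteria are conjunctive; filters therefore commute.  An empty result
    is returned with a warning, not an error.
    """
    mask = pd.Series(True, index=records.index)
    for col, crit in criteria.items():
        if col not in records.columns:
            raise ContractError(f"unknown covariate {col!r} in filter")
        mask &= records[col].map(crit) if callable(crit) else records[col] == crit
    out = records[mask]
    if out.empty:
        warnings.warn("cohort filter matched no records", stacklevel=2)
    return out
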