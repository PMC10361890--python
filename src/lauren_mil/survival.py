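"""Survival analysis: Kaplan–Meier, log-rank, Cox PH, three-tier strata.

Endpoints (overall, cancer-specific and disease-free survival, in months)
are truncated at a 5-year horizon: later events become censorings at 60
months.  Group comparisons use pairwise log-rank tests at α = 0.05 with no
multiplicity correction; effect sizes come from Cox proportional-hazards
models (Efron tie handling by default).  Estimation is delegated to
``lifelines``; the agreement-based three-tier stratification is implemented
here:

    pathologist says intestinal            → best prognosis (model not consulted)
    pathologist diffuse, model diffuse     → worst prognosis (unanimity)
    pathologist diffuse, model intestinal  → intermediate prognosis (discordance)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.stats import norm
from statsmodels.duration.hazard_regression import PHReg

from .synthetic import DIFFUSE, INTESTINAL

ENDPOINTS = ("OS", "CSS", "DFS")
HORIZON_MONTHS = 60.0
BEST, INTERMEDIATE, WORST = "best", "intermediate", "worst"
STRATA = (BEST, INTERMEDIATE, WORST)


@dataclass
class SurvivalRecord:
    """One case's follow-up on one endpoint, plus covariates and group."""

    case_id: str
    endpoint: str
    time: float                 # months
    event: bool
    covariates: dict[str, float | str] = field(default_factory=dict)
    group: str | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("survival time must be non-negative")
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {self.endpoint!r}")


@dataclass
class KMCurve:
    """Product-limit estimate as a right-continuous step function."""

    times: np.ndarray        # distinct event/censoring times, ascending
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray     # S(t) just after each time

    def survival_at(self, t: float) -> float:
        """S(t): value of the step function at time t (S=1 before any event)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxCovariateResult:
    name: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    coef: float

    def __post_init__(self) -> None:
        if self.hazard_ratio <= 0:
            raise ValueError("hazard ratio must be positive")
        if not self.ci_low <= self.hazard_ratio <= self.ci_high:
            raise ValueError("CI must contain the hazard ratio")


@dataclass
class CoxResult:
    """Per-covariate hazard ratios with Wald CIs from one Cox PH fit."""

    covariates: dict[str, CoxCovariateResult]
    converged: bool
    ties: str
    n: int
    n_events: int

    def __getitem__(self, name: str) -> CoxCovariateResult:
        return self.covariates[name]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def truncate_endpoint(
    records: list[SurvivalRecord],
    horizon: float = HORIZON_MONTHS,
) -> list[SurvivalRecord]:
    """Administratively censor at the horizon: t > horizon ⇒ (horizon, no event)."""
    out = []
    for r in records:
        if r.time > horizon:
            out.append(replace(r, time=horizon, event=False))
        else:
            out.append(r)
    return out


def truncate_frame(
    df: pd.DataFrame,
    time_col: str,
    event_col: str,
    horizon: float = HORIZON_MONTHS,
) -> pd.DataFrame:
    """Column-wise version of :func:`truncate_endpoint` for case tables."""
    df = df.copy()
    over = df[time_col] > horizon
    df.loc[over, event_col] = False
    df.loc[over, time_col] = horizon
    return df


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    Ties between events and censorings at the same time follow the usual
    convention: censorings are taken to occur just *after* events, so tied
    censored subjects still count as at risk for the tied event.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) == 0:
        raise ValueError("need at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    # keep only times where subjects actually leave (drops the t=0 anchor row)
    table = table[table["removed"] > 0]
    tt = table.index.to_numpy(dtype=float)
    sf = kmf.survival_function_["KM_estimate"]
    surv = sf.loc[tt].to_numpy(dtype=float)
    return KMCurve(
        times=tt,
        at_risk=table["at_risk"].to_numpy(),
        events=table["observed"].to_numpy(),
        survival=surv,
    )


def logrank_test(times_a, events_a, times_b, events_b):
    """Two-group log-rank test: (chi-square statistic on 1 d.f., p-value)."""
    if len(times_a) == 0 or len(times_b) == 0:
        raise ValueError("both groups must be non-empty")
    res = _ll_logrank(times_a, times_b,
                      event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def logrank_pairwise(groups: dict[str, tuple[np.ndarray, np.ndarray]]):
    """All pairwise log-rank tests among named groups; no multiplicity
    correction (comparisons are reported as-is)."""
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            out[(a, b)] = logrank_test(*groups[a], *groups[b])
    return out


def cox_fit(
    df: pd.DataFrame,
    time_col: str,
    event_col: str,
    covariates: list[str],
    ties: str = "efron",
) -> CoxResult:
    """Cox proportional-hazards fit via partial-likelihood maximization.

    Newton-type maximization of the partial likelihood with Efron (default)
    or Breslow tie handling; per-covariate hazard ratio, Wald 95% CI and
    p-value.  Constant covariates are rejected up front ("degenerate
    covariate"); non-convergence is flagged rather than raised.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    n_events = int(df[event_col].sum())
    if n_events < len(covariates):
        raise ValueError(
            f"{n_events} events cannot support {len(covariates)} covariates"
        )
    for c in covariates:
        if df[c].nunique() < 2:
            raise ValueError(f"degenerate covariate {c!r}: constant in data")
    X = df[covariates].to_numpy(dtype=float)
    model = PHReg(
        df[time_col].to_numpy(dtype=float),
        X,
        status=df[event_col].to_numpy(dtype=int),
        ties=ties,
    )
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=False)
        if not np.all(np.isfinite(res.params)) or not np.all(
            np.isfinite(res.bse)
        ):
            converged = False
    except Exception:
        converged = False
        res = model.fit_regularized(alpha=0.1)
    zcrit = norm.ppf(0.975)
    results = {}
    for i, c in enumerate(covariates):
        coef = float(res.params[i])
        se = float(res.bse[i]) if np.isfinite(res.bse[i]) else np.inf
        results[c] = CoxCovariateResult(
            name=c,
            hazard_ratio=float(np.exp(coef)),
            ci_low=float(np.exp(coef - zcrit * se)),
            ci_high=float(np.exp(coef + zcrit * se)),
            p_value=float(2 * norm.sf(abs(coef) / se)) if se > 0 else 1.0,
            coef=coef,
        )
    return CoxResult(results, converged, ties, len(df), n_events)


def agreement_stratify(
    pathologist_labels: dict[str, str],
    model_labels: dict[str, str],
) -> dict[str, str]:
    """Three-tier prognostic stratification from pathologist+model labels.

    Pathologist-intestinal cases go straight to the best group (the model is
    not consulted); pathologist-diffuse cases split by model unanimity
    (worst) versus discordance (intermediate).  Missing labels raise.
    """
    strata = {}
    for case_id, path in pathologist_labels.items():
        if path is None:
            raise ValueError(f"missing pathologist label for {case_id}")
        if path not in (INTESTINAL, DIFFUSE):
            raise ValueError(f"label {path!r} for {case_id} not binary")
        if path == INTESTINAL:
            strata[case_id] = BEST
            continue
        model = model_labels.get(case_id)
        if model is None:
            raise ValueError(f"missing model label for {case_id}")
        strata[case_id] = WORST if model == DIFFUSE else INTERMEDIATE
    return strata
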