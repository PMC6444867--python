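"""Downstream biomarker statistics: response rates, grouping, and survival.

Implements the clinical-endpoint layer of a cfDNA biomarker study: disease
control rate with a Wald interval, the elevated-versus-healthy-controls
rule (90th-percentile threshold), median dichotomization and quartile
grouping of biomarker values, Kaplan-Meier estimation, the log-rank test,
and univariable / multivariable Cox proportional-hazards fits.

Grouping conventions follow the usual biomarker-table layout: values equal
to the median go to the low group ("<= median"), and quartile boundaries
likewise assign ties downward.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times
from scipy import stats

logger = logging.getLogger(__name__)

#: Best-response categories counted as disease control.
DISEASE_CONTROL = frozenset({"CR", "PR", "SD", "nonCRnonPD"})
RESPONSE_CATEGORIES = frozenset({"CR", "PR", "SD", "nonCRnonPD", "PD", "NE"})


def _wald_ci(p: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    zcrit = stats.norm.ppf(1 - alpha / 2)
    half = zcrit * np.sqrt(p * (1 - p) / n)
    return float(p - half), float(p + half)


def dcr(best_response: pd.Series | list[str]) -> tuple[float, tuple[float, float]]:
    """Disease control rate in percent, with a 95% Wald CI.

    Disease control = best response of CR, PR, SD or non-CR/non-PD.
    """
    responses = pd.Series(best_response, dtype=str)
    if responses.empty:
        raise ValueError("no subjects")
    unknown = set(responses) - RESPONSE_CATEGORIES
    if unknown:
        raise ValueError(f"unknown best-response categories: {sorted(unknown)}")
    n = len(responses)
    p = responses.isin(DISEASE_CONTROL).sum() / n
    lo, hi = _wald_ci(p, n)
    return 100.0 * p, (100.0 * lo, 100.0 * hi)


def elevated_fraction(values: np.ndarray | list[float],
                      controls: np.ndarray | list[float],
                      percentile: float = 90.0
                      ) -> tuple[float, tuple[float, float]]:
    """Fraction of subjects strictly above the controls' percentile.

    Returns (percent, 95% Wald CI in percent).
    """
    values = np.asarray(values, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if controls.size == 0:
        raise ValueError("no control values")
    if values.size == 0:
        raise ValueError("no subject values")
    threshold = np.percentile(controls, percentile)
    p = float(np.mean(values > threshold))
    lo, hi = _wald_ci(p, values.size)
    return 100.0 * p, (100.0 * lo, 100.0 * hi)


def dichotomize_median(values: np.ndarray | list[float]) -> np.ndarray:
    """Split at the median: "low" iff value <= median, else "high".

    The median is midpoint-interpolated for even n, so distinct values
    split |n_low - n_high| <= 1.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need >= 2 values to dichotomize")
    med = np.median(values)
    labels = np.where(values <= med, "low", "high").astype(object)
    if np.all(labels == "low"):
        logger.warning("dichotomize_median: all values <= median "
                       "(identical values?); single group")
    return labels


def quartile_groups(values: np.ndarray | list[float]) -> np.ndarray:
    """Assign Q1 (lowest) .. Q4 (highest) by the 25/50/75th percentiles.

    Boundary values go to the lower quartile, consistent with the median
    rule.  Heavy ties that empty a group trigger a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need >= 4 values for quartiles")
    q25, q50, q75 = np.percentile(values, [25, 50, 75])
    labels = np.full(values.size, "Q4", dtype=object)
    labels[values <= q75] = "Q3"
    labels[values <= q50] = "Q2"
    labels[values <= q25] = "Q1"
    sizes = pd.Series(labels).value_counts()
    if len(sizes) < 4:
        logger.warning("quartile_groups: ties collapsed a quartile "
                       "(group sizes: %s)", sizes.to_dict())
    return labels


@dataclass
class KmResult:
    """Kaplan-Meier estimate: step function, median, and median 95% CI.

    ``median`` is the earliest time with S(t) <= 0.5; NaN means the median
    was not reached.  CI bounds may be NaN/inf when undetermined.
    """

    times: np.ndarray
    survival: np.ndarray
    median: float
    median_ci: tuple[float, float]

    @property
    def median_reached(self) -> bool:
        return np.isfinite(self.median)


def km_estimate(times: np.ndarray | list[float],
                events: np.ndarray | list[int]) -> KmResult:
    """Product-limit survival estimate with a log-log median CI."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape:
        raise ValueError("times and events have different lengths")
    if np.any(times < 0):
        raise ValueError("negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    median = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    sf = kmf.survival_function_
    return KmResult(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        median=median,
        median_ci=(lo, hi),
    )


def logrank(times: np.ndarray | list[float], events: np.ndarray | list[int],
            groups: np.ndarray | list) -> tuple[float, float]:
    """Log-rank test across groups: (chi-square statistic, two-sided p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("log-rank needs >= 2 groups")
    result = multivariate_logrank_test(times, groups, events)
    return float(result.test_statistic), float(result.p_value)


def cox_fit(cohort: pd.DataFrame, endpoint: str, covariates: list[str],
            mode: str = "univariable", alpha_screen: float = 0.05
            ) -> pd.DataFrame:
    """Proportional-hazards fit(s) for one endpoint.

    ``cohort`` needs columns ``{endpoint}_months`` and ``{endpoint}_event``
    plus the covariate columns (numeric; encode binary factors as 0/1
    before calling).  Ties are handled by lifelines' Efron approximation.

    mode="univariable": one single-covariate fit per name.
    mode="multivariable": covariates with univariable Wald p < alpha_screen
    enter a joint model (mirroring the screen-then-adjust convention).

    Returns one row per reported covariate with columns
    hr, ci_low, ci_high, p, mode.
    """
    if endpoint not in ("ttp", "os"):
        raise ValueError(f"endpoint must be 'ttp' or 'os', got {endpoint!r}")
    tcol, ecol = f"{endpoint}_months", f"{endpoint}_event"
    for col in (tcol, ecol, *covariates):
        if col not in cohort.columns:
            raise ValueError(f"cohort is missing column {col!r}")
    n_events = int(cohort[ecol].sum())

    def _fit(cols: list[str]) -> pd.DataFrame:
        if n_events < len(cols):
            raise ValueError(
                f"{n_events} events cannot support {len(cols)} coefficients"
            )
        df = cohort[[tcol, ecol, *cols]].astype(float)
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=tcol, event_col=ecol)
        summ = cph.summary
        return pd.DataFrame({
            "hr": summ["exp(coef)"],
            "ci_low": summ["exp(coef) lower 95%"],
            "ci_high": summ["exp(coef) upper 95%"],
            "p": summ["p"],
        })

    uni = pd.concat([_fit([c]) for c in covariates])
    uni["mode"] = "univariable"
    if mode == "univariable":
        return uni
    if mode != "multivariable":
        raise ValueError(f"unknown mode {mode!r}")
    selected = [c for c in covariates if uni.loc[c, "p"] < alpha_screen]
    if not selected:
        logger.warning("cox_fit: no covariate passed univariable screening "
                       "at alpha=%s; returning univariable results", alpha_screen)
        return uni
    multi = _fit(selected)
    multi["mode"] = "multivariable"
    return multi
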