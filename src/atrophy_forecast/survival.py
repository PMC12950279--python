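"""Time-varying-covariate Cox models for conversion to dementia.

Longitudinal imaging metrics (measured at scans after the predictor scan
pair) are z-scored and entered as time-dependent predictors in a Cox
proportional-hazards model on the counting-process scale: each included
scan opens an episode ``(start, stop]`` carrying the metric value measured
at ``start`` (last observation carried forward), the final episode ending
at the conversion visit (event) or at the last observation (censored).
Hazard ratios are per one SD of the predictor, with age at episode start
(and optionally TIV) as covariates. Partial-likelihood maximization is
delegated to ``lifelines.CoxTimeVaryingFitter`` (Efron ties).

Subsets mirror the study design: all carriers, per-gene, per-sex, and an
asymptomatic-at-baseline (CDR = 0 at both predictor scans) sensitivity
subset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, SubjectSeries
from .exceptions import DegenerateCovariateError, FitError

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalEpisode",
    "CoxFit",
    "zscore",
    "build_episodes",
    "fit_cox",
    "survival_analysis",
    "SUBSETS",
]

SUBSETS = ("all", "C9orf72", "GRN", "MAPT", "female", "male", "cdr0")


@dataclass(frozen=True)
class SurvivalEpisode:
    """One counting-process row ``(start, stop]`` with covariates in force."""

    subject_id: str
    start_years: float
    stop_years: float
    event: bool
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.start_years < self.stop_years:
            raise FitError(
                f"{self.subject_id}: episode start must precede stop")


@dataclass(frozen=True)
class CoxCoefficient:
    name: str
    beta: float
    se: float

    @property
    def hr(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci(self) -> tuple[float, float]:
        with np.errstate(over="ignore"):
            # an uninformative fit may give an infinite upper bound
            return (float(np.exp(self.beta - 1.96 * self.se)),
                    float(np.exp(self.beta + 1.96 * self.se)))

    @property
    def p(self) -> float:
        if self.se == 0:
            return 1.0
        return float(2 * stats.norm.sf(abs(self.beta / self.se)))


@dataclass
class CoxFit:
    """Fitted time-varying Cox model summary."""

    coefficients: list[CoxCoefficient]
    log_likelihood: float
    n_subjects: int
    n_events: int

    def coefficient(self, name: str) -> CoxCoefficient:
        for c in self.coefficients:
            if c.name == name:
                return c
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "n": self.n_subjects,
            "n_events": self.n_events,
            "loglik": self.log_likelihood,
            "covariates": [
                {"name": c.name, "beta": c.beta, "hr": c.hr,
                 "ci_low": c.ci[0], "ci_high": c.ci[1], "se": c.se, "p": c.p}
                for c in self.coefficients
            ],
        }


def zscore(values) -> np.ndarray:
    """Standardize to mean 0, SD 1 (population SD over the included values)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2 or np.unique(values).size < 2:
        raise DegenerateCovariateError(
            "z-score requires at least two distinct values")
    sd = values.std()
    return (values - values.mean()) / sd


def _in_subset(subject: SubjectSeries, subset: str) -> bool:
    if subset == "all":
        return True
    if subset in ("C9orf72", "GRN", "MAPT"):
        return subject.group == subset
    if subset == "female":
        return subject.sex == "F"
    if subset == "male":
        return subject.sex == "M"
    if subset == "cdr0":
        return all(s.cdr_global == 0.0 for s in subject.scans[:2])
    raise ValueError(f"unknown subset {subset!r}; choose from {SUBSETS}")


def build_episodes(cohort: Cohort, metrics: pd.DataFrame, metric_name: str,
                   covariates: tuple[str, ...] = ("age",),
                   subset: str = "all",
                   min_scan_index: int = 2) -> list[SurvivalEpisode]:
    """Counting-process episodes for one imaging metric.

    ``metrics`` is the long table with columns ``subject_id, scan_index,
    scan_time_years, metric_name, value``. Only carrier scans with index >=
    ``min_scan_index`` (the predictor pair is never a predictor) and time
    strictly before the subject's event/censoring time contribute; a
    converter whose conversion precedes its first usable scan is excluded
    and logged.
    """
    rows = metrics[metrics["metric_name"] == metric_name]
    episodes: list[SurvivalEpisode] = []
    for subj in cohort.carriers:
        if not _in_subset(subj, subset):
            continue
        end = (subj.conversion_time_years if subj.is_converter
               else subj.censor_time_years)
        usable = []
        for scan in subj.scans:
            if scan.scan_index < min_scan_index:
                continue
            if scan.scan_time_years >= end:
                continue
            val = rows[(rows["subject_id"] == subj.subject_id)
                       & (rows["scan_index"] == scan.scan_index)]["value"]
            if val.empty:
                continue
            usable.append((scan, float(val.iloc[0])))
        if not usable:
            logger.info("survival: excluding %s (no usable scans before "
                        "event/censoring)", subj.subject_id)
            continue
        for i, (scan, val) in enumerate(usable):
            stop = usable[i + 1][0].scan_time_years if i + 1 < len(usable) else end
            cov = {metric_name: val}
            if "age" in covariates:
                cov["age"] = scan.age_at_scan
            if "tiv" in covariates:
                cov["tiv"] = scan.tiv_mm3
            episodes.append(SurvivalEpisode(
                subject_id=subj.subject_id,
                start_years=scan.scan_time_years, stop_years=stop,
                event=(subj.is_converter and i == len(usable) - 1),
                covariates=cov))
    return episodes


def episodes_frame(episodes: list[SurvivalEpisode]) -> pd.DataFrame:
    rows = []
    for ep in episodes:
        row = {"subject_id": ep.subject_id, "start": ep.start_years,
               "stop": ep.stop_years, "event": ep.event}
        row.update(ep.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def fit_cox(episodes: list[SurvivalEpisode] | pd.DataFrame,
            covariate_names: tuple[str, ...]) -> CoxFit:
    """Maximize the time-varying Cox partial likelihood (Efron ties).

    Raises on zero events or on a covariate constant across all rows.
    """
    from lifelines import CoxTimeVaryingFitter

    df = episodes if isinstance(episodes, pd.DataFrame) \
        else episodes_frame(episodes)
    if df.empty or int(df["event"].sum()) == 0:
        raise FitError("no events: cannot fit a Cox model")
    for name in covariate_names:
        if name not in df.columns:
            raise FitError(f"missing covariate column {name!r}")
        if np.unique(df[name].to_numpy()).size < 2:
            raise DegenerateCovariateError(
                f"covariate {name!r} is constant across all episodes")

    cols = ["subject_id", "start", "stop", "event", *covariate_names]
    # heavy-tailed predictors can make the full Newton step overshoot;
    # retry deterministically with damped steps before giving up
    last_exc: Exception | None = None
    for step_size in (None, 0.25, 0.1, 0.02):
        ctv = CoxTimeVaryingFitter(penalizer=0.0)
        fit_options = {"step_size": step_size} if step_size else None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ctv.fit(df[cols], id_col="subject_id", start_col="start",
                        stop_col="stop", event_col="event",
                        fit_options=fit_options)
            break
        except Exception as exc:
            last_exc = exc
            logger.info("Cox Newton step %s failed (%s); damping",
                        step_size or "full", exc)
    else:
        raise FitError(f"Cox model did not converge: {last_exc}") from last_exc
    coefs = [CoxCoefficient(name=str(name),
                            beta=float(ctv.params_[name]),
                            se=float(ctv.standard_errors_[name]))
             for name in covariate_names]
    return CoxFit(coefficients=coefs,
                  log_likelihood=float(ctv.log_likelihood_),
                  n_subjects=int(df["subject_id"].nunique()),
                  n_events=int(df["event"].sum()))


def simulate_tv_episodes(n_subjects: int, log_hr: float,
                         rng: np.random.Generator,
                         baseline_hazard: float = 0.08,
                         n_intervals: int = 5,
                         interval_years: float = 1.0) -> pd.DataFrame:
    """Simulate counting-process data with a known per-SD log hazard ratio.

    Each subject is observed over ``n_intervals`` intervals with a fresh
    standard-normal covariate per interval; events arrive with hazard
    ``baseline_hazard * exp(log_hr * z)`` within the interval (inversion
    sampling), censoring at the end of follow-up. Used for calibration and
    parameter-recovery checks of the Cox stage.
    """
    rows = []
    for i in range(n_subjects):
        z = rng.normal(size=n_intervals)
        exp_budget = rng.exponential()
        t = 0.0
        for k in range(n_intervals):
            rate = baseline_hazard * np.exp(log_hr * z[k])
            cum = rate * interval_years
            if exp_budget < cum:
                stop = t + exp_budget / rate
                rows.append({"subject_id": f"S{i}", "start": t, "stop": stop,
                             "event": True, "z": z[k]})
                break
            rows.append({"subject_id": f"S{i}", "start": t,
                         "stop": t + interval_years, "event": False, "z": z[k]})
            exp_budget -= cum
            t += interval_years
    return pd.DataFrame(rows)


def survival_analysis(cohort: Cohort, metrics: pd.DataFrame, metric_name: str,
                      covariates: tuple[str, ...] = ("age",),
                      subset: str = "all") -> CoxFit:
    """Build episodes, z-score the metric within the subset, and fit.

    The metric is standardized over all observations entering this model,
    so the hazard ratio reads per-SD within the analyzed subset.
    """
    episodes = build_episodes(cohort, metrics, metric_name,
                              covariates=covariates, subset=subset)
    df = episodes_frame(episodes)
    if df.empty:
        raise FitError(f"no episodes for metric {metric_name!r} in subset "
                       f"{subset!r}")
    df[metric_name] = zscore(df[metric_name].to_numpy())
    return fit_cox(df, (metric_name, *[c for c in ("age", "tiv")
                                       if c in covariates]))
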