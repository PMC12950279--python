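"""24-month proximity-marker classification: subset rules, AUC, DeLong.

A cross-sectional subset emulating a hypothetical 24-month clinical trial:
converters contribute their one pre-conversion scan closest to (and within)
27 months (24 + 3-month buffer) before conversion; non-converters must have
a scan at least 24 months before their last observation and contribute the
qualifying scan closest to that boundary. AUCs use the Mann-Whitney pair
statistic (ties count one half), variances and paired comparisons the
DeLong structural-components method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .exceptions import FitError

logger = logging.getLogger(__name__)

__all__ = [
    "HorizonRecord",
    "HorizonSubset",
    "RocResult",
    "DeLongComparison",
    "select_horizon_subset",
    "roc_auc",
    "delong_test",
]


@dataclass(frozen=True)
class HorizonRecord:
    subject_id: str
    label: str  # "converter" | "nonconverter"
    selected_scan_index: int
    months_before_anchor: float  # before conversion (converters) / last obs
    metrics: dict = field(default_factory=dict)


@dataclass
class HorizonSubset:
    horizon_months: float
    buffer_months: float
    records: list[HorizonRecord]

    @property
    def n_converters(self) -> int:
        return sum(r.label == "converter" for r in self.records)

    @property
    def n_nonconverters(self) -> int:
        return sum(r.label == "nonconverter" for r in self.records)

    def scores_labels(self, metric_name: str) -> tuple[np.ndarray, np.ndarray]:
        recs = [r for r in self.records if metric_name in r.metrics]
        scores = np.array([r.metrics[metric_name] for r in recs], dtype=float)
        labels = np.array([r.label == "converter" for r in recs], dtype=bool)
        return scores, labels


@dataclass(frozen=True)
class RocResult:
    auc: float
    variance: float
    ci: tuple[float, float]
    p_vs_chance: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class DeLongComparison:
    auc_a: float
    auc_b: float
    z: float
    p: float


def _metric_lookup(metrics: pd.DataFrame) -> dict:
    table: dict = {}
    for row in metrics.itertuples(index=False):
        table.setdefault((row.subject_id, int(row.scan_index)), {})[
            row.metric_name] = float(row.value)
    return table


def select_horizon_subset(cohort: Cohort, metrics: pd.DataFrame,
                          horizon_months: float = 24.0,
                          buffer_months: float = 3.0,
                          min_scan_index: int = 2) -> HorizonSubset:
    """Select one scan per subject for the horizon classification analysis.

    Converters: scans at/after conversion or more than horizon+buffer
    months before it are dropped; the remaining scan closest to the
    horizon+buffer boundary is kept (earlier scan on ties). Non-converters:
    need a scan at least ``horizon_months`` before last observation; the
    qualifying scan closest to that boundary is kept. Subjects with no
    qualifying scan are excluded and logged. Months are years x 12.
    """
    window = horizon_months + buffer_months
    lookup = _metric_lookup(metrics)
    records: list[HorizonRecord] = []
    for subj in sorted(cohort.carriers, key=lambda s: s.subject_id):
        if subj.is_converter:
            anchor, boundary, label = subj.conversion_time_years, window, "converter"
        else:
            anchor, boundary, label = subj.censor_time_years, horizon_months, \
                "nonconverter"
        candidates = []
        for scan in subj.scans:
            if scan.scan_index < min_scan_index:
                continue
            if (subj.subject_id, scan.scan_index) not in lookup:
                continue
            months_before = (anchor - scan.scan_time_years) * 12.0
            if subj.is_converter:
                if months_before <= 0 or months_before > window:
                    continue
            else:
                if months_before < horizon_months:
                    continue
            candidates.append((abs(months_before - boundary),
                               scan.scan_time_years, scan.scan_index,
                               months_before))
        if not candidates:
            logger.info("horizon subset: excluding %s (%s, no qualifying scan)",
                        subj.subject_id, label)
            continue
        _, _, idx, months_before = min(candidates)
        records.append(HorizonRecord(
            subject_id=subj.subject_id, label=label, selected_scan_index=idx,
            months_before_anchor=months_before,
            metrics=lookup[(subj.subject_id, idx)]))
    return HorizonSubset(horizon_months=horizon_months,
                         buffer_months=buffer_months, records=records)


# ---------------------------------------------------------------------------
# AUC with DeLong variance

def _structural_components(pos: np.ndarray, neg: np.ndarray
                           ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong placement components V10 (per positive), V01."""
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return float(psi.mean()), v10, v01


def roc_auc(scores, labels, higher_is_positive: bool = True) -> RocResult:
    """AUC as the Mann-Whitney pair statistic with DeLong variance.

    ``higher_is_positive`` states the metric's orientation explicitly
    (larger cluster volumes score toward conversion; smaller ROI volumes
    do, so pass ``False`` for them). CI is the normal interval clipped to
    [0, 1]; p tests AUC = 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise FitError("scores and labels must have equal length")
    if labels.all() or not labels.any():
        raise FitError("both classes must be present")
    if not higher_is_positive:
        scores = -scores
    pos, neg = scores[labels], scores[~labels]
    auc, v10, v01 = _structural_components(pos, neg)
    m, n = len(pos), len(neg)
    var = (v10.var(ddof=1) / m if m > 1 else 0.0) + \
          (v01.var(ddof=1) / n if n > 1 else 0.0)
    sd = np.sqrt(var)
    ci = (float(np.clip(auc - 1.96 * sd, 0, 1)),
          float(np.clip(auc + 1.96 * sd, 0, 1)))
    if sd == 0:
        p = 0.0 if auc != 0.5 else 1.0
    else:
        p = float(2 * stats.norm.sf(abs(auc - 0.5) / sd))
    return RocResult(auc=auc, variance=var, ci=ci, p_vs_chance=p,
                     n_pos=m, n_neg=n)


def delong_test(scores_a, scores_b, labels,
                higher_is_positive: tuple[bool, bool] = (True, True)
                ) -> DeLongComparison:
    """Paired DeLong comparison of two markers scored on the same subjects."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not (scores_a.shape == scores_b.shape == labels.shape):
        raise FitError("paired scores and labels must have equal length")
    if labels.all() or not labels.any():
        raise FitError("both classes must be present")
    if not higher_is_positive[0]:
        scores_a = -scores_a
    if not higher_is_positive[1]:
        scores_b = -scores_b

    pos_a, neg_a = scores_a[labels], scores_a[~labels]
    pos_b, neg_b = scores_b[labels], scores_b[~labels]
    auc_a, v10_a, v01_a = _structural_components(pos_a, neg_a)
    auc_b, v10_b, v01_b = _structural_components(pos_b, neg_b)
    m, n = len(pos_a), len(neg_a)

    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var_diff <= 0:
        z = 0.0 if diff == 0 else np.sign(diff) * np.inf
    else:
        z = diff / np.sqrt(var_diff)
    p = 1.0 if z == 0 else float(2 * stats.norm.sf(abs(z)))
    return DeLongComparison(auc_a=auc_a, auc_b=auc_b, z=float(z), p=p)
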