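"""End-to-end orchestration: simulate -> metrics -> survival -> ROC.

Ties the stages into one reproducible run: fit the control models, score
every carrier's follow-up scans (BLME erf maps, W-maps, ROI volumes) into a
long metrics table, fit time-varying Cox models per metric and subset, run
the 24-month horizon ROC analysis with paired DeLong comparisons against
the BLME cluster volume, and write a manifest recording the config hash and
seed. Identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import blme, roc, survival, wscore
from .cohort import (
    Cohort,
    CohortConfig,
    METADATA_COLUMNS,
    read_cohort,
    read_metadata,
    simulate_cohort,
)
from .exceptions import ConfigError, FitError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "compute_metrics",
    "run_all",
    "validate_metadata",
]

METRIC_COLUMNS = ["subject_id", "scan_index", "scan_time_years",
                  "metric_name", "value"]


def blme_metric_name(threshold: float) -> str:
    return f"blme_cluster_mm3@{threshold:g}"


def wmap_metric_name(sigma: float) -> str:
    return f"wmap_cluster_mm3@{sigma:g}"


ROI_METRICS = ("roi_frontal_mm3", "roi_temporal_mm3")


@dataclass
class PipelineConfig:
    """Configuration for one full pipeline run."""

    cohort: CohortConfig | str | Path = field(default_factory=CohortConfig)
    erf_thresholds: tuple[float, ...] = blme.DEFAULT_ERF_THRESHOLDS
    sigma_thresholds: tuple[float, ...] = wscore.DEFAULT_SIGMA_THRESHOLDS
    stages: tuple[str, ...] = ("blme", "wmap", "roi")
    survival_metrics: tuple[str, ...] | None = None  # default: headline metrics
    survival_subsets: tuple[str, ...] = ("all",)
    roc_horizon_months: float = 24.0
    roc_buffer_months: float = 3.0
    control_model_mode: str = "pooled"
    seed: int | None = None

    def default_survival_metrics(self) -> tuple[str, ...]:
        out: list[str] = []
        if "blme" in self.stages:
            out.append(blme_metric_name(min(self.erf_thresholds)))
        if "wmap" in self.stages:
            out.append(wmap_metric_name(max(self.sigma_thresholds)))
        if "roi" in self.stages:
            out.extend(ROI_METRICS)
        return tuple(out)

    def validate(self) -> None:
        for thr in self.erf_thresholds:
            if not -1.0 < thr < 0.0:
                raise ConfigError(f"erf threshold {thr} outside (-1, 0)")
        for s in self.sigma_thresholds:
            if s <= 0:
                raise ConfigError(f"sigma threshold {s} must be positive")
        unknown = set(self.stages) - {"blme", "wmap", "roi"}
        if unknown:
            raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
        for m in self.survival_metrics or ():
            if m.startswith("blme_") and "blme" not in self.stages:
                raise ConfigError(f"metric {m!r} requires the disabled "
                                  "'blme' stage")
            if m.startswith("wmap_") and "wmap" not in self.stages:
                raise ConfigError(f"metric {m!r} requires the disabled "
                                  "'wmap' stage")
            if m.startswith("roi_") and "roi" not in self.stages:
                raise ConfigError(f"metric {m!r} requires the disabled "
                                  "'roi' stage")
        for s in self.survival_subsets:
            if s not in survival.SUBSETS:
                raise ConfigError(f"unknown survival subset {s!r}")


def compute_metrics(cohort: Cohort,
                    erf_thresholds=blme.DEFAULT_ERF_THRESHOLDS,
                    sigma_thresholds=wscore.DEFAULT_SIGMA_THRESHOLDS,
                    stages=("blme", "wmap", "roi"),
                    control_model_mode: str = "pooled",
                    max_cdr: float = 0.5,
                    maps_dir: str | Path | None = None) -> pd.DataFrame:
    """Score every eligible carrier follow-up scan under the enabled stages.

    Returns the long metrics table (one row per scan x metric). Carriers
    ineligible for the BLME stage (predictor pair above the CDR cap) are
    skipped with a log entry; W-map and ROI metrics are computed at the
    same follow-up scans used for the BLME analysis.
    """
    rows: list[dict] = []
    vox = cohort.voxel_volume_mm3
    if maps_dir is not None:
        import nibabel as nib
        maps_dir = Path(maps_dir)
        maps_dir.mkdir(parents=True, exist_ok=True)
        aff = np.diag([cohort.voxel_size_mm] * 3 + [1.0])

    def _save_map(values: np.ndarray, name: str) -> None:
        if maps_dir is not None:
            nib.save(nib.Nifti1Image(values.astype(np.float32), aff),
                     maps_dir / name)

    control_model = blme.fit_control_model(cohort, mode=control_model_mode) \
        if "blme" in stages else None
    w_model = wscore.fit_wscore_model(cohort) if "wmap" in stages else None

    for subj in cohort.carriers:
        if len(subj.scans) < 3:
            logger.info("metrics: skipping %s (<3 scans)", subj.subject_id)
            continue
        if any(s.cdr_global > max_cdr for s in subj.scans[:2]):
            logger.info("metrics: skipping %s (predictor pair CDR > %g)",
                        subj.subject_id, max_cdr)
            continue
        posterior = blme.fit_subject_posterior(cohort, subj, control_model) \
            if control_model is not None else None
        for scan in subj.scans[2:]:
            base = {"subject_id": subj.subject_id,
                    "scan_index": scan.scan_index,
                    "scan_time_years": scan.scan_time_years}
            if posterior is not None:
                dmap = blme.deviation_map(cohort, subj, scan.scan_index,
                                          posterior, control_model)
                _save_map(dmap.values,
                          f"{subj.subject_id}_s{scan.scan_index}_erf.nii.gz")
                for thr in erf_thresholds:
                    res = blme.cluster_volume(dmap, thr, vox)
                    rows.append({**base, "metric_name": blme_metric_name(thr),
                                 "value": res.volume_mm3})
            if w_model is not None:
                wmap = wscore.w_map(cohort, subj, scan.scan_index, w_model)
                _save_map(wmap.values,
                          f"{subj.subject_id}_s{scan.scan_index}_w.nii.gz")
                for sig in sigma_thresholds:
                    res = wscore.w_cluster_volume(wmap, sig, vox)
                    rows.append({**base, "metric_name": wmap_metric_name(sig),
                                 "value": res.volume_mm3})
            if "roi" in stages:
                img = cohort.images[(subj.subject_id, scan.scan_index)]
                for r in wscore.roi_mean_volume(img.values, cohort.atlas,
                                                cohort.atlas_labels,
                                                cohort.mask):
                    rows.append({**base,
                                 "metric_name": f"roi_{r.label_name}_mm3",
                                 "value": r.mean_volume})
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline and write its report bundle to ``out_dir``.

    Produces ``metrics.csv``, ``survival.json``/``survival.csv``,
    ``roc.json``/``roc.csv`` and ``manifest.json``; returns the report as a
    dict.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if isinstance(config.cohort, (str, Path)):
        cohort = read_cohort(config.cohort)
        cohort_desc = str(config.cohort)
    else:
        cc = config.cohort
        if config.seed is not None:
            cc = dataclasses.replace(cc, seed=config.seed)
        cohort = simulate_cohort(cc)
        cohort_desc = json.dumps(cc.to_dict(), sort_keys=True)

    metrics = compute_metrics(
        cohort, erf_thresholds=config.erf_thresholds,
        sigma_thresholds=config.sigma_thresholds, stages=config.stages,
        control_model_mode=config.control_model_mode)
    metrics.to_csv(out_dir / "metrics.csv", index=False, float_format="%.10g")

    surv_metrics = config.survival_metrics or config.default_survival_metrics()
    surv_report, surv_rows = [], []
    for metric in surv_metrics:
        covs = ("age", "tiv") if metric.startswith("roi_") else ("age",)
        for subset in config.survival_subsets:
            try:
                fit = survival.survival_analysis(cohort, metrics, metric,
                                                 covariates=covs, subset=subset)
            except FitError as exc:
                logger.warning("survival %s/%s failed: %s", metric, subset, exc)
                continue
            entry = {"metric": metric, "subset": subset, **fit.to_dict()}
            surv_report.append(entry)
            c = fit.coefficient(metric)
            surv_rows.append({"metric": metric, "subset": subset,
                              "n": fit.n_subjects, "n_events": fit.n_events,
                              "hr": c.hr, "ci_low": c.ci[0],
                              "ci_high": c.ci[1], "p": c.p})
    with open(out_dir / "survival.json", "w") as fh:
        json.dump(surv_report, fh, indent=2)
    pd.DataFrame(surv_rows).to_csv(out_dir / "survival.csv", index=False,
                                   float_format="%.10g")

    subset = roc.select_horizon_subset(
        cohort, metrics, horizon_months=config.roc_horizon_months,
        buffer_months=config.roc_buffer_months)
    roc_report, roc_rows = [], []
    roc_metrics = [m for m in surv_metrics]
    orientations = {m: not m.startswith("roi_") for m in roc_metrics}
    results = {}
    for metric in roc_metrics:
        scores, labels = subset.scores_labels(metric)
        if labels.size == 0 or labels.all() or not labels.any():
            logger.warning("roc: skipping %s (single-class subset)", metric)
            continue
        res = roc.roc_auc(scores, labels,
                          higher_is_positive=orientations[metric])
        results[metric] = res
        entry = {"metric": metric, "n_pos": res.n_pos, "n_neg": res.n_neg,
                 "auc": res.auc, "ci_low": res.ci[0], "ci_high": res.ci[1],
                 "p": res.p_vs_chance}
        roc_report.append(entry)
        roc_rows.append(entry)
    comparisons = []
    ref = roc_metrics[0] if roc_metrics else None
    if ref in results:
        ref_scores, labels = subset.scores_labels(ref)
        for metric in roc_metrics[1:]:
            if metric not in results:
                continue
            other, _ = subset.scores_labels(metric)
            comp = roc.delong_test(
                ref_scores, other, labels,
                higher_is_positive=(orientations[ref], orientations[metric]))
            comparisons.append({"metric_a": ref, "metric_b": metric,
                                "auc_a": comp.auc_a, "auc_b": comp.auc_b,
                                "z": comp.z, "p": comp.p})
    with open(out_dir / "roc.json", "w") as fh:
        json.dump({"results": roc_report, "comparisons": comparisons}, fh,
                  indent=2)
    pd.DataFrame(roc_rows).to_csv(out_dir / "roc.csv", index=False,
                                  float_format="%.10g")

    manifest = {
        "config_hash": hashlib.sha256(cohort_desc.encode()).hexdigest(),
        "seed": config.seed if config.seed is not None else (
            cohort.config.seed if cohort.config else None),
        "n_subjects": len(cohort.subjects),
        "n_carriers": len(cohort.carriers),
        "n_converters": sum(s.is_converter for s in cohort.carriers),
        "stages": list(config.stages),
        "n_metric_rows": int(len(metrics)),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return {"manifest": manifest, "survival": surv_report,
            "roc": {"results": roc_report, "comparisons": comparisons},
            "horizon_subset": {"n_converters": subset.n_converters,
                               "n_nonconverters": subset.n_nonconverters}}


# ---------------------------------------------------------------------------
# metadata validation

def validate_metadata(csv_path: str | Path) -> list[str]:
    """Check a metadata CSV against the cohort schema and protocol rules.

    Returns a list of human-readable violations (empty iff valid).
    """
    try:
        df = read_metadata(csv_path)
    except SchemaError as exc:
        return [str(exc)]
    violations: list[str] = []
    for sid, g in df.groupby("subject_id", sort=False):
        g = g.sort_values("scan_index")
        times = g["scan_time_years"].to_numpy()
        if len(times) and times[0] != 0.0:
            violations.append(f"{sid}: first scan time is {times[0]}, not 0")
        if np.any(np.diff(times) <= 0):
            violations.append(f"{sid}: scan times not strictly increasing")
        if not np.array_equal(g["scan_index"].to_numpy(),
                              np.arange(len(g))):
            violations.append(f"{sid}: scan_index not contiguous from 0")
        is_carrier = g["group"].iloc[0] != "control"
        if is_carrier:
            first_two = g.head(2)["cdr_global"].to_numpy()
            if np.any(first_two > 0.5):
                violations.append(
                    f"{sid}: predictor scan pair has CDR > 0.5 "
                    "(eligibility rule)")
        conv = g["conversion_time_years"].iloc[0]
        cens = g["censor_time_years"].iloc[0]
        if pd.notna(conv):
            if conv > cens:
                violations.append(
                    f"{sid}: conversion_time_years {conv} exceeds "
                    f"censor_time_years {cens}")
            at_conv = g[g["scan_time_years"] >= conv]
            if at_conv.empty or at_conv["cdr_global"].iloc[0] < 1:
                violations.append(
                    f"{sid}: conversion time has no visit with CDR >= 1")
        bad_cdr = ~g["cdr_global"].isin([0, 0.5, 1, 2, 3])
        if bad_cdr.any():
            violations.append(f"{sid}: invalid cdr_global value(s)")
    return violations
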