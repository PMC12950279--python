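"""Cross-sectional normative comparators: W-score maps and atlas ROI volumes.

The W-score at a voxel is the standardized residual of a subject's
gray-matter volume from an ordinary-least-squares control regression on
age, total intracranial volume (TIV), and scanner (reference-coded
indicators) — atrophy expressed in control residual-SD units. Biological
sex is deliberately not a covariate; sex effects are examined in
stratified survival models instead. ROI volumes are plain means of the
gray-matter image over atlas labels (with frontal/temporal composites).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cohort import Cohort, ScanRecord, SubjectSeries
from .exceptions import AtlasError, CovariateError, FitError

logger = logging.getLogger(__name__)

__all__ = [
    "WScoreModel",
    "WMap",
    "RoiVolumeResult",
    "fit_wscore_model",
    "w_map",
    "w_cluster_volume",
    "roi_mean_volume",
    "DEFAULT_SIGMA_THRESHOLDS",
]

#: sigma sweep, permissive to stringent; -3.0 is the headline threshold
DEFAULT_SIGMA_THRESHOLDS = (1.0, 1.5, 2.0, 2.5, 3.0)


@dataclass
class WScoreModel:
    """Per-voxel OLS control model: intercept, age, TIV, scanner indicators."""

    coef: np.ndarray  # (p, V)
    resid_sd: np.ndarray  # (V,)
    scanner_levels: tuple[str, ...]  # first level is the reference
    mask: np.ndarray
    n_controls: int

    def __post_init__(self) -> None:
        if np.any(self.resid_sd < 0):
            raise FitError("residual SD must be non-negative")
        p_expected = 3 + max(len(self.scanner_levels) - 1, 0)
        if self.coef.shape[0] != p_expected:
            raise FitError(
                f"coefficient count {self.coef.shape[0]} != expected {p_expected}")

    def design_row(self, age: float, tiv: float, scanner: str) -> np.ndarray:
        if scanner not in self.scanner_levels:
            raise CovariateError(
                f"unknown scanner level {scanner!r}; model knows "
                f"{self.scanner_levels}")
        row = [1.0, age, tiv]
        for level in self.scanner_levels[1:]:
            row.append(1.0 if scanner == level else 0.0)
        return np.asarray(row)


@dataclass
class WMap:
    """Per-voxel W values for one scan (NaN outside mask / degenerate voxels)."""

    values: np.ndarray
    mask: np.ndarray
    subject_id: str
    scan_index: int


@dataclass(frozen=True)
class RoiVolumeResult:
    """Mean gray-matter volume over one atlas label."""

    label_id: int
    label_name: str
    mean_volume: float
    n_voxels: int


def _control_design(scans: list[ScanRecord], scanner_levels: tuple[str, ...]
                    ) -> np.ndarray:
    rows = [[1.0, s.age_at_scan, s.tiv_mm3]
            + [1.0 if s.scanner_id == lvl else 0.0 for lvl in scanner_levels[1:]]
            for s in scans]
    return np.asarray(rows)


def fit_wscore_model(cohort: Cohort) -> WScoreModel:
    """Fit the cross-sectional W-score reference model on control baselines.

    One observation per control (the first scan) to avoid double-counting
    subjects. With a single scanner the indicator columns are dropped.
    """
    controls = cohort.controls
    if not controls:
        raise FitError("no control subjects")
    scans = [s.scans[0] for s in controls]
    scanner_levels = tuple(sorted({s.scanner_id for s in scans}))
    if len(scanner_levels) == 1:
        logger.info("single scanner (%s): dropping scanner indicators",
                    scanner_levels[0])
    X = _control_design(scans, scanner_levels)
    p = X.shape[1]
    if len(scans) < p + 1:
        raise FitError(
            f"need more than {p} controls to fit {p} coefficients")
    if np.linalg.matrix_rank(X) < p:
        raise FitError("rank-deficient W-score design")
    Y = np.stack([cohort.images[(s.subject_id, 0)].values[cohort.mask]
                  for s in scans])  # (n, V)
    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    dof = len(scans) - p
    resid_sd = np.sqrt((resid ** 2).sum(axis=0) / dof)
    return WScoreModel(coef=coef, resid_sd=resid_sd,
                       scanner_levels=scanner_levels, mask=cohort.mask,
                       n_controls=len(controls))


def w_map(cohort: Cohort, subject: SubjectSeries, scan_index: int,
          model: WScoreModel) -> WMap:
    """Covariate-adjusted atrophy map in control residual-SD units.

    Voxels with zero control residual SD cannot be standardized; they are
    excluded (NaN) and logged. An unknown scanner level is a hard error.
    """
    scan = next(s for s in subject.scans if s.scan_index == scan_index)
    x = model.design_row(scan.age_at_scan, scan.tiv_mm3, scan.scanner_id)
    observed = cohort.images[(subject.subject_id, scan_index)].values[cohort.mask]
    predicted = x @ model.coef

    ok = model.resid_sd > 0
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("%s scan %d: excluding %d zero-SD voxel(s)",
                    subject.subject_id, scan_index, n_bad)
    flat = np.full(observed.shape, np.nan)
    flat[ok] = (observed[ok] - predicted[ok]) / model.resid_sd[ok]
    values = np.full(cohort.mask.shape, np.nan)
    values[cohort.mask] = flat
    return WMap(values=values, mask=cohort.mask,
                subject_id=subject.subject_id, scan_index=scan_index)


def w_cluster_volume(wmap: WMap, sigma_threshold: float,
                     voxel_volume_mm3: float):
    """Count in-mask voxels with W <= -sigma_threshold; volume in mm^3."""
    from .blme import ClusterVolumeResult

    if sigma_threshold <= 0:
        raise ValueError("sigma_threshold must be positive")
    vals = wmap.values[wmap.mask]
    with np.errstate(invalid="ignore"):
        n = int(np.sum(vals <= -sigma_threshold))
    return ClusterVolumeResult(threshold=-sigma_threshold, n_voxels=n,
                               voxel_volume_mm3=voxel_volume_mm3)


def roi_mean_volume(image_values: np.ndarray, atlas: np.ndarray,
                    labels: dict[int, str], mask: np.ndarray | None = None
                    ) -> list[RoiVolumeResult]:
    """Mean gray-matter volume per atlas label (in-mask voxels only)."""
    if atlas.shape != image_values.shape:
        raise AtlasError(
            f"atlas shape {atlas.shape} != image shape {image_values.shape}")
    if mask is None:
        mask = np.ones_like(atlas, dtype=bool)
    results = []
    for label_id, name in labels.items():
        sel = (atlas == label_id) & mask
        n = int(sel.sum())
        if n == 0:
            raise AtlasError(f"atlas label {label_id} ({name}) is empty")
        results.append(RoiVolumeResult(
            label_id=label_id, label_name=name,
            mean_volume=float(image_values[sel].mean()), n_voxels=n))
    return results
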