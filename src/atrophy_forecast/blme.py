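"""Voxel-wise Bayesian linear mixed-effects trajectory prediction.

The normative model at each voxel is a random-intercept, random-slope
linear mixed model fit to control scans::

    y_ij = beta0 + beta1 * t_ij + a_i + b_i * t_ij + eps_ij

with subject effects (a_i, b_i) ~ N(0, Sigma_b) and residual
eps ~ N(0, sigma_eps^2). Variance components are estimated by REML
(empirical Bayes); per-voxel fixed effects then come from the closed-form
GLS solve given those components.

A new subject's first two scans (the "predictor scan pair", both acquired
at global CDR <= 0.5) update the zero-mean random-effect prior by
normal-normal conjugacy, yielding a per-voxel posterior over the subject's
(intercept, slope) offsets and hence a Gaussian posterior-predictive
distribution for the volume at any later time. Follow-up scans are scored
with the error function of the standardized deviation,

    erf((y_obs - mu(t)) / (s(t) * sqrt(2)))  in (-1, 1),

negative where observed volume falls below prediction; |erf| = 0.999
corresponds to a two-sided predictive tail probability of 0.001. Voxels
with erf at or below a negative threshold are counted and multiplied by
voxel volume to form the atrophy cluster volume in mm^3 (no
connected-component constraint).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special

from .cohort import Cohort, SubjectSeries, VolumeImage
from .exceptions import (
    ConfigError,
    DegeneratePredictionError,
    EligibilityError,
    FitError,
    ProtocolError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ControlModel",
    "SubjectPosterior",
    "PosteriorPrediction",
    "DeviationMap",
    "ClusterVolumeResult",
    "fit_control_model",
    "fit_subject_posterior",
    "predict",
    "erf_score",
    "deviation_map",
    "cluster_volume",
    "DEFAULT_ERF_THRESHOLDS",
]

#: threshold sweep used throughout: from permissive to stringent
DEFAULT_ERF_THRESHOLDS = (-0.7, -0.8, -0.9, -0.99, -0.999)

_ZERO_TOL = 1e-12


@dataclass
class ControlModel:
    """Normative trajectory model estimated from control scans.

    ``beta`` holds per-voxel fixed (intercept, slope); ``sigma_b`` the
    2x2 random-effect covariance, either shared (``(2, 2)``) or per voxel
    (``(V, 2, 2)``); ``sigma2_eps`` the residual variance, scalar or
    ``(V,)``. ``V`` is the number of in-mask voxels, in C order of the
    mask's True entries.
    """

    beta: np.ndarray  # (2, V)
    sigma_b: np.ndarray
    sigma2_eps: np.ndarray | float
    mask: np.ndarray
    n_controls: int
    n_scans: int

    def __post_init__(self) -> None:
        if np.any(np.atleast_1d(self.sigma2_eps) < -_ZERO_TOL):
            raise FitError("residual variance must be non-negative")
        sb = np.atleast_3d(self.sigma_b.reshape(-1, 2, 2))
        eig = np.linalg.eigvalsh(sb)
        if np.any(eig < -1e-8 * (1 + np.abs(eig).max())):
            raise FitError("random-effect covariance must be PSD")

    @property
    def n_voxels(self) -> int:
        return self.beta.shape[1]

    def sigma_b_at(self) -> np.ndarray:
        """Random-effect covariance broadcast to (V, 2, 2)."""
        if self.sigma_b.ndim == 2:
            return np.broadcast_to(self.sigma_b, (self.n_voxels, 2, 2))
        return self.sigma_b

    def sigma2_at(self) -> np.ndarray:
        """Residual variance broadcast to (V,)."""
        return np.broadcast_to(np.asarray(self.sigma2_eps, dtype=float),
                               (self.n_voxels,))


@dataclass
class SubjectPosterior:
    """Per-voxel Gaussian posterior over a subject's random effects."""

    subject_id: str
    mean: np.ndarray  # (2, V)
    cov: np.ndarray  # (2, 2) shared or (V, 2, 2)
    pair_times: tuple[float, float]

    def cov_at(self, n_voxels: int) -> np.ndarray:
        if self.cov.ndim == 2:
            return np.broadcast_to(self.cov, (n_voxels, 2, 2))
        return self.cov


@dataclass
class PosteriorPrediction:
    """Gaussian predictive distribution for voxel volumes at time ``t``."""

    t: float
    mean: np.ndarray  # (V,)
    sd: np.ndarray  # (V,)


@dataclass
class DeviationMap:
    """Per-voxel erf deviation scores for one follow-up scan."""

    values: np.ndarray  # 3D; NaN outside mask / at degenerate voxels
    mask: np.ndarray
    subject_id: str
    scan_index: int
    t: float


@dataclass(frozen=True)
class ClusterVolumeResult:
    """Thresholded deviation-map summary: voxel count and volume in mm^3."""

    threshold: float
    n_voxels: int
    voxel_volume_mm3: float

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3


# ---------------------------------------------------------------------------
# variance-component estimation

def _subject_ols(y: np.ndarray, t: np.ndarray, groups: np.ndarray):
    """Per-subject straight-line fits; returns coefs, pooled SSE and df."""
    coefs, sse, df = [], 0.0, 0
    for g in np.unique(groups):
        idx = groups == g
        X = np.column_stack([np.ones(idx.sum()), t[idx]])
        c, res, rank, _ = np.linalg.lstsq(X, y[idx], rcond=None)
        coefs.append(c)
        if idx.sum() > 2 and res.size:
            sse += float(res[0])
            df += idx.sum() - 2
    return np.array(coefs), sse, df


def _moment_components(y: np.ndarray, t: np.ndarray, groups: np.ndarray):
    """Method-of-moments variance components (degenerate-safe fallback).

    Between-subject covariance of per-subject OLS coefficients minus the
    average sampling covariance, eigenvalue-clipped to PSD.
    """
    coefs, sse, df = _subject_ols(y, t, groups)
    sigma2 = sse / df if df > 0 else 0.0
    between = np.cov(coefs.T, ddof=1) if len(coefs) > 1 else np.zeros((2, 2))
    sampling = np.zeros((2, 2))
    for g in np.unique(groups):
        idx = groups == g
        X = np.column_stack([np.ones(idx.sum()), t[idx]])
        sampling += sigma2 * np.linalg.inv(X.T @ X)
    sampling /= len(coefs)
    sigma_b = np.atleast_2d(between) - sampling
    w, v = np.linalg.eigh(sigma_b)
    sigma_b = (v * np.maximum(w, 0.0)) @ v.T
    return coefs.mean(axis=0), sigma_b, max(sigma2, 0.0)


def _reml_components(y: np.ndarray, t: np.ndarray, groups: np.ndarray):
    """REML fit of the random-intercept/random-slope model at one voxel.

    Falls back to method-of-moments when the data are (near-)noise-free or
    the optimizer fails — both logged.
    """
    import statsmodels.api as sm

    scale = float(np.std(y)) or 1.0
    _, sse, df = _subject_ols(y, t, groups)
    if df == 0 or sse / max(df, 1) < (1e-7 * scale) ** 2:
        logger.debug("near-noise-free voxel: method-of-moments components")
        return _moment_components(y, t, groups)
    X = np.column_stack([np.ones_like(t), t])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = sm.MixedLM(y, X, groups=groups, exog_re=X)
            fit = md.fit(reml=True, method="lbfgs", maxiter=200, disp=False)
        beta = np.asarray(fit.fe_params, dtype=float)
        sigma_b = np.asarray(fit.cov_re, dtype=float)
        sigma2 = float(fit.scale)
        if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(sigma_b))
                and np.isfinite(sigma2)):
            raise FitError("non-finite REML estimates")
        w, v = np.linalg.eigh(sigma_b)
        sigma_b = (v * np.maximum(w, 0.0)) @ v.T
        return beta, sigma_b, max(sigma2, 0.0)
    except Exception as exc:  # pragma: no cover - rare optimizer failures
        logger.warning("REML failed (%s); method-of-moments fallback", exc)
        return _moment_components(y, t, groups)


def _gls_fixed_effects(Y: np.ndarray, t: np.ndarray, groups: np.ndarray,
                       sigma_b: np.ndarray, sigma2: float) -> np.ndarray:
    """Closed-form GLS fixed effects for all voxels sharing components.

    ``Y`` is (n_obs, V). With marginal covariance
    V_i = X_i Sigma_b X_i' + sigma2 I per subject, solves
    beta = (sum X'V^-1 X)^-1 (sum X'V^-1 Y).
    """
    if sigma2 < _ZERO_TOL and np.abs(sigma_b).max() < _ZERO_TOL:
        # degenerate limit: plain OLS on the pooled design
        X = np.column_stack([np.ones_like(t), t])
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        return beta
    A = np.zeros((2, 2))
    B = np.zeros((2, Y.shape[1]))
    for g in np.unique(groups):
        idx = groups == g
        X = np.column_stack([np.ones(idx.sum()), t[idx]])
        V = X @ sigma_b @ X.T + sigma2 * np.eye(idx.sum())
        if sigma2 < _ZERO_TOL:
            Vinv = np.linalg.pinv(V)
        else:
            Vinv = np.linalg.inv(V)
        A += X.T @ Vinv @ X
        B += X.T @ Vinv @ Y[idx]
    return np.linalg.solve(A, B)


def _stack_control_data(cohort: Cohort, voxel_values: np.ndarray | None = None):
    controls = cohort.controls
    times, groups, rows = [], [], []
    for i, subj in enumerate(controls):
        for scan in subj.scans:
            times.append(scan.scan_time_years)
            groups.append(i)
            rows.append(cohort.images[(subj.subject_id, scan.scan_index)]
                        .values[cohort.mask])
    return (np.asarray(times), np.asarray(groups),
            np.asarray(rows))  # (n_obs,), (n_obs,), (n_obs, V)


def fit_control_model(cohort: Cohort, mode: str = "pooled",
                      n_sample_voxels: int = 40) -> ControlModel:
    """Estimate the normative trajectory model from a cohort's controls.

    ``mode="pooled"`` (default) estimates one shared random-effect
    covariance and residual variance by REML on an evenly spaced sample of
    in-mask voxels — the practical choice on small grids; ``mode="voxel"``
    runs REML at every voxel. Fixed effects are always per voxel.
    """
    controls = cohort.controls
    if len(controls) < 2:
        raise FitError("need at least 2 control subjects")
    if any(len(s.scans) < 2 for s in controls):
        raise FitError("every control needs at least 2 scans")
    if mode not in ("pooled", "voxel"):
        raise ConfigError(f"unknown mode {mode!r}")

    t, groups, Y = _stack_control_data(cohort)
    n_voxels = Y.shape[1]
    n_scans = len(t)

    if mode == "voxel":
        beta = np.empty((2, n_voxels))
        sigma_b = np.empty((n_voxels, 2, 2))
        sigma2 = np.empty(n_voxels)
        for v in range(n_voxels):
            b, sb, s2 = _reml_components(Y[:, v], t, groups)
            sigma_b[v] = sb
            sigma2[v] = s2
            beta[:, v] = _gls_fixed_effects(Y[:, [v]], t, groups, sb, s2)[:, 0]
        return ControlModel(beta=beta, sigma_b=sigma_b, sigma2_eps=sigma2,
                            mask=cohort.mask, n_controls=len(controls),
                            n_scans=n_scans)

    sample = np.unique(np.linspace(0, n_voxels - 1,
                                   min(n_sample_voxels, n_voxels)).astype(int))
    comps = [_reml_components(Y[:, v], t, groups) for v in sample]
    sigma_b = np.mean([c[1] for c in comps], axis=0)
    sigma2 = float(np.mean([c[2] for c in comps]))
    beta = _gls_fixed_effects(Y, t, groups, sigma_b, sigma2)
    return ControlModel(beta=beta, sigma_b=sigma_b, sigma2_eps=sigma2,
                        mask=cohort.mask, n_controls=len(controls),
                        n_scans=n_scans)


# ---------------------------------------------------------------------------
# subject posterior and prediction

def posterior_update(times: np.ndarray, y: np.ndarray, beta: np.ndarray,
                     sigma_b: np.ndarray, sigma2: np.ndarray | float
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Conjugate normal update of the random-effect prior at every voxel.

    Uses the innovation form ``K = Sigma_b X' S^-1`` with
    ``S = X Sigma_b X' + sigma2 I``, which stays valid in the degenerate
    limits Sigma_b -> 0 (posterior pinned to the population trajectory) and
    sigma2 -> 0 (posterior interpolates the observations).

    Returns posterior mean ``(2, V)`` and covariance (``(2, 2)`` when the
    prior components are shared, else ``(V, 2, 2)``).
    """
    times = np.asarray(times, dtype=float)
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n = times.size
    X = np.column_stack([np.ones(n), times])
    resid = y - X @ beta  # (n, V)

    shared = (np.asarray(sigma_b).ndim == 2 and np.ndim(sigma2) == 0)
    if shared:
        S = X @ sigma_b @ X.T + float(sigma2) * np.eye(n)
        Sinv = np.linalg.pinv(S)
        K = sigma_b @ X.T @ Sinv  # (2, n)
        mean = K @ resid  # (2, V)
        cov = sigma_b - K @ X @ sigma_b
        cov = (cov + cov.T) / 2
        return mean, cov

    V = y.shape[1]
    sb = np.broadcast_to(np.asarray(sigma_b, dtype=float),
                         (V, 2, 2)) if np.asarray(sigma_b).ndim == 2 \
        else np.asarray(sigma_b, dtype=float)
    s2 = np.broadcast_to(np.asarray(sigma2, dtype=float), (V,))
    S = np.einsum("ij,vjk,lk->vil", X, sb, X) + s2[:, None, None] * np.eye(n)
    Sinv = np.linalg.pinv(S)
    K = np.einsum("vij,kj,vkl->vil", sb, X, Sinv)  # (V, 2, n)
    mean = np.einsum("vin,nv->iv", K, resid)
    cov = sb - np.einsum("vin,nj,vjk->vik", K, X, sb)
    cov = (cov + np.swapaxes(cov, 1, 2)) / 2
    return mean, cov


def fit_subject_posterior(cohort: Cohort, subject: SubjectSeries,
                          model: ControlModel,
                          max_cdr: float = 0.5) -> SubjectPosterior:
    """Condition the control model on a subject's predictor scan pair.

    Only the subject's first two scans are used; both must have global
    CDR <= ``max_cdr`` (0.5 by default; set 0 for the asymptomatic-only
    sensitivity analysis).
    """
    if len(subject.scans) < 3:
        raise EligibilityError(
            f"{subject.subject_id}: needs >= 3 scans (has {len(subject.scans)})")
    pair = subject.scans[:2]
    if pair[0].scan_index != 0 or pair[1].scan_index != 1:
        raise EligibilityError(f"{subject.subject_id}: predictor pair out of order")
    if pair[1].scan_time_years <= pair[0].scan_time_years:
        raise EligibilityError(f"{subject.subject_id}: pair times not increasing")
    for scan in pair:
        if scan.cdr_global > max_cdr:
            raise EligibilityError(
                f"{subject.subject_id}: scan {scan.scan_index} has CDR "
                f"{scan.cdr_global} > {max_cdr}")

    times = np.array([s.scan_time_years for s in pair])
    y = np.stack([cohort.images[(subject.subject_id, s.scan_index)]
                  .values[cohort.mask] for s in pair])
    mean, cov = posterior_update(times, y, model.beta, model.sigma_b,
                                 model.sigma2_eps)
    return SubjectPosterior(subject_id=subject.subject_id, mean=mean, cov=cov,
                            pair_times=(times[0], times[1]))


def predict(posterior: SubjectPosterior, model: ControlModel,
            t: float) -> PosteriorPrediction:
    """Posterior-predictive volume distribution at time ``t`` (years).

    Mean follows the subject-specific line; the variance combines the
    propagated posterior parameter uncertainty with the residual variance.
    """
    if t < 0:
        raise ValueError("prediction time must be non-negative")
    x = np.array([1.0, t])
    mean = x @ (model.beta + posterior.mean)  # (V,)
    if posterior.cov.ndim == 2:
        param_var = float(x @ posterior.cov @ x)
    else:
        param_var = np.einsum("i,vij,j->v", x, posterior.cov, x)
    var = param_var + model.sigma2_at()
    return PosteriorPrediction(t=float(t), mean=mean, sd=np.sqrt(np.maximum(var, 0.0)))


def erf_score(observed: np.ndarray | float,
              prediction: PosteriorPrediction) -> np.ndarray | float:
    """Error-function deviation score of observed volume against prediction.

    ``erf((obs - mu) / (s * sqrt(2)))`` in (-1, 1); negative iff observed
    volume falls below the predictive mean. Raises on zero predictive SD.
    """
    sd = np.asarray(prediction.sd, dtype=float)
    if np.any(sd <= 0):
        raise DegeneratePredictionError(
            "zero predictive SD; degenerate voxels must be excluded")
    return special.erf((observed - prediction.mean) / (sd * np.sqrt(2.0)))


def deviation_map(cohort: Cohort, subject: SubjectSeries, scan_index: int,
                  posterior: SubjectPosterior, model: ControlModel
                  ) -> DeviationMap:
    """Score one follow-up scan voxel-wise against the subject's prediction.

    The predictor scan pair (indices 0 and 1) is never scored. Voxels with
    a degenerate (zero-SD) prediction are excluded from the map (NaN) and
    logged.
    """
    if scan_index < 2:
        raise ProtocolError(
            "the predictor scan pair must not be scored (scan_index >= 2)")
    scan = next(s for s in subject.scans if s.scan_index == scan_index)
    pred = predict(posterior, model, scan.scan_time_years)
    observed = cohort.images[(subject.subject_id, scan_index)].values[cohort.mask]

    ok = pred.sd > 0
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("%s scan %d: excluding %d degenerate voxel(s)",
                    subject.subject_id, scan_index, n_bad)
    flat = np.full(pred.mean.shape, np.nan)
    flat[ok] = special.erf(
        (observed[ok] - pred.mean[ok]) / (pred.sd[ok] * np.sqrt(2.0)))
    values = np.full(cohort.mask.shape, np.nan)
    values[cohort.mask] = flat
    return DeviationMap(values=values, mask=cohort.mask,
                        subject_id=subject.subject_id, scan_index=scan_index,
                        t=scan.scan_time_years)


def cluster_volume(dmap: DeviationMap, threshold: float,
                   voxel_volume_mm3: float) -> ClusterVolumeResult:
    """Count in-mask voxels with erf <= threshold; volume in mm^3.

    ``threshold`` must lie in (-1, 0): only unexpectedly *low* volumes are
    counted. NaN (excluded) voxels never count.
    """
    if not -1.0 < threshold < 0.0:
        raise ValueError(f"threshold must lie in (-1, 0), got {threshold}")
    vals = dmap.values[dmap.mask]
    with np.errstate(invalid="ignore"):
        n = int(np.sum(vals <= threshold))
    return ClusterVolumeResult(threshold=threshold, n_voxels=n,
                               voxel_volume_mm3=voxel_volume_mm3)
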