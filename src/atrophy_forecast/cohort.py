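"""Synthetic longitudinal gray-matter cohorts.

Generates cohorts of mutation carriers and family controls with the
longitudinal structure the downstream analyses assume: per-voxel linear
decline with subject-level random intercepts and slopes, and, in a subset
of carriers, a change-point acceleration of volume loss confined to a
spherical voxel cluster. Conversion to dementia (global CDR reaching 1)
follows acceleration onset after a lag and is recorded at scheduled visits,
mirroring how CDR is ascertained in observational FTLD cohorts.

The control generative model for voxel ``v`` of subject ``i`` at time ``t``
(years since the subject's first scan) is::

    y_iv(t) = (a_v + a_i) + (b_v + b_i) * t + eps,   eps ~ N(0, sigma_eps^2)

with subject effects ``a_i ~ N(0, baseline_volume_sd^2)`` and
``b_i ~ N(0, control_slope_sd^2)``. Accelerating carriers additionally lose
``acceleration_magnitude`` (a negative slope increment) per year inside
their cluster for ``t`` past their onset time.

Randomness is organised as one root seed with per-subject substreams keyed
by a stable hash of the subject identifier, so enlarging a cohort never
reshuffles existing subjects.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import ConfigError, SchemaError

__all__ = [
    "CohortConfig",
    "ScanRecord",
    "SubjectSeries",
    "VolumeImage",
    "Cohort",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "METADATA_COLUMNS",
]

#: exact header of the per-scan metadata table
METADATA_COLUMNS = [
    "subject_id",
    "group",
    "sex",
    "scan_index",
    "scan_time_years",
    "age_at_scan",
    "tiv_mm3",
    "scanner_id",
    "cdr_global",
    "conversion_time_years",
    "censor_time_years",
    "image_path",
]

CARRIER_GROUPS = ("C9orf72", "GRN", "MAPT")
#: carrier gene mix of a large familial-FTLD consortium sample (96:76:63)
_GENE_PROBS = (96 / 235, 76 / 235, 63 / 235)
_CDR_LEVELS = (0.0, 0.5, 1.0, 2.0, 3.0)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Defaults emulate a familial-FTLD observational cohort: ~annual MRI
    visits, baseline age 47.8 (SD 12.5) years, 56.8% female, three scanner
    platforms, and roughly one carrier in ten converting to dementia within
    the observation window. Voxel values are modulated gray-matter volumes
    on an arbitrary but internally consistent scale (~0.6 per voxel at
    baseline, ~1%/year normative decline).
    """

    n_controls: int = 60
    n_carriers: int = 120
    prop_converters: float = 0.15
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    voxel_size_mm: float = 2.0
    n_scans_per_subject: int = 5
    scan_interval_years: float = 1.1
    scan_interval_jitter_sd: float = 0.15
    baseline_volume_mean: float = 0.60
    baseline_volume_sd: float = 0.05
    control_slope_mean: float = -0.006
    control_slope_sd: float = 0.003
    residual_noise_sd: float = 0.02
    acceleration_magnitude: float = -0.04
    acceleration_cluster_radius_voxels: float = 3.0
    onset_time_mean_years: float = 2.5
    onset_time_sd_years: float = 1.5
    conversion_lag_years: float = 1.0
    prop_baseline_cdr_half: float = 0.145
    age_mean: float = 47.8
    age_sd: float = 12.5
    prop_female: float = 0.568
    tiv_mean_mm3: float = 1.45e6
    tiv_sd_mm3: float = 1.5e5
    n_scanners: int = 3
    age_effect_per_year: float = 0.0
    tiv_effect_per_mm3: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 0 or self.n_carriers < 0:
            raise ConfigError("subject counts must be non-negative")
        if not 0.0 <= self.prop_converters <= 1.0:
            raise ConfigError("prop_converters must lie in [0, 1]")
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ConfigError("grid_shape must be 3 positive integers")
        if self.voxel_size_mm <= 0:
            raise ConfigError("voxel_size_mm must be positive")
        if self.n_scans_per_subject < 3:
            raise ConfigError("need at least 3 scans per subject")
        if self.scan_interval_years <= 0:
            raise ConfigError("scan_interval_years must be positive")
        if self.control_slope_mean > 0:
            raise ConfigError("control_slope_mean must be <= 0 (volume loss)")
        for name in (
            "scan_interval_jitter_sd", "baseline_volume_sd", "control_slope_sd",
            "residual_noise_sd", "onset_time_sd_years", "age_sd", "tiv_sd_mm3",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.acceleration_cluster_radius_voxels <= 0:
            raise ConfigError("acceleration_cluster_radius_voxels must be positive")
        if self.n_scanners < 1:
            raise ConfigError("n_scanners must be >= 1")
        vals = [getattr(self, f.name) for f in self.__dataclass_fields__.values()
                if f.name not in ("grid_shape",)]
        if not np.all(np.isfinite([v for v in vals if isinstance(v, (int, float))])):
            raise ConfigError("config parameters must be finite")

    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f in self.__dataclass_fields__}
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(int(x) for x in d["grid_shape"])
        return cls(**d)


@dataclass(frozen=True)
class ScanRecord:
    """One MRI visit of one subject."""

    subject_id: str
    scan_index: int
    scan_time_years: float
    age_at_scan: float
    cdr_global: float
    tiv_mm3: float
    scanner_id: str

    def __post_init__(self) -> None:
        if self.cdr_global not in _CDR_LEVELS:
            raise SchemaError(
                f"cdr_global must be one of {_CDR_LEVELS}, got {self.cdr_global}"
            )


@dataclass
class SubjectSeries:
    """Ordered longitudinal scan series of one subject.

    ``conversion_time_years`` is the time of the first visit with global
    CDR >= 1, or ``None`` for non-converters; ``censor_time_years`` is the
    time of the last observation.
    """

    subject_id: str
    group: str  # "control" or a carrier gene
    sex: str  # "F" / "M"
    scans: list[ScanRecord] = field(default_factory=list)
    conversion_time_years: float | None = None
    censor_time_years: float = 0.0
    #: generator ground truth (random effects, onset, cluster center);
    #: None for cohorts loaded from disk
    truth: dict | None = None

    @property
    def is_carrier(self) -> bool:
        return self.group in CARRIER_GROUPS

    @property
    def is_converter(self) -> bool:
        return self.conversion_time_years is not None

    def validate(self) -> None:
        times = [s.scan_time_years for s in self.scans]
        if times and times[0] != 0.0:
            raise SchemaError(f"{self.subject_id}: first scan time must be 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise SchemaError(f"{self.subject_id}: scan times not strictly increasing")
        if self.conversion_time_years is not None:
            if self.conversion_time_years > self.censor_time_years:
                raise SchemaError(
                    f"{self.subject_id}: conversion after censoring time"
                )


@dataclass
class VolumeImage:
    """Masked 3D grid of modulated gray-matter volume values."""

    values: np.ndarray
    mask: np.ndarray
    voxel_volume_mm3: float

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ConfigError("values and mask shapes disagree")
        if self.voxel_volume_mm3 <= 0:
            raise ConfigError("voxel_volume_mm3 must be positive")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ConfigError("in-mask voxel values must be finite")


@dataclass
class Cohort:
    """A full synthetic (or loaded) cohort: metadata plus images."""

    subjects: list[SubjectSeries]
    images: dict[tuple[str, int], VolumeImage]
    mask: np.ndarray
    atlas: np.ndarray
    atlas_labels: dict[int, str]
    voxel_size_mm: float
    config: CohortConfig | None = None

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size_mm) ** 3

    def subject(self, subject_id: str) -> SubjectSeries:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    @property
    def controls(self) -> list[SubjectSeries]:
        return [s for s in self.subjects if s.group == "control"]

    @property
    def carriers(self) -> list[SubjectSeries]:
        return [s for s in self.subjects if s.is_carrier]

    def metadata_frame(self, image_paths: Mapping[tuple[str, int], str] | None = None
                       ) -> pd.DataFrame:
        """Per-scan metadata as a DataFrame with the canonical column set."""
        rows = []
        for subj in self.subjects:
            for scan in subj.scans:
                key = (subj.subject_id, scan.scan_index)
                rows.append({
                    "subject_id": subj.subject_id,
                    "group": subj.group,
                    "sex": subj.sex,
                    "scan_index": scan.scan_index,
                    "scan_time_years": scan.scan_time_years,
                    "age_at_scan": scan.age_at_scan,
                    "tiv_mm3": scan.tiv_mm3,
                    "scanner_id": scan.scanner_id,
                    "cdr_global": scan.cdr_global,
                    "conversion_time_years": subj.conversion_time_years,
                    "censor_time_years": subj.censor_time_years,
                    "image_path": (image_paths or {}).get(key, ""),
                })
        return pd.DataFrame(rows, columns=METADATA_COLUMNS)


def _substream(seed: int, *key: object) -> np.random.Generator:
    """Deterministic RNG substream keyed by arbitrary strings.

    Stable across processes and insertion order: the spawn key is a SHA-256
    digest of the key tuple, so a subject's stream depends only on its id.
    """
    digest = hashlib.sha256("/".join(map(str, key)).encode()).digest()
    spawn = tuple(int.from_bytes(digest[i:i + 4], "little") for i in range(0, 16, 4))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=spawn))


def _spatial_intercept(config: CohortConfig) -> np.ndarray:
    """Smooth fixed spatial baseline pattern a_v, shared by all subjects."""
    rng = _substream(config.seed, "spatial")
    coarse = rng.normal(size=(3, 3, 3))
    zoom = [s / 3 for s in config.grid_shape]
    smooth = ndimage.zoom(coarse, zoom, order=1, mode="nearest")
    smooth = smooth[: config.grid_shape[0], : config.grid_shape[1], : config.grid_shape[2]]
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    # +-5% smooth spatial variation around the mean baseline volume
    return config.baseline_volume_mean * (1.0 + 0.05 * smooth)


def _default_atlas(grid_shape: tuple[int, int, int]) -> tuple[np.ndarray, dict[int, str]]:
    """Two disjoint composite labels standing in for frontal/temporal lobes."""
    atlas = np.zeros(grid_shape, dtype=np.int16)
    half = grid_shape[0] // 2
    atlas[:half] = 1
    atlas[half:] = 2
    return atlas, {1: "frontal", 2: "temporal"}


def _cluster_mask(grid_shape: tuple[int, int, int], center: np.ndarray,
                  radius: float) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in grid_shape)]
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return dist2 <= radius ** 2


def _simulate_subject(subject_id: str, group: str, config: CohortConfig,
                      a_v: np.ndarray, mask: np.ndarray
                      ) -> tuple[SubjectSeries, dict[tuple[str, int], VolumeImage]]:
    rng = _substream(config.seed, "subject", subject_id)
    radius = config.acceleration_cluster_radius_voxels

    # fixed draw order; all covariates first, then trajectory effects
    age0 = float(np.clip(rng.normal(config.age_mean, config.age_sd), 18.0, 90.0))
    sex = "F" if rng.random() < config.prop_female else "M"
    tiv = float(max(rng.normal(config.tiv_mean_mm3, config.tiv_sd_mm3),
                    0.5 * config.tiv_mean_mm3))
    scanner = f"scanner{rng.integers(config.n_scanners)}"
    a_i = rng.normal(0.0, config.baseline_volume_sd)
    b_i = rng.normal(0.0, config.control_slope_sd)

    is_carrier = group in CARRIER_GROUPS
    baseline_cdr = 0.0
    accelerates = False
    onset = np.inf
    lag = np.inf
    center = np.zeros(3)
    if is_carrier:
        baseline_cdr = 0.5 if rng.random() < config.prop_baseline_cdr_half else 0.0
        accelerates = rng.random() < config.prop_converters
        onset = max(rng.normal(config.onset_time_mean_years,
                               config.onset_time_sd_years), 0.1)
        lag = max(rng.normal(config.conversion_lag_years,
                             0.25 * config.conversion_lag_years), 0.1)
        lo = np.ceil(radius)
        hi = np.array(config.grid_shape) - 1 - np.ceil(radius)
        center = np.array([rng.integers(lo, h + 1) for h in hi])

    # visit schedule: jittered around a regular grid, strictly increasing
    increments = config.scan_interval_years + rng.normal(
        0.0, config.scan_interval_jitter_sd, size=config.n_scans_per_subject - 1)
    increments = np.maximum(increments, 0.25)
    times = np.concatenate([[0.0], np.cumsum(increments)])

    cluster = None
    if accelerates and config.acceleration_magnitude != 0.0:
        cluster = _cluster_mask(config.grid_shape, center, radius)

    # conversion observed at the first visit of index >= 2 at/after onset+lag
    conversion_time = None
    if accelerates:
        for k in range(2, len(times)):
            if times[k] >= onset + lag:
                conversion_time = float(times[k])
                break

    slope = config.control_slope_mean + b_i
    scans: list[ScanRecord] = []
    images: dict[tuple[str, int], VolumeImage] = {}
    for k, t in enumerate(times):
        values = a_v + a_i + slope * t
        values = values + config.age_effect_per_year * (age0 + t - config.age_mean)
        values = values + config.tiv_effect_per_mm3 * (tiv - config.tiv_mean_mm3)
        if cluster is not None and t > onset:
            values = values + config.acceleration_magnitude * (t - onset) * cluster
        if config.residual_noise_sd > 0:
            values = values + rng.normal(0.0, config.residual_noise_sd,
                                         size=config.grid_shape)
        else:
            values = values.copy() if values.base is not None else values
        values = np.maximum(values, 0.0)

        if conversion_time is not None and t >= conversion_time:
            cdr = 1.0
        else:
            cdr = baseline_cdr
        scans.append(ScanRecord(
            subject_id=subject_id, scan_index=k, scan_time_years=float(t),
            age_at_scan=age0 + float(t), cdr_global=cdr, tiv_mm3=tiv,
            scanner_id=scanner,
        ))
        images[(subject_id, k)] = VolumeImage(
            values=values, mask=mask, voxel_volume_mm3=config.voxel_size_mm ** 3)

    series = SubjectSeries(
        subject_id=subject_id, group=group, sex=sex, scans=scans,
        conversion_time_years=conversion_time,
        censor_time_years=float(times[-1]),
        truth={
            "intercept_offset": float(a_i),
            "slope_offset": float(b_i),
            "accelerates": bool(accelerates and config.acceleration_magnitude != 0),
            "onset_years": float(onset) if accelerates else None,
            "cluster_center": center.tolist() if accelerates else None,
        },
    )
    series.validate()
    return series, images


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Simulate a full longitudinal cohort from ``config``.

    Deterministic for identical ``(config, seed)``. Raises
    :class:`~atrophy_forecast.exceptions.ConfigError` if the grid cannot
    contain the acceleration cluster.
    """
    radius = config.acceleration_cluster_radius_voxels
    if config.n_carriers > 0 and any(
            s < 2 * np.ceil(radius) + 1 for s in config.grid_shape):
        raise ConfigError(
            f"grid {config.grid_shape} too small for acceleration cluster "
            f"of radius {radius} voxels")

    mask = np.ones(config.grid_shape, dtype=bool)
    a_v = _spatial_intercept(config)
    atlas, labels = _default_atlas(config.grid_shape)

    subjects: list[SubjectSeries] = []
    images: dict[tuple[str, int], VolumeImage] = {}

    for i in range(config.n_controls):
        sid = f"CTRL{i:04d}"
        series, im = _simulate_subject(sid, "control", config, a_v, mask)
        subjects.append(series)
        images.update(im)
    for i in range(config.n_carriers):
        sid = f"CARR{i:04d}"
        # gene drawn from the subject's own substream: enlarging the cohort
        # never relabels existing carriers
        gene = _substream(config.seed, "gene", sid).choice(
            CARRIER_GROUPS, p=_GENE_PROBS)
        series, im = _simulate_subject(sid, str(gene), config, a_v, mask)
        subjects.append(series)
        images.update(im)

    return Cohort(subjects=subjects, images=images, mask=mask, atlas=atlas,
                  atlas_labels=labels, voxel_size_mm=config.voxel_size_mm,
                  config=config)


# ---------------------------------------------------------------------------
# serialization

def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


def write_cohort(cohort: Cohort, directory: str | Path) -> Path:
    """Serialize a cohort: one NIfTI per scan, mask/atlas images, metadata CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = _affine(cohort.voxel_size_mm)

    nib.save(nib.Nifti1Image(cohort.mask.astype(np.uint8), aff),
             directory / "mask.nii.gz")
    nib.save(nib.Nifti1Image(cohort.atlas.astype(np.int16), aff),
             directory / "atlas.nii.gz")
    with open(directory / "atlas_labels.json", "w") as fh:
        json.dump({str(k): v for k, v in cohort.atlas_labels.items()}, fh, indent=2)
    if cohort.config is not None:
        import yaml
        with open(directory / "config.yaml", "w") as fh:
            yaml.safe_dump(cohort.config.to_dict(), fh)

    paths: dict[tuple[str, int], str] = {}
    for (sid, k), img in cohort.images.items():
        name = f"{sid}_s{k}.nii.gz"
        nib.save(nib.Nifti1Image(img.values.astype(np.float32), aff),
                 directory / name)
        paths[(sid, k)] = name
    cohort.metadata_frame(paths).to_csv(directory / "metadata.csv", index=False)
    return directory


def _parse_optional_float(x) -> float | None:
    if x is None or (isinstance(x, float) and np.isnan(x)) or x == "":
        return None
    return float(x)


def read_metadata(csv_path: str | Path) -> pd.DataFrame:
    """Read and schema-check a cohort metadata CSV."""
    csv_path = Path(csv_path)
    if not csv_path.exists():
        raise SchemaError(f"metadata file not found: {csv_path}")
    df = pd.read_csv(csv_path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata CSV missing column(s): {', '.join(missing)}")
    return df


def read_cohort(directory: str | Path) -> Cohort:
    """Load a cohort previously produced by :func:`write_cohort`."""
    directory = Path(directory)
    df = read_metadata(directory / "metadata.csv")

    mask_img = nib.load(directory / "mask.nii.gz")
    mask = np.asarray(mask_img.dataobj).astype(bool)
    voxel_size = float(mask_img.header.get_zooms()[0])
    atlas = np.asarray(nib.load(directory / "atlas.nii.gz").dataobj).astype(int)
    with open(directory / "atlas_labels.json") as fh:
        labels = {int(k): v for k, v in json.load(fh).items()}
    config = None
    cfg_path = directory / "config.yaml"
    if cfg_path.exists():
        import yaml
        with open(cfg_path) as fh:
            config = CohortConfig.from_dict(yaml.safe_load(fh))

    subjects: list[SubjectSeries] = []
    images: dict[tuple[str, int], VolumeImage] = {}
    for sid, g in df.groupby("subject_id", sort=False):
        g = g.sort_values("scan_index")
        first = g.iloc[0]
        scans = []
        for _, row in g.iterrows():
            scans.append(ScanRecord(
                subject_id=sid, scan_index=int(row["scan_index"]),
                scan_time_years=float(row["scan_time_years"]),
                age_at_scan=float(row["age_at_scan"]),
                cdr_global=float(row["cdr_global"]),
                tiv_mm3=float(row["tiv_mm3"]),
                scanner_id=str(row["scanner_id"]),
            ))
            img_path = directory / str(row["image_path"])
            if not img_path.exists():
                raise SchemaError(f"image file missing: {img_path}")
            values = np.asarray(nib.load(img_path).dataobj, dtype=np.float64)
            images[(sid, int(row["scan_index"]))] = VolumeImage(
                values=values, mask=mask, voxel_volume_mm3=voxel_size ** 3)
        series = SubjectSeries(
            subject_id=sid, group=str(first["group"]), sex=str(first["sex"]),
            scans=scans,
            conversion_time_years=_parse_optional_float(
                first["conversion_time_years"]),
            censor_time_years=float(first["censor_time_years"]),
        )
        series.validate()
        subjects.append(series)

    return Cohort(subjects=subjects, images=images, mask=mask, atlas=atlas,
                  atlas_labels=labels, voxel_size_mm=voxel_size, config=config)
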