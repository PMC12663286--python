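"""Synthetic study datasets with known ground truth.

Generates everything a real cupping session would produce — cohort
metadata, fiducial correspondences with a known optical->thermal affine
transform, thermal frame series, flat optical frames with the ID card
and cup-imprint ring, and point erythema series — with the spatial and
temporal statistical structure of the study:

* regional temperature kinetics follow a single-exponential relaxation
  ``delta(t) = asymptote + (initial - asymptote) * exp(-t / tau)`` per
  region, anchored so that the minute-0 medians are +0.37 °C (Peri-ROI),
  -0.06 °C (ROI Edge) and -0.54 °C (ROI Center) and the ROI Center
  crosses baseline between minutes 3 and 4;
* erythema deltas are drawn per Monk-Skin-Tone group from the reported
  group means and SDs at each post-cupping minute;
* between-subject spread is modeled as a per-region additive offset on
  the temperature delta, with SDs chosen to roughly match the reported
  cohort interquartile ranges.

Setting every SD to zero makes generation fully deterministic and
noise-free, so the downstream pipeline can be tested for exact
parameter recovery.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError, DatasetError, InvalidArgumentError
from .metrics import POST_TIMEPOINTS, TIMEPOINTS, ThermalFrame
from .register import AffineTransform2D, EllipseSpec, FiducialSet, map_ellipse
from .roi import REGION_NAMES, derive_concentric, rasterize_masks
from .stats import classify_bmi, classify_eumelanin, classify_mst_group

THERMAL_SHAPE = (240, 320)  # rows, cols — long-wave IR camera resolution
OPTICAL_SHAPE = (480, 640)

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectRecord:
    """One participant's covariates; derived fields are kept consistent."""

    subject_id: str
    sex: str
    bmi: float
    melanin_index: float
    mst_level: int
    bmi_category: str = ""
    eumelanin_category: str = ""
    mst_group: str = ""

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise InvalidArgumentError(f"sex must be female/male, got {self.sex!r}")
        object.__setattr__(self, "bmi_category", classify_bmi(self.bmi))
        object.__setattr__(self, "eumelanin_category", classify_eumelanin(self.melanin_index))
        object.__setattr__(self, "mst_group", classify_mst_group(self.mst_level))

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "sex": self.sex,
            "bmi": self.bmi,
            "bmi_category": self.bmi_category,
            "melanin_index": self.melanin_index,
            "eumelanin_category": self.eumelanin_category,
            "mst_level": self.mst_level,
            "mst_group": self.mst_group,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectRecord":
        return cls(
            subject_id=str(d["subject_id"]),
            sex=str(d["sex"]),
            bmi=float(d["bmi"]),
            melanin_index=float(d["melanin_index"]),
            mst_level=int(d["mst_level"]),
        )


@dataclass(frozen=True)
class RegionKinetics:
    """Exponential-relaxation parameters for one region's temperature delta."""

    initial_delta: float  # °C at minute 0
    asymptote_delta: float  # °C as t -> infinity
    tau: float  # minutes
    subject_sd: float = 0.0  # between-subject SD of an additive offset, °C

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise InvalidArgumentError(f"tau must be > 0, got {self.tau}")
        if self.subject_sd < 0:
            raise InvalidArgumentError("subject_sd must be >= 0")

    def delta(self, t_minutes) -> np.ndarray:
        t = np.asarray(t_minutes, dtype=float)
        return self.asymptote_delta + (self.initial_delta - self.asymptote_delta) * np.exp(-t / self.tau)


@dataclass(frozen=True)
class KineticsParams:
    """Regional temperature-response parameters.

    Defaults anchor the minute-0 region deltas at the reported values
    and give the ROI Center a baseline crossing near minute 3.5; the
    between-subject SDs approximate the reported cohort IQR widths
    (IQR / 1.349 for a normal spread).  ``baseline_temp`` defaults to a
    typical sacral skin temperature.
    """

    peri: RegionKinetics = field(default_factory=lambda: RegionKinetics(0.37, 0.0, 0.5, 0.55))
    edge: RegionKinetics = field(default_factory=lambda: RegionKinetics(-0.06, 0.25, 2.0, 0.50))
    center: RegionKinetics = field(default_factory=lambda: RegionKinetics(-0.54, 0.30, 3.4, 0.65))
    baseline_temp: float = 33.0  # °C
    noise_sd: float = 0.1  # i.i.d. pixel noise, °C
    smoothing_scale: float = 2.0  # Gaussian blur of the delta map, px

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")
        if self.smoothing_scale < 0:
            raise InvalidArgumentError("smoothing_scale must be >= 0")

    @property
    def regions(self) -> dict[str, RegionKinetics]:
        return {"Peri-ROI": self.peri, "ROI Edge": self.edge, "ROI Center": self.center}

    def noise_free(self) -> "KineticsParams":
        return replace(
            self,
            peri=replace(self.peri, subject_sd=0.0),
            edge=replace(self.edge, subject_sd=0.0),
            center=replace(self.center, subject_sd=0.0),
            noise_sd=0.0,
        )


#: Reported per-group erythema-delta means and SDs (colorimeter units) at
#: minutes 0..7 post-cupping.
DARKER_ERYTHEMA_MEANS = (1.11, 0.98, 0.68, 1.17, 1.21, 1.29, 1.20, 1.02)
DARKER_ERYTHEMA_SDS = (1.76, 1.90, 3.53, 1.70, 1.61, 1.55, 1.54, 1.75)
LIGHTER_ERYTHEMA_MEANS = (3.80, 3.69, 3.99, 3.88, 3.67, 3.80, 3.80, 3.59)
LIGHTER_ERYTHEMA_SDS = (2.23, 2.19, 1.89, 1.78, 1.94, 2.20, 2.13, 2.27)


@dataclass(frozen=True)
class ErythemaGroupParams:
    """Per-MST-group erythema-delta distributions plus a baseline level."""

    mean_delta: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {"darker": DARKER_ERYTHEMA_MEANS, "lighter": LIGHTER_ERYTHEMA_MEANS}
    )
    sd_delta: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {"darker": DARKER_ERYTHEMA_SDS, "lighter": LIGHTER_ERYTHEMA_SDS}
    )
    baseline_mean: float = 10.0  # c.u.; only deltas matter downstream
    baseline_sd: float = 2.0

    def __post_init__(self) -> None:
        for group, vec in self.mean_delta.items():
            if group not in self.sd_delta:
                raise ConfigurationError(f"sd_delta missing group {group!r}")
            if len(vec) != 8 or len(self.sd_delta[group]) != 8:
                raise ConfigurationError("mean/sd vectors must have length 8 (minutes 0..7)")
            if any(s < 0 for s in self.sd_delta[group]):
                raise ConfigurationError("erythema SDs must be >= 0")
        if self.baseline_sd < 0:
            raise ConfigurationError("baseline_sd must be >= 0")

    def noise_free(self) -> "ErythemaGroupParams":
        return replace(
            self,
            sd_delta={g: (0.0,) * 8 for g in self.sd_delta},
            baseline_sd=0.0,
        )


@dataclass(frozen=True)
class GroundTruth:
    """Per-subject generation truth, for parameter-recovery tests."""

    true_transform: AffineTransform2D
    true_outer_ellipse: EllipseSpec  # thermal coordinates
    true_region_deltas: dict[str, dict[str, float]]  # region -> timepoint -> °C
    true_erythema_deltas: dict[str, float]  # timepoint -> c.u.

    def to_dict(self) -> dict:
        return {
            "true_transform": self.true_transform.to_dict(),
            "true_outer_ellipse": self.true_outer_ellipse.to_dict("thermal"),
            "true_region_deltas": self.true_region_deltas,
            "true_erythema_deltas": self.true_erythema_deltas,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            AffineTransform2D.from_dict(d["true_transform"]),
            EllipseSpec.from_dict(d["true_outer_ellipse"]),
            d["true_region_deltas"],
            d["true_erythema_deltas"],
        )


@dataclass(frozen=True)
class CohortParams:
    """Marginal distributions for cohort covariates (defaults approximate
    the study population: mean BMI 29.4 kg/m², mean Melanin Index ~56,
    69% female, darker-group MST levels concentrated at level 7)."""

    female_prob: float = 0.69
    bmi_mean: float = 29.41
    bmi_sd: float = 6.83
    bmi_min: float = 16.0
    melanin_darker: tuple[float, float] = (60.0, 10.0)  # mean, sd
    melanin_lighter: tuple[float, float] = (35.0, 8.0)
    mst_darker_levels: tuple[int, ...] = (6, 7, 8)
    mst_darker_weights: tuple[float, ...] = (7.0, 22.0, 1.0)
    mst_lighter_levels: tuple[int, ...] = (2, 4, 5)
    mst_lighter_weights: tuple[float, ...] = (3.0, 1.0, 1.0)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def generate_cohort(
    n_darker: int,
    n_lighter: int,
    seed: int,
    params: CohortParams | None = None,
) -> list[SubjectRecord]:
    """Sample a cohort with the requested MST-group sizes."""
    if n_darker < 0 or n_lighter < 0 or n_darker + n_lighter < 1:
        raise InvalidArgumentError("need n_darker >= 0, n_lighter >= 0 and at least one subject")
    p = params or CohortParams()
    rng = np.random.default_rng(seed)
    records = []
    groups = ["darker"] * n_darker + ["lighter"] * n_lighter
    for i, group in enumerate(groups):
        if group == "darker":
            levels, weights = p.mst_darker_levels, p.mst_darker_weights
            mi_mean, mi_sd = p.melanin_darker
        else:
            levels, weights = p.mst_lighter_levels, p.mst_lighter_weights
            mi_mean, mi_sd = p.melanin_lighter
        w = np.asarray(weights, dtype=float)
        mst = int(rng.choice(levels, p=w / w.sum()))
        bmi = float(max(p.bmi_min, rng.normal(p.bmi_mean, p.bmi_sd)))
        mi = float(np.clip(rng.normal(mi_mean, mi_sd), 1.0, 150.0))
        sex = "female" if rng.random() < p.female_prob else "male"
        records.append(
            SubjectRecord(
                subject_id=f"S{i + 1:03d}",
                sex=sex,
                bmi=round(bmi, 2),
                melanin_index=round(mi, 2),
                mst_level=mst,
            )
        )
    return records


def generate_thermal_series(
    subject: SubjectRecord,
    roi: EllipseSpec,
    params: KineticsParams,
    seed: int,
    grid_shape: tuple[int, int] = THERMAL_SHAPE,
    true_transform: AffineTransform2D | None = None,
) -> tuple[list[ThermalFrame], GroundTruth]:
    """Generate the nine-frame thermal series for one subject.

    ``roi`` is the cup-imprint outer ellipse in thermal coordinates.  The
    pre-cupping frame is flat at ``baseline_temp``; each post frame adds
    the per-region exponential-relaxation delta (plus a per-subject
    offset drawn once per region), Gaussian-smoothed across region
    boundaries, plus i.i.d. pixel noise.
    """
    rows, cols = grid_shape
    concentric = derive_concentric(roi)
    a = concentric.peri_outer.semi_axes[0]
    cx, cy = roi.center
    if cx - a < -0.5 or cy - a < -0.5 or cx + a > cols - 0.5 or cy + a > rows - 0.5:
        raise InvalidArgumentError("ROI (including its 1.25x envelope) must lie inside the frame")
    masks = rasterize_masks(concentric, grid_shape)
    rng = np.random.default_rng(seed)
    offsets = {name: float(rng.normal(0.0, k.subject_sd)) for name, k in params.regions.items()}

    frames: list[ThermalFrame] = []
    true_deltas: dict[str, dict[str, float]] = {name: {"pre": 0.0} for name in REGION_NAMES}
    for tp in TIMEPOINTS:
        if tp == "pre":
            field_map = np.zeros(grid_shape)
        else:
            minute = float(tp[1:])
            field_map = np.zeros(grid_shape)
            for name, mask in masks:
                d = float(params.regions[name].delta(minute)) + offsets[name]
                field_map[mask] = d
                true_deltas[name][tp] = d
            if params.smoothing_scale > 0:
                field_map = gaussian_filter(field_map, sigma=params.smoothing_scale)
        noise = rng.normal(0.0, params.noise_sd, grid_shape) if params.noise_sd > 0 else 0.0
        frames.append(
            ThermalFrame(params.baseline_temp + field_map + noise, tp, subject.subject_id)
        )
    truth = GroundTruth(
        true_transform=true_transform or AffineTransform2D.identity(),
        true_outer_ellipse=roi,
        true_region_deltas=true_deltas,
        true_erythema_deltas={},
    )
    return frames, truth


def generate_erythema_series(
    subject: SubjectRecord,
    params: ErythemaGroupParams,
    seed: int,
) -> dict[str, float]:
    """Nine colorimeter readings: baseline plus eight post-cupping values.

    Post-minus-baseline deltas are Normal(mean_delta[t], sd_delta[t]) for
    the subject's MST group; with all SDs zero the emitted deltas equal
    the group mean vector exactly.
    """
    group = subject.mst_group
    if group not in params.mean_delta:
        raise ConfigurationError(f"no erythema parameters configured for group {group!r}")
    rng = np.random.default_rng(seed)
    baseline = float(rng.normal(params.baseline_mean, params.baseline_sd))
    series = {"pre": baseline}
    for i, tp in enumerate(POST_TIMEPOINTS):
        delta = float(rng.normal(params.mean_delta[group][i], params.sd_delta[group][i]))
        series[tp] = baseline + delta
    return series


def generate_fiducials(
    true_transform: AffineTransform2D,
    corner_points,
    jitter_sd: float = 0.0,
    seed: int = 0,
    labels: tuple[str, ...] | None = None,
) -> FiducialSet:
    """Project card corners through the true transform, with optional jitter.

    The optical-side points are the given corners; the thermal-side
    points are their images under ``true_transform`` plus isotropic
    Gaussian jitter of ``jitter_sd`` pixels.
    """
    corners = np.asarray(corner_points, dtype=float).reshape(-1, 2)
    if jitter_sd < 0:
        raise InvalidArgumentError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    thermal = true_transform(corners)
    if jitter_sd > 0:
        thermal = thermal + rng.normal(0.0, jitter_sd, thermal.shape)
    if labels is None:
        labels = tuple(f"corner_{i}" for i in range(len(corners)))
    return FiducialSet(labels, corners, thermal)


# Card corners (optical coordinates) used by the study-dataset generator.
CARD_CORNERS = np.array([[60.0, 50.0], [200.0, 50.0], [200.0, 140.0], [60.0, 140.0]])


def _render_optical(
    shape: tuple[int, int],
    melanin_index: float,
    card_corners: np.ndarray,
    imprint: EllipseSpec,
) -> np.ndarray:
    """Flat skin-tone patch with a white ID card and the cup-imprint ring.

    Decorative for the analysis (erythema comes from the colorimeter);
    sufficient for registration bookkeeping and visual checks only.
    """
    rows, cols = shape
    # darker skin (higher melanin index) -> darker patch
    shade = np.clip(210.0 - 1.4 * melanin_index, 40.0, 220.0)
    img = np.empty((rows, cols, 3), dtype=np.uint8)
    img[..., 0] = np.uint8(shade)
    img[..., 1] = np.uint8(shade * 0.72)
    img[..., 2] = np.uint8(shade * 0.55)
    x0, y0 = card_corners.min(axis=0).astype(int)
    x1, y1 = card_corners.max(axis=0).astype(int)
    img[max(y0, 0):y1 + 1, max(x0, 0):x1 + 1] = 245
    yy, xx = np.mgrid[0:rows, 0:cols]
    p = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float) - np.asarray(imprint.center)
    m = imprint.quadratic_form()
    q = (m[0, 0] * p[:, 0] ** 2 + 2 * m[0, 1] * p[:, 0] * p[:, 1] + m[1, 1] * p[:, 1] ** 2).reshape(rows, cols)
    ring = (q > 0.9) & (q < 1.1)
    img[ring] = np.array([180, 60, 60], dtype=np.uint8)
    return img


@dataclass
class SubjectData:
    """Everything generated for one subject."""

    record: SubjectRecord
    frames: list[ThermalFrame]
    optical: dict[str, np.ndarray]
    erythema: dict[str, float]
    fiducials: FiducialSet
    roi_optical: EllipseSpec
    ground_truth: GroundTruth


@dataclass
class StudyDataset:
    """A full synthetic study: cohort plus per-subject data."""

    subjects: list[SubjectData]
    #: subject_id -> reason, for subjects skipped while reading from disk
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def cohort(self) -> list[SubjectRecord]:
        return [s.record for s in self.subjects]


def _random_true_transform(rng: np.random.Generator) -> AffineTransform2D:
    """Plausible optical->thermal map: ~0.5x scale, small rotation/shear."""
    s = rng.uniform(0.45, 0.55)
    theta = rng.uniform(-0.1, 0.1)
    shear = rng.uniform(-0.02, 0.02)
    c, sn = np.cos(theta), np.sin(theta)
    a = s * np.array([[c, -sn], [sn, c]]) @ np.array([[1.0, shear], [0.0, 1.0]])
    opt_center = np.array([OPTICAL_SHAPE[1] / 2, OPTICAL_SHAPE[0] / 2])
    th_center = np.array([THERMAL_SHAPE[1] / 2, THERMAL_SHAPE[0] / 2])
    t = th_center - a @ opt_center + rng.uniform(-5, 5, 2)
    return AffineTransform2D(a, t, "optical->thermal")


def generate_subject(
    record: SubjectRecord,
    kinetics: KineticsParams,
    erythema_params: ErythemaGroupParams,
    seed: int,
    fiducial_jitter_sd: float = 0.0,
    grid_shape: tuple[int, int] = THERMAL_SHAPE,
    render_optical: bool = True,
) -> SubjectData:
    """Generate one subject's complete session (frames, fiducials, erythema)."""
    ss = np.random.SeedSequence(seed)
    s_geom, s_thermal, s_ery, s_fid = (int(c.generate_state(1, dtype='uint64')[0] >> 33) for c in ss.spawn(4))
    rng = np.random.default_rng(s_geom)
    transform = _random_true_transform(rng)
    rows, cols = grid_shape
    center = (
        cols / 2 + rng.uniform(-cols / 64, cols / 64),
        rows / 2 + rng.uniform(-rows / 48, rows / 48),
    )
    # imprint spans ~half the frame width; scales with the grid so the
    # 1.25x envelope always fits
    axes = (
        0.25 * cols * rng.uniform(0.95, 1.05),
        (64.0 / 240.0) * rows * rng.uniform(0.95, 1.05),
    )
    roi_thermal = EllipseSpec(center, axes, rng.uniform(0, np.pi))
    frames, truth = generate_thermal_series(
        record, roi_thermal, kinetics, s_thermal, grid_shape, true_transform=transform
    )
    erythema = generate_erythema_series(record, erythema_params, s_ery)
    truth = replace(
        truth,
        true_erythema_deltas={tp: erythema[tp] - erythema["pre"] for tp in POST_TIMEPOINTS},
    )
    fiducials = generate_fiducials(transform, CARD_CORNERS, fiducial_jitter_sd, s_fid)
    roi_optical = map_ellipse(transform.invert(), roi_thermal)
    optical = {}
    if render_optical:
        img = _render_optical(OPTICAL_SHAPE, record.melanin_index, CARD_CORNERS, roi_optical)
        optical = {tp: img for tp in TIMEPOINTS}
    return SubjectData(record, frames, optical, erythema, fiducials, roi_optical, truth)


def generate_study(
    n_darker: int = 30,
    n_lighter: int = 5,
    seed: int = 0,
    kinetics: KineticsParams | None = None,
    erythema_params: ErythemaGroupParams | None = None,
    cohort_params: CohortParams | None = None,
    fiducial_jitter_sd: float = 0.0,
    grid_shape: tuple[int, int] = THERMAL_SHAPE,
    render_optical: bool = True,
) -> StudyDataset:
    """Generate a complete study dataset in memory (default: 30 + 5 subjects)."""
    kinetics = kinetics or KineticsParams()
    erythema_params = erythema_params or ErythemaGroupParams()
    ss = np.random.SeedSequence(seed)
    cohort_seed = int(ss.generate_state(1, dtype='uint64')[0] >> 33)
    cohort = generate_cohort(n_darker, n_lighter, cohort_seed, cohort_params)
    subject_seeds = [int(c.generate_state(1, dtype='uint64')[0] >> 33) for c in ss.spawn(len(cohort))]
    subjects = [
        generate_subject(
            rec, kinetics, erythema_params, s,
            fiducial_jitter_sd=fiducial_jitter_sd,
            grid_shape=grid_shape,
            render_optical=render_optical,
        )
        for rec, s in zip(cohort, subject_seeds)
    ]
    return StudyDataset(subjects)


# ---------------------------------------------------------------------------
# On-disk layout
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_dataset(dataset: StudyDataset, out_dir) -> dict:
    """Write a study dataset to disk and return a checksummed manifest.

    Layout::

        cohort.csv
        ground_truth.json
        manifest.json
        subjects/<id>/thermal_<tp>.csv   # rectangular matrix of °C
        subjects/<id>/optical_<tp>.png   # 8-bit RGB
        subjects/<id>/fiducials.json
        subjects/<id>/erythema.csv
        subjects/<id>/roi.json           # outer ellipse, optical coords

    Timepoint labels are ``pre`` and ``m0``..``m7``; all coordinates are
    0-based x=column / y=row pixel centers.
    """
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []

    cohort_path = out / "cohort.csv"
    with open(cohort_path, "w", newline="", encoding="utf-8") as fh:
        fields = list(dataset.cohort[0].to_dict()) if dataset.subjects else [
            "subject_id", "sex", "bmi", "bmi_category", "melanin_index",
            "eumelanin_category", "mst_level", "mst_group",
        ]
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for rec in dataset.cohort:
            writer.writerow(rec.to_dict())
    paths.append(cohort_path)

    truth = {s.record.subject_id: s.ground_truth.to_dict() for s in dataset.subjects}
    truth_path = out / "ground_truth.json"
    truth_path.write_text(json.dumps(truth, indent=1))
    paths.append(truth_path)

    for s in dataset.subjects:
        sdir = out / "subjects" / s.record.subject_id
        sdir.mkdir(parents=True, exist_ok=True)
        for frame in s.frames:
            p = sdir / f"thermal_{frame.timepoint}.csv"
            np.savetxt(p, frame.temperatures, fmt="%.4f", delimiter=",")
            paths.append(p)
        for tp, img in s.optical.items():
            p = sdir / f"optical_{tp}.png"
            Image.fromarray(img, mode="RGB").save(p)
            paths.append(p)
        p = sdir / "fiducials.json"
        s.fiducials.save(p)
        paths.append(p)
        p = sdir / "roi.json"
        p.write_text(json.dumps(s.roi_optical.to_dict("optical"), indent=1))
        paths.append(p)
        p = sdir / "erythema.csv"
        with open(p, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["timepoint", "value"])
            for tp in TIMEPOINTS:
                writer.writerow([tp, f"{s.erythema[tp]:.6f}"])
        paths.append(p)

    manifest = {
        "n_subjects": len(dataset.subjects),
        "files": {str(p.relative_to(out)): _sha256(p) for p in paths},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _load_thermal_csv(path: Path, timepoint: str, subject_id: str) -> ThermalFrame:
    try:
        grid = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError as exc:
        raise DatasetError(f"cannot parse thermal matrix {path}: {exc}") from exc
    return ThermalFrame(grid, timepoint, subject_id)


def _read_subject(sdir: Path, rec: SubjectRecord, truths: dict, load_optical: bool) -> SubjectData:
    from PIL import Image

    frames = []
    for tp in TIMEPOINTS:
        p = sdir / f"thermal_{tp}.csv"
        if not p.exists():
            raise DatasetError(f"missing thermal frame: {p}")
        frames.append(_load_thermal_csv(p, tp, rec.subject_id))
    p = sdir / "erythema.csv"
    if not p.exists():
        raise DatasetError(f"missing erythema file: {p}")
    erythema = {}
    with open(p, newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            try:
                erythema[row["timepoint"]] = float(row["value"])
            except (KeyError, ValueError, TypeError) as exc:
                raise DatasetError(f"cannot parse {p} line {i + 2}: {exc}") from exc
    p = sdir / "fiducials.json"
    if not p.exists():
        raise DatasetError(f"missing fiducials file: {p}")
    try:
        fiducials = FiducialSet.load(p)
    except (KeyError, ValueError) as exc:
        raise DatasetError(f"cannot parse {p}: {exc}") from exc
    p = sdir / "roi.json"
    if not p.exists():
        raise DatasetError(f"missing ROI file: {p}")
    try:
        roi_optical = EllipseSpec.from_dict(json.loads(p.read_text()))
    except (KeyError, ValueError) as exc:
        raise DatasetError(f"cannot parse {p}: {exc}") from exc
    optical = {}
    if load_optical:
        for tp in TIMEPOINTS:
            op = sdir / f"optical_{tp}.png"
            if op.exists():
                optical[tp] = np.asarray(Image.open(op).convert("RGB"))
    truth = truths.get(rec.subject_id)
    gt = GroundTruth.from_dict(truth) if truth else GroundTruth(
        AffineTransform2D.identity(), roi_optical, {}, {}
    )
    return SubjectData(rec, frames, optical, erythema, fiducials, roi_optical, gt)


def read_dataset(path, load_optical: bool = False, skip_bad: bool = False) -> StudyDataset:
    """Read a dataset written by :func:`write_dataset` back into memory.

    ``ground_truth.json`` is optional (a real, non-synthetic dataset in
    the same layout would lack it).  A malformed or incomplete subject
    directory raises :class:`~thermacup.errors.DatasetError` naming the
    file; with ``skip_bad=True`` the subject is skipped instead and the
    reason recorded in ``StudyDataset.failures``, so one corrupted
    subject never aborts a cohort read.
    """
    root = Path(path)
    cohort_path = root / "cohort.csv"
    if not cohort_path.exists():
        raise DatasetError(f"missing cohort file: {cohort_path}")
    with open(cohort_path, newline="", encoding="utf-8") as fh:
        try:
            cohort = [SubjectRecord.from_dict(row) for row in csv.DictReader(fh)]
        except (KeyError, ValueError) as exc:
            raise DatasetError(f"cannot parse {cohort_path}: {exc}") from exc

    truth_path = root / "ground_truth.json"
    truths = json.loads(truth_path.read_text()) if truth_path.exists() else {}

    subjects = []
    failures: dict[str, str] = {}
    for rec in cohort:
        sdir = root / "subjects" / rec.subject_id
        try:
            subjects.append(_read_subject(sdir, rec, truths, load_optical))
        except DatasetError as exc:
            if not skip_bad:
                raise
            failures[rec.subject_id] = str(exc)
    if not subjects:
        raise DatasetError(f"no readable subjects in {root}: {failures or 'empty cohort'}")
    return StudyDataset(subjects, failures)
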