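"""Per-subject reduction: region summaries and baseline-differenced series.

Each subject contributes nine thermal frames (one pre-cupping baseline,
then minutes 0–7 post-cupping) and nine point erythema readings taken
at the ROI center with a colorimeter.  Frames are reduced to per-region
median temperature (with IQR), and both modalities are converted to
deltas by subtracting the pre-cupping value.  Quartiles use linear
interpolation between order statistics (the "type 7" rule), the default
of both numpy and R, fixed here because IQRs are compared across
implementations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyRegionError, InvalidArgumentError
from .roi import REGION_NAMES, RegionMasks

TIMEPOINTS = ("pre", "m0", "m1", "m2", "m3", "m4", "m5", "m6", "m7")
POST_TIMEPOINTS = TIMEPOINTS[1:]

#: Plausibility window for skin temperature (°C); values outside warn.
PLAUSIBLE_TEMP_RANGE = (10.0, 45.0)


@dataclass(frozen=True)
class ThermalFrame:
    """One gridded skin-temperature snapshot (°C) at a labeled timepoint."""

    temperatures: np.ndarray
    timepoint: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        if t.ndim != 2:
            raise InvalidArgumentError("temperatures must be a 2-D grid")
        if self.timepoint not in TIMEPOINTS:
            raise InvalidArgumentError(
                f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}"
            )
        if not np.all(np.isfinite(t)):
            raise InvalidArgumentError("temperature grid contains non-finite values")
        lo, hi = PLAUSIBLE_TEMP_RANGE
        if t.min() < lo or t.max() > hi:
            warnings.warn(
                f"frame {self.subject_id}/{self.timepoint}: temperatures outside "
                f"plausibility window {PLAUSIBLE_TEMP_RANGE} °C",
                stacklevel=2,
            )
        object.__setattr__(self, "temperatures", t)

    @property
    def shape(self) -> tuple[int, int]:
        return self.temperatures.shape


@dataclass(frozen=True)
class SubjectSeries:
    """Per-subject medians, IQRs and baseline deltas across all timepoints.

    ``medians[region][tp]`` / ``iqrs[region][tp]`` hold the raw per-region
    summaries; ``delta_t[region][tp] = median[tp] - median["pre"]`` and
    ``delta_e[tp] = E[tp] - E["pre"]`` for the post timepoints.
    """

    subject_id: str
    medians: dict[str, dict[str, float]]
    iqrs: dict[str, dict[str, tuple[float, float]]]
    means: dict[str, dict[str, float]]
    erythema: dict[str, float]

    @property
    def delta_t(self) -> dict[str, dict[str, float]]:
        return {
            region: {tp: self.medians[region][tp] - self.medians[region]["pre"] for tp in POST_TIMEPOINTS}
            for region in REGION_NAMES
        }

    @property
    def delta_e(self) -> dict[str, float]:
        return {tp: self.erythema[tp] - self.erythema["pre"] for tp in POST_TIMEPOINTS}


def summarize_region(frame: ThermalFrame, mask: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Median and (Q1, Q3) of the masked pixels of one frame."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != frame.shape:
        raise InvalidArgumentError(
            f"mask shape {mask.shape} does not match frame shape {frame.shape}"
        )
    values = frame.temperatures[mask]
    if values.size == 0:
        raise EmptyRegionError("mask selects no pixels")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])  # type 7 / linear
    return float(med), (float(q1), float(q3))


def build_subject_series(
    frames: list[ThermalFrame],
    masks: RegionMasks,
    erythema: dict[str, float] | list[float],
) -> SubjectSeries:
    """Reduce one subject's frames and erythema readings to a SubjectSeries.

    All nine timepoints must be present exactly once in both modalities.
    """
    by_tp: dict[str, ThermalFrame] = {}
    for f in frames:
        if f.timepoint in by_tp:
            raise InvalidArgumentError(f"duplicated timepoint {f.timepoint!r}")
        by_tp[f.timepoint] = f
    missing = [tp for tp in TIMEPOINTS if tp not in by_tp]
    if missing:
        raise InvalidArgumentError(f"missing thermal timepoints: {missing}")
    extra = set(by_tp) - set(TIMEPOINTS)
    if extra:
        raise InvalidArgumentError(f"unknown timepoints: {sorted(extra)}")

    if not isinstance(erythema, dict):
        values = list(erythema)
        if len(values) != len(TIMEPOINTS):
            raise InvalidArgumentError(
                f"erythema series must have {len(TIMEPOINTS)} values, got {len(values)}"
            )
        erythema = dict(zip(TIMEPOINTS, values))
    missing_e = [tp for tp in TIMEPOINTS if tp not in erythema]
    if missing_e:
        raise InvalidArgumentError(f"missing erythema timepoints: {missing_e}")

    subject_id = next(iter(by_tp.values())).subject_id
    region_masks = dict(masks)
    medians: dict[str, dict[str, float]] = {r: {} for r in REGION_NAMES}
    iqrs: dict[str, dict[str, tuple[float, float]]] = {r: {} for r in REGION_NAMES}
    means: dict[str, dict[str, float]] = {r: {} for r in REGION_NAMES}
    for tp in TIMEPOINTS:
        frame = by_tp[tp]
        for region in REGION_NAMES:
            med, iqr = summarize_region(frame, region_masks[region])
            medians[region][tp] = med
            iqrs[region][tp] = iqr
            means[region][tp] = float(frame.temperatures[region_masks[region]].mean())
    return SubjectSeries(
        subject_id=subject_id,
        medians=medians,
        iqrs=iqrs,
        means=means,
        erythema={tp: float(erythema[tp]) for tp in TIMEPOINTS},
    )


COHORT_COLUMNS = [
    "subject_id", "modality", "region", "timepoint", "minute", "delta",
    "median", "q1", "q3", "mean",
    "sex", "bmi", "bmi_category", "melanin_index", "eumelanin_category",
    "mst_level", "mst_group",
]


def assemble_cohort(series: list[SubjectSeries], cohort: list) -> pd.DataFrame:
    """Join subject series to covariates as one tidy long table.

    One row per (subject, region, post timepoint) for temperature and one
    per (subject, post timepoint) for erythema: 3*8 + 8 = 32 rows per
    subject.  ``cohort`` is a list of subject records (see
    :class:`thermacup.synth.SubjectRecord`) or of dicts with the same
    fields; every series must match exactly one record by ``subject_id``.
    """
    records = {}
    for rec in cohort:
        d = rec if isinstance(rec, dict) else rec.to_dict()
        records[d["subject_id"]] = d
    rows = []
    for s in series:
        if s.subject_id not in records:
            raise InvalidArgumentError(f"no cohort record for subject {s.subject_id!r}")
        cov = records[s.subject_id]
        base = {k: cov.get(k) for k in (
            "sex", "bmi", "bmi_category", "melanin_index",
            "eumelanin_category", "mst_level", "mst_group",
        )}
        dt = s.delta_t
        for region in REGION_NAMES:
            for i, tp in enumerate(POST_TIMEPOINTS):
                rows.append({
                    "subject_id": s.subject_id, "modality": "temperature",
                    "region": region, "timepoint": tp, "minute": i,
                    "delta": dt[region][tp],
                    "median": s.medians[region][tp],
                    "q1": s.iqrs[region][tp][0], "q3": s.iqrs[region][tp][1],
                    "mean": s.means[region][tp],
                    **base,
                })
        de = s.delta_e
        for i, tp in enumerate(POST_TIMEPOINTS):
            rows.append({
                "subject_id": s.subject_id, "modality": "erythema",
                "region": None, "timepoint": tp, "minute": i,
                "delta": de[tp],
                "median": None, "q1": None, "q3": None, "mean": None,
                **base,
            })
    table = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    return table
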