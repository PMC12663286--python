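"""Study-level analysis model and results.

:class:`CuppingStudy` is the modelling entry point, in the spirit of a
statsmodels model: it is built from data (an in-memory
:class:`~thermacup.synth.StudyDataset`, an on-disk dataset directory,
or a pre-assembled tidy cohort table), and :meth:`CuppingStudy.fit`
runs the full analysis — per-subject fiducial registration, mapping of
the annotated outer ellipse into thermal coordinates, concentric-ROI
rasterization, baseline-differenced series extraction — and returns a
:class:`CuppingStudyResults` carrying the cohort table, every
statistical test with its provenance, and a ``summary()`` report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats
from .errors import ThermacupError
from .metrics import POST_TIMEPOINTS, SubjectSeries, assemble_cohort, build_subject_series
from .register import DEFAULT_RESIDUAL_WARN_PX, estimate_affine, map_ellipse
from .roi import REGION_NAMES, derive_concentric, rasterize_masks

logger = logging.getLogger(__name__)


@dataclass
class SubjectAnalysis:
    """Per-subject intermediate results from the processing stage."""

    subject_id: str
    series: SubjectSeries
    rms_residual: float
    warnings: list[str] = field(default_factory=list)


class CuppingStudy:
    """Analysis model for one cupping study (cohort of subjects).

    Parameters
    ----------
    dataset
        A :class:`~thermacup.synth.StudyDataset` (in memory).  Use
        :meth:`from_dataset` for an on-disk directory or
        :meth:`from_cohort_table` when the per-subject reduction has
        already been done.
    region, minutes
        Region and minute window for the temperature/erythema
        correlation (defaults: ROI Center, minutes 1–7).
    anova_minutes
        Minutes at which group differences are tested (default 0 and 7).
    anova_factors
        Subject characteristics entering the ANOVA.
    residual_warn_px
        Registration RMS residual above which a warning is recorded.
    """

    def __init__(
        self,
        dataset=None,
        cohort_table: pd.DataFrame | None = None,
        region: str = "ROI Center",
        minutes: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7),
        anova_minutes: tuple[int, ...] = (0, 7),
        anova_factors: tuple[str, ...] = ("sex", "bmi_category", "eumelanin_category"),
        residual_warn_px: float = DEFAULT_RESIDUAL_WARN_PX,
    ) -> None:
        if (dataset is None) == (cohort_table is None):
            raise ValueError("provide exactly one of dataset or cohort_table")
        self.dataset = dataset
        self._cohort_table = cohort_table
        self.region = region
        self.minutes = tuple(minutes)
        self.anova_minutes = tuple(anova_minutes)
        self.anova_factors = tuple(anova_factors)
        self.residual_warn_px = residual_warn_px

    @classmethod
    def from_dataset(cls, path, skip_bad: bool = True, **kwargs) -> "CuppingStudy":
        """Build the model from a dataset directory on disk.

        By default a corrupted subject directory is skipped (recorded in
        the fitted results) rather than aborting the cohort.
        """
        from .synth import read_dataset

        return cls(dataset=read_dataset(path, skip_bad=skip_bad), **kwargs)

    @classmethod
    def from_cohort_table(cls, table: pd.DataFrame, **kwargs) -> "CuppingStudy":
        """Build the model from a pre-assembled tidy cohort table."""
        return cls(cohort_table=table, **kwargs)

    # -- processing stage ------------------------------------------------
    def _process_subject(self, subject) -> SubjectAnalysis:
        """Registration -> ellipse mapping -> masks -> series for one subject."""
        transform, rms = estimate_affine(subject.fiducials)
        warns = []
        if rms > self.residual_warn_px:
            warns.append(f"registration residual {rms:.2f} px exceeds {self.residual_warn_px} px")
        roi_thermal = map_ellipse(transform, subject.roi_optical)
        concentric = derive_concentric(roi_thermal)
        grid_shape = subject.frames[0].shape
        masks = rasterize_masks(concentric, grid_shape)
        series = build_subject_series(subject.frames, masks, subject.erythema)
        return SubjectAnalysis(subject.record.subject_id, series, rms, warns)

    def fit(self) -> "CuppingStudyResults":
        """Run the full pipeline and the cohort statistics."""
        failures: dict[str, str] = dict(getattr(self.dataset, "failures", None) or {})
        analyses: list[SubjectAnalysis] = []
        if self._cohort_table is not None:
            table = self._cohort_table
        else:
            for subject in self.dataset.subjects:
                sid = subject.record.subject_id
                try:
                    analyses.append(self._process_subject(subject))
                except ThermacupError as exc:
                    logger.warning("subject %s skipped: %s", sid, exc)
                    failures[sid] = str(exc)
            if not analyses:
                raise ThermacupError("every subject failed processing")
            table = assemble_cohort([a.series for a in analyses], self.dataset.cohort)
        return CuppingStudyResults(self, table, analyses, failures)


class CuppingStudyResults:
    """Fitted results: cohort table, tests, summaries and serialization."""

    def __init__(
        self,
        model: CuppingStudy,
        cohort_table: pd.DataFrame,
        subject_analyses: list[SubjectAnalysis],
        failures: dict[str, str],
    ) -> None:
        self.model = model
        self.cohort_table = cohort_table
        self.subject_analyses = subject_analyses
        self.failures = failures
        self._run_statistics()

    # -- statistics stage ------------------------------------------------
    def _run_statistics(self) -> None:
        table = self.cohort_table
        self.t_tests: list[stats.TestResult] = []
        for region in REGION_NAMES:
            for minute in range(8):
                sel = table[
                    (table["modality"] == "temperature")
                    & (table["region"] == region)
                    & (table["minute"] == minute)
                ]["delta"]
                if len(sel) >= 2 and sel.std(ddof=1) > 0:
                    self.t_tests.append(
                        stats.one_sample_t(sel, modality="temperature", region=region, minute=minute)
                    )
        for minute in range(8):
            sel = table[(table["modality"] == "erythema") & (table["minute"] == minute)]["delta"]
            if len(sel) >= 2 and sel.std(ddof=1) > 0:
                self.t_tests.append(
                    stats.one_sample_t(sel, modality="erythema", region=None, minute=minute)
                )

        self.correlations = stats.correlation_analysis(
            table, region=self.model.region, minutes=self.model.minutes,
            stratify_by="eumelanin_category",
        )

        self.anovas: list[stats.TestResult] = []
        for factor in self.model.anova_factors:
            for modality in ("temperature", "erythema"):
                try:
                    self.anovas.extend(
                        stats.anova_analysis(
                            table, by=factor, region=self.model.region,
                            minutes=self.model.anova_minutes, modality=modality,
                        )
                    )
                except ThermacupError as exc:
                    logger.warning("ANOVA by %s (%s) skipped: %s", factor, modality, exc)

        ery0 = table[(table["modality"] == "erythema") & (table["minute"] == 0)]
        self.erythema_group_summary = (
            stats.group_summary(ery0, "delta", "mst_group") if not ery0.empty else pd.DataFrame()
        )

    # -- accessors -------------------------------------------------------
    def region_delta(self, region: str, minute: int, statistic: str = "median") -> float:
        """Cohort aggregate of per-subject temperature deltas for one region/minute."""
        sel = self.cohort_table[
            (self.cohort_table["modality"] == "temperature")
            & (self.cohort_table["region"] == region)
            & (self.cohort_table["minute"] == minute)
        ]["delta"]
        return float(getattr(sel, statistic)())

    def erythema_delta(self, minute: int, statistic: str = "mean") -> float:
        sel = self.cohort_table[
            (self.cohort_table["modality"] == "erythema")
            & (self.cohort_table["minute"] == minute)
        ]["delta"]
        return float(getattr(sel, statistic)())

    @property
    def n_subjects(self) -> int:
        return int(self.cohort_table["subject_id"].nunique())

    # -- reporting -------------------------------------------------------
    def to_report(self) -> dict:
        """All results as one JSON-serializable structure."""
        return {
            "n_subjects": self.n_subjects,
            "failed_subjects": self.failures,
            "registration": [
                {"subject_id": a.subject_id, "rms_residual_px": a.rms_residual, "warnings": a.warnings}
                for a in self.subject_analyses
            ],
            "t_tests": [t.to_dict() for t in self.t_tests],
            "correlations": [c.to_dict() for c in self.correlations],
            "anova": [a.to_dict() for a in self.anovas],
            "erythema_group_summary_m0": (
                self.erythema_group_summary.reset_index().to_dict(orient="records")
                if not self.erythema_group_summary.empty else []
            ),
            "notes": [
                "p-values are raw (no multiple-testing correction, matching the analysis plan)",
                "correlation CIs treat pooled subject-minute pairs as independent",
            ],
        }

    def save_report(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_report(), fh, indent=1, default=_json_default)

    def summary(self) -> str:
        """Human-readable summary of the main findings."""
        lines = []
        w = 72
        lines.append("=" * w)
        lines.append("Post-cupping skin response — cohort analysis".center(w))
        lines.append("=" * w)
        lines.append(f"Subjects analyzed: {self.n_subjects}"
                     + (f"  (skipped: {len(self.failures)})" if self.failures else ""))
        lines.append("")
        lines.append("Temperature delta vs baseline (cohort median, °C)")
        lines.append(f"{'region':<12}" + "".join(f"  m{m}" .rjust(7) for m in range(8)))
        for region in REGION_NAMES:
            vals = [self.region_delta(region, m) for m in range(8)]
            lines.append(f"{region:<12}" + "".join(f"{v:7.2f}" for v in vals))
        lines.append("")
        lines.append("Erythema delta vs baseline (cohort mean, c.u.)")
        vals = [self.erythema_delta(m) for m in range(8)]
        lines.append(f"{'all':<12}" + "".join(f"{v:7.2f}" for v in vals))
        lines.append("")
        lines.append("One-sample t-tests against zero (selected)")
        for t in self.t_tests:
            if t.context.get("minute") in (0, 7):
                where = t.context.get("region") or t.context["modality"]
                star = "*" if t.p_value < t.alpha else " "
                lines.append(
                    f"  {where:<12} m{t.context['minute']}: mean={t.estimate:+.3f} "
                    f"t={t.statistic:+.2f} p={t.p_value:.4g}{star}"
                )
        lines.append("")
        lines.append("Temperature/erythema correlation (minutes "
                     f"{min(self.model.minutes)}–{max(self.model.minutes)}, {self.model.region})")
        for c in self.correlations:
            if c.insufficient:
                lines.append(f"  {c.stratum:<18} n={c.n:<4} insufficient data")
            else:
                lines.append(
                    f"  {c.stratum:<18} n={c.n:<4} r={c.r:+.3f} "
                    f"95% CI [{c.ci_low:+.3f}, {c.ci_high:+.3f}] p={c.p_value:.4g}"
                )
        lines.append("")
        lines.append("One-way ANOVA of deltas across subject characteristics")
        for a in self.anovas:
            df1, df2 = a.df
            lines.append(
                f"  {a.context['modality']:<11} by {a.context['by']:<20} m{a.context['minute']}: "
                f"F({df1:.0f},{df2:.0f})={a.statistic:.2f} p={a.p_value:.4g}"
            )
        lines.append("=" * w)
        return "\n".join(lines)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
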