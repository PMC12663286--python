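"""Cohort statistics: one-sample t-tests, Pearson/Fisher-z correlation,
one-way ANOVA, group summaries, and subject classification helpers.

All tests mirror the study's analysis plan: baseline-differenced values
are tested against zero with one-sample t-tests; the erythema/temperature
relationship is assessed with Pearson correlation over pooled
(subject x minute) observations from minutes 1–7, with a Fisher-z
confidence interval; differences across participant characteristics use
one-way ANOVA at minutes 0 and 7.  No multiple-testing correction is
applied (none was in the study design); raw p-values are reported.

A caveat recorded with every correlation result: the confidence interval
treats pooled subject-minute pairs as independent, ignoring the
within-subject dependence of repeated measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, DegenerateSampleError, InvalidArgumentError
from .roi import REGION_NAMES

EUMELANIN_CATEGORIES = (
    "EumelaninLow",
    "IntermediateLow",
    "Intermediate",
    "IntermediateMid",
    "IntermediateHigh",
    "EumelaninHigh",
)

#: Melanin-index bin edges for the six-category eumelanin scale.  The
#: endpoints 25 (below -> EumelaninLow) and 100 (at or above ->
#: EumelaninHigh) are fixed by the scale definition; the three interior
#: cut points are NOT published with the scale's endpoints and are
#: package defaults — override them via the ``thresholds`` argument of
#: :func:`classify_eumelanin` if your instrument's mapping differs.
DEFAULT_EUMELANIN_THRESHOLDS = (25.0, 40.0, 50.0, 70.0, 100.0)

DEFAULT_BMI_CUTS = (25.0, 30.0)


@dataclass(frozen=True)
class TestResult:
    """Outcome of a t-test or ANOVA with its provenance."""

    statistic: float
    df: float | tuple[float, float]
    p_value: float
    estimate: float
    ci_low: float
    ci_high: float
    n: int
    alpha: float = 0.05
    test: str = ""
    context: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "test": self.test,
            "statistic": self.statistic,
            "df": list(self.df) if isinstance(self.df, tuple) else self.df,
            "p_value": self.p_value,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n": self.n,
            "alpha": self.alpha,
        }
        d.update(self.context)
        return d


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with a Fisher-z confidence interval."""

    r: float
    n: int
    p_value: float
    ci_low: float
    ci_high: float
    stratum: str = "all"
    alpha: float = 0.05
    degenerate_ci: bool = False
    insufficient: bool = False
    context: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "test": "pearson",
            "r": self.r,
            "n": self.n,
            "p_value": self.p_value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "stratum": self.stratum,
            "alpha": self.alpha,
            "degenerate_ci": self.degenerate_ci,
            "insufficient": self.insufficient,
            "ci_caveat": "Fisher-z CI treats pooled subject-minute pairs as independent",
        }
        d.update(self.context)
        return d


def one_sample_t(values, mu: float = 0.0, alpha: float = 0.05, **context) -> TestResult:
    """Two-sided one-sample t-test of ``mean(values) == mu``.

    ``t = (mean - mu) / (sd / sqrt(n))`` with ``n - 1`` degrees of
    freedom; the CI is ``mean ± t_crit * sd / sqrt(n)``.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if len(x) < 2:
        raise InvalidArgumentError("one_sample_t requires n >= 2")
    if not np.all(np.isfinite(x)):
        raise InvalidArgumentError("values must be finite")
    if np.std(x, ddof=1) == 0:
        raise DegenerateSampleError("sample has zero variance")
    res = sps.ttest_1samp(x, popmean=mu)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    return TestResult(
        statistic=float(res.statistic),
        df=float(len(x) - 1),
        p_value=float(res.pvalue),
        estimate=float(x.mean()),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        n=len(x),
        alpha=alpha,
        test="one_sample_t",
        context=dict(context, mu=mu),
    )


def fisher_ci(r: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation.

    ``tanh(atanh(r) ± z_{1-alpha/2} / sqrt(n - 3))``; requires n >= 4
    and |r| < 1.
    """
    if n < 4:
        raise InvalidArgumentError("Fisher CI requires n >= 4")
    if abs(r) >= 1:
        raise DegenerateSampleError("|r| = 1 has no finite Fisher-z interval")
    z = np.arctanh(r)
    half = sps.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def pearson_p_value(r: float, n: int) -> float:
    """Two-sided p for a Pearson r via ``t = r sqrt(n-2) / sqrt(1-r^2)``."""
    if abs(r) >= 1:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    return float(2 * sps.t.sf(abs(t), df=n - 2))


def pearson_fisher(x, y, alpha: float = 0.05, stratum: str = "all", **context) -> CorrelationResult:
    """Pearson correlation with two-sided p and Fisher-z CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 4:
        raise InvalidArgumentError("pearson_fisher requires n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateSampleError("a variable has zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0 - 1e-15:
        r = float(np.sign(r))
        return CorrelationResult(
            r=r, n=n, p_value=0.0, ci_low=r, ci_high=r,
            stratum=stratum, alpha=alpha, degenerate_ci=True,
            context=dict(context),
        )
    lo, hi = fisher_ci(r, n, alpha)
    return CorrelationResult(
        r=r, n=n, p_value=pearson_p_value(r, n), ci_low=lo, ci_high=hi,
        stratum=stratum, alpha=alpha, context=dict(context),
    )


def correlation_analysis(
    table: pd.DataFrame,
    region: str = "ROI Center",
    minutes: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7),
    stratify_by: str | None = None,
    alpha: float = 0.05,
) -> list[CorrelationResult]:
    """Correlate temperature and erythema deltas pooled over subjects and minutes.

    Pairs ``(delta_T in region, delta_E)`` are formed per subject and
    included minute (default minutes 1–7, the study's correlation
    window).  Returns the overall result first, then one per stratum if
    ``stratify_by`` names a categorical column; a stratum with fewer
    than 4 pairs is reported with ``insufficient=True`` rather than
    dropped.
    """
    if region not in REGION_NAMES:
        raise InvalidArgumentError(f"unknown region {region!r}")
    temp = table[
        (table["modality"] == "temperature")
        & (table["region"] == region)
        & (table["minute"].isin(minutes))
    ][["subject_id", "minute", "delta"]].rename(columns={"delta": "delta_t"})
    ery_cols = ["subject_id", "minute", "delta"]
    if stratify_by is not None:
        ery_cols.append(stratify_by)
    ery = table[
        (table["modality"] == "erythema") & (table["minute"].isin(minutes))
    ][ery_cols].rename(columns={"delta": "delta_e"})
    pairs = temp.merge(ery, on=["subject_id", "minute"], how="inner")
    if pairs.empty:
        raise InvalidArgumentError("no paired temperature/erythema observations")

    def _one(df: pd.DataFrame, label: str) -> CorrelationResult:
        ctx = {"region": region, "minutes": list(minutes)}
        if len(df) < 4:
            return CorrelationResult(
                r=float("nan"), n=len(df), p_value=float("nan"),
                ci_low=float("nan"), ci_high=float("nan"),
                stratum=label, alpha=alpha, insufficient=True, context=ctx,
            )
        return pearson_fisher(
            df["delta_t"].to_numpy(), df["delta_e"].to_numpy(),
            alpha=alpha, stratum=label, **ctx,
        )

    results = [_one(pairs, "all")]
    if stratify_by is not None:
        for label, df in pairs.groupby(stratify_by, observed=True, sort=True):
            results.append(_one(df, str(label)))
    return results


def one_way_anova(values, groups, alpha: float = 0.05, **context) -> TestResult:
    """Classical one-way fixed-effects ANOVA F-test.

    ``F = MS_between / MS_within`` with ``(k - 1, N - k)`` degrees of
    freedom.  Requires at least two groups, each with at least two
    observations.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape or values.ndim != 1:
        raise InvalidArgumentError("values and groups must be 1-D of equal length")
    labels, inverse = np.unique(groups, return_inverse=True)
    samples = [values[inverse == i] for i in range(len(labels))]
    if len(samples) < 2:
        raise InvalidArgumentError("ANOVA requires at least 2 groups")
    if any(len(s) < 2 for s in samples):
        raise InvalidArgumentError("every group needs at least 2 observations")
    f, p = sps.f_oneway(*samples)
    k = len(samples)
    n = len(values)
    grand = float(values.mean())
    return TestResult(
        statistic=float(f),
        df=(float(k - 1), float(n - k)),
        p_value=float(p),
        estimate=grand,
        ci_low=float("nan"),
        ci_high=float("nan"),
        n=n,
        alpha=alpha,
        test="one_way_anova",
        context=dict(context, groups=[str(x) for x in labels]),
    )


def anova_analysis(
    table: pd.DataFrame,
    by: str,
    region: str = "ROI Center",
    minutes: tuple[int, ...] = (0, 7),
    modality: str = "temperature",
    alpha: float = 0.05,
) -> list[TestResult]:
    """One-way ANOVA of deltas across a subject characteristic, per minute.

    Default: temperature deltas in the ROI Center at minutes 0 and 7,
    matching the study's analysis plan; pass ``minutes=tuple(range(8))``
    for all timepoints.  Groups with fewer than 2 subjects are dropped
    from that minute's test (recorded in the result context).
    """
    out = []
    for minute in minutes:
        sel = table[(table["modality"] == modality) & (table["minute"] == minute)]
        if modality == "temperature":
            sel = sel[sel["region"] == region]
        counts = sel.groupby(by, observed=True)["delta"].count()
        keep = counts[counts >= 2].index
        dropped = sorted(str(x) for x in counts[counts < 2].index)
        sel = sel[sel[by].isin(keep)]
        res = one_way_anova(
            sel["delta"].to_numpy(), sel[by].to_numpy(), alpha=alpha,
            by=by, minute=minute, region=region if modality == "temperature" else None,
            modality=modality, dropped_groups=dropped,
        )
        out.append(res)
    return out


def group_summary(table: pd.DataFrame, value_column: str, by: str) -> pd.DataFrame:
    """Per-group and overall mean, sample sd (n-1) and n of one column.

    Returns a DataFrame indexed by group label with an ``__all__`` row
    for the pooled sample; a single observation yields sd = NA.
    """
    if table.empty:
        return pd.DataFrame(columns=["mean", "sd", "n"])
    g = table.groupby(by, observed=True)[value_column]
    out = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1), "n": g.count()})
    overall = table[value_column]
    out.loc["__all__"] = [overall.mean(), overall.std(ddof=1), overall.count()]
    out["n"] = out["n"].astype(int)
    return out


def pooled_weighted_mean(means, ns) -> float:
    """Sample-size-weighted mean of subgroup means: sum(m_i n_i) / sum(n_i)."""
    means = np.asarray(means, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if means.shape != ns.shape or means.ndim != 1 or len(means) < 1:
        raise InvalidArgumentError("means and ns must be 1-D of equal length >= 1")
    if np.any(ns <= 0):
        raise InvalidArgumentError("group sizes must be positive")
    return float(np.sum(means * ns) / np.sum(ns))


def classify_mst_group(mst_level: int) -> str:
    """Map a Monk Skin Tone level (1–10) to the study's two groups.

    Levels 6 and above form the darker group, 5 and below the lighter.
    """
    level = int(mst_level)
    if level != mst_level or not 1 <= level <= 10:
        raise InvalidArgumentError(f"MST level must be an integer in 1..10, got {mst_level!r}")
    return "darker" if level >= 6 else "lighter"


def classify_eumelanin(melanin_index: float, thresholds=DEFAULT_EUMELANIN_THRESHOLDS) -> str:
    """Bin a Melanin Index into the six-category modified eumelanin scale.

    Bins are left-closed: category ``i`` covers ``thresholds[i-1] <= MI
    < thresholds[i]``, with EumelaninLow below 25 and EumelaninHigh at
    or above 100.  See :data:`DEFAULT_EUMELANIN_THRESHOLDS` for the
    provenance of the interior cut points.
    """
    thresholds = tuple(float(t) for t in thresholds)
    if len(thresholds) != 5 or any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ConfigurationError("thresholds must be 5 strictly increasing values")
    if thresholds[0] != 25.0 or thresholds[-1] != 100.0:
        raise ConfigurationError("eumelanin scale endpoints are fixed at 25 and 100")
    mi = float(melanin_index)
    if not np.isfinite(mi) or mi < 0:
        raise InvalidArgumentError(f"melanin index must be >= 0, got {melanin_index!r}")
    idx = int(np.searchsorted(thresholds, mi, side="right"))
    return EUMELANIN_CATEGORIES[idx]


def classify_bmi(bmi: float, cuts=DEFAULT_BMI_CUTS) -> str:
    """WHO-style BMI categories; left-closed bins (25.0 -> overweight)."""
    b = float(bmi)
    if not np.isfinite(b) or b <= 0:
        raise InvalidArgumentError(f"BMI must be positive, got {bmi!r}")
    lo, hi = cuts
    if not lo < hi:
        raise ConfigurationError("BMI cuts must be increasing")
    if b < lo:
        return "normal"
    if b < hi:
        return "overweight"
    return "obese"
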