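"""Statistical layer: one-way ANOVA, 95% intervals, the pooling rule, and
the organ-specific action-level report.

The reproducibility question is whether contour variability (Dice, mSSD
versus the group consensus) depends on which synthetic deformation was
applied.  Per ROI and correction mode, a one-way fixed-effects ANOVA is run
across deformation groups; when the deformation effect is not significant
(p >= alpha, default 0.05) all deformations are pooled into a single 95%
interval — the organ's contouring action level.  Significant ROIs are
flagged and reported stratified per deformation.  Dose-volume constraint
values are always stratified by plan type (IMRT vs VMAT systematically
differ) with deformations pooled within plan type.  No multiplicity
correction is applied across ROIs; raw p values are reported.

Intervals are empirical 2.5/97.5 percentiles by default (linearly
interpolated order statistics), with a normal-theory mean +/- 1.96 sd
alternative; both are clipped to the metric's domain ([0, 1] for Dice,
>= 0 for mSSD).

The analysis is exposed statsmodels-style: build an
:class:`ActionLevelAnalysis` from the comparison and dose-metric tables,
call :meth:`~ActionLevelAnalysis.fit`, and read tables or ``summary()`` off
the returned :class:`ActionLevelResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

ALPHA_DEFAULT = 0.05
Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class AnovaResult:
    """Classical one-way fixed-effects ANOVA."""

    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    group_labels: list
    degenerate: bool = False
    roi: str | None = None
    metric: str | None = None


def one_way_anova(groups: Sequence[Sequence[float]], labels: Sequence | None = None) -> AnovaResult:
    """F = MS_between / MS_within with p from the F distribution.

    Requires >= 2 groups of >= 2 samples.  Zero pooled within-group variance
    yields a degenerate result (p = nan, flagged) rather than an exception.
    """
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValidationError("every group needs at least two samples")
    labels = list(labels) if labels is not None else list(range(1, len(arrays) + 1))

    n_total = sum(a.size for a in arrays)
    grand = sum(a.sum() for a in arrays) / n_total
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = len(arrays) - 1
    df_within = n_total - len(arrays)

    if ss_within <= 0:
        f = np.inf if ss_between > 0 else 0.0
        return AnovaResult(f, np.nan, df_between, df_within, labels, degenerate=True)
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return AnovaResult(float(f), p, df_between, df_within, labels)


@dataclass
class IntervalEstimate:
    lower: float
    upper: float
    level: float = 0.95
    method: str = "percentile"

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise ValidationError("level must be in (0, 1)")
        if self.lower > self.upper:
            raise ValidationError("lower must be <= upper")


def interval_95(
    samples: Sequence[float],
    method: str = "percentile",
    level: float = 0.95,
    domain: tuple[float, float] | None = None,
) -> IntervalEstimate:
    """Two-sided interval from an empirical distribution.

    ``percentile`` uses interpolated 2.5th/97.5th order statistics;
    ``normal`` uses mean +/- 1.96 sd.  ``domain`` clips the endpoints (e.g.
    (0, 1) for Dice, (0, inf) for distances).
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValidationError("interval estimation needs >= 2 samples")
    tail = 100.0 * (1.0 - level) / 2.0
    if method == "percentile":
        lo, hi = np.percentile(x, [tail, 100.0 - tail])
    elif method == "normal":
        z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
        m, s = x.mean(), x.std(ddof=1)
        lo, hi = m - z * s, m + z * s
    else:
        raise ValidationError(f"unknown interval method {method!r}")
    if domain is not None:
        lo = float(np.clip(lo, *domain))
        hi = float(np.clip(hi, *domain))
    return IntervalEstimate(float(lo), float(hi), level, method)


# ---------------------------------------------------------------------------
# Action-level model
# ---------------------------------------------------------------------------

DSC_DOMAIN = (0.0, 1.0)
MSSD_DOMAIN = (0.0, np.inf)

ANOVA_COLUMNS = ["roi", "mode", "metric", "f_statistic", "p_value", "df_between", "df_within", "degenerate"]
CONTOUR_LEVEL_COLUMNS = [
    "roi", "mode", "pooling", "deformation_id", "p_value", "n",
    "dsc_ci_lo", "dsc_ci_hi", "mssd_ci_lo_mm", "mssd_ci_hi_mm",
]
DOSE_LEVEL_COLUMNS = ["constraint", "roi", "plan_type", "n", "ci_lo", "ci_hi", "unit"]


@dataclass
class ActionLevelResults:
    """Fitted action levels: per-ROI contour intervals and per-constraint
    dose intervals, with the ANOVA evidence behind each pooling decision."""

    anova_table: pd.DataFrame
    contour_action_levels: pd.DataFrame
    dose_action_levels: pd.DataFrame
    alpha: float
    ci_method: str
    gaps: list = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Action-level report",
            "===================",
            f"pooling rule: pool deformations when ANOVA p >= {self.alpha:g}"
            f" | intervals: {self.ci_method} 95%",
            "",
            "Contour action levels (per ROI and correction mode)",
            self.contour_action_levels.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
            "",
            "Dose-volume action levels (per constraint and plan type)",
            self.dose_action_levels.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        ]
        if self.gaps:
            lines += ["", "Gaps: " + "; ".join(self.gaps)]
        return "\n".join(lines)


class ActionLevelAnalysis:
    """Model: derive organ-specific action levels from a virtual (or real)
    end-to-end study.

    Parameters
    ----------
    comparisons
        Long table with columns (roi, deformation_id, plan_type, mode,
        fraction, dsc, mssd_mm): each repetition's agreement with its group
        consensus.
    dose_metrics
        Optional long table with columns (constraint, roi, plan_type,
        deformation_id, fraction, achieved, unit, passed).
    alpha
        Significance level of the deformation-effect ANOVA driving the
        pooling decision.
    ci_method
        'percentile' (default) or 'normal'.
    """

    def __init__(
        self,
        comparisons: pd.DataFrame,
        dose_metrics: pd.DataFrame | None = None,
        alpha: float = ALPHA_DEFAULT,
        ci_method: str = "percentile",
    ) -> None:
        required = {"roi", "deformation_id", "plan_type", "mode", "fraction", "dsc", "mssd_mm"}
        missing = required - set(comparisons.columns)
        if missing:
            raise ValidationError(f"comparisons table lacks columns {sorted(missing)}")
        self.comparisons = comparisons.copy()
        self.dose_metrics = None if dose_metrics is None else dose_metrics.copy()
        self.alpha = float(alpha)
        self.ci_method = ci_method

    # -- contour side ------------------------------------------------------
    def _fit_contours(self) -> tuple[pd.DataFrame, pd.DataFrame, list]:
        anova_rows, level_rows, gaps = [], [], []
        for (roi, mode), sub in sorted(
            self.comparisons.groupby(["roi", "mode"]), key=lambda kv: kv[0]
        ):
            groups, labels = [], []
            for d, g in sorted(sub.groupby("deformation_id")):
                if len(g) >= 2:
                    groups.append(g["dsc"].to_numpy())
                    labels.append(int(d))
            if len(groups) < 2:
                gaps.append(f"{roi}/{mode}: fewer than two deformation groups")
                continue
            res = one_way_anova(groups, labels)
            anova_rows.append(
                {
                    "roi": roi,
                    "mode": mode,
                    "metric": "dsc",
                    "f_statistic": res.f_statistic,
                    "p_value": res.p_value,
                    "df_between": res.df_between,
                    "df_within": res.df_within,
                    "degenerate": res.degenerate,
                }
            )
            pooled = res.degenerate or res.p_value >= self.alpha
            strata = [("all", sub)] if pooled else [(str(d), g) for d, g in sorted(sub.groupby("deformation_id"))]
            for stratum, g in strata:
                dsc_ci = interval_95(g["dsc"], self.ci_method, domain=DSC_DOMAIN)
                mssd_ci = interval_95(g["mssd_mm"], self.ci_method, domain=MSSD_DOMAIN)
                level_rows.append(
                    {
                        "roi": roi,
                        "mode": mode,
                        "pooling": "pooled" if pooled else "stratified",
                        "deformation_id": stratum,
                        "p_value": res.p_value,
                        "n": len(g),
                        "dsc_ci_lo": dsc_ci.lower,
                        "dsc_ci_hi": dsc_ci.upper,
                        "mssd_ci_lo_mm": mssd_ci.lower,
                        "mssd_ci_hi_mm": mssd_ci.upper,
                    }
                )
        return (
            pd.DataFrame(anova_rows, columns=ANOVA_COLUMNS),
            pd.DataFrame(level_rows, columns=CONTOUR_LEVEL_COLUMNS),
            gaps,
        )

    # -- dose side ---------------------------------------------------------
    def _fit_dose(self) -> tuple[pd.DataFrame, pd.DataFrame, list]:
        if self.dose_metrics is None or self.dose_metrics.empty:
            return (
                pd.DataFrame(columns=ANOVA_COLUMNS),
                pd.DataFrame(columns=DOSE_LEVEL_COLUMNS),
                [],
            )
        anova_rows, level_rows, gaps = [], [], []
        for (constraint, roi), sub in sorted(
            self.dose_metrics.groupby(["constraint", "roi"]), key=lambda kv: kv[0]
        ):
            # plan-type effect, reported as evidence for the stratification
            plan_groups = [g["achieved"].to_numpy() for _, g in sorted(sub.groupby("plan_type")) if len(g) >= 2]
            if len(plan_groups) >= 2:
                res = one_way_anova(plan_groups, sorted(sub["plan_type"].unique()))
                anova_rows.append(
                    {
                        "roi": roi,
                        "mode": "plan_type",
                        "metric": constraint,
                        "f_statistic": res.f_statistic,
                        "p_value": res.p_value,
                        "df_between": res.df_between,
                        "df_within": res.df_within,
                        "degenerate": res.degenerate,
                    }
                )
            for plan, g in sorted(sub.groupby("plan_type")):
                if len(g) < 2:
                    gaps.append(f"{constraint}/{roi}/{plan}: fewer than two fractions")
                    continue
                ci = interval_95(g["achieved"], self.ci_method)
                level_rows.append(
                    {
                        "constraint": constraint,
                        "roi": roi,
                        "plan_type": plan,
                        "n": len(g),
                        "ci_lo": ci.lower,
                        "ci_hi": ci.upper,
                        "unit": g["unit"].iloc[0],
                    }
                )
        return (
            pd.DataFrame(anova_rows, columns=ANOVA_COLUMNS),
            pd.DataFrame(level_rows, columns=DOSE_LEVEL_COLUMNS),
            gaps,
        )

    def fit(self) -> ActionLevelResults:
        contour_anova, contour_levels, gaps_c = self._fit_contours()
        dose_anova, dose_levels, gaps_d = self._fit_dose()
        anova_table = pd.concat([contour_anova, dose_anova], ignore_index=True)
        return ActionLevelResults(
            anova_table, contour_levels, dose_levels, self.alpha, self.ci_method, gaps_c + gaps_d
        )


def build_action_level_report(
    comparisons: pd.DataFrame,
    dose_metrics: pd.DataFrame | None = None,
    alpha: float = ALPHA_DEFAULT,
    ci_method: str = "percentile",
) -> ActionLevelResults:
    """Functional wrapper over :class:`ActionLevelAnalysis`."""
    return ActionLevelAnalysis(comparisons, dose_metrics, alpha, ci_method).fit()
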