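"""Meaningful-change-threshold candidates and their triangulation.

Three estimator families produce candidate thresholds for the target
instrument (QLDS, improvement negative):

* **anchor mean** — the mean target change among patients who improved
  exactly one category (or one point) on a qualified anchor;
* **regression projection** — for a continuous anchor with its own
  published threshold (EQ-VAS, 7 points), ordinary least squares of target
  change on anchor change evaluated at that threshold:
  ``beta0 + beta1 * anchor_mct``;
* **half SD** — the distribution-based supportive estimate, one-half the
  standard deviation of the target change in the full analysis set.

Triangulation pools the candidates: mean, median, range, and a recommended
integer threshold equal to the median's magnitude rounded half-away-from-
zero, reported with the improvement sign (a median of −8.09 recommends an
8-point improvement).

Group summaries follow conventional trial reporting: sample SD (n−1),
median as midpoint of the middle two for even n, 95% CI from the t
distribution, standardized response mean (mean change / SD of change) and
standardized effect size (mean change / SD of baseline scores).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "EstimationError",
    "GroupChangeSummary",
    "summarize_group",
    "RegressionFit",
    "fit_change_regression",
    "MCTCandidate",
    "project_regression_mct",
    "half_sd_mct",
    "anchor_mean_candidate",
    "TriangulationResult",
    "triangulate",
    "change_from_means",
]

CandidateSource = Literal["anchor_mean", "regression_projection", "half_sd"]


class EstimationError(ValueError):
    """Raised on degenerate estimation inputs."""


def change_from_means(baseline_mean: float, endpoint_mean: float) -> float:
    """Group-level mean change from the two visit means.

    The mean of within-patient changes equals the difference of visit means
    on the same analysis set, so published visit means determine the
    published mean change: endpoint − baseline.
    """
    return endpoint_mean - baseline_mean


# ---------------------------------------------------------------------------
# Group summaries

@dataclass(frozen=True)
class GroupChangeSummary:
    """Descriptives of target change within one anchor-change group.

    ``ci_low``/``ci_high``, ``srm`` and ``ses`` are ``None`` when undefined
    (n = 1, zero SD, or no baseline SD supplied) — undefined is reported as
    such, never silently zero.
    """

    anchor: str
    category: int
    n: int
    mean: float
    sd: Optional[float]
    median: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    srm: Optional[float]
    ses: Optional[float]
    flagged_small: bool = False

    def to_dict(self) -> dict:
        return {
            "anchor": self.anchor,
            "category": self.category,
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "median": self.median,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "srm": self.srm,
            "ses": self.ses,
            "flagged_small": self.flagged_small,
        }


def summarize_group(
    changes: Sequence[float],
    baseline_sd: Optional[float] = None,
    anchor: str = "",
    category: int = 0,
    flagged_small: bool = False,
) -> GroupChangeSummary:
    """Mean/SD/median/95% CI/SRM/SES of one group's change vector.

    95% CI = mean ± t(0.975, n−1) · SD/√n.  The SES denominator is the
    baseline SD of the full analysis set (pass it in), not of the group.
    """
    x = np.asarray(changes, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n == 0:
        raise EstimationError("empty change vector")
    mean = float(np.mean(x))
    median = float(np.median(x))
    if n == 1:
        sd = None
        ci_low = ci_high = srm = None
    else:
        sd = float(np.std(x, ddof=1))
        half = stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
        ci_low, ci_high = mean - half, mean + half
        srm = mean / sd if sd > 0 else None
    ses = None
    if baseline_sd is not None and baseline_sd > 0:
        ses = mean / baseline_sd
    return GroupChangeSummary(
        anchor=anchor,
        category=category,
        n=n,
        mean=mean,
        sd=sd,
        median=median,
        ci_low=ci_low,
        ci_high=ci_high,
        srm=srm,
        ses=ses,
        flagged_small=flagged_small,
    )


# ---------------------------------------------------------------------------
# Regression projection

@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of target change on anchor change."""

    beta0: float
    beta1: float
    pvalue_beta0: float
    pvalue_beta1: float
    se_beta0: float
    se_beta1: float
    n: int


def fit_change_regression(
    anchor_changes: Sequence[float], target_changes: Sequence[float]
) -> RegressionFit:
    """Ordinary least squares of target change on anchor change.

    Pairwise-complete; requires n ≥ 3 and non-degenerate anchor variance.
    Coefficient p-values are two-sided t-tests.
    """
    x = np.asarray(anchor_changes, dtype=float)
    y = np.asarray(target_changes, dtype=float)
    if x.shape != y.shape:
        raise EstimationError("anchor and target vectors must align")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise EstimationError(f"need >= 3 complete pairs, got {len(x)}")
    if np.ptp(x) == 0:
        raise EstimationError("degenerate design: anchor change has zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionFit(
        beta0=float(model.params[0]),
        beta1=float(model.params[1]),
        pvalue_beta0=float(model.pvalues[0]),
        pvalue_beta1=float(model.pvalues[1]),
        se_beta0=float(model.bse[0]),
        se_beta1=float(model.bse[1]),
        n=int(model.nobs),
    )


# ---------------------------------------------------------------------------
# Candidates

@dataclass(frozen=True)
class MCTCandidate:
    """One candidate threshold with full provenance.

    ``value`` is signed in the target's improvement direction (negative for
    a symptom/impact scale like the QLDS).
    """

    source: CandidateSource
    value: float
    anchor: Optional[str] = None
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise EstimationError("candidate value must be finite")

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "anchor": self.anchor,
            "value": self.value,
            "n": self.n,
        }


def anchor_mean_candidate(summary: GroupChangeSummary) -> MCTCandidate:
    """Candidate from a one-category/one-point improvement group mean."""
    return MCTCandidate(
        source="anchor_mean",
        value=summary.mean,
        anchor=summary.anchor,
        n=summary.n,
    )


def project_regression_mct(
    fit: RegressionFit, anchor_mct: float, anchor: Optional[str] = None
) -> MCTCandidate:
    """Target change projected at the anchor's own meaningful change.

    value = beta0 + beta1 · anchor_mct; ``anchor_mct`` is expressed in the
    anchor's improvement direction (e.g. +7 for EQ-VAS).
    """
    return MCTCandidate(
        source="regression_projection",
        value=fit.beta0 + fit.beta1 * anchor_mct,
        anchor=anchor,
        n=fit.n,
    )


def half_sd_mct(
    sd_of_change: float,
    improvement_sign: int = 1,
    n: Optional[int] = None,
) -> MCTCandidate:
    """Distribution-based candidate: one-half the SD of the target change."""
    if sd_of_change < 0:
        raise EstimationError("SD of change must be >= 0")
    if improvement_sign not in (1, -1):
        raise EstimationError("improvement_sign must be +1 or -1")
    return MCTCandidate(
        source="half_sd",
        value=improvement_sign * sd_of_change / 2.0,
        anchor=None,
        n=n,
    )


# ---------------------------------------------------------------------------
# Triangulation

def _round_half_away_from_zero(value: float) -> int:
    return int(math.copysign(math.floor(abs(value) + 0.5), value))


@dataclass(frozen=True)
class TriangulationResult:
    candidates: tuple[MCTCandidate, ...]
    mean: float
    median: float
    range: tuple[float, float]
    recommended: int

    def to_dict(self) -> dict:
        return {
            "candidates": [c.to_dict() for c in self.candidates],
            "mean": self.mean,
            "median": self.median,
            "range": list(self.range),
            "recommended": self.recommended,
        }


def triangulate(
    candidates: Sequence[MCTCandidate],
    include: Optional[Sequence[bool]] = None,
) -> TriangulationResult:
    """Pool candidate thresholds into a single recommendation.

    ``include`` optionally masks candidates out (config-driven exclusion).
    The recommendation is the median's magnitude rounded half-away-from-zero
    to an integer, carrying the median's sign; the median of an even count
    is the midpoint of the two central values.
    """
    if include is not None:
        if len(include) != len(candidates):
            raise EstimationError("include mask must match candidate count")
        candidates = [c for c, keep in zip(candidates, include) if keep]
    if not candidates:
        raise EstimationError("no candidates to triangulate")
    values = np.array([c.value for c in candidates], dtype=float)
    median = float(np.median(values))
    return TriangulationResult(
        candidates=tuple(candidates),
        mean=float(np.mean(values)),
        median=median,
        range=(float(values.min()), float(values.max())),
        recommended=_round_half_away_from_zero(median),
    )
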