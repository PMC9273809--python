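"""Change scores, anchor qualification and anchor-change grouping.

The anchor-based approach to a meaningful change threshold needs three
pieces of plumbing before any estimation happens:

1. per-patient change scores (endpoint − baseline) for the target and each
   candidate anchor, with the anchor additionally recoded onto an
   improvement-positive categorical scale (MADRS severity-band change or
   CGI point change);
2. a rank-correlation gate: an anchor is usable only if the Spearman
   correlation between its change and the target change is at least 0.40
   in magnitude;
3. exact-change groups ("improved exactly one category") holding the
   target-change vectors that the estimators summarize.

Sign conventions: negative QLDS/MADRS change means improvement, positive
EQ-VAS change means improvement.  Category and point changes are coded
baseline − endpoint, so that positive values always mean improvement.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import (
    SCORE_COLUMNS,
    SeverityCriteria,
    BUILTIN_CRITERIA,
    builtin_criteria,
    categorize_madrs,
)
from .synthetic import BASELINE_VISIT, ENDPOINT_VISIT

__all__ = [
    "AnchorSpec",
    "AnchorType",
    "ChangeError",
    "compute_changes",
    "spearman_rho",
    "SpearmanResult",
    "qualify_anchor",
    "QualificationDecision",
    "group_by_anchor_change",
    "AnchorGroups",
    "TARGET_CHANGE",
]

AnchorType = Literal["severity_categorical", "ordinal_point", "continuous"]

#: Default target variable: the QLDS change score (improvement negative).
TARGET_CHANGE = "qlds_change"

#: Instruments whose raw change is improvement-negative (symptom scales).
_IMPROVEMENT_NEGATIVE = {"qlds_total", "madrs_total", "cgi_ss_r", "cgi_sr_i"}


class ChangeError(ValueError):
    """Raised on invalid change-analysis inputs."""


@dataclass(frozen=True)
class AnchorSpec:
    """One anchor instrument and how it defines "meaningfully changed".

    ``severity_categorical`` anchors (MADRS) group patients by severity-band
    change under a :class:`SeverityCriteria`; ``ordinal_point`` anchors
    (the CGI scales) group by exact point change; ``continuous`` anchors
    (EQ-VAS) carry their own published meaningful-change threshold
    (``external_mct``, 7 points for EQ-VAS) and feed the regression
    projection instead of categorical grouping.
    """

    instrument: str
    anchor_type: AnchorType
    criteria: Optional[SeverityCriteria] = None
    qualification_threshold: float = 0.40
    external_mct: Optional[float] = None

    def __post_init__(self) -> None:
        if self.instrument not in SCORE_COLUMNS:
            raise ChangeError(f"unknown anchor instrument {self.instrument!r}")
        if self.qualification_threshold <= 0:
            raise ChangeError("qualification threshold must be > 0")
        if self.anchor_type == "severity_categorical" and self.criteria is None:
            raise ChangeError("severity_categorical anchors need criteria")
        if self.anchor_type == "continuous" and self.external_mct is None:
            raise ChangeError("continuous anchors need an external_mct")
        if self.anchor_type != "continuous" and self.external_mct is not None:
            raise ChangeError("external_mct only applies to continuous anchors")

    @property
    def name(self) -> str:
        if self.anchor_type == "severity_categorical":
            return f"{self.instrument}:{self.criteria.name}"
        return self.instrument

    def change_column(self) -> str:
        """Name of the improvement-coded grouping column in a change table."""
        if self.anchor_type == "severity_categorical":
            return f"madrs_cat_change_{self.criteria.name}"
        if self.anchor_type == "ordinal_point":
            return f"{self.instrument}_point_change"
        return f"{self.instrument.removesuffix('_total')}_change"

    def raw_change_column(self) -> str:
        """Name of the signed endpoint−baseline change column."""
        return f"{self.instrument.removesuffix('_total')}_change"


# ---------------------------------------------------------------------------
# Change table

def compute_changes(
    records: pd.DataFrame,
    criteria: Optional[Sequence[SeverityCriteria]] = None,
    baseline_visit: str = BASELINE_VISIT,
    endpoint_visit: str = ENDPOINT_VISIT,
) -> tuple[pd.DataFrame, dict]:
    """Build the per-patient change table from a long visit-record table.

    Returns ``(changes, dropped_log)``.  One output row per patient present
    at both visits; each change column is NaN when either visit's score is
    missing (complete-case handling is per anchor/target pair downstream).
    Columns:

    * ``<instrument>_change`` — endpoint − baseline, signed;
    * ``madrs_cat_change_<criteria>`` — baseline severity index − endpoint
      severity index per criteria set (positive = improvement, range −3..3);
    * ``cgi_ss_r_point_change`` / ``cgi_sr_i_point_change`` — baseline −
      endpoint (positive = improvement, range −6..6).
    """
    if criteria is None:
        criteria = tuple(BUILTIN_CRITERIA.values())

    dup = records.duplicated(subset=["patient_id", "visit"])
    if dup.any():
        pairs = records.loc[dup, ["patient_id", "visit"]].values.tolist()
        raise ChangeError(f"duplicate (patient_id, visit) rows: {pairs}")
    known = {baseline_visit, endpoint_visit}
    unknown = set(records["visit"].unique()) - known
    if unknown:
        raise ChangeError(
            f"unresolvable visit labels {sorted(unknown)}; "
            f"expected {sorted(known)}"
        )

    wide = records.pivot(index="patient_id", columns="visit", values=list(SCORE_COLUMNS))
    for visit in known:
        for name in SCORE_COLUMNS:
            if (name, visit) not in wide.columns:
                wide[(name, visit)] = pd.array([pd.NA] * len(wide), dtype="Int64")

    have_baseline = set(records.loc[records["visit"] == baseline_visit, "patient_id"])
    have_endpoint = set(records.loc[records["visit"] == endpoint_visit, "patient_id"])
    complete = sorted(have_baseline & have_endpoint)
    dropped_log = {
        "missing_baseline_visit": sorted(have_endpoint - have_baseline),
        "missing_endpoint_visit": sorted(have_baseline - have_endpoint),
    }
    wide = wide.loc[complete]

    out = pd.DataFrame(index=pd.Index(complete, name="patient_id"))
    arms = records.drop_duplicates("patient_id").set_index("patient_id")["arm"]
    out["arm"] = arms.reindex(complete)
    for name in SCORE_COLUMNS:
        short = name.removesuffix("_total")
        b = wide[(name, baseline_visit)].astype("Float64")
        e = wide[(name, endpoint_visit)].astype("Float64")
        out[f"{short}_baseline"] = b
        out[f"{short}_change"] = e - b
    for crit in criteria:
        out[f"madrs_cat_change_{crit.name}"] = _category_change(
            wide[("madrs_total", baseline_visit)],
            wide[("madrs_total", endpoint_visit)],
            crit,
        )
    for cgi in ("cgi_ss_r", "cgi_sr_i"):
        b = wide[(cgi, baseline_visit)].astype("Float64")
        e = wide[(cgi, endpoint_visit)].astype("Float64")
        out[f"{cgi}_point_change"] = b - e
    return out.reset_index(), dropped_log


def _category_change(
    baseline: pd.Series, endpoint: pd.Series, criteria: SeverityCriteria
) -> pd.Series:
    def idx(v):
        if pd.isna(v):
            return pd.NA
        return categorize_madrs(int(v), criteria)[1]

    b = baseline.map(idx)
    e = endpoint.map(idx)
    return (b.astype("Float64") - e.astype("Float64"))


# ---------------------------------------------------------------------------
# Spearman correlation and anchor qualification

@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    pvalue: float
    n: int


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ChangeError("change vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def spearman_rho(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["t-approx", "exact"] = "t-approx",
) -> SpearmanResult:
    """Spearman rank correlation on pairwise-complete observations.

    Ranks use the average-rank (midrank) convention for ties; the p-value
    comes from the t approximation with n−2 degrees of freedom, which is
    the standard choice at trial sample sizes.  ``method="exact"`` computes
    a permutation p-value by full enumeration and is only feasible for
    n ≤ 8; the estimate of rho is identical either way.
    """
    xv, yv = _pairwise_complete(x, y)
    n = len(xv)
    if n < 3:
        raise ChangeError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ChangeError("correlation undefined: zero variance in a vector")
    rho, pvalue = stats.spearmanr(xv, yv)
    if method == "exact":
        if n > 8:
            raise ChangeError("exact permutation p-value limited to n <= 8")
        pvalue = _exact_permutation_p(xv, yv, abs(rho))
    return SpearmanResult(rho=float(rho), pvalue=float(pvalue), n=n)


def _exact_permutation_p(x: np.ndarray, y: np.ndarray, observed: float) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    count = total = 0
    for perm in itertools.permutations(range(len(ry))):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        total += 1
        if abs(r) >= observed - 1e-12:
            count += 1
    return count / total


@dataclass(frozen=True)
class QualificationDecision:
    anchor: str
    rho: float
    pvalue: Optional[float]
    threshold: float
    qualified: bool

    def to_dict(self) -> dict:
        return {
            "anchor": self.anchor,
            "rho": self.rho,
            "pvalue": self.pvalue,
            "threshold": self.threshold,
            "qualified": self.qualified,
        }


def qualify_anchor(
    rho: Union[float, SpearmanResult], spec: AnchorSpec
) -> QualificationDecision:
    """Gate an anchor on |rho| >= threshold (default 0.40).

    The magnitude is the operative rule: a health-state anchor whose change
    runs opposite in sign to a symptom-scale target (e.g. EQ-VAS vs QLDS,
    rho ≈ −0.5) is as informative as a concordant one.
    """
    pvalue = None
    if isinstance(rho, SpearmanResult):
        pvalue = rho.pvalue
        rho = rho.rho
    if not (-1.0 <= rho <= 1.0):
        raise ChangeError(f"rho {rho} outside [-1, 1]")
    return QualificationDecision(
        anchor=spec.name,
        rho=float(rho),
        pvalue=pvalue,
        threshold=spec.qualification_threshold,
        qualified=abs(rho) >= spec.qualification_threshold,
    )


# ---------------------------------------------------------------------------
# Anchor-change grouping

@dataclass
class AnchorGroups:
    """Target-change vectors keyed by exact anchor-change category.

    Categories are improvement-coded integers (1 = improved exactly one
    category/point; negative = worsened).  ``flagged_small`` lists the
    categories whose n fell below the configured minimum.
    """

    anchor: str
    groups: dict[int, np.ndarray]
    min_group_n: int
    cumulative: bool = False

    @property
    def sizes(self) -> dict[int, int]:
        return {k: len(v) for k, v in self.groups.items()}

    @property
    def flagged_small(self) -> list[int]:
        return [k for k, v in self.groups.items() if len(v) < self.min_group_n]

    @property
    def n_total(self) -> int:
        return sum(len(v) for v in self.groups.values())


def group_by_anchor_change(
    changes: pd.DataFrame,
    spec: AnchorSpec,
    target: str = TARGET_CHANGE,
    min_group_n: int = 25,
    cumulative: bool = False,
    qualified: bool = True,
) -> AnchorGroups:
    """Split target changes into exact anchor-change groups.

    ``cumulative=True`` instead keys group ``k > 0`` by "improved at least
    k".  ``qualified=False`` marks that the anchor failed its correlation
    gate but grouping was forced anyway; a warning is emitted.

    Complete-case per anchor/target pair: a patient enters iff both the
    anchor change and the target change are present.
    """
    if changes.empty:
        raise ChangeError("empty change table")
    if spec.anchor_type == "continuous":
        raise ChangeError(
            f"{spec.name} is a continuous anchor; use the regression "
            "projection rather than categorical grouping"
        )
    if not qualified:
        warnings.warn(
            f"anchor {spec.name} did not meet its qualification threshold; "
            "grouping forced",
            stacklevel=2,
        )
    col = spec.change_column()
    if col not in changes.columns or target not in changes.columns:
        raise ChangeError(f"change table lacks column {col!r} or {target!r}")
    sub = changes[[col, target]].dropna()
    cats = sub[col].astype(float)
    if not np.allclose(cats, np.rint(cats)):
        raise ChangeError(f"{col} contains non-integer category changes")
    cats = cats.astype(int)
    groups: dict[int, np.ndarray] = {}
    for k in sorted(cats.unique()):
        if cumulative and k > 0:
            mask = cats >= k
        else:
            mask = cats == k
        groups[int(k)] = sub.loc[mask, target].to_numpy(dtype=float)
    return AnchorGroups(
        anchor=spec.name,
        groups=groups,
        min_group_n=min_group_n,
        cumulative=cumulative,
    )
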