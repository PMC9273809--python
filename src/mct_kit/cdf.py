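"""Empirical CDF curves of change scores, stratified by anchor category.

Responder CDF curves plot the empirical cumulative distribution of target
change scores separately per anchor-change group; visible horizontal
separation between adjacent curves supports the anchor categorization.
Here the visual claim is quantified by the two-sample Kolmogorov–Smirnov
distance between adjacent categories — an explicit operationalization this
package adds; the source analyses report the curves only.

Curves are emitted as tables of step points so any plotting stack can
reproduce the figures; plotting itself is deliberately out of contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CdfError", "EcdfCurve", "empirical_cdf", "stratified_cdfs", "KsSeparation"]


class CdfError(ValueError):
    """Raised on invalid CDF inputs."""


@dataclass(frozen=True)
class EcdfCurve:
    """A right-continuous empirical CDF as (value, cumulative proportion) steps.

    Duplicated observations collapse into a single step carrying their
    combined mass, so proportions rise from 1/n (or more) to exactly 1.
    """

    label: str
    values: tuple[float, ...]  # sorted observations, with duplicates
    steps: tuple[tuple[float, float], ...]  # unique value -> F(value)

    @property
    def n(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.label,
                "value": [v for v, _ in self.steps],
                "cumulative_proportion": [p for _, p in self.steps],
            }
        )


def empirical_cdf(changes: Sequence[float], label: str = "") -> EcdfCurve:
    """Empirical CDF of a change vector (NaNs excluded; n >= 1 required)."""
    x = np.asarray(changes, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) == 0:
        raise CdfError("empty change vector")
    x = np.sort(x)
    uniq, counts = np.unique(x, return_counts=True)
    cum = np.cumsum(counts) / len(x)
    cum[-1] = 1.0  # guard against float drift
    return EcdfCurve(
        label=label,
        values=tuple(float(v) for v in x),
        steps=tuple((float(v), float(p)) for v, p in zip(uniq, cum)),
    )


@dataclass(frozen=True)
class KsSeparation:
    group_a: str
    group_b: str
    distance: float

    def to_dict(self) -> dict:
        return {"group_a": self.group_a, "group_b": self.group_b,
                "distance": self.distance}


def stratified_cdfs(
    grouped_changes: Mapping[int, Sequence[float]],
) -> tuple[list[EcdfCurve], list[KsSeparation]]:
    """One ECDF per anchor-change category plus adjacent-pair separation.

    Groups are ordered by category key; the Kolmogorov–Smirnov distance
    sup|F_a − F_b| is reported for each adjacent pair as the separation
    summary (0 = indistinguishable, 1 = disjoint supports).
    """
    items = [(k, np.asarray(v, dtype=float)) for k, v in sorted(grouped_changes.items())]
    items = [(k, v[~np.isnan(v)]) for k, v in items]
    items = [(k, v) for k, v in items if len(v) > 0]
    if len(items) < 2:
        raise CdfError("need >= 2 non-empty groups for stratified CDFs")
    curves = [empirical_cdf(v, label=str(k)) for k, v in items]
    separations = []
    for (ka, va), (kb, vb) in zip(items, items[1:]):
        with np.errstate(divide="ignore"):  # p-value internals at n=1
            d = stats.ks_2samp(va, vb, method="asymp").statistic
        separations.append(
            KsSeparation(group_a=str(ka), group_b=str(kb), distance=float(d))
        )
    return curves, separations
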