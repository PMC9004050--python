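"""Attrition breakdowns, survival and retention rates, and median
survival time.

Two distinct rate definitions are computed from the cleaned cohort
matrix, each with its own denominator over nets surveyed at a round
(rounds at which the household was not visited never enter a
denominator):

* **survival rate** — proportion of nets present *and serviceable*
  (pHI <= 642); nets lost because they were given away, sold/stolen or
  exchanged are excluded from the denominator, since their ultimate
  fate is unknown.  This rate tracks loss of physical integrity.
* **retention rate** — proportion of nets physically present; nets
  lost because they were damaged-and-discarded or repurposed are
  excluded from the denominator.  This rate tracks whether households
  keep their nets.

Proportions carry two-sided 95% Wilson score intervals, which remain
well behaved at the small denominators of late survey rounds.

The median survival time Tm is obtained by linear interpolation of the
rate between two time points:

    Tm = t1 + (t2 - t1) * (p1 - 50) / (p1 - p2)

with its confidence interval from applying the same formula to the
lower limits of p1 and p2, and to the upper limits, respectively.
Projection toward the median is only considered reliable when the
first time point is at 85% or lower; above that a warning flag is set.
The formula happily extrapolates beyond t2; extrapolated results are
flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .holes import SERVICEABLE_MAX
from .matrix import CohortMatrix, net_causes
from .statuses import (
    CAUSES,
    DISCARD_CAUSES,
    NOT_FOUND_CAUSES,
    STATUS_CODE,
    NetStatus,
)

_PRESENT = STATUS_CODE[NetStatus.PRESENT]
_DISCARDED = STATUS_CODE[NetStatus.DISCARDED]
_NOT_FOUND = STATUS_CODE[NetStatus.NOT_FOUND]
_UNKNOWN = STATUS_CODE[NetStatus.UNKNOWN]

#: Flag value reported when a rate has a zero denominator.
UNDEFINED = float("nan")


class DegenerateSlopeError(ValueError):
    """p1 == p2: the interpolation line never crosses 50%."""


@dataclass(frozen=True)
class ReasonBreakdown:
    """Counts and percentages of attrition causes at one round.

    ``counts`` covers the five recorded causes and sums to ``total``;
    absent nets with no recorded cause are reported separately in
    ``unattributed`` and take no part in the percentages.
    """

    round: object
    counts: dict[str, int]
    total: int
    percentages: dict[str, float]
    unattributed: int = 0

    @classmethod
    def from_counts(cls, round_label, counts: dict[str, int], unattributed: int = 0):
        counts = {c: int(counts.get(c, 0)) for c in CAUSES}
        total = sum(counts.values())
        if total == 0:
            pct = {c: UNDEFINED for c in CAUSES}
        else:
            pct = {c: round(100.0 * n / total, 2) for c, n in counts.items()}
        return cls(round_label, counts, total, pct, unattributed)


@dataclass(frozen=True)
class RateEstimate:
    round: object
    kind: str  # "SURVIVAL" or "RETENTION"
    numerator: int
    denominator: int
    proportion: float  # percent
    ci_low: float
    ci_high: float

    @classmethod
    def from_counts(cls, round_label, kind: str, numerator: int, denominator: int):
        if numerator > denominator:
            raise ValueError("numerator cannot exceed denominator")
        if denominator == 0:
            return cls(round_label, kind, 0, 0, UNDEFINED, UNDEFINED, UNDEFINED)
        lo, hi = proportion_confint(numerator, denominator, alpha=0.05, method="wilson")
        return cls(
            round_label,
            kind,
            int(numerator),
            int(denominator),
            100.0 * numerator / denominator,
            100.0 * lo,
            100.0 * hi,
        )


@dataclass(frozen=True)
class MedianSurvivalTime:
    t1: float
    t2: float
    p1: float
    p2: float
    tm: float
    ci_low: float
    ci_high: float
    projection_warning: bool = False  # first time point above 85%
    extrapolated: bool = False  # tm outside [t1, t2]


def _round_masks(matrix: CohortMatrix, round_label):
    j = matrix.round_index(round_label)
    surveyed = matrix.observed[:, j]
    status = matrix.status[:, j]
    present = surveyed & (status == _PRESENT)
    absent = surveyed & np.isin(status, (_DISCARDED, _NOT_FOUND, _UNKNOWN))
    return j, surveyed, status, present, absent


def round_accounting(matrix: CohortMatrix, round_label) -> tuple[int, int, int]:
    """(present, absent, surveyed) counts at a round.

    present + absent == surveyed by construction: every net whose
    household was visited is either present or absent for some reason.
    """
    _, surveyed, _, present, absent = _round_masks(matrix, round_label)
    return int(present.sum()), int(absent.sum()), int(surveyed.sum())


def reason_breakdown(matrix: CohortMatrix, round_label) -> ReasonBreakdown:
    """Tabulate attrition causes among nets absent at a round."""
    _, _, _, _, absent = _round_masks(matrix, round_label)
    causes = net_causes(matrix)[absent]
    counts = {c: int((causes == c).sum()) for c in CAUSES}
    unattributed = int((causes == "").sum())
    return ReasonBreakdown.from_counts(round_label, counts, unattributed)


def survival_rate(
    matrix: CohortMatrix, phi_table: pd.DataFrame | None, round_label
) -> RateEstimate:
    """Proportion of nets present and serviceable at a round.

    The denominator excludes nets lost to the not-found family (given
    away, stolen, exchanged, or absent with no recorded cause): their
    fate is unknown, so they carry no information about physical decay.
    Present nets with no pHI record are counted serviceable.
    """
    _, surveyed, status, present, absent = _round_masks(matrix, round_label)
    causes = net_causes(matrix)
    excluded = absent & (
        np.isin(causes, list(NOT_FOUND_CAUSES))
        | ((causes == "") & (status == _NOT_FOUND))
    )
    denominator = int(surveyed.sum() - excluded.sum())

    serviceable = present.copy()
    if phi_table is not None:
        tab = phi_table[phi_table["round"] == round_label]
        torn_ids = set(tab.loc[tab["phi"] > SERVICEABLE_MAX, "net_id"])
        if torn_ids:
            serviceable &= ~np.isin(matrix.net_ids, list(torn_ids))
    return RateEstimate.from_counts(round_label, "SURVIVAL", int(serviceable.sum()), denominator)


def retention_rate(matrix: CohortMatrix, round_label) -> RateEstimate:
    """Proportion of nets physically present at a round.

    The denominator excludes nets lost to the discard family (damaged
    and discarded, repurposed, or discarded with no recorded cause).
    """
    _, surveyed, status, present, absent = _round_masks(matrix, round_label)
    causes = net_causes(matrix)
    excluded = absent & (
        np.isin(causes, list(DISCARD_CAUSES))
        | ((causes == "") & np.isin(status, (_DISCARDED, _UNKNOWN)))
    )
    denominator = int(surveyed.sum() - excluded.sum())
    return RateEstimate.from_counts(round_label, "RETENTION", int(present.sum()), denominator)


def median_survival_time(
    t1: float,
    t2: float,
    p1: float,
    p2: float,
    ci1: tuple[float, float] | None = None,
    ci2: tuple[float, float] | None = None,
) -> MedianSurvivalTime:
    """Median survival time by linear interpolation between two rates.

    Parameters are times in years and rates in percent; ``ci1``/``ci2``
    are (low, high) percent bounds on p1 and p2.  The CI on Tm applies
    the formula to lower-with-lower and upper-with-upper limits.
    """
    if p1 == p2:
        raise DegenerateSlopeError(f"p1 == p2 == {p1}: median undefined")

    def tm_of(a: float, b: float) -> float:
        if a == b:
            return UNDEFINED
        return t1 + (t2 - t1) * (a - 50.0) / (a - b)

    tm = tm_of(p1, p2)
    lo = hi = UNDEFINED
    if ci1 is not None and ci2 is not None:
        b1 = tm_of(ci1[0], ci2[0])
        b2 = tm_of(ci1[1], ci2[1])
        if not (math.isnan(b1) or math.isnan(b2)):
            lo, hi = min(b1, b2), max(b1, b2)
        else:
            lo, hi = b1, b2
    return MedianSurvivalTime(
        t1=t1,
        t2=t2,
        p1=p1,
        p2=p2,
        tm=tm,
        ci_low=lo,
        ci_high=hi,
        projection_warning=p1 > 85.0,
        extrapolated=not (min(t1, t2) <= tm <= max(t1, t2)),
    )


def subset_matrix(matrix: CohortMatrix, mask: np.ndarray) -> CohortMatrix:
    """Row subset of a cohort matrix (e.g. one brand or one zone)."""
    from dataclasses import replace

    return replace(
        matrix,
        net_ids=matrix.net_ids[mask],
        household_ids=matrix.household_ids[mask],
        status=matrix.status[mask],
        reason=matrix.reason[mask],
        observed=matrix.observed[mask],
        filled=matrix.filled[mask],
    )


def rate_table(
    matrix: CohortMatrix,
    roster: pd.DataFrame,
    phi_table: pd.DataFrame | None = None,
    by: str = "brand",
) -> pd.DataFrame:
    """Per-group, per-round survival and retention rates.

    ``by`` is a roster column ("brand" or "zone"); pass None for the
    pooled cohort.
    """
    roster_idx = roster.set_index("net_id")
    groups = (
        {"all": np.ones(matrix.n_nets, dtype=bool)}
        if by is None
        else {
            g: roster_idx.loc[matrix.net_ids, by].to_numpy() == g
            for g in sorted(roster_idx[by].unique())
        }
    )
    rows = []
    for gname, gmask in groups.items():
        sub = subset_matrix(matrix, gmask)
        for r in matrix.rounds:
            for est in (survival_rate(sub, phi_table, r), retention_rate(sub, r)):
                rows.append(
                    {
                        "group": gname,
                        "round": r,
                        "kind": est.kind,
                        "numerator": est.numerator,
                        "denominator": est.denominator,
                        "proportion": est.proportion,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                    }
                )
    return pd.DataFrame(rows)
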