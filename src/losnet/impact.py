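"""Opportunity-cost simulation of efficient interventions on predicted stays.

The thought experiment: management intervenes on every hospitalization the
model flags as positive, and the interventions are completely efficient —
each flagged stay is shortened exactly to its DRG's national reference LOS
(the benchmark by default; optionally the outlier threshold).  Stays already
at or below the reference, and unflagged stays, are untouched, so false
positives cost nothing in days.

The freed bed-days convert into additional hospitalizations by dividing by
the post-intervention (model-supported) mean LOS of the group, and into
additional revenue by multiplying by the group's observed case-mix mean DRG
reimbursement.  Day and hospitalization counts are rounded half away from
zero after aggregation; the division uses the unrounded day total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from losnet.evaluation import round_half_away
from losnet.outcomes import UnknownDRGError
from losnet.records import DRGReference, HospitalizationRecord


@dataclass
class ImpactRow:
    """Impact of efficient interventions for one group of hospitalizations."""

    group: str
    n_hosp: int
    mean_los_observed: float
    mean_los_benchmark: float
    mean_los_supported: float
    additional_days: int
    additional_hospitalizations: int
    additional_revenue: float


@dataclass
class ImpactReport:
    grouping: str
    rows: list[ImpactRow]
    overall: ImpactRow

    def to_records(self) -> list[dict]:
        out = [vars(r).copy() for r in self.rows]
        out.append(vars(self.overall).copy())
        return out


def theoretical_los(
    records: list[HospitalizationRecord],
    predictions,
    drg_ref: dict[str, DRGReference],
    target: str = "benchmark",
) -> np.ndarray:
    """Per-record LOS after fully efficient interventions on predicted positives.

    Flagged stays are reduced to min(observed, reference); ``target`` selects
    the benchmark (default) or the outlier threshold as reference.
    """
    if target not in ("benchmark", "threshold"):
        raise ValueError("target must be 'benchmark' or 'threshold'")
    predictions = np.asarray(predictions)
    if len(predictions) != len(records):
        raise ValueError("predictions must align with records")
    out = np.empty(len(records))
    for i, (rec, flagged) in enumerate(zip(records, predictions)):
        try:
            ref = drg_ref[rec.drg_code]
        except KeyError:
            raise UnknownDRGError(
                f"record {rec.record_id}: DRG code {rec.drg_code!r} not in reference table"
            ) from None
        goal = ref.benchmark_los if target == "benchmark" else ref.threshold_los
        out[i] = min(rec.los_days, goal) if flagged else rec.los_days
    return out


def additional_days(n: int, mean_obs: float, mean_supported: float) -> int:
    """Freed bed-days: round(n·(mean_obs − mean_supported)), half away from zero."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if mean_supported > mean_obs:
        raise ValueError("supported mean LOS cannot exceed the observed mean")
    return int(round_half_away(n * (mean_obs - mean_supported)))


def additional_hospitalizations(days_unrounded: float, mean_supported: float) -> int:
    """Freed days converted at the post-intervention mean LOS of the group."""
    if mean_supported <= 0:
        raise ValueError("post-intervention mean LOS must be positive")
    return int(round_half_away(days_unrounded / mean_supported))


def additional_revenue(additional_hosp: int, mean_revenue: float) -> float:
    """Additional hospitalizations valued at the group's mean reimbursement."""
    if additional_hosp < 0 or mean_revenue < 0:
        raise ValueError("inputs must be non-negative")
    return additional_hosp * mean_revenue


_GROUPERS = {
    "unit": lambda r: r.unit,
    "diagnosis_group": lambda r: r.diagnosis_group,
    "diagnosis_code": lambda r: r.diagnosis_code,
    "overall": lambda r: "overall",
}


def impact_by_group(
    records: list[HospitalizationRecord],
    predictions,
    drg_ref: dict[str, DRGReference],
    grouping: str = "unit",
    target: str = "benchmark",
) -> ImpactReport:
    """Per-group and overall impact of efficient interventions.

    For each group: observed mean LOS, case-mix benchmark mean, supported
    (post-intervention) mean, freed days, additional hospitalizations and
    revenue.  Day/hospitalization rounding happens after aggregation, from
    the groups' unrounded means.
    """
    if grouping not in _GROUPERS:
        raise ValueError(f"grouping must be one of {sorted(_GROUPERS)}")
    key = _GROUPERS[grouping]
    adjusted = theoretical_los(records, predictions, drg_ref, target=target)

    groups: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        groups.setdefault(key(rec), []).append(i)

    def _row(name: str, idx: list[int]) -> ImpactRow:
        n = len(idx)
        obs = float(np.mean([records[i].los_days for i in idx]))
        bench = float(np.mean([drg_ref[records[i].drg_code].benchmark_los for i in idx]))
        supp = float(np.mean(adjusted[idx]))
        days_exact = n * (obs - supp)
        revenue_mean = float(
            np.mean([drg_ref[records[i].drg_code].mean_reimbursement for i in idx])
        )
        n_extra = additional_hospitalizations(days_exact, supp) if supp > 0 else 0
        return ImpactRow(
            group=name,
            n_hosp=n,
            mean_los_observed=obs,
            mean_los_benchmark=bench,
            mean_los_supported=supp,
            additional_days=additional_days(n, obs, supp),
            additional_hospitalizations=n_extra,
            additional_revenue=additional_revenue(n_extra, revenue_mean),
        )

    rows = [_row(name, idx) for name, idx in sorted(groups.items())]
    overall = _row("overall", list(range(len(records))))
    if grouping == "overall":
        rows = []
    return ImpactReport(grouping=grouping, rows=rows, overall=overall)
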