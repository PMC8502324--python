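"""Binary stay-length outcomes against the national DRG references.

A hospitalization is *long* when its stay strictly exceeds the national mean
LOS for its DRG (the dynamic annual benchmark), and an *outlier* when it
strictly exceeds the fixed ministerial cutoff for that DRG.  Because every
threshold lies above its benchmark, outliers are a subset of the long stays;
ties with either reference value are labelled 0.  All discharge modes (home,
transfer, death, other) are included.
"""

from __future__ import annotations

from dataclasses import dataclass

from losnet.records import DRGReference, HospitalizationRecord


@dataclass(frozen=True)
class OutcomeLabels:
    long: int
    outlier: int

    def __post_init__(self) -> None:
        if self.outlier and not self.long:
            raise ValueError("outlier stays must also be long (threshold > benchmark)")


class UnknownDRGError(KeyError):
    pass


def label(record: HospitalizationRecord, drg_ref: dict[str, DRGReference]) -> OutcomeLabels:
    """Label one record: long iff LOS > benchmark, outlier iff LOS > threshold."""
    try:
        ref = drg_ref[record.drg_code]
    except KeyError:
        raise UnknownDRGError(
            f"record {record.record_id}: DRG code {record.drg_code!r} not in reference table"
        ) from None
    return OutcomeLabels(
        long=int(record.los_days > ref.benchmark_los),
        outlier=int(record.los_days > ref.threshold_los),
    )


def label_all(
    records: list[HospitalizationRecord], drg_ref: dict[str, DRGReference]
) -> list[OutcomeLabels]:
    return [label(rec, drg_ref) for rec in records]


def outcome_rates(
    records: list[HospitalizationRecord], drg_ref: dict[str, DRGReference]
) -> tuple[float, float]:
    """(fraction long, fraction outlier) over a non-empty record set."""
    if not records:
        raise ValueError("records must be non-empty")
    labels = label_all(records, drg_ref)
    n = len(labels)
    return sum(l.long for l in labels) / n, sum(l.outlier for l in labels) / n
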