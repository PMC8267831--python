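"""Marker-based genome completeness/contamination screening.

Completeness = % of the marker set present in at least one copy;
contamination = % of surplus marker copies.  The marker set itself is an
input (synthetic datasets designate a subset of simulated core genes;
real datasets supply their own marker labels).
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import StrainRecord, Thresholds


@dataclass
class QCReport:
    strain_id: str
    completeness: float
    contamination: float
    passed: bool
    reason: str = ""


def assess_quality(record: StrainRecord, marker_set: list[str],
                   thresholds: Thresholds | None = None) -> QCReport:
    if not marker_set:
        raise ValueError("empty marker set")
    thresholds = thresholds or Thresholds()
    counts = record.marker_counts()
    present = sum(1 for m in marker_set if counts.get(m, 0) >= 1)
    surplus = sum(max(0, counts.get(m, 0) - 1) for m in marker_set)
    completeness = 100.0 * present / len(marker_set)
    contamination = 100.0 * surplus / len(marker_set)
    reasons = []
    if completeness < thresholds.completeness_min:
        reasons.append("completeness")
    if contamination > thresholds.contamination_max:
        reasons.append("contamination")
    return QCReport(
        strain_id=record.strain_id,
        completeness=completeness,
        contamination=contamination,
        passed=not reasons,
        reason=",".join(reasons),
    )


def filter_dataset(records: list[StrainRecord], marker_set: list[str],
                   thresholds: Thresholds | None = None
                   ) -> tuple[list[StrainRecord], list[QCReport]]:
    """Split records into (kept, excluded-with-reasons); records unchanged."""
    thresholds = thresholds or Thresholds()
    kept = []
    excluded = []
    for record in records:
        report = assess_quality(record, marker_set, thresholds)
        if report.passed:
            kept.append(record)
        else:
            excluded.append(report)
    return kept, excluded
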