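"""Copy-number segment classification, genomic burden, and burden-tertile
grade imputation."""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np

from .types import CohortRecord, SegmentRecord

logger = logging.getLogger("germtrace")

GAIN_THRESHOLD = 0.3
LOSS_THRESHOLD = -0.3
ARTIFACT_THRESHOLD = -15.0


def classify_segment(log2_ratio: float) -> str:
    """Threshold a log2 copy ratio into neutral/gain/loss/artifact.

    Inequalities are strict: exactly +/-0.3 is neutral; below -15 is an
    artifact to be excluded downstream.
    """
    if not math.isfinite(log2_ratio):
        raise ValueError(f"non-finite log2 ratio: {log2_ratio}")
    if log2_ratio < ARTIFACT_THRESHOLD:
        return "artifact"
    if log2_ratio > GAIN_THRESHOLD:
        return "gain"
    if log2_ratio < LOSS_THRESHOLD:
        return "loss"
    return "neutral"


def cn_burden(segments: Sequence[SegmentRecord], sample_id: str = "") -> dict[str, object]:
    """Fraction of the segmented genome in a gain or loss.

    Burden = sum of gain/loss segment sizes over the sum of all segment
    sizes; artifact segments are excluded from both numerator and
    denominator.
    """
    kept = [s for s in segments if classify_segment(s.log2_ratio) != "artifact"]
    if not kept:
        raise ValueError("no usable segments: cannot compute burden")
    total_bp = sum(s.length for s in kept)
    altered_bp = sum(
        s.length for s in kept if classify_segment(s.log2_ratio) in ("gain", "loss")
    )
    return {
        "sample_id": sample_id,
        "burden": altered_bp / total_bp,
        "total_bp": total_bp,
        "altered_bp": altered_bp,
    }


def impute_grade_from_burden(
    cohort: Sequence[CohortRecord],
    burdens: dict[str, float],
) -> list[CohortRecord]:
    """Fill missing nuclear grades from copy-number burden tertiles.

    Tertile cut points come from the cohort's burden distribution (inclusive
    linear-interpolation quantiles); bottom/middle/top tertiles map to grades
    1/2/3, ties break toward the lower grade, and observed grades are never
    overwritten. Degenerate tertiles (all burdens equal) assign grade 2 to
    every missing grade with a warning.
    """
    values = np.asarray(list(burdens.values()), dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 burden values to form tertiles")
    missing = [rec for rec in cohort if rec.grade is None]
    for rec in missing:
        if rec.patient_id not in burdens:
            raise ValueError(f"no burden available for grade-missing patient {rec.patient_id}")
    q1, q2 = np.quantile(values, [1 / 3, 2 / 3], method="linear")
    degenerate = q1 == q2
    if degenerate:
        logger.warning("degenerate burden tertiles (q1 == q2); assigning grade 2 to missing")
    out: list[CohortRecord] = []
    for rec in cohort:
        if rec.grade is not None:
            out.append(rec)
            continue
        b = burdens[rec.patient_id]
        if degenerate:
            grade = 2
        elif b <= q1:
            grade = 1
        elif b <= q2:
            grade = 2
        else:
            grade = 3
        out.append(
            CohortRecord(
                patient_id=rec.patient_id,
                event=rec.event,
                time=rec.time,
                grade=grade,
                size_cm=rec.size_cm,
                age_group=rec.age_group,
                european_ancestry=rec.european_ancestry,
                prs_values=dict(rec.prs_values),
            )
        )
    return out
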