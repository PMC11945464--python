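"""High-/low-exposure (HEX/LEX) classification of welders.

Welders are split on their recent cumulative exposure index: a subject is
HEX iff CEI_3M (respirable airborne Mn integrated over the past three
months, mg/m^3*yr) strictly exceeds the threshold, 0.04 mg/m^3*yr by
default. The inequality is strict — a welder at exactly 0.04 is LEX — and
values are compared as parsed, with no epsilon, since exposure tables carry
exact decimals. Controls are not classified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import CohortTableError
from .volume_io import SubjectRecord

__all__ = ["DEFAULT_CEI3M_THRESHOLD", "ExposureClass", "classify_exposure"]

DEFAULT_CEI3M_THRESHOLD = 0.04  # mg/m^3 * yr


@dataclass(frozen=True)
class ExposureClass:
    subject_id: str
    label: str  # "HEX" or "LEX"
    cei_3m: float


def classify_exposure(
    records: Sequence[SubjectRecord],
    threshold: float = DEFAULT_CEI3M_THRESHOLD,
) -> list[ExposureClass]:
    """Classify every welder record as HEX (cei_3m > threshold) or LEX."""
    classes = []
    for record in records:
        if record.group != "welder":
            continue
        if record.cei_3m is None:
            raise CohortTableError(f"welder {record.subject_id} has no cei_3m value")
        label = "HEX" if record.cei_3m > threshold else "LEX"
        classes.append(ExposureClass(record.subject_id, label, record.cei_3m))
    return classes
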