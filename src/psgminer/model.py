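"""Core data model for polysomnography (PSG) report mining.

A PSG study produces a free-text narrative note in the medical record.  The
pipeline turns such notes into one structured row per sleep parameter:
total sleep time (TST), sleep onset latency (SOL), sleep efficiency (SE),
wake after sleep onset (WASO) and the apnea-hypopnea index (AHI).  Two
further parameters — REM and stage N1 — take part only in document quality
scoring, never in value extraction.
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass, field
from typing import Optional


class ParameterKind(enum.Enum):
    """The seven sleep-parameter concepts the pipeline knows about.

    Five are extraction targets; REM and N1 exist only as document
    quality components.
    """

    TST = "TST"
    SOL = "SOL"
    SE = "SE"
    WASO = "WASO"
    AHI = "AHI"
    REM = "REM"
    N1 = "N1"

    @property
    def is_extraction_target(self) -> bool:
        return self in EXTRACTION_TARGETS


EXTRACTION_TARGETS: tuple[ParameterKind, ...] = (
    ParameterKind.TST,
    ParameterKind.SOL,
    ParameterKind.SE,
    ParameterKind.WASO,
    ParameterKind.AHI,
)

#: Canonical output unit per extraction target.
CANONICAL_UNITS: dict[ParameterKind, str] = {
    ParameterKind.TST: "minutes",
    ParameterKind.SOL: "minutes",
    ParameterKind.WASO: "minutes",
    ParameterKind.SE: "percent",
    ParameterKind.AHI: "events-per-hour",
}


@dataclass(frozen=True)
class PSGNote:
    """One clinical note: identifiers, visit date, title, body, CPT codes.

    ``body`` may be empty — downstream stages filter such notes but never
    crash on them.
    """

    note_id: str
    patient_id: str
    visit_date: _dt.date
    title: str
    body: str
    cpt_codes: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class GoldAnnotation:
    """A rater's label for one (note, parameter) cell.

    ``value`` is set iff ``present`` is true — enforced at construction.
    """

    note_id: str
    parameter: ParameterKind
    present: bool
    value: Optional[float] = None
    unit: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.parameter.is_extraction_target:
            raise ValueError(
                f"gold annotations cover extraction targets only, got "
                f"{self.parameter.value}; allowed: "
                f"{[p.value for p in EXTRACTION_TARGETS]}"
            )
        if self.present and self.value is None:
            raise ValueError(f"{self.note_id}/{self.parameter.value}: present=true requires a value")
        if not self.present and self.value is not None:
            raise ValueError(f"{self.note_id}/{self.parameter.value}: present=false forbids a value")


@dataclass(frozen=True)
class Provenance:
    """Where an extracted value came from inside its note."""

    line_index: int
    char_start: int
    char_end: int
    matched_pattern: str


@dataclass(frozen=True)
class ExtractionRecord:
    """One structured output row: (patient, visit, parameter, value, unit).

    ``status`` is ``"extracted"`` iff ``value`` is non-missing; the unit is
    fixed per parameter after normalization (TST/SOL/WASO → minutes,
    SE → percent, AHI → events-per-hour).
    """

    patient_id: str
    visit_date: _dt.date
    parameter: ParameterKind
    value: Optional[float]
    unit: Optional[str]
    status: str
    note_id: str
    provenance: Optional[Provenance] = None

    def __post_init__(self) -> None:
        if self.status not in ("extracted", "not_found"):
            raise ValueError(f"unknown status {self.status!r}")
        if (self.status == "extracted") != (self.value is not None):
            raise ValueError("status must be 'extracted' exactly when value is present")
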