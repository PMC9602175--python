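"""Corpus inclusion rules and the document quality index (DQI).

PSG reports are pulled from the record system with SQL ``LIKE`` predicates,
so the filter layer reproduces ``LIKE`` semantics exactly: ``%`` matches any
(possibly empty) run of characters, matching is case-insensitive, and a
pattern must cover the whole string.  That deliberately means ``%SE%``
matches the "se" inside "onset" — the DQI is defined by LIKE semantics, not
token semantics.  A stricter word-boundary mode is available as an opt-in
flag for users who want token-level components.

The inclusion chain for a note:

1. title contains ``poly`` or ``PSG``;
2. body contains ``PSG`` or ``polysomno``;
3. body contains neither ``titrat`` nor ``split`` (split-night/titration
   studies do not describe a full diagnostic night);
4. DQI — the count of documented sleep-parameter components out of seven
   (TST, SOL, SE, WASO, REM, N1, AHI) — is at least 4, the cut recommended
   by the sleep physicians who designed the index.

An optional CPT restriction (diagnostic PSG 95810 / PSG with titration
95811) is applied when the note carries procedure codes, and skipped with a
logged warning otherwise.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .model import PSGNote, ParameterKind

logger = logging.getLogger(__name__)

TITLE_PATTERNS = ["%poly%", "%PSG%"]
BODY_PATTERNS = ["%PSG%", "%polysomno%"]
SPLIT_NIGHT_PATTERNS = ["%titrat%", "%split%"]

#: DQI component patterns, in component order TST, SOL, SE, WASO, REM, N1, AHI.
DQI_PATTERNS: dict[ParameterKind, list[str]] = {
    ParameterKind.TST: ["%TST%", "%total sleep time%"],
    ParameterKind.SOL: ["%SoL%", "%onset latency%"],
    ParameterKind.SE: ["%SE%", "%sleep efficiency%"],
    ParameterKind.WASO: ["%WASO%", "%wake after sleep onset%"],
    ParameterKind.REM: ["%REM%"],
    ParameterKind.N1: ["%N1%"],
    ParameterKind.AHI: ["%AHI%", "%apnea%index%"],
}

DQI_COMPONENT_ORDER: tuple[ParameterKind, ...] = (
    ParameterKind.TST,
    ParameterKind.SOL,
    ParameterKind.SE,
    ParameterKind.WASO,
    ParameterKind.REM,
    ParameterKind.N1,
    ParameterKind.AHI,
)

DEFAULT_DQI_CUT = 4
DEFAULT_CPT_CODES = frozenset({"95810", "95811"})


def like_match(pattern: str, text: str, word_boundary: bool = False) -> bool:
    """SQL ``LIKE`` matching with ``%`` wildcards, case-insensitive.

    ``%`` matches any character run including newlines; the pattern must
    cover the whole text (so a containment test is written ``%foo%``).
    With ``word_boundary=True`` every literal segment must additionally
    start and end at a word boundary — an opt-in tightening, not LIKE
    semantics.
    """
    if not pattern:
        raise ValueError("empty LIKE pattern")
    parts = pattern.split("%")
    if word_boundary:
        segments = [rf"\b{re.escape(p)}\b" if p else "" for p in parts]
    else:
        segments = [re.escape(p) for p in parts]
    regex = ".*".join(segments)
    return re.fullmatch(regex, text, flags=re.IGNORECASE | re.DOTALL) is not None


def _any_match(patterns: Sequence[str], text: str, word_boundary: bool = False) -> bool:
    return any(like_match(p, text, word_boundary) for p in patterns)


@dataclass(frozen=True)
class DQIResult:
    """Seven boolean documentation components plus their 0–7 sum."""

    note_id: str
    components: tuple[bool, bool, bool, bool, bool, bool, bool]
    score: int

    def component(self, parameter: ParameterKind) -> bool:
        return self.components[DQI_COMPONENT_ORDER.index(parameter)]


@dataclass(frozen=True)
class FilterDecision:
    """Whether a note passed the inclusion chain, with the rules it failed.

    ``included`` is true iff ``reasons`` is empty.  Reason identifiers:
    ``title_fail``, ``body_fail``, ``split_night``, ``cpt_fail``,
    ``dqi_below_cut``.
    """

    note_id: str
    included: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.included != (len(self.reasons) == 0):
            raise ValueError("included must be true exactly when reasons is empty")


def dqi_components(
    note: PSGNote,
    include_title: bool = False,
    word_boundary: bool = False,
) -> DQIResult:
    """Score documentation completeness of a note.

    Each component is true iff the note body matches any of that
    component's LIKE patterns; the DQI is the number of true components.
    ``include_title`` widens the match text to title + body.
    """
    text = note.title + "\n" + note.body if include_title else note.body
    flags = tuple(
        _any_match(DQI_PATTERNS[param], text, word_boundary) for param in DQI_COMPONENT_ORDER
    )
    return DQIResult(note_id=note.note_id, components=flags, score=sum(flags))


def title_body_filter(note: PSGNote, require_cpt: bool = False) -> FilterDecision:
    """Apply the title/body inclusion rules (stage before the DQI cut)."""
    reasons: list[str] = []
    if not _any_match(TITLE_PATTERNS, note.title):
        reasons.append("title_fail")
    if not _any_match(BODY_PATTERNS, note.body):
        reasons.append("body_fail")
    if _any_match(SPLIT_NIGHT_PATTERNS, note.body):
        reasons.append("split_night")
    if require_cpt:
        if note.cpt_codes:
            if not (note.cpt_codes & DEFAULT_CPT_CODES):
                reasons.append("cpt_fail")
        else:
            logger.warning("note %s has no CPT codes; CPT restriction skipped", note.note_id)
    return FilterDecision(note_id=note.note_id, included=not reasons, reasons=tuple(reasons))


def apply_dqi_cut(
    notes: Iterable[PSGNote],
    cut: int = DEFAULT_DQI_CUT,
    include_title: bool = False,
    word_boundary: bool = False,
) -> tuple[list[PSGNote], list[PSGNote]]:
    """Partition notes into (retained, rejected) by DQI score ≥ ``cut``.

    Order is preserved in both halves and the sizes sum to the input size.
    """
    if not 0 <= cut <= 7:
        raise ValueError(f"DQI cut must be in 0..7, got {cut}")
    retained: list[PSGNote] = []
    rejected: list[PSGNote] = []
    for note in notes:
        result = dqi_components(note, include_title=include_title, word_boundary=word_boundary)
        (retained if result.score >= cut else rejected).append(note)
    return retained, rejected


def filter_corpus(
    notes: Iterable[PSGNote],
    cut: int = DEFAULT_DQI_CUT,
    require_cpt: bool = False,
    include_title: bool = False,
    word_boundary: bool = False,
) -> tuple[list[PSGNote], list[FilterDecision]]:
    """Run the full inclusion chain and return (retained notes, decisions).

    Title/body rules run first; the DQI is evaluated only for notes that
    pass them (``dqi_components`` itself is callable on any note).
    """
    retained: list[PSGNote] = []
    decisions: list[FilterDecision] = []
    for note in notes:
        decision = title_body_filter(note, require_cpt=require_cpt)
        if decision.included:
            result = dqi_components(note, include_title=include_title, word_boundary=word_boundary)
            if result.score < cut:
                decision = FilterDecision(
                    note_id=note.note_id, included=False, reasons=("dqi_below_cut",)
                )
        if decision.included:
            retained.append(note)
        decisions.append(decision)
    return retained, decisions
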