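"""The five-step extraction engine: read, tokenize, locate, mine, store.

Each PSG note is tokenized into lines and sentences; parameter mentions are
located line-by-line with literal phrase sets (longest match wins); the
numeric quantity associated with a mention is mined by nearest neighbor on
the same line, skipping clock times and dates, and falling back to the next
nearest candidate when the nearest one fails unit-compatibility or
plausibility validation ("second nearest" rule).  Validated values are
normalized to canonical units — minutes for TST/SOL/WASO, percent for SE,
events per hour for AHI — and emitted as one record per target parameter
per note, with character-level provenance.

All offsets are 0-based, half-open, into the original note body.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .config import ExtractionConfig, PatternSet, PlausibilityRange
from .io import write_records
from .model import (
    CANONICAL_UNITS,
    EXTRACTION_TARGETS,
    ExtractionRecord,
    PSGNote,
    ParameterKind,
    Provenance,
)


@dataclass(frozen=True)
class Span:
    """Half-open [start, end) character interval."""

    start: int
    end: int

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def contains(self, other: "Span") -> bool:
        return self.start <= other.start and other.end <= self.end and self != other


@dataclass(frozen=True)
class Token:
    text: str
    span: Span


@dataclass(frozen=True)
class TokenizedNote:
    """Line, sentence and token spans over a note body.

    Line spans cover the body completely and without overlap (each line
    owns its trailing newline); sentence spans nest within lines.
    """

    note_id: str
    body: str
    lines: tuple[Span, ...]
    sentences: tuple[Span, ...]
    tokens_per_line: tuple[tuple[Token, ...], ...]

    def line_of(self, offset: int) -> int:
        for i, line in enumerate(self.lines):
            if line.start <= offset < line.end:
                return i
        if self.lines and offset == self.lines[-1].end:
            return len(self.lines) - 1
        raise IndexError(f"offset {offset} outside body of note {self.note_id}")

    def line_text(self, index: int) -> str:
        span = self.lines[index]
        return self.body[span.start : span.end]


@dataclass(frozen=True)
class ParameterMention:
    """A located parameter phrase: where it is and which phrase matched."""

    parameter: ParameterKind
    matched_pattern: str
    line_index: int
    char_span: Span

    @property
    def anchor(self) -> float:
        return self.char_span.midpoint


@dataclass(frozen=True)
class QuantityCandidate:
    """A numeric token on a line, possibly excluded as clock time or date."""

    raw_text: str
    value: float
    unit_hint: str  # minutes | hours | percent | events-per-hour | none
    char_span: Span
    excluded_reason: Optional[str] = None  # clock_time | date | out_of_range


_SENTENCE_BREAK = re.compile(r"(?<=[.!?])\s+")
_TOKEN = re.compile(r"\S+")

_DATE = re.compile(r"\b\d{1,2}/\d{1,2}/\d{2,4}\b|\b\d{4}-\d{2}-\d{2}\b")
_CLOCK = re.compile(r"\b([01]?\d|2[0-3]):[0-5]\d\b")
_COMPOUND_DURATION = re.compile(
    r"(\d+(?:\.\d+)?)\s*(?:hours|hour|hrs|hr|h)\b\s*(?:and\s+)?(\d+(?:\.\d+)?)\s*(?:minutes|minute|mins|min)\b",
    re.IGNORECASE,
)
_NUMBER = re.compile(r"[+-]?\d+(?:\.\d+)?")

_UNIT_AFTER = [
    (re.compile(r"^\s*(?:%|percent\b)"), "percent"),
    (
        re.compile(r"^\s*(?:events?|ev)\s*(?:/|\bper\b)\s*(?:hr|hour|h)\b", re.IGNORECASE),
        "events-per-hour",
    ),
    (re.compile(r"^\s*/\s*(?:hr|hour|h)\b", re.IGNORECASE), "events-per-hour"),
    (re.compile(r"^\s*(?:minutes|minute|mins|min)\b\.?", re.IGNORECASE), "minutes"),
    (re.compile(r"^\s*(?:hours|hour|hrs|hr)\b\.?", re.IGNORECASE), "hours"),
]

#: Unit hints a parameter can accept before normalization.
_COMPATIBLE_HINTS: dict[str, frozenset[str]] = {
    "minutes": frozenset({"none", "minutes", "hours"}),
    "percent": frozenset({"none", "percent"}),
    "events-per-hour": frozenset({"none", "events-per-hour"}),
}


def tokenize(note: PSGNote) -> TokenizedNote:
    """Split a note body into line, sentence and token spans.

    Lines break on ``\\n`` (the newline belongs to the line it ends);
    sentences are segmented within each line on ``.!?`` followed by
    whitespace; tokens are maximal non-whitespace runs.  An empty body
    yields zero lines.
    """
    body = note.body
    lines: list[Span] = []
    start = 0
    while start < len(body):
        nl = body.find("\n", start)
        end = len(body) if nl == -1 else nl + 1
        lines.append(Span(start, end))
        start = end

    sentences: list[Span] = []
    tokens_per_line: list[tuple[Token, ...]] = []
    for line in lines:
        text = body[line.start : line.end]
        # sentence segmentation restricted within the line
        cursor = 0
        for m in _SENTENCE_BREAK.finditer(text):
            seg = text[cursor : m.start()]
            if seg.strip():
                sentences.append(Span(line.start + cursor, line.start + m.start()))
            cursor = m.end()
        tail = text[cursor:]
        if tail.strip():
            sentences.append(Span(line.start + cursor, line.start + cursor + len(tail.rstrip("\n"))))
        tokens_per_line.append(
            tuple(
                Token(m.group(), Span(line.start + m.start(), line.start + m.end()))
                for m in _TOKEN.finditer(text)
            )
        )
    return TokenizedNote(
        note_id=note.note_id,
        body=body,
        lines=tuple(lines),
        sentences=tuple(sentences),
        tokens_per_line=tuple(tokens_per_line),
    )


def locate(tokenized: TokenizedNote, patterns: PatternSet) -> list[ParameterMention]:
    """Find all non-overlapping phrase matches for one parameter.

    Matching is case-insensitive on the raw body.  When two phrases of the
    set overlap, the longest match wins (ties: the earlier one); mentions
    are returned in document order.
    """
    raw_matches: list[tuple[Span, str]] = []
    for phrase in patterns.phrases:
        for m in re.finditer(re.escape(phrase), tokenized.body, flags=re.IGNORECASE):
            raw_matches.append((Span(m.start(), m.end()), phrase))
    # longest-match-wins overlap resolution
    raw_matches.sort(key=lambda t: (-(t[0].end - t[0].start), t[0].start))
    chosen: list[tuple[Span, str]] = []
    for span, phrase in raw_matches:
        if all(span.end <= c.start or span.start >= c.end for c, _ in chosen):
            chosen.append((span, phrase))
    chosen.sort(key=lambda t: t[0].start)
    return [
        ParameterMention(
            parameter=patterns.parameter,
            matched_pattern=phrase,
            line_index=tokenized.line_of(span.start),
            char_span=span,
        )
        for span, phrase in chosen
    ]


def find_quantities(tokenized: TokenizedNote, line_index: int) -> list[QuantityCandidate]:
    """Enumerate numeric candidates on one line, in position order.

    Clock times (``hh:mm``) and dates (``mm/dd/yyyy`` or ISO) become
    excluded candidates; compound durations like ``1 hr 53 min`` collapse
    into a single minutes-valued candidate; every remaining maximal
    numeric token becomes a plain candidate whose unit hint is read from
    the text immediately following it.
    """
    line_span = tokenized.lines[line_index]
    text = tokenized.body[line_span.start : line_span.end]
    consumed: list[tuple[int, int]] = []
    candidates: list[QuantityCandidate] = []

    def overlaps(start: int, end: int) -> bool:
        return any(start < e and s < end for s, e in consumed)

    for m in _DATE.finditer(text):
        consumed.append(m.span())
        first = _NUMBER.search(m.group())
        candidates.append(
            QuantityCandidate(
                raw_text=m.group(),
                value=float(first.group()) if first else float("nan"),
                unit_hint="none",
                char_span=Span(line_span.start + m.start(), line_span.start + m.end()),
                excluded_reason="date",
            )
        )
    for m in _CLOCK.finditer(text):
        if overlaps(*m.span()):
            continue
        consumed.append(m.span())
        hh, mm = m.group().split(":")
        candidates.append(
            QuantityCandidate(
                raw_text=m.group(),
                value=float(hh) + float(mm) / 60,
                unit_hint="none",
                char_span=Span(line_span.start + m.start(), line_span.start + m.end()),
                excluded_reason="clock_time",
            )
        )
    for m in _COMPOUND_DURATION.finditer(text):
        if overlaps(*m.span()):
            continue
        consumed.append(m.span())
        hours, minutes = float(m.group(1)), float(m.group(2))
        candidates.append(
            QuantityCandidate(
                raw_text=m.group(),
                value=hours * 60 + minutes,
                unit_hint="minutes",
                char_span=Span(line_span.start + m.start(), line_span.start + m.end()),
            )
        )
    for m in _NUMBER.finditer(text):
        if overlaps(*m.span()):
            continue
        following = text[m.end() : m.end() + 24]
        unit_hint = "none"
        for regex, hint in _UNIT_AFTER:
            if regex.search(following):
                unit_hint = hint
                break
        candidates.append(
            QuantityCandidate(
                raw_text=m.group(),
                value=float(m.group()),
                unit_hint=unit_hint,
                char_span=Span(line_span.start + m.start(), line_span.start + m.end()),
            )
        )
    candidates.sort(key=lambda c: c.char_span.start)
    return candidates


def validate(
    parameter: ParameterKind,
    candidate: QuantityCandidate,
    range: PlausibilityRange,
) -> bool:
    """True iff the candidate's unit is compatible with the parameter's
    canonical unit and its normalized value lies within the plausibility
    range."""
    if candidate.excluded_reason is not None:
        return False
    canonical = CANONICAL_UNITS[parameter]
    if candidate.unit_hint not in _COMPATIBLE_HINTS[canonical]:
        return False
    value, _ = normalize(parameter, candidate)
    return range.min <= value <= range.max


def normalize(parameter: ParameterKind, candidate: QuantityCandidate) -> tuple[float, str]:
    """Convert a validated candidate to the parameter's canonical unit.

    Hours become minutes (× 60) for duration parameters; percent signs are
    already stripped by the numeric grammar; values already canonical pass
    through unchanged.
    """
    canonical = CANONICAL_UNITS[parameter]
    value = candidate.value
    if canonical == "minutes" and candidate.unit_hint == "hours":
        value = value * 60
    return float(value), canonical


def _distance(
    mention: ParameterMention,
    candidate: QuantityCandidate,
    tokenized: TokenizedNote,
    metric: str,
) -> float:
    if metric == "char":
        return abs(candidate.char_span.midpoint - mention.anchor)
    tokens = tokenized.tokens_per_line[mention.line_index]
    def token_index(span: Span) -> int:
        for i, tok in enumerate(tokens):
            if tok.span.start <= span.start < tok.span.end or span.start <= tok.span.start < span.end:
                return i
        return min(range(len(tokens)), key=lambda i: abs(tokens[i].span.midpoint - span.midpoint))
    return abs(token_index(candidate.char_span) - token_index(mention.char_span))


def associate(
    mention: ParameterMention,
    candidates: Sequence[QuantityCandidate],
    range: PlausibilityRange,
    tokenized: Optional[TokenizedNote] = None,
    distance_metric: str = "char",
    tie_break: str = "after",
) -> Optional[QuantityCandidate]:
    """Pick the quantity for a mention by nearest neighbor with fallback.

    Among non-excluded candidates on the mention's line, the one with the
    smallest distance to the mention anchor wins — whether it precedes or
    follows the phrase.  If the nearest fails validation (unit clash or
    implausible value) the next nearest passing candidate is taken, down
    the whole line if need be; ``None`` when nothing passes.  Ties at
    equal distance go to the candidate after the mention by default.
    """
    viable = [c for c in candidates if c.excluded_reason is None]
    if not viable:
        return None
    if distance_metric == "token" and tokenized is None:
        raise ValueError("token distance needs the tokenized note")

    def sort_key(c: QuantityCandidate) -> tuple[float, int, int]:
        if distance_metric == "char":
            d = abs(c.char_span.midpoint - mention.anchor)
        else:
            d = _distance(mention, c, tokenized, "token")
        after = c.char_span.midpoint > mention.anchor
        preferred = after if tie_break == "after" else not after
        return (d, 0 if preferred else 1, c.char_span.start)

    for candidate in sorted(viable, key=sort_key):
        if validate(mention.parameter, candidate, range):
            return candidate
    return None


def _suppress_cross_parameter(
    mentions_by_param: dict[ParameterKind, list[ParameterMention]],
) -> dict[ParameterKind, list[ParameterMention]]:
    """Drop mentions strictly contained in a longer mention of another parameter.

    "sleep onset" inside "Wake After Sleep Onset (WASO)" names WASO, not
    SOL; containment against the longer phrase decides.
    """
    all_mentions = [m for ms in mentions_by_param.values() for m in ms]
    kept: dict[ParameterKind, list[ParameterMention]] = {}
    for param, mentions in mentions_by_param.items():
        kept[param] = [
            m
            for m in mentions
            if not any(
                other.parameter != m.parameter and other.char_span.contains(m.char_span)
                for other in all_mentions
            )
        ]
    return kept


def extract_note(note: PSGNote, config: Optional[ExtractionConfig] = None) -> list[ExtractionRecord]:
    """Run locate → mine → normalize for all five target parameters.

    For each parameter, mentions are visited in document order (or reverse
    under ``mention_policy="last"``); the first mention whose line yields a
    validated quantity wins.  A pure function of (note, config): repeated
    runs give identical records.
    """
    config = config or ExtractionConfig()
    tokenized = tokenize(note)
    mentions_by_param = {
        param: locate(tokenized, config.pattern_sets[param]) for param in EXTRACTION_TARGETS
    }
    if config.cross_parameter_suppression:
        mentions_by_param = _suppress_cross_parameter(mentions_by_param)

    records: list[ExtractionRecord] = []
    for param in EXTRACTION_TARGETS:
        mentions = mentions_by_param[param]
        if config.mention_policy == "last":
            mentions = list(reversed(mentions))
        found: Optional[tuple[ParameterMention, QuantityCandidate]] = None
        for mention in mentions:
            candidates = find_quantities(tokenized, mention.line_index)
            chosen = associate(
                mention,
                candidates,
                config.ranges[param],
                tokenized=tokenized,
                distance_metric=config.distance_metric,
                tie_break=config.tie_break,
            )
            if chosen is not None:
                found = (mention, chosen)
                break
        if found is None:
            records.append(
                ExtractionRecord(
                    patient_id=note.patient_id,
                    visit_date=note.visit_date,
                    parameter=param,
                    value=None,
                    unit=None,
                    status="not_found",
                    note_id=note.note_id,
                )
            )
        else:
            mention, candidate = found
            value, unit = normalize(param, candidate)
            records.append(
                ExtractionRecord(
                    patient_id=note.patient_id,
                    visit_date=note.visit_date,
                    parameter=param,
                    value=value,
                    unit=unit,
                    status="extracted",
                    note_id=note.note_id,
                    provenance=Provenance(
                        line_index=mention.line_index,
                        char_start=mention.char_span.start,
                        char_end=mention.char_span.end,
                        matched_pattern=mention.matched_pattern,
                    ),
                )
            )
    return records


def extract_corpus(
    notes: Iterable[PSGNote],
    config: Optional[ExtractionConfig] = None,
    out_path: Optional[str | Path] = None,
    filter_inline: bool = False,
    dqi_cut: int = 4,
) -> tuple[list[ExtractionRecord], dict[str, dict[str, int]]]:
    """Extract every note and optionally write the record CSV.

    With ``filter_inline`` the corpus inclusion chain runs first and only
    retained notes are extracted.  Returns the records plus per-parameter
    counts of extracted / not_found.
    """
    notes = list(notes)
    if filter_inline:
        from .filters import filter_corpus

        notes, _ = filter_corpus(notes, cut=dqi_cut)
    records: list[ExtractionRecord] = []
    for note in notes:
        records.extend(extract_note(note, config))
    summary = {
        param.value: {
            "extracted": sum(
                1 for r in records if r.parameter == param and r.status == "extracted"
            ),
            "not_found": sum(
                1 for r in records if r.parameter == param and r.status == "not_found"
            ),
        }
        for param in EXTRACTION_TARGETS
    }
    if out_path is not None:
        write_records(records, out_path)
    return records, summary
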