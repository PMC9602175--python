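"""Readers and writers for the plain-text formats the pipeline touches.

Two corpus layouts are supported:

* ``delimited`` — a single RFC-4180 CSV with one row per note and columns
  ``note_id, patient_id, visit_date, title, body, cpt_codes`` (CPT codes
  ``;``-separated inside the cell);
* ``per-file`` — a directory of one ``.txt`` file per note body plus a
  ``manifest.csv`` carrying the metadata columns above (``filename``
  instead of ``body``).

Note text is preserved byte-for-byte at read time (decoded as UTF-8 with
replacement of undecodable bytes); no normalization happens here.  Dates
are ISO-8601 and rejected otherwise — they are provenance, not extraction
targets.
"""

from __future__ import annotations

import csv
import datetime as _dt
import logging
from pathlib import Path
from typing import Iterable, Sequence

from .model import (
    EXTRACTION_TARGETS,
    ExtractionRecord,
    GoldAnnotation,
    PSGNote,
    ParameterKind,
    Provenance,
)

logger = logging.getLogger(__name__)

CORPUS_COLUMNS = ["note_id", "patient_id", "visit_date", "title", "body", "cpt_codes"]
MANIFEST_COLUMNS = ["note_id", "patient_id", "visit_date", "title", "cpt_codes", "filename"]
RECORD_COLUMNS = [
    "patient_id",
    "visit_date",
    "parameter",
    "value",
    "unit",
    "status",
    "note_id",
    "line_index",
    "char_start",
    "char_end",
    "matched_pattern",
]
GOLD_COLUMNS = ["note_id", "parameter", "present", "value", "unit"]


class CorpusFormatError(ValueError):
    """A corpus, gold, or record file violates its schema."""


def _parse_date(raw: str, context: str) -> _dt.date:
    try:
        return _dt.date.fromisoformat(raw.strip())
    except ValueError as exc:
        raise CorpusFormatError(f"{context}: visit_date {raw!r} is not ISO-8601 (YYYY-MM-DD)") from exc


def _parse_cpt(raw: str) -> frozenset[str]:
    return frozenset(c.strip() for c in raw.split(";") if c.strip())


def _require_columns(header: Sequence[str], required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise CorpusFormatError(f"{path}: missing required column(s) {', '.join(missing)}")


def _read_text(path: Path) -> str:
    data = path.read_bytes()
    text = data.decode("utf-8", errors="replace")
    if "�" in text and b"\xef\xbf\xbd" not in data:
        logger.warning("%s: undecodable bytes replaced with U+FFFD", path)
    return text


def read_corpus(path: str | Path, format: str = "delimited") -> list[PSGNote]:
    """Read a corpus of PSG notes.

    Parameters
    ----------
    path
        The corpus CSV (``format="delimited"``) or the directory holding
        ``manifest.csv`` plus one ``.txt`` per note (``format="per-file"``).
    format
        ``"delimited"`` or ``"per-file"``.

    Returns one :class:`~psgminer.model.PSGNote` per row/file, in file
    order, with note text unchanged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"corpus path does not exist: {path}")
    if format == "delimited":
        return _read_delimited(path)
    if format == "per-file":
        return _read_per_file(path)
    raise ValueError(f"unknown corpus format {format!r}; use 'delimited' or 'per-file'")


def _read_delimited(path: Path) -> list[PSGNote]:
    notes: list[PSGNote] = []
    seen: set[str] = set()
    with open(path, newline="", encoding="utf-8", errors="replace") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CorpusFormatError(f"{path}: empty file, header row required")
        _require_columns(reader.fieldnames, CORPUS_COLUMNS, path)
        for i, row in enumerate(reader):
            ctx = f"{path} row {i + 2}"
            note_id = row["note_id"]
            if note_id in seen:
                raise CorpusFormatError(f"{ctx}: duplicate note_id {note_id!r}")
            seen.add(note_id)
            notes.append(
                PSGNote(
                    note_id=note_id,
                    patient_id=row["patient_id"],
                    visit_date=_parse_date(row["visit_date"], ctx),
                    title=row["title"],
                    body=row["body"],
                    cpt_codes=_parse_cpt(row["cpt_codes"]),
                )
            )
    return notes


def _read_per_file(directory: Path) -> list[PSGNote]:
    manifest = directory / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"per-file corpus needs {manifest}")
    notes: list[PSGNote] = []
    seen: set[str] = set()
    with open(manifest, newline="", encoding="utf-8", errors="replace") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CorpusFormatError(f"{manifest}: empty file, header row required")
        _require_columns(reader.fieldnames, MANIFEST_COLUMNS, manifest)
        for i, row in enumerate(reader):
            ctx = f"{manifest} row {i + 2}"
            note_id = row["note_id"]
            if note_id in seen:
                raise CorpusFormatError(f"{ctx}: duplicate note_id {note_id!r}")
            seen.add(note_id)
            body_path = directory / row["filename"]
            if not body_path.exists():
                raise FileNotFoundError(f"{ctx}: note file missing: {body_path}")
            notes.append(
                PSGNote(
                    note_id=note_id,
                    patient_id=row["patient_id"],
                    visit_date=_parse_date(row["visit_date"], ctx),
                    title=row["title"],
                    body=_read_text(body_path),
                    cpt_codes=_parse_cpt(row["cpt_codes"]),
                )
            )
    return notes


def _format_value(value: float | None) -> str:
    """Render a value with up to 2 decimal places, no thousands separators."""
    if value is None:
        return ""
    return f"{value:.2f}".rstrip("0").rstrip(".")


def write_records(records: Iterable[ExtractionRecord], path: str | Path) -> None:
    """Write extraction records as CSV with a fixed column order.

    Missing values become empty fields; the file round-trips through
    :func:`read_records` into an equal collection (values compared after
    canonical 2-decimal formatting).
    """
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RECORD_COLUMNS)
        for rec in records:
            prov = rec.provenance
            writer.writerow(
                [
                    rec.patient_id,
                    rec.visit_date.isoformat(),
                    rec.parameter.value,
                    _format_value(rec.value),
                    rec.unit or "",
                    rec.status,
                    rec.note_id,
                    "" if prov is None else prov.line_index,
                    "" if prov is None else prov.char_start,
                    "" if prov is None else prov.char_end,
                    "" if prov is None else prov.matched_pattern,
                ]
            )


def read_records(path: str | Path) -> list[ExtractionRecord]:
    """Read back a record CSV written by :func:`write_records`."""
    path = Path(path)
    records: list[ExtractionRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CorpusFormatError(f"{path}: empty file, header row required")
        _require_columns(reader.fieldnames, RECORD_COLUMNS, path)
        for i, row in enumerate(reader):
            ctx = f"{path} row {i + 2}"
            prov = None
            if row["line_index"] != "":
                prov = Provenance(
                    line_index=int(row["line_index"]),
                    char_start=int(row["char_start"]),
                    char_end=int(row["char_end"]),
                    matched_pattern=row["matched_pattern"],
                )
            records.append(
                ExtractionRecord(
                    patient_id=row["patient_id"],
                    visit_date=_parse_date(row["visit_date"], ctx),
                    parameter=_parse_parameter(row["parameter"], ctx),
                    value=float(row["value"]) if row["value"] != "" else None,
                    unit=row["unit"] or None,
                    status=row["status"],
                    note_id=row["note_id"],
                    provenance=prov,
                )
            )
    return records


def _parse_parameter(raw: str, ctx: str) -> ParameterKind:
    try:
        kind = ParameterKind(raw.strip())
    except ValueError:
        allowed = ", ".join(p.value for p in EXTRACTION_TARGETS)
        raise CorpusFormatError(f"{ctx}: unknown parameter {raw!r}; allowed: {allowed}") from None
    if not kind.is_extraction_target:
        allowed = ", ".join(p.value for p in EXTRACTION_TARGETS)
        raise CorpusFormatError(f"{ctx}: parameter {raw!r} is not an extraction target; allowed: {allowed}")
    return kind


def read_gold(path: str | Path) -> list[GoldAnnotation]:
    """Read a gold-annotation CSV (note_id, parameter, present, value, unit).

    One annotation per (note_id, parameter); duplicates are rejected, as is
    any row whose ``present`` flag disagrees with the value field.
    """
    path = Path(path)
    annotations: list[GoldAnnotation] = []
    seen: set[tuple[str, ParameterKind]] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CorpusFormatError(f"{path}: empty file, header row required")
        _require_columns(reader.fieldnames, GOLD_COLUMNS, path)
        for i, row in enumerate(reader):
            ctx = f"{path} row {i + 2}"
            parameter = _parse_parameter(row["parameter"], ctx)
            key = (row["note_id"], parameter)
            if key in seen:
                raise CorpusFormatError(f"{ctx}: duplicate (note_id, parameter) = {key[0]!r}/{parameter.value}")
            seen.add(key)
            present_raw = row["present"].strip().lower()
            if present_raw not in ("true", "false", "1", "0"):
                raise CorpusFormatError(f"{ctx}: present must be true/false, got {row['present']!r}")
            present = present_raw in ("true", "1")
            value = float(row["value"]) if row["value"].strip() != "" else None
            if present and value is None:
                raise CorpusFormatError(f"{ctx}: present=true requires a value")
            if not present and value is not None:
                raise CorpusFormatError(f"{ctx}: present=false forbids a value")
            annotations.append(
                GoldAnnotation(
                    note_id=row["note_id"],
                    parameter=parameter,
                    present=present,
                    value=value,
                    unit=row["unit"] or None,
                )
            )
    return annotations


def write_gold(annotations: Iterable[GoldAnnotation], path: str | Path) -> None:
    """Write gold annotations in the format :func:`read_gold` expects."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(GOLD_COLUMNS)
        for ann in annotations:
            writer.writerow(
                [
                    ann.note_id,
                    ann.parameter.value,
                    "true" if ann.present else "false",
                    _format_value(ann.value),
                    ann.unit or "",
                ]
            )


def write_corpus(notes: Iterable[PSGNote], path: str | Path) -> None:
    """Write notes as a delimited corpus CSV readable by :func:`read_corpus`."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CORPUS_COLUMNS)
        for note in notes:
            writer.writerow(
                [
                    note.note_id,
                    note.patient_id,
                    note.visit_date.isoformat(),
                    note.title,
                    note.body,
                    ";".join(sorted(note.cpt_codes)),
                ]
            )
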