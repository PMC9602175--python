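"""Seeded generator of synthetic PSG reports with gold labels.

Real PSG narratives sit behind hospital firewalls, so the pipeline is
exercised on generated notes that emulate the documentation variability
sleep labs actually produce: the same parameter phrased fully, abbreviated
or parenthesized; the quantity before or after the phrase; distractor
numbers (clock times, dates, stage percentages) sharing the line;
split-night/titration notes that the corpus filter must drop; and
thinly-documented notes whose document quality index falls below the cut.

Every note carries its own gold labels by construction: the rendered value
string appears verbatim in the body, and a parameter's gold is present iff
its sentence was rendered.  All output is a pure function of
(config, seed).

What the generator does NOT emulate: spelling errors, OCR noise,
section-header boilerplate, negated findings, or multi-night longitudinal
notes — conclusions drawn from it speak to format variability, not to
arbitrary real-world text.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import write_corpus, write_gold
from .model import (
    CANONICAL_UNITS,
    EXTRACTION_TARGETS,
    GoldAnnotation,
    PSGNote,
    ParameterKind,
)

TEMPLATE_IDS = ("canonical", "abbreviated", "value_first", "narrative", "distractor_rich")

DEFAULT_TEMPLATE_MIX: dict[str, float] = {
    "canonical": 0.30,
    "abbreviated": 0.20,
    "value_first": 0.15,
    "narrative": 0.15,
    "distractor_rich": 0.20,
}

#: Sampling intervals per parameter, in canonical units.
DEFAULT_VALUE_RANGES: dict[ParameterKind, tuple[float, float]] = {
    ParameterKind.TST: (180.0, 540.0),
    ParameterKind.SOL: (2.0, 120.0),
    ParameterKind.SE: (50.0, 99.0),
    ParameterKind.WASO: (5.0, 180.0),
    ParameterKind.AHI: (0.0, 120.0),
}

# One sentence per (template, parameter); {v} is the rendered value.
_SENTENCES: dict[str, dict[ParameterKind, str]] = {
    "canonical": {
        ParameterKind.TST: "Total Sleep Time (TST): {v} minutes.",
        ParameterKind.SOL: "Sleep Onset Latency (SOL): {v} minutes.",
        ParameterKind.SE: "Sleep Efficiency (SE): {v}%.",
        ParameterKind.WASO: "Wake After Sleep Onset (WASO): {v} minutes.",
        ParameterKind.AHI: "Apnea Hypopnea Index (AHI): {v} events/hr.",
    },
    "abbreviated": {
        ParameterKind.TST: "The patient slept for {v} min.",
        ParameterKind.SOL: "Sleep onset occurred after {v} min.",
        ParameterKind.SE: "Sleep efficiency {v}%.",
        ParameterKind.WASO: "Total wake time {v} min.",
        ParameterKind.AHI: "AHI for the night was {v}.",
    },
    "value_first": {
        ParameterKind.TST: "{v} minutes of total sleep time were recorded.",
        ParameterKind.SOL: "{v} min sleep onset latency.",
        ParameterKind.SE: "{v}% sleep efficiency.",
        ParameterKind.WASO: "{v} min of wake after sleep onset.",
        ParameterKind.AHI: "{v} events/hr apnea/hypopnea index.",
    },
    "narrative": {
        ParameterKind.TST: "Overnight the patient was monitored for {v} minutes of sleep in total.",
        ParameterKind.SOL: "The latency for sleep onset was {v} minutes per the technician.",
        ParameterKind.SE: "The overall sleep efficiency for the night was {v} percent.",
        ParameterKind.WASO: "The patient had {v} minutes of wake after sleep onset overnight.",
        ParameterKind.AHI: "The apnea hypopnea index was measured at {v} events per hour.",
    },
    "distractor_rich": {
        ParameterKind.TST: "Lights out at 22:45; the patient slept for {v} minutes (study dated 03/12/2018).",
        ParameterKind.SOL: "After lights off at 23:10, sleep onset came at {v} minutes.",
        ParameterKind.SE: "Sleep efficiency was {v}% for bed period 22:30 to 06:15.",
        ParameterKind.WASO: "Total wake time {v} min, final awakening 05:45.",
        ParameterKind.AHI: "AHI for the diagnostic night of 06/21/2019 was {v} events/hr.",
    },
}
# Stress template: canonical summary plus a later narrative repetition with a
# perturbed value, so the first-vs-last mention policy is observable.
_SENTENCES["repeated_mention"] = _SENTENCES["canonical"]

_REPEATED_NARRATIVE: dict[ParameterKind, str] = {
    ParameterKind.TST: "By tech impression the patient slept for {v} minutes.",
    ParameterKind.SOL: "Tech impression: sleep onset near {v} minutes.",
    ParameterKind.SE: "Tech impression: sleep efficiency roughly {v}%.",
    ParameterKind.WASO: "Tech impression: total wake near {v} min.",
    ParameterKind.AHI: "Tech impression: AHI for the night near {v}.",
}

_HEADER = "Diagnostic polysomnography was performed."
_SPLIT_SENTENCE = "The second portion of the night involved CPAP titration."
_MATCHING_TITLES = ("Polysomnography report", "Sleep study PSG")
_NON_MATCHING_TITLE = "Clinic follow-up note"


@dataclass(frozen=True)
class SynthesisConfig:
    """Generation parameters; the defaults define the study conditions.

    ``template_mix`` weights must sum to 1; rates are probabilities per
    note (split-night, low-DQI, bad title) or per parameter (missing).
    ``coherent_se`` derives SE from TST/(TST+SOL+WASO) instead of
    sampling it independently.
    """

    n_notes: int = 200
    seed: int = 7
    template_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TEMPLATE_MIX))
    split_night_rate: float = 0.05
    low_dqi_rate: float = 0.05
    missing_parameter_rate: float = 0.05
    bad_title_rate: float = 0.0
    coherent_se: bool = False
    value_ranges: dict[ParameterKind, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_VALUE_RANGES)
    )

    def __post_init__(self) -> None:
        if abs(sum(self.template_mix.values()) - 1.0) > 1e-9:
            raise ValueError("template_mix weights must sum to 1")
        for name, rate in [
            ("split_night_rate", self.split_night_rate),
            ("low_dqi_rate", self.low_dqi_rate),
            ("missing_parameter_rate", self.missing_parameter_rate),
            ("bad_title_rate", self.bad_title_rate),
        ]:
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticNote:
    """A generated note with its gold labels and per-parameter template ids."""

    note: PSGNote
    gold: tuple[GoldAnnotation, ...]
    template_used: dict[ParameterKind, str]
    kind: str  # normal | split_night | low_dqi


def sample_values(
    rng: np.random.Generator,
    value_ranges: dict[ParameterKind, tuple[float, float]] | None = None,
    coherent_se: bool = False,
) -> dict[ParameterKind, float]:
    """Draw one plausible value per parameter, uniform within its range.

    With ``coherent_se`` the efficiency is TST/(TST+SOL+WASO)·100 —
    internally consistent with the durations — clipped into the SE range.
    """
    ranges = value_ranges or DEFAULT_VALUE_RANGES
    values: dict[ParameterKind, float] = {}
    for param in EXTRACTION_TARGETS:
        lo, hi = ranges[param]
        values[param] = float(rng.uniform(lo, hi))
    if coherent_se:
        tst = values[ParameterKind.TST]
        denom = tst + values[ParameterKind.SOL] + values[ParameterKind.WASO]
        lo, hi = ranges[ParameterKind.SE]
        values[ParameterKind.SE] = float(np.clip(100.0 * tst / denom, lo, hi))
    return values


def _render_value(value: float, decimals: int) -> str:
    return f"{value:.{decimals}f}"


def render_note(
    values: dict[ParameterKind, float],
    template_ids: dict[ParameterKind, str],
    rng: np.random.Generator,
    note_id: str = "note-0000",
    patient_id: str = "pt-0000",
    visit_date: _dt.date = _dt.date(2010, 1, 1),
    present: dict[ParameterKind, bool] | None = None,
    kind: str = "normal",
    title: str | None = None,
    decimals: int | None = None,
) -> SyntheticNote:
    """Instantiate one note body from per-parameter templates.

    Each present parameter contributes exactly one gold-bearing sentence
    on its own line, in the fixed summary order TST, SOL, SE, WASO, AHI.
    ``kind="split_night"`` appends titration vocabulary;
    ``kind="low_dqi"`` keeps only the TST and AHI sentences so the note
    scores below the quality cut.  Values render with 0 or 1 decimal
    places (drawn per note) and the gold stores the rendered number.
    """
    present = present or {p: True for p in EXTRACTION_TARGETS}
    if kind == "low_dqi":
        present = {p: p in (ParameterKind.TST, ParameterKind.AHI) for p in EXTRACTION_TARGETS}
        template_ids = {p: "canonical" for p in EXTRACTION_TARGETS}
    if decimals is None:
        decimals = int(rng.integers(0, 2))

    lines = [_HEADER]
    gold: list[GoldAnnotation] = []
    repeated: list[str] = []
    for param in EXTRACTION_TARGETS:
        if not present[param]:
            gold.append(GoldAnnotation(note_id, param, present=False))
            continue
        template = template_ids[param]
        rendered = _render_value(values[param], decimals)
        lines.append(_SENTENCES[template][param].format(v=rendered))
        gold.append(
            GoldAnnotation(
                note_id, param, present=True, value=float(rendered), unit=CANONICAL_UNITS[param]
            )
        )
        if template == "repeated_mention":
            wrong = _render_value(values[param] + 7.0, decimals)
            repeated.append(_REPEATED_NARRATIVE[param].format(v=wrong))
    if kind != "low_dqi":
        n1 = int(rng.integers(2, 9))
        rem = int(rng.integers(15, 26))
        lines.append(f"Sleep staging: stage N1 {n1}% and REM {rem}% of the night.")
        if any(template_ids[p] == "distractor_rich" for p in EXTRACTION_TARGETS if present[p]):
            lines.append("Recording period 21:58 to 06:10; report dated 04/02/2019.")
    lines.extend(repeated)
    if kind == "split_night":
        lines.append(_SPLIT_SENTENCE)

    if title is None:
        title = _MATCHING_TITLES[int(rng.integers(0, len(_MATCHING_TITLES)))]
    cpt = frozenset({"95811"}) if kind == "split_night" else frozenset({"95810"})
    note = PSGNote(
        note_id=note_id,
        patient_id=patient_id,
        visit_date=visit_date,
        title=title,
        body="\n".join(lines),
        cpt_codes=cpt,
    )
    return SyntheticNote(note=note, gold=tuple(gold), template_used=dict(template_ids), kind=kind)


def generate_notes(config: SynthesisConfig) -> list[SyntheticNote]:
    """Generate ``config.n_notes`` synthetic notes, reproducibly from the seed."""
    rng = np.random.default_rng(config.seed)
    template_names = list(config.template_mix)
    template_weights = np.array([config.template_mix[t] for t in template_names])
    notes: list[SyntheticNote] = []
    for i in range(config.n_notes):
        u = rng.random()
        if u < config.split_night_rate:
            kind = "split_night"
        elif u < config.split_night_rate + config.low_dqi_rate:
            kind = "low_dqi"
        else:
            kind = "normal"
        title = _NON_MATCHING_TITLE if rng.random() < config.bad_title_rate else None
        values = sample_values(rng, config.value_ranges, config.coherent_se)
        present = {
            p: bool(rng.random() >= config.missing_parameter_rate) for p in EXTRACTION_TARGETS
        }
        template_ids = {
            p: template_names[int(rng.choice(len(template_names), p=template_weights))]
            for p in EXTRACTION_TARGETS
        }
        visit_date = _dt.date(2001, 1, 1) + _dt.timedelta(days=int(rng.integers(0, 6900)))
        notes.append(
            render_note(
                values,
                template_ids,
                rng,
                note_id=f"note-{i:04d}",
                patient_id=f"pt-{i:04d}",
                visit_date=visit_date,
                present=present,
                kind=kind,
                title=title,
            )
        )
    return notes


def generate_corpus(config: SynthesisConfig, out_dir: str | Path) -> dict:
    """Write corpus CSV, gold CSV and a JSON manifest to ``out_dir``.

    The manifest records the full config, the seed and the realized
    per-kind counts, so a corpus is auditable and reproducible.  Returns
    the manifest dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    synthetic = generate_notes(config)
    write_corpus([s.note for s in synthetic], out_dir / "corpus.csv")
    write_gold([g for s in synthetic for g in s.gold], out_dir / "gold.csv")
    manifest = {
        "config": {
            **{
                k: v
                for k, v in dataclasses.asdict(config).items()
                if k != "value_ranges"
            },
            "value_ranges": {p.value: list(r) for p, r in config.value_ranges.items()},
        },
        "n_notes": config.n_notes,
        "realized_counts": {
            kind: sum(1 for s in synthetic if s.kind == kind)
            for kind in ("normal", "split_night", "low_dqi")
        },
        "files": {"corpus": "corpus.csv", "gold": "gold.csv"},
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
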