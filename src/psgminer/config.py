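"""Extraction configuration: phrase sets, plausibility ranges, policies.

Defaults encode the phrase lists the rule set was built around; everything
is overridable from a YAML file so site-specific report templates can be
accommodated without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .model import EXTRACTION_TARGETS, CANONICAL_UNITS, ParameterKind


@dataclass(frozen=True)
class PatternSet:
    """Ordered literal phrases locating one parameter, matched case-insensitively."""

    parameter: ParameterKind
    phrases: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.phrases:
            raise ValueError(f"empty pattern set for {self.parameter.value}")


@dataclass(frozen=True)
class PlausibilityRange:
    """Clinically plausible value interval for one parameter, in its canonical unit."""

    parameter: ParameterKind
    min: float
    max: float
    unit: str

    def __post_init__(self) -> None:
        if not self.min < self.max:
            raise ValueError(f"{self.parameter.value}: need min < max, got [{self.min}, {self.max}]")


DEFAULT_PHRASES: dict[ParameterKind, tuple[str, ...]] = {
    ParameterKind.TST: (
        "total sleep time",
        "slept for",
        "monitored for",
        "spent for",
        "Total Sleep Time (TST)",
    ),
    ParameterKind.SOL: (
        "sleep onset latency",
        "sleep onset",
        "latency for",
        "Sleep Onset Latency (SOL)",
    ),
    ParameterKind.SE: (
        "sleep efficiency",
        "sleep efficiency for",
        "Sleep Efficiency (SE)",
    ),
    ParameterKind.WASO: (
        "wake after",
        "wake time after",
        "total wake",
        "WASO",
        "Wake After Sleep Onset (WASO)",
    ),
    ParameterKind.AHI: (
        "apnea hypopnea index",
        "apnea/hypopnea index",
        "AHI for",
        "Apnea Hypopnea Index (AHI)",
    ),
}

# Bounds chosen from sleep-lab reporting conventions: a night is at most
# 1440 min, latencies/wake rarely exceed 12 h, SE is a percentage, AHI
# above 200 events/h is not physiologic.
DEFAULT_RANGES: dict[ParameterKind, tuple[float, float]] = {
    ParameterKind.TST: (0.0, 1440.0),
    ParameterKind.SOL: (0.0, 720.0),
    ParameterKind.WASO: (0.0, 720.0),
    ParameterKind.SE: (0.0, 100.0),
    ParameterKind.AHI: (0.0, 200.0),
}


def default_pattern_sets() -> dict[ParameterKind, PatternSet]:
    return {p: PatternSet(p, DEFAULT_PHRASES[p]) for p in EXTRACTION_TARGETS}


def default_ranges() -> dict[ParameterKind, PlausibilityRange]:
    return {
        p: PlausibilityRange(p, DEFAULT_RANGES[p][0], DEFAULT_RANGES[p][1], CANONICAL_UNITS[p])
        for p in EXTRACTION_TARGETS
    }


@dataclass(frozen=True)
class ExtractionConfig:
    """Everything the extraction engine needs, with documented defaults.

    mention_policy
        Which located mention wins when a note repeats a parameter:
        ``"first"`` (summary sections usually precede narrative
        repetition) or ``"last"``.
    distance_metric
        ``"char"`` — absolute difference of character-span midpoints —
        or ``"token"`` — token-count distance on the line.
    tie_break
        At equal distance prefer the candidate ``"after"`` the mention
        (clinical convention "parameter: value") or ``"before"``.
    cross_parameter_suppression
        Drop a mention strictly contained in a longer mention of a
        different parameter (e.g. "sleep onset" inside
        "Wake After Sleep Onset (WASO)").
    """

    pattern_sets: dict[ParameterKind, PatternSet] = field(default_factory=default_pattern_sets)
    ranges: dict[ParameterKind, PlausibilityRange] = field(default_factory=default_ranges)
    mention_policy: str = "first"
    distance_metric: str = "char"
    tie_break: str = "after"
    cross_parameter_suppression: bool = True

    def __post_init__(self) -> None:
        if self.mention_policy not in ("first", "last"):
            raise ValueError(f"mention_policy must be 'first' or 'last', got {self.mention_policy!r}")
        if self.distance_metric not in ("char", "token"):
            raise ValueError(f"distance_metric must be 'char' or 'token', got {self.distance_metric!r}")
        if self.tie_break not in ("after", "before"):
            raise ValueError(f"tie_break must be 'after' or 'before', got {self.tie_break!r}")


def load_config(path: str | Path) -> ExtractionConfig:
    """Load an :class:`ExtractionConfig` from YAML, filling gaps with defaults.

    Recognized keys: ``phrases`` (parameter → list of strings), ``ranges``
    (parameter → [min, max]), ``mention_policy``, ``distance_metric``,
    ``tie_break``, ``cross_parameter_suppression``.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    config = ExtractionConfig()
    if "phrases" in raw:
        sets = dict(config.pattern_sets)
        for name, phrases in raw["phrases"].items():
            param = ParameterKind(name)
            sets[param] = PatternSet(param, tuple(phrases))
        config = replace(config, pattern_sets=sets)
    if "ranges" in raw:
        ranges = dict(config.ranges)
        for name, (lo, hi) in raw["ranges"].items():
            param = ParameterKind(name)
            ranges[param] = PlausibilityRange(param, float(lo), float(hi), CANONICAL_UNITS[param])
        config = replace(config, ranges=ranges)
    for key in ("mention_policy", "distance_metric", "tie_break", "cross_parameter_suppression"):
        if key in raw:
            config = replace(config, **{key: raw[key]})
    return config
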