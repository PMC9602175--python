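"""Scoring, reliability and sample-size statistics for the extraction study.

Extraction output is scored against gold labels note-by-note and
parameter-by-parameter.  An extracted value counts as a true positive when
it lies within an absolute tolerance of the gold value (default 0.05 after
unit normalization, absorbing rounding in the note text); a wrong value
counts as a false positive only, so the four cells always partition the
scored note set and accuracy keeps its "over all notes" denominator.

Rater agreement uses Cohen's κ on dichotomized present/absent labels and
the intraclass correlation coefficient ICC(2,1) — two-way random effects,
absolute agreement, single rater — with a 95% confidence interval.  The
ICC model is a declared choice (the consistency form is available via
``icc_type``).  Sample sizing inverts the exact power of the chi-square
test via the noncentral chi-square distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, ncx2

from .model import EXTRACTION_TARGETS, ExtractionRecord, GoldAnnotation, ParameterKind

DEFAULT_TOLERANCE = 0.05


@dataclass(frozen=True)
class ConfusionCounts:
    """Note-level confusion cells for one parameter; cells sum to total."""

    parameter: ParameterKind
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy, precision, recall and F1 for one parameter.

    A metric whose denominator vanishes is ``None`` (reported as
    undefined, never silently zero).
    """

    parameter: ParameterKind
    accuracy: Optional[float]
    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]

    def rounded(self, digits: int = 2) -> dict[str, Optional[float]]:
        return {
            name: (None if v is None else round(v, digits))
            for name, v in [
                ("accuracy", self.accuracy),
                ("precision", self.precision),
                ("recall", self.recall),
                ("f1", self.f1),
            ]
        }


def score_extraction(
    records: Iterable[ExtractionRecord],
    gold: Iterable[GoldAnnotation],
    tolerance: float = DEFAULT_TOLERANCE,
    strict: bool = False,
) -> dict[ParameterKind, ConfusionCounts]:
    """Compare records with gold annotations, one confusion table per parameter.

    Per (note, parameter): TP — extracted and within ``tolerance`` of the
    gold value; FP — extracted but gold absent or value off; FN — gold
    present but nothing extracted; TN — gold absent and nothing extracted.
    Every gold note must appear in the records' note set; with ``strict``
    a record note lacking gold raises instead of being ignored.
    """
    gold = list(gold)
    records = list(records)
    gold_map = {(g.note_id, g.parameter): g for g in gold}
    rec_map = {(r.note_id, r.parameter): r for r in records}
    gold_notes = {g.note_id for g in gold}
    record_notes = {r.note_id for r in records}
    missing = gold_notes - record_notes
    if missing:
        raise ValueError(f"gold notes missing from records: {sorted(missing)[:5]} ...")
    if strict:
        unlabeled = record_notes - gold_notes
        if unlabeled:
            raise ValueError(f"record notes missing gold labels: {sorted(unlabeled)[:5]} ...")

    counts: dict[ParameterKind, ConfusionCounts] = {}
    for param in EXTRACTION_TARGETS:
        tp = fp = fn = tn = 0
        for note_id in sorted(gold_notes):
            g = gold_map.get((note_id, param))
            r = rec_map.get((note_id, param))
            extracted = r is not None and r.status == "extracted"
            present = g is not None and g.present
            if extracted and present and abs(r.value - g.value) <= tolerance:
                tp += 1
            elif extracted:
                fp += 1
            elif present:
                fn += 1
            else:
                tn += 1
        counts[param] = ConfusionCounts(param, tp, fp, fn, tn)
    return counts


def f1_from_precision_recall(precision: float, recall: float) -> Optional[float]:
    """Harmonic mean 2pr/(p+r); undefined when p + r = 0."""
    if precision + recall == 0:
        return None
    return 2 * precision * recall / (precision + recall)


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall and F1 from one confusion table.

    accuracy = (TP+TN)/total, precision = TP/(TP+FP),
    recall = TP/(TP+FN), F1 = 2·p·r/(p+r); a zero denominator makes the
    metric undefined (``None``).
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics over zero notes")
    accuracy = (counts.tp + counts.tn) / counts.total
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else None
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    if precision is None or recall is None:
        f1 = None
    else:
        f1 = f1_from_precision_recall(precision, recall)
    return MetricsReport(counts.parameter, accuracy, precision, recall, f1)


def evaluate_extraction(
    records: Iterable[ExtractionRecord],
    gold: Iterable[GoldAnnotation],
    tolerance: float = DEFAULT_TOLERANCE,
) -> dict[ParameterKind, MetricsReport]:
    """score_extraction then compute_metrics, per parameter."""
    return {p: compute_metrics(c) for p, c in score_extraction(records, gold, tolerance).items()}


# ---------------------------------------------------------------------------
# rater agreement


def make_rater_table(
    gold_a: Iterable[GoldAnnotation],
    gold_b: Iterable[GoldAnnotation],
) -> pd.DataFrame:
    """Join two raters' annotations into a long table.

    Columns: note_id, parameter, rater_a, rater_b (NaN where the rater
    marked the parameter absent).  Both raters must cover the same
    (note, parameter) grid.
    """
    def frame(gold: Iterable[GoldAnnotation], col: str) -> pd.DataFrame:
        rows = [
            {
                "note_id": g.note_id,
                "parameter": g.parameter.value,
                col: g.value if g.present else np.nan,
            }
            for g in gold
        ]
        return pd.DataFrame(rows, columns=["note_id", "parameter", col])

    a, b = frame(gold_a, "rater_a"), frame(gold_b, "rater_b")
    merged = a.merge(b, on=["note_id", "parameter"], how="outer", indicator=True)
    if (merged["_merge"] != "both").any():
        raise ValueError("raters do not cover the same (note, parameter) grid")
    return merged.drop(columns="_merge")


def cohens_kappa(table: pd.DataFrame, parameter: ParameterKind) -> Optional[float]:
    """Chance-corrected present/absent agreement between the two raters.

    Ratings are dichotomized (value recorded vs not); κ = (p_o − p_e) /
    (1 − p_e) on the 2×2 table.  ``None`` when the expected agreement is
    1 (no marginal variation, κ undefined).
    """
    sub = table[table["parameter"] == parameter.value]
    if len(sub) < 2:
        raise ValueError(f"need ≥ 2 notes rated by both raters for {parameter.value}")
    a = sub["rater_a"].notna().to_numpy()
    b = sub["rater_b"].notna().to_numpy()
    return kappa_from_binary(a, b)


def kappa_from_binary(a: np.ndarray, b: np.ndarray) -> Optional[float]:
    """Cohen's κ for two boolean rating vectors."""
    n = len(a)
    p_o = float(np.mean(a == b))
    p_e = float(np.mean(a) * np.mean(b) + (1 - np.mean(a)) * (1 - np.mean(b)))
    if math.isclose(p_e, 1.0):
        return None
    return (p_o - p_e) / (1 - p_e)


def kappa_from_table(table: Sequence[Sequence[int]]) -> Optional[float]:
    """Cohen's κ from a 2×2 agreement table [[both_yes, a_yes_b_no], [a_no_b_yes, both_no]]."""
    (tp, fp), (fn, tn) = table
    n = tp + fp + fn + tn
    p_o = (tp + tn) / n
    a_yes, b_yes = (tp + fp) / n, (tp + fn) / n
    p_e = a_yes * b_yes + (1 - a_yes) * (1 - b_yes)
    if math.isclose(p_e, 1.0):
        return None
    return (p_o - p_e) / (1 - p_e)


@dataclass(frozen=True)
class ICCResult:
    """ICC point estimate with 95% CI; ``truncated`` clips negatives at 0
    for band interpretation only (``icc`` keeps the raw value)."""

    icc: float
    ci95: tuple[float, float]

    @property
    def truncated(self) -> float:
        return max(0.0, self.icc)


def icc_agreement(
    table: pd.DataFrame,
    parameter: ParameterKind,
    icc_type: str = "ICC2",
) -> ICCResult:
    """ICC for the two raters' numeric values on one parameter.

    Default is ICC(2,1): two-way random effects, absolute agreement,
    single rater, with the standard F-based 95% CI.  Pairs where either
    rater recorded no value are dropped.  ``icc_type="ICC3"`` switches to
    the consistency form.
    """
    sub = table[table["parameter"] == parameter.value].dropna(subset=["rater_a", "rater_b"])
    if len(sub) < 2:
        raise ValueError(f"need ≥ 2 complete pairs for {parameter.value}")
    if float(sub[["rater_a", "rater_b"]].to_numpy().std()) == 0:
        raise ValueError("zero total variance: ICC undefined")
    import pingouin as pg

    long = pd.concat(
        [
            pd.DataFrame({"note": sub["note_id"], "rater": "A", "score": sub["rater_a"]}),
            pd.DataFrame({"note": sub["note_id"], "rater": "B", "score": sub["rater_b"]}),
        ],
        ignore_index=True,
    )
    result = pg.intraclass_corr(data=long, targets="note", raters="rater", ratings="score")
    # pingouin labels the absolute-agreement single-rater form ICC2 or
    # ICC(A,1) depending on version; same for the consistency form.
    aliases = {"ICC2": ("ICC2", "ICC(A,1)"), "ICC3": ("ICC3", "ICC(C,1)")}
    if icc_type not in aliases:
        raise ValueError(f"icc_type must be 'ICC2' or 'ICC3', got {icc_type!r}")
    row = result[result["Type"].isin(aliases[icc_type])].iloc[0]
    ci_col = "CI95%" if "CI95%" in result.columns else "CI95"
    lo, hi = row[ci_col]
    return ICCResult(icc=float(row["ICC"]), ci95=(float(lo), float(hi)))


def interpret_icc(icc: float) -> str:
    """Band an ICC as poor (<0.5), moderate (0.5–0.7), good (0.75–0.9) or
    excellent (≥0.9); the conventional bands leave [0.70, 0.75) uncovered,
    which is reported as such rather than guessed."""
    if math.isnan(icc):
        raise ValueError("ICC undefined")
    if icc < 0.5:
        return "poor"
    if icc < 0.70:
        return "moderate"
    if icc < 0.75:
        return "unclassified (paper gap)"
    if icc < 0.9:
        return "good"
    return "excellent"


# ---------------------------------------------------------------------------
# sample size


@dataclass(frozen=True)
class PowerSpec:
    """Chi-square power specification: Cohen's w, alpha, target power, df."""

    effect_size_w: float
    alpha: float
    power: float
    df: int

    def __post_init__(self) -> None:
        if self.effect_size_w <= 0:
            raise ValueError("effect size w must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.df < 1:
            raise ValueError("df must be a positive integer")


def chi_square_power(n: int, spec: PowerSpec) -> float:
    """Exact power of the chi-square test at sample size ``n``.

    The test statistic is noncentral chi-square with noncentrality
    λ = n·w² under the alternative; power is the mass above the central
    (1−α) quantile.
    """
    critical = chi2.ppf(1 - spec.alpha, spec.df)
    return float(ncx2.sf(critical, spec.df, n * spec.effect_size_w**2))


def chi_square_sample_size(spec: PowerSpec, n_max: int = 10**7) -> int:
    """Smallest N whose exact chi-square power reaches the target.

    Power is monotone in N (the noncentrality grows linearly), so a
    bisection over [1, n_max] finds the threshold; unattainable power
    within ``n_max`` raises.
    """
    if chi_square_power(n_max, spec) < spec.power:
        raise ValueError(f"target power {spec.power} unattainable within N ≤ {n_max}")
    lo, hi = 1, n_max
    while lo < hi:
        mid = (lo + hi) // 2
        if chi_square_power(mid, spec) >= spec.power:
            hi = mid
        else:
            lo = mid + 1
    return lo


# ---------------------------------------------------------------------------
# study plumbing


def train_validation_split(
    note_ids: Sequence[str],
    n_train: int = 160,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Seeded partition of note ids into training and validation sets."""
    if n_train > len(note_ids):
        raise ValueError(f"n_train={n_train} exceeds corpus size {len(note_ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(note_ids))
    ids = [note_ids[i] for i in order]
    return sorted(ids[:n_train]), sorted(ids[n_train:])


def merge_gold(*annotation_sets: Iterable[GoldAnnotation]) -> list[GoldAnnotation]:
    """Merge priority-ordered annotation sets into one adjudicated gold.

    The first set naming a (note, parameter) wins — the adjudicator's file
    goes first, the original raters after.
    """
    merged: dict[tuple[str, ParameterKind], GoldAnnotation] = {}
    for annotations in annotation_sets:
        for ann in annotations:
            merged.setdefault((ann.note_id, ann.parameter), ann)
    return sorted(merged.values(), key=lambda g: (g.note_id, g.parameter.value))
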