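# Methods

## The extraction model

`psgminer` treats a PSG note as a sequence of lines, each line a sequence
of sentences and tokens over explicit character spans (0-based, half-open,
into the original body; the text itself is never normalized or rewritten).
Extraction of one parameter from one note is a deterministic five-step
procedure:

1. **Read** — load the note text unchanged (UTF-8, undecodable bytes
   replaced and logged; a crash on one dirty byte in an EMR export is
   unacceptable).
2. **Tokenize** — split on newlines into line spans that cover the body
   exactly; segment sentences within each line on `.!?` followed by
   whitespace. Sentence segmentation is a small regex splitter: PSG
   summary sections are line-oriented and the association step operates
   on lines, so nothing heavier is warranted.
3. **Locate** — find case-insensitive literal matches of the parameter's
   phrase set. Overlapping matches of the same set resolve to the longest
   (ties to the earlier). The default sets are, per parameter:
   TST: *total sleep time, slept for, monitored for, spent for,
   Total Sleep Time (TST)*; SOL: *sleep onset latency, sleep onset,
   latency for, Sleep Onset Latency (SOL)*; SE: *sleep efficiency,
   sleep efficiency for, Sleep Efficiency (SE)*; WASO: *wake after,
   wake time after, total wake, WASO, Wake After Sleep Onset (WASO)*;
   AHI: *apnea hypopnea index, apnea/hypopnea index, AHI for,
   Apnea Hypopnea Index (AHI)*.
4. **Mine** — enumerate numeric candidates on the mention's line:
   integers and decimals with optional sign; `hh:mm` clock times and
   `mm/dd/yyyy` / ISO dates are enumerated but excluded from selection;
   `H hr M min` compounds collapse into one minutes-valued candidate.
   A unit word within the text just after a number (min/minutes,
   hr/hours, %/percent, events per hour) sets its unit hint. The
   candidate chosen is the nearest to the mention — distance is the
   absolute difference of character-span midpoints — whether it precedes
   or follows the phrase. If the nearest candidate fails **validation**
   (unit hint incompatible with the parameter's canonical unit, or
   normalized value outside its plausibility range), the next nearest is
   tried, down the whole line; absence is reported as `not_found`, never
   as an error.
5. **Store** — normalize (hours → minutes for the duration parameters;
   SE stays percent; AHI stays events/hour) and write one CSV row per
   parameter with note id, patient id, visit date, value, unit, status and
   provenance (line index, character span, matched phrase).

### Design choices that were genuinely open

- **Distance metric.** "Nearest" is implemented as character-midpoint
  distance because it is well-defined for multi-token phrases; a
  token-count metric is available via `distance_metric="token"`.
- **Ties.** At exactly equal distance the candidate *after* the mention
  wins, matching the clinical convention "parameter: value"; configurable.
- **Second-nearest rule.** The fallback is validation-driven (unit
  compatibility plus plausibility range) rather than a fixed list of
  special cases, and is capped only by the candidates on the line.
- **Plausibility ranges** (canonical units): TST 0–1440 min, SOL 0–720
  min, WASO 0–720 min, SE 0–100 %, AHI 0–200 events/h. Overridable per
  deployment.
- **Repeated mentions.** The first validated mention in document order
  wins (`mention_policy="first"`): summary blocks typically precede
  narrative repetition. `"last"` is available.
- **Cross-parameter suppression** (default on). A located phrase strictly
  contained in a longer located phrase of a *different* parameter is not
  a mention of the shorter one: in "Wake After Sleep Onset (WASO): 42
  minutes" the inner "Sleep Onset" names WASO's spelled-out form, not
  SOL. Without this rule every spelled-out WASO line would also produce a
  spurious SOL extraction. Note the rule is containment-based: partial
  overlaps (e.g. "wake after" followed by "sleep onset" in running prose)
  are left alone, and genuinely ambiguous prose can still mislead SOL —
  visible as the one SOL false positive in the README example.
- **Locality.** Association never leaves the mention's line; the line is
  the unit the tokenizer hands to the miner, and PSG summary values
  co-occur with their labels on a line.

## Corpus filter and DQI

Inclusion is `LIKE`-semantics throughout (`%` wildcards, case-insensitive,
whole-string): title `%poly%` or `%PSG%`; body `%PSG%` or `%polysomno%`;
body free of `%titrat%` and `%split%`. The DQI then counts seven
documentation components found in the body — TST (`%TST%`,
`%total sleep time%`), SOL (`%SoL%`, `%onset latency%`), SE (`%SE%`,
`%sleep efficiency%`), WASO (`%WASO%`, `%wake after sleep onset%`), REM
(`%REM%`), N1 (`%N1%`), AHI (`%AHI%`, `%apnea%index%`) — and notes scoring
below 4 are dropped. Deliberately, `%SE%` matches the "se" inside "onset":
the index is defined by `LIKE` semantics, and a word-boundary mode exists
only as an opt-in flag. The DQI is computed on the body only (that is what
"documented in the note" is taken to mean); `include_title=True` widens it.
A CPT restriction (95810/95811) applies when codes are present and is
skipped with a warning otherwise. The `%SoL%` pattern is folded
case-insensitively like every other pattern — nothing suggests
case-sensitive matching anywhere in the filter chain.

## Evaluation conventions

- A parameter on a note scores **TP** if extracted within an absolute
  tolerance of the gold value (default 0.05 in canonical units, absorbing
  rendering rounding); **FP** if extracted but wrong or gold-absent; **FN**
  if gold-present but not extracted; **TN** if gold-absent and not
  extracted. A wrong value is FP only — the four cells partition the note
  set, keeping accuracy's "all notes" denominator exact. What counts as a
  "correct" extraction is otherwise undefined in the field; the tolerance
  is configurable.
- Zero-denominator metrics are reported as undefined, never as 0.
- **ICC form:** ICC(2,1), two-way random effects, absolute agreement,
  single rater (computed via pingouin), because both raters score every
  note and rater identity is a random draw from the clinician pool; the
  consistency form ICC(3,1) is one argument away. Band labels: poor
  (<0.5), moderate (0.5–0.7), good (0.75–0.9), excellent (≥0.9); the
  conventional bands leave [0.70, 0.75) uncovered, and values there are
  labelled "unclassified (paper gap)" rather than silently assigned.
- **Sample size:** smallest N with
  1 − F<sub>ncχ²(df, N·w²)</sub>(χ²<sub>1−α, df</sub>) ≥ power, found by
  bisection (power is monotone in N). At w=0.3, α=0.05, power 0.80, df=5
  this gives 143 notes per parameter.
- A seeded 160/40 train/validation split utility and a priority-ordered
  gold-merge (adjudicator file first) support the annotation workflow.

## The synthetic corpus

The generator emulates the documentation variability that drives
extraction error on real reports: five phrasing templates per parameter
(canonical `Total Sleep Time (TST): 391.5 minutes.`; abbreviated; value
first — "the quantity precedes the phrase"; narrative; distractor-rich
with clock times, dates and stage percentages sharing lines), a
`repeated_mention` stress template that adds a later conflicting
narrative value, split-night notes carrying titration vocabulary, and
low-DQI notes documenting only TST and AHI. Default study conditions:
200 notes, template mix canonical 0.30 / abbreviated 0.20 / value-first
0.15 / narrative 0.15 / distractor-rich 0.20, split-night rate 0.05,
low-DQI rate 0.05, per-parameter missing rate 0.05. Values are drawn
uniformly per parameter (TST 180–540 min, SOL 2–120 min, SE 50–99 %,
WASO 5–180 min, AHI 0–120 events/h — ordinary adult sleep-lab ranges),
rendered with 0 or 1 decimals per note to exercise tolerance matching; a
`coherent_se` flag derives SE from TST/(TST+SOL+WASO) instead. Every
random draw flows through one `numpy` generator seeded from the config,
so corpora are byte-reproducible, and the manifest records the realized
per-stratum counts.

What it does **not** emulate: misspellings, OCR noise, section
boilerplate, negation ("sleep onset latency could not be determined"),
multi-study notes, or institution-specific templates. Perfect scores on
the canonical-template corpus therefore certify the pipeline mechanics,
not performance on arbitrary real-world text; the mixed-template corpus
probes robustness only within the phrase inventory above.

## Numerical and degenerate-input notes

- Empty bodies tokenize to zero lines and extract to five `not_found`
  records; empty corpora produce header-only CSVs.
- All offsets are 0-based half-open; a token's span re-slices the body to
  the token text exactly (property-tested).
- Record values are written with at most 2 decimals (clinical reporting
  granularity); round-tripping a record file reproduces the collection
  field-for-field.
- κ is undefined (reported as such) when expected agreement is 1; ICC is
  undefined at zero total variance; negative ICC point estimates are kept
  raw and clipped at 0 only for band interpretation.

## Known limitations

- Phrase sets are literal strings, not regular-expression grammars;
  formats outside the inventory (e.g. "TST=391.5") need config additions.
- No negation or hedge handling: "sleep efficiency was not assessed 85%
  of nights" would extract.
- Association never crosses lines, so a value on the following line
  ("Total sleep time:\n391.5") is missed by design.
- Notes are processed independently; duplicate notes per patient-visit
  are not deduplicated.
- The problem sizes used in the test suite (200-note corpora, 500
  simulation replicates) were chosen to make the statistical assertions
  stable at comfortable margins.
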