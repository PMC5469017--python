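# Methods notes

This note records how `echopairs` models the extraction problem, the
parameters that matter, what the synthetic data does and does not emulate,
and the design choices made where more than one reasonable option existed.

## Problem model

A *measurement-value pair* links a standardized measurement concept (one of
27 cardiac structure/function targets, e.g. left ventricular ejection
fraction, left ventricular dimension at end diastole, aortic valve
stenosis) to a value found in text: a number or numeric range with an
optional unit, or an ordered qualitative severity grade. Extraction is
deliberately rule-based and precision-first: echocardiogram reporting is a
narrow sublanguage in which a small set of co-occurrence patterns covers
nearly all measurement statements, and deterministic rules behave
predictably across report templates from different sites.

The concept inventory, term dictionary, anatomy/measure word lexicon,
mutual-exclusion constraints, unit table, qualitative grade scale, and the
38 linking rules are all curated data files under
`src/echopairs/resources/`, not code. Two of the 27 concepts (aortic valve
regurgitation peak velocity, tricuspid valve orifice area) are clinically
rare; they are fully supported but down-weighted in the synthetic
generator.

## Term recognition and mapping

* **Normalization.** All dictionary comparisons use lower-case text with
  whitespace collapsed and spaces around `/` removed, so `LV  EF`, `lv ef`
  and `E / e'` have stable normal forms. Phrase regexes tolerate
  whitespace/hyphen variation inside a term but never cross a line break —
  the line is the semi-structured unit, and allowing wrap-around merges
  would risk gluing unrelated column fragments together.
* **Token boundaries.** Matches must start and end at transitions between
  alphanumeric and non-alphanumeric text (`relief` does not contain the
  term `ef`); `/` and `'` are treated as term-internal so `e/e'` matches
  whole.
* **Concept builder.** Consecutive anatomy/measure words separated only by
  connectors (whitespace, hyphen, slash, *of/the/at/a/an*) merge into a
  candidate term. A run must contain at least one anatomy and one measure
  word and at most 8 categorized words; the cap prevents runaway merging
  across clauses. The builder runs on every document because curation can
  never enumerate all phrase variants in advance.
* **Scoring.** Token-overlap scores count *distinct* query tokens (a
  repeated token counts once) and ignore the connective stop tokens
  *of/the/at/a/an/to/and*, which would otherwise create spurious overlap.
  Ties at the maximum are reported ambiguous and produce no output pair;
  given the precision-first goal, discarding a coin-flip mapping is cheaper
  than a wrong one.
* **Constraints.** Mutual exclusions are declared between word-level
  semantic groups (atrium–ventricle, atrium–mitral, atrium–tricuspid,
  volume–dimension, volume–velocity, volume–pressure, plus curated extras
  such as diastole–systole and max–mean, which separate the end-systolic
  from end-diastolic dimension concepts and peak from mean gradients). A
  concept's groups come from its declared tags in `concepts.csv`, not from
  re-deriving them at runtime, so curators control exactly what a
  constraint can discard. Constraints apply uniformly to exact and partial
  matches.

## Value recognition

* Quantities are period-decimal only (US clinical convention). A unit
  attaches to a number when it starts within 2 characters (`16mm`,
  `45-50 %`); unit variants resolve longest-first so `mmHg` is never read
  as `mm`.
* Guards: a number adjacent to `/digit` (blood pressures, dates, fractions)
  or `:digit` (times) is not a standalone value. A number running directly
  into letters that are not a unit (`40mg`) is rejected.
* Range merging is left-greedy and only ever joins two *point* mentions of
  the same kind, so a chain `40 - 45 - 50` deterministically yields the
  range 40–45 plus the point 50, and mixed quantitative/qualitative ranges
  never form. The merged unit is the right endpoint's when present (ranges
  are usually written `50-55%`), else the left's.
* Qualitative grades carry integer ranks (normal/preserved/hyperdynamic 0,
  trace/trivial/borderline 1, low/reduced/depressed/mild 2, moderate 3,
  moderately severe 4, severe 5). Ranks exist to order range endpoints
  ("low to moderate" → 2–3); they are not clinical equivalences. Compound
  grades are handled by range merging rather than by compound lexicon
  entries.

## Relation linking

The 38 shipped rules realize the dominant slot template crossed with the
observed variation: {`=`, `:`, bare whitespace column} × {point, range} ×
{unit attached, detached, absent} for line-scoped quantitative statements;
the same value/unit crossing for sentence-scoped verb-phrase narrative; a
parenthesized-value variant; and qualitative rules for grade-after-term,
grade-before-term, grade-within-term (the head and tail of the split phrase
are re-mapped as one concatenated candidate), and line-scoped qualitative
columns. Rule semantics live in `patterns.cfg`; the engine only knows the
slot vocabulary and separator classes.

Matching is nearest-first with no intervening term allowed between the term
and its value, `max_gap` defaults to 40 characters (25 for bare-column
rules, which are the least anchored), and every mention is consumed by at
most one pair. When two terms flank a value, the term-first scan gives the
nearest preceding term priority; a value that cannot be licensed by any
rule is simply dropped. Unit–concept incompatibility (e.g. an orifice area
reported in `cm`) flags the pair rather than dropping it by default
(`--unit-mismatch drop` reverses this), since such statements are usually
transcription shorthand rather than extraction errors.

## Synthetic data

The generator emulates the *structural* phenomena the extractor must
survive: semi-structured blocks (one `TERM sep value unit` statement per
line, separators `=`/`:`), narrative sentences in all supported qualitative
positions and verb phrases, mixed reports whose interpretation section
restates a tabulated pair (gold-marked `is_repeated`), term-variant
sampling from the dictionary, single-character misspellings of term words
(never digits), and distractor lines (demographics, dates, rhythm
statements, heart rates). LVEF appears in every document and is therefore
the modal concept, matching its dominance in real reports; other concepts
are sampled with curated weights. Per-concept plausible value ranges
(LVEF 15–75%, LVEDD 35–70 mm, TR velocity 1.5–4.5 m/s, …) are generator
metadata only — extraction never range-checks values.

The generator does **not** emulate: split terms interleaved with other
mentions, negation/hedging/temporality, cross-line wrap-around, OCR noise,
or the lexical diversity of free dictation. Perfect scores on noise-free
synthetic corpora therefore demonstrate internal consistency of the
pipeline and its resources, not expected performance on clinical text.
Misspelling noise is applied from a random stream separate from content
generation, so raising the noise level perturbs a superset of the same
terms — which is what makes recall-vs-noise comparisons meaningful at a
fixed seed.

## Evaluation

Scoring is pair-level: a prediction is a true positive when document,
concept and both value endpoints match an unclaimed gold annotation
(endpoint equality is exact — values are transcribed, not computed — and
the unit is checked only when gold specifies one). Degenerate zero
denominators define the metric as 0. `recall_collapsed` removes from the
false negatives any missed annotation whose (concept, value) was correctly
extracted elsewhere in the same document, the appropriate reading when a
report restates a measurement it has already tabulated; both recall
variants are always computed.

## Problem sizes and determinism

Test-suite corpora use 60–100 documents, which is ample to exercise every
template, rule, and noise path the generator owns; extraction runs at
thousands of lines per second so the whole suite completes in seconds. All
randomness is seeded (generator documents are a pure function of
`(seed, doc_index)`), extraction is fully deterministic, and re-running any
command with the same inputs reproduces byte-identical outputs.

## Known limitations

* Split-term statements (term words interleaved with other terms or
  values) are out of scope by design and are the main real-world recall
  cost of this architecture.
* The dictionary ships with a curated but modest variant list per concept;
  real deployments are expected to grow it through the
  `bootstrap` → curate → `merge-candidates` loop.
* Qualitative ranks are ordinal within a concept's grading convention;
  comparing ranks across concepts is not meaningful.
* No unit conversion: values are reported as written (`4.9 cm` is not
  normalized to `49 mm`), so downstream harmonization is the consumer's
  responsibility.
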