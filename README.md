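# echopairs

Rule-based extraction of **measurement-value pairs** from echocardiogram-style
clinical text.

Echocardiography reports record the numbers cardiologists and heart-failure
researchers care about — left ventricular ejection fraction (LVEF), chamber
dimensions, valve gradients and orifice areas, regurgitation and stenosis
severity — but they record them as free text: sometimes a semi-structured
measurement block (`LVEF = 55%`, one statement per line), sometimes narrative
prose ("The ejection fraction was visually estimated in a range of 50 to
55%"), and often both in the same report. `echopairs` turns that text into
structured records *(document, concept, value, unit, provenance span)* for a
fixed inventory of 27 standardized cardiac structure/function concepts. It is
aimed at clinical-NLP practitioners and cardiovascular epidemiologists who
need high-precision measurement retrieval from report text, and at anyone who
wants a fully testable reference implementation of this extraction style.

## Method

The pipeline runs four stages per document:

1. **Term recognition.** Complete-phrase regexes over a curated term
   dictionary, abbreviation regexes (`LVEF`, `LVIDd`, `e/e'`, …), and a
   *concept builder* that merges consecutive anatomy- and measure-category
   words ("dimension of the left ventricle at the end of diastole") into new
   candidate terms that need not appear in the dictionary verbatim.
   Overlapping candidates resolve longest-first.
2. **Concept mapping.** Two-step lookup: exact dictionary match first;
   otherwise each concept *c* is scored by token overlap,

   `score(c) = |{distinct query tokens that appear in some dictionary surface of c}|`,

   and the strict maximum wins (ties are ambiguous and discarded). Before
   ranking, **semantic constraints** — mutual-exclusion pairs between word
   groups — prune wrong candidates: a phrase containing *atrial* cannot map
   to a ventricular/mitral/tricuspid concept; a phrase containing *volume*
   cannot map to a dimension/velocity/pressure concept.
3. **Value recognition.** Quantitative values (integers/decimals with
   optional attached unit) and qualitative severity grades (*normal* … 
   *severe*, integer-ranked), with adjacent points merged into ranges
   (`50-55%`, "low to moderate") and context guards against blood pressures,
   dates and times (`120/80`, `03/04/2015`, `12:30`).
4. **Relation linking.** 38 co-occurrence pattern rules over the slot
   template `<Term><separating string><Value><Unit>` license a link:
   semi-structured separators (`=`, `:`, bare column) scoped to a line,
   narrative verb phrases ("is", "was measured at", "was visually estimated
   in a range of") scoped to a sentence, and qualitative variants where the
   grade precedes the term ("mild aortic stenosis") or splits it ("the
   aortic valve has mild stenosis"). Each mention participates in at most
   one pair.

A synthetic report generator emulates the three source formats with exact
gold annotations, and an evaluation harness computes precision/recall/F1
per concept and overall, including a recall variant that does not penalize
missed *repeated mentions* (the same pair restated elsewhere in the report).

## Worked example

```python
from echopairs import load_resources, extract_document

resources = load_resources()
report = """ECHOCARDIOGRAM REPORT
LVEF = 55%
LVEDD: 49mm
The ejection fraction was visually estimated in a range of 50 to 55%.
There is mild mitral regurgitation.
"""
for p in extract_document(report, resources):
    print(f"{p.concept_id:45s} {p.value.low!s:>5} {p.value.high!s:>5} "
          f"{p.value.kind.value:5s} {p.unit_id or '-':8s} rule={p.rule_id} line={p.line_number}")
```

prints

```
left_ventricular_ejection_fraction               55    55 QUANT percent  rule=q02 line=2
left_ventricular_dimension_end_diastole          49    49 QUANT mm       rule=q08 line=3
left_ventricular_ejection_fraction               50    55 QUANT percent  rule=n19 line=4
mitral_valve_regurgitation                        2     2 QUAL  -        rule=v36 line=5
```

Each row is one measurement-value pair: the LVEF stated twice (once in the
measurement block, once as a narrative range 50–55%), the end-diastolic
dimension in mm, and a qualitative mitral-regurgitation grade (rank 2 =
"mild" on the shipped severity scale).

The same workflow is available from the shell:

```bash
echopairs generate --seed 5 --n 100 --out run/          # synthetic corpus + gold
echopairs extract  --in run/corpus.jsonl --out run/pred.csv
echopairs evaluate --pred run/pred.csv --gold run/gold.csv --collapse-repeated
echopairs bootstrap --in run/corpus.jsonl --out run/candidates.csv
echopairs validate-resources
```

## Layout

```
src/echopairs/
  lexicon.py            # concepts, dictionary, word/unit/grade tables, constraints
  term_recognition.py   # phrase + abbreviation matching, concept builder
  concept_mapping.py    # exact match, token-overlap scoring, disambiguation
  value_recognition.py  # quantities, grades, units, range merging
  relation_linking.py   # pattern rules and the extraction pipeline
  corpus_tools.py       # corpus IO, filters, harvesting, evaluation
  synthetic.py          # synthetic report generator with gold annotations
  cli.py                # command-line interface
  resources/            # shipped curated tables (all plain CSV/text)
docs/methods.md         # modelling notes, parameter choices, limitations
```
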