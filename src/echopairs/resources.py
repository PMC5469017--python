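"""Loading and bundling of the shipped (or user-supplied) resource files."""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from .lexicon import (
    Concept,
    ConstraintSet,
    QualLexicon,
    TermEntry,
    UnitTable,
    WordLexicon,
    load_concepts,
    load_constraints,
    load_dictionary,
    load_qualitative,
    load_units,
    load_word_lexicon,
    validate_resources,
)
from .relation_linking import PatternRule, load_patterns

_RESOURCE_DIR = Path(__file__).parent / "resources"

FILENAMES = {
    "concepts": "concepts.csv",
    "dictionary": "dictionary.csv",
    "words": "words.csv",
    "constraints": "constraints.csv",
    "units": "units.csv",
    "qualitative": "qualitative.csv",
    "patterns": "patterns.cfg",
    "abbreviations": "abbreviations.txt",
}


def default_resource_path(name: str) -> Path:
    return _RESOURCE_DIR / name


def load_abbreviations(path: str | Path) -> list[str]:
    """One regex per line; comments and blanks skipped."""
    out = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if line and not line.startswith("#"):
            re.compile(line)  # fail fast on a bad pattern
            out.append(line)
    return out


@dataclass
class ResourceBundle:
    concepts: list[Concept]
    entries: list[TermEntry]
    lexicon: WordLexicon
    constraints: ConstraintSet
    units: UnitTable
    qualitative: QualLexicon
    patterns: list[PatternRule]
    abbreviations: list[str]
    concept_map: dict[str, Concept] = field(init=False)
    abbreviation_patterns: list[re.Pattern] = field(init=False)

    def __post_init__(self):
        self.concept_map = {c.concept_id: c for c in self.concepts}
        self.abbreviation_patterns = [
            re.compile(rf"(?<![A-Za-z0-9])(?:{p})(?![A-Za-z0-9])", re.IGNORECASE)
            for p in self.abbreviations
        ]

    def validate(self):
        return validate_resources(
            self.entries, self.concepts, self.lexicon, self.constraints, self.units
        )


def load_resources(directory: str | Path | None = None) -> ResourceBundle:
    """Load a full bundle from *directory* (default: the shipped resources)."""
    d = Path(directory) if directory is not None else _RESOURCE_DIR
    concepts = load_concepts(d / FILENAMES["concepts"])
    entries, concepts = load_dictionary(d / FILENAMES["dictionary"], concepts)
    return ResourceBundle(
        concepts=concepts,
        entries=entries,
        lexicon=load_word_lexicon(d / FILENAMES["words"]),
        constraints=load_constraints(d / FILENAMES["constraints"]),
        units=load_units(d / FILENAMES["units"]),
        qualitative=load_qualitative(d / FILENAMES["qualitative"]),
        patterns=load_patterns(d / FILENAMES["patterns"]),
        abbreviations=load_abbreviations(d / FILENAMES["abbreviations"]),
    )
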