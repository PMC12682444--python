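"""Classify local species-uses against the literature.

Each species' locally documented uses are compared with the uses reported
for it in prior studies: a species with no literature record at all is a
*novel* use; one whose literature uses, once normalized onto the ailment
vocabulary, share at least one category with the local uses is
*corroborated*; a species reported in the literature but only for other
purposes is *divergent*.

Term matching is done with a keyword lexicon that folds free-text
literature phrases ("treating gastritis in horses", "endo- and
ectoparasitic") onto the ailment-category vocabulary.  Whether two folk
disease labels denote "the same" use is ultimately a judgment call; the
packaged reference labels beyond the three unambiguous textbook cases are
therefore marked provisional, and :func:`classify_reference_uses` emits a
diff between the lexicon-driven matcher and the packaged labels rather
than hiding disagreements.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .indices import round_half_up
from .survey_data import (
    LiteratureUse,
    ValidationError,
    load_reference_table,
    load_species_registry,
    normalize_category,
    resolve_species_name,
)

LABELS = ("novel", "divergent", "corroborated")

#: Ordered (keyword, category) lexicon; the first keyword contained in a
#: lowercased literature phrase decides its category.  Bone-setting folk
#: terms (bruises, dislocations, strains) fold into "fractures"; internal
#: parasites into "digestive"; skin parasites into "scabies"; wound-family
#: terms into "infected wound".  Phrases matching nothing are recorded as
#: unmatched, never silently dropped.
LITERATURE_LEXICON: tuple[tuple[str, str], ...] = (
    ("worm", "digestive"),
    ("larva", "digestive"),
    ("parasit", "digestive"),
    ("diarrh", "digestive"),
    ("bloat", "digestive"),
    ("gastr", "digestive"),
    ("intestin", "digestive"),
    ("enterit", "digestive"),
    ("indigest", "digestive"),
    ("stomach", "digestive"),
    ("colic", "digestive"),
    ("constipat", "digestive"),
    ("dysenter", "digestive"),
    ("ulcer", "digestive"),
    ("flatulen", "digestive"),
    ("abdominal", "digestive"),
    ("vomit", "digestive"),
    ("poison", "digestive"),
    ("joint pain", "muscle and joint pain"),
    ("musculoskeletal", "muscle and joint pain"),
    ("arthrit", "muscle and joint pain"),
    ("muscle", "muscle and joint pain"),
    ("dislocat", "fractures"),
    ("bruise", "fractures"),
    ("strain", "fractures"),
    ("fracture", "fractures"),
    ("cough", "respiratory"),
    ("bronchit", "respiratory"),
    ("asthma", "respiratory"),
    ("respirat", "respiratory"),
    ("flu", "respiratory"),
    ("mange", "scabies"),
    ("tick", "scabies"),
    ("scabies", "scabies"),
    ("leishmania", "scabies"),
    ("skin", "scabies"),
    ("wound", "infected wound"),
    ("proud flesh", "infected wound"),
    ("dermatolog", "infected wound"),
    ("mastitis", "udder problems"),
    ("lactation", "increasing milk production"),
    ("milk", "increasing milk production"),
    ("nosebleed", "epistaxis"),
    ("epistax", "epistaxis"),
    ("fever", "fever"),
    ("uterus", "lambing"),
    ("prolapse", "lambing"),
    ("urinar", "urinary retention"),
)


def normalize_literature_term(
    term: str,
    lexicon: Sequence[tuple[str, str]] = LITERATURE_LEXICON,
) -> Optional[str]:
    """Map one literature phrase to an ailment category, or None."""
    text = str(term).strip().lower()
    for keyword, category in lexicon:
        if keyword in text:
            return category
    return None


@dataclass(frozen=True)
class UseClassification:
    species_id: str
    label: str
    matched_terms: tuple[str, ...] = ()
    unmatched_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValidationError(f"label must be one of {LABELS}")
        if self.label == "corroborated" and not self.matched_terms:
            raise ValidationError("a corroborated call needs a matched term")


def classify(
    species_id: str,
    local_categories: Iterable[str],
    literature: Sequence[LiteratureUse],
    lexicon: Sequence[tuple[str, str]] = LITERATURE_LEXICON,
) -> UseClassification:
    """Label one species-use as novel, divergent or corroborated.

    Empty literature is novel by definition.  Otherwise each literature
    phrase is normalized onto the category vocabulary; any overlap with
    the local categories corroborates the use, no overlap makes it
    divergent.  Unmappable phrases are carried in ``unmatched_terms``.
    """
    local = {normalize_category(c) for c in local_categories}
    if not literature:
        return UseClassification(species_id=species_id, label="novel")
    matched, unmatched = [], []
    for entry in literature:
        category = normalize_literature_term(entry.reported_use, lexicon)
        if category is None:
            unmatched.append(entry.reported_use)
        elif category in local:
            matched.append(entry.reported_use)
    label = "corroborated" if matched else "divergent"
    return UseClassification(
        species_id=species_id,
        label=label,
        matched_terms=tuple(matched),
        unmatched_terms=tuple(unmatched),
    )


def summarize_classifications(
    classifications: Sequence[UseClassification],
    total_uses: Optional[int] = None,
) -> pd.DataFrame:
    """Counts and integer percentages (half-up) per label."""
    total = total_uses if total_uses is not None else len(classifications)
    if total <= 0:
        raise ValidationError("total_uses must be positive")
    counts = Counter(c.label for c in classifications)
    return pd.DataFrame(
        [
            {
                "label": label,
                "count": counts.get(label, 0),
                "percent": int(round_half_up(100.0 * counts.get(label, 0) / total)),
            }
            for label in LABELS
        ]
    )


def classify_reference_uses(
    lexicon: Sequence[tuple[str, str]] = LITERATURE_LEXICON,
) -> pd.DataFrame:
    """Run the matcher over the packaged reference use table.

    Returns one row per documented species-use with the matcher's label,
    the packaged label (the study's own categorization, provisional beyond
    the three discussed examples) and an ``agrees`` flag — a diff, not a
    silent override.
    """
    registry = load_species_registry()
    df = load_reference_table("species_uses")
    rows = []
    for row in df.itertuples(index=False):
        sid = resolve_species_name(row.species, registry)
        local = [c.strip() for c in str(row.local_categories).split(";") if c.strip()]
        literature = [
            LiteratureUse(species_id=sid, reported_use=t.strip())
            for t in str(row.literature_terms).split(";")
            if t.strip()
        ]
        result = classify(sid, local, literature, lexicon)
        rows.append(
            {
                "species_id": sid,
                "species": row.species,
                "use_description": row.use_description,
                "matcher_label": result.label,
                "reference_label": row.label,
                "provisional": str(row.provisional).lower() in ("yes", "true", "1"),
                "agrees": result.label == row.label,
                "matched_terms": "; ".join(result.matched_terms),
                "unmatched_terms": "; ".join(result.unmatched_terms),
            }
        )
    return pd.DataFrame(rows)
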