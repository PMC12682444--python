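"""Data model and I/O for informant use-report surveys.

The atomic datum of a quantitative ethnobotany survey is the *use report*:
one informant citing one plant species for one ailment category.  A survey
is a set of such reports plus the total number of informants interviewed
(``N``), which is the denominator of every per-informant index (UV, RFC,
CI).  This module defines the record types, long-format CSV input/output,
the canonical species registry with synonym resolution, the ailment-category
vocabulary, and loaders for the packaged reference tables of a published
ethnoveterinary survey from southern Fars, Iran (200 informants in 27
communities, 31 species, 15 ailment categories).
"""

from __future__ import annotations

import hashlib
import io
import logging
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

log = logging.getLogger("ethnosurvey")

ROUTES = ("oral", "topical", "nasal", "vapor")

#: The 15 canonical ailment-category labels of the reference survey,
#: stored lowercase.  User-facing free text is mapped onto these through
#: :data:`CATEGORY_ALIASES`.
CATEGORIES = (
    "animal bite",
    "digestive",
    "epistaxis",
    "fever",
    "fractures",
    "grass tetany",
    "increasing milk production",
    "infected wound",
    "lambing",
    "muscle and joint pain",
    "respiratory",
    "scabies",
    "udder problems",
    "urinary retention",
    "weaning",
)

#: Free-text ailment phrases that fold into the canonical vocabulary.
CATEGORY_ALIASES = {
    "diarrhea": "digestive",
    "diarrhoea": "digestive",
    "poisoning": "digestive",
    "intestinal worms": "digestive",
    "parasites": "digestive",
    "gastrointestinal": "digestive",
    "muscular pain": "muscle and joint pain",
    "muscle pain": "muscle and joint pain",
    "joint pain": "muscle and joint pain",
    "muscle stiffness": "muscle and joint pain",
    "muscle cramps": "muscle and joint pain",
    "nosebleed": "epistaxis",
    "nosebleeding": "epistaxis",
    "cough": "respiratory",
    "weaning livestock": "weaning",
    "infected wounds": "infected wound",
    "wound healing": "infected wound",
    "animal bites": "animal bite",
    "fracture": "fractures",
    "urinary": "urinary retention",
    "udder": "udder problems",
    "milk production": "increasing milk production",
    "lactation": "increasing milk production",
}


class FormatError(ValueError):
    """Malformed input file (missing columns, bad values)."""


class ValidationError(ValueError):
    """Input that parses but violates a dataset invariant."""


class IntegrityError(RuntimeError):
    """A packaged reference table does not match its recorded fingerprint."""


class AmbiguousSpeciesError(KeyError):
    """A name (e.g. 'Ziziphus sp.') matches more than one registered species."""

    def __init__(self, name: str, candidates: Sequence[str]):
        super().__init__(name)
        self.name = name
        self.candidates = tuple(candidates)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.name!r} is ambiguous between {', '.join(self.candidates)}"


def normalize_category(label: str, strict: bool = False) -> str:
    """Map a free-text ailment phrase onto the category vocabulary.

    Unknown labels pass through lowercased (surveys are not limited to the
    reference vocabulary) unless ``strict`` is set.
    """
    key = " ".join(str(label).strip().lower().split())
    if key in CATEGORIES:
        return key
    if key in CATEGORY_ALIASES:
        return CATEGORY_ALIASES[key]
    if strict:
        raise ValidationError(f"unknown ailment category: {label!r}")
    return key


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class UseRecord:
    """One informant citing one species for one ailment category.

    The (informant, species, category) triple is the identity of a record:
    an informant describing several preparations of the same species for the
    same ailment still contributes a single report.  This is the only
    counting convention under which the cultural-importance index equals the
    use value for every species, as it does in the reference survey.
    """

    informant_id: str
    species_id: str
    category_id: str
    plant_part: Optional[str] = None
    preparation: Optional[str] = None
    route: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("informant_id", "species_id", "category_id"):
            if not str(getattr(self, name)).strip():
                raise ValidationError(f"{name} must be non-empty")
        if self.route is not None and self.route not in ROUTES:
            raise ValidationError(
                f"route must be one of {ROUTES}, got {self.route!r}"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.informant_id, self.species_id, self.category_id)


@dataclass(frozen=True)
class SpeciesInfo:
    """Registry entry: canonical name, family and known synonyms."""

    species_id: str
    accepted_name: str
    family: str
    synonyms: tuple[str, ...] = ()
    voucher: Optional[str] = None


@dataclass(frozen=True)
class LiteratureUse:
    """A previously reported use of a species, from the literature review."""

    species_id: str
    reported_use: str
    source_tag: str = ""


@dataclass
class SurveyDataset:
    """A deduplicated set of use reports plus the total informant count.

    ``n_informants`` counts everyone interviewed, not only informants who
    contributed a veterinary citation; the reference survey interviewed 200
    informants of whom fewer appear in the use-report records.
    """

    records: tuple[UseRecord, ...]
    n_informants: int

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str, str], UseRecord] = {}
        dupes = 0
        for rec in self.records:
            if rec.key in seen:
                dupes += 1
            else:
                seen[rec.key] = rec
        if dupes:
            log.warning("collapsed %d duplicate use-report triple(s)", dupes)
        self.records = tuple(seen.values())
        if self.n_informants <= 0:
            raise ValidationError("n_informants must be positive")
        distinct = len({r.informant_id for r in self.records})
        if self.n_informants < distinct:
            raise ValidationError(
                f"n_informants={self.n_informants} is smaller than the "
                f"{distinct} distinct informants present in the records"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(sorted({r.species_id for r in self.records}))

    @property
    def category_ids(self) -> tuple[str, ...]:
        return tuple(sorted({r.category_id for r in self.records}))

    def to_frame(self) -> pd.DataFrame:
        """Long-format view, one row per use report."""
        return pd.DataFrame(
            [
                {
                    "informant_id": r.informant_id,
                    "species_id": r.species_id,
                    "category_id": r.category_id,
                    "plant_part": r.plant_part,
                    "preparation": r.preparation,
                    "route": r.route,
                }
                for r in sorted(self.records)
            ],
            columns=[
                "informant_id",
                "species_id",
                "category_id",
                "plant_part",
                "preparation",
                "route",
            ],
        )


# ---------------------------------------------------------------------------
# Species registry and synonym resolution
# ---------------------------------------------------------------------------

#: Names that deliberately resolve to more than one species.  The reference
#: choice-value table prints "Ziziphus sp." for a value consistent with
#: either Ziziphus species; the registry records the ambiguity instead of
#: guessing.
AMBIGUOUS_NAMES = {
    "ziziphus sp": ("ziziphus-nummularia", "ziziphus-spina-christi"),
}


def _normalize_name(name: str) -> str:
    s = unicodedata.normalize("NFKC", str(name))
    s = s.replace("*", "").replace("×", "x")
    s = " ".join(s.split()).strip().lower()
    return s.rstrip(".")


def load_species_registry() -> dict[str, SpeciesInfo]:
    """Load the packaged registry of the 31 reference species."""
    df = load_reference_table("species")
    registry: dict[str, SpeciesInfo] = {}
    for row in df.itertuples(index=False):
        synonyms = tuple(
            s.strip() for s in str(row.synonyms or "").split("|") if s.strip()
        )
        registry[row.species_id] = SpeciesInfo(
            species_id=row.species_id,
            accepted_name=row.accepted_name,
            family=row.family,
            synonyms=synonyms,
            voucher=(str(row.voucher) if str(row.voucher) else None),
        )
    return registry


def _name_index(registry: Mapping[str, SpeciesInfo]) -> dict[str, str]:
    index: dict[str, str] = {}
    for info in registry.values():
        for name in (info.accepted_name, *info.synonyms):
            index[_normalize_name(name)] = info.species_id
    return index


def resolve_species_name(
    name: str,
    registry: Optional[Mapping[str, SpeciesInfo]] = None,
    strict: bool = True,
) -> str:
    """Resolve a printed species name to its canonical ``species_id``.

    Handles exact canonical names, registered synonyms (e.g. *Amygdalus
    lycioides* for *Prunus eburnea*) and genus-initial abbreviations as
    printed in index tables ("A. lycioides Spach", "T. undulata (Sm.)
    Seem").  Raises :class:`AmbiguousSpeciesError` for names registered as
    ambiguous.  Unknown names raise ``KeyError`` when ``strict`` else pass
    through as a slug, so user surveys may contain unregistered species.
    """
    if registry is None:
        registry = load_species_registry()
    if name in registry:  # already an id
        return name
    norm = _normalize_name(name)
    if norm in AMBIGUOUS_NAMES:
        raise AmbiguousSpeciesError(name, AMBIGUOUS_NAMES[norm])
    index = _name_index(registry)
    if norm in index:
        return index[norm]
    # genus-initial abbreviation: "a. lycioides spach" vs "amygdalus ..."
    m = re.match(r"^([a-z])\.\s+(.+)$", norm)
    if m:
        initial, tail = m.group(1), m.group(2)
        hits = set()
        for full, sid in index.items():
            parts = full.split(" ", 1)
            if len(parts) == 2 and parts[0][0] == initial and parts[1] == tail:
                hits.add(sid)
        if len(hits) == 1:
            return hits.pop()
        if len(hits) > 1:
            raise AmbiguousSpeciesError(name, sorted(hits))
    if strict:
        raise KeyError(f"unknown species name: {name!r}")
    return re.sub(r"[^a-z0-9]+", "-", norm).strip("-")


# ---------------------------------------------------------------------------
# Long-format survey CSV I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("informant", "species", "category")


def read_survey(
    source: Union[str, Path, IO[str]],
    n_informants: Optional[int] = None,
    config: Optional[Union[str, Path, Mapping]] = None,
    registry: Optional[Mapping[str, SpeciesInfo]] = None,
) -> SurveyDataset:
    """Read a long-format survey CSV into a :class:`SurveyDataset`.

    The file needs at least ``informant``, ``species`` and ``category``
    columns; ``plant_part``, ``preparation`` and ``route`` are carried when
    present.  ``n_informants`` comes from the argument or from a YAML
    sidecar config (key ``n_informants``); duplicated triples collapse with
    a warning; species names are resolved through the registry synonyms
    before keying, unknown names are slugged as-is.
    """
    if config is not None:
        if isinstance(config, (str, Path)):
            with open(config, "r", encoding="utf-8") as fh:
                config = yaml.safe_load(fh) or {}
        if n_informants is None:
            n_informants = config.get("n_informants")
    if n_informants is None:
        raise ValidationError(
            "n_informants must be supplied (argument or sidecar config)"
        )
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"survey CSV is missing column(s): {missing}")
    if registry is None:
        registry = load_species_registry()
    records = []
    for row in df.itertuples(index=False):
        species = str(row.species)
        try:
            sid = resolve_species_name(species, registry, strict=False)
        except AmbiguousSpeciesError:
            log.warning("keeping ambiguous species name %r verbatim", species)
            sid = re.sub(r"[^a-z0-9]+", "-", _normalize_name(species)).strip("-")
        records.append(
            UseRecord(
                informant_id=str(row.informant),
                species_id=sid,
                category_id=normalize_category(str(row.category)),
                plant_part=(getattr(row, "plant_part", "") or None),
                preparation=(getattr(row, "preparation", "") or None),
                route=(getattr(row, "route", "") or None),
            )
        )
    return SurveyDataset(records=tuple(records), n_informants=int(n_informants))


def write_survey(dataset: SurveyDataset, target: Union[str, Path, IO[str]]) -> None:
    """Write a dataset back to long-format CSV (round-trips with read_survey)."""
    df = dataset.to_frame().rename(
        columns={
            "informant_id": "informant",
            "species_id": "species",
            "category_id": "category",
        }
    )
    df.to_csv(target, index=False)


# ---------------------------------------------------------------------------
# Packaged reference tables
# ---------------------------------------------------------------------------

# filename, expected row count, sha256 of the packaged bytes.  The checksums
# pin the transcriptions; a mismatch means the fixture was edited.
_FIXTURES: dict[str, tuple[str, int, str]] = {
    "species": ("species.csv", 31, "a591e25e90e4e6eae18b3d64ff04459d72c99deebc5e5dc16a54346cfee112a0"),
    "species_uses": ("species_uses.csv", 31, "3d6ad0f6d514a39735d3f807636dd793b192f16532fbdcb3f2545880d7ae5a2b"),
    "species_indices": ("species_indices.csv", 31, "9cca5ef705c413a48c92941cd80e3aa8c75c6574693c7fe3cd8a9f1efe0f3cc6"),
    "ailment_consensus": ("ailment_consensus.csv", 15, "a78a24ffb0307458b55fef39f2991bd66703aee36a07c5902c7d0cc3f2fe45e3"),
    "choice_values": ("choice_values.csv", 19, "78a60d5b6cf67c8bea1a76b82c3bee2f5597dd705fa99849a1eed229cc18725f"),
    "fidelity_levels": ("fidelity_levels.csv", 59, "2c8a64f1fcba02eae3acaa9b99bc98e3acb56982fefcfe59076666523b924c5d"),
}

#: Short aliases for callers that think in terms of the printed tables.
_TABLE_ALIASES = {
    "T1": "species_uses",
    "T3": "species_indices",
    "T4": "ailment_consensus",
    "T5": "choice_values",
    "T6": "fidelity_levels",
}


def load_reference_table(name: str) -> pd.DataFrame:
    """Load one packaged reference table, verifying its fingerprint.

    ``name`` is one of ``species``, ``species_uses``, ``species_indices``,
    ``ailment_consensus``, ``choice_values``, ``fidelity_levels`` (or the
    short aliases T1/T3/T4/T5/T6).
    """
    name = _TABLE_ALIASES.get(name, name)
    if name not in _FIXTURES:
        raise KeyError(f"unknown reference table: {name!r}")
    filename, n_rows, digest = _FIXTURES[name]
    data = resources.files("ethnosurvey.data").joinpath(filename).read_bytes()
    observed = hashlib.sha256(data).hexdigest()
    if not digest.startswith("@SHA:") and observed != digest:
        raise IntegrityError(
            f"reference table {name} ({filename}) checksum mismatch: "
            f"expected {digest}, got {observed}"
        )
    df = pd.read_csv(io.BytesIO(data), dtype=str, keep_default_na=False)
    if len(df) != n_rows:
        raise IntegrityError(
            f"reference table {name} has {len(df)} rows, expected {n_rows}"
        )
    for col in ("UR", "FC", "NU", "Nur", "Ntaxa"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    for col in ("UV", "RFC", "CI", "RI", "ICF", "FL", "CV"):
        if col in df.columns:
            df[col] = df[col].astype(float)
    return df


def load_literature_uses() -> dict[str, list[LiteratureUse]]:
    """Literature-reported uses per species, from the packaged use table.

    Species whose reported-usage cell is empty get an empty list; the
    single species absent from the use table (Ephedra pachyclada, recorded
    only through a complex remedy) is keyed with an empty list as well so
    the mapping is total on the registry.
    """
    registry = load_species_registry()
    uses: dict[str, list[LiteratureUse]] = {sid: [] for sid in registry}
    df = load_reference_table("species_uses")
    for row in df.itertuples(index=False):
        sid = resolve_species_name(row.species, registry)
        for term in str(row.literature_terms).split(";"):
            term = term.strip()
            if term:
                entry = LiteratureUse(species_id=sid, reported_use=term)
                if entry not in uses[sid]:
                    uses[sid].append(entry)
    return uses
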