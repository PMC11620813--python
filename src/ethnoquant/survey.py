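"""Domain model and file I/O for ethnomedicinal survey tables.

The atomic observation is the *use report*: one informant citing one plant
for one ailment, with the plant part, preparation and administration route
attached.  A :class:`SurveyDataset` joins the use reports with the plant
attribute records (one row per species), the informant records (one row per
traditional health practitioner), and the ailment→category map used to pool
free-text ailment labels into analysis categories.

All tables are plain UTF-8, comma-separated files with a header row; the
column names are fixed (see ``USE_REPORT_COLUMNS`` etc.).  Multi-valued
cells (a species' parts or ailments) are pipe-separated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    MappingError,
    ReferentialError,
    SchemaError,
    TaxonParseError,
)

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

PART_CODES = ("leaf", "root", "bark", "whole plant", "fruit", "flower", "seed", "rhizome")
PREPARATION_CODES = ("decoction", "infusion", "powder", "chew", "steam inhalation", "other")
ADMINISTRATION_CODES = ("oral", "inhalation", "topical", "other")
ORIGIN_CODES = ("native", "introduced")
LIFE_FORM_CODES = ("tree", "herb", "shrub")
SOURCE_CODES = ("wild", "cultivated", "both")
# IUCN Red List categories plus "NoRecord" for taxa never assessed.
IUCN_CODES = ("LC", "NT", "VU", "EN", "CR", "EW", "EX", "DD", "NoRecord")

GENDER_CODES = ("male", "female")
AGE_GROUPS = ("<20", "21-40", "41-60", ">60")
EDUCATION_LEVELS = ("illiterate", "primary", "secondary", "tertiary")
EXPERIENCE_GROUPS = ("<5", "5-10", "11-15", ">15")
KNOWLEDGE_SOURCES = ("family", "herbalist", "divine")

USE_REPORT_COLUMNS = ("informant_id", "taxon", "ailment", "part_used", "preparation", "administration")
PLANT_COLUMNS = (
    "taxon",
    "family",
    "local_name",
    "origin",
    "life_form",
    "parts_used",
    "source",
    "ailments",
    "iucn_category",
)
INFORMANT_COLUMNS = (
    "informant_id",
    "gender",
    "age_group",
    "education",
    "experience_group",
    "knowledge_source",
)
MAP_COLUMNS = ("raw_label", "category")

_MULTI_SEP = "|"
_BINOMIAL_RE = re.compile(r"^[A-Z][a-z-]+ [a-z][a-z-]*$")
# Infrageneric / qualifier tokens that may sit between genus and epithet.
_RANK_MARKERS = frozenset({"cf.", "aff.", "sp.", "subsp.", "ssp.", "var.", "sect."})


# ---------------------------------------------------------------------------
# Name and label normalisation
# ---------------------------------------------------------------------------

def canonicalize_taxon(raw_name: str) -> str:
    """Reduce a scientific name to the canonical ``Genus epithet`` binomial.

    Authorship strings ("Steud. ex A.Rich."), basionym authors in
    parentheses, hybrid signs and infrageneric markers are stripped; the
    genus is capitalised and the epithet lowercased.  The operation is
    idempotent: applying it to its own output returns the input unchanged.

    Raises
    ------
    TaxonParseError
        If the string does not contain a genus and an epithet token.
    """
    if raw_name is None or not str(raw_name).strip():
        raise TaxonParseError("empty scientific name")
    tokens = str(raw_name).replace("×", " ").split()
    if len(tokens) < 2:
        raise TaxonParseError(f"cannot parse binomial from {raw_name!r}: fewer than two name tokens")
    genus = tokens[0]
    if not genus.replace("-", "").isalpha():
        raise TaxonParseError(f"cannot parse genus from {raw_name!r}")
    epithet = None
    for tok in tokens[1:]:
        if tok.lower() in _RANK_MARKERS:
            continue
        if tok.replace("-", "").isalpha():
            epithet = tok
            break
        # First non-alphabetic token (authorship, parenthesis) before any
        # epithet candidate means the name has no usable epithet.
        break
    if epithet is None:
        raise TaxonParseError(f"cannot parse species epithet from {raw_name!r}")
    return f"{genus.capitalize()} {epithet.lower()}"


def fold_label(label: str) -> str:
    """Normalise a free-text ailment label for matching.

    Lowercases, collapses internal whitespace, and folds a trailing plural
    "s" ("coughs" ≡ "cough", "colds" ≡ "cold") while leaving words ending in
    "-ss", "-sis" or "-us" (tuberculosis, ...) untouched.
    """
    out = " ".join(str(label).strip().lower().split())
    if out.endswith("s") and not out.endswith(("ss", "sis", "us")):
        out = out[:-1]
    return out


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UseReport:
    """One informant's citation of one plant for one ailment."""

    informant_id: str
    taxon: str
    ailment: str
    part_used: str
    preparation: str
    administration: str

    def validate(self) -> None:
        if not self.informant_id:
            raise SchemaError("use report with empty informant_id")
        if not _BINOMIAL_RE.match(self.taxon):
            raise SchemaError(f"use report taxon {self.taxon!r} is not a canonical binomial")
        _check_code("part_used", self.part_used, PART_CODES)
        _check_code("preparation", self.preparation, PREPARATION_CODES)
        _check_code("administration", self.administration, ADMINISTRATION_CODES)


@dataclass(frozen=True)
class PlantRecord:
    """A species' attribute row: taxonomy, vernacular name, ecology, uses."""

    taxon: str
    family: str
    local_name: str
    origin: str
    life_form: str
    parts_used: tuple[str, ...]
    source: str
    ailments: tuple[str, ...]
    iucn_category: str
    scientific_name: str = ""   # verbatim name with authorship, if known
    voucher: str = ""
    preparation_notes: str = ""
    preparation_codes: tuple[str, ...] = ()
    administration_codes: tuple[str, ...] = ()

    def validate(self) -> None:
        if not _BINOMIAL_RE.match(self.taxon):
            raise SchemaError(f"plant taxon {self.taxon!r} is not a canonical binomial")
        if not self.family:
            raise SchemaError(f"plant {self.taxon}: empty family")
        if not self.parts_used:
            raise SchemaError(f"plant {self.taxon}: parts_used must be non-empty")
        for p in self.parts_used:
            _check_code("part", p, PART_CODES)
        _check_code("origin", self.origin, ORIGIN_CODES)
        _check_code("life_form", self.life_form, LIFE_FORM_CODES)
        _check_code("source", self.source, SOURCE_CODES)
        _check_code("iucn_category", self.iucn_category, IUCN_CODES)
        for p in self.preparation_codes:
            _check_code("preparation", p, PREPARATION_CODES)
        for a in self.administration_codes:
            _check_code("administration", a, ADMINISTRATION_CODES)

    @property
    def genus(self) -> str:
        return self.taxon.split()[0]


@dataclass(frozen=True)
class InformantRecord:
    """Demographic attributes of one traditional health practitioner."""

    informant_id: str
    gender: str
    age_group: str
    education: str
    experience_group: str
    knowledge_source: str

    def validate(self) -> None:
        if not self.informant_id:
            raise SchemaError("informant with empty informant_id")
        _check_code("gender", self.gender, GENDER_CODES)
        _check_code("age_group", self.age_group, AGE_GROUPS)
        _check_code("education", self.education, EDUCATION_LEVELS)
        _check_code("experience_group", self.experience_group, EXPERIENCE_GROUPS)
        _check_code("knowledge_source", self.knowledge_source, KNOWLEDGE_SOURCES)


def _check_code(name: str, value: str, allowed: Sequence[str]) -> None:
    if value not in allowed:
        raise SchemaError(f"{name} {value!r} not in controlled vocabulary {tuple(allowed)}")


class AilmentCategoryMap:
    """Total map from raw ailment labels to analysis categories.

    Lookup is case- and whitespace-insensitive and folds singular/plural
    variants (see :func:`fold_label`).  A label absent from the map raises
    :class:`~ethnoquant.errors.MappingError`; labels are never dropped
    silently.
    """

    def __init__(self, entries: Mapping[str, str] | Iterable[tuple[str, str]]):
        items = entries.items() if isinstance(entries, Mapping) else entries
        self._entries: dict[str, str] = {}
        self._categories: list[str] = []
        for raw, category in items:
            category = str(category).strip()
            self._entries[fold_label(raw)] = category
            if category not in self._categories:
                self._categories.append(category)

    def map(self, raw_label: str) -> str:
        key = fold_label(raw_label)
        if key not in self._entries:
            raise MappingError([raw_label])
        return self._entries[key]

    def map_all(self, raw_labels: Iterable[str]) -> list[str]:
        """Map a batch of labels, reporting *all* offenders at once."""
        missing, out = [], []
        for raw in raw_labels:
            key = fold_label(raw)
            if key in self._entries:
                out.append(self._entries[key])
            else:
                missing.append(raw)
        if missing:
            raise MappingError(sorted(set(missing)))
        return out

    def __contains__(self, raw_label: str) -> bool:
        return fold_label(raw_label) in self._entries

    @property
    def categories(self) -> tuple[str, ...]:
        """Category labels in first-appearance order."""
        return tuple(self._categories)

    @property
    def entries(self) -> dict[str, str]:
        return dict(self._entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, AilmentCategoryMap) and self._entries == other._entries

    def __len__(self) -> int:
        return len(self._entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self._entries.items()), columns=list(MAP_COLUMNS)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AilmentCategoryMap":
        _require_columns(frame, MAP_COLUMNS, "ailment map")
        return cls(zip(frame["raw_label"], frame["category"]))


def map_ailment(raw_label: str, category_map: AilmentCategoryMap) -> str:
    """Resolve one raw ailment label to its category (errors if unmapped)."""
    return category_map.map(raw_label)


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurveyDataset:
    """Validated join of use reports, plants, informants and the category map.

    Invariants enforced at construction: taxa and informant ids are unique;
    every use report references a known plant and informant; every ailment
    label (in reports and in plant records) resolves through the map;
    duplicate identical use-report tuples have been collapsed.
    """

    use_reports: tuple[UseReport, ...]
    plants: tuple[PlantRecord, ...]
    informants: tuple[InformantRecord, ...]
    category_map: AilmentCategoryMap

    def __post_init__(self):
        for plant in self.plants:
            plant.validate()
        for rec in self.informants:
            rec.validate()
        for rep in self.use_reports:
            rep.validate()
        taxa = [p.taxon for p in self.plants]
        if len(set(taxa)) != len(taxa):
            dupes = sorted({t for t in taxa if taxa.count(t) > 1})
            raise SchemaError(f"duplicate plant taxa: {dupes}")
        ids = [i.informant_id for i in self.informants]
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate informant ids")
        if len(set(self.use_reports)) != len(self.use_reports):
            raise SchemaError("duplicate use-report tuples (collapse before constructing)")
        taxa_set, id_set = set(taxa), set(ids)
        for rep in self.use_reports:
            if rep.taxon not in taxa_set:
                raise ReferentialError(f"use report cites unknown taxon {rep.taxon!r}")
            if rep.informant_id not in id_set:
                raise ReferentialError(f"use report cites unknown informant {rep.informant_id!r}")
        labels = {a for p in self.plants for a in p.ailments}
        labels.update(rep.ailment for rep in self.use_reports)
        self.category_map.map_all(sorted(labels))

    # -- construction -------------------------------------------------------

    @classmethod
    def from_records(
        cls,
        use_reports: Iterable[UseReport],
        plants: Iterable[PlantRecord],
        informants: Iterable[InformantRecord],
        category_map: AilmentCategoryMap,
    ) -> "SurveyDataset":
        """Build a dataset, collapsing duplicate identical use reports."""
        seen: dict[UseReport, None] = {}
        for rep in use_reports:
            seen.setdefault(rep)
        return cls(tuple(seen), tuple(plants), tuple(informants), category_map)

    # -- derived quantities --------------------------------------------------

    @property
    def n_informants(self) -> int:
        """N of the consensus indices: total informants interviewed."""
        return len(self.informants)

    @property
    def n_species(self) -> int:
        return len(self.plants)

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(p.taxon for p in self.plants)

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(sorted({p.family for p in self.plants}))

    @property
    def genera(self) -> tuple[str, ...]:
        return tuple(sorted({p.genus for p in self.plants}))

    def plant(self, taxon: str) -> PlantRecord:
        for p in self.plants:
            if p.taxon == taxon:
                return p
        raise KeyError(taxon)

    # -- frames --------------------------------------------------------------

    def use_reports_frame(self, with_category: bool = True) -> pd.DataFrame:
        frame = pd.DataFrame(
            [(r.informant_id, r.taxon, r.ailment, r.part_used, r.preparation, r.administration) for r in self.use_reports],
            columns=list(USE_REPORT_COLUMNS),
        )
        if with_category and len(frame):
            frame["category"] = self.category_map.map_all(frame["ailment"])
        elif with_category:
            frame["category"] = pd.Series(dtype=str)
        return frame

    def plants_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.plants:
            rows.append(
                {
                    "taxon": p.taxon,
                    "family": p.family,
                    "local_name": p.local_name,
                    "origin": p.origin,
                    "life_form": p.life_form,
                    "parts_used": _MULTI_SEP.join(p.parts_used),
                    "source": p.source,
                    "ailments": _MULTI_SEP.join(p.ailments),
                    "iucn_category": p.iucn_category,
                    "scientific_name": p.scientific_name,
                    "voucher": p.voucher,
                    "preparation_notes": p.preparation_notes,
                    "preparation_codes": _MULTI_SEP.join(p.preparation_codes),
                    "administration_codes": _MULTI_SEP.join(p.administration_codes),
                }
            )
        return pd.DataFrame(rows, columns=list(PLANT_COLUMNS) + [
            "scientific_name", "voucher", "preparation_notes", "preparation_codes", "administration_codes"
        ])

    def informants_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (i.informant_id, i.gender, i.age_group, i.education, i.experience_group, i.knowledge_source)
                for i in self.informants
            ],
            columns=list(INFORMANT_COLUMNS),
        )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _read_csv(path, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{what} file not found: {path}")
    # Strictly comma-separated UTF-8 with a header row; no NA coercion so
    # that empty strings survive as such.
    return pd.read_csv(path, sep=",", dtype=str, na_filter=False, encoding="utf-8")


def _require_columns(frame: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what} table is missing required column(s): {', '.join(missing)}")


def _split_multi(cell: str) -> tuple[str, ...]:
    return tuple(s.strip() for s in str(cell).split(_MULTI_SEP) if s.strip())


def load_survey(use_reports_path, plants_path, informants_path, category_map_path) -> SurveyDataset:
    """Load and validate the four survey tables into a :class:`SurveyDataset`.

    Duplicate identical use-report rows are collapsed; taxa in both the plant
    table and the use reports are canonicalized; all referential and mapping
    invariants are checked (violations raise, they are never dropped).
    """
    reports_df = _read_csv(use_reports_path, "use reports")
    plants_df = _read_csv(plants_path, "plants")
    informants_df = _read_csv(informants_path, "informants")
    map_df = _read_csv(category_map_path, "ailment map")

    _require_columns(reports_df, USE_REPORT_COLUMNS, "use reports")
    _require_columns(plants_df, PLANT_COLUMNS, "plants")
    _require_columns(informants_df, INFORMANT_COLUMNS, "informants")
    category_map = AilmentCategoryMap.from_frame(map_df)

    plants = []
    for row in plants_df.to_dict("records"):
        plants.append(
            PlantRecord(
                taxon=canonicalize_taxon(row["taxon"]),
                family=row["family"].strip(),
                local_name=row["local_name"].strip(),
                origin=row["origin"].strip(),
                life_form=row["life_form"].strip(),
                parts_used=_split_multi(row["parts_used"]),
                source=row["source"].strip(),
                ailments=_split_multi(row["ailments"]),
                iucn_category=row["iucn_category"].strip(),
                scientific_name=row.get("scientific_name", ""),
                voucher=row.get("voucher", ""),
                preparation_notes=row.get("preparation_notes", ""),
                preparation_codes=_split_multi(row.get("preparation_codes", "")),
                administration_codes=_split_multi(row.get("administration_codes", "")),
            )
        )
    informants = [
        InformantRecord(
            informant_id=row["informant_id"].strip(),
            gender=row["gender"].strip(),
            age_group=row["age_group"].strip(),
            education=row["education"].strip(),
            experience_group=row["experience_group"].strip(),
            knowledge_source=row["knowledge_source"].strip(),
        )
        for row in informants_df.to_dict("records")
    ]
    reports = [
        UseReport(
            informant_id=row["informant_id"].strip(),
            taxon=canonicalize_taxon(row["taxon"]),
            ailment=row["ailment"].strip(),
            part_used=row["part_used"].strip(),
            preparation=row["preparation"].strip(),
            administration=row["administration"].strip(),
        )
        for row in reports_df.to_dict("records")
    ]
    return SurveyDataset.from_records(reports, plants, informants, category_map)


def save_survey(dataset: SurveyDataset, out_dir) -> dict[str, Path]:
    """Serialise a dataset back to the four-CSV schema (round-trip safe)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "use_reports": out_dir / "use_reports.csv",
        "plants": out_dir / "plants.csv",
        "informants": out_dir / "informants.csv",
        "ailment_map": out_dir / "ailment_map.csv",
    }
    dataset.use_reports_frame(with_category=False).to_csv(paths["use_reports"], index=False, lineterminator="\n")
    dataset.plants_frame().to_csv(paths["plants"], index=False, lineterminator="\n")
    dataset.informants_frame().to_csv(paths["informants"], index=False, lineterminator="\n")
    dataset.category_map.to_frame().to_csv(paths["ailment_map"], index=False, lineterminator="\n")
    return paths
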