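"""PhenoSSU schema, lexicons and the lab knowledge base.

The PhenoSSU model pairs one phenotype concept with a fixed set of 10
attribute slots: 7 phrase-based (assertion, severity, temporal pattern,
laterality, spatial pattern, quadrant pattern, body location) and 3
logic-based (specimen, analyte, abnormality).  Attribute values are closed,
user-extensible sets; SNOMED CT codes are carried as opaque normalization
labels only.

All three resource kinds (schema, lexicon, lab KB) are plain text files
(YAML / TSV), loadable, validatable and round-trippable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .alphabet import LEXICON_LETTERS

logger = logging.getLogger(__name__)

PHRASE_ATTRIBUTES = (
    "assertion",
    "severity",
    "temporal pattern",
    "laterality",
    "spatial pattern",
    "quadrant pattern",
    "body location",
)
LOGIC_ATTRIBUTES = ("specimen", "analyte", "abnormality")
ABNORMALITY_VALUES = frozenset({"higher", "lower", "normal"})


class SchemaError(ValueError):
    """A schema, lexicon or knowledge-base file violates an invariant."""


@dataclass(frozen=True)
class AttributeDef:
    """One attribute category with its closed value set."""

    name: str
    subtype: str  # "phrase-based" | "logic-based"
    values: tuple[str, ...]
    snomed: dict[str, str] = field(default_factory=dict)  # value label -> code
    default: str | None = None

    def __post_init__(self) -> None:
        if self.subtype not in ("phrase-based", "logic-based"):
            raise SchemaError(f"attribute {self.name!r}: bad subtype {self.subtype!r}")
        if not self.values:
            raise SchemaError(f"attribute {self.name!r}: empty value set")
        if self.default is not None and self.default not in self.values:
            raise SchemaError(
                f"attribute {self.name!r}: default {self.default!r} not in value set"
            )


@dataclass(frozen=True)
class PhenoSSUSchema:
    attributes: tuple[AttributeDef, ...]
    version: str = "1.0"

    def __post_init__(self) -> None:
        names = [a.name for a in self.attributes]
        if len(self.attributes) != 10:
            raise SchemaError(f"schema must define exactly 10 attributes, got {len(names)}")
        phrase = {a.name for a in self.attributes if a.subtype == "phrase-based"}
        logic = {a.name for a in self.attributes if a.subtype == "logic-based"}
        if phrase != set(PHRASE_ATTRIBUTES):
            raise SchemaError(f"phrase-based attribute set mismatch: {sorted(phrase)}")
        if logic != set(LOGIC_ATTRIBUTES):
            raise SchemaError(f"logic-based attribute set mismatch: {sorted(logic)}")
        by_name = self.by_name
        if {"present", "absent"} - set(by_name["assertion"].values):
            raise SchemaError("assertion values must contain 'present' and 'absent'")
        if set(by_name["abnormality"].values) != ABNORMALITY_VALUES:
            raise SchemaError("abnormality values must be exactly {higher, lower, normal}")

    @property
    def by_name(self) -> dict[str, AttributeDef]:
        return {a.name: a for a in self.attributes}

    def validate_value(self, attribute: str, value: str) -> None:
        attr = self.by_name.get(attribute)
        if attr is None:
            raise SchemaError(f"unknown attribute category {attribute!r}")
        if value not in attr.values:
            raise SchemaError(f"value {value!r} not in closed set of {attribute!r}")


@dataclass(frozen=True)
class LexiconEntry:
    surface: str
    letter: str  # one of LEXICON_LETTERS
    normalization: str
    category: str = ""  # attribute category, required for A entries


@dataclass
class Lexicon:
    """Surface-form dictionary driving the single-letter encoder."""

    entries: list[LexiconEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        deduped: list[LexiconEntry] = []
        for e in self.entries:
            if not e.surface:
                raise SchemaError("lexicon entry with empty surface form")
            if e.letter not in LEXICON_LETTERS:
                raise SchemaError(f"lexicon surface {e.surface!r}: unknown letter {e.letter!r}")
            if e.letter == "A" and not e.category:
                raise SchemaError(f"A-entry {e.surface!r} names no attribute category")
            prev = seen.get(e.surface)
            if prev is not None:
                if prev != e.letter:
                    raise SchemaError(
                        f"surface {e.surface!r} assigned to two letters: {prev}, {e.letter}"
                    )
                logger.warning("duplicate lexicon row for %r collapsed", e.surface)
                continue
            seen[e.surface] = e.letter
            deduped.append(e)
        self.entries = deduped

    def validate_against(self, schema: PhenoSSUSchema) -> None:
        """Every A-entry must name a phrase-based category and a value from its set."""
        phrase = {a.name for a in schema.attributes if a.subtype == "phrase-based"}
        for e in self.entries:
            if e.letter != "A":
                continue
            if e.category not in phrase:
                raise SchemaError(
                    f"A-entry {e.surface!r}: {e.category!r} is not a phrase-based attribute"
                )
            schema.validate_value(e.category, e.normalization)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


@dataclass(frozen=True)
class LabKBEntry:
    """Reference-range knowledge for one analyte.

    ``conversions`` maps a unit surface to the multiplicative factor that
    converts a value expressed in that unit into the canonical unit.  The
    canonical unit itself always carries factor 1.
    """

    analyte: str
    synonyms: tuple[str, ...]
    specimen: str  # may be "" (no specimen required)
    unit: str
    low: float
    high: float
    conversions: dict[str, float]
    snomed_map: dict[str, str]  # abnormality value -> concept code

    def __post_init__(self) -> None:
        if not self.unit:
            raise SchemaError(f"analyte {self.analyte!r}: missing canonical unit")
        if not self.low < self.high:
            raise SchemaError(
                f"analyte {self.analyte!r}: reference range low ({self.low}) must be "
                f"below high ({self.high})"
            )
        for u, f in self.conversions.items():
            if f <= 0:
                raise SchemaError(f"analyte {self.analyte!r}: conversion {u!r} factor {f} <= 0")
        if set(self.snomed_map) - ABNORMALITY_VALUES:
            raise SchemaError(f"analyte {self.analyte!r}: snomed_map keys must be abnormalities")

    def to_canonical(self, value: float, unit: str) -> float:
        if unit == self.unit:
            return value
        try:
            return value * self.conversions[unit]
        except KeyError:
            raise SchemaError(
                f"unit {unit!r} not convertible to {self.unit!r} for analyte {self.analyte!r}"
            ) from None

    def from_canonical(self, value: float, unit: str) -> float:
        if unit == self.unit:
            return value
        return value / self.conversions[unit]


# ---------------------------------------------------------------------------
# loading / saving


def _schema_from_mapping(doc: dict) -> PhenoSSUSchema:
    attrs = []
    for raw in doc.get("attributes", []):
        try:
            values, snomed = [], {}
            for v in raw["values"]:
                if isinstance(v, str):
                    values.append(v)
                else:
                    values.append(v["label"])
                    if v.get("snomed"):
                        snomed[v["label"]] = str(v["snomed"])
            attrs.append(
                AttributeDef(
                    name=raw["name"],
                    subtype=raw["subtype"],
                    values=tuple(values),
                    snomed=snomed,
                    default=raw.get("default"),
                )
            )
        except KeyError as exc:
            raise SchemaError(f"attribute entry {raw.get('name', '?')!r} missing {exc}") from None
    return PhenoSSUSchema(attributes=tuple(attrs), version=str(doc.get("version", "1.0")))


def load_schema(path: str | Path) -> PhenoSSUSchema:
    """Load and validate a PhenoSSU schema from a YAML file."""
    try:
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise SchemaError(f"cannot parse schema file {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaError(f"schema file {path} is not a mapping")
    return _schema_from_mapping(doc)


def save_schema(schema: PhenoSSUSchema, path: str | Path) -> None:
    doc = {
        "version": schema.version,
        "attributes": [
            {
                "name": a.name,
                "subtype": a.subtype,
                **({"default": a.default} if a.default else {}),
                "values": [
                    {"label": v, **({"snomed": a.snomed[v]} if v in a.snomed else {})}
                    for v in a.values
                ],
            }
            for a in schema.attributes
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, allow_unicode=True, sort_keys=False), "utf-8")


_LEXICON_COLUMNS = ["surface", "letter", "category", "normalization"]


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a tab-delimited lexicon (columns: surface, letter, category, normalization)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_LEXICON_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"lexicon {path} missing columns: {sorted(missing)}")
    entries = [
        LexiconEntry(
            surface=row.surface,
            letter=row.letter,
            category=row.category,
            normalization=row.normalization,
        )
        for row in df.itertuples()
    ]
    return Lexicon(entries=entries)


def save_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    df = pd.DataFrame(
        [(e.surface, e.letter, e.category, e.normalization) for e in lexicon],
        columns=_LEXICON_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def _parse_conversions(text: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for chunk in filter(None, (c.strip() for c in text.split(";"))):
        unit, _, factor = chunk.rpartition(":")
        out[unit] = float(factor)
    return out


def load_lab_kb(path: str | Path) -> list[LabKBEntry]:
    """Load the laboratory knowledge base (one analyte per TSV row)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"analyte", "specimen", "unit", "low", "high"}
    if required - set(df.columns):
        raise SchemaError(f"lab KB {path} missing columns: {sorted(required - set(df.columns))}")
    entries = []
    for i, row in enumerate(df.itertuples(), start=2):
        try:
            low, high = float(row.low), float(row.high)
        except ValueError:
            raise SchemaError(f"lab KB {path} line {i}: non-numeric reference range") from None
        snomed = {
            abn: getattr(row, f"snomed_{abn}", "")
            for abn in ("higher", "lower", "normal")
        }
        conversions = _parse_conversions(getattr(row, "conversions", ""))
        conversions.setdefault(row.unit, 1.0)
        entries.append(
            LabKBEntry(
                analyte=row.analyte,
                synonyms=tuple(filter(None, getattr(row, "synonyms", "").split("|"))),
                specimen=row.specimen,
                unit=row.unit,
                low=low,
                high=high,
                conversions=conversions,
                snomed_map={k: v for k, v in snomed.items() if v},
            )
        )
    return entries


def save_lab_kb(entries: list[LabKBEntry], path: str | Path) -> None:
    rows = []
    for e in entries:
        rows.append(
            {
                "analyte": e.analyte,
                "synonyms": "|".join(e.synonyms),
                "specimen": e.specimen,
                "unit": e.unit,
                "low": repr(e.low) if e.low != int(e.low) else str(int(e.low)),
                "high": repr(e.high) if e.high != int(e.high) else str(int(e.high)),
                "conversions": ";".join(f"{u}:{f!r}" for u, f in e.conversions.items()),
                "snomed_higher": e.snomed_map.get("higher", ""),
                "snomed_lower": e.snomed_map.get("lower", ""),
                "snomed_normal": e.snomed_map.get("normal", ""),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# shipped defaults


def _data_path(name: str):
    return resources.files("phenossu.data").joinpath(name)


def default_schema() -> PhenoSSUSchema:
    with resources.as_file(_data_path("schema.yaml")) as p:
        return load_schema(p)


def default_lexicon() -> Lexicon:
    with resources.as_file(_data_path("lexicon.tsv")) as p:
        return load_lexicon(p)


def default_lab_kb() -> list[LabKBEntry]:
    with resources.as_file(_data_path("lab_kb.tsv")) as p:
        return load_lab_kb(p)
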