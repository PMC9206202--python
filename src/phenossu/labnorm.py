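"""Interpretation of logic-based phenotype matches (lab results).

A quantitative match (analyte + number + unit, pattern ``S*LNU``) is
normalized by converting the value to the analyte's canonical unit and
comparing it against the closed reference interval [low, high]: values
inside the interval (bounds included) are ``normal``, above it ``higher``,
below it ``lower``.  A qualitative match (analyte + direction word, pattern
``S*LR``) takes the direction word's normalized value directly.  When the
knowledge base maps the resulting abnormality to a SNOMED CT concept, the
code is attached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .schema import LabKBEntry, SchemaError

logger = logging.getLogger(__name__)


@dataclass
class LabObservation:
    """A normalized lab result (or an error record when unresolvable)."""

    analyte: str
    specimen: str | None = None
    value: float | None = None  # in canonical unit (quantitative only)
    direction: str | None = None  # direction word value (qualitative only)
    abnormality: str | None = None  # higher | lower | normal
    snomed: str | None = None
    entry: LabKBEntry | None = None
    error: str | None = None  # "unresolved-analyte" | "ambiguous-analyte" | "unit"


class LabKBIndex:
    """Analyte-name (and synonym) index over knowledge-base entries."""

    def __init__(self, entries: list[LabKBEntry]):
        self.entries = list(entries)
        self._by_name: dict[str, list[LabKBEntry]] = {}
        for e in entries:
            for name in (e.analyte, *e.synonyms):
                self._by_name.setdefault(name, []).append(e)

    def resolve(self, analyte: str, specimen: str | None = None):
        """Candidate entries for an analyte label, narrowed by specimen."""
        candidates = self._by_name.get(analyte, [])
        if specimen:
            narrowed = [e for e in candidates if e.specimen in (specimen, "")]
            if narrowed:
                candidates = narrowed
        return candidates


def _as_index(kb) -> LabKBIndex:
    return kb if isinstance(kb, LabKBIndex) else LabKBIndex(kb)


def _resolve_one(index: LabKBIndex, analyte: str, specimen: str | None):
    candidates = index.resolve(analyte, specimen)
    if not candidates:
        logger.warning("analyte %r not in the knowledge base", analyte)
        return None, LabObservation(analyte=analyte, specimen=specimen,
                                    error="unresolved-analyte")
    if len(candidates) > 1:
        names = [f"{e.analyte}/{e.specimen or '-'}" for e in candidates]
        logger.warning("analyte %r ambiguous between %s", analyte, names)
        return None, LabObservation(analyte=analyte, specimen=specimen,
                                    error=f"ambiguous-analyte: {', '.join(names)}")
    return candidates[0], None


def classify_value(entry: LabKBEntry, value_canonical: float) -> str:
    """Closed-interval comparison against the reference range."""
    if value_canonical > entry.high:
        return "higher"
    if value_canonical < entry.low:
        return "lower"
    return "normal"


def interpret_lnu(
    analyte: str,
    value: float,
    unit: str,
    kb,
    specimen: str | None = None,
) -> LabObservation:
    """Interpret an analyte + number + unit match against the knowledge base."""
    index = _as_index(kb)
    entry, err = _resolve_one(index, analyte, specimen)
    if err is not None:
        return err
    try:
        canonical = entry.to_canonical(value, unit)
    except SchemaError as exc:
        logger.warning("%s", exc)
        return LabObservation(
            analyte=entry.analyte, specimen=specimen or entry.specimen or None,
            entry=entry, error=f"unit: {exc}",
        )
    abnormality = classify_value(entry, canonical)
    return LabObservation(
        analyte=entry.analyte,
        specimen=specimen or entry.specimen or None,
        value=canonical,
        abnormality=abnormality,
        snomed=entry.snomed_map.get(abnormality),
        entry=entry,
    )


def interpret_lr(
    analyte: str,
    direction: str,
    kb,
    specimen: str | None = None,
) -> LabObservation:
    """Interpret an analyte + direction-word match (e.g. "high blood glucose")."""
    if direction not in ("higher", "lower", "normal"):
        raise ValueError(f"direction word payload {direction!r} is not an abnormality")
    index = _as_index(kb)
    entry, err = _resolve_one(index, analyte, specimen)
    if err is not None:
        err.direction = direction
        return err
    return LabObservation(
        analyte=entry.analyte,
        specimen=specimen or entry.specimen or None,
        direction=direction,
        abnormality=direction,
        snomed=entry.snomed_map.get(direction),
        entry=entry,
    )
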