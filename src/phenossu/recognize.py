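"""Pattern scanning and PhenoSSU instance assembly.

A document is encoded as a single-letter sequence, scanned left to right
with the pattern library (highest-priority pattern first at each position,
greedy-longest match, accepted matches never overlap), and every match is
assembled into PhenoSSU instances: one instance per phenotype letter for
phrase-based matches, with attribute triggers propagated to their
phenotypes; logic-based matches are delegated to the lab normalizer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .encoding import EncodedSequence, encode
from .labnorm import interpret_lnu, interpret_lr
from .patterns import PatternLibrary, RegexPattern, builtin_library
from .schema import Lexicon, PhenoSSUSchema

logger = logging.getLogger(__name__)

Span = tuple[int, int]


@dataclass
class PatternMatch:
    """One accepted match of a library pattern over the letter sequence."""

    pattern: RegexPattern
    start: int  # letter index, inclusive
    end: int  # letter index, exclusive

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class PhenoSSUInstance:
    """One phenotype concept with its attribute slots and evidence spans."""

    phenotype: str
    phenotype_span: Span | None
    attributes: dict[str, tuple[str, Span | None]] = field(default_factory=dict)
    category: str = "phrase-based"  # phrase-based | logic-based
    snomed: str | None = None
    pattern: str | None = None
    doc_id: str | None = None

    def key(self, with_span: bool = False):
        """Hashable identity used for comparison (spans optional)."""
        attrs = frozenset((k, v) for k, (v, _) in self.attributes.items())
        if with_span:
            return (self.phenotype, self.phenotype_span, attrs)
        return (self.phenotype, attrs)

    def attribute_values(self) -> dict[str, str]:
        return {k: v for k, (v, _) in self.attributes.items()}

    def validate_against(self, schema: PhenoSSUSchema) -> None:
        from .schema import LOGIC_ATTRIBUTES, PHRASE_ATTRIBUTES

        allowed = PHRASE_ATTRIBUTES if self.category == "phrase-based" else LOGIC_ATTRIBUTES
        for name, (value, _) in self.attributes.items():
            if name not in allowed:
                raise ValueError(
                    f"{self.category} instance {self.phenotype!r} carries attribute {name!r}"
                )
            if name == "analyte":
                # analyte labels come from the lab KB; schema list is advisory
                continue
            schema.validate_value(name, value)


def scan(seq: EncodedSequence, library: PatternLibrary) -> list[PatternMatch]:
    """Left-to-right non-overlapping scan of the letter sequence.

    At each position the highest-priority pattern that matches is taken
    (pattern order in the library is the priority; each pattern matches
    greedily), and scanning resumes after the match.
    """
    matches: list[PatternMatch] = []
    letters = seq.letters
    i = 0
    while i < len(letters):
        taken = None
        best_key = None
        for pattern in library:
            m = pattern.compiled.match(letters, i)
            if m and m.end() > i:
                # priority band first (longer required skeleton, more runs),
                # longest match within a band
                key = (-pattern.required_length, -len(pattern.units), i - m.end())
                if best_key is None or key < best_key:
                    best_key = key
                    taken = PatternMatch(pattern=pattern, start=i, end=m.end())
        if taken is None:
            i += 1
        else:
            matches.append(taken)
            i = taken.end
    return matches


def _fill(slots: dict, category: str, value: str, span: Span, distance: int) -> None:
    """Attribute conflict resolution: the occurrence nearest its P wins."""
    if category in slots and slots[category][2] <= distance:
        logger.warning(
            "attribute conflict on %r: keeping %r, ignoring %r",
            category, slots[category][0], value,
        )
        return
    if category in slots:
        logger.warning(
            "attribute conflict on %r: %r replaced by nearer %r",
            category, slots[category][0], value,
        )
    slots[category] = (value, span, distance)


def assemble(
    matches: list[PatternMatch],
    seq: EncodedSequence,
    lexicon: Lexicon | None = None,
    schema: PhenoSSUSchema | None = None,
) -> list[PhenoSSUInstance]:
    """Build phrase-based PhenoSSU instances from scan matches.

    Attribute propagation: A letters before the first P apply to every P of
    the match; A letters after a P attach to the nearest preceding P.
    Unfilled attributes take schema defaults (assertion defaults to
    "present").  Logic-based matches (containing L) are skipped here; see
    :func:`recognize_document`.
    """
    instances: list[PhenoSSUInstance] = []
    for match in matches:
        letters = seq.letters[match.start : match.end]
        if "L" in letters:
            continue
        p_positions = [match.start + k for k, c in enumerate(letters) if c == "P"]
        if not p_positions:
            continue
        pre: list[tuple[str, str, Span, int]] = []  # A letters before the first P
        post: dict[int, list[tuple[str, str, Span, int]]] = {p: [] for p in p_positions}
        first_p = p_positions[0]
        for k, c in enumerate(letters):
            pos = match.start + k
            if c != "A":
                continue
            payload = seq.payloads[pos]
            if not isinstance(payload, tuple):
                _, _, surface = seq.decode_span(pos, pos + 1)
                raise ValueError(
                    f"A letter {surface!r} carries no attribute category; "
                    "fix the lexicon entry"
                )
            category, value = payload
            span = seq.spans[pos]
            if pos < first_p:
                pre.append((category, value, span, first_p - pos))
            else:
                owner = max(p for p in p_positions if p < pos)
                post[owner].append((category, value, span, pos - owner))
        for p in p_positions:
            concept = seq.payloads[p]
            slots: dict[str, tuple[str, Span, int]] = {}
            for category, value, span, dist in pre + post[p]:
                _fill(slots, category, value, span, dist)
            attributes: dict[str, tuple[str, Span | None]] = {
                cat: (value, span) for cat, (value, span, _) in slots.items()
            }
            if "assertion" not in attributes:
                default = "present"
                if schema is not None:
                    default = schema.by_name["assertion"].default or "present"
                attributes["assertion"] = (default, None)
            instances.append(
                PhenoSSUInstance(
                    phenotype=concept,
                    phenotype_span=seq.spans[p],
                    attributes=attributes,
                    category="phrase-based",
                    pattern=match.pattern.pattern,
                )
            )
    return instances


def _assemble_logic(match: PatternMatch, seq: EncodedSequence, lab_kb) -> PhenoSSUInstance | None:
    letters = seq.letters[match.start : match.end]
    bindings: dict[str, int] = {}
    for k, c in enumerate(letters):
        if c in "SLNUR":
            bindings.setdefault(c, match.start + k)
    if "L" not in bindings:
        return None
    specimen = seq.payloads[bindings["S"]] if "S" in bindings else None
    analyte = seq.payloads[bindings["L"]]
    if "N" in bindings and "U" in bindings:
        obs = interpret_lnu(
            analyte=analyte,
            value=seq.payloads[bindings["N"]],
            unit=seq.payloads[bindings["U"]],
            kb=lab_kb,
            specimen=specimen,
        )
    elif "R" in bindings:
        obs = interpret_lr(
            analyte=analyte,
            direction=seq.payloads[bindings["R"]],
            kb=lab_kb,
            specimen=specimen,
        )
    else:
        return None
    attributes: dict[str, tuple[str, Span | None]] = {
        "analyte": (obs.analyte, seq.spans[bindings["L"]]),
    }
    if obs.specimen:
        span = seq.spans[bindings["S"]] if "S" in bindings else None
        attributes["specimen"] = (obs.specimen, span)
    if obs.abnormality:
        if "R" in bindings:
            evid_span = seq.spans[bindings["R"]]
        else:  # the written result is number plus unit
            evid_span = (seq.spans[bindings["N"]][0], seq.spans[bindings["U"]][1])
        attributes["abnormality"] = (obs.abnormality, evid_span)
        phenotype = f"{obs.analyte} {obs.abnormality}"
    else:
        phenotype = obs.analyte
        logger.warning("lab match %r left without abnormality (%s)", letters, obs.error)
    return PhenoSSUInstance(
        phenotype=phenotype,
        phenotype_span=seq.spans[bindings["L"]],
        attributes=attributes,
        category="logic-based",
        snomed=obs.snomed,
        pattern=match.pattern.pattern,
    )


def recognize_document(
    text: str,
    lexicon: Lexicon,
    library: PatternLibrary | None = None,
    lab_kb=None,
    schema: PhenoSSUSchema | None = None,
    doc_id: str | None = None,
) -> list[PhenoSSUInstance]:
    """Full-document recognition: encode, scan, assemble, normalize labs."""
    if library is None:
        library = builtin_library()
    seq = encode(text, lexicon)
    matches = scan(seq, library)
    instances = assemble(matches, seq, lexicon, schema)
    if lab_kb is not None:
        for match in matches:
            if "L" in seq.letters[match.start : match.end]:
                inst = _assemble_logic(match, seq, lab_kb)
                if inst is not None:
                    instances.append(inst)
    for inst in instances:
        inst.doc_id = doc_id
    instances.sort(key=lambda x: (x.phenotype_span or (0, 0), x.phenotype))
    return instances


class PhenoSSURecognizer:
    """Predict-shaped front end over the recognition pipeline.

    Resources (lexicon, pattern library, lab KB, schema) are the
    parameters; :meth:`fit` optionally runs enrichment against gold
    documents, :meth:`predict` maps a list of documents to a list of
    instance lists.
    """

    def __init__(
        self,
        lexicon: Lexicon | None = None,
        library: PatternLibrary | None = None,
        lab_kb=None,
        schema: PhenoSSUSchema | None = None,
    ):
        self.lexicon = lexicon
        self.library = library
        self.lab_kb = lab_kb
        self.schema = schema

    def get_params(self, deep: bool = True) -> dict:
        return {
            "lexicon": self.lexicon,
            "library": self.library,
            "lab_kb": self.lab_kb,
            "schema": self.schema,
        }

    def set_params(self, **params) -> "PhenoSSURecognizer":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _resources(self):
        from .schema import default_lexicon

        lexicon = self.lexicon if self.lexicon is not None else default_lexicon()
        library = self.library if self.library is not None else builtin_library()
        return lexicon, library

    def fit(self, X: list[str], y: list[list[PhenoSSUInstance]] | None = None):
        """Enrich the library against gold instances ``y`` (no-op without gold)."""
        from .patterns import enrich

        lexicon, library = self._resources()
        if y is not None:
            library, self.enrichment_report_ = enrich(
                library, list(zip(X, y)), lexicon, lab_kb=self.lab_kb, schema=self.schema
            )
        self.library_ = library
        return self

    def predict(self, X: list[str]) -> list[list[PhenoSSUInstance]]:
        lexicon, library = self._resources()
        library = getattr(self, "library_", library)
        return [
            recognize_document(
                text, lexicon, library, lab_kb=self.lab_kb, schema=self.schema,
                doc_id=str(i),
            )
            for i, text in enumerate(X)
        ]
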