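"""Linguistic-pattern library: induction from motif segments and enrichment.

A linguistic pattern is a small regular expression over the letter alphabet
(e.g. ``A+P``: one or more attribute triggers followed by a phenotype).
Patterns are induced from O-free motif segments by run-length abstraction:

* boundary punctuation (C) is trimmed from segments, like O;
* a trailing alternation ``(CP)^k`` after a phenotype collapses into the
  conjunction group ``(CP)+`` (attributes distribute over the conjoined
  phenotypes, so the preceding attribute run is promoted to ``A+``);
* segments with the same run skeleton form a family; a skeleton that is an
  order-preserving subsequence of a longer one (with the final run anchored)
  merges into it, the missing runs becoming ``*`` (zero-or-more);
* within a family a run whose length varies becomes ``+``, a constant run
  stays literal; families where several runs vary with no optionality
  evidence are split along one varying axis at a time, which separates
  e.g. the "many attributes, one phenotype" family (``A+P``) from the
  "one attribute, many phenotypes" family (``AP+``).

Induced patterns are filtered for interpretability (a phrase pattern must
bind at least one required attribute to a phenotype; a logic pattern must be
lab-interpretable: L with NU or R) and consolidated by structural
subsumption, so redundant specializations collapse into their
generalization.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field

from sklearn.base import BaseEstimator

from .alphabet import LETTER_SET
from .schema import Lexicon

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# pattern AST


@dataclass(frozen=True)
class Unit:
    """One run of a pattern: a letter or the (CP) conjunction group."""

    kind: str  # "lit" | "group"
    letters: str  # single letter for lit, "CP" for group
    lo: int
    hi: int | None  # None = unbounded

    def render(self) -> str:
        if self.kind == "group":
            return f"({self.letters})+"
        if (self.lo, self.hi) == (1, 1):
            return self.letters
        if (self.lo, self.hi) == (1, None):
            return self.letters + "+"
        if (self.lo, self.hi) == (0, None):
            return self.letters + "*"
        if (self.lo, self.hi) == (0, 1):
            return self.letters + "?"
        return self.letters * self.lo  # constant repeat

    @property
    def key(self) -> tuple[str, str]:
        return (self.kind, self.letters)


def parse_pattern(text: str) -> tuple[Unit, ...]:
    """Parse a pattern string into units (letters, +, *, ?, one-level groups)."""
    units: list[Unit] = []
    i = 0
    while i < len(text):
        if text[i] == "(":
            j = text.index(")", i)
            letters = text[i + 1 : j]
            quant = text[j + 1] if j + 1 < len(text) and text[j + 1] in "+*?" else ""
            lo, hi = {"+": (1, None), "*": (0, None), "?": (0, 1), "": (1, 1)}[quant]
            units.append(Unit("group", letters, lo, hi))
            i = j + 1 + len(quant)
        else:
            ch = text[i]
            if ch not in LETTER_SET:
                raise ValueError(f"pattern {text!r}: letter {ch!r} outside the alphabet")
            count = 1
            while i + count < len(text) and text[i + count] == ch:
                count += 1
            i += count
            quant = text[i] if i < len(text) and text[i] in "+*?" else ""
            if quant:
                i += 1
            if quant == "+":
                lo, hi = (count, None) if count > 1 else (1, None)
            elif quant == "*":
                lo, hi = (count - 1, None) if count > 1 else (0, None)
            elif quant == "?":
                lo, hi = (count - 1, count) if count > 1 else (0, 1)
            else:
                lo, hi = count, count
            units.append(Unit("lit", ch, lo, hi))
    return tuple(units)


def units_covered(a: tuple[Unit, ...], b: tuple[Unit, ...]) -> bool:
    """True if every string matched by units ``a`` is matched by units ``b``.

    Exact for the run-structured grammar used here (no adjacent same-letter
    units, nesting depth <= 1).
    """

    def rec(i: int, j: int) -> bool:
        if i == len(a) and j == len(b):
            return True
        if j == len(b):
            return False
        bu = b[j]
        if bu.lo == 0 and rec(i, j + 1):
            return True
        if i == len(a):
            return False
        au = a[i]
        if (
            au.key == bu.key
            and au.lo >= bu.lo
            and (bu.hi is None or (au.hi is not None and au.hi <= bu.hi))
        ):
            return rec(i + 1, j + 1)
        return False

    return rec(0, 0)


# ---------------------------------------------------------------------------
# patterns and the library


@dataclass
class RegexPattern:
    """One linguistic-pattern class."""

    pattern: str
    category: str  # "phrase-based" | "logic-based"
    provenance: str = "discovered"  # builtin | discovered | enriched
    support: int = 0
    review_flag: bool = False
    segments: tuple[str, ...] = ()  # recorded source segments

    def __post_init__(self) -> None:
        self.units = parse_pattern(self.pattern)
        self.compiled = re.compile(self.pattern)
        letters = {u.letters for u in self.units if u.kind == "lit"} | {
            c for u in self.units if u.kind == "group" for c in u.letters
        }
        if self.category == "phrase-based" and "P" not in letters:
            raise ValueError(f"phrase-based pattern {self.pattern!r} contains no P")
        if self.category == "logic-based" and "L" not in letters:
            raise ValueError(f"logic-based pattern {self.pattern!r} contains no L")
        for seg in self.segments:
            if not self.compiled.fullmatch(seg):
                raise ValueError(f"pattern {self.pattern!r} does not match its source {seg!r}")

    @property
    def required_length(self) -> int:
        """Number of letters that every match must contain (scan priority key)."""
        return sum(
            (len(u.letters) if u.kind == "group" else 1) * u.lo for u in self.units
        )

    def matches(self, word: str) -> bool:
        return self.compiled.fullmatch(word) is not None


def categorize(pattern_text: str) -> str:
    if "L" in pattern_text:
        return "logic-based"
    if "P" in pattern_text:
        return "phrase-based"
    raise ValueError(f"pattern {pattern_text!r} has neither P nor L")


@dataclass
class PatternLibrary:
    """Ordered pattern set; scan priority is longest required skeleton first."""

    patterns: list[RegexPattern] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        unique = []
        for p in self.patterns:
            if p.pattern in seen:
                continue
            seen.add(p.pattern)
            unique.append(p)
        self.patterns = unique
        self._sort()

    def _sort(self) -> None:
        # scan priority: longest required skeleton first, then the more
        # structured pattern (more runs), then insertion order
        order = {id(p): i for i, p in enumerate(self.patterns)}
        self.patterns.sort(
            key=lambda p: (-p.required_length, -len(p.units), order[id(p)])
        )

    def add(self, patterns: list[RegexPattern]) -> None:
        existing = {p.pattern for p in self.patterns}
        for p in patterns:
            if p.pattern not in existing:
                self.patterns.append(p)
                existing.add(p.pattern)
        self._sort()

    def __iter__(self):
        return iter(self.patterns)

    def __len__(self) -> int:
        return len(self.patterns)

    def pattern_set(self) -> set[str]:
        return {p.pattern for p in self.patterns}


def builtin_library() -> PatternLibrary:
    """The six built-in linguistic-pattern classes (4 phrase-based, 2 logic-based)."""
    specs = [
        ("A+P(CP)+", "phrase-based"),
        ("AP+", "phrase-based"),
        ("A+P", "phrase-based"),
        ("A*PC*A+", "phrase-based"),
        ("S*LNU", "logic-based"),
        ("S*LR", "logic-based"),
    ]
    return PatternLibrary(
        [RegexPattern(p, c, provenance="builtin") for p, c in specs]
    )


# ---------------------------------------------------------------------------
# segment abstraction


def _rle(segment: str) -> list[tuple[str, int]]:
    runs: list[tuple[str, int]] = []
    for ch in segment:
        if runs and runs[-1][0] == ch:
            runs[-1] = (ch, runs[-1][1] + 1)
        else:
            runs.append((ch, 1))
    return runs


def _collapse_conjunction(runs: list[tuple[str, int]]):
    """Fold a trailing (CP)^k alternation after a phenotype into one group run."""
    r = list(runs)
    k = 0
    while len(r) >= 3 and r[-1] == ("P", 1) and r[-2] == ("C", 1) and r[-3][0] == "P":
        r = r[:-2]
        k += 1
    if k >= 1 and r and r[-1][0] == "P":
        return r, k
    return list(runs), 0


def _segment_units(segment: str):
    """Skeleton (unit keys) and per-run counts of one trimmed segment."""
    runs, k = _collapse_conjunction(_rle(segment))
    keys = [("lit", letter) for letter, _ in runs]
    counts = [c for _, c in runs]
    if k:
        keys.append(("group", "CP"))
        counts.append(k)
    return tuple(keys), tuple(counts)


def _anchored_embedding(short: tuple, long: tuple) -> list[int] | None:
    """Rightmost order-preserving embedding with the final run anchored."""
    if not short or not long or short[-1] != long[-1] or len(short) >= len(long):
        return None
    positions = [len(long) - 1]
    j = len(long) - 2
    for i in range(len(short) - 2, -1, -1):
        while j >= 0 and long[j] != short[i]:
            j -= 1
        if j < 0:
            return None
        positions.append(j)
        j -= 1
    return positions[::-1]


def _abstract_family(skeleton: tuple, members: list[dict[int, int]]) -> tuple[Unit, ...]:
    """Quantify each run of a merged family (counts keyed by run position)."""
    units: list[Unit] = []
    has_group = any(k[0] == "group" for k in skeleton)
    first_p = next(
        (i for i, k in enumerate(skeleton) if k == ("lit", "P")), len(skeleton)
    )
    for pos, key in enumerate(skeleton):
        counts = [m[pos] for m in members if pos in m]
        absent = len(counts) < len(members)
        if key[0] == "group":
            units.append(Unit("group", key[1], 1, None))
        elif absent:
            units.append(Unit("lit", key[1], 0, None))
        elif len(set(counts)) > 1:
            units.append(Unit("lit", key[1], 1, None))
        elif has_group and key == ("lit", "A") and pos < first_p:
            # conjunction distributes attributes over phenotypes
            units.append(Unit("lit", key[1], 1, None))
        else:
            units.append(Unit("lit", key[1], counts[0], counts[0]))
    return tuple(units)


def _render(units: tuple[Unit, ...]) -> str:
    return "".join(u.render() for u in units)


def reduce_segments(
    segments: list[str],
    provenance: str = "discovered",
    review_flag: bool = False,
) -> list[RegexPattern]:
    """Abstract a family of O-free letter segments into linguistic patterns.

    Every input segment is guaranteed to match one of the returned patterns;
    segments containing neither a phenotype (P) nor an analyte (L) after
    boundary-punctuation trimming are skipped.
    """
    if not segments:
        raise ValueError("no segments to reduce")
    trimmed: list[str] = []
    for seg in segments:
        if "O" in seg:
            raise ValueError(f"segment {seg!r} contains O; split it first")
        if set(seg) - LETTER_SET:
            raise ValueError(f"segment {seg!r} has letters outside the alphabet")
        core = seg.strip("C")
        if len(core) < 2 or not (set(core) & {"P", "L"}):
            logger.debug("segment %r skipped (no phenotype or analyte core)", seg)
            continue
        trimmed.append(core)
    if not trimmed:
        return []

    families: dict[tuple, list[tuple[tuple[int, ...], str]]] = defaultdict(list)
    for seg in trimmed:
        keys, counts = _segment_units(seg)
        families[keys].append((counts, seg))

    # merge each skeleton into a maximal skeleton (anchored subsequence)
    skeletons = sorted(families, key=lambda s: (-len(s), s))
    maximal = [
        s for s in skeletons
        if not any(_anchored_embedding(s, t) for t in skeletons if t != s)
    ]
    clusters: dict[tuple, list[dict[int, int]]] = {s: [] for s in maximal}
    for s in skeletons:
        if s in clusters:
            clusters[s].extend(
                {i: c for i, c in enumerate(counts)} for counts, _ in families[s]
            )
            continue
        host = next(t for t in maximal if _anchored_embedding(s, t))
        emb = _anchored_embedding(s, host)
        clusters[host].extend(
            {emb[i]: c for i, c in enumerate(counts)} for counts, _ in families[s]
        )

    candidates: list[tuple[Unit, ...]] = []
    for skeleton in maximal:
        members = clusters[skeleton]
        has_group = any(k[0] == "group" for k in skeleton)
        has_absent = any(len(m) < len(skeleton) for m in members)
        varying = [
            pos
            for pos in range(len(skeleton))
            if skeleton[pos][0] == "lit"
            and len({m[pos] for m in members if pos in m}) > 1
        ]
        if not has_group and not has_absent and len(varying) >= 2:
            # several runs vary with no optionality evidence: one axis at a time
            base = [min(m[pos] for m in members) for pos in range(len(skeleton))]
            for axis in varying:
                sub = [
                    m for m in members
                    if all(m[p] == base[p] for p in range(len(skeleton)) if p != axis)
                ]
                if sub:
                    candidates.append(_abstract_family(skeleton, sub))
        else:
            candidates.append(_abstract_family(skeleton, members))

    # deduplicate while keeping order
    seen: set[str] = set()
    unique: list[tuple[Unit, ...]] = []
    for units in candidates:
        text = _render(units)
        if text not in seen:
            seen.add(text)
            unique.append(units)

    # assign every segment to the first pattern that matches it; leftovers
    # become literal patterns so the reduction is always sound
    compiled = [(u, re.compile(_render(u))) for u in unique]
    assignment: dict[str, list[str]] = defaultdict(list)
    extras: list[str] = []
    for seg in trimmed:
        for units, rx in compiled:
            if rx.fullmatch(seg):
                assignment[_render(units)].append(seg)
                break
        else:
            extras.append(seg)
    for seg in sorted(set(extras)):
        keys, counts = _segment_units(seg)
        units = tuple(
            Unit("group", k[1], 1, None) if k[0] == "group" else Unit("lit", k[1], c, c)
            for k, c in zip(keys, counts)
        )
        text = _render(units)
        if text not in assignment:
            compiled.append((units, re.compile(text)))
        assignment[text].extend(s for s in extras if s == seg)

    out: list[RegexPattern] = []
    for units, _ in compiled:
        text = _render(units)
        sources = assignment.get(text, [])
        if not sources:
            continue
        out.append(
            RegexPattern(
                pattern=text,
                category=categorize(text),
                provenance=provenance,
                support=len(sources),
                review_flag=review_flag,
                segments=tuple(sorted(set(sources))),
            )
        )
    return out


# ---------------------------------------------------------------------------
# validity and consolidation


def _is_interpretable(p: RegexPattern) -> bool:
    """A pattern must yield non-trivial instances when matched.

    Phrase patterns need a phenotype and at least one required attribute;
    logic patterns need an analyte plus either number+unit or a direction
    word (otherwise the lab normalizer cannot interpret the match).
    """
    required = {u.letters for u in p.units if u.lo >= 1 and u.kind == "lit"}
    in_group = {c for u in p.units if u.kind == "group" and u.lo >= 1 for c in u.letters}
    if p.category == "logic-based":
        return "L" in required and (
            {"N", "U"} <= required or "R" in required
        )
    return "P" in (required | in_group) and "A" in required


def filter_interpretable(patterns: list[RegexPattern]) -> list[RegexPattern]:
    kept = []
    for p in patterns:
        if _is_interpretable(p):
            kept.append(p)
        else:
            logger.info("pattern %r dropped (not interpretable)", p.pattern)
    return kept


def consolidate(patterns: list[RegexPattern]) -> list[RegexPattern]:
    """Drop patterns structurally subsumed by another pattern in the list."""
    kept: list[RegexPattern] = []
    for i, p in enumerate(patterns):
        covered_by = None
        for j, q in enumerate(patterns):
            if i == j or p.pattern == q.pattern:
                continue
            if units_covered(p.units, q.units) and not (
                units_covered(q.units, p.units) and j > i
            ):
                covered_by = q
                break
        if covered_by is None:
            kept.append(p)
        else:
            covered_by.support += p.support
            covered_by.segments = tuple(sorted(set(covered_by.segments + p.segments)))
            logger.info("pattern %r merged into %r", p.pattern, covered_by.pattern)
    return kept


# ---------------------------------------------------------------------------
# enrichment against gold annotations


def _as_doc(doc):
    if isinstance(doc, tuple):
        return doc
    return doc.text, doc.instances


def enrich(
    library: PatternLibrary,
    gold_docs: list,
    lexicon: Lexicon,
    lab_kb=None,
    schema=None,
) -> tuple[PatternLibrary, dict]:
    """Close linguistic-pattern gaps against gold-annotated documents.

    Documents are recognized with the current library; every gold instance
    that is not recovered contributes the letter word of its minimal
    covering span.  The collected words are abstracted with
    :func:`reduce_segments` and added (provenance ``enriched``,
    ``review_flag=True``) unless subsumed by an existing pattern.  The
    report lists each new pattern with exemplar sentences, plus gold spans
    that encode to nothing usable.
    """
    from .encoding import encode
    from .recognize import recognize_document

    words: list[str] = []
    exemplars: dict[str, list[str]] = defaultdict(list)
    unencodable: list[str] = []
    for doc in gold_docs:
        text, gold_instances = _as_doc(doc)
        predicted = recognize_document(text, lexicon, library, lab_kb=lab_kb, schema=schema)
        pred_keys = {inst.key(with_span=True) for inst in predicted}
        seq = None
        for gold in gold_instances:
            if gold.key(with_span=True) in pred_keys:
                continue
            if seq is None:
                seq = encode(text, lexicon)
            spans = [gold.phenotype_span] + [
                span for _, span in gold.attributes.values() if span is not None
            ]
            lo = min(s for s, _ in spans)
            hi = max(e for _, e in spans)
            idx = [
                i for i, (s, e) in enumerate(seq.spans) if s < hi and e > lo
            ]
            if idx:
                # expand to the enclosing O-free clause so the word carries
                # the phenotype's full local context even when the gold
                # annotations record no attribute evidence spans
                i0, i1 = idx[0], idx[-1]
                while i0 > 0 and seq.letters[i0 - 1] != "O":
                    i0 -= 1
                while i1 + 1 < len(seq.letters) and seq.letters[i1 + 1] != "O":
                    i1 += 1
                word = seq.letters[i0 : i1 + 1]
            else:
                word = ""
            if not word.strip("O"):
                unencodable.append(text[lo:hi])
                continue
            words.append(word)
            exemplars[word].append(text[lo:hi])

    report: dict = {"added": [], "unencodable": unencodable, "words": sorted(set(words))}
    if not words:
        return library, report

    new = filter_interpretable(
        reduce_segments(words, provenance="enriched", review_flag=True)
    )
    merged = consolidate(list(library) + new)
    existing_texts = library.pattern_set()
    out = PatternLibrary(merged)
    for p in out:
        if p.pattern not in existing_texts and p.provenance == "enriched":
            report["added"].append(
                {
                    "pattern": p.pattern,
                    "segments": list(p.segments),
                    "exemplars": [
                        ex for seg in p.segments for ex in exemplars.get(seg, [])
                    ][:5],
                }
            )
    return out, report


def enrichment_report_markdown(report: dict) -> str:
    lines = ["# Pattern enrichment report", ""]
    if not report["added"]:
        lines.append("No new patterns were added.")
    for item in report["added"]:
        lines.append(f"## `{item['pattern']}` (pending review)")
        lines.append("")
        lines.append(f"Source segments: {', '.join(item['segments'])}")
        for ex in item["exemplars"]:
            lines.append(f"- {ex}")
        lines.append("")
    if report["unencodable"]:
        lines.append("## Unencodable gold spans")
        lines.extend(f"- {t}" for t in report["unencodable"])
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# end-to-end pattern learning (fit-shaped)


class PatternLearner(BaseEstimator):
    """Learn a linguistic-pattern library from raw documents.

    ``fit(X, y)`` encodes the documents with the lexicon, discovers motifs
    with :class:`~phenossu.motifs.MotifMiner`, splits consensus strings on
    O, abstracts the segments into patterns and, when gold instances ``y``
    are supplied, runs gap-driven enrichment to a fixed point.  The learned
    library is in ``library_``; the fitted miner in ``miner_``.
    """

    def __init__(
        self,
        lexicon: Lexicon | None = None,
        lab_kb=None,
        schema=None,
        min_w: int = 2,
        max_w: int = 5,
        n_motifs: int = 8,
        n_shuffles: int = 99,
        evalue_threshold: float = 0.05,
        max_null_starts: int | None = 100,
        random_state: int = 0,
    ):
        self.lexicon = lexicon
        self.lab_kb = lab_kb
        self.schema = schema
        self.min_w = min_w
        self.max_w = max_w
        self.n_motifs = n_motifs
        self.n_shuffles = n_shuffles
        self.evalue_threshold = evalue_threshold
        self.max_null_starts = max_null_starts
        self.random_state = random_state

    def fit(self, X: list[str], y: list[list] | None = None) -> "PatternLearner":
        from .encoding import encode
        from .motifs import MotifMiner
        from .schema import default_lexicon

        lexicon = self.lexicon if self.lexicon is not None else default_lexicon()
        sequences = [encode(text, lexicon).letters for text in X]
        self.miner_ = MotifMiner(
            min_w=self.min_w,
            max_w=self.max_w,
            n_motifs=self.n_motifs,
            n_shuffles=self.n_shuffles,
            evalue_threshold=self.evalue_threshold,
            max_null_starts=self.max_null_starts,
            random_state=self.random_state,
        ).fit(sequences)
        # keep only corpus-attested consensus segments: a segment that never
        # occurs verbatim is an artifact of a diffuse PWM consensus
        attested = [
            seg for seg in self.miner_.segments_
            if any(seg in s for s in sequences)
        ]
        discovered: list[RegexPattern] = []
        if attested:
            discovered = filter_interpretable(
                reduce_segments(attested, provenance="discovered")
            )
        library = PatternLibrary(consolidate(discovered))
        self.enrichment_report_ = None
        if y is not None:
            library, self.enrichment_report_ = enrich(
                library, list(zip(X, y)), lexicon, lab_kb=self.lab_kb, schema=self.schema
            )
        self.library_ = library
        return self


# ---------------------------------------------------------------------------
# persistence


def save_library(library: PatternLibrary, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("category\tpattern\tprovenance\tsupport\n")
        for p in library:
            fh.write(f"{p.category}\t{p.pattern}\t{p.provenance}\t{p.support}\n")


def load_library(path) -> PatternLibrary:
    patterns = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("category"):
            raise ValueError(f"{path}: not a pattern library file")
        for line in fh:
            if not line.strip():
                continue
            category, pattern, provenance, support = line.rstrip("\n").split("\t")
            patterns.append(
                RegexPattern(
                    pattern=pattern,
                    category=category,
                    provenance=provenance,
                    support=int(support),
                    review_flag=provenance == "enriched",
                )
            )
    return PatternLibrary(patterns)
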