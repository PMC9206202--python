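"""Synthetic clinical corpora with gold annotations, and planted-motif
sequences for testing the miner.

The corpus generator emulates the structure of phenotype narratives in
clinical records: each sentence instantiates one of the six
linguistic-pattern classes (a phenotype preceded by attribute triggers, a
negated conjunction of phenotypes, a trailing-attribute construction, or a
lab result as analyte + value + unit or analyte + direction word),
surrounded by narrative filler and sentence punctuation.  Gold annotations
(entities with exact spans, plus full PhenoSSU instances) are emitted by
construction.  Everything is deterministic given the seed.

Filler runs are drawn from a closed list of tokens that never collide with
lexicon surfaces, and by default separate every pair of sentences — in real
records phenotype phrases are embedded in narrative text, and the spacing
keeps adjacent pattern sentences from blending into each other.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .labnorm import classify_value
from .motifs import Background
from .alphabet import ALPHABET
from .encoding import parse_number
from .recognize import PhenoSSUInstance
from .schema import LabKBEntry, Lexicon, default_lab_kb, default_lexicon

Span = tuple[int, int]

#: narrative filler that encodes to O with the shipped lexicon
FILLER_TOKENS = (
    "患者主诉",
    "入院后",
    "既往史如前",
    "精神状态良好",
    "饮食睡眠可",
    "自述近日来",
    "查随访记录",
)

PATTERN_CLASSES = ("A+P(CP)+", "AP+", "A+P", "A*PC*A+", "S*LNU", "S*LR")

#: default class mix: negated conjunctions and attribute+phenotype phrases
#: dominate, lab results are a smaller share
DEFAULT_WEIGHTS = {
    "A+P(CP)+": 0.15,
    "AP+": 0.25,
    "A+P": 0.22,
    "A*PC*A+": 0.13,
    "S*LNU": 0.15,
    "S*LR": 0.10,
}

_ENTITY_TYPES = {
    "P": "Phenotype",
    "S": "Specimen",
    "L": "Analyte",
    "N": "Number",
    "U": "Unit",
    "R": "Result",
}


@dataclass
class GeneratorConfig:
    n_docs: int = 500
    sentences_per_doc: tuple[int, int] = (2, 5)
    template_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    filler_rate: float = 1.0
    lexicon: Lexicon | None = None
    lab_kb: list[LabKBEntry] | None = None
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.template_weights.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"template weights sum to {total}, expected 1")
        if not all(0 <= r <= 1 for r in (self.filler_rate, self.noise_rate)):
            raise ValueError("rates must lie in [0, 1]")
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")
        unknown = set(self.template_weights) - set(PATTERN_CLASSES)
        if unknown:
            raise ValueError(f"unknown template classes: {sorted(unknown)}")


@dataclass
class SyntheticDocument:
    doc_id: str
    text: str
    entities: list[tuple[str, int, int]]  # (type, start, end)
    instances: list[PhenoSSUInstance]


class _LexiconPools:
    def __init__(self, lexicon: Lexicon):
        self.phenotypes = [e for e in lexicon if e.letter == "P"]
        self.attributes: dict[str, list] = {}
        for e in lexicon:
            if e.letter == "A":
                self.attributes.setdefault(e.category, []).append(e)
        self.specimens = {e.normalization: e for e in lexicon if e.letter == "S"}
        self.analytes: dict[str, list] = {}
        for e in lexicon:
            if e.letter == "L":
                self.analytes.setdefault(e.normalization, []).append(e)
        self.directions = [e for e in lexicon if e.letter == "R"]
        self.units = {e.normalization: e for e in lexicon if e.letter == "U"}

    def require(self, letter: str, what: str) -> None:
        pools = {
            "P": self.phenotypes,
            "A": self.attributes,
            "S": self.specimens,
            "L": self.analytes,
            "R": self.directions,
            "U": self.units,
        }
        if not pools[letter]:
            raise ValueError(f"lexicon has no {letter} entries; cannot build {what}")


def _choice(rng: np.random.Generator, items: list):
    return items[int(rng.integers(len(items)))]


def _sample_categories(rng, pools: _LexiconPools, k: int, exclude=()):
    cats = [c for c in sorted(pools.attributes) if c not in exclude]
    k = min(k, len(cats))
    idx = rng.choice(len(cats), size=k, replace=False)
    return [cats[int(i)] for i in sorted(idx)]


@dataclass
class _Piece:
    surface: str
    letter: str
    category: str = ""
    value: str = ""


def _phrase_instance(concept, pieces_attrs, p_piece_index, assertion_default="present"):
    """Attribute map (without spans yet) for one phenotype of a phrase sentence."""
    attrs = {cat: val for cat, val in pieces_attrs}
    if "assertion" not in attrs:
        attrs["assertion"] = assertion_default
    return attrs


class CorpusGenerator:
    """Template-based document generator (one instance per phenotype)."""

    def __init__(self, config: GeneratorConfig):
        self.config = config
        self.lexicon = config.lexicon if config.lexicon is not None else default_lexicon()
        self.lab_kb = config.lab_kb if config.lab_kb is not None else default_lab_kb()
        self.pools = _LexiconPools(self.lexicon)
        phrase_weight = sum(
            w for c, w in config.template_weights.items() if not c.startswith("S")
        )
        if phrase_weight > 0:
            self.pools.require("P", "phrase templates")
            self.pools.require("A", "phrase templates")
        if config.template_weights.get("S*LNU", 0) > 0:
            self.pools.require("L", "S*LNU")
            self.pools.require("U", "S*LNU")
        if config.template_weights.get("S*LR", 0) > 0:
            self.pools.require("L", "S*LR")
            self.pools.require("R", "S*LR")
        self._usable_kb = [
            e for e in self.lab_kb if e.analyte in self.pools.analytes
        ]
        if not self._usable_kb and any(
            config.template_weights.get(c, 0) > 0 for c in ("S*LNU", "S*LR")
        ):
            raise ValueError("no lab KB entry has a matching analyte lexicon entry")

    # -- sentence templates -------------------------------------------------

    def _attr_pieces(self, rng, cats):
        pieces = []
        for cat in cats:
            entry = _choice(rng, self.pools.attributes[cat])
            pieces.append(_Piece(entry.surface, "A", cat, entry.normalization))
        return pieces

    def _sentence_a_plus_p(self, rng):
        cats = _sample_categories(rng, self.pools, int(rng.integers(1, 5)))
        pieces = self._attr_pieces(rng, cats)
        p = _choice(rng, self.pools.phenotypes)
        pieces.append(_Piece(p.surface, "P", value=p.normalization))
        attrs = _phrase_instance(p.normalization, [(x.category, x.value) for x in pieces[:-1]], len(pieces) - 1)
        return pieces, [(len(pieces) - 1, p.normalization, attrs)]

    def _sentence_ap_plus(self, rng):
        # most often a negation distributing over several phenotypes
        if "assertion" in self.pools.attributes and rng.random() < 0.6:
            cat = "assertion"
        else:
            cat = _sample_categories(rng, self.pools, 1)[0]
        a = _choice(rng, self.pools.attributes[cat])
        n_p = int(rng.integers(2, 5))
        idx = rng.choice(len(self.pools.phenotypes), size=min(n_p, len(self.pools.phenotypes)), replace=False)
        pieces = [_Piece(a.surface, "A", cat, a.normalization)]
        out = []
        for i in idx:
            p = self.pools.phenotypes[int(i)]
            pieces.append(_Piece(p.surface, "P", value=p.normalization))
            attrs = _phrase_instance(p.normalization, [(cat, a.normalization)], None)
            out.append((len(pieces) - 1, p.normalization, attrs))
        return pieces, out

    def _sentence_conjunction(self, rng):
        cats = _sample_categories(rng, self.pools, int(rng.integers(1, 3)))
        pieces = self._attr_pieces(rng, cats)
        shared = [(x.category, x.value) for x in pieces]
        n_p = 2 + int(rng.integers(0, 3))
        idx = rng.choice(len(self.pools.phenotypes), size=min(n_p, len(self.pools.phenotypes)), replace=False)
        out = []
        for j, i in enumerate(idx):
            if j > 0:
                pieces.append(_Piece("、" if rng.random() < 0.5 else "，", "C"))
            p = self.pools.phenotypes[int(i)]
            pieces.append(_Piece(p.surface, "P", value=p.normalization))
            out.append((len(pieces) - 1, p.normalization, _phrase_instance(p.normalization, shared, None)))
        return pieces, out

    def _sentence_trailing(self, rng):
        n_lead = int(rng.integers(0, 3))
        has_comma = bool(rng.integers(0, 2)) if n_lead == 0 else True
        # with a leading attribute the pause before the trailing attribute is
        # written out, which keeps the construction unambiguous
        n_trail = 1 + int(rng.integers(0, 2))
        lead_cats = _sample_categories(rng, self.pools, n_lead, exclude=("assertion",))
        trail_cats = _sample_categories(
            rng, self.pools, n_trail, exclude=("assertion", *lead_cats)
        )
        pieces = self._attr_pieces(rng, lead_cats)
        p = _choice(rng, self.pools.phenotypes)
        p_index = len(pieces)
        pieces.append(_Piece(p.surface, "P", value=p.normalization))
        if has_comma:
            pieces.append(_Piece("，", "C"))
        pieces += self._attr_pieces(rng, trail_cats)
        all_attrs = [(x.category, x.value) for x in pieces if x.letter == "A"]
        return pieces, [(p_index, p.normalization, _phrase_instance(p.normalization, all_attrs, p_index))]

    def _format_value(self, entry: LabKBEntry, canonical: float):
        """Written (number text, unit surface) for a canonical value."""
        m = re.fullmatch(r"10\^(\d+)/L", entry.unit)
        if m and "/L" in self.pools.units:
            return f"{round(canonical, 1):g}×10^{m.group(1)}", "/L"
        return f"{round(canonical, 1):g}", entry.unit

    def _draw_value(self, rng, entry: LabKBEntry) -> float:
        kind = rng.choice(["higher", "lower", "normal"], p=[0.4, 0.2, 0.4])
        span = entry.high - entry.low
        if kind == "higher":
            return entry.high + span * (0.1 + 0.9 * rng.random())
        if kind == "lower":
            return max(0.0, entry.low - span * (0.1 + 0.9 * rng.random()))
        return entry.low + span * (0.15 + 0.7 * rng.random())

    def _lab_common(self, rng):
        entry = _choice(rng, self._usable_kb)
        pieces = []
        specimen_written = False
        if entry.specimen and entry.specimen in self.pools.specimens and rng.random() < 0.5:
            s = self.pools.specimens[entry.specimen]
            pieces.append(_Piece(s.surface, "S", value=s.normalization))
            specimen_written = True
        lex = _choice(rng, self.pools.analytes[entry.analyte])
        pieces.append(_Piece(lex.surface, "L", value=entry.analyte))
        return entry, pieces, specimen_written

    def _lab_attrs(self, entry, abnormality, specimen_written):
        attrs = {"analyte": entry.analyte, "abnormality": abnormality}
        if entry.specimen:
            attrs["specimen"] = entry.specimen
        return attrs

    def _sentence_lnu(self, rng):
        entry, pieces, specimen_written = self._lab_common(rng)
        value = self._draw_value(rng, entry)
        number_text, unit_surface = self._format_value(entry, value)
        pieces.append(_Piece(number_text, "N"))
        pieces.append(_Piece(unit_surface, "U", value=unit_surface))
        # gold abnormality from the *written* value, like the recognizer
        written = parse_number(number_text)
        canonical = entry.to_canonical(written, unit_surface)
        abnormality = classify_value(entry, canonical)
        l_index = 1 if specimen_written else 0
        attrs = self._lab_attrs(entry, abnormality, specimen_written)
        meta = (entry, abnormality)
        return pieces, [(l_index, f"{entry.analyte} {abnormality}", attrs, meta)]

    def _sentence_lr(self, rng):
        entry, pieces, specimen_written = self._lab_common(rng)
        r = _choice(rng, self.pools.directions)
        pieces.append(_Piece(r.surface, "R", value=r.normalization))
        abnormality = r.normalization
        l_index = 1 if specimen_written else 0
        attrs = self._lab_attrs(entry, abnormality, specimen_written)
        meta = (entry, abnormality)
        return pieces, [(l_index, f"{entry.analyte} {abnormality}", attrs, meta)]

    # -- document assembly --------------------------------------------------

    def _build_sentence(self, rng, cls: str):
        builder = {
            "A+P": self._sentence_a_plus_p,
            "AP+": self._sentence_ap_plus,
            "A+P(CP)+": self._sentence_conjunction,
            "A*PC*A+": self._sentence_trailing,
            "S*LNU": self._sentence_lnu,
            "S*LR": self._sentence_lr,
        }[cls]
        return builder(rng)

    def generate(self) -> list[SyntheticDocument]:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        classes = sorted(cfg.template_weights)
        probs = np.array([cfg.template_weights[c] for c in classes])
        probs = probs / probs.sum()
        docs = []
        for d in range(cfg.n_docs):
            doc_id = f"doc{d:04d}"
            n_sent = int(rng.integers(cfg.sentences_per_doc[0], cfg.sentences_per_doc[1] + 1))
            text_parts: list[str] = []
            offset = 0
            entities: list[tuple[str, int, int]] = []
            instances: list[PhenoSSUInstance] = []

            def emit(chunk: str) -> int:
                nonlocal offset
                start = offset
                text_parts.append(chunk)
                offset += len(chunk)
                return start

            for _ in range(n_sent):
                if rng.random() < cfg.filler_rate:
                    for _ in range(int(rng.integers(1, 3))):
                        emit(_choice(rng, list(FILLER_TOKENS)))
                cls = classes[int(rng.choice(len(classes), p=probs))]
                pieces, specs = self._build_sentence(rng, cls)
                spans: list[Span] = []
                for piece in pieces:
                    start = emit(piece.surface)
                    spans.append((start, start + len(piece.surface)))
                    if piece.letter in _ENTITY_TYPES:
                        entities.append((_ENTITY_TYPES[piece.letter], *spans[-1]))
                    elif piece.letter == "A":
                        etype = piece.category.title().replace(" ", "_")
                        entities.append((etype, *spans[-1]))
                emit("。")
                for spec in specs:
                    if cls in ("S*LNU", "S*LR"):
                        p_index, concept, attrs, meta = spec
                        entry, abnormality = meta
                        inst = PhenoSSUInstance(
                            phenotype=concept,
                            phenotype_span=spans[p_index],
                            attributes=self._attr_spans(pieces, spans, attrs, p_index),
                            category="logic-based",
                            snomed=entry.snomed_map.get(abnormality),
                            doc_id=doc_id,
                        )
                    else:
                        p_index, concept, attrs = spec
                        inst = PhenoSSUInstance(
                            phenotype=concept,
                            phenotype_span=spans[p_index],
                            attributes=self._attr_spans(pieces, spans, attrs, p_index),
                            category="phrase-based",
                            doc_id=doc_id,
                        )
                    instances.append(inst)
            instances.sort(key=lambda x: (x.phenotype_span or (0, 0), x.phenotype))
            docs.append(
                SyntheticDocument(
                    doc_id=doc_id,
                    text="".join(text_parts),
                    entities=entities,
                    instances=instances,
                )
            )
        return docs

    @staticmethod
    def _attr_spans(pieces, spans, attrs: dict[str, str], p_index: int):
        """Attach evidence spans to attribute values (None for defaults)."""
        out: dict[str, tuple[str, Span | None]] = {}
        for cat, val in attrs.items():
            span = None
            if cat in ("analyte",):
                span = spans[p_index]
            elif cat == "specimen":
                for k, piece in enumerate(pieces):
                    if piece.letter == "S" and piece.value == val:
                        span = spans[k]
                        break
            elif cat == "abnormality":
                # evidence is the written result: number plus unit, or the
                # direction word
                lo = hi = None
                for k, piece in enumerate(pieces):
                    if piece.letter in "NUR":
                        lo = spans[k][0] if lo is None else lo
                        hi = spans[k][1]
                if lo is not None:
                    span = (lo, hi)
            else:
                for k, piece in enumerate(pieces):
                    if piece.letter == "A" and piece.category == cat and piece.value == val:
                        span = spans[k]
                        break
            out[cat] = (val, span)
        return out


def generate_corpus(config: GeneratorConfig | None = None, **kwargs) -> list[SyntheticDocument]:
    """Generate a gold-annotated synthetic corpus (deterministic given the seed)."""
    if config is None:
        config = GeneratorConfig(**kwargs)
    return CorpusGenerator(config).generate()


def generate_planted_sequences(
    background: Background,
    word: str,
    copies: int,
    n_seqs: int,
    seq_len: int,
    noise_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[str], list[tuple[int, int]]]:
    """Background sequences with ``copies`` non-overlapping planted words.

    Each planted letter is independently corrupted (replaced by a different
    alphabet letter) with probability ``noise_rate``.  Returns the sequences
    and the ground-truth (sequence id, offset) sites.
    """
    w = len(word)
    if set(word) - set(ALPHABET):
        raise ValueError(f"word {word!r} not over the alphabet")
    capacity_per_seq = seq_len // w
    if copies > capacity_per_seq * n_seqs:
        raise ValueError(
            f"cannot pack {copies} copies of a width-{w} word into "
            f"{n_seqs} sequences of length {seq_len}"
        )
    rng = np.random.default_rng(seed)
    # deal copies to sequences as evenly as allowed
    per_seq = [0] * n_seqs
    for c in range(copies):
        candidates = [i for i in range(n_seqs) if per_seq[i] < capacity_per_seq]
        order = sorted(candidates, key=lambda i: per_seq[i])
        per_seq[order[int(rng.integers(len(order)))] if len(order) > 1 else order[0]] += 1
    sequences, sites = [], []
    probs = background.freqs / background.freqs.sum()
    letters = np.array(list(ALPHABET))
    for sid in range(n_seqs):
        seq = list(rng.choice(letters, size=seq_len, p=probs))
        k = per_seq[sid]
        if k:
            # non-overlapping offsets via the gap transform
            free = seq_len - k * w
            cuts = np.sort(rng.choice(free + k, size=k, replace=False))
            offsets = [int(cuts[i]) + i * (w - 1) for i in range(k)]
            for off in offsets:
                for j, ch in enumerate(word):
                    if noise_rate > 0 and rng.random() < noise_rate:
                        others = [c for c in ALPHABET if c != ch]
                        seq[off + j] = others[int(rng.integers(len(others)))]
                    else:
                        seq[off + j] = ch
                sites.append((sid, off))
        sequences.append("".join(seq))
    return sequences, sites
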