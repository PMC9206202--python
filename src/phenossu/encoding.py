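"""Encode free text as a single-letter sequence with span back-mapping.

Lexicon surface forms are matched leftmost-longest with a trie; numeric
literals (including scientific forms like ``12.5×10^9``) become one ``N``
letter carrying the parsed value; clause punctuation becomes ``C``; maximal
unmatched runs collapse to a single ``O``.  Every letter records the exact
half-open character span it came from (0-based code points, brat
compatible), so pattern matches over letters can always be mapped back to
the original text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any

from .alphabet import LETTER_SET
from .schema import Lexicon

#: clause-level punctuation encoded as C; everything else unmatched becomes O
PUNCTUATION = frozenset("，,、;；。:：")

_FULLWIDTH_DIGITS = str.maketrans("０１２３４５６７８９．", "0123456789.")

#: sign, decimal number, optional "×10^k" / "×10k" / e-notation exponent
NUMBER_RE = re.compile(
    r"""[+-]?\d+(?:\.\d+)?
        (?:
            \s*[×xX*]\s*10(?:\^|\*\*)?[+-]?\d+
          | [eE][+-]?\d+
        )?""",
    re.VERBOSE,
)

_EXP_RE = re.compile(r"\s*[×xX*]\s*10(?:\^|\*\*)?([+-]?\d+)$")


def parse_number(text: str) -> float:
    """Evaluate a numeric literal matched by :data:`NUMBER_RE`."""
    text = text.translate(_FULLWIDTH_DIGITS)
    m = _EXP_RE.search(text)
    if m:
        mantissa = float(text[: m.start()])
        return mantissa * 10.0 ** int(m.group(1))
    return float(text)


@dataclass
class EncodedSequence:
    """A letter string plus, per letter, its source span and payload.

    Payloads carry the lexicon normalization for P/A/S/L/R letters (for A
    letters a ``(category, value)`` tuple), the parsed numeric value for N,
    the unit surface for U, and ``None`` for C/O.
    """

    source: str
    letters: str = ""
    spans: list[tuple[int, int]] = field(default_factory=list)
    payloads: list[Any] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (len(self.letters) == len(self.spans) == len(self.payloads)):
            raise ValueError("letters, spans and payloads must have equal length")

    def __len__(self) -> int:
        return len(self.letters)

    def validate(self) -> None:
        """Check the structural invariants (span coverage, alphabet, order)."""
        pos = 0
        for letter, (start, end) in zip(self.letters, self.spans):
            if letter not in LETTER_SET:
                raise ValueError(f"letter {letter!r} outside the alphabet")
            if start != pos or end <= start:
                raise ValueError(f"span ({start},{end}) breaks exact coverage at {pos}")
            pos = end
        if pos != len(self.source):
            raise ValueError(f"spans cover [0,{pos}) but source has {len(self.source)} chars")

    def decode_span(self, i: int, j: int) -> tuple[int, int, str]:
        """Smallest character interval covering letters ``i..j-1``.

        Returns ``(start, end, substring)`` with ``substring == source[start:end]``.
        """
        if not (0 <= i < j <= len(self.letters)):
            raise IndexError(f"letter range [{i},{j}) out of bounds for {len(self.letters)}")
        start = self.spans[i][0]
        end = self.spans[j - 1][1]
        return start, end, self.source[start:end]


class _TrieNode(dict):
    __slots__ = ("entry",)

    def __init__(self) -> None:
        super().__init__()
        self.entry = None


def build_trie(lexicon: Lexicon) -> _TrieNode:
    root = _TrieNode()
    for e in lexicon:
        node = root
        for ch in e.surface:
            node = node.setdefault(ch, _TrieNode())
        node.entry = e
    return root


def _trie_longest(root: _TrieNode, text: str, pos: int):
    """Longest lexicon entry starting at ``pos``, or None."""
    node, best, best_end = root, None, pos
    for i in range(pos, len(text)):
        node = node.get(text[i])
        if node is None:
            break
        if node.entry is not None:
            best, best_end = node.entry, i + 1
    return best, best_end


def encode(text: str, lexicon: Lexicon) -> EncodedSequence:
    """Encode ``text`` into a single-letter sequence over {P,A,C,O,S,L,N,U,R}.

    Matching is leftmost-longest; at a position where both a lexicon surface
    and a numeric literal start, the longer match wins (ties go to the
    lexicon).  Unmatched runs collapse to one O per maximal run; runs that
    are pure whitespace are absorbed into the neighbouring letter's span so
    that spans still tile the text exactly.
    """
    root = build_trie(lexicon)
    norm = text.translate(_FULLWIDTH_DIGITS)
    letters: list[str] = []
    spans: list[tuple[int, int]] = []
    payloads: list[Any] = []
    pending_start: int | None = None  # start of the current unmatched run

    def flush(end: int, next_start_known: bool) -> int:
        """Close the pending unmatched run ending at ``end``.

        Returns the start offset the next letter should use (whitespace-only
        runs are glued to a neighbour instead of becoming O).
        """
        nonlocal pending_start
        if pending_start is None:
            return end
        start, pending_start = pending_start, None
        if text[start:end].isspace():
            if letters:  # glue to the previous letter
                s0, _ = spans[-1]
                spans[-1] = (s0, end)
                return end
            return start  # glue to the following letter
        letters.append("O")
        spans.append((start, end))
        payloads.append(None)
        return end

    i = 0
    n = len(text)
    while i < n:
        entry, entry_end = _trie_longest(root, text, i)
        num = NUMBER_RE.match(norm, i)
        num_end = num.end() if num else i
        if entry is not None and entry_end >= num_end:
            start = flush(i, True)
            letter = entry.letter
            if letter == "A":
                payload: Any = (entry.category, entry.normalization)
            else:
                payload = entry.normalization
            letters.append(letter)
            spans.append((start, entry_end))
            payloads.append(payload)
            i = entry_end
        elif num is not None and num_end > i:
            start = flush(i, True)
            letters.append("N")
            spans.append((start, num_end))
            payloads.append(parse_number(norm[i:num_end]))
            i = num_end
        elif text[i] in PUNCTUATION:
            start = flush(i, True)
            letters.append("C")
            spans.append((start, i + 1))
            payloads.append(None)
            i += 1
        else:
            if pending_start is None:
                pending_start = i
            i += 1
    flush(n, False)
    # trailing whitespace with no previous letter: whole text is whitespace/empty
    if not letters and text:
        letters, spans, payloads = ["O"], [(0, n)], [None]
    seq = EncodedSequence(source=text, letters="".join(letters), spans=spans, payloads=payloads)
    seq.validate()
    return seq


def decode_span(seq: EncodedSequence, i: int, j: int) -> tuple[int, int, str]:
    """Functional alias for :meth:`EncodedSequence.decode_span`."""
    return seq.decode_span(i, j)
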