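"""The single-letter alphabet used to encode clinical text.

Each chunk of text is mapped to one letter: P (phenotype), A (attribute
trigger), C (punctuation), O (other/filler), S (specimen), L (analyte),
N (number), U (unit), R (lab-result direction word).  The mask letter is
reserved for motif-site erasure during sequential discovery and is never
produced by the encoder.
"""

ALPHABET = "PACOSLNUR"
LETTER_SET = frozenset(ALPHABET)
LETTER_INDEX = {c: i for i, c in enumerate(ALPHABET)}

#: letters a lexicon may assign to a surface form (O is derived, never listed)
LEXICON_LETTERS = frozenset("PACSLNUR")

#: reserved symbol used to erase discovered motif sites between rounds
MASK_LETTER = "Z"
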