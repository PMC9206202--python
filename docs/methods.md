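# Methods

## The PhenoSSU information model

A PhenoSSU instance is an entity–attribute–value record: one phenotype
concept plus a fixed set of ten attribute slots.  Seven slots describe
phrase-based phenotypes — assertion, severity, temporal pattern,
laterality, spatial pattern, quadrant pattern, body location — and three
describe logic-based phenotypes (lab results) — specimen, analyte,
abnormality.  Every attribute has a closed value set (user-extensible via
the YAML schema); abnormality is exactly {higher, lower, normal};
assertion defaults to `present` because clinical prose rarely asserts
presence explicitly.  SNOMED CT codes are opaque normalization labels; no
terminology service is involved.

## Encoding

The encoder is deliberately a dictionary machine, not a tagger: surface
forms from a lexicon are matched leftmost-longest over a character trie
(ties between letters for one surface are a lexicon-validation error), and
each emitted letter records its half-open span in Unicode code points
(brat-compatible).  Design points:

* One `O` per *maximal* unmatched run, so narrative filler of any length
  is a single symbol.
* The number grammar accepts signs, decimals, full-width digits, and
  scientific forms `×10^k`, `×10k`, and e-notation, so "12.5 × 10⁹" is a
  single `N` with payload 1.25e10.
* Whitespace-only unmatched runs are glued to a neighbouring letter's
  span; this keeps the invariant that spans tile the document exactly,
  which in turn makes the decode round trip (concatenating single-letter
  decodes reproduces the source byte for byte) testable as a property.
* Sentence boundaries do not reset encoding; clause and sentence
  punctuation are both `C`.  Consequence: when two pattern sentences are
  directly adjacent with no intervening text, a trailing-attribute pattern
  can in principle read across the boundary.  In practice phenotype
  phrases are embedded in narrative, and the synthetic generator reflects
  that (see below).

## Motif discovery

The site model is a two-component mixture (the "any number of
repetitions" distribution): every length-w window of the corpus is
independently a motif site with probability λ.  EM alternates a posterior
E-step with a pseudocounted M-step.  Numerical choices:

* **Pseudocount 0.1 per PWM cell.**  The objective EM ascends is therefore
  the window log-likelihood *plus* the Dirichlet term
  `0.1·Σ log θ`; the returned per-iteration trace records that penalized
  objective, which is provably non-decreasing (the plain likelihood can
  dip by O(pseudocount) and would make the monotonicity property
  unassertable).
* **λ initialisation** `min(0.1, √n/n)` for n windows; **tol 1e-6**;
  **max_iter 200**.  `tol=inf` is defined to take no M-step, so the seed
  PWM is returned unchanged.
* **Warm starts.**  Every distinct w-mer in the data seeds one EM
  iteration (vectorised across seeds); the best start by the penalized
  likelihood is run to convergence.  Ties break lexicographically.
* **Site selection.**  Windows with posterior > 0.5, taken greedily by
  descending posterior, never overlapping within a sequence.  The motif
  LLR is the summed log-odds of the selected sites.
* **E-values by resampling.**  The null is a composition-preserving letter
  permutation of the corpus; per shuffle the same width-w discovery is
  rerun and its LLR recorded; `p = (1+#{null ≥ obs})/(n_shuffles+1)` and
  `E = p × widths_scanned`.  The shuffle is canonicalised (letters pooled
  and sorted before permutation, sequences taken in sorted order) so
  discovery is invariant to the order of input sequences.  Null reruns cap
  warm starts at the 100 most frequent w-mers: shuffled corpora have far
  more distinct w-mers than real encoded text, and the cap bounds the
  null's cost without touching the observed fit.
* **Sequential erasure.**  Per round the minimum-E width wins (ties to the
  larger LLR) and its sites are replaced by a reserved mask letter that
  never enters windows; discovery stops when no width reaches E < 0.05.
  The 0.05 default is a convention — the threshold is exposed in the
  estimator parameters.

Note the minimum attainable E-value is `widths_scanned/(n_shuffles+1)`;
callers must budget shuffles accordingly (the pattern learner's defaults,
widths 2–5 with 99 shuffles, give a floor of 0.04).

## From motifs to linguistic patterns

Motif consensus strings are split on `O`, and segments shorter than two
letters are dropped.  The pattern learner additionally keeps only
*corpus-attested* segments (occurring verbatim in the encoded corpus):
a diffuse PWM can have a consensus that never occurs, and such artifacts
should not seed patterns.  Abstraction then proceeds:

1. boundary punctuation is trimmed (like `O`, a leading or trailing comma
   binds nothing);
2. a trailing `(CP)^k` alternation after a phenotype collapses into the
   conjunction group `(CP)+`, and the preceding attribute run is promoted
   to `A+` — in a conjunction the attribute distributes over the conjoined
   phenotypes, so its multiplicity is inherently variable (this is what
   turns the single exemplar `APCPCP` into `A+P(CP)+`);
3. segments group by run skeleton; a skeleton that embeds into a longer
   one as an order-preserving subsequence *with the final run anchored*
   merges into it, missing runs becoming `*` (zero-or-more) — anchoring
   the final run prevents `A+P` from dissolving into `A*PC*A+`;
4. within a family, a run with varying length becomes `+`, a constant run
   stays literal; when several runs vary and there is no optionality
   evidence, the family is split one varying axis at a time, which
   separates `A+P` (attributes vary, one phenotype) from `AP+` (one
   attribute, phenotypes vary) even though both share the skeleton (A, P);
5. any segment not matched by a produced pattern falls back to its literal
   pattern, so reduction is sound by construction (every source segment
   matches its pattern).

Induced patterns pass an interpretability filter — a phrase pattern must
bind at least one *required* attribute to a phenotype, a logic pattern
must be normalizable (analyte with number+unit, or analyte with a
direction word) — and a structural-subsumption consolidation that folds
specializations (e.g. a literal `AAP`) into their generalization (`A+P`),
summing support.  The zero-or-more reading of optional runs (rather than
`?`) follows the pattern classes' own notation, where a marked letter may
be absent or repeated.

Enrichment recognizes gold-annotated documents with the current library;
for every gold instance not recovered exactly, the minimal covering span
of its evidence is expanded to the enclosing O-free clause and its letter
word collected.  The words are abstracted with the same reduction,
consolidated against the library, and added with provenance `enriched`
and `review_flag=true` — the human checkpoint of a semi-automatic loop is
preserved as a review report rather than a blocking prompt.  Enrichment is
idempotent: a second pass on the same documents adds nothing.

## Scanning and assembly

The library is ordered by descending required-skeleton length, then by
number of runs (a more structured pattern outranks a bare one of equal
required length), then insertion order.  Scanning is left-to-right and
non-overlapping: at each position the highest-priority band that matches
wins, taking its longest match within the band; scanning resumes after the
match.  The band rule makes `A+P(CP)+` beat its prefix `A+P` on `APCP`,
`A*PC*A+` beat `AP+` on `APCA`, and resolves `A+P` vs `AP+` on `AAP`/`APP`
by match length — the overlap between those two classes on the word `AP`
is genuinely ambiguous and is logged per match.

Assembly creates one instance per `P` letter.  Attribute triggers before
the first phenotype apply to every phenotype of the match; triggers after
a phenotype attach to the nearest preceding one (this deliberately
propagates e.g. "severe" to both "abdominal pain" and "diarrhea" in
`AP+`).  Two triggers of one category on the same phenotype resolve to the
occurrence nearest the phenotype, with a warning.  Unfilled assertion
takes the schema default `present`; other unfilled slots are omitted from
output.

Logic-based matches are normalized against the lab knowledge base: the
analyte label (plus the specimen, when written) must resolve to exactly
one entry; the value is converted to the canonical unit and compared to
the closed reference interval [low, high] — bounds inclusive count as
`normal`.  Unresolvable analytes, ambiguous entries and unconvertible
units yield error records (the instance is emitted without abnormality and
logged), never exceptions.

## The synthetic corpus generator

The generator is the stand-in for protected clinical records: each
sentence instantiates one of the six pattern classes by sampling lexicon
surfaces (attribute counts 1–4 for `A+P`, phenotype counts 2–4 for `AP+`
and conjunctions, optional leading attributes and pause for the
trailing-attribute class, specimen written with probability 0.5 for lab
sentences), so the segment families realized in a corpus span each
class's quantifiers.  Lab values are drawn below, inside, or above the
reference range (0.2/0.4/0.4), formatted as written text, and the gold
abnormality is recomputed from the *written* value exactly as the
recognizer will compute it.  Default mix: `AP+` 0.25, `A+P` 0.22,
`A+P(CP)+` 0.15, `S*LNU` 0.15, `A*PC*A+` 0.13, `S*LR` 0.10 — negations
and attribute+phenotype phrases dominate, lab mentions are a smaller
share.  Sentences end with a full stop and are separated by narrative
filler drawn from a closed token list disjoint from the lexicon
(`filler_rate`, default 1.0 — phenotype phrases in real records are
embedded in narrative, and the spacing also keeps adjacent pattern
sentences from blending, see the encoding note on sentence boundaries).
In the trailing-attribute class the pause comma is always written when a
leading attribute is present; `剧烈咳嗽呈持续性` without any pause is
genuinely ambiguous against `A+P` and real clinicians write the comma.

What the generator does **not** emulate: discourse structure, section
headers, misspellings, segmentation ambiguity beyond the lexicon, nested
or overlapping mentions, and the empirical pattern-frequency profile of
any real corpus.  Passing the end-to-end consistency test therefore shows
the pipeline is internally exact on clean, lexicon-covered text — not that
it reaches any particular accuracy on real records.

Planted-motif mode plants non-overlapping copies of a letter word into
i.i.d. background sequences (offsets via the gap transform, exact
non-overlap), corrupting each planted letter independently with the noise
rate.

## Problem sizes

The shipped defaults are desk-scale: the default synthetic corpus is 500
documents (≈3,000 instances), and the pattern learner mines widths 2–5
with 99 shuffles and up to 8 rounds — on one CPU the full
encode→discover→reduce→enrich pipeline takes a few minutes and recovers
exactly the six pattern classes.  Width 30 (the miner's upper bound) is
supported but pointless on letter sequences whose constructions are under
ten letters.

## Known limitations

* Pattern letters are category-blind: `A` does not know which attribute it
  triggers, so patterns cannot specialize per category.
* The `A+P` / `AP+` overlap on the two-letter word `AP` is resolved by
  priority, not semantics.
* Attribute propagation in `AP+` applies the shared trigger to every
  phenotype; whether e.g. severity truly distributes over a conjunction is
  occasionally debatable in real prose.
* Reference ranges are age- and sex-blind; qualitative results beyond
  direction words are out of scope.
* With `filler_rate < 1` the generator can emit directly adjacent pattern
  sentences whose concatenated letters admit a cross-boundary parse; the
  recognizer then has no sentence signal to prefer the intended one.
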