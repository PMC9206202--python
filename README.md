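# phenossu

Pattern-based deep phenotyping of clinical free text.

Clinical narratives record phenotypes ("a sudden severe pain in the
right-lower abdomen", "WBC 12.5 × 10⁹/L") as unstructured prose.
Structuring them at fine granularity — the phenotype concept *plus* its
attributes (assertion, severity, temporal pattern, body location, lab
abnormality, …) — normally requires large annotated corpora that simply do
not exist for most languages and hospital systems.  `phenossu` implements a
low-resource alternative aimed at clinical-NLP researchers and medical
informatics engineers: it treats clinical text as a DNA-like sequence and
borrows sequence-motif discovery from bioinformatics to learn the
*linguistic patterns* in which phenotypes are described, then recognizes
structured phenotype instances by scanning those patterns.

## The method

1. **Encoding.** Keyword lexicons map text chunks to a single-letter
   alphabet: `P` phenotype, `A` attribute trigger, `C` punctuation, `S`
   specimen, `L` analyte, `N` number, `U` unit, `R` result direction, `O`
   everything else.  Matching is leftmost-longest over a trie, and each
   letter remembers its exact character span, so every later match maps
   back to the text.  "右下腹部突发剧烈疼痛" becomes `AAAAP`.

2. **Motif discovery.** The encoded corpus is mined for recurring
   constructions with expectation-maximization under a two-component
   mixture: every length-*w* window is independently a motif site
   (probability λ, letters from a position weight matrix θ) or background
   (order-0 frequencies).  EM maximizes

   LL = Σᵢ log( λ·P(xᵢ | θ) + (1−λ)·P(xᵢ | bg) )

   over widths *w* ∈ [2, 30]; significance is a Monte-Carlo E-value from
   composition-preserving letter shuffles, and found sites are erased
   before the next round.

3. **Pattern induction.** O-containing motifs are split, and segment
   families are abstracted into regular expressions by run-length
   generalization — {`AP`, `AAP`, `AAAP`} → `A+P`; {`LNU`, `SLNU`} →
   `S*LNU`; `APCPCP` → `A+P(CP)+` — then consolidated by structural
   subsumption.  A gap-driven enrichment loop encodes gold instances the
   current library misses and adds their generalizations (flagged for
   review).  The library converges to six pattern classes: `A+P(CP)+`,
   `AP+`, `A+P`, `A*PC*A+` (phrase-based) and `S*LNU`, `S*LR`
   (logic-based).

4. **Recognition.** Documents are scanned with the library; each match is
   assembled into PhenoSSU instances (one per phenotype letter, attributes
   propagated to their phenotypes).  Quantitative lab matches are
   normalized against reference ranges — value outside [low, high] ⇒
   abnormality `higher`/`lower` — and mapped to SNOMED CT concepts.

A synthetic corpus generator emits gold-annotated documents instantiating
the six classes, so the whole pipeline is testable without access to
protected health records.

## Worked example

```python
import phenossu as ph

lexicon, kb, schema = ph.default_lexicon(), ph.default_lab_kb(), ph.default_schema()
library = ph.builtin_library()

for inst in ph.recognize_document("右下腹部突发剧烈疼痛", lexicon, library,
                                  lab_kb=kb, schema=schema):
    print(inst.phenotype, inst.attribute_values())

for inst in ph.recognize_document("WBC 12.5 × 10^9/L", lexicon, library,
                                  lab_kb=kb, schema=schema):
    print(inst.phenotype, inst.attribute_values(), inst.snomed)
```

prints

```
pain {'quadrant pattern': 'right-lower', 'body location': 'abdomen',
      'temporal pattern': 'acute', 'severity': 'severe', 'assertion': 'present'}
WBC higher {'analyte': 'WBC', 'specimen': 'blood', 'abnormality': 'higher'} 414478003
```

— the first sentence encodes to `AAAAP`, matches `A+P`, and all four
attribute triggers attach to "pain" (assertion defaults to `present`); the
lab result is 12.5 × 10⁹/L against a 4–10 × 10⁹/L reference range, hence
`higher`, normalized to SNOMED CT 414478003 (increased blood leukocyte
number).

Learning the library from data instead of using the built-ins:

```python
docs = ph.generate_corpus(ph.GeneratorConfig(n_docs=500, seed=0))
learner = ph.PatternLearner().fit([d.text for d in docs],
                                  [d.instances for d in docs])
print(sorted(learner.library_.pattern_set()))
# ['A*PC*A+', 'A+P', 'A+P(CP)+', 'AP+', 'S*LNU', 'S*LR']
```

The same pipeline is scriptable from the shell:

```bash
phenossu simulate --out corpus/ --n-docs 100 --seed 1
phenossu discover --docs corpus/ --out motifs.txt
phenossu recognize --docs corpus/ --out pred.jsonl
phenossu evaluate --pred pred.jsonl --gold corpus/gold.jsonl
```

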