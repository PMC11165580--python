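# enzner — dictionary- and rule-based enzyme named-entity annotation

`enzner` annotates enzyme mentions in full-text biomedical articles. It
builds a hierarchical gazetteer from enzyme nomenclature (EC numbers and
synonyms), matches it against BioC-JSON articles in two steps — exact
dictionary lookup followed by rule-based fuzzy matching on "-ase" root
terms — resolves enzyme abbreviations, exports the annotated sentences as
a SOBIE/BIO-tagged training corpus, and scores annotation sets with
partial-match credit and Jaccard inter-annotator agreement.

The design goal is the classic silver-standard recipe: a high-precision
dictionary step supplies reliable annotations at scale, and a recall-
oriented keyword step recovers enzymes the dictionary has never seen
("deoxycytidine kinase" from the root term "kinase"), so that the output
can train downstream sequence-labelling models without manual annotation
of the training split.

## How it works

1. **Dictionary construction** (`enzner.dictionary`). Each nomenclature
   name is expanded into spelling variants (hyphen ↔ space separators,
   Greek letters ↔ spelled-out names: `beta-galactosidase` →
   4 variants) and filed into a *branch* keyed by its final word, the
   *root term*. Names not ending in "-ase" (trypsin, lysozyme) live in a
   parallel branch set. Branches keep longer names first so matching is
   greedy.
2. **Direct matching** (`enzner.annotator.direct_match`). Sentences are
   scanned for verbatim dictionary forms, case-insensitively, with
   whole-word boundaries. Hyphens are *not* boundaries: nothing matches
   inside `catalase-positive`. Overlaps resolve to the longest form
   (`aliphatic alcohol dehydrogenase` beats the nested
   `alcohol dehydrogenase`). Each match carries its EC number.
3. **Keyword matching** (`enzner.annotator.keyword_match`). Remaining
   tokens ending in "-ase" (minus a stoplist: *database*, *phase*,
   *increase*, ...) seed a span that grows backwards over up to four
   acceptable modifier tokens — words from the branch vocabulary or
   chemical-modifier-shaped words, but never determiners/prepositions or
   generic adjectives like *human*/*serum* — and forwards over one
   bracketed qualifier, one number, or one Greek letter. The identifier
   is the root term itself.
4. **Abbreviations** (`find_enzyme_abbreviations`). Short forms whose
   long-form definition is itself matched as an enzyme (covering the
   definition's head word) are annotated at every later occurrence with
   the definition's identifier.
5. **Corpus export** (`enzner.corpus`). Abbreviations are replaced by
   their definitions, enzyme-bearing sentences are tokenized and tagged
   with SOBIE (or BIO) labels, written as CoNLL, and split 75:10:15 per
   domain (validation/test floored, remainder to training: 1006 articles
   → 756/100/150).
6. **Evaluation** (`enzner.evaluation`). Predictions overlapping gold
   entities that capture only the root term or drop a trailing isoform
   marker are *partial positives* earning half credit; agreement is a
   Jaccard index at the entity or character level.

A seeded synthetic-corpus generator (`enzner.synth`) plants verbatim
dictionary forms, root-plus-unseen-modifier constructions, stoplist
confounders and recurring abbreviations into realistic carrier prose, so
every stage is testable end to end without downloading anything.

## Worked example

```python
from enzner.annotator import RuleConfig, annotate_document
from enzner.bioc_io import BioCDoc, Passage
from enzner.dictionary import build_hierarchy, load_mini_dictionary

tree = build_hierarchy(load_mini_dictionary())
doc = BioCDoc(pmcid="PMC0000001", passages=[Passage(
    text="Alcohol dehydrogenase (ADH) was elevated in cases. "
         "Serum catalase and alkaline phosphatase were unchanged. "
         "We also detected deoxycytidine kinase in most samples.",
    offset=0, section_label="results")])
out = annotate_document(doc, tree, {"ADH": "alcohol dehydrogenase"},
                        RuleConfig())
for a in out.all_annotations():
    print(f"[{a.offset:>4}] {a.text!r:<28} "
          f"id={a.infons['identifier']:<10} via {a.infons['method']}")
```

prints

```
[   0] 'Alcohol dehydrogenase'      id=1.1.1.1    via direct
[  23] 'ADH'                        id=1.1.1.1    via abbreviation
[  57] 'catalase'                   id=1.11.1.6   via direct
[  70] 'alkaline phosphatase'       id=3.1.3.1    via direct
[ 124] 'deoxycytidine kinase'       id=kinase     via keyword
```

The scripts in `examples/` walk through each stage with commentary:
dictionary construction, annotation, training-corpus export, and
evaluation. The `enzner` CLI exposes the same stages (`build-dict`,
`annotate`, `synth`, `corpus`, `eval`); try `enzner --help`.

## Layout

```
src/enzner/        library (dictionary, annotator, bioc_io, corpus,
                   evaluation, synth, cli) + bundled data files
examples/          narrative walk-throughs of each stage
scripts/           acceptance.py — headline quantities as JSON
tests/             pytest suite incl. property-based tests
docs/methods.md    modelling decisions and their rationale
```
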