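"""Turn annotated articles into a token-labelled training corpus.

Sentences that contain at least one enzyme annotation are exported with
SOBIE tags (Singleton / Begin / Inside / End / Outside; BIO also
available), abbreviations are replaced by their definitions first, and
documents are split 75:10:15 into train/validation/test within each
domain (validation and test sizes are floored, training takes the
remainder — 1006 metabolomics articles give 756/100/150).

Run:  python examples/03_training_corpus.py
"""

from enzner.annotator import RuleConfig, annotate_document
from enzner.corpus import (
    extract_tagged_sentences,
    replace_abbreviations,
    split_corpus,
    split_counts,
)
from enzner.dictionary import build_hierarchy, load_mini_dictionary
from enzner.synth import SynthSpec, generate_corpus

tree = build_hierarchy(load_mini_dictionary())
cfg = RuleConfig()

corpus = generate_corpus(SynthSpec(n_docs=12, seed=11), tree)
docs = []
for doc in corpus.docs:
    expanded = replace_abbreviations(doc, corpus.abbrevs[doc.pmcid])
    docs.append(annotate_document(expanded, tree, {}, cfg))

sentences = extract_tagged_sentences(docs, scheme="sobie")
print(f"{len(sentences)} enzyme-bearing sentences extracted\n")

sent = sentences[0]
print("sentence id:", sent.sentence_id)
for token, tag in zip(sent.tokens, sent.tags):
    marker = "  <-" if tag != "O" else ""
    print(f"  {tag:>2}  {token}{marker}")

# the published-style split
print("\nsplit of 1006 articles (train/val/test):", split_counts(1006))

by_domain: dict[str, list[str]] = {}
for doc in docs:
    by_domain.setdefault(doc.domain_tag, []).append(doc.pmcid)
split = split_corpus(by_domain, seed=0)
print(f"this corpus: {len(split.train)} train, "
      f"{len(split.validation)} validation, {len(split.test)} test")
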