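# Methods

This note records the modelling decisions behind `enzner`, the parameters
they introduce, and the reasoning where the underlying method left room
for interpretation.

## Dictionary model

An enzyme nomenclature entry is an EC number (four dot-separated
integers, possibly with a trailing dash for incomplete classes) plus one
or more names. Loading supports a plain two-column TSV
(`EC<TAB>name; name; ...`) and KEGG REST dumps (`ec:` prefixes;
"Transferred …"/"Deleted …" entries are skipped, since they carry no
usable surface form).

**Variant expansion.** Biomedical spelling varies along two independent
axes: separator (hyphen vs space) and Greek letters (symbol vs
spelled-out name). Each name is segmented at separators, each segment
that is a Greek letter or letter-name contributes both spellings, and the
cartesian product of choices is enumerated (`beta-galactosidase` → 4
forms). Expansion is a closure: expanding any produced variant yields the
same set (property-tested). A cap of 4,096 variants per name guards
against pathological inputs; no real nomenclature name approaches it.

**Hierarchy.** Forms are lowercased and filed under their *root term* —
the final whitespace token — with "-ase"-final forms and other forms in
separate branch maps. Within a branch, forms sort by descending token
count, then descending character length, then lexicographically, making
a branch scan greedy by construction. Each form maps to its EC number in
a flat index; when two entries claim the same surface form the first
(file order) wins and the conflict is logged, since a surface form must
resolve to a single identifier at annotation time.

**Trigger index.** Branch keys are final whitespace tokens, so names
ending in a parenthesized qualifier ("… dehydrogenase (NADP+)") get
punctuation-laden keys that never equal a sentence token. Matching
therefore triggers on a separate index keyed by each form's final *word*
(maximal letter/digit/hyphen run). This is an indexing detail only: the
test suite checks the indexed matcher against a brute-force scan that
tries every form at every position, and they agree exactly.

## Matching rules

**Word boundaries.** A form matches only between word boundaries, and a
hyphen is deliberately *not* a boundary: `catalase-positive` contains no
enzyme mention, while `beta-galactosidase` (its own dictionary form)
matches whole. Internal spaces in a form match any whitespace run.
Matching is case-insensitive; the surface text is preserved.

**Greedy selection.** Candidate matches are ranked by length (longest
first), then start position; overlapping shorter candidates are dropped.
This resolves nested nomenclature ("alcohol dehydrogenase" inside
"aliphatic alcohol dehydrogenase") in favour of the most specific name.

**Keyword step.** Tokens ending in "-ase" that survive the stoplist
(*database*, *phase*, *increase*, … — common English "-ase"-final words)
and do not fall inside a direct match seed a candidate span. The span
extends backwards over at most **4** tokens; a token is accepted iff it
occurs in the matched branch's vocabulary or looks like a chemical
modifier (letters/digits/hyphens/Greek letters), and is rejected if it is
a closed-class function word (*the*, *of*, *with*, …) or a generic
descriptive adjective (*human*, *serum*, *bacterial*) not found in the
vocabulary. Extension never crosses sentence start or non-hyphen
punctuation. Forwards, the span may absorb exactly one of: a balanced
round-bracket group, a bare integer, or a Greek letter — and the
extension is reverted if it would swallow a direct match. The rationale:
backward extension is what recovers unseen modifiers ("deoxycytidine
kinase") while the function-word blocker prevents "the … dehydrogenase"
over-captures; the cap of 4 bounds worst-case spans.

Keyword matches are identified by their root term rather than an EC
number, because the dictionary by construction does not know the
modifier-qualified enzyme.

**Abbreviations.** Given a short-form → long-form map (as produced by
standard abbreviation extractors), a short form is accepted as an enzyme
iff running the matcher on the definition yields a match covering the
definition's head (final) word — "alcohol dehydrogenase activity" defines
an activity, not an enzyme, and is rejected. Accepted short forms are
annotated at every whole-word, case-sensitive occurrence with the
definition's identifier. Case-sensitive, because short forms collide with
ordinary words when case-folded.

**Sections.** Only passages whose section label is configured is
annotated (default: abstract, introduction, methods, results,
discussion, references). Sentence splitting is a light rule-based
splitter (terminal `.!?` followed by whitespace and an
uppercase/digit/bracket, with guards for species initials like
"E. coli", "e.g.", decimals); enzyme names never span sentences, so a
conservative splitter suffices.

## Corpus export

Abbreviation short forms are replaced by their definitions before
tokenization, so models train on full names; annotation offsets are
remapped through the edit list. Tokenization splits on whitespace and
peels off edge punctuation but keeps internal hyphens. A token belongs to
an entity if it overlaps the annotation span by at least one character.
Tag sequences are validated against the scheme grammar — SOBIE:
`(O | S | B I* E)*`, BIO: `(O | B I*)*` — and conversions
SOBIE ↔ spans ↔ BIO are exact inverses (property-tested). Only sentences
containing at least one entity are exported; each carries the ID
`PMCID:section:paragraph:sentence`.

**Split rule.** The 75:10:15 train/validation/test split is applied per
domain as `val = floor(0.10·n)`, `test = floor(0.15·n)`, train = the
remainder, with a `1e-9` nudge before flooring so that exact products
(e.g. 0.15 × 1006 = 150.9 in floating point arithmetic, but 0.10 × 1006
= 100.60000000000001) are not floored one short. This reproduces, e.g.,
1006 → 756/100/150. Assignment within a domain uses a single seeded
`random.Random` shuffle, so splits are deterministic given the seed and
sizes are seed-independent.

## Evaluation

Predictions and gold annotations are paired greedily in document order,
one-to-one. An exact span match is a true positive. An overlapping pair
in a *partial* relation is a **partial positive (PP)**: the prediction is
a token-suffix of the gold entity (root term captured, modifiers missed)
or the gold entity equals the prediction plus one trailing isoform
marker (a number, Roman numeral, or letter-digit code). Anything else
unpaired is a false positive / false negative.

PPs earn half credit: `tp' = tp + pp/2`, `fn' = fn + pp/2`, and by
default also `fp' = fp + pp/2` so precision discounts partial matches
too; a switch (`pp_in_fp=False`) keeps precision strict-positive-only,
since conventions differ on whether a partial hit should also count
against precision. F1 is the harmonic mean. With `pp = 0` the scores
reduce exactly to ordinary confusion-matrix precision/recall (tested
against an independent oracle).

Inter-annotator agreement is a Jaccard index: entity level counts exact
(offset, length, text) triples; character level compares the sets of
annotated character positions. True negatives never appear anywhere —
annotations are entity sets, not token grids.

## Synthetic corpus generator

`enzner.synth.generate_corpus` builds seeded BioC-JSON articles with
planted gold spans so the whole pipeline is testable offline. Plants are
(a) verbatim dictionary forms, (b) root term + modifier constructions
using modifiers deliberately absent from the dictionary (only the keyword
step can recover these), and (c) abbreviations introduced at a definition
site and re-planted in later sentences. Carrier templates always precede
the entity slot with a function word or punctuation so the
backward-extension blocker is actually exercised, and confounder
sentences embed stoplist words that must never be annotated. Domain
labels are drawn with weights proportional to a realistic four-domain
corpus profile. The generator self-checks that every gold span slices
back to its surface text.

Scope and limits: the generator produces clean declarative prose — no
tables, figure captions, citation noise, or OCR artifacts — so recall
measured on it is an upper bound on real-article recall; its purpose is
verifying the machinery (offsets, greedy selection, rule firing), not
estimating field performance. Default sizes (50 documents of 20–40
sentences) keep any single check under a couple of minutes on one CPU.

## Determinism and numerics

Every stochastic component takes an explicit seed (`SynthSpec.seed`,
`split_corpus(seed=…)`). `RuleConfig` fixes its provenance timestamp at
construction, so annotating the same document twice with the same config
is bit-identical. The only floating-point subtlety in the package is the
split-rule flooring nudge described above; scores are plain ratios of
small integers (plus halves) and need no special treatment.
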