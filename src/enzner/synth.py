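"""Seeded synthetic-corpus generator.

Produces BioC-JSON articles with planted gold enzyme annotations so the
matcher, corpus builder and scorer are testable without any download.
Planted entities are verbatim dictionary surface forms (including hyphen
and Greek-letter variants), root-word + unseen-modifier constructions that
only the keyword step can recover, and optional abbreviations whose short
forms recur later in the article.  Carrier sentences use realistic
function-word-heavy prose so the backward-extension blocker is exercised,
plus stoplist confounders ("database", "phase", ...) that must never be
annotated.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping

from .bioc_io import Annotation, BioCDoc, Passage, article_text
from .dictionary import EC_RE, HierarchicalDictionary

__all__ = ["SynthSpec", "SynthCorpus", "generate_corpus"]

_SECTIONS = ["abstract", "introduction", "methods", "results", "discussion"]

# carrier templates; {E} is the entity slot, {C} the confounder slot
_ENTITY_TEMPLATES = [
    "The activity of {E} was measured in plasma samples.",
    "We observed that {E} was significantly elevated in the patient cohort.",
    "Levels of {E} correlated with clinical outcome in this study.",
    "Expression of {E} decreased after the intervention period.",
    "Analysis showed that {E} contributes to the observed metabolic shift.",
    "In the treated group, {E} remained within the normal range.",
    "Concentrations of {E} were quantified by a standard colorimetric assay.",
    "The assay detected {E} in most urine specimens examined.",
]

_CONFOUNDER_TEMPLATES = [
    "The {C} of the trial lasted twelve weeks in total.",
    "All records were stored in a relational {C} for later retrieval.",
    "A marked {C} in body weight was recorded across visits.",
    "Progression of the {C} was monitored at every follow-up.",
]

_PLAIN_SENTENCES = [
    "Participants provided written informed consent before enrollment.",
    "Samples were collected after an overnight fast and frozen immediately.",
    "Statistical analysis used mixed models adjusted for age and sex.",
    "The cohort included volunteers recruited from two clinical centres.",
    "Dietary intake was recorded with a validated questionnaire.",
    "All measurements were performed in duplicate by trained staff.",
    "Results were considered significant at an adjusted threshold.",
    "The findings were consistent across both recruitment sites.",
]

_CONFOUNDERS = ["phase", "database", "increase", "decrease", "disease", "release"]

#: modifiers for root+modifier constructions; none are dictionary words,
#: function words or excluded descriptive adjectives
_MODIFIERS = [
    "deoxycytidine", "mitochondrial", "cytosolic", "ribosomal",
    "lysosomal", "salivary", "myocardial", "placental", "erythrocyte",
    "neuronal",
]

_ABBREV_SENTENCES = [
    "Levels of {S} correlated strongly with disease severity.",
    "Treatment reduced {S} in the intervention arm.",
    "No association between {S} and age was detected.",
]


@dataclass(frozen=True)
class SynthSpec:
    """Study-shape parameters of the generated corpus.

    ``entity_rate``/``confounder_rate`` are expected counts per sentence;
    ``abbreviation_rate`` is the probability that a planted multiword
    enzyme also introduces an abbreviation; ``keyword_fraction`` is the
    share of plants built as root + unseen modifier instead of verbatim
    dictionary forms.
    """

    n_docs: int = 50
    domains: Mapping[str, float] = field(
        default_factory=lambda: {
            "GWAS": 884 / 3525,
            "proteomics": 446 / 3525,
            "metabolomics": 1006 / 3525,
            "microbiome": 1189 / 3525,
        }
    )
    sentences_per_doc: tuple[int, int] = (20, 40)
    entity_rate: float = 0.3
    confounder_rate: float = 0.2
    abbreviation_rate: float = 0.1
    keyword_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.entity_rate, self.confounder_rate,
               self.abbreviation_rate) < 0:
            raise ValueError("rates must be non-negative")
        total = sum(self.domains.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("domain weights must sum to 1")


@dataclass
class SynthCorpus:
    docs: list[BioCDoc]
    gold: dict[str, list[Annotation]]
    abbrevs: dict[str, dict[str, str]]


def _verbatim_pool(tree: HierarchicalDictionary) -> list[str]:
    """Dictionary forms usable as plants (known EC preferred)."""
    forms = sorted(f for f in tree.all_forms() if f in tree.ec_index)
    return forms or sorted(tree.all_forms())


_CLEAN_ROOT = __import__("re").compile(r"^[a-z]+(?:-[a-z]+)*ase$")


def _keyword_roots(tree: HierarchicalDictionary) -> list[str]:
    """Branch root terms usable for root+modifier plants: clean "-ase"
    words that are not themselves standalone dictionary forms."""
    forms = tree.all_forms()
    return sorted(
        k for k in tree.branches
        if k not in forms and _CLEAN_ROOT.match(k)
    )


def generate_corpus(spec: SynthSpec, tree: HierarchicalDictionary) -> SynthCorpus:
    """Generate a deterministic synthetic corpus with planted gold spans."""
    if len(tree) == 0:
        raise ValueError("dictionary is empty")
    rng = random.Random(spec.seed)
    pool = _verbatim_pool(tree)
    roots = _keyword_roots(tree)
    forms = tree.all_forms()
    domains = sorted(spec.domains)
    weights = [spec.domains[d] for d in domains]

    docs: list[BioCDoc] = []
    gold: dict[str, list[Annotation]] = {}
    abbrevs: dict[str, dict[str, str]] = {}

    for d_idx in range(spec.n_docs):
        pmcid = f"PMC{9000000 + d_idx}"
        domain = rng.choices(domains, weights=weights)[0]
        n_sent = rng.randint(*spec.sentences_per_doc)
        doc_abbrevs: dict[str, str] = {}
        pending_short: list[str] = []  # shorts to re-plant in later sentences
        gold_spans: list[tuple[int, int, str, str]] = []  # local per sentence

        # build sentences first, tracking plants relative to sentence starts
        sentences: list[tuple[str, list[tuple[int, str, str]]]] = []
        for _ in range(n_sent):
            plants: list[tuple[int, str, str]] = []  # (local offset, text, id)
            r = rng.random()
            if pending_short and rng.random() < 0.5:
                short = pending_short.pop()
                template = rng.choice(_ABBREV_SENTENCES)
                pos = template.index("{S}")
                text = template.replace("{S}", short)
                plants.append(
                    (pos, short, _definition_identifier(doc_abbrevs, tree, short))
                )
            elif r < spec.entity_rate:
                if rng.random() < spec.keyword_fraction and roots:
                    root = rng.choice(roots)
                    modifier = rng.choice(_MODIFIERS)
                    entity = f"{modifier} {root}"
                    if rng.random() < 0.3:
                        entity = f"{entity} {rng.randint(1, 9)}"
                    if entity.lower() in forms:  # accidentally a real form
                        entity = f"{modifier} {root}"
                    ident = root
                else:
                    entity = rng.choice(pool)
                    ident = tree.ec_index.get(entity, entity.split()[-1])
                template = rng.choice(_ENTITY_TEMPLATES)
                pos = template.index("{E}")
                text = template.replace("{E}", entity)
                plants.append((pos, entity, ident))
                # optionally introduce an abbreviation for multiword plants
                words = entity.split()
                if (
                    len(words) >= 2
                    and rng.random() < spec.abbreviation_rate
                    and entity in tree.ec_index
                ):
                    short = "".join(w[0] for w in words if w[0].isalpha()).upper()
                    if (
                        len(short) >= 2
                        and short not in doc_abbrevs
                        and short.lower() not in forms
                    ):
                        doc_abbrevs[short] = entity
                        text = text[:-1] + f" ({short})."
                        plants.append((text.index(f"({short})") + 1, short, ident))
                        pending_short.extend([short] * rng.randint(1, 3))
            elif r < spec.entity_rate + spec.confounder_rate:
                confounder = rng.choice(_CONFOUNDERS)
                template = rng.choice(_CONFOUNDER_TEMPLATES)
                text = template.replace("{C}", confounder)
            else:
                text = rng.choice(_PLAIN_SENTENCES)
            sentences.append((text, plants))

        # group sentences into passages with cycling section labels
        passages: list[Passage] = []
        doc_gold: list[Annotation] = []
        offset = 0
        i = 0
        section_i = 0
        while i < len(sentences):
            k = min(rng.randint(2, 4), len(sentences) - i)
            chunk = sentences[i : i + k]
            i += k
            label = _SECTIONS[section_i % len(_SECTIONS)]
            section_i += 1
            parts: list[str] = []
            local = 0
            for text, plants in chunk:
                for pos, surface, ident in plants:
                    doc_gold.append(
                        Annotation(
                            text=surface,
                            infons={"identifier": ident, "type": "enzyme"},
                            id=str(len(doc_gold) + 1),
                            locations=[{
                                "offset": offset + local + pos,
                                "length": len(surface),
                            }],
                        )
                    )
                parts.append(text)
                local += len(text) + 1  # joined by single spaces
            passage_text = " ".join(parts)
            passages.append(
                Passage(
                    text=passage_text,
                    offset=offset,
                    section_label=label,
                    infons={"section_type": label},
                )
            )
            offset += len(passage_text) + 1  # newline between passages

        doc = BioCDoc(
            pmcid=pmcid,
            passages=passages,
            domain_tag=domain,
            infons={"domain": domain},
        )
        # generator self-check: every gold span slices to its surface
        full = article_text(doc)
        for ann in doc_gold:
            assert full[ann.offset:ann.end] == ann.text, (
                pmcid, ann.offset, ann.text, full[ann.offset:ann.end])
        docs.append(doc)
        gold[pmcid] = doc_gold
        abbrevs[pmcid] = doc_abbrevs

    return SynthCorpus(docs=docs, gold=gold, abbrevs=abbrevs)


def _definition_identifier(doc_abbrevs: Mapping[str, str],
                           tree: HierarchicalDictionary, short: str) -> str:
    definition = doc_abbrevs[short].lower()
    ec = tree.ec_index.get(definition)
    if ec and EC_RE.match(ec):
        return ec
    return definition.split()[-1]
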