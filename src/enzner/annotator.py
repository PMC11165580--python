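"""The two-step enzyme search engine.

Step 1 (*direct matching*) finds exact, case-insensitive occurrences of
dictionary surface forms, greedily keeping the longest span when candidates
nest or overlap — "aliphatic alcohol dehydrogenase" wins over the contained
"alcohol dehydrogenase" and "dehydrogenase".

Step 2 (*keyword matching*) fires on any remaining token ending in "-ase"
(stoplist words such as "phase" and "database" excluded) and extends the
span: up to four acceptable tokens backwards, and forwards over a bracketed
group, a single bare number, or a Greek letter ("carboxylesterase 2").

Abbreviations are resolved by running the same pipeline over the article's
short-form → definition map and then annotating occurrences of the short
forms whose definitions contain an enzyme.
"""

from __future__ import annotations

import copy
import re
import time
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

from . import __version__
from ._text import iter_sentence_spans, tokenize_words
from .bioc_io import Annotation, BioCDoc
from .dictionary import (
    HierarchicalDictionary,
    default_greek_table,
    default_stoplist,
    root_term_of,
)

__all__ = [
    "Sentence", "Match", "RuleConfig",
    "split_sentences", "direct_match", "flat_direct_match", "keyword_match",
    "find_enzyme_abbreviations", "annotate_document",
]

DEFAULT_SECTIONS = frozenset(
    {"abstract", "introduction", "methods", "results", "discussion",
     "references"}
)

#: closed list of function words that never join an enzyme span
FUNCTION_WORDS = frozenset(
    """the a an of in on at by for with to and or but nor as from into onto
    over under than then that this these those which where when while during
    between among within without about against is are was were be been being
    has have had having do does did done can could may might must shall
    should will would we they it he she its their his her our your not no
    also only all each both any some several many few more most other such
    same new via per respectively significantly significant increased
    decreased elevated reduced higher lower high low using used showed shown
    found identified measured observed detected reported associated compared
    including enzyme enzymes activity activities level levels expression
    gene genes study studies analysis sample samples patient patients
    """.split()
)

#: descriptive modifiers excluded from spans unless part of an exact match
MODIFIER_EXCLUSIONS = frozenset({"human", "serum", "bacterial"})

_MODIFIER_RE = re.compile(r"^[^\W_]+(?:-+[^\W_]+)*$", re.UNICODE)


@dataclass(frozen=True)
class Sentence:
    """A sentence with its global start offset and word tokens."""

    text: str
    start_offset: int
    tokens: tuple[tuple[str, int], ...]

    @classmethod
    def from_text(cls, text: str, start_offset: int) -> "Sentence":
        return cls(
            text=text,
            start_offset=start_offset,
            tokens=tuple(tokenize_words(text, start_offset)),
        )


@dataclass(frozen=True)
class Match:
    """A matched enzyme span in the article.

    ``identifier`` is the EC number for direct matches with a known EC
    (otherwise the root word), the root word for keyword matches, and the
    definition's identifier for abbreviation occurrences.
    """

    surface: str
    start: int
    length: int
    identifier: str
    method: str  # {"direct", "keyword", "abbreviation"}

    @property
    def end(self) -> int:
        return self.start + self.length


def _utc_now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime())


@dataclass(frozen=True)
class RuleConfig:
    """Tunable matching rules.

    ``max_backward`` is the number of words considered before a root term
    (most multiword enzyme names have five words or fewer, so four words of
    left context suffice).  The timestamp is fixed at config creation so
    that annotating the same document twice with one config is
    byte-identical.
    """

    sections: frozenset[str] = DEFAULT_SECTIONS
    stoplist: frozenset[str] = field(default_factory=default_stoplist)
    greek: Mapping[str, str] = field(default_factory=default_greek_table)
    function_words: frozenset[str] = FUNCTION_WORDS
    modifier_exclusions: frozenset[str] = MODIFIER_EXCLUSIONS
    max_backward: int = 4
    annotator: str = f"enzner:{__version__}"
    timestamp: str = field(default_factory=_utc_now)

    def greek_letters(self) -> frozenset[str]:
        return frozenset(self.greek.values())


def split_sentences(paragraph_text: str, paragraph_offset: int = 0) -> list[Sentence]:
    """Split a paragraph into sentences with global character offsets."""
    if paragraph_offset < 0:
        raise ValueError("paragraph_offset must be >= 0")
    return [
        Sentence.from_text(paragraph_text[s:e], paragraph_offset + s)
        for s, e in iter_sentence_spans(paragraph_text)
    ]


@lru_cache(maxsize=65536)
def _form_regex(form: str) -> re.Pattern[str]:
    """Whole-word regex for a dictionary form.

    Word boundaries exclude letters, digits *and hyphens*: a form never
    matches inside a hyphenated token ("galactosidase-positive").
    Internal spaces tolerate any whitespace run.
    """
    pattern = re.escape(form).replace(r"\ ", r"\s+")
    return re.compile(
        rf"(?<![^\W_])(?<!-){pattern}(?![^\W_])(?!-)",
        re.IGNORECASE | re.UNICODE,
    )


def _greedy_select(cands: list[tuple[int, int, str]]) -> list[tuple[int, int, str]]:
    """Keep the longest candidates, dropping overlaps; ties go leftmost."""
    chosen: list[tuple[int, int, str]] = []
    for s, e, payload in sorted(cands, key=lambda c: (-(c[1] - c[0]), c[0], c[2])):
        if all(e <= cs or s >= ce for cs, ce, _ in chosen):
            chosen.append((s, e, payload))
    chosen.sort(key=lambda c: c[0])
    return chosen


def _identifier_for(form: str, tree: HierarchicalDictionary) -> str:
    ec = tree.ec_index.get(form)
    return ec if ec else form.split()[-1]


def _match_forms(sentence: Sentence, forms: Iterable[str],
                 tree: HierarchicalDictionary) -> list[Match]:
    cands: list[tuple[int, int, str]] = []
    for form in set(forms):
        for m in _form_regex(form).finditer(sentence.text):
            cands.append((m.start(), m.end(), form))
    out = []
    for s, e, form in _greedy_select(cands):
        out.append(
            Match(
                surface=sentence.text[s:e],
                start=sentence.start_offset + s,
                length=e - s,
                identifier=_identifier_for(form, tree),
                method="direct",
            )
        )
    return out


def direct_match(sentence: Sentence, tree: HierarchicalDictionary) -> list[Match]:
    """Exact dictionary matching, scanning only the branches whose root
    term occurs as a token of the sentence (the hierarchical speed-up)."""
    keys = {tok.lower() for tok, _ in sentence.tokens}
    index = tree.trigger_index()
    forms: list[str] = []
    for key in keys:
        forms.extend(index.get(key, ()))
    return _match_forms(sentence, forms, tree)


def flat_direct_match(sentence: Sentence, tree: HierarchicalDictionary) -> list[Match]:
    """Exact dictionary matching by scanning every form (the standard,
    non-hierarchical approach; identical output, slower)."""
    return _match_forms(sentence, tree.all_forms(), tree)


def _gap_is_space(text: str, a_end: int, b_start: int) -> bool:
    return all(ch.isspace() for ch in text[a_end:b_start])


def _acceptable_backward(token: str, root: str, tree: HierarchicalDictionary,
                         cfg: RuleConfig) -> bool:
    low = token.lower()
    if low in cfg.function_words or low in cfg.modifier_exclusions:
        return low in tree.vocab.get(root, ())
    if low in tree.vocab.get(root, ()):
        return True
    return bool(_MODIFIER_RE.match(token))


def _is_greek_token(token: str, cfg: RuleConfig) -> bool:
    return len(token) == 1 and token.lower() in cfg.greek_letters()


def keyword_match(
    sentence: Sentence,
    tree: HierarchicalDictionary,
    cfg: RuleConfig | None = None,
    direct: Sequence[Match] | None = None,
) -> list[Match]:
    """Rule-based fuzzy matching around "-ase" root tokens.

    Only tokens outside direct-match spans fire.  The span extends backward
    over up to ``cfg.max_backward`` acceptable tokens (branch-vocabulary
    words or chemical-modifier-shaped words, never function words, never
    across punctuation) and forward over one bracketed group, bare number
    or Greek letter.
    """
    if cfg is None:
        cfg = RuleConfig()
    if direct is None:
        direct = direct_match(sentence, tree)
    occupied = [(m.start, m.end) for m in direct]

    def in_direct(a: int, b: int) -> bool:
        return any(a < e and b > s for s, e in occupied)

    text = sentence.text
    base = sentence.start_offset
    tokens = sentence.tokens
    cands: list[tuple[int, int, str]] = []

    for idx, (tok, off) in enumerate(tokens):
        tok_end = off + len(tok)
        if in_direct(off, tok_end):
            continue
        root = root_term_of(tok, cfg.stoplist)
        if root is None:
            continue

        # backward extension: longest acceptable contiguous run, <= 4 tokens
        start_idx = idx
        while (
            idx - start_idx < cfg.max_backward
            and start_idx - 1 >= 0
        ):
            ptok, poff = tokens[start_idx - 1]
            pend = poff + len(ptok)
            if not _gap_is_space(text, pend - base, tokens[start_idx][1] - base):
                break
            if in_direct(poff, pend):
                break
            if not _acceptable_backward(ptok, root, tree, cfg):
                break
            start_idx -= 1

        span_start = tokens[start_idx][1]
        span_end = tok_end

        # forward extension: one bracketed group, bare integer or Greek letter
        ext_end = span_end
        local_after = span_end - base
        k = local_after
        while k < len(text) and text[k] == " ":
            k += 1
        if k < len(text) and text[k] == "(":
            depth = 0
            for j in range(k, len(text)):
                if text[j] == "(":
                    depth += 1
                elif text[j] == ")":
                    depth -= 1
                    if depth == 0:
                        ext_end = base + j + 1
                        break
        elif idx + 1 < len(tokens):
            ntok, noff = tokens[idx + 1]
            if _gap_is_space(text, span_end - base, noff - base) and (
                ntok.isdigit() or _is_greek_token(ntok, cfg)
            ):
                ext_end = noff + len(ntok)
        if ext_end > span_end and in_direct(span_end, ext_end):
            ext_end = span_end  # never swallow a direct match
        span_end = ext_end

        if in_direct(span_start, span_end):
            continue
        cands.append((span_start - base, span_end - base, root))

    out = []
    for s, e, root in _greedy_select(cands):
        out.append(
            Match(
                surface=text[s:e],
                start=base + s,
                length=e - s,
                identifier=root,
                method="keyword",
            )
        )
    return out


def find_enzyme_abbreviations(
    abbrevs: Mapping[str, str],
    tree: HierarchicalDictionary,
    cfg: RuleConfig | None = None,
) -> dict[str, Match]:
    """The subset of abbreviations whose definition is an enzyme.

    Each definition is run through direct then keyword matching; the
    abbreviation qualifies when a match covers the definition's head (its
    final word).  The returned template carries the identifier found for
    the definition.
    """
    if cfg is None:
        cfg = RuleConfig()
    out: dict[str, Match] = {}
    for short, definition in abbrevs.items():
        if not definition or not definition.strip():
            continue
        sent = Sentence.from_text(definition.strip(), 0)
        if not sent.tokens:
            continue
        head_tok, head_off = sent.tokens[-1]
        head_end = head_off + len(head_tok)
        matches = direct_match(sent, tree)
        matches += keyword_match(sent, tree, cfg, direct=matches)
        for m in matches:
            if m.start <= head_off and m.end >= head_end:
                out[short] = m
                break
    return out


def _abbrev_regex(short: str) -> re.Pattern[str]:
    pattern = re.escape(short)
    return re.compile(rf"(?<![^\W_])(?<!-){pattern}(?![^\W_])(?!-)", re.UNICODE)


def _match_to_annotation(m: Match, ann_id: int, cfg: RuleConfig) -> Annotation:
    return Annotation(
        text=m.surface,
        infons={
            "identifier": m.identifier,
            "type": "enzyme",
            "annotator": cfg.annotator,
            "updated_at": cfg.timestamp,
            "method": m.method,
        },
        id=str(ann_id),
        locations=[{"offset": m.start, "length": m.length}],
    )


def annotate_document(
    doc: BioCDoc,
    tree: HierarchicalDictionary,
    abbrevs: Mapping[str, str] | None = None,
    cfg: RuleConfig | None = None,
) -> BioCDoc:
    """Annotate every configured passage of *doc* with enzyme entities.

    Passages whose section label names one of the configured sections are
    sentence-split and run through direct matching, keyword matching and
    abbreviation-occurrence search; annotations get sequential ids in
    document order and global character offsets.  The input document is
    not modified.
    """
    if cfg is None:
        cfg = RuleConfig()
    doc.check_offsets()
    out = copy.deepcopy(doc)
    enzyme_abbrevs = find_enzyme_abbreviations(abbrevs or {}, tree, cfg)

    def selected(label: str) -> bool:
        low = label.lower()
        return any(name in low for name in cfg.sections)

    per_passage: list[list[Match]] = []
    for passage in out.passages:
        matches: list[Match] = []
        if passage.text and selected(passage.section_label):
            for sent in split_sentences(passage.text, passage.offset):
                d = direct_match(sent, tree)
                k = keyword_match(sent, tree, cfg, direct=d)
                matches.extend(d)
                matches.extend(k)
            # abbreviation occurrences (case-sensitive whole words)
            spans = [(m.start, m.end) for m in matches]
            for short, template in sorted(enzyme_abbrevs.items()):
                for m in _abbrev_regex(short).finditer(passage.text):
                    s = passage.offset + m.start()
                    e = passage.offset + m.end()
                    if any(s < e2 and e > s2 for s2, e2 in spans):
                        continue
                    matches.append(
                        Match(
                            surface=m.group(0),
                            start=s,
                            length=e - s,
                            identifier=template.identifier,
                            method="abbreviation",
                        )
                    )
                    spans.append((s, e))
        matches.sort(key=lambda m: m.start)
        per_passage.append(matches)

    ann_id = 0
    for passage, matches in zip(out.passages, per_passage):
        passage.annotations = []
        for m in matches:
            ann_id += 1
            passage.annotations.append(_match_to_annotation(m, ann_id, cfg))
    return out
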