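"""Training-corpus construction from annotated documents.

Annotated sentences are exported with SOBIE (Singleton / Begin / Inside /
End / Outside) or BIO labels; only sentences containing at least one
enzyme entity enter the corpus.  Documents are split 75:10:15 into
training : validation : test with an equal domain balance — per domain the
validation set gets floor(n*0.10) articles, the test set floor(n*0.15) and
the training set the remainder.
"""

from __future__ import annotations

import math
import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._text import iter_sentence_spans
from .bioc_io import Annotation, BioCDoc, Passage
from .dictionary import EC_RE

__all__ = [
    "TaggedSentence", "CorpusSplit", "replace_abbreviations",
    "extract_tagged_sentences", "split_corpus", "corpus_stats",
    "write_conll", "read_conll", "tokenize_for_tagging",
    "tags_to_spans", "spans_to_tags", "convert_tags",
]

_SOBIE_GRAMMAR = re.compile(r"^(O|S|BI*E)*$")
_BIO_GRAMMAR = re.compile(r"^(O|BI*)*$")

_PUNCT = ".,;:!?\"'()[]{}%/"


@dataclass
class TaggedSentence:
    """A tokenized sentence with per-token entity labels.

    ``sentence_id`` is ``PMCID:section:paragraph:index``; the scheme is
    either ``sobie`` (labels O/S/B/I/E) or ``bio`` (O/B/I).
    """

    sentence_id: str
    tokens: list[str]
    tags: list[str]
    scheme: str = "sobie"

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.tags):
            raise ValueError("tokens and tags must align")
        if self.scheme not in {"sobie", "bio"}:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        grammar = _SOBIE_GRAMMAR if self.scheme == "sobie" else _BIO_GRAMMAR
        if not grammar.match("".join(self.tags)):
            raise ValueError(f"ill-formed {self.scheme} sequence: {self.tags}")

    def entity_spans(self) -> list[tuple[int, int]]:
        return tags_to_spans(self.tags, self.scheme)


@dataclass
class CorpusSplit:
    """A 75:10:15 partition of document ids, balanced per domain."""

    train: list[str] = field(default_factory=list)
    validation: list[str] = field(default_factory=list)
    test: list[str] = field(default_factory=list)
    ratios: tuple[float, float, float] = (0.75, 0.10, 0.15)
    seed: int = 0


def tags_to_spans(tags: Sequence[str], scheme: str = "sobie") -> list[tuple[int, int]]:
    """Decode a label sequence into half-open token-index spans."""
    spans: list[tuple[int, int]] = []
    start: int | None = None
    for i, tag in enumerate(tags):
        if tag == "O":
            start = None
        elif tag == "S":
            spans.append((i, i + 1))
        elif tag == "B":
            start = i
            if scheme == "bio" and (i + 1 == len(tags) or tags[i + 1] != "I"):
                spans.append((i, i + 1))
        elif tag == "I":
            if scheme == "bio":
                assert start is not None
                if i + 1 == len(tags) or tags[i + 1] != "I":
                    spans.append((start, i + 1))
        elif tag == "E":
            assert start is not None
            spans.append((start, i + 1))
            start = None
    return spans


def spans_to_tags(n_tokens: int, spans: Iterable[tuple[int, int]],
                  scheme: str = "sobie") -> list[str]:
    """Encode half-open token-index spans as a label sequence."""
    tags = ["O"] * n_tokens
    for a, b in spans:
        if b - a == 1:
            tags[a] = "S" if scheme == "sobie" else "B"
        else:
            tags[a] = "B"
            for i in range(a + 1, b - 1):
                tags[i] = "I"
            tags[b - 1] = "E" if scheme == "sobie" else "I"
    return tags


def convert_tags(tags: Sequence[str], source: str, target: str) -> list[str]:
    """Convert between SOBIE and BIO through the span representation."""
    return spans_to_tags(len(tags), tags_to_spans(tags, source), target)


def _replacement_spans(text: str, abbrevs: Mapping[str, str]) -> list[tuple[int, int, str, str]]:
    spans: list[tuple[int, int, str, str]] = []
    for short, definition in sorted(abbrevs.items(), key=lambda kv: -len(kv[0])):
        pattern = re.compile(
            rf"(?<![^\W_])(?<!-){re.escape(short)}(?![^\W_])(?!-)", re.UNICODE
        )
        for m in pattern.finditer(text):
            if any(m.start() < e and m.end() > s for s, e, _, _ in spans):
                continue
            spans.append((m.start(), m.end(), definition, short))
    spans.sort(key=lambda t: t[0])
    return spans


def replace_abbreviations(doc: BioCDoc, enzyme_abbrevs: Mapping[str, str]) -> BioCDoc:
    """Replace enzyme short-form occurrences by their full definitions.

    ``enzyme_abbrevs`` maps short form → definition (only the abbreviations
    resolved as enzymes should be passed; others are left untouched).
    Passage offsets and annotation offsets are recomputed; an annotation
    covering a replaced short form is rewritten to cover the inserted
    definition.
    """
    new_passages: list[Passage] = []
    delta = 0  # cumulative change in character count
    for passage in doc.passages:
        repls = _replacement_spans(passage.text, enzyme_abbrevs)
        new_offset = passage.offset + delta
        pieces: list[str] = []
        pos = 0
        # (old_start, old_end, new_start, new_length) per replacement
        edits: list[tuple[int, int, int, int]] = []
        for s, e, definition, _short in repls:
            pieces.append(passage.text[pos:s])
            new_s = sum(len(p) for p in pieces)
            pieces.append(definition)
            edits.append((s, e, new_s, len(definition)))
            pos = e
        pieces.append(passage.text[pos:])
        new_text = "".join(pieces)

        def remap(old_local: int) -> int:
            shift = 0
            for s, e, new_s, new_len in edits:
                if old_local >= e:
                    shift += new_len - (e - s)
                elif old_local > s:
                    return new_s  # inside a replacement: snap to its start
            return old_local + shift

        new_anns: list[Annotation] = []
        for ann in passage.annotations:
            old_s = ann.offset - passage.offset
            old_e = old_s + ann.length
            covering = [
                (s, e, d) for s, e, d, _ in repls if s < old_e and e > old_s
            ]
            if covering:
                # annotation over a replaced short form: cover the definition
                s, e, definition = covering[0]
                new_s = remap(s)
                new_anns.append(
                    Annotation(
                        text=definition,
                        infons=dict(ann.infons),
                        id=ann.id,
                        locations=[{"offset": new_offset + new_s,
                                    "length": len(definition)}],
                    )
                )
            else:
                new_s = remap(old_s)
                new_anns.append(
                    Annotation(
                        text=ann.text,
                        infons=dict(ann.infons),
                        id=ann.id,
                        locations=[{"offset": new_offset + new_s,
                                    "length": ann.length}],
                    )
                )
        new_passages.append(
            Passage(
                text=new_text,
                offset=new_offset,
                section_label=passage.section_label,
                infons=dict(passage.infons),
                annotations=new_anns,
            )
        )
        delta += len(new_text) - len(passage.text)
    return BioCDoc(
        pmcid=doc.pmcid,
        passages=new_passages,
        domain_tag=doc.domain_tag,
        infons=dict(doc.infons),
    )


def tokenize_for_tagging(text: str, base_offset: int = 0) -> list[tuple[str, int]]:
    """Whitespace tokenization with edge punctuation split off.

    Leading/trailing punctuation and brackets become their own tokens;
    hyphens stay inside tokens because enzyme names hyphenate.
    """
    out: list[tuple[str, int]] = []
    for m in re.finditer(r"\S+", text):
        chunk, start = m.group(0), m.start()
        left = 0
        while left < len(chunk) and chunk[left] in _PUNCT:
            out.append((chunk[left], base_offset + start + left))
            left += 1
        right = len(chunk)
        trailing: list[tuple[str, int]] = []
        while right > left and chunk[right - 1] in _PUNCT:
            right -= 1
            trailing.append((chunk[right], base_offset + start + right))
        if right > left:
            out.append((chunk[left:right], base_offset + start + left))
        out.extend(reversed(trailing))
    return out


def _sentence_tags(
    tokens: list[tuple[str, int]],
    spans: list[tuple[int, int]],
    scheme: str,
) -> list[str]:
    token_spans: list[tuple[int, int]] = []
    for a, b in spans:
        hit = [
            i for i, (tok, off) in enumerate(tokens)
            if off < b and off + len(tok) > a  # >= 1 character of overlap
        ]
        if hit:
            token_spans.append((hit[0], hit[-1] + 1))
    return spans_to_tags(len(tokens), token_spans, scheme)


def extract_tagged_sentences(
    docs: Iterable[BioCDoc], scheme: str = "sobie"
) -> list[TaggedSentence]:
    """Annotated sentences of the corpus, labeled per the chosen scheme.

    Only sentences overlapping at least one annotation are kept.  A token
    partially covered by an annotation is tagged inside the entity.
    """
    out: list[TaggedSentence] = []
    for doc in docs:
        for p_idx, passage in enumerate(doc.passages):
            if not passage.annotations:
                continue
            anns = [(a.offset, a.end) for a in passage.annotations]
            for s_idx, (s, e) in enumerate(iter_sentence_spans(passage.text)):
                g_s, g_e = passage.offset + s, passage.offset + e
                overlapping = [(a, b) for a, b in anns if a < g_e and b > g_s]
                if not overlapping:
                    continue
                tokens = tokenize_for_tagging(passage.text[s:e], g_s)
                tags = _sentence_tags(tokens, overlapping, scheme)
                if all(t == "O" for t in tags):
                    continue
                out.append(
                    TaggedSentence(
                        sentence_id=(
                            f"{doc.pmcid}:{passage.section_label}:{p_idx}:{s_idx}"
                        ),
                        tokens=[tok for tok, _ in tokens],
                        tags=tags,
                        scheme=scheme,
                    )
                )
    return out


def split_counts(n: int, ratios: tuple[float, float, float] = (0.75, 0.10, 0.15)
                 ) -> tuple[int, int, int]:
    """(train, validation, test) sizes: floor the two small parts, the
    remainder trains."""
    n_val = math.floor(n * ratios[1] + 1e-9)
    n_test = math.floor(n * ratios[2] + 1e-9)
    return n - n_val - n_test, n_val, n_test


def split_corpus(
    doc_ids_by_domain: Mapping[str, Sequence[str]],
    ratios: tuple[float, float, float] = (0.75, 0.10, 0.15),
    seed: int = 0,
) -> CorpusSplit:
    """Deterministic per-domain 75:10:15 partition of document ids."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    rng = random.Random(seed)
    split = CorpusSplit(ratios=ratios, seed=seed)
    for domain in sorted(doc_ids_by_domain):
        ids = list(doc_ids_by_domain[domain])
        rng.shuffle(ids)
        _, n_val, n_test = split_counts(len(ids), ratios)
        split.validation.extend(ids[:n_val])
        split.test.extend(ids[n_val:n_val + n_test])
        split.train.extend(ids[n_val + n_test:])
    return split


def _is_keyword_annotation(ann: Annotation) -> bool:
    method = ann.infons.get("method")
    if method is not None:
        return method == "keyword"
    return not EC_RE.match(ann.identifier or "")


def corpus_stats(docs: Iterable[BioCDoc]) -> dict[str, pd.DataFrame]:
    """Corpus summary tables.

    Returns ``by_domain`` (entity totals and mean ± sd per article) and
    ``components`` (root term × word-count buckets {1, 2, 3, >3} for the
    entities found by keyword searching).
    """
    per_doc: list[tuple[str, int]] = []
    comp: dict[str, dict[str, int]] = {}
    buckets = ["1", "2", "3", ">3"]
    for doc in docs:
        anns = doc.all_annotations()
        per_doc.append((doc.domain_tag, len(anns)))
        for ann in anns:
            if not _is_keyword_annotation(ann):
                continue
            root = ann.identifier.lower()
            n_words = len(ann.text.split())
            bucket = str(n_words) if n_words <= 3 else ">3"
            comp.setdefault(root, dict.fromkeys(buckets, 0))[bucket] += 1

    rows = []
    df = pd.DataFrame(per_doc, columns=["domain", "n"])
    for domain, grp in df.groupby("domain"):
        rows.append({
            "domain": domain,
            "annotated_enzymes": int(grp["n"].sum()),
            "mean": float(grp["n"].mean()),
            "sd": float(grp["n"].std(ddof=1)) if len(grp) > 1 else 0.0,
            "articles": int(len(grp)),
        })
    rows.append({
        "domain": "total",
        "annotated_enzymes": int(df["n"].sum()) if len(df) else 0,
        "mean": float(df["n"].mean()) if len(df) else 0.0,
        "sd": float(df["n"].std(ddof=1)) if len(df) > 1 else 0.0,
        "articles": int(len(df)),
    })
    by_domain = pd.DataFrame(rows).set_index("domain")

    comp_rows = []
    for root, counts in comp.items():
        row = {"root_term": root, **counts}
        row["total"] = sum(counts.values())
        comp_rows.append(row)
    components = (
        pd.DataFrame(comp_rows).set_index("root_term").sort_values(
            "total", ascending=False)
        if comp_rows
        else pd.DataFrame(columns=["1", "2", "3", ">3", "total"])
    )
    return {"by_domain": by_domain, "components": components}


def write_conll(sentences: Iterable[TaggedSentence], path: str | Path) -> None:
    """CoNLL-style TSV: ``# id`` header, token<TAB>tag lines, blank line
    between sentences."""
    lines: list[str] = []
    for sent in sentences:
        lines.append(f"# {sent.sentence_id}\t{sent.scheme}")
        for tok, tag in zip(sent.tokens, sent.tags):
            lines.append(f"{tok}\t{tag}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def read_conll(path: str | Path) -> list[TaggedSentence]:
    out: list[TaggedSentence] = []
    sid, scheme = "", "sobie"
    tokens: list[str] = []
    tags: list[str] = []

    def flush() -> None:
        nonlocal tokens, tags
        if tokens:
            out.append(TaggedSentence(sid, tokens, tags, scheme))
        tokens, tags = [], []

    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            flush()
        elif line.startswith("# "):
            head = line[2:].split("\t")
            sid = head[0]
            scheme = head[1] if len(head) > 1 else "sobie"
        else:
            tok, tag = line.rsplit("\t", 1)
            tokens.append(tok)
            tags.append(tag)
    flush()
    return out
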