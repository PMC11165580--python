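"""Low-level text utilities shared by the dictionary and the annotator.

Word tokens are maximal runs of letters, digits and hyphens (Greek letters
included); hyphens are kept inside tokens because enzyme names hyphenate
("beta-galactosidase").  A hyphen is consequently *not* a word boundary for
dictionary matching: a form never matches inside a hyphenated token.
"""

from __future__ import annotations

import re
from typing import Iterator

# letters (any script, so Greek included), digits and hyphens; no underscore
WORD_RE = re.compile(r"[^\W_]+(?:-+[^\W_]+)*", re.UNICODE)

# characters that terminate a sentence
_TERMINALS = ".!?"

# tokens after which a period never ends a sentence
_ABBREVS = {
    "e.g", "i.e", "etc", "et", "al", "vs", "cf", "fig", "figs", "eq",
    "eqs", "ref", "refs", "no", "ca", "approx", "resp", "dr", "prof",
    "st", "mr", "mrs", "ms", "inc", "ltd", "spp", "sp", "var", "subsp",
}


def tokenize_words(text: str, base_offset: int = 0) -> list[tuple[str, int]]:
    """Return ``(token, offset)`` pairs for every word token in *text*.

    Offsets are global: ``base_offset`` plus the local character index.
    """
    return [(m.group(0), base_offset + m.start()) for m in WORD_RE.finditer(text)]


def normalize_ws(text: str) -> str:
    """Collapse runs of whitespace to single spaces and strip the ends."""
    return " ".join(text.split())


def _is_boundary_ok(text: str, end: int) -> bool:
    """Decide whether a terminal character at index ``end`` ends a sentence."""
    # look at the token immediately before the period
    before = text[:end]
    m = re.search(r"([^\W_]+(?:\.[^\W_]+)*)$", before, re.UNICODE)
    if m:
        tok = m.group(1)
        if tok.lower() in _ABBREVS:
            return False
        # single capital letter: species/author initial ("E. coli", "J. Smith")
        if len(tok) == 1 and tok.isupper():
            return False
    # decimal number: "0.5s", "3.1.3.1"
    if end + 1 < len(text) and text[end] == "." and text[end + 1].isdigit():
        return False
    return True


def iter_sentence_spans(text: str) -> Iterator[tuple[int, int]]:
    """Yield ``(start, end)`` local spans of sentences in *text*.

    A sentence ends at ``. ! ?`` followed by whitespace and an upper-case
    letter, digit or opening bracket, unless the period belongs to a known
    abbreviation, an initial or a number.  Leading/trailing whitespace is
    excluded from each span.
    """
    n = len(text)
    start = 0
    i = 0
    while i < n:
        ch = text[i]
        if ch in _TERMINALS:
            # absorb closing quotes/brackets following the terminal
            j = i + 1
            while j < n and text[j] in ")]}\"'":
                j += 1
            nxt = j
            while nxt < n and text[nxt].isspace():
                nxt += 1
            at_end = nxt >= n
            starts_new = (not at_end) and (
                text[nxt].isupper() or text[nxt].isdigit() or text[nxt] in "([{\"'"
            )
            if (at_end or (starts_new and nxt > j)) and _is_boundary_ok(text, i):
                span = text[start:j]
                s0 = start + (len(span) - len(span.lstrip()))
                e0 = start + len(span.rstrip())
                if e0 > s0:
                    yield (s0, e0)
                start = nxt
                i = nxt
                continue
        i += 1
    if start < n:
        span = text[start:]
        s0 = start + (len(span) - len(span.lstrip()))
        e0 = start + len(span.rstrip())
        if e0 > s0:
            yield (s0, e0)
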