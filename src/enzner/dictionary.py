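"""Enzyme nomenclature parsing, spelling-variant expansion and the
hierarchical (root-term-branched) search dictionary.

Enzyme names are clustered into branches keyed by their *root term* — the
final token of the name, which for most enzymes ends in "-ase"
("dehydrogenase", "kinase", ...).  The matcher only ever scans the branch
selected by a root token found in the sentence, which keeps matching fast
without changing its result.  Names whose final token does not end in
"-ase" (lysozyme, trypsin, ...) live in a parallel set of branches.

Matching is case-insensitive; the dictionary stores lowercase surface
forms, while annotations preserve the article's original casing.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import re
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from ._text import WORD_RE, normalize_ws

logger = logging.getLogger(__name__)

EC_RE = re.compile(r"^\d+\.\d+\.\d+\.\d+$")

#: hard cap on variants generated per name (guards pathological inputs)
MAX_VARIANTS = 4096

_DATA = resources.files("enzner") / "data"


def default_greek_table() -> dict[str, str]:
    """Latin-name → Greek-letter table bundled with the package."""
    with (_DATA / "greek.json").open(encoding="utf-8") as fh:
        return json.load(fh)


def default_stoplist() -> frozenset[str]:
    """Common non-enzyme "-ase" words that must never act as root terms."""
    text = (_DATA / "stoplist.txt").read_text(encoding="utf-8")
    return frozenset(w.strip().lower() for w in text.splitlines() if w.strip())


def load_stoplist(path: str | Path) -> frozenset[str]:
    words = Path(path).read_text(encoding="utf-8").splitlines()
    return frozenset(w.strip().lower() for w in words if w.strip())


def load_greek_table(path: str | Path) -> dict[str, str]:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


@dataclass(frozen=True)
class EnzymeEntry:
    """One nomenclature record: an EC number and its surface names."""

    ec_number: str
    names: tuple[str, ...]
    source_line: str = ""

    def __post_init__(self) -> None:
        if not self.names or any(not normalize_ws(n) for n in self.names):
            raise ValueError("EnzymeEntry requires at least one non-empty name")
        if self.ec_number and not EC_RE.match(self.ec_number):
            raise ValueError(f"malformed EC number: {self.ec_number!r}")


def load_enzyme_list(path: str | Path, dialect: str = "tsv") -> list[EnzymeEntry]:
    """Parse an enzyme nomenclature file into :class:`EnzymeEntry` records.

    Two dialects are supported:

    ``tsv``
        ``EC<TAB>name1; name2; ...`` — one record per line.
    ``kegg``
        the KEGG-REST flat list, ``ec:EC_number<whitespace>name1; name2;
        ...``; records flagged "Transferred" or "Deleted" are skipped.

    Duplicate surface forms across records keep their first EC assignment
    (logged); later records never overwrite earlier ones.
    """
    if dialect not in {"tsv", "kegg"}:
        raise ValueError(f"unknown dialect: {dialect!r}")
    try:
        text = Path(path).read_text(encoding="utf-8")
    except OSError as exc:
        raise IOError(f"cannot read enzyme list {path}: {exc}") from exc

    entries: list[EnzymeEntry] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if dialect == "tsv":
            parts = line.split("\t", 1)
            if len(parts) != 2:
                continue
            ec, names_field = parts
        else:  # kegg
            m = re.match(r"(?:ec:)?(\d+\.\d+\.\d+\.[\dn]+)\s+(.*)$", line)
            if not m:
                continue
            ec, names_field = m.group(1), m.group(2)
            if re.match(r"(?i)\s*(Transferred|Deleted)", names_field):
                logger.info("skipping transferred/deleted record: %s", line)
                continue
        ec = ec.strip()
        if not EC_RE.match(ec):
            ec = ""
        names = [normalize_ws(n) for n in names_field.split(";")]
        names = [n for n in names if n]
        if not names:
            continue
        entries.append(EnzymeEntry(ec_number=ec, names=tuple(names), source_line=raw))

    if not entries:
        raise ValueError(f"no enzyme entries parsed from {path} (dialect {dialect!r})")
    return entries


def _segment(name: str) -> tuple[list[str], list[str]]:
    """Split *name* into alternating segments and separators.

    Separators are single spaces or hyphens between word segments; returns
    ``(segments, separators)`` with ``len(separators) == len(segments)-1``.
    """
    parts = re.split(r"([ -])", name)
    segments = parts[0::2]
    separators = parts[1::2]
    return segments, separators


def expand_variants(
    name: str, greek: Mapping[str, str] | None = None
) -> set[str]:
    """All spelling variants of an enzyme name.

    For every internal hyphen or space the alternative separator is also
    generated, and every Greek word segment is swapped with its Latin
    spelled-out name (and vice versa); all combinations are produced, so
    the returned set is a fixed point of the expansion.
    """
    if not name:
        raise ValueError("name must be non-empty")
    name = normalize_ws(name)
    if greek is None:
        greek = default_greek_table()
    letter_to_name = {v: k for k, v in greek.items()}

    segments, separators = _segment(name)
    seg_choices: list[list[str]] = []
    for seg in segments:
        low = seg.lower()
        if low in greek:
            seg_choices.append([seg, greek[low]])
        elif seg in letter_to_name or low in letter_to_name:
            key = seg if seg in letter_to_name else low
            seg_choices.append([seg, letter_to_name[key]])
        else:
            seg_choices.append([seg])
    sep_choices = [[" ", "-"] if s in (" ", "-") else [s] for s in separators]

    out: set[str] = set()
    for combo in itertools.product(*seg_choices, *sep_choices):
        segs = combo[: len(segments)]
        seps = combo[len(segments):]
        pieces = [segs[0]]
        for sep, seg in zip(seps, segs[1:]):
            pieces.append(sep)
            pieces.append(seg)
        out.add("".join(pieces))
        if len(out) >= MAX_VARIANTS:
            logger.warning("variant cap reached for %r", name)
            break
    out.add(name)
    return out


def root_term_of(token: str, stoplist: Iterable[str] | None = None) -> str | None:
    """The lowercased token when it can act as an enzyme root term.

    A root term ends in "ase" (case-insensitive) and is not a stoplist
    word ("phase", "database", ...).  Returns ``None`` otherwise.
    """
    low = token.lower()
    if stoplist is None:
        stoplist = default_stoplist()
    if low.endswith("ase") and low not in stoplist:
        return low
    return None


def _form_sort_key(form: str) -> tuple[int, int, str]:
    # longest token count first, then longest in characters, then lexicographic
    return (-len(form.split()), -len(form), form)


@dataclass
class HierarchicalDictionary:
    """Root-term-branched search dictionary.

    ``branches`` maps a root term (final token of a name, ending in "ase")
    to that branch's surface forms, longest-first; ``non_ase_branch`` holds
    the forms whose final token does not end in "ase".  ``ec_index`` maps
    every surface form with a known EC number to it, and ``vocab`` holds,
    per branch, all non-final tokens seen in that branch (used by the
    keyword matcher to judge candidate modifiers).
    """

    branches: dict[str, list[str]] = field(default_factory=dict)
    non_ase_branch: dict[str, list[str]] = field(default_factory=dict)
    ec_index: dict[str, str] = field(default_factory=dict)
    vocab: dict[str, set[str]] = field(default_factory=dict)
    _trigger_cache: dict[str, list[str]] | None = field(
        default=None, repr=False, compare=False
    )

    def all_forms(self) -> set[str]:
        forms: set[str] = set()
        for branch in self.branches.values():
            forms.update(branch)
        for branch in self.non_ase_branch.values():
            forms.update(branch)
        return forms

    def branch_of(self, key: str) -> list[str]:
        """Surface forms of the branch keyed by *key* (both trees)."""
        key = key.lower()
        return self.branches.get(key, []) + self.non_ase_branch.get(key, [])

    def trigger_index(self) -> dict[str, list[str]]:
        """Map each form's final *word* (letter/digit/hyphen run) to its
        forms.

        The branch key is the final whitespace token, which for names with
        parenthesized qualifiers ("... dehydrogenase (NADP+)") contains
        punctuation that never appears inside a word token of a sentence;
        the final word is what a tokenized sentence can actually trigger
        on.
        """
        if self._trigger_cache is None:
            index: dict[str, list[str]] = {}
            for form in self.all_forms():
                words = WORD_RE.findall(form)
                key = words[-1].lower() if words else form
                index.setdefault(key, []).append(form)
            self._trigger_cache = index
        return self._trigger_cache

    def __len__(self) -> int:
        return len(self.all_forms())


def build_hierarchy(
    entries: Iterable[EnzymeEntry],
    greek: Mapping[str, str] | None = None,
) -> HierarchicalDictionary:
    """Expand every name of every entry and index the variants by root term."""
    entries = list(entries)
    if not entries:
        raise ValueError("cannot build a dictionary from zero entries")
    if greek is None:
        greek = default_greek_table()

    tree = HierarchicalDictionary()
    by_branch: dict[str, set[str]] = {}
    by_branch_non_ase: dict[str, set[str]] = {}

    for entry in entries:
        for name in entry.names:
            for variant in expand_variants(name, greek):
                form = variant.lower()
                final = form.split()[-1]
                target = by_branch if final.endswith("ase") else by_branch_non_ase
                target.setdefault(final, set()).add(form)
                if entry.ec_number:
                    prev = tree.ec_index.get(form)
                    if prev is None:
                        tree.ec_index[form] = entry.ec_number
                    elif prev != entry.ec_number:
                        logger.info(
                            "EC conflict for %r: keeping %s, ignoring %s",
                            form, prev, entry.ec_number,
                        )

    for key, forms in by_branch.items():
        tree.branches[key] = sorted(forms, key=_form_sort_key)
    for key, forms in by_branch_non_ase.items():
        tree.non_ase_branch[key] = sorted(forms, key=_form_sort_key)

    for key, forms in itertools.chain(
        tree.branches.items(), tree.non_ase_branch.items()
    ):
        voc: set[str] = set()
        for form in forms:
            voc.update(form.split()[:-1])
        tree.vocab[key] = voc
    return tree


def load_mini_dictionary() -> list[EnzymeEntry]:
    """The bundled miniature nomenclature (all seven EC classes)."""
    with resources.as_file(_DATA / "mini_enzymes.tsv") as p:
        return load_enzyme_list(p, dialect="tsv")


def save_dictionary(tree: HierarchicalDictionary, path: str | Path,
                    source: str | Path | None = None) -> None:
    """Serialize a dictionary to JSON with a build timestamp and, when the
    source file is given, its SHA-256 checksum."""
    meta: dict[str, str] = {
        "built_at": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
    }
    if source is not None:
        meta["source_sha256"] = hashlib.sha256(
            Path(source).read_bytes()
        ).hexdigest()
    payload = {
        "meta": meta,
        "branches": tree.branches,
        "non_ase_branch": tree.non_ase_branch,
        "ec_index": tree.ec_index,
        "vocab": {k: sorted(v) for k, v in tree.vocab.items()},
    }
    Path(path).write_text(
        json.dumps(payload, ensure_ascii=False, indent=1, sort_keys=True),
        encoding="utf-8",
    )


def load_dictionary(path: str | Path) -> HierarchicalDictionary:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return HierarchicalDictionary(
        branches=payload["branches"],
        non_ase_branch=payload["non_ase_branch"],
        ec_index=payload["ec_index"],
        vocab={k: set(v) for k, v in payload["vocab"].items()},
    )
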