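"""BioC-JSON reading and writing.

The dialect handled here is the one produced by full-text HTML→BioC
converters: a collection with one document per article, passages carrying
an IAO-derived section label in their infons, a character ``offset`` into
the whole article, and stand-off ``annotations`` with four elements —
``text``, ``infons``, ``id`` and ``locations`` — whose offsets are global
character positions.  Unknown infon keys are preserved verbatim.

Validation is structural: missing or mistyped elements are reported with a
JSON-pointer-style path to the offending node.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

__all__ = [
    "Annotation", "Passage", "BioCDoc", "BioCValidationError",
    "read_bioc", "write_bioc", "read_abbreviations", "write_abbreviations",
    "validate_collection", "article_text",
]

DOMAINS = ("GWAS", "proteomics", "metabolomics", "microbiome", "other")

#: infon keys under which converters store the section label
_SECTION_KEYS = ("section_type", "iao_name_1", "section_heading", "section_title_1")


class BioCValidationError(ValueError):
    """Schema violation; ``path`` is a JSON-pointer to the offending node."""

    def __init__(self, path: str, message: str) -> None:
        self.path = path
        super().__init__(f"{path}: {message}")


@dataclass
class Annotation:
    """A stand-off entity annotation (text, infons, id, locations)."""

    text: str
    infons: dict[str, Any]
    id: str
    locations: list[dict[str, int]]

    @property
    def offset(self) -> int:
        return int(self.locations[0]["offset"])

    @property
    def length(self) -> int:
        return int(self.locations[0]["length"])

    @property
    def end(self) -> int:
        return self.offset + self.length

    @property
    def identifier(self) -> str:
        return str(self.infons.get("identifier", ""))

    def to_json(self) -> dict[str, Any]:
        return {
            "text": self.text,
            "infons": dict(self.infons),
            "id": self.id,
            "locations": [dict(loc) for loc in self.locations],
        }


@dataclass
class Passage:
    """One paragraph of the article with its global character offset."""

    text: str
    offset: int
    section_label: str = "other"
    infons: dict[str, Any] = field(default_factory=dict)
    annotations: list[Annotation] = field(default_factory=list)

    def to_json(self) -> dict[str, Any]:
        infons = dict(self.infons)
        infons.setdefault("section_type", self.section_label)
        return {
            "offset": self.offset,
            "infons": infons,
            "text": self.text,
            "annotations": [a.to_json() for a in self.annotations],
        }


@dataclass
class BioCDoc:
    """An article: ordered passages plus its PMCID and omics domain tag."""

    pmcid: str
    passages: list[Passage] = field(default_factory=list)
    domain_tag: str = "other"
    infons: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> dict[str, Any]:
        infons = dict(self.infons)
        infons.setdefault("domain", self.domain_tag)
        return {
            "id": self.pmcid,
            "infons": infons,
            "passages": [p.to_json() for p in self.passages],
        }

    def all_annotations(self) -> list[Annotation]:
        return [a for p in self.passages for a in p.annotations]

    def check_offsets(self) -> None:
        """Passage offsets must be non-decreasing running positions."""
        pos = 0
        for i, p in enumerate(self.passages):
            if p.offset < pos:
                raise BioCValidationError(
                    f"/passages/{i}/offset",
                    f"offset {p.offset} overlaps previous passage (ends at {pos})",
                )
            pos = p.offset + len(p.text)


def article_text(doc: BioCDoc) -> str:
    """Reconstruct the full article text.

    Passages are placed at their recorded offsets; gaps between them are
    padded with newlines so that global annotation offsets slice correctly.
    """
    if not doc.passages:
        return ""
    end = max(p.offset + len(p.text) for p in doc.passages)
    buf = ["\n"] * end
    for p in doc.passages:
        buf[p.offset : p.offset + len(p.text)] = list(p.text)
    return "".join(buf)


def _require(obj: Any, key: str, typ: type | tuple[type, ...], path: str) -> Any:
    if not isinstance(obj, dict):
        raise BioCValidationError(path, f"expected object, got {type(obj).__name__}")
    if key not in obj:
        raise BioCValidationError(path, f"missing required element {key!r}")
    val = obj[key]
    if not isinstance(val, typ):
        raise BioCValidationError(
            f"{path}/{key}",
            f"expected {typ}, got {type(val).__name__}",
        )
    return val


def _parse_annotation(obj: Any, path: str) -> Annotation:
    text = _require(obj, "text", str, path)
    infons = _require(obj, "infons", dict, path)
    aid = obj.get("id")
    if not isinstance(aid, (str, int)):
        raise BioCValidationError(f"{path}/id", "missing or non-scalar id")
    locations = _require(obj, "locations", list, path)
    if not locations:
        raise BioCValidationError(f"{path}/locations", "locations must be non-empty")
    locs = []
    for j, loc in enumerate(locations):
        off = _require(loc, "offset", int, f"{path}/locations/{j}")
        length = _require(loc, "length", int, f"{path}/locations/{j}")
        locs.append({"offset": off, "length": length})
    return Annotation(text=text, infons=dict(infons), id=str(aid), locations=locs)


def _section_label(infons: dict[str, Any]) -> str:
    for key in _SECTION_KEYS:
        if key in infons and infons[key]:
            return str(infons[key]).strip().lower()
    return "other"


def parse_collection(payload: Any) -> list[BioCDoc]:
    """Parse an in-memory BioC collection object into documents."""
    documents = _require(payload, "documents", list, "")
    docs: list[BioCDoc] = []
    for i, dobj in enumerate(documents):
        dpath = f"/documents/{i}"
        pmcid = str(_require(dobj, "id", (str, int), dpath))
        dinfons = dict(dobj.get("infons") or {})
        domain = str(dinfons.get("domain", "other"))
        if domain not in DOMAINS:
            domain = "other"
        passages_raw = _require(dobj, "passages", list, dpath)
        passages = []
        for j, pobj in enumerate(passages_raw):
            ppath = f"{dpath}/passages/{j}"
            text = _require(pobj, "text", str, ppath)
            offset = _require(pobj, "offset", int, ppath)
            pinfons = dict(pobj.get("infons") or {})
            anns = [
                _parse_annotation(aobj, f"{ppath}/annotations/{k}")
                for k, aobj in enumerate(pobj.get("annotations") or [])
            ]
            passages.append(
                Passage(
                    text=text,
                    offset=offset,
                    section_label=_section_label(pinfons),
                    infons=pinfons,
                    annotations=anns,
                )
            )
        doc = BioCDoc(pmcid=pmcid, passages=passages, domain_tag=domain,
                      infons=dinfons)
        doc.check_offsets()
        docs.append(doc)
    return docs


def validate_collection(payload: Any) -> None:
    """Raise :class:`BioCValidationError` when *payload* is malformed."""
    parse_collection(payload)


def collection_json(docs: list[BioCDoc], source: str = "enzner") -> dict[str, Any]:
    return {
        "source": source,
        "date": "",
        "key": "",
        "infons": {},
        "documents": [d.to_json() for d in docs],
    }


def read_bioc(path: str | Path) -> list[BioCDoc]:
    """Read a BioC-JSON file; returns its documents in order."""
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return parse_collection(payload)


def write_bioc(docs: BioCDoc | list[BioCDoc], path: str | Path,
               source: str = "enzner") -> None:
    """Write documents as a BioC-JSON collection (stable key order)."""
    if isinstance(docs, BioCDoc):
        docs = [docs]
    payload = collection_json(docs, source=source)
    Path(path).write_text(
        json.dumps(payload, ensure_ascii=False, indent=1, sort_keys=True),
        encoding="utf-8",
    )


def read_abbreviations(path: str | Path) -> dict[str, str]:
    """Read a per-article abbreviation JSON (short form → definition).

    Tolerant: nested one-document wrappers are unwrapped, non-string values
    skipped, and a duplicate short form keeps its first definition.
    """
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if not isinstance(payload, dict):
        raise ValueError(f"abbreviation file {path} must contain a JSON object")
    # some converters nest the map one level down ({pmcid: {short: def}})
    if payload and all(isinstance(v, dict) for v in payload.values()):
        merged: dict[str, str] = {}
        for sub in payload.values():
            for k, v in sub.items():
                if isinstance(v, str) and k not in merged:
                    merged[k] = v
        return merged
    out: dict[str, str] = {}
    for k, v in payload.items():
        if not isinstance(v, str):
            continue
        if k in out:
            continue
        out[k] = v
    return out


def write_abbreviations(abbrevs: dict[str, str], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(abbrevs, ensure_ascii=False, indent=1, sort_keys=True),
        encoding="utf-8",
    )
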