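"""Dialect-aware parsing of repository metadata into one canonical record.

Every repository speaks its own metadata dialect (different element names,
XML vs JSON). A declarative field map per dialect (``data/dialects.yaml``)
names where dataset identifiers, cross-references and publication provenance
live; everything else is flattened to dotted-path attributes. Adding a
repository means adding a dialect entry, not code.

The same field map drives serialization, so ``parse_metadata`` and
``serialize_metadata`` round-trip every canonical field the dialect can
express.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Optional

import yaml

from .errors import ConfigurationError, MetadataParseError

__all__ = [
    "CrossReference",
    "Provenance",
    "DatasetMetadata",
    "DatasetQuery",
    "available_dialects",
    "load_dialect_map",
    "parse_metadata",
    "serialize_metadata",
]

_PROVENANCE_FIELDS = ("authors", "email", "title")


# ---------------------------------------------------------------------------
# Canonical records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossReference:
    """Reference from one dataset's metadata to another dataset."""

    target_id: str
    target_host: str = ""


@dataclass(frozen=True)
class Provenance:
    """Publication provenance triple: authors, contact email, title."""

    authors: Optional[str] = None
    email: Optional[str] = None
    title: Optional[str] = None

    def filled_fields(self) -> tuple[str, ...]:
        return tuple(name for name in _PROVENANCE_FIELDS
                     if (getattr(self, name) or "").strip())


@dataclass
class DatasetMetadata:
    """Dialect-independent record of one dataset's metadata."""

    repository_id: str
    format: str  # "XML" or "JSON"
    raw_text: str
    attributes: dict[str, list[str]] = field(default_factory=dict)
    identifiers: list[str] = field(default_factory=list)
    cross_references: list[CrossReference] = field(default_factory=list)
    provenance: Optional[Provenance] = None
    dialect: str = "generic"

    def __post_init__(self) -> None:
        if any(not name for name in self.attributes):
            raise ValueError("attribute names must be nonempty")
        if any(not ident.strip() for ident in self.identifiers):
            raise ValueError("identifiers must be nonblank")

    def search_text(self) -> str:
        """Text the keyword check (F2) runs against.

        The raw document when available, otherwise a canonical join of all
        extracted fields (for records built in memory).
        """
        if self.raw_text:
            return self.raw_text
        parts: list[str] = list(self.identifiers)
        for values in self.attributes.values():
            parts.extend(values)
        if self.provenance:
            parts.extend(getattr(self.provenance, f) or ""
                         for f in _PROVENANCE_FIELDS)
        return "\n".join(parts)


@dataclass(frozen=True)
class DatasetQuery:
    """One use case's search: keywords the researcher typed plus the
    accession of the dataset they settled on."""

    use_case: str
    repository_id: str
    keywords: tuple[str, ...]
    dataset_id: str

    def __init__(self, use_case: str, repository_id: str,
                 keywords, dataset_id: str):
        cleaned: list[str] = []
        seen: set[str] = set()
        for kw in keywords:
            kw = kw.strip()
            if not kw:
                continue
            if kw.lower() not in seen:
                seen.add(kw.lower())
                cleaned.append(kw)
        if not cleaned:
            raise ValueError("a query needs at least one nonblank keyword")
        if not dataset_id.strip():
            raise ValueError("a query needs a nonblank dataset id")
        object.__setattr__(self, "use_case", use_case)
        object.__setattr__(self, "repository_id", repository_id)
        object.__setattr__(self, "keywords", tuple(cleaned))
        object.__setattr__(self, "dataset_id", dataset_id.strip())


# ---------------------------------------------------------------------------
# Dialect map
# ---------------------------------------------------------------------------

def load_dialect_map(path: Optional[str] = None) -> dict:
    """Load the dialect field maps (packaged YAML by default)."""
    if path is None:
        text = (resources.files("fairmi") / "data/dialects.yaml").read_text()
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    dialects = yaml.safe_load(text)
    if not isinstance(dialects, dict) or not dialects:
        raise ConfigurationError("dialect map must be a nonempty mapping")
    return dialects


_DIALECTS: Optional[dict] = None


def _dialect_config(dialect: str) -> dict:
    global _DIALECTS
    if _DIALECTS is None:
        _DIALECTS = load_dialect_map()
    try:
        return _DIALECTS[dialect]
    except KeyError:
        raise ConfigurationError(
            f"unknown metadata dialect {dialect!r}; "
            f"known: {sorted(_DIALECTS)}") from None


def available_dialects() -> list[str]:
    _dialect_config("generic")  # force load
    assert _DIALECTS is not None
    return sorted(_DIALECTS)


# ---------------------------------------------------------------------------
# Document walking (shared by XML and JSON)
# ---------------------------------------------------------------------------

def _walk_json(node, path: str) -> Iterator[tuple[str, object]]:
    """Yield (dotted_path, leaf_value) pairs; list items share their path."""
    if isinstance(node, dict):
        for key, value in node.items():
            child = f"{path}.{key}" if path else str(key)
            yield from _walk_json(value, child)
    elif isinstance(node, list):
        for item in node:
            yield from _walk_json(item, path)
    else:
        yield path, node


def _walk_xml(element: ET.Element, path: str) -> Iterator[tuple[str, object]]:
    children = list(element)
    if not children:
        yield path, (element.text or "")
    else:
        for child in children:
            tag = child.tag.split("}")[-1]  # namespace-agnostic
            yield from _walk_xml(child, f"{path}.{tag}" if path else tag)


def _json_entries_at(node, segments: list[str]) -> list[dict]:
    """Collect dict entries at a dotted path (descending through lists)."""
    if not segments:
        if isinstance(node, list):
            return [e for e in node if isinstance(e, dict)]
        return [node] if isinstance(node, dict) else []
    if isinstance(node, list):
        out: list[dict] = []
        for item in node:
            out.extend(_json_entries_at(item, segments))
        return out
    if isinstance(node, dict) and segments[0] in node:
        return _json_entries_at(node[segments[0]], segments[1:])
    return []


def _xml_entries_at(element: ET.Element, path: str,
                    prefix: str = "") -> list[dict]:
    out: list[dict] = []
    for child in element:
        tag = child.tag.split("}")[-1]
        child_path = f"{prefix}.{tag}" if prefix else tag
        if child_path == path:
            entry = {sub.tag.split("}")[-1]: (sub.text or "")
                     for sub in child}
            out.append(entry)
        elif path.startswith(child_path + "."):
            out.extend(_xml_entries_at(child, path, child_path))
    return out


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def parse_metadata(document: str, dialect: str,
                   repository_id: Optional[str] = None,
                   dialect_map: Optional[dict] = None) -> DatasetMetadata:
    """Parse one metadata document into the canonical record.

    ``dialect`` selects the field map; unknown dialects raise a
    :class:`~fairmi.errors.ConfigurationError` (use ``"generic"`` explicitly
    to flatten an unmapped document). Parsing is lossless: the full document
    text is kept in ``raw_text``.
    """
    if not document or not document.strip():
        raise MetadataParseError("empty document", dialect=dialect)
    cfg = (dialect_map or {}).get(dialect) if dialect_map else None
    if cfg is None:
        cfg = _dialect_config(dialect)

    fmt, leaves, xref_entries = _load_document(document, dialect, cfg)

    id_paths = list(cfg.get("identifier_paths", []))
    identifiers = [str(v).strip()
                   for p in id_paths for v in leaves.get(p, [])
                   if str(v).strip()]

    xref_cfg = cfg.get("xref") or {}
    id_key = xref_cfg.get("id_key", "id")
    host_key = xref_cfg.get("host_key", "host")
    own = {i.lower() for i in identifiers}
    cross_references = []
    for entry in xref_entries:
        target = str(entry.get(id_key, "")).strip()
        if target and target.lower() not in own:  # drop self-references
            cross_references.append(
                CrossReference(target, str(entry.get(host_key, "")).strip()))

    prov_cfg = cfg.get("provenance") or {}
    provenance = None
    if prov_cfg:
        values = {}
        for name in _PROVENANCE_FIELDS:
            path = prov_cfg.get(name)
            vals = leaves.get(path, []) if path else []
            text = str(vals[0]).strip() if vals else ""
            values[name] = text or None
        provenance = Provenance(**values)

    consumed = set(id_paths) | {p for p in prov_cfg.values() if p}
    xref_path = xref_cfg.get("path", "")
    attributes: dict[str, list[str]] = {}
    for path, vals in leaves.items():
        if path in consumed or not path:
            continue
        if xref_path and (path == xref_path
                          or path.startswith(xref_path + ".")):
            continue
        texts = [str(v) for v in vals if str(v).strip()]
        if texts:
            attributes[path] = texts

    return DatasetMetadata(
        repository_id=repository_id or dialect,
        format=fmt,
        raw_text=document,
        attributes=attributes,
        identifiers=identifiers,
        cross_references=cross_references,
        provenance=provenance,
        dialect=dialect,
    )


def _load_document(document: str, dialect: str, cfg: dict):
    """Return (format, leaves, xref_entries) for a document."""
    fmt = str(cfg.get("format", "any")).lower()
    xref_path = (cfg.get("xref") or {}).get("path", "")

    def _from_json() -> tuple[str, dict, list]:
        data = json.loads(document)
        leaves: dict[str, list] = {}
        for path, value in _walk_json(data, ""):
            leaves.setdefault(path, []).append(value)
        entries = (_json_entries_at(data, xref_path.split("."))
                   if xref_path else [])
        return "JSON", leaves, entries

    def _from_xml() -> tuple[str, dict, list]:
        root = ET.fromstring(document)
        leaves = {}
        for path, value in _walk_xml(root, ""):
            leaves.setdefault(path, []).append(value)
        entries = _xml_entries_at(root, xref_path) if xref_path else []
        # xref leaf values are structured entries, not plain attributes
        return "XML", leaves, entries

    attempts = {"json": [_from_json], "xml": [_from_xml]}.get(
        fmt, [_from_json, _from_xml])
    last_error: Exception | None = None
    for attempt in attempts:
        try:
            return attempt()
        except (ValueError, ET.ParseError) as exc:
            last_error = exc
    position = getattr(last_error, "position", None) \
        or getattr(last_error, "pos", None)
    raise MetadataParseError(f"malformed {fmt} document: {last_error}",
                             dialect=dialect, position=position)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def serialize_metadata(meta: DatasetMetadata,
                       dialect_map: Optional[dict] = None) -> str:
    """Write a canonical record back out in its dialect.

    Round-trips with :func:`parse_metadata` for every field the dialect
    expresses (a dialect without provenance paths cannot carry provenance).
    """
    cfg = (dialect_map or {}).get(meta.dialect) if dialect_map else None
    if cfg is None:
        cfg = _dialect_config(meta.dialect)
    return build_document(
        cfg,
        fmt=meta.format,
        identifiers=meta.identifiers,
        cross_references=meta.cross_references,
        provenance=meta.provenance,
        attributes=meta.attributes,
    )


def build_document(cfg: dict, fmt: str, identifiers: list[str],
                   cross_references: list[CrossReference],
                   provenance: Optional[Provenance],
                   attributes: dict[str, list[str]]) -> str:
    """Construct a dialect document from canonical fields (also used by the
    synthetic-evidence generator)."""
    tree: dict = {}
    id_paths = list(cfg.get("identifier_paths", []))
    if identifiers and not id_paths:
        raise ConfigurationError("dialect has no identifier path")
    for ident in identifiers:
        _insert(tree, id_paths[0], ident)

    prov_cfg = cfg.get("provenance") or {}
    if provenance:
        for name in _PROVENANCE_FIELDS:
            value = getattr(provenance, name)
            if value is None:
                continue
            path = prov_cfg.get(name)
            if path is None:
                raise ConfigurationError(
                    f"dialect cannot express provenance field {name!r}")
            _insert(tree, path, value)

    xref_cfg = cfg.get("xref") or {}
    if cross_references:
        if not xref_cfg:
            raise ConfigurationError("dialect has no cross-reference path")
        entries = [{xref_cfg.get("id_key", "id"): ref.target_id,
                    xref_cfg.get("host_key", "host"): ref.target_host}
                   for ref in cross_references]
        _insert(tree, xref_cfg["path"], entries, as_entries=True)

    for path, values in attributes.items():
        for value in values:
            _insert(tree, path, value)

    if fmt.upper() == "JSON":
        return json.dumps(_to_json(tree), indent=2, sort_keys=False)
    root_tag = cfg.get("root", "dataset")
    root = ET.Element(root_tag)
    _to_xml(root, tree)
    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=False)


def _insert(tree: dict, path: str, value, as_entries: bool = False) -> None:
    segments = path.split(".")
    node = tree
    for seg in segments[:-1]:
        nxt = node.setdefault(seg, {})
        if not isinstance(nxt, dict):
            raise ConfigurationError(
                f"path conflict at {seg!r} while inserting {path!r}")
        node = nxt
    leaf = segments[-1]
    if as_entries:
        node[leaf] = ("__entries__", list(value))
        return
    slot = node.setdefault(leaf, ("__values__", []))
    if isinstance(slot, dict) or slot[0] != "__values__":
        raise ConfigurationError(
            f"path conflict at {leaf!r} while inserting {path!r}")
    slot[1].append(str(value))


def _to_json(node):
    if isinstance(node, dict):
        return {k: _to_json(v) for k, v in node.items()}
    kind, payload = node
    if kind == "__entries__":
        return payload
    return payload[0] if len(payload) == 1 else payload


def _to_xml(parent: ET.Element, node: dict) -> None:
    for key, value in node.items():
        if isinstance(value, dict):
            child = ET.SubElement(parent, key)
            _to_xml(child, value)
            continue
        kind, payload = value
        if kind == "__entries__":
            for entry in payload:
                child = ET.SubElement(parent, key)
                for sub_key, sub_val in entry.items():
                    ET.SubElement(child, sub_key).text = str(sub_val)
        else:
            for text in payload:
                ET.SubElement(parent, key).text = text
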