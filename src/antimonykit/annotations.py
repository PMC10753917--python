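"""Knowledge-source ranking, querying and annotation-statement writing.

Model elements are linked to ontology terms (MIRIAM-style controlled
vocabulary): ChEBI for small-molecule species, Rhea for reactions, the Gene
Ontology for reactions/processes, UniProt for protein species.  Sources are
ranked by type appropriateness for the element being annotated; queries go
through a pluggable backend so the library works offline against canned
fixtures and online against REST services alike.  Selected hits become
Antimony annotation statements with identifiers.org URIs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol

from .parser import parse
from .render import render_math
from .symbols import MAIN_SCOPE, build_symbol_table


@dataclass(frozen=True)
class KnowledgeSource:
    id: str
    name: str
    serves_types: frozenset[str]


SOURCE_REGISTRY: list[KnowledgeSource] = [
    KnowledgeSource("chebi", "ChEBI", frozenset({"species"})),
    KnowledgeSource("rhea", "Rhea", frozenset({"reaction"})),
    KnowledgeSource("go", "Gene Ontology", frozenset({"reaction", "model"})),
    KnowledgeSource("uniprot", "UniProt", frozenset({"species"})),
]


def register_source(source: KnowledgeSource) -> None:
    """Extend the registry (user-supplied ontologies)."""
    SOURCE_REGISTRY.append(source)


def rank_sources(element_type: str) -> list[tuple[KnowledgeSource, bool]]:
    """All registered sources, type-appropriate ones first and flagged True.

    The full list is always returned so a user can still pick a source that
    is not the obvious one for the element's type.
    """
    appropriate = [
        (s, True) for s in SOURCE_REGISTRY if element_type in s.serves_types
    ]
    rest = [(s, False) for s in SOURCE_REGISTRY if element_type not in s.serves_types]
    return appropriate + rest


@dataclass(frozen=True)
class AnnotationHit:
    source_id: str
    term_id: str  # e.g. CHEBI:17234
    label: str
    uri: str  # identifiers.org-style resolvable URI

    @staticmethod
    def from_term(source_id: str, term_id: str, label: str) -> "AnnotationHit":
        prefix, _, local = term_id.partition(":")
        uri = f"https://identifiers.org/{prefix.lower()}/{term_id}"
        return AnnotationHit(source_id, term_id, label, uri)


class QueryError(RuntimeError):
    """Backend/network failure; distinct from an empty hit list (retriable)."""


class AnnotationBackend(Protocol):
    def search(self, source_id: str, text: str) -> list[AnnotationHit]:
        ...


@dataclass
class OfflineFixtureBackend:
    """Canned query responses: {query: [{source, termId, label, uri?}, ...]}."""

    fixtures: dict[str, list[dict]] = field(default_factory=dict)

    @classmethod
    def from_json(cls, path: str | Path) -> "OfflineFixtureBackend":
        return cls(json.loads(Path(path).read_text()))

    def search(self, source_id: str, text: str) -> list[AnnotationHit]:
        hits = []
        for entry in self.fixtures.get(text, []):
            if entry.get("source") != source_id:
                continue
            uri = entry.get("uri")
            if uri:
                hits.append(
                    AnnotationHit(source_id, entry["termId"], entry["label"], uri)
                )
            else:
                hits.append(
                    AnnotationHit.from_term(source_id, entry["termId"], entry["label"])
                )
        return hits


_SEARCH_URLS = {
    "chebi": "https://www.ebi.ac.uk/ols4/api/search?ontology=chebi&q={q}",
    "go": "https://www.ebi.ac.uk/ols4/api/search?ontology=go&q={q}",
    "rhea": "https://www.rhea-db.org/rhea?query={q}&format=json",
    "uniprot": "https://rest.uniprot.org/uniprotkb/search?query={q}&format=json",
}


class RestBackend:
    """Thin live REST backend (EBI OLS / Rhea / UniProt); requires network."""

    def __init__(self, timeout: float = 10.0):
        self.timeout = timeout

    def search(self, source_id: str, text: str) -> list[AnnotationHit]:
        import urllib.error
        import urllib.parse
        import urllib.request

        url_t = _SEARCH_URLS.get(source_id)
        if url_t is None:
            raise QueryError(f"no REST endpoint registered for source '{source_id}'")
        url = url_t.format(q=urllib.parse.quote(text))
        try:
            with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                payload = json.loads(resp.read().decode())
        except (urllib.error.URLError, OSError, ValueError) as exc:
            raise QueryError(f"query to {source_id} failed: {exc}") from exc
        return _parse_rest_payload(source_id, payload)


def _parse_rest_payload(source_id: str, payload: dict) -> list[AnnotationHit]:
    hits: list[AnnotationHit] = []
    if source_id in ("chebi", "go"):
        for doc in payload.get("response", {}).get("docs", []):
            term = doc.get("obo_id") or doc.get("short_form", "")
            if term:
                hits.append(AnnotationHit.from_term(source_id, term, doc.get("label", term)))
    elif source_id == "rhea":
        for result in payload.get("results", []):
            rid = f"RHEA:{result.get('id')}"
            hits.append(AnnotationHit.from_term(source_id, rid, result.get("equation", rid)))
    elif source_id == "uniprot":
        for result in payload.get("results", []):
            acc = result.get("primaryAccession", "")
            if acc:
                label = (
                    result.get("proteinDescription", {})
                    .get("recommendedName", {})
                    .get("fullName", {})
                    .get("value", acc)
                )
                hits.append(
                    AnnotationHit(source_id, acc, label, f"https://identifiers.org/uniprot/{acc}")
                )
    return hits


def query_source(
    source: KnowledgeSource | str,
    text: str,
    backend: AnnotationBackend,
    limit: int = 20,
) -> list[AnnotationHit]:
    """Search one knowledge source, in backend order, capped at ``limit``.

    An empty query returns no hits without touching the backend; backend
    failures surface as :class:`QueryError` (retriable), never as an empty
    list.
    """
    source_id = source.id if isinstance(source, KnowledgeSource) else source
    if not text.strip():
        return []
    try:
        hits = backend.search(source_id, text)
    except QueryError:
        raise
    except Exception as exc:
        raise QueryError(f"backend failure querying {source_id}: {exc}") from exc
    return hits[:limit]


def apply_annotation(
    document: str,
    element_name: str,
    hit: AnnotationHit,
    qualifier: str = "identity",
) -> str:
    """Append an annotation statement for ``element_name`` at the bottom of
    its enclosing model block (idempotent per (element, uri) pair)."""
    result = parse(document)
    table = build_symbol_table(result.ast)
    owner_scope = None
    for scope_name, scope in table.scopes.items():
        if element_name in scope.symbols:
            owner_scope = scope_name
            break
    if owner_scope is None:
        raise KeyError(f"element '{element_name}' not found in document")
    sym = table.scopes[owner_scope].symbols[element_name]
    if any(uri == hit.uri for _q, uri in sym.annotations):
        return document  # already annotated with this term

    statement = f'{element_name} {qualifier} "{hit.uri}"'
    lines = document.split("\n")
    if owner_scope == MAIN_SCOPE:
        while lines and lines[-1].strip() == "":
            lines.pop()
        lines.append(statement)
        lines.append("")
        return "\n".join(lines)
    model_node = table.models[owner_scope].node
    end_line = model_node.span.line_end  # line holding 'end'
    indent = "  "
    lines.insert(end_line, indent + statement)
    return "\n".join(lines)
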