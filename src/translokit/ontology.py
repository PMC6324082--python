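"""Gene Ontology handling: OBO ingest and ancestor-closed annotation sets.

Proteins are annotated with GO terms plus all of their transitive ancestors
reached through ``is_a`` and ``part_of`` edges, so that a protein annotated
with a specific term also carries every more general term above it.  These
closed sets are the domain over which the binary GO features of the
translocation model are evaluated.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: Relations propagated during ancestor closure.  ``regulates`` and other
#: cross-ontology relations are deliberately ignored; override via the
#: ``relations`` argument of :func:`ancestor_closure` if needed.
CLOSURE_RELATIONS: tuple[str, ...] = ("is_a", "part_of")

NAMESPACES = ("cellular_component", "biological_process", "molecular_function")


class OntologyError(ValueError):
    """Malformed or internally inconsistent ontology input."""


class UnknownTermError(KeyError):
    """A term id that cannot be resolved in the loaded ontology."""

    def __init__(self, term_ids: Iterable[str]):
        self.term_ids = sorted(term_ids)
        super().__init__(f"unknown term id(s): {', '.join(self.term_ids)}")


@dataclass
class OntologyDAG:
    """A directed acyclic graph of ontology terms.

    Edges point child -> parent and carry a relation label.  Obsolete terms
    are kept (so stale annotation files can still be diagnosed) but never
    participate in closures.
    """

    graph: nx.MultiDiGraph
    alt_ids: dict[str, str] = field(default_factory=dict)
    obsolete: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        closure = self._closure_view()
        if not nx.is_directed_acyclic_graph(closure):
            cycle = nx.find_cycle(closure)
            raise OntologyError(f"is_a/part_of cycle detected: {cycle}")

    # -- term access ---------------------------------------------------
    def __contains__(self, term_id: str) -> bool:
        return term_id in self.graph or term_id in self.alt_ids

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def name(self, term_id: str) -> str | None:
        return self.graph.nodes[self.canonical(term_id)].get("name")

    def namespace(self, term_id: str) -> str | None:
        return self.graph.nodes[self.canonical(term_id)].get("namespace")

    def canonical(self, term_id: str) -> str:
        """Resolve an alt_id to its canonical term id (identity otherwise)."""
        if term_id in self.graph:
            return term_id
        if term_id in self.alt_ids:
            return self.alt_ids[term_id]
        raise UnknownTermError([term_id])

    def is_obsolete(self, term_id: str) -> bool:
        return self.canonical(term_id) in self.obsolete

    def _closure_view(self, relations: tuple[str, ...] = CLOSURE_RELATIONS) -> nx.MultiDiGraph:
        return nx.restricted_view(
            self.graph,
            nodes=[],
            edges=[
                (u, v, k)
                for u, v, k in self.graph.edges(keys=True)
                if k not in relations
            ],
        )


def _validate_obo_lines(text: str) -> None:
    """Light structural check so format errors name the offending line."""
    in_stanza = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            in_stanza = True
            continue
        if ":" not in line:
            where = "stanza" if in_stanza else "header"
            raise OntologyError(
                f"malformed OBO {where} line {lineno}: {raw.strip()!r}"
            )


def load_ontology(obo_stream: TextIO | str) -> OntologyDAG:
    """Load an OBO 1.2/1.4 ontology into an :class:`OntologyDAG`.

    ``alt_id`` aliases are mapped to their canonical ids; obsolete terms are
    retained but flagged.  Raises :class:`OntologyError` on malformed stanzas
    (with the line number) and on is_a/part_of cycles.
    """
    if isinstance(obo_stream, str):
        text = obo_stream
    else:
        text = obo_stream.read()
    _validate_obo_lines(text)
    graph = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)

    alt_ids: dict[str, str] = {}
    obsolete: set[str] = set()
    for term_id, data in graph.nodes(data=True):
        for alt in data.get("alt_id", []):
            alt_ids[alt] = term_id
        if str(data.get("is_obsolete", "")).lower() == "true":
            obsolete.add(term_id)

    for u, v, _k in graph.edges(keys=True):
        if u not in graph or v not in graph:  # pragma: no cover - obonet adds both
            raise OntologyError(f"edge endpoint not declared as a term: {u} -> {v}")

    return OntologyDAG(graph=graph, alt_ids=alt_ids, obsolete=obsolete)


def ancestor_closure(
    dag: OntologyDAG,
    terms: Iterable[str],
    relations: tuple[str, ...] = CLOSURE_RELATIONS,
) -> set[str]:
    """Input terms plus all transitive is_a/part_of ancestors.

    Obsolete terms are dropped from the result.  Unknown ids raise
    :class:`UnknownTermError` listing every offending id.
    """
    terms = list(terms)
    unknown = [t for t in terms if t not in dag]
    if unknown:
        raise UnknownTermError(unknown)
    canonical = {dag.canonical(t) for t in terms}
    view = dag._closure_view(relations)
    closed = set()
    for t in canonical:
        if t in dag.obsolete:
            continue
        closed.add(t)
        closed.update(nx.descendants(view, t))  # child->parent edges: ancestors
    return closed - dag.obsolete


def annotate_proteins(
    raw_annotations: Mapping[str, Iterable[str]],
    dag: OntologyDAG,
) -> dict[str, frozenset[str]]:
    """Replace every protein's term set by its ancestor closure.

    Obsolete terms are dropped with a logged warning; an empty annotation
    table yields an empty mapping.
    """
    closed: dict[str, frozenset[str]] = {}
    for protein_id, terms in raw_annotations.items():
        terms = list(terms)
        stale = [t for t in terms if t in dag and dag.is_obsolete(t)]
        if stale:
            logger.warning(
                "protein %s: dropping obsolete term(s) %s",
                protein_id,
                ", ".join(sorted(stale)),
            )
        closed[protein_id] = frozenset(ancestor_closure(dag, terms))
    return closed


def read_annotations(stream: TextIO) -> dict[str, set[str]]:
    """Read protein->GO annotations from TSV or GAF 2.x.

    Plain TSV rows are ``protein_id<TAB>go_id``.  GAF lines (detected by the
    ``!`` comment prefix or >=15 columns) contribute columns 2 (DB object id)
    and 5 (GO id) only.
    """
    annotations: dict[str, set[str]] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        fields = line.split("\t")
        if len(fields) >= 15:  # GAF 2.x record
            protein_id, go_id = fields[1], fields[4]
        elif len(fields) >= 2:
            protein_id, go_id = fields[0], fields[1]
        else:
            raise OntologyError(
                f"annotation line {lineno}: expected at least 2 tab-separated "
                f"columns, got {len(fields)}"
            )
        annotations.setdefault(protein_id, set()).add(go_id)
    return annotations
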