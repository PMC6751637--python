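"""OBO ontology handling: parsing, subsumption closures and class term sets.

The association-mining method treats an ontology as a set of classes linked
by ``is_a`` (subsumption) edges.  Two derived notions drive everything
downstream:

* ``descendants(C)`` — the reflexive transitive subclass closure of ``C``;
* ``terms_of(C)`` — the union of labels and synonyms over that closure,
  i.e. the full set of strings that can refer to ``C`` (``Terms(C)``).

Only ``is_a`` edges define subsumption; other relationship types are
ignored.  Obsolete classes are parsed and kept in the container but are
excluded from closures and therefore from every dictionary built from the
ontology.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict, deque
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import IO, Iterable, Union

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyClass",
    "Ontology",
    "OboParseError",
    "UnknownClassError",
    "parse_obo",
]


class OboParseError(ValueError):
    """Raised for structurally invalid OBO input (id-less stanza, is_a cycle)."""


class UnknownClassError(KeyError):
    """Raised when a class identifier is not present in the ontology."""


@dataclass
class OntologyClass:
    """A single ontology class (a pathogen taxon or a disease).

    Parameters
    ----------
    id:
        CURIE identifier, e.g. ``"DOID:11205"``.
    label:
        Primary name.  ``labels`` returns label plus synonyms.
    synonyms:
        All synonym strings, regardless of scope (EXACT/RELATED/NARROW/BROAD).
    parents:
        Identifiers of direct ``is_a`` parents.
    obsolete:
        Obsolete classes are retained for reference but excluded from
        closures and dictionaries.
    """

    id: str
    label: str = ""
    synonyms: set[str] = field(default_factory=set)
    parents: set[str] = field(default_factory=set)
    obsolete: bool = False

    def labels(self) -> set[str]:
        """Labels(C): the label and synonyms attached directly to this class."""
        out = set(self.synonyms)
        if self.label:
            out.add(self.label)
        return out


# quoted string at the start of an OBO synonym clause
_SYNONYM_RE = re.compile(r'"((?:[^"\\]|\\.)*)"')


@dataclass
class Ontology:
    """Container for one OBO ontology restricted to its ``is_a`` graph."""

    classes: dict[str, OntologyClass] = field(default_factory=dict)

    def __contains__(self, class_id: str) -> bool:
        return class_id in self.classes

    def __len__(self) -> int:
        return len(self.classes)

    def __getitem__(self, class_id: str) -> OntologyClass:
        try:
            return self.classes[class_id]
        except KeyError:
            raise UnknownClassError(class_id) from None

    @property
    def roots(self) -> set[str]:
        """Identifiers of non-obsolete classes without parents."""
        return {
            c.id for c in self.classes.values() if not c.parents and not c.obsolete
        }

    def _children_index(self) -> dict[str, set[str]]:
        children: dict[str, set[str]] = defaultdict(set)
        for cls in self.classes.values():
            for parent in cls.parents:
                children[parent].add(cls.id)
        return children

    def descendants(self, class_id: str) -> set[str]:
        """Reflexive transitive is_a closure below ``class_id``.

        Includes ``class_id`` itself; obsolete classes are excluded from the
        result (and not traversed through).
        """
        if class_id not in self.classes:
            raise UnknownClassError(class_id)
        children = self._children_index()
        seen: set[str] = set()
        queue = deque([class_id])
        while queue:
            current = queue.popleft()
            if current in seen:
                continue
            seen.add(current)
            queue.extend(children.get(current, ()))
        return {i for i in seen if not self.classes[i].obsolete}

    def ancestors(self, class_id: str) -> set[str]:
        """Reflexive transitive is_a closure above ``class_id`` (used for
        count propagation).  Excludes obsolete classes."""
        if class_id not in self.classes:
            raise UnknownClassError(class_id)
        seen: set[str] = set()
        queue = deque([class_id])
        while queue:
            current = queue.popleft()
            if current in seen:
                continue
            seen.add(current)
            queue.extend(self.classes[current].parents)
        return {i for i in seen if not self.classes[i].obsolete}

    def terms_of(self, class_id: str) -> set[str]:
        """Terms(C): every label or synonym of C or of any subclass of C."""
        terms: set[str] = set()
        for did in self.descendants(class_id):
            terms |= self.classes[did].labels()
        return terms

    def extract_branch(self, root_ids: Iterable[str]) -> set[str]:
        """Union of ``descendants`` over ``root_ids``.

        Used to restrict dictionaries to the pathogen groups or to the
        infectious-disease branch of a disease ontology.
        """
        branch: set[str] = set()
        for rid in root_ids:
            branch |= self.descendants(rid)
        return branch

    def curie_prefixes(self) -> set[str]:
        return {c.split(":", 1)[0] for c in self.classes}


def _validate_stanzas(text: str) -> None:
    """Reject [Term] stanzas without an id, naming the offending line."""
    in_term = False
    term_line = 0
    has_id = False
    lines = text.splitlines()
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if stripped.startswith("["):
            if in_term and not has_id:
                raise OboParseError(
                    f"[Term] stanza starting at line {term_line} has no id"
                )
            in_term = stripped == "[Term]"
            term_line = lineno
            has_id = False
        elif in_term and stripped.startswith("id:"):
            has_id = True
    if in_term and not has_id:
        raise OboParseError(f"[Term] stanza starting at line {term_line} has no id")


def _declared_term_ids(text: str) -> set[str]:
    """Ids declared by [Term] stanzas (distinguishes dangling parents from
    genuinely declared classes)."""
    ids: set[str] = set()
    in_term = False
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("["):
            in_term = stripped == "[Term]"
        elif in_term and stripped.startswith("id:"):
            ids.add(stripped[3:].split("!")[0].strip())
            in_term = False  # only the first id clause counts
    return ids


def parse_obo(source: Union[str, Path, IO[str]]) -> Ontology:
    """Parse an OBO 1.2/1.4 flat file into an :class:`Ontology`.

    ``source`` may be a path, a text stream, or OBO text itself (anything
    containing a newline is treated as raw text).  Synonyms of every scope
    are ingested; ``is_a`` targets become parents; obsolete classes are kept
    but flagged.  Dangling parent references are dropped with a warning;
    cyclic ``is_a`` graphs and id-less stanzas are rejected.
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str):
        text = source if "\n" in source else Path(source).read_text()
    else:
        text = source.read()

    _validate_stanzas(text)
    declared = _declared_term_ids(text)

    graph = obonet.read_obo(StringIO(text), ignore_obsolete=False)

    classes: dict[str, OntologyClass] = {}
    for node, data in graph.nodes(data=True):
        if node not in declared:
            continue  # phantom node for a dangling parent reference
        synonyms: set[str] = set()
        for raw in data.get("synonym", []):
            match = _SYNONYM_RE.match(raw)
            if match:
                synonyms.add(match.group(1).replace('\\"', '"'))
        parents = set(data.get("is_a", []))
        dangling = parents - declared
        if dangling:
            logger.warning(
                "class %s references missing parents %s; dropped",
                node,
                sorted(dangling),
            )
            parents -= dangling
        classes[node] = OntologyClass(
            id=node,
            label=data.get("name", ""),
            synonyms=synonyms,
            parents=parents,
            obsolete=str(data.get("is_obsolete", "")).lower() == "true",
        )

    digraph = nx.DiGraph()
    digraph.add_nodes_from(classes)
    for cls in classes.values():
        for parent in cls.parents:
            digraph.add_edge(cls.id, parent)
    try:
        cycle = nx.find_cycle(digraph)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
        raise OboParseError(f"cyclic is_a hierarchy: {path}")

    return Ontology(classes=classes)
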