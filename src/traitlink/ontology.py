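"""Trait/function ontology handling.

A trait ontology (TO) organises plant trait terms — and, identically, a gene
ontology (GO) organises function terms — as a rooted directed acyclic graph:
each term carries ``is_a`` links to one or more parents, the parentless terms
are the root trait groups, and every term sits on a hierarchical *level*
counted downward from the roots (level 1).

This module parses the OBO flat-file dialect those vocabularies are shipped
in, validates the DAG, computes levels and ancestor closures, and implements
the information-content machinery used to compare phenotype descriptions:

* the information content of a term ``t`` is ``I(t) = -ln P(X = t)`` where
  ``P(X = t)`` is the annotation frequency of ``t`` over some counting basis;
* two Entity-Quality phenotype profiles ``P`` and ``R``, each carrying a
  class set ``Cl(.)`` of ontology terms, are compared by

      sim(P, R) = sum of I(x) over Cl(P) & Cl(R)
                  ---------------------------------
                  sum of I(y) over Cl(P) | Cl(R)

  which is 1 for identical class sets and 0 for disjoint ones.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
import math
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd

__all__ = [
    "OntologyError",
    "OntologyStructureError",
    "UnknownTermError",
    "UndefinedICError",
    "UndefinedSimilarityError",
    "OntologyTerm",
    "Ontology",
    "TermFrequencyTable",
    "PhenotypeProfile",
    "parse_obo",
    "term_level",
    "information_content",
    "semantic_similarity",
    "ancestors",
    "descendants",
]


class OntologyError(Exception):
    """Base class for ontology problems."""


class OntologyStructureError(OntologyError):
    """The term graph is not a rooted DAG (cycle or dangling parent)."""


class UnknownTermError(OntologyError, KeyError):
    """A term accession is not present in the ontology."""


class UndefinedICError(OntologyError):
    """Information content requested for a term with zero count."""


class UndefinedSimilarityError(OntologyError):
    """Every term in the profile union has IC 0 (frequency 1)."""


@dataclass(frozen=True)
class OntologyTerm:
    """One ontology term: accession, label, root category, parent links."""

    term_id: str
    name: str = ""
    parent_ids: frozenset[str] = frozenset()
    category: str | None = None


class Ontology:
    """A validated rooted DAG of :class:`OntologyTerm`.

    Construction checks the invariants once: parent references resolve,
    the parent graph is acyclic, and every non-root term reaches a root.
    Levels (1 = root) and the per-term root *category* are derived eagerly.

    Parameters
    ----------
    terms
        The term collection; ``parent_ids`` must refer to members.
    max_depth
        Optional cap on the deepest allowed level (the plant TO layout uses
        6; the supplementary level table allows 7). ``None`` disables the
        check for synthetic ontologies of arbitrary depth.
    """

    def __init__(self, terms: Iterable[OntologyTerm], max_depth: int | None = None):
        self._terms: dict[str, OntologyTerm] = {}
        for t in terms:
            if t.term_id in self._terms:
                raise OntologyStructureError(f"duplicate term id {t.term_id!r}")
            self._terms[t.term_id] = t

        for t in self._terms.values():
            for p in t.parent_ids:
                if p not in self._terms:
                    raise OntologyStructureError(
                        f"term {t.term_id!r} has dangling is_a target {p!r}"
                    )

        # parent graph: edge child -> parent
        g = nx.DiGraph()
        g.add_nodes_from(self._terms)
        for t in self._terms.values():
            for p in t.parent_ids:
                g.add_edge(t.term_id, p)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            member = cycle[0][0]
            raise OntologyStructureError(f"is_a cycle detected involving {member!r}")
        self._graph = g

        self.roots: frozenset[str] = frozenset(
            tid for tid, t in self._terms.items() if not t.parent_ids
        )
        if self._terms and not self.roots:
            raise OntologyStructureError("ontology has terms but no root")

        # level = 1 + shortest parent-path length to any root; BFS down from
        # the roots over the reversed (parent -> child) direction.
        self._levels: dict[str, int] = {r: 1 for r in self.roots}
        queue = deque(self.roots)
        children: dict[str, list[str]] = {tid: [] for tid in self._terms}
        for t in self._terms.values():
            for p in t.parent_ids:
                children[p].append(t.term_id)
        while queue:
            tid = queue.popleft()
            for c in children[tid]:
                if c not in self._levels:
                    self._levels[c] = self._levels[tid] + 1
                    queue.append(c)
        unreached = set(self._terms) - set(self._levels)
        if unreached:
            raise OntologyStructureError(
                f"{len(unreached)} terms cannot reach a root, e.g. {sorted(unreached)[0]!r}"
            )
        if max_depth is not None:
            deepest = max(self._levels.values(), default=1)
            if deepest > max_depth:
                raise OntologyStructureError(
                    f"ontology depth {deepest} exceeds max_depth={max_depth}"
                )

        # category: root trait group a term belongs to. With several
        # reachable roots the lexicographically smallest root wins
        # (deterministic; multi-rooted terms are rare in practice).
        self._categories: dict[str, str] = {}
        for tid in self._terms:
            reach = self._reachable_roots(tid)
            root = min(reach)
            self._categories[tid] = self._terms[root].name or root

    # -- container protocol -------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def __len__(self) -> int:
        return len(self._terms)

    def __iter__(self):
        return iter(self._terms.values())

    def __getitem__(self, term_id: str) -> OntologyTerm:
        try:
            return self._terms[term_id]
        except KeyError:
            raise UnknownTermError(term_id) from None

    @property
    def term_ids(self) -> frozenset[str]:
        return frozenset(self._terms)

    # -- derived structure --------------------------------------------------

    def _reachable_roots(self, term_id: str) -> set[str]:
        if term_id in self.roots:
            return {term_id}
        return {a for a in self.ancestors(term_id) if a in self.roots}

    def level(self, term_id: str) -> int:
        """Hierarchical level: roots are 1, children one below their
        *shallowest* parent (shortest path to a root)."""
        if term_id not in self._terms:
            raise UnknownTermError(term_id)
        return self._levels[term_id]

    @property
    def max_level(self) -> int:
        return max(self._levels.values(), default=0)

    def category(self, term_id: str) -> str:
        if term_id not in self._terms:
            raise UnknownTermError(term_id)
        return self._categories[term_id]

    def ancestors(self, term_id: str) -> frozenset[str]:
        """Transitive closure over parents, excluding the term itself."""
        if term_id not in self._terms:
            raise UnknownTermError(term_id)
        return frozenset(nx.descendants(self._graph, term_id))

    def descendants(self, term_id: str) -> frozenset[str]:
        """All terms below ``term_id`` (children, grandchildren, ...)."""
        if term_id not in self._terms:
            raise UnknownTermError(term_id)
        return frozenset(nx.ancestors(self._graph, term_id))

    def level_table(self) -> pd.DataFrame:
        """Wide level table: one row per term, one ``LevelK`` column per
        hierarchy layer; a term's id appears in the column of its level.

        Mirrors the supplementary "Level1~7" export layout.
        """
        depth = self.max_level
        rows = []
        for tid in sorted(self._terms):
            lv = self._levels[tid]
            row = {"term_id": tid, "name": self._terms[tid].name}
            for k in range(1, depth + 1):
                row[f"Level{k}"] = tid if k == lv else ""
            rows.append(row)
        return pd.DataFrame(rows)

    def write_level_table(self, path) -> None:
        self.level_table().to_csv(path, sep="\t", index=False)


def parse_obo(path, max_depth: int | None = None) -> Ontology:
    """Load an OBO flat file into an :class:`Ontology`.

    Only the subset used by trait/gene ontologies is honoured: ``[Term]``
    stanzas with ``id``, ``name`` and ``is_a``. Obsolete terms are dropped
    (obonet skips them), and non-``is_a`` relationships (``part_of`` etc.)
    are ignored — the hierarchy here is pure parent layering.

    Raises
    ------
    OntologyStructureError
        On an ``is_a`` cycle or a dangling ``is_a`` target.
    """
    graph = obonet.read_obo(str(path), ignore_obsolete=True)
    terms = []
    node_ids = set(graph.nodes)
    for tid, data in graph.nodes(data=True):
        parents = frozenset(
            v for _, v, key in graph.out_edges(tid, keys=True) if key == "is_a"
        )
        missing = parents - node_ids
        if missing:
            raise OntologyStructureError(
                f"term {tid!r} has dangling is_a target {sorted(missing)[0]!r}"
            )
        terms.append(OntologyTerm(term_id=tid, name=data.get("name", ""), parent_ids=parents))
    return Ontology(terms, max_depth=max_depth)


def term_level(ontology: Ontology, term_id: str) -> int:
    """Level of a term: 1 + length of the shortest parent path to any root."""
    return ontology.level(term_id)


def ancestors(ontology: Ontology, term_id: str) -> frozenset[str]:
    return ontology.ancestors(term_id)


def descendants(ontology: Ontology, term_id: str) -> frozenset[str]:
    return ontology.descendants(term_id)


class TermFrequencyTable:
    """Annotation counts per term, backing ``P(X = t)`` and ``I(t)``.

    The counting basis (phenotype descriptions, genes, name tokens, ...) is
    the caller's choice; the table only requires non-negative counts and a
    positive total. The ``total`` defaults to the sum of counts but may be
    supplied explicitly when counts are a subset of a larger universe.
    """

    def __init__(self, counts: Mapping[str, int], total: int | None = None):
        self._counts = {t: int(c) for t, c in counts.items()}
        if any(c < 0 for c in self._counts.values()):
            raise ValueError("term counts must be non-negative")
        self.total = int(total) if total is not None else sum(self._counts.values())
        if self.total <= 0:
            raise ValueError("total must be positive")
        if self._counts and self.total < max(self._counts.values()):
            raise ValueError("total smaller than a per-term count")

    def count(self, term_id: str) -> int:
        return self._counts.get(term_id, 0)

    def probability(self, term_id: str) -> float:
        """P(X = t) = count(t) / total."""
        return self.count(term_id) / self.total

    def information_content(self, term_id: str) -> float:
        """I(t) = -ln P(X = t), in nats; 0 iff P(X = t) = 1."""
        c = self.count(term_id)
        if c == 0:
            raise UndefinedICError(
                f"term {term_id!r} has zero count; IC undefined (smooth or exclude)"
            )
        return -math.log(c / self.total)

    @classmethod
    def from_annotations(cls, term_to_entities: Mapping[str, Iterable[str]]) -> "TermFrequencyTable":
        """Build counts from a term -> annotated-entity mapping."""
        return cls({t: len(set(es)) for t, es in term_to_entities.items()})


def information_content(freq: TermFrequencyTable, term_id: str) -> float:
    return freq.information_content(term_id)


@dataclass(frozen=True)
class PhenotypeProfile:
    """An Entity-Quality phenotype description.

    ``class_set`` is Cl(.), the non-empty set of ontology terms the entity
    descriptor resolves to; the remaining fields carry the EQ bookkeeping
    (organism/species on the entity side, value/character tags on the
    quality side) and play no role in the similarity score.
    """

    class_set: frozenset[str]
    organism: str = ""
    species: str = ""
    qualities: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.class_set:
            raise ValueError("PhenotypeProfile requires a non-empty class set")


def semantic_similarity(
    p: PhenotypeProfile | Iterable[str],
    r: PhenotypeProfile | Iterable[str],
    freq: TermFrequencyTable,
) -> float:
    """EQ-profile similarity: IC mass of the class-set intersection over the
    IC mass of the union.

    Accepts full profiles or bare class sets. Symmetric in its arguments;
    returns a value in [0, 1].

    Raises
    ------
    UndefinedSimilarityError
        If every union member has IC 0 (all frequencies equal 1), leaving a
        0/0 ratio.
    """
    cl_p = frozenset(p.class_set if isinstance(p, PhenotypeProfile) else p)
    cl_r = frozenset(r.class_set if isinstance(r, PhenotypeProfile) else r)
    if not cl_p or not cl_r:
        raise ValueError("both class sets must be non-empty")
    union = cl_p | cl_r
    denom = sum(freq.information_content(t) for t in union)
    if denom == 0.0:
        raise UndefinedSimilarityError(
            "all union terms have IC 0 (P = 1); similarity undefined"
        )
    num = sum(freq.information_content(t) for t in cl_p & cl_r)
    return num / denom
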