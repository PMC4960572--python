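"""Disease Ontology handling: OBO parsing and DAG queries.

The Disease Ontology (DO) is a single-rooted ``is_a`` DAG of human disease
terms.  Every similarity measure in this package is defined on that
structure, so this module exposes the DAG with the conventions the
measures expect:

* ancestor sets are **self-inclusive** (a term is its own ancestor), which
  makes ``sim(t, t)`` reduce correctly in all measures;
* only ``is_a`` edges are retained — DO's hierarchy carries no other
  relation of interest here;
* multi-rooted input is closed under a synthesized virtual root so that
  every pair of terms has at least one common ancestor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import obonet

from dsim.errors import DataIntegrityError, InputError

logger = logging.getLogger(__name__)

VIRTUAL_ROOT = "VIRTUAL:ROOT"


def _normalize_id(term_id: str) -> str:
    """Upper-case the CURIE prefix: ``doid:4`` -> ``DOID:4``."""
    prefix, _, local = term_id.strip().partition(":")
    if local:
        return f"{prefix.upper()}:{local}"
    return term_id.strip()


@dataclass(frozen=True)
class OntologyTerm:
    """A single ontology term with its direct ``is_a`` parents."""

    id: str
    name: str
    parents: frozenset[str] = field(default_factory=frozenset)
    obsolete: bool = False


class OntologyDAG:
    """Rooted ``is_a`` DAG over non-obsolete ontology terms.

    Parameters
    ----------
    terms
        Mapping term id -> :class:`OntologyTerm`.  Parent references must
        resolve within the mapping; a cycle or dangling parent raises
        :class:`~dsim.errors.DataIntegrityError`.
    alt_ids
        Optional mapping from alternate (merged) ids to canonical ids.
    """

    def __init__(
        self,
        terms: dict[str, OntologyTerm],
        alt_ids: dict[str, str] | None = None,
    ):
        self.terms: dict[str, OntologyTerm] = dict(terms)
        self.alt_ids: dict[str, str] = dict(alt_ids or {})
        self._g = nx.DiGraph()  # edges child -> parent
        self._g.add_nodes_from(self.terms)
        for t in self.terms.values():
            for p in t.parents:
                if p not in self.terms:
                    raise DataIntegrityError(
                        f"dangling is_a target(s): {t.id} -> {p}"
                    )
                self._g.add_edge(t.id, p)
        if not nx.is_directed_acyclic_graph(self._g):
            cycle = nx.find_cycle(self._g)
            raise DataIntegrityError(
                f"is_a cycle detected involving term {cycle[0][0]}"
            )

        roots = sorted(n for n in self._g if self._g.out_degree(n) == 0)
        if not roots:
            raise DataIntegrityError("ontology has no root term")
        if len(roots) == 1:
            self.root = roots[0]
        else:
            # Close a forest under one virtual root so common_ancestors
            # stays total; its IC is pinned to 0 downstream.
            self.root = VIRTUAL_ROOT
            self.terms[VIRTUAL_ROOT] = OntologyTerm(VIRTUAL_ROOT, "virtual root")
            self._g.add_node(VIRTUAL_ROOT)
            for r in roots:
                self._g.add_edge(r, VIRTUAL_ROOT)
                old = self.terms[r]
                self.terms[r] = OntologyTerm(
                    old.id, old.name, frozenset({VIRTUAL_ROOT}), old.obsolete
                )
        logger.info(
            "ontology DAG: %d terms, %d is_a edges, root %s",
            len(self.terms), self._g.number_of_edges(), self.root,
        )

    # -- structural queries -------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def resolve(self, term_id: str) -> str:
        """Normalize an id and map alt_ids to their canonical term."""
        tid = _normalize_id(term_id)
        tid = self.alt_ids.get(tid, tid)
        if tid not in self.terms:
            raise KeyError(f"unknown ontology term: {term_id!r}")
        return tid

    def _check(self, term_id: str) -> str:
        if term_id not in self.terms:
            raise KeyError(f"unknown ontology term: {term_id!r}")
        return term_id

    def parents(self, term_id: str) -> set[str]:
        return set(self._g.successors(self._check(term_id)))

    def children(self, term_id: str) -> set[str]:
        return set(self._g.predecessors(self._check(term_id)))

    @lru_cache(maxsize=None)
    def ancestors(self, term_id: str) -> frozenset[str]:
        """Self-inclusive transitive ``is_a`` closure of a term."""
        self._check(term_id)
        return frozenset(nx.descendants(self._g, term_id)) | {term_id}

    @lru_cache(maxsize=None)
    def descendants(self, term_id: str) -> frozenset[str]:
        """Self-inclusive set of terms at or below a term."""
        self._check(term_id)
        return frozenset(nx.ancestors(self._g, term_id)) | {term_id}

    def common_ancestors(self, t1: str, t2: str) -> frozenset[str]:
        """``ancestors(t1) & ancestors(t2)``; never empty in a rooted DAG."""
        return self.ancestors(t1) & self.ancestors(t2)

    def topological_order(self) -> list[str]:
        """Terms ordered leaves-first (every child before its parents)."""
        return list(nx.topological_sort(self._g))


def load_obo(path) -> OntologyDAG:
    """Parse an OBO 1.2/1.4 file into an :class:`OntologyDAG`.

    Only ``[Term]`` stanzas and ``is_a`` edges are used; obsolete terms are
    excluded; term ids and ``alt_id`` lines are normalized to an upper-case
    prefix, with alternate ids mapped onto their canonical term.
    """
    try:
        graph = obonet.read_obo(path, ignore_obsolete=True)
    except FileNotFoundError as exc:
        raise InputError(f"ontology file not found: {path}") from exc

    terms: dict[str, OntologyTerm] = {}
    alt_ids: dict[str, str] = {}
    dangling: set[str] = set()
    for node, data in graph.nodes(data=True):
        nid = _normalize_id(node)
        if "name" not in data:
            # obonet materializes is_a targets that have no stanza
            dangling.add(nid)
            continue
        parents = frozenset(
            _normalize_id(v)
            for _, v, key in graph.out_edges(node, keys=True)
            if key == "is_a"
        )
        terms[nid] = OntologyTerm(nid, data["name"], parents)
        for alt in data.get("alt_id", []):
            alt_ids[_normalize_id(alt)] = nid
    referenced = {p for t in terms.values() for p in t.parents}
    dangling &= referenced
    dangling |= referenced - set(terms)
    if dangling:
        raise DataIntegrityError(
            "dangling is_a target(s): " + ", ".join(sorted(dangling))
        )
    if not terms:
        raise InputError(f"no usable [Term] stanzas in {path}")
    return OntologyDAG(terms, alt_ids)
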