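"""Semantic similarity between Disease Ontology terms.

Three classical term-level measures:

* **Resnik** — the information content of the most informative common
  ancestor (MICA): ``max_{a in CA(t1,t2)} IC(a)``.  Unbounded above;
  reported raw, with optional display normalization by the corpus
  maximum IC.
* **Lin** — Resnik rescaled by the terms' own IC:
  ``2 IC(MICA) / (IC(t1) + IC(t2))``, in [0, 1].
* **Wang** — purely structural.  Each ancestor ``a`` of a term ``t``
  contributes an S-value: 1 for ``t`` itself, and otherwise the best
  child S-value within ``t``'s ancestor subgraph decayed by the per-hop
  ``is_a`` factor ``w``.  Similarity aggregates the S-values of shared
  ancestors against both terms' S-value totals, giving a score in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

from dsim.annotations import ICTable
from dsim.ontology_do import OntologyDAG


@dataclass(frozen=True)
class WangParams:
    """Semantic-contribution decay for one ``is_a`` hop (0 < w_isa < 1)."""

    w_isa: float = 0.8

    def __post_init__(self):
        if not 0.0 < self.w_isa < 1.0:
            raise ValueError(f"w_isa must lie in (0, 1), got {self.w_isa}")


@dataclass(frozen=True)
class SValueMap:
    """S-values of one term's ancestors; s[anchor] == 1."""

    anchor: str
    s: dict[str, float]

    def total(self) -> float:
        return sum(self.s.values())


def _require_ic(term: str, ic_table: ICTable) -> float:
    if term not in ic_table:
        raise KeyError(f"term {term!r} is absent from the IC table")
    return ic_table[term]


def mica(t1: str, t2: str, dag: OntologyDAG, ic_table: ICTable) -> tuple[str, float]:
    """Most informative common ancestor and its IC.

    Ties on IC are broken toward the lexicographically smallest term id
    so the reported MICA is deterministic; the IC value itself is
    tie-independent.
    """
    _require_ic(t1, ic_table)
    _require_ic(t2, ic_table)
    candidates = [
        (a, ic_table[a]) for a in dag.common_ancestors(t1, t2) if a in ic_table
    ]
    best_ic = max(ic for _, ic in candidates)
    best_term = min(a for a, ic in candidates if ic == best_ic)
    return best_term, best_ic


def resnik(
    t1: str,
    t2: str,
    dag: OntologyDAG,
    ic_table: ICTable,
    normalize: bool = False,
) -> float:
    """IC of the MICA; with ``normalize`` divided by the corpus max IC.

    Normalization is a display aid for cross-method comparison only.
    """
    _, value = mica(t1, t2, dag, ic_table)
    if normalize and ic_table.max_ic > 0:
        return value / ic_table.max_ic
    return value


def lin(t1: str, t2: str, dag: OntologyDAG, ic_table: ICTable) -> float:
    """``2 IC(MICA) / (IC(t1) + IC(t2))``; 0 when both terms sit at the root."""
    ic1 = _require_ic(t1, ic_table)
    ic2 = _require_ic(t2, ic_table)
    if ic1 + ic2 == 0.0:
        return 0.0
    _, shared = mica(t1, t2, dag, ic_table)
    return 2.0 * shared / (ic1 + ic2)


def wang_svalues(
    t: str, dag: OntologyDAG, params: WangParams = WangParams()
) -> SValueMap:
    """Wang S-values of every ancestor of ``t``.

    ``s[t] = 1``; for a proper ancestor ``a``,
    ``s[a] = max over children c of a inside t's ancestor set of w * s[c]``,
    evaluated leaves-first so each child is finished before its parents.
    """
    ancestors = dag.ancestors(t)
    s: dict[str, float] = {t: 1.0}
    w = params.w_isa
    for term in dag.topological_order():
        if term not in ancestors or term == t:
            continue
        s[term] = max(
            w * s[c] for c in dag.children(term) if c in ancestors
        )
    return SValueMap(anchor=t, s=s)


def wang(
    t1: str,
    t2: str,
    dag: OntologyDAG,
    params: WangParams = WangParams(),
) -> float:
    """Wang similarity: shared S-value mass over both S-value totals."""
    sv1 = wang_svalues(t1, dag, params)
    sv2 = wang_svalues(t2, dag, params)
    shared = set(sv1.s) & set(sv2.s)
    numerator = sum(sv1.s[a] + sv2.s[a] for a in shared)
    return numerator / (sv1.total() + sv2.total())
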