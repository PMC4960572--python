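"""Annotation loading, true-path propagation and information content.

Three annotation channels feed the similarity measures:

* disease -> gene associations (TSV), propagated up the DO DAG under the
  true-path rule (an annotation to a term implicitly annotates all its
  ancestors);
* gene -> GO biological-process annotations (GAF 2.x or two-column TSV);
* a weighted gene functional network (HumanNet-style three-column TSV of
  log-likelihood scores).

The information-content table is derived from the disease corpus: the
annotation probability of a term is the fraction of annotated *diseases*
found at or below it, and IC is its negative natural log.  Rarer terms are
therefore more informative, the root carries IC 0, and IC never decreases
along a path away from the root.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd
from Bio.UniProt import GOA

from dsim.errors import InputError
from dsim.ontology_do import OntologyDAG

logger = logging.getLogger(__name__)


@dataclass
class AnnotationCorpus:
    """Disease -> gene sets, direct and true-path propagated."""

    direct: dict[str, set[str]]
    propagated: dict[str, set[str]]
    n_skipped_unknown: int = 0

    @property
    def n_diseases_annotated(self) -> int:
        return sum(1 for genes in self.direct.values() if genes)

    def genes(self, doid: str) -> set[str]:
        """Propagated gene set of a term (empty if unannotated)."""
        return self.propagated.get(doid, set())


@dataclass
class ICTable:
    """Per-term information content in natural-log units.

    ``p[t]`` is the annotation probability of term ``t`` (fraction of
    annotated diseases at or below it); terms with ``p == 0`` are absent
    from both maps and are thereby excluded from MICA candidacy.
    """

    ic: dict[str, float]
    p: dict[str, float]
    n_diseases: int = 0
    log_base: str = "e"

    def __contains__(self, term: str) -> bool:
        return term in self.ic

    def __getitem__(self, term: str) -> float:
        try:
            return self.ic[term]
        except KeyError:
            raise KeyError(
                f"term {term!r} has no information content "
                "(no annotated disease at or below it)"
            ) from None

    @property
    def max_ic(self) -> float:
        return max(self.ic.values(), default=0.0)


@dataclass
class GeneNetwork:
    """Symmetric weighted gene-pair store (raw LLS scores)."""

    edges: dict[frozenset[str], float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.edges)

    def score(self, g1: str, g2: str) -> float | None:
        """Raw score of the pair, or None if absent (self-pairs excluded)."""
        return self.edges.get(frozenset((g1, g2)))

    @property
    def min_score(self) -> float:
        return min(self.edges.values())

    @property
    def max_score(self) -> float:
        return max(self.edges.values())


@dataclass
class GeneBPAnnotation:
    """Gene -> set of GO biological-process term ids."""

    bp: dict[str, set[str]] = field(default_factory=dict)

    def terms(self, gene: str) -> set[str]:
        return self.bp.get(gene, set())


def load_disease_genes(
    path, dag: OntologyDAG, strict: bool = False
) -> AnnotationCorpus:
    """Load a two-column (DOID, gene) TSV and propagate up the DAG.

    Rows naming DOIDs absent from the ontology are skipped and counted
    (``strict=True`` promotes them to :class:`~dsim.errors.InputError`).
    Duplicate rows are harmless: gene sets have set semantics.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, dtype=str,
            names=["doid", "gene"], usecols=[0, 1],
        )
    except FileNotFoundError as exc:
        raise InputError(f"disease-gene file not found: {path}") from exc
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"disease-gene file is empty: {path}") from exc
    df = df.dropna()
    if df.empty:
        raise InputError(f"disease-gene file has no usable rows: {path}")

    direct: dict[str, set[str]] = {}
    skipped = 0
    for doid, gene in df.itertuples(index=False):
        try:
            tid = dag.resolve(doid)
        except KeyError:
            if strict:
                raise InputError(f"unknown DOID in disease-gene file: {doid!r}")
            skipped += 1
            continue
        direct.setdefault(tid, set()).add(gene.strip())
    if skipped:
        logger.warning("skipped %d disease-gene rows with unknown DOIDs", skipped)

    # True-path propagation, leaves-first so each term unions its children.
    propagated: dict[str, set[str]] = {}
    for term in dag.topological_order():
        genes = set(direct.get(term, ()))
        for child in dag.children(term):
            genes |= propagated[child]
        propagated[term] = genes
    return AnnotationCorpus(direct, propagated, n_skipped_unknown=skipped)


def compute_ic(corpus: AnnotationCorpus, dag: OntologyDAG) -> ICTable:
    """Derive the information-content table from a propagated corpus.

    p(t) = |annotated diseases at-or-below t| / |annotated diseases|,
    ic(t) = -ln p(t).  The root (virtual or real) always has IC 0.
    """
    annotated = {d for d, genes in corpus.direct.items() if genes}
    n = len(annotated)
    if n == 0:
        raise InputError("empty corpus: no disease has an annotated gene")

    # exact counts need the descendant-set intersection, not a sum over
    # children, because closures overlap under multiple parents
    counts = {
        term: len(annotated & dag.descendants(term))
        for term in dag.terms
    }
    ic: dict[str, float] = {}
    p: dict[str, float] = {}
    for term, k in counts.items():
        if k == 0:
            continue
        p[term] = k / n
        ic[term] = -math.log(k / n)
    ic[dag.root] = 0.0
    p[dag.root] = 1.0
    return ICTable(ic=ic, p=p, n_diseases=n)


def load_gene_network(path) -> GeneNetwork:
    """Load a three-column (geneA, geneB, score) TSV into a symmetric store.

    Self-edges are dropped; duplicate/reversed pairs keep the maximal
    score; non-numeric scores skip the row with a warning.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, dtype=str,
            names=["a", "b", "score"], usecols=[0, 1, 2],
        )
    except FileNotFoundError as exc:
        raise InputError(f"gene network file not found: {path}") from exc
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"gene network file is empty: {path}") from exc

    net = GeneNetwork()
    bad = 0
    for a, b, raw in df.dropna().itertuples(index=False):
        try:
            score = float(raw)
        except ValueError:
            bad += 1
            continue
        if not math.isfinite(score) or a == b:
            bad += 1
            continue
        key = frozenset((a.strip(), b.strip()))
        prev = net.edges.get(key)
        net.edges[key] = score if prev is None else max(prev, score)
    if bad:
        logger.warning("skipped %d malformed gene-network rows", bad)
    if not net.edges:
        raise InputError(f"gene network file has no usable rows: {path}")
    return net


def _looks_like_gaf(path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.startswith("!"):
                return True
            return len(line.rstrip("\n").split("\t")) >= 15
    return False


def load_gene_bp(path) -> GeneBPAnnotation:
    """Load gene -> GO-BP annotations from GAF 2.x or a two-column TSV.

    GAF rows with a NOT qualifier or an aspect other than P (biological
    process) are dropped.  The gene key is the DB object symbol when
    present, else the DB object id.
    """
    annot = GeneBPAnnotation()
    try:
        is_gaf = _looks_like_gaf(path)
    except FileNotFoundError as exc:
        raise InputError(f"gene annotation file not found: {path}") from exc

    if is_gaf:
        with open(path) as fh:
            for rec in GOA.gafiterator(fh):
                if rec["Aspect"] != "P":
                    continue
                if any("NOT" in q for q in rec["Qualifier"]):
                    continue
                gene = rec["DB_Object_Symbol"] or rec["DB_Object_ID"]
                annot.bp.setdefault(gene, set()).add(rec["GO_ID"])
    else:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, dtype=str,
            names=["gene", "go"], usecols=[0, 1],
        ).dropna()
        for gene, go in df.itertuples(index=False):
            go = go.strip()
            if not go.upper().startswith("GO:"):
                logger.warning("skipping non-GO annotation %r for %r", go, gene)
                continue
            annot.bp.setdefault(gene.strip(), set()).add(go)
    return annot
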