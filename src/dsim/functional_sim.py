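"""Gene-function-based disease similarity: PSB and SemFunSim.

Both measures compare the gene complements of two diseases rather than
their positions in the DO hierarchy, using the **propagated** gene sets
(annotations inherited from descendant disease terms).

* **SemFunSim** scores the two gene sets with a best-match average (BMA)
  over a pairwise gene functional similarity derived from a weighted
  gene network: identical genes score 1, connected genes score their
  min-max-normalized log-likelihood score, unconnected genes 0.
* **PSB** compares the biological-process profiles the two gene sets
  induce: the union of GO-BP terms annotated to each disease's genes,
  scored by a weighted Jaccard index.  Weights are 1 by default, or
  IDF-style (``-ln`` of the fraction of diseases whose profile contains
  the term) to damp ubiquitous processes.

Diseases lacking the required inputs for a measure yield ``None`` (a null
result cell), never a zero: absence of evidence is not evidence of
dissimilarity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from dsim.annotations import AnnotationCorpus, GeneBPAnnotation, GeneNetwork

logger = logging.getLogger(__name__)


def gene_funsim(g1: str, g2: str, network: GeneNetwork) -> float:
    """Pairwise gene functional similarity in [0, 1].

    1 for identical genes; the min-max-normalized network score for a
    stored pair; 0 for a pair absent from the network.  A degenerate
    network (all scores equal) maps every stored edge to 1.
    """
    if g1 == g2:
        return 1.0
    raw = network.score(g1, g2)
    if raw is None:
        return 0.0
    lo, hi = network.min_score, network.max_score
    if hi == lo:
        logger.warning("degenerate gene network (max == min): edges map to 1")
        return 1.0
    return (raw - lo) / (hi - lo)


def bma_setsim(G1, G2, pair_sim) -> float | None:
    """Best-match average of two gene sets under a pairwise measure.

    ``(sum_g max_h sim(g,h) + sum_h max_g sim(g,h)) / (|G1| + |G2|)``.
    Symmetric; returns None (undefined) when either set is empty.
    """
    G1, G2 = list(G1), list(G2)
    if not G1 or not G2:
        return None
    forward = sum(max(pair_sim(g, h) for h in G2) for g in G1)
    backward = sum(max(pair_sim(g, h) for g in G1) for h in G2)
    return (forward + backward) / (len(G1) + len(G2))


def semfunsim(
    d1: str, d2: str, corpus: AnnotationCorpus, network: GeneNetwork
) -> float | None:
    """BMA over the two diseases' propagated gene sets."""
    return bma_setsim(
        corpus.genes(d1),
        corpus.genes(d2),
        lambda a, b: gene_funsim(a, b, network),
    )


@dataclass
class DiseaseBPProfile:
    """Weighted GO-BP term profile induced by a disease's genes."""

    disease: str
    weights: dict[str, float] = field(default_factory=dict)

    @property
    def bp_terms(self) -> set[str]:
        return set(self.weights)


def disease_bp_profile(
    d: str,
    corpus: AnnotationCorpus,
    bp_annot: GeneBPAnnotation,
    term_weights: dict[str, float] | None = None,
) -> DiseaseBPProfile:
    """Union of BP terms over the disease's propagated genes.

    Each term weighs 1 unless ``term_weights`` supplies a value (IDF mode).
    """
    terms: set[str] = set()
    for gene in corpus.genes(d):
        terms |= bp_annot.terms(gene)
    if term_weights is None:
        weights = {t: 1.0 for t in terms}
    else:
        weights = {t: term_weights.get(t, 1.0) for t in terms}
    return DiseaseBPProfile(disease=d, weights=weights)


def weighted_jaccard(p1: DiseaseBPProfile, p2: DiseaseBPProfile) -> float | None:
    """Weighted Jaccard of two profiles; None when either is empty."""
    if not p1.weights or not p2.weights:
        return None
    union = set(p1.weights) | set(p2.weights)
    inter = set(p1.weights) & set(p2.weights)
    w = {**p2.weights, **p1.weights}
    denom = sum(w[t] for t in union)
    if denom == 0.0:
        # all shared mass weighted away (every term ubiquitous under IDF)
        return 1.0 if set(p1.weights) == set(p2.weights) else 0.0
    return sum(w[t] for t in inter) / denom


def psb(
    d1: str,
    d2: str,
    corpus: AnnotationCorpus,
    bp_annot: GeneBPAnnotation,
    term_weights: dict[str, float] | None = None,
) -> float | None:
    """Weighted Jaccard of the two diseases' BP profiles."""
    p1 = disease_bp_profile(d1, corpus, bp_annot, term_weights)
    p2 = disease_bp_profile(d2, corpus, bp_annot, term_weights)
    return weighted_jaccard(p1, p2)


class SemFunSimScorer:
    """Callable ``(d1, d2) -> score`` closing over corpus and network."""

    def __init__(self, corpus: AnnotationCorpus, network: GeneNetwork):
        self.corpus = corpus
        self.network = network

    def __call__(self, d1: str, d2: str) -> float | None:
        return semfunsim(d1, d2, self.corpus, self.network)


class PSBScorer:
    """Callable ``(d1, d2) -> score`` with precomputed profiles.

    ``weight="unit"`` scores a plain Jaccard; ``weight="idf"`` weighs each
    BP term by ``-ln`` of its document frequency across the diseases'
    profiles, computed once over ``diseases`` at construction.
    """

    def __init__(
        self,
        corpus: AnnotationCorpus,
        bp_annot: GeneBPAnnotation,
        diseases,
        weight: str = "unit",
    ):
        if weight not in ("unit", "idf"):
            raise ValueError(f"unknown PSB weight mode {weight!r}")
        self.weight = weight
        raw = {
            d: disease_bp_profile(d, corpus, bp_annot) for d in diseases
        }
        term_weights: dict[str, float] | None = None
        if weight == "idf":
            nonempty = [p for p in raw.values() if p.weights]
            n = len(nonempty)
            df: dict[str, int] = {}
            for p in nonempty:
                for t in p.weights:
                    df[t] = df.get(t, 0) + 1
            term_weights = {t: -math.log(k / n) for t, k in df.items()}
        self._term_weights = term_weights
        self._profiles = {
            d: disease_bp_profile(d, corpus, bp_annot, term_weights)
            for d in diseases
        }
        self.corpus = corpus
        self.bp_annot = bp_annot

    def profile(self, d: str) -> DiseaseBPProfile:
        if d not in self._profiles:
            self._profiles[d] = disease_bp_profile(
                d, self.corpus, self.bp_annot, self._term_weights
            )
        return self._profiles[d]

    def __call__(self, d1: str, d2: str) -> float | None:
        return weighted_jaccard(self.profile(d1), self.profile(d2))
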