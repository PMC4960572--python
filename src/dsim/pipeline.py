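"""End-to-end orchestration: load inputs, score all pairs, attach significance.

The unit of work is a :class:`DataBundle` (ontology + annotation channels
+ TC store) and a :class:`RunResult` (long record table with z/p/q, the
per-method background statistics, and run metadata).  The CLI is a thin
wrapper over these two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from dsim.annotations import (
    AnnotationCorpus,
    GeneBPAnnotation,
    GeneNetwork,
    ICTable,
    compute_ic,
    load_disease_genes,
    load_gene_bp,
    load_gene_network,
)
from dsim.errors import InputError
from dsim.functional_sim import PSBScorer, SemFunSimScorer
from dsim.ontology_do import OntologyDAG, load_obo
from dsim.semantic_sim import WangParams, lin, resnik, wang
from dsim.significance import BackgroundStats, attach_significance
from dsim.therapeutics import Chemical, load_tcs

ALL_METHODS = ("resnik", "lin", "wang", "psb", "semfunsim")


@dataclass
class DataBundle:
    """All loaded inputs of one analysis run."""

    dag: OntologyDAG
    corpus: AnnotationCorpus
    ic: ICTable
    network: GeneNetwork | None = None
    bp: GeneBPAnnotation | None = None
    tc_map: dict[str, set[Chemical]] = field(default_factory=dict)

    @classmethod
    def load(
        cls,
        obo,
        disease_genes,
        gene_net=None,
        gaf=None,
        chemicals=None,
        strict: bool = False,
    ) -> "DataBundle":
        dag = load_obo(obo)
        corpus = load_disease_genes(disease_genes, dag, strict=strict)
        ic = compute_ic(corpus, dag)
        network = load_gene_network(gene_net) if gene_net else None
        bp = load_gene_bp(gaf) if gaf else None
        tc_map = load_tcs(chemicals) if chemicals else {}
        return cls(dag=dag, corpus=corpus, ic=ic, network=network, bp=bp,
                   tc_map=tc_map)

    def diseases(self) -> list[str]:
        """Diseases of the run: terms with at least one direct gene."""
        return sorted(d for d, genes in self.corpus.direct.items() if genes)


def make_scorers(
    bundle: DataBundle,
    methods=ALL_METHODS,
    wang_w: float = 0.8,
    psb_weight: str = "unit",
    normalize_resnik: bool = False,
):
    """Per-method callables ``(d1, d2) -> score-or-None``."""
    unknown = [m for m in methods if m not in ALL_METHODS]
    if unknown:
        raise InputError(f"unknown method(s): {', '.join(unknown)}")
    params = WangParams(w_isa=wang_w)
    scorers = {}
    for m in methods:
        if m == "resnik":
            scorers[m] = lambda a, b: resnik(
                a, b, bundle.dag, bundle.ic, normalize=normalize_resnik
            )
        elif m == "lin":
            scorers[m] = lambda a, b: lin(a, b, bundle.dag, bundle.ic)
        elif m == "wang":
            scorers[m] = lambda a, b: wang(a, b, bundle.dag, params)
        elif m == "psb":
            if bundle.bp is None:
                raise InputError("PSB requires gene GO-BP annotations (--gaf)")
            scorers[m] = PSBScorer(
                bundle.corpus, bundle.bp, bundle.diseases(), weight=psb_weight
            )
        elif m == "semfunsim":
            if bundle.network is None:
                raise InputError(
                    "SemFunSim requires a gene functional network (--gene-net)"
                )
            scorers[m] = SemFunSimScorer(bundle.corpus, bundle.network)
    return scorers


def score_all_pairs(
    bundle: DataBundle,
    methods=ALL_METHODS,
    diseases=None,
    wang_w: float = 0.8,
    psb_weight: str = "unit",
    normalize_resnik: bool = False,
) -> pd.DataFrame:
    """Long (d1, d2, method, score) table over all unordered disease pairs.

    Pair order is canonical (d1 < d2).  A method that is undefined for a
    pair (missing gene set or profile) yields a null score.
    """
    if diseases is None:
        diseases = bundle.diseases()
    scorers = make_scorers(bundle, methods, wang_w=wang_w,
                           psb_weight=psb_weight,
                           normalize_resnik=normalize_resnik)
    rows = []
    for d1, d2 in combinations(sorted(diseases), 2):
        for m in methods:
            score = scorers[m](d1, d2)
            rows.append((d1, d2, m, score))
    return pd.DataFrame(rows, columns=["d1", "d2", "method", "score"])


@dataclass
class RunResult:
    """Scored, significance-annotated output of one run."""

    records: pd.DataFrame  # long: d1, d2, method, score, z, p, q
    backgrounds: dict[str, BackgroundStats]
    metadata: dict

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        """Long records with q < alpha."""
        return self.records[self.records["q"] < alpha].reset_index(drop=True)


def run(
    bundle: DataBundle,
    methods=ALL_METHODS,
    diseases=None,
    wang_w: float = 0.8,
    psb_weight: str = "unit",
    normalize_resnik: bool = False,
) -> RunResult:
    """Score all pairs and attach the empirical significance layer."""
    scores = score_all_pairs(
        bundle, methods, diseases=diseases, wang_w=wang_w,
        psb_weight=psb_weight, normalize_resnik=normalize_resnik,
    )
    records, backgrounds = attach_significance(scores)
    metadata = {
        "methods": list(methods),
        "n_diseases": len(diseases) if diseases is not None
        else len(bundle.diseases()),
        "ic_log_base": bundle.ic.log_base,
        "ic_corpus_unit": "disease",
        "ic_n_diseases": bundle.ic.n_diseases,
        "wang_w_isa": wang_w,
        "psb_weight": psb_weight,
        "resnik_normalized": normalize_resnik,
        "network_score_bounds": (
            [bundle.network.min_score, bundle.network.max_score]
            if bundle.network is not None and len(bundle.network) else None
        ),
        "backgrounds": {
            m: {"mean": s.mean, "sd": s.sd, "n_pairs": s.n_pairs}
            for m, s in backgrounds.items()
        },
    }
    return RunResult(records=records, backgrounds=backgrounds,
                     metadata=metadata)
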